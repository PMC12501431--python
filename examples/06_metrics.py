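"""Balanced accuracy and information transfer rate, by the numbers.

ITR(N, P, T) = (60/T) [log2 N + P log2 P + (1-P) log2((1-P)/(N-1))]
rewards many targets, high accuracy and short selections; it is zero at
chance accuracy and caps at (60/T) log2 N for a perfect decoder.
"""

import numpy as np

from ssvepkit import balanced_accuracy, itr

print("N=40 targets, T=1 s selections:")
for p in (1 / 40, 0.5, 0.9, 1.0):
    print(f"  P = {p:5.3f}  ->  ITR = {itr(40, p, 1.0):7.2f} bits/min")

conf = np.array([[5, 1], [0, 6]])
print(f"\nconfusion {conf.tolist()} -> balanced accuracy "
      f"{balanced_accuracy(conf):.3f}")
print("(mean of per-class recalls 5/6 and 6/6 - immune to class imbalance)")
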