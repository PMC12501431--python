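"""Compress the trained decoder by knowledge distillation.

Trains a teacher with BGMix on the sparse condition, then a student with a
single encoder layer at half the embedding width, supervised by ground
truth (weight 0.7) plus the teacher's temperature-5 softened outputs
(weight 0.3).
"""

from ssvepkit.experiments import distillation_demo

res = distillation_demo(seed=0)
print(f"teacher: {res['teacher_params']:6d} parameters, "
      f"held-out BA {100 * res['teacher_ba']:5.1f} %")
print(f"student: {res['student_params']:6d} parameters "
      f"({100 * res['student_params'] / res['teacher_params']:.0f} % of teacher), "
      f"held-out BA {100 * res['student_ba']:5.1f} %")

# The student trades a modest accuracy drop for roughly a third of the
# weights - the softened teacher outputs carry inter-class similarity
# information that hard labels alone do not.
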