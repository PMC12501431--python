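# Methods

## Signal model and preprocessing

An epoched trial is `X ∈ R^{N_c × N_s}` at sampling rate `fs`, with an
integer class label per trial.  Band-pass filtering uses a Chebyshev
type-I design (order 4, 0.5 dB passband ripple) applied forward–backward
(`sosfiltfilt`), so templates keep zero group delay at the cost of
squaring the magnitude response; both the type/order and the zero-phase
flag are configurable in `FilterSpec` because neither is pinned down by
common practice alone.  Window cropping uses the floor convention
`N_s = ⌊t_len · fs⌋` on half-open, 0-based sample windows (0.2 s at
256 Hz → 51 samples).  Whether filtering precedes or follows cropping is
the caller's choice; the pipeline filters first so filter transients fall
outside short windows.

Readers normalise MATLAB arrays (declarative axis layout, v7 via
scipy.io, v7.3 via HDF5 with MATLAB's reversed axis order), EDF
(annotations with integer descriptions become epochs), and an internal
HDF5 container (`/data`, `/labels`, attributes `fs`, `channel_names`).
Labels are always 0-based internally; readers translate.  No per-trial
normalisation is applied by default.

## Cross-validation

Trial-level K-fold: the number of folds equals the smallest per-class
trial count; per fold each class contributes exactly one test trial and
one validation trial (shuffled once per class under the seed, then rotated
across folds), the remainder training.  With 3 trials per class this
degenerates to 1 train / 1 val / 1 test per class.

## Background-EEG mixing

Trials of a class share a stimulus-locked task component; the residual
after subtracting the class template is treated as task-unrelated
background.  Per draw, `n` target-class trials form the template and `n`
donor-class trials form the donor template and residuals, yielding `n`
generated samples (the operational subset convention; a `template_scope =
"all"` switch uses full class averages instead).  Choices that the source
material leaves open, resolved here:

- **Donor class**: uniform over classes other than the target.
- **λ distribution**: `Beta(1, 1)` by default; λ is drawn per generated
  sample and used only in the loss, never in the waveform.
- **Loss pairing**: the `(1 − λ)` term applies to the *mirror* sample of
  the swap (donor template + target background) against the donor label,
  so every waveform is supervised by the label whose task component it
  carries.  Weighting the donor label against the *same* waveform instead
  would place, in expectation, `E[1 − λ]` of the supervision on a class
  the signal does not contain; at desk scale that variant demonstrably
  cancels the augmentation benefit, and it is not what the loss equation
  with the mirror term prescribes.
- **Exact factors**: each original trial receives exactly `factor`
  generated samples per pass (the last draw of a pass is truncated), so
  the published 80×/120× schedules hold exactly and per-class counts stay
  balanced.

Second-moment bookkeeping under the subset convention (white-noise
backgrounds of variance σ²): a donor residual carries `σ²(1 − 1/n)`, the
target template `σ²/n`, so a generated sample's background power is σ² —
identical to a real trial's.  The property test asserts exactly this
algebra against a Monte-Carlo oracle.

Mixup is included as a comparator: `x̃ = λ x_i + (1 − λ) x_j` blends the
waveforms themselves, and both loss terms legitimately score the same
blended sample.

## The Transformer decoder

Front end: a per-time-point affine map across channels with tanh
(`N_sp = 2 N_c` spatial filters), then a 'same'-padded time convolution
with `N_fr = 8` kernels of length `⌊fs/2⌋` (resolves ≥ 2 Hz), ELU, and
batch normalisation per feature map over batch, space and time.  The
`(N_fr, N_sp, N_s)` stack is read as `N_s` tokens of width
`d_model = N_fr · N_sp` — time points as tokens, matching attention maps
of size `N_s × N_s` — plus the standard base-10000 sinusoidal positional
code.  Encoder layers use multihead self-attention (`N_fr` heads,
`d_k = d_model / heads`), a position-wise feed-forward with leaky-ReLU
(slope 0.01), residual connections and post-layer-norm.  The head is a
linear map on the flattened sequence.

Unstated widths fixed here: `ff_dim = 2 · d_model` (a 4× feed-forward
would dwarf the published parameter budgets), dropout 0.1 inside encoder
layers, batch-norm momentum 0.1 with running statistics in evaluation.
For windows shorter than `⌊fs/2⌋` samples the kernel is clipped to the
window with a warning.  The distillation student keeps the front end,
halves `d_model` by halving `N_sp`, uses one encoder layer, and reduces
the head count to the largest divisor when needed.

The network and its reverse-mode gradients are implemented directly on
NumPy in float64; backprop is verified against central finite differences
to ~1e-9 relative error, comfortably inside the 1e-4 contract.

## Classical decoders

TRCA: with per-trial mean-removed covariances (1/N_s normalisation), `S`
sums cross-covariances over ordered trial pairs `h1 ≠ h2` and `Q` pools
within-trial covariances; the filter is the leading generalized
eigenvector of `(S, Q)`, unit-norm, sign fixed so the largest-magnitude
entry is positive.  Sums-versus-means normalisation cancels in the
Rayleigh quotient (property-tested, not assumed).  Singular `Q` (or `S_w`
below) receives a ridge of `1e-8 · trace/dim`.

eTRCA stacks the per-class filters into `W ∈ R^{N_c × N_f}` and scores a
trial per sub-band by `corr(vec(WᵀX), vec(WᵀX̄_k))`, combining sub-bands
(`m·8–90 Hz`, 3 by default where the sampling rate allows) with the
standard weights `a(m) = m^{−1.25} + 0.25` (uniform optional).  The
correlation-to-template decision rule follows the original decoder
literature since the source text leaves it implicit; ties break to the
lowest class index, and a zero-variance projection contributes 0.

TDCA: delay embedding stacks `l` left-shifted copies (zero-padded — or
using real trailing samples when the trial carries them), the reference
projector is `P_i = QQᵀ` from the QR decomposition of the `2N_h`
sine/cosine harmonics sampled at `t = 1/fs … N_s/fs`, and the secondary
augmentation is `X_a = [X̃, X̃P_i]`.  Fisher scatters assemble from class
centers (`S_b`) and within-class deviations (`S_w`); `W` keeps the top
`K_dims = 8` generalized eigenvectors (scale factors on the scatter
matrices are immaterial for the eigenvectors).  The filter bank applies to
TDCA as in its original formulation, switchable off.  Defaults `l = 5`,
`N_h = 5`.

## Training protocol

Stage 1 trains one inter-subject model on data pooled from all subjects
(no augmentation); stage 2 clones its weights per subject and fine-tunes.
BGMix runs only in stage 2: the training set becomes the generated samples
built from the subject's original train+validation trials, and the
validation set becomes those original trials concatenated.  Adam with
weight decay 1e-2, learning rate 1e-3, batch 64, up to 500 epochs,
patience 20 — all configurable, none prescribed by the source material.
Early stopping halts once the running validation-loss minimum has gone
`patience` consecutive epochs without improving; the best-validation
checkpoint is restored.  Distillation loss:
`0.7 · CE(student, hard) + 0.3 · T² · KL(softmax(teacher/T) ‖
softmax(student/T))` with `T = 5`.  Determinism is promised per device
only.

## Metrics

Balanced accuracy is the mean of per-class recalls from the accumulated
confusion matrix.  ITR uses the `0·log 0 := 0` convention at `P ∈ {0, 1}`
and floors below-chance accuracies (`P < 1/N`) to 0 bits/min.  The
selection time `T` defaults to the data window plus a 0.5 s gaze-shift
overhead, recorded in the report.

## Synthetic data: what it does and does not emulate

Each class is a deterministic sum of harmonics (amplitudes 1, 0.5, 0.25 by
default; harmonic k at frequency k·f with phase k·φ), phase-locked across
trials and mapped to channels by a class-specific unit-norm spatial
pattern.  Background is per-channel 1/f noise (FFT-shaped, unit variance,
log–log slope −1) smeared by a random full-rank channel-mixing matrix —
spatially correlated like real EEG while the task lives in a low-rank
subspace, which is what makes spatial filtering meaningful — plus a 10 %
white sensor-noise floor.  Noise is rescaled per trial so the realised
task-to-background power ratio equals `snr_db` exactly.  An optional
latency-jitter parameter breaks phase locking for robustness studies.

Not emulated: volume-conduction head geometry, eye-blink/EMG artifacts,
non-stationary background spectra, inter-subject amplitude differences
beyond the random mixing.  Passing tests on this generator therefore show
algorithmic correctness and the *mechanism* of the augmentation benefit,
not performance on recorded EEG.

## Study conditions at desk scale

Two pinned conditions drive the evaluation (`ssvepkit.experiments`):

- **Classical benchmark**: the 12-target joint frequency–phase grid
  (9.25–14.75 Hz in 0.5 Hz steps, 0.5π phase steps) at 10 dB SNR, 8
  channels, fs 250 Hz, 0.5 s windows, 6 trials/class, 2 folds.
- **Sparse-data condition** (augmentation and ablation experiments): 6
  classes at 8–13 Hz, 2 harmonics, 4 channels, fs 64 Hz, 0.5 s windows,
  −8 dB SNR, 3 training + 1 validation trials per class, BGMix schedule
  (n=2)×8 + (n=3)×8, decoder with one encoder layer and `d_model = 32`,
  up to 50 epochs at patience 8; held-out evaluation on 3 fresh-noise
  trials per class from the same simulated subject, mean over 5 seeds.
  The condition is chosen so that data sparsity — not signal quality — is
  the binding constraint, the regime the augmentation targets.

## Known limitations

- The NumPy training loop is single-threaded; it is sized for the pinned
  desk-scale conditions, not for full-scale EEG benchmarks.
- The EDF reader epochs on integer-described annotations only.
- `mixed_loss` supports scalar fusion for any two losses, but classical
  decoders cannot consume mixed labels; BGMix is a deep-decoder tool.
- Attention-map export is per forward pass (`collect_attention`), not a
  persistent artifact format.
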