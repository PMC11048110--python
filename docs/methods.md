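# Methods

## The problem

In a rapid serial visual presentation (RSVP) experiment, images flash at
~10 Hz while EEG is recorded; a rare target image (about 1 in 25) evokes a
P300-like positive deflection over centro-parietal electrodes ~350 ms
after onset.  Single-trial detection of that response is the decoding
task.  The obstacle to deployment is calibration: EEG differs enough
between people that a classifier trained on one group usually degrades on
a new user.  The model here is trained so that a **new subject is decoded
with zero calibration data**.

## Model

Every epoch `x` (channels x time) is mapped by a convolutional encoder
`f` to a 1024-dimensional batch-normalized feature vector.  Each class
k ∈ {nontarget = 0, target = 1} is represented by a prototype

    p_k = Σ_i α_i · f̄_{i,k}

where `f̄_{i,k}` is training subject i's class-k mean feature and α is a
softmax over support subjects (subject-level attention):

    e_i = Σ_j tanh( g(f̄_i) ⊙ g(f(x̂)) )_j ,   α = softmax(e)

with a shared linear map `g` applied to both the subject mean and the
query feature.  α is recomputed per query sample (configurable to per
batch).  With this attention disabled α is uniform and p_k is the plain
mean over subjects.

A query is scored by a feature-weighted squared Euclidean distance

    d(f, p_k) = Σ_j z_k[j] · (f[j] − p_k[j])²

where z_k is produced by a small feature-attention net (1-D convolution
over the support class-mean feature, ReLU, softmax over the 1024
dimensions scaled by 1024, so mean(z_k) = 1).  Disabled, z_k ≡ 1 and the
distance is exactly squared Euclidean.  Class probabilities are
`softmax(−d)` — the *negative* sign makes the nearer prototype more
probable, consistent with nearest-prototype classification.  Ties in the
hard decision break toward nontarget.

Training minimizes mean binary cross-entropy plus λ·metric term, where
the metric term is mean(d_to_own_class − d_to_other_class); λ defaults
to 1.  Probabilities are clipped at 1e-12 before the log.

### Encoder

EEGNet-lineage architecture with a multiscale first stage:

* Block 1: three parallel temporal convolutions (default kernels 0.256,
  0.128, 0.064 s, converted to odd sample counts; 8 filters each),
  concatenated; squeeze-and-excitation over the 24 maps (reduction 4);
  depthwise spatial convolution collapsing the electrode axis (2 filters
  per map); batch norm; ELU; average-pool 4; dropout 0.25.
* Block 2: depthwise temporal convolution (16 samples); efficient channel
  attention (1-D convolution, kernel 3, over map descriptors) replacing a
  pointwise convolution; batch norm; ELU; average-pool 8; dropout.
* Head: flatten → linear → 1024 → batch norm (no activation).

The `plain` variant drops the SE and ECA blocks and is the ablation
baseline (pattern A).  Ablation patterns: A = plain encoder, no
attention; B = full encoder only; C = + feature attention; D = + subject
attention; E = both.

### Episodic training

One epoch = one episode per training subject: that subject provides a
class-stratified query batch (default 12 trials, ≥ 1 target) and is
excluded from the support set; every other training subject contributes a
**class-balanced** subsample of trials (up to `support_cap/2` per class).
Balancing matters: prototypes are class means, and at 1:24 imbalance the
target prototype would otherwise carry ~20x the sampling variance of the
nontarget prototype, which biases every distance comparison toward the
nontarget class (empirically: TPR ≈ 0.2, TNR ≈ 0.8 regardless of signal).
Support and query trials are encoded in a single training-mode batch, so
batch-norm statistics are shared within the episode.

Optimizer: Adam with β1 = 0.9, cosine-annealed learning rate (floor =
lr/100, no restarts), default base rate 1e-4, query size 12, default 50
epochs with early stopping on a rotating-validation BA plateau
(patience 10).  The held-out test subject is structurally outside `fit`
— the API only ever receives training subjects.

## Synthetic cohorts

The simulator generates what the method needs to be tested against:

* rare targets — exactly `round(trials · ratio)` per subject, default
  ratio 1/25, placed uniformly at random;
* a P300-like Gaussian bump, `A_s · exp(−(t−L)²/2w²)` (width 0.08 s),
  projected onto a fixed unit-norm raised-cosine topography peaking at a
  Pz-like channel (index `round(5/8 · n_channels)`), plus a per-subject
  topography perturbation;
* between-subject variation: amplitude `A_s ~ N(A, σ_A)`, latency
  `L_s ~ N(0.35 s, 0.03 s)` with 0.02 s per-trial jitter;
* colored background noise: independent AR(1) per channel, coefficient
  0.95, driven by white noise of sd `noise_sd`, stationary initial
  condition.

Randomness is one Philox counter-based stream per subject keyed by
`seed + subject_index`, so any subject can be regenerated in isolation.

What the simulator does **not** emulate: eye/muscle artifacts, multi-
component ERPs (N200/P1), inter-stimulus overlap between consecutive
10 Hz epochs, real electrode covariance structure, or session drift.
Passing tests therefore demonstrate correct mechanics and cross-subject
transfer on idealized signals, not performance on real recordings.

### Detectability of the default operating point

The AR(1) coefficient 0.95 concentrates noise power exactly where the
ERP lives.  The ideal observer (whitened matched filter with oracle
knowledge of amplitude, latency, topography and the noise model) has

    d'² = (A/σ)² · Σ_t (p_t − a·p_{t−1})² ,

which at amplitude/noise = 1, a = 0.95, 250 Hz gives d' = 0.36 — AUC
0.60, best possible balanced accuracy ≈ 0.57 *for any classifier*.  The
amplitude/noise = 1 setting is therefore a near-chance regime by
construction; detectability rises steeply as `a` falls (d' = 2.4 at
a = 0.6, 4.2 at a = 0.3, 5.9 for white noise).  End-to-end checks that
demand high absolute accuracy under a = 0.95 at unit amplitude ratio are
not achievable by any method, and the test suite reports them as such;
demonstrations of actual learning use lower `a`.

## Preprocessing

Zero-phase (forward-backward) Butterworth bandpass, 2-30 Hz, order 4 —
zero-phase preserves the ERP peak latency, at the cost of doubling the
effective order.  Filtering runs per epoch with reflect padding (the
container is epoch-based).  Default analysis rate 125 Hz (polyphase
resampling).  Channel standardization is fit on training subjects only
and applied unchanged to held-out data.  Windows are half-open
`[start, end)` with sample index `floor(t·sfreq)`, 0-based.

## Evaluation

Balanced accuracy BA = (TPR + TNR)/2 (chance = 0.5 under any
label-independent rule), confusion counts, rank-based Mann–Whitney AUC
(ties count ½), and two-sided Wilcoxon signed-rank tests for paired
subject-level comparisons (zero differences dropped; all-zero vector
yields p = 1 with a warning).  The AUC ranking score is `d0 − d1`, a
strictly monotone transform of P(y = 1) that stays resolvable when the
probability softmax saturates (distances are sums over 1024 dimensions).
Leave-one-subject-out is the outer protocol; the evaluation of a held-out
subject uses the encoder in eval mode (running batch-norm statistics) and
prototypes built exclusively from training subjects.

## Desk-scale problem sizes

The numerical engine is a small NumPy reverse-mode autodiff tape written
for this package (validated against finite differences); everything runs
single-CPU.  The stock experiment driver (`protoerp.experiments.desk_run`)
uses 6 subjects x 400 trials, 16 channels, 1 s epochs at 250 Hz
(downsampled to 125 Hz), 12 training epochs at learning rate 3e-3, and
pools confusion counts over 4 freshly simulated held-out subjects.  Two
choices depart from the library defaults and deserve note:

* learning rate 3e-3 (not the 1e-4 default): a desk-scale run performs
  ~60 optimizer steps, two orders of magnitude fewer than a full-scale
  training; at 1e-4 the encoder cannot move measurably in that budget.
* pooled evaluation over several held-out subjects: a single subject has
  only ~16 target trials, putting a ±0.1 granularity on TPR; pooling
  brings the BA standard error near 0.03.

## Known limitations

* Training at desk scale reaches roughly BA 0.6-0.7 where the ideal
  observer allows 0.9+; closing that gap needs the full-scale cohort
  sizes and training budgets the method was designed for.
* The metric loss is unbounded below; batch norm is what keeps feature
  scales (and hence distances) from diverging.
* Class probabilities saturate for well-separated queries; calibrated
  probabilities were not a design goal.
* The simulator's single-component ERP and AR(1) noise are deliberately
  minimal; no claim is made about artifact robustness.
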