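# Methods

## Problem and model

The package classifies binary affect states (valence or arousal above vs
below the rating midpoint 5) from multichannel EEG. Each 6 s segment is
represented as a graph signal: 32 electrode nodes, each carrying four
features — the z-scored average power spectral density in the θ, α, β and γ
bands. The inductive bias lives in the adjacency matrix, which encodes two
complementary kinds of channel relationship:

- **Distance topology** `A_ij = min(1, δ/d_ij²)`: volume conduction and the
  dipole-driven nature of scalp EEG make nearby electrodes redundant; an
  inverse-square law over 3D inter-electrode distance, capped at 1,
  captures these local relationships. The calibration constant δ is chosen
  so that a target fraction (default 20%) of connections exceeds a
  "nonignorable" cutoff (0.1): the off-diagonal squared distances are
  sorted and δ is placed at the corresponding quantile, halfway between the
  two bracketing values. This is deterministic, needs no search, and the
  retained fraction is exact up to one edge-count step (ties in distance
  extend the retained block).
- **Functional connectivity** `B_ij = r_ij · 1[|r_ij| > λ]`: the Pearson
  correlation between channels' feature vectors, keeping the *signed*
  value. Distant but functionally coupled regions get edges that distance
  cannot provide. The default λ = 0.98 is the published operating point for
  full-scale recordings; on small synthetic datasets the attainable
  correlations are lower and a smaller λ (we use 0.3 in the ablation
  harness) is needed for the matrix to be non-empty. The correlation is
  computed from the normalized band-PSD vectors of the *training* segments
  only; a raw-time-series mode exists for comparison.

The fused adjacency is the entrywise sum `C = A + B`. No clipping is
applied: entries up to 2 are legal and the degree normalization absorbs
them. Diagonals of both parents are set to 1 (the `d → 0` limit of the
distance formula saturates the cap; self-correlation is 1), so `C_ii = 2`;
both diagonals are configurable to 0.

## Spectral filtering

From `C` we form the normalized Laplacian `L = I − D^{−1/2} C D^{−1/2}`
with `D_ii = Σ_j |C_ij|`. The absolute values keep `D^{−1/2}` real when
signed correlations make entries negative (rare at high λ, but legal). The
spectrum is rescaled by `L̃ = L/λ_max − I`, which maps `[0, λ_max]` to
`[−1, 0]` — inside the Chebyshev domain. The conventional ChebNet rescaling
`2L/λ_max − I` (spectrum `[−1, 1]`) is available behind a flag; both
satisfy the filter identity `Σ_k θ_k T_k(L̃) x = U g(Λ̃) Uᵀ x`, which the
test suite verifies against an explicit eigendecomposition to 1e−8.

A graph with no off-diagonal structure (e.g. a connectivity matrix whose
threshold retained nothing) has `λ_max = 0`; the rescaling is then
undefined and the Laplacian constructor raises rather than producing NaNs.
Laplacians are computed lazily so such a matrix can still be fused before
ever being used alone.

## Classifier and training

One graph-convolution layer maps the 4 input bands to `hidden_width = 32`
features per node (`y = Σ_k T_k(L̃) X θ_k + b`), followed by ReLU, dropout
(0.2, after the activation and before the dense layer), a flatten, one
dense layer to 2 logits, and softmax. The depth follows the published
architecture sketch (a single convolution block before the dense head); the
hidden width is our choice, configurable.

The loss is mean cross-entropy (probabilities clamped at 1e−12) plus
`α‖w‖`. The penalty norm is not specified by the source formulation; we
default to the true L2 norm (with subgradient 0 at the origin), with
squared-L2 and L1 options, `α = 10⁻³`, applied to the multiplicative
weights (θ and the dense weight matrix) and not to biases. The optimizer is
Adam at the published learning rate `5×10⁻⁴` (no optimizer is named in the
source; Adam is the contemporary default), batch size 128. Parameters are
initialized with seeded Glorot-uniform bounds. Implementation is pure
NumPy with hand-derived gradients; a central-finite-difference check holds
to 1e−4 relative on every parameter class and regularizer.

The training loop stops when the epoch loss falls to the threshold
`e = 10⁻⁴` **or** the epoch budget MAX is exhausted, i.e. it continues
while `loss > e` *and* `epoch < MAX`. (The published pseudocode writes the
continuation condition with an OR, which taken literally never stops before
MAX whenever the loss stays high; we implement the evident intent.) In
practice the L2 penalty alone usually exceeds `e`, so MAX is the binding
constraint — matching the published behaviour of training for a fixed
budget. The per-epoch log records loss and training accuracy; the accuracy
is aggregated from the dropout-active minibatch passes to avoid a second
full sweep per epoch.

## Synthetic data

The generator emulates exactly the statistical structure the pipeline
consumes, in the DEAP per-subject layout (40 trials × 32 + peripheral
channels × 8064 samples at 128 Hz; 3 s baseline + 60 s stimulus; ratings
1–9 on four axes):

- **Broadband noise**: white Gaussian noise shaped to a 1/f amplitude
  spectrum (DC removed), RMS `noise_amp = 20 µV`, mixed across channels
  through the Cholesky factor of `exp(−d_ij/spatial_corr_scale)` over the
  bundled montage distances (default scale 0.5 head radii) — so the
  connectivity matrix has genuine spatial structure to find.
- **Band oscillations**: one sinusoid per band and channel at a random
  in-band frequency and phase, base amplitudes θ 4, α 8, β 3, γ 3 µV —
  amplitudes in the range of ongoing scalp rhythms. Class effects multiply
  these per `band_effect`; the default plants a γ ×2 amplitude boost in
  class-1 trials, a recoverable but not degenerate effect on top of the
  1/f background.
- **Trial-invariant artifact**: a smooth waveform periodic with the 3 s
  baseline duration, identical in every trial (amplitude 10 µV), standing
  in for stimulus-unrelated activity. Because it repeats exactly with the
  baseline period, tiled-baseline subtraction cancels it to float
  precision — which the tests assert by comparing against an identically
  seeded artifact-free realization. Real spontaneous background activity is
  not trial-invariant, so calibration on real data removes it only in
  expectation; the synthetic model tests the mechanism, not that premise.
- **Scale confound** (off by default): a per-channel log-uniform gain
  (`channel_scale_spread`) used by the ablation harness to create the
  feature-scale heterogeneity that z-scoring should absorb.

Ratings are 7 (class 1) / 3 (class 0) on valence and arousal — clear of the
binarization threshold 5, whose tie is otherwise resolved to the low class
by a documented, configurable rule. Everything is reproducible from the
config seed; the artifact and gain substreams are independent of the main
stream so ablating them leaves the other components bit-identical.

What passing on this data does **not** show: robustness to ocular/muscular
artifacts, nonstationarity, volume-conduction physics, inter-subject
variability of real EEG, or performance at published-benchmark scale.

## Evaluation design

Cross-validation is seeded random 5-fold at segment granularity: 80/20
splits within one subject's segments (subject-dependent) or over the
pooled segments of all subjects (subject-independent), matching the
published protocol in which "subject-independent" pools all subjects'
data. Two stricter extensions are provided and labelled as such:
leave-one-subject-out, and trial-granularity splitting (segments of one
trial never straddle train and test). Normalization statistics and the
connectivity matrix are recomputed from the training split of each fold;
an instrumentation hook exposes them so tests can verify the absence of
leakage. F1 with no positives anywhere is reported as NaN with a warning
and excluded from averages. The chance-level null permutes labels at the
segment level, making train and test labels jointly independent of the
signal (trial-level permutation would leave within-trial similarity as a
memorizable cue under segment-granularity splits).

The ablation harness re-runs the pipeline over adjacency variants
(distance / connectivity / fused at given λ) and normalization on/off on
identical seeded splits, and fails loudly if any variant saw different
folds.

## Problem sizes and budgets

The end-to-end recovery check uses 4 subjects × 40 trials (3040 segments)
with generator defaults, pooled 5-fold CV, and a 150-epoch training budget
— accuracy on the planted effect saturates long before that, and the
published 1000-epoch budget adds nothing on data this size. The
ablation-direction check uses 2 subjects × 16 trials per seed across 10
seeds (γ effect ×1.35, scale spread 1.0, spatial correlation scale 2.0,
λ = 0.3, 80 epochs), comparing 10-seed medians; conditions were chosen so
the comparisons are non-degenerate (connectivity edges exist, accuracy is
below ceiling). Unit tests use smaller fixtures still.

## Known limitations

- The distance/connectivity fusion is additive with fixed unit weights; no
  learned or convex combination is offered (deliberately — learnable
  adjacency is the design this method argues against).
- The NumPy training loop is single-threaded BLAS-bound; it is sized for
  desk-scale experiments, not for 32-subject benchmark sweeps.
- Welch with 1 s Hann sub-windows gives 1 Hz resolution; the θ band then
  averages ~4 bins. A periodogram option exists where exact narrow-band
  bookkeeping matters.
- `δ` calibration assumes distinct inter-electrode distances; exact ties
  extend the retained set to the whole tied block, which can overshoot the
  target fraction by more than one step on pathological montages.
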