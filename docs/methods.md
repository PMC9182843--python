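# Methods

## Model

A gait window is a fixed-length matrix `X ∈ R^{N×6}` (N = 200 time steps;
columns Ax, Ay, Az, Gx, Gy, Gz). The pipeline has five stages.

**Normalization.** At every time step the accelerometer triple and the
gyroscope triple are each divided by their Euclidean norm. This makes the
representation invariant to the overall magnitude (and therefore to scalar
gain/orientation-magnitude changes of the phone) while retaining the
directional waveform. The granularity — per step, per sensor triple — is a
design choice: it is the variant that cancels rigid magnitude changes from
device placement, which is the reason L2 normalization is used at all.
Time steps whose triple norm is below 1e-12 are left as zeros; an all-zero
window is returned unchanged with a warning. Gait-cycle boundary detection
is out of scope; fixed windows with a configurable stride replace it.

**Multi-scale reconstruction.** Scale τ block-averages non-overlapping runs
of τ consecutive samples. For N not divisible by τ the trailing `N mod τ`
samples are discarded: the block index runs to ⌊N/τ⌋ and never reaches the
remainder. The default scale set is {2, 3, 4, 5} (four branches), the
configuration reported to perform best; a τ = 1 branch is supported but not
default. Block averaging at τ dividing N preserves per-channel means
exactly, and composes: averaging at a then b equals averaging at ab.

**Backbone.** Each scale has its own copy (structure shared, weights not) of
a four-conv-layer 1D CNN: Conv 9×1/32 (valid) → MaxPool 2/2 →
Conv 5×1/64 (valid) → Conv 5×1/128 (stride 2, same) → MaxPool 2/2 →
Conv 3×1/128 (valid), ReLU after every convolution, dropout 0.5 after the
conv stack, L2 kernel penalty 1e-4 (configurable; no coefficient is
standard, 1e-4 is the common default). The third conv layer's stride-2
same-padding is forced by the published shape arithmetic: a 5-wide valid
stride-1 convolution cannot map 92 locations to 46; stride 2 with same
padding does, and parameter counts are unaffected. Convolution uses the
cross-correlation convention; same-padding splits the pad TensorFlow-style
(extra sample on the right). Weights are Kaiming-normal (fan-in k·C_in),
biases zero. Forward and backward passes are implemented directly on NumPy
arrays (einsum over sliding windows); gradients were verified against
central finite differences to ~1e-10.

**Weight-update sub-network.** Per branch, with feature map
`f ∈ R^{h×c}` (c = 128):

* GAP vector `F_k = (1/h) Σ_i f_{i,k}`;
* localized scores `s_i = f_i · W_c ∈ R^C` for the branch classifier
  `W_c ∈ R^{c×C}` (the per-location reading of the localized-classification
  sum: a double sum over locations and channels would collapse the locations
  it is meant to score);
* within-class scatter `Σ_w = Σ_i Σ_{s∈c_i} (s−m_i)(s−m_i)'` and
  between-class scatter `Σ_b = Σ_i (m_i−m)(m_i−m)'` over all location-score
  vectors of a batch (B·h samples; Σ_b is the unweighted sum over classes —
  for balanced batches the n_i-weighted form differs only by a constant
  factor, which the max-normalization below removes);
* generalized eigenvalues/vectors of `(Σ_b, Σ_w + εI)`, ridge
  `ε = 1e-6·trace(Σ_w)/dim` (unit fallback when the trace is zero) so a
  singular Σ_w never aborts training; the top
  `n' = min(C−1, c)` pairs are kept (C−1 bounds the rank of Σ_b).

Numerical choices that matter: the solver's eigenvectors are
Σ_w-orthonormal, so their Euclidean scale shrinks as the scatter grows and
their sign is arbitrary; each eigenvector is therefore rescaled to unit norm
with its largest-magnitude component positive. Without this the fused
representation drifts in scale and flips direction between batches and the
global head cannot converge (observed directly: the global loss stays at
chance while the local losses fall). Eigenvalues below zero by round-off are
clipped to 0.

The mechanism by which λ multiplies features is a design decision (the
source material does not print one): the GAP vector is projected onto the
discriminant directions — pulled back to feature space through the branch
classifier, `P = W_c V ∈ R^{c×n'}` — and component j is scaled by
`λ_j / max(λ)`, so the most discriminative direction keeps weight 1 and the
rest are attenuated proportionally (bounded, scale-free). Scatters are
accumulated across batches with an exponential running average (momentum
0.9) so λ is stable batch-to-batch; λ and P are treated as analytically
derived constants — no gradient flows through them (λ is defined by an
eigenproblem, not by backprop). The ablation switch `use_ws=False` forces
unit weights and changes nothing else.

**Fusion and heads.** `F_global = Σ_s F̂_τs W_τs` with learned
`W_τ ∈ R^{n'×64}` (fused dimension 64), dropout 0.8 after fusion during
training, then a softmax head. Each branch also has a local softmax head on
its GAP vector. The training objective is
`α Σ_i α_i CE_i + β CE_global + L2`, α = 0.99, β = 0.87, α_i uniform 1/s
(no published values; exposed in config). Cross-entropy is the standard
categorical form with probability clipping at 1e-7 (the printed binary form
is its K = 2 special case). Optimization: Adam, lr 0.001, batch 32, up to
200 epochs, early stopping on the overall validation loss with patience 50.
The validation monitor is a stratified 10% of the gallery (the monitor set
is not specified in the source; this is the package's choice). Best-
validation weights are restored; optimizer state is not. An optional
curriculum (pretraining branches from few to many scales) is not
implemented: its schedule is unspecified, and the joint scheme with
per-batch Fisher refresh trains to convergence without it.

## Synthetic data

The generator emulates the one property of inertial gait data the model
depends on: class-structured quasi-periodicity. Channel ch of subject s is

    x_ch(t) = Σ_{m=1..H} A_{ch,m} sin(2π f_s m t + φ_{ch,m}) + ε_t,

with H ∈ {3,4,5} harmonics, cadence f_s ~ U(1.6, 2.4) steps/s (a realistic
walking range), sampling rate 50 Hz, amplitudes `|T + spread·δ|` around a
shared template T ~ U(0.3, 1.0) with per-subject offsets δ ~ N(0, 0.35²),
phases U(0, 2π), and white noise ε with sd 0.25 by default (moderate
relative to unit-order amplitudes). `amplitude_spread` gives closed-form
control of inter-subject separability; with zero noise, windows of a subject
are identical and a nearest-centroid classifier is perfect by construction.
All draws descend from seeded `SeedSequence`s, so datasets are bit-
reproducible and subjects individually re-drawable.

Covariates map to physical effects: `fast_walk` compresses the period by
1 + 0.5·magnitude via circular resampling; `load_left/right` adds a constant
accelerometer bias (0.3·magnitude) and an Ax amplitude asymmetry
(∓0.25·magnitude by side); `pocket_hand` attenuates the gyroscope by
1 − 0.5·magnitude; `mixed` picks one of the four per window.

What the generator does **not** emulate: biomechanical waveform shape,
sensor-noise physics, orientation drift, within-subject gait variability
beyond additive noise (no phase jitter or cadence wander by default), or
session effects. Tests passing on this data therefore establish the
correctness and trainability of the pipeline, not field performance on real
smartphone recordings.

## Benchmark problem sizes

The end-to-end benchmark (tests and `scripts/acceptance.py`) uses
10 subjects × 40 windows, a 75/25 gallery/probe split, default noise, and
trains both the full and the Ws-ablated model with the standard
hyperparameters — a size chosen so the whole exercise runs in a few minutes
on one CPU while leaving the identification task non-trivial under the
ablation. Verification uses all probe-probe cosine pairs (450 genuine /
4,500 impostor at this size).

## Metric conventions

Rank-k IR breaks score ties in favour of the lowest class index
(deterministic). The ROC sweeps every distinct score as an accept threshold
(score ≥ threshold accepts) plus accept-all/reject-all endpoints; TAR is the
true-positive rate TP/(TP+FN) by default — the precision-style ratio
TP/(TP+FP) that is sometimes printed for TAR is available as
`tar_definition="printed"`, but a precision-based "ROC" is not monotone and
is not used for VR. VR@FAR interpolates TAR linearly at the target FAR
(default 10⁻³; a stated "0.001%" convention corresponds to 10⁻⁵ and is
selectable via `far_targets`), warning and returning the smallest achievable
operating point when the target is below it.

## Known limitations

* Early stopping monitors the overall loss on a small validation split
  (10% of the gallery ≈ 30 windows at benchmark size). The optimization
  occasionally plateaus for longer than the 50-epoch patience window before
  the global head converges, in which case training is truncated at the
  plateau and rank-1 identification suffers on that seed; the losses and the
  per-epoch log make such runs easy to spot (overall loss still ≫ 1), and a
  larger `early_stop_patience` lets them run to convergence.
* Pure-NumPy training is single-threaded BLAS-bound; fine at desk scale
  (seconds per epoch on the benchmark), not intended for corpus-scale runs.
* Fisher statistics assume batches containing ≥ 2 classes; single-class
  batches skip the refresh.
* The localized-score scatter is C-dimensional (C = number of classes), so
  n' ≤ C − 1 discriminant directions exist; for very small galleries the
  fused representation is correspondingly low-dimensional.
* Real-data covariate robustness claims cannot be validated with the
  synthetic generator (see above).
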