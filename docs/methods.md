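# Methods

This note documents the models and procedures implemented in `opsalign`,
the defaults they use, the design choices that were genuinely open, and the
limits of what the synthetic benchmarks demonstrate.

## SPD geometry

Spatial covariances of zero-mean EEG trials are treated as points on the
manifold of symmetric positive-definite (SPD) matrices with the
affine-invariant metric.  All matrix functions (powers, logs, exponentials)
go through symmetric eigendecomposition with post-hoc symmetrization
`(A + Aᵀ)/2`; the distance is evaluated on the symmetric pencil
`C₁^{-1/2} C₂ C₁^{-1/2}`, which shares the spectrum of `C₁⁻¹C₂` but keeps
the eigenproblem symmetric and numerically stable.

The Karcher mean is computed by the standard fixed-point iteration:
initialize at the arithmetic mean, map all matrices to the tangent space at
the current iterate, average, and map back with unit step size.
Convergence is declared when the Frobenius norm of the tangent-space mean
falls below `tol = 1e-8` (default), within `max_iter = 50` iterations;
non-convergence raises an error carrying the last gradient norm rather than
returning silently.  Weighted means are supported but unused by the
decoding pipeline.

Trial covariances come in two normalizations: `plain` (`E Eᵀ / N_s`,
consistent with the `1/√N_s` factor of the alignment transform) and
`trace_normalized` (`E Eᵀ / tr(E Eᵀ)`, used when averaging class
covariances for CSP so high-power trials do not dominate).  If the smallest
eigenvalue of a trial covariance falls below `1e-10 · trace/N_c`, a ridge
of that size is added; with the ridge disabled a rank-deficient trial is an
error.

## Re-centering (PS) and online re-centering (OPS)

Batch pre-alignment fits the Riemannian center `M` of a subject's trial
covariances and whitens every trial by `M^{-1/2}` (with the `1/√N_s`
factor, so the Gram matrix of an aligned trial *is* its aligned
covariance).  Two scoping rules matter:

* **One state per subject.**  Alignment removes subject- and dataset-level
  mixing; fitting one center across subjects would collapse distinct
  centers and is rejected unless explicitly overridden.
* **Training-partition fitting.**  In within-subject experiments the center
  is fitted on the training partition only and applied to validation and
  test trials, so no test statistics leak into the transform.  (Fitting on
  all trials is a defensible alternative for a purely unsupervised
  transform; the leakage-free choice is stricter and costs nothing.)

The online variant keeps a running inductive mean.  On trial `i+1` the mean
moves along the geodesic toward the incoming covariance by step `1/(i+1)`
**before** that same trial is aligned — the aligner always uses the mean
that includes the current trial, and the first trial whitens itself
exactly.  The stream consumes trials strictly in acquisition order, one at
a time, and never reads labels.  State (the current mean, the trial count,
the subject scope) serializes to a small archive so streaming inference can
resume; by default the state resets per recording.

Only re-centering is implemented — no dispersion (stretching) or rotation
correction.  This is deliberate: re-centering alone removes invertible
linear channel transforms up to an orthogonal factor, needs no class
markers, and works online.  The residual orthogonal factor is a known
limitation (see *Limitations*).

## Classical decoders

**CSP** solves the generalized eigenproblem `C̄₁ w = λ C̄₂ w` on the summed
trace-normalized class covariances and keeps the eigenvectors of the `L/2`
largest and `L/2` smallest eigenvalues (`L = 2` by default, matching the
two-filter configuration used for three-channel montages).  Filters are
defined only up to sign and scale; they are normalized so
`wᵀ(C̄₁+C̄₂)w = 1` with the largest-magnitude entry positive, which makes
fitted models reproducible.  Features are log normalized variances
`f_j = log(var_j / Σ var)`.

**FBCSP** runs CSP per band of the 4–9 / 8–15 / 15–30 Hz filter bank.  With
three channels each band contributes 2 candidate filters (on montages with
more channels, 4 per band: 2 top + 2 bottom); each candidate's scalar
log-variance feature is scored by histogram mutual information against the
label — 10 equal-frequency bins, plug-in estimate — and the 4 highest-MI
filters are kept.  The final feature vector applies the joint log-variance
normalization over the selected filters.  The per-band candidate count and
the MI estimator are conventions of this implementation; both are exposed
as parameters.

**LDA** is standard two-class linear discriminant analysis with pooled
covariance (delegated to scikit-learn's `lsqr` solver); exact decision ties
resolve to the lower class index.

**MDRM** stores one Karcher center per class (plain covariances) and
assigns a test covariance to the nearest center under the affine-invariant
distance, ties to the lowest class index.

## Convolutional decoders

ShallowNet and EEGNet are built layer-exactly for 1 × 3 × 300 inputs
(three channels, 3 s at 100 Hz):

* ShallowNet: 10 temporal kernels (1×21, pad 0×10) → batch norm → 15
  spatial kernels (3×1) → batch norm → square → average pool (1×55, stride
  1×15) → log → dropout → linear (255 → 2).  The log uses a `1e-6` floor so
  degenerate inputs stay finite.
* EEGNet: 8 temporal kernels (1×31, pad 0×15) → batch norm → depthwise
  spatial convolution (depth multiplier 2 → 16 maps) → batch norm → ELU →
  pool /4 → dropout → depthwise-separable temporal convolution (1×15, pad
  0×7, followed by a 1×1 pointwise mix) → batch norm → ELU → pool /8 →
  dropout → linear (144 → 2).

Both run on a compact numpy layer engine written for this package:
unit-stride grouped 2-D convolution via contiguous im2col and BLAS
contractions, with hand-derived backward passes verified against numeric
differentiation to ~1e-9 relative error.  Parameters are float32 (the
engine also runs in float64, which the gradient tests use); the networks
have ~1.2k parameters each, so full training runs take seconds per fold on
one CPU.

Training: softmax cross-entropy with Adam (learning rate 0.001, moments
0.9/0.999, no weight decay, no schedule), dropout 0.5, batch size 16 for
within-subject runs and 128 for pooled cross-subject/cross-dataset runs, a
fixed number of epochs (120 by default; the scaled-down benchmarks use
30–40) with no early stopping.  After every epoch validation accuracy is
recorded with batch-norm running statistics; the returned weights are from
the epoch with the highest validation accuracy, earliest on ties.  Weight
initialization is Glorot uniform, batch norm starts at (1, 0), and the
seed drives initialization, shuffling and dropout, so runs are exactly
reproducible.

## Synthetic data

The generator emulates the two components that make cross-dataset EEG
decoding hard: *physiological* variability (per-subject source mixing
`A_s = exp(physio_scale · (skew + small symmetric))`, guaranteed
invertible) and *environmental* variability (per-dataset transform
`D_d = diag(gains) · (I + env_scale · mixing)` with log-uniform gains in
[0.5, 2] at full strength, plus a dataset-level noise factor).  Three
band-limited Gaussian sources (8–15 Hz, the mu band targeted by
motor-imagery paradigms, inside the 3–40 Hz analysis band) map to C3-, Cz-
and C4-like channels.  The class signal is event-related
desynchronization: left-hand imagery divides the contralateral C4-like
source variance by `effect_size`, right-hand the C3-like source; the
Cz-like source is class-neutral.  Trials are `E = D_d A_s S + noise`,
interleaved in randomized acquisition order, then passed through the same
preprocessing chain as real data (3–40 Hz zero-phase band-pass,
demeaning).

Defaults, chosen once as a plausible desk-scale study: 2 datasets × 6
subjects × 50 trials/class, `effect_size = 4` (a strong, clearly decodable
contralateral suppression), `physio_scale = 0.2`, `env_scale = 1.0`,
`noise_sd = 0.3`.  A `null_mode` flag forces the effect ratio to 1 for
calibration checks.  Ground-truth mixing matrices are stored for oracle
tests only.

`transfer_demo_world` is the canonical transfer experiment: because the
random dataset transforms of `generate_multidataset` can coincide by
chance, the demo world fixes the environmental contrast by design — dataset
0 applies channel gains 0.6/1.0/1.8, dataset 1 the opposite profile, with
seed-drawn residual mixing, and the sensor-noise level identical in both so
the manipulated factor is exactly the linear channel transform that
re-centering removes.

What the generator does **not** emulate: realistic head geometry and
forward fields, 1/f background spectra, ocular/muscular artifacts,
within-session non-stationarity, or inter-subject variation in rhythm
frequency.  Passing benchmarks on this data therefore demonstrates the
*mechanism* — that re-centering removes linear channel transforms and
restores transfer — not field performance on real recordings.

## Evaluation protocols

* **Within-subject**: 10 independent stratified 80/10/10 splits per subject
  (train = ⌊0.8·N⌋ on the whole set, validation takes the odd remainder;
  per-partition class quotas by largest remainder; fold *f* seeded with
  *f*).  Classical decoders fit on train+validation; networks use the
  validation partition for best-epoch selection.  Condition "PS" re-centers
  with the training partition's mean.
* **Cross-subject (LOSO)**: leave one subject out per dataset; under
  condition "OPS" every subject — training and held-out alike — is aligned
  by their own online stream before any pooling, so the held-out subject
  needs no calibration data.
* **Cross-dataset**: train on all subjects of one dataset, test on every
  subject of the others; the diagonal of the resulting accuracy matrix is
  the within-dataset LOSO accuracy, and the OPS-minus-none difference
  matrix summarizes the alignment effect.

Method comparisons use the two-sided Wilcoxon signed-rank test on accuracy
vectors paired by identical (dataset, subject/fold) cells: zero differences
dropped, exact null distribution for up to 12 untied pairs, normal
approximation with continuity and tie corrections beyond.  Chance level is
fixed at 0.5 (two balanced classes).

Scaled-down problem sizes used by the repository's own benchmarks (chosen
as desk-scale study conditions): the transfer benchmark runs 2 datasets ×
6 subjects × 100 trials with 30 training epochs; the null-calibration check
uses 4 subjects × 200 trials; the repeated LOSO protocols re-seed weight
initialization and splits per repetition.

## Known limitations

* Re-centering removes mixing only up to an orthogonal factor.  Networks
  trained on aligned time series can still latch onto residual
  dataset-specific cues (e.g. the whitened noise profile `σ² M⁻¹` differs
  between datasets when channel gains differ strongly), so OPS narrows but
  does not close the cross-dataset gap for the conv-nets — covariance-based
  decoders such as MDRM recover almost fully in the same worlds.  This
  mirrors the motivation for adding rotation correction in supervised
  transfer settings, which is deliberately out of scope here.
* The inductive mean is order-dependent; its first few alignments are noisy
  until the stream has seen enough trials, which depresses streaming
  accuracy on the earliest trials of a session.
* The Karcher iteration assumes reasonably conditioned covariances; the
  ridge guards rank deficiency but heavy-tailed artifacts (not modeled
  here) would call for robust covariance estimation.
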