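# Methods

This note documents the models and procedures the package implements,
the defaults and why they were chosen, what the synthetic generators do
and do not emulate, and the numerical choices that matter for
reproducing results.

## The estimator

### Generative model

M node time courses (source-cluster activities) are assumed to follow a
nonlinear multivariate autoregression of order p: the current sample
vector x(n) is a function f of the stacked p past samples of all nodes,
plus i.i.d. residual noise. f is implemented by a single-hidden-layer
perceptron: tanh hidden units (H = 10 by default), linear outputs.

### Standardization and lagged design

Trials are concatenated observation-wise: within each trial, rows
(x(n); x_p) are formed for n = p+1 … T and pooled; rows never span a
trial boundary (cross-boundary rows would mix unrelated samples, so
they are excluded even though that loses p rows per trial). Node
series are z-scored with pooled per-node statistics and the design
columns are then re-centred/rescaled exactly, so the network sees
zero-mean, unit-variance inputs and targets. Consequences: all
connectivity values live on the standardized scale (doubling raw
amplitudes changes nothing), and the Taylor expansion point x = 0 is
the data median region, where tanh is well approximated by its
first-order term.

### Training

Incremental (per-pattern) gradient descent with momentum
(default α = 0.9) and a per-epoch adaptive learning rate: start at
η = 0.01, multiply by 1.05 after an epoch that lowered the training
MSE, reject the epoch's updates and multiply by 0.7 after an epoch that
raised it by more than 4%. Non-finite error halves η and retries, up to
five times before aborting. Weights start uniform in [−0.5, 0.5].
Each of the cross-validation folds (default 10) draws an independent
random permutation of the pooled rows and splits it 80% train / 10%
validation / 10% test; early stopping keeps the best-validation
weights. The patience default is 20 consecutive non-improving epochs:
with per-epoch validation checks on datasets of 10³–10⁴ rows, a
patience of ~6 halts training well short of the linear-least-squares
error floor and leaves spurious weight mass on absent edges (measured
as inflated lC on true-zero edges and an edge-rank correlation with the
OLS oracle of ~0.5 instead of 1.0). The training loop is compiled with
numba; all randomness (permutations, initializations, shuffles) derives
from a single integer seed via counter-based substreams, so fits are
bit-reproducible.

### Connectivity extraction

First-order Taylor expansion at 0 gives the linear map
A = W2 · diag(g′(b1)) · W1, reshaped into p lag matrices A_d. The
zeroth-order term (a constant offset) is excluded from both parts:
connectivity must not depend on intercepts. Linear connectivity
lC(i→j) is the mean over lags of |a_ji^d|. Nonlinear connectivity
NC(i→j) is ln(MSE_j restricted / MSE_j full), where the restricted
prediction for source i is f(x̃) + A·(x − x̃) with x̃ zeroing all p lag
columns of node i — node i then acts only through the linear term
while every other node acts through the full map. The matrix
convention is mat[j, i] = i→j (row target, column source) everywhere,
recorded in all output metadata. NC is computed on each fold's test
partition (training-partition residuals would bias the ratio
optimistically); lC, NC and the A_d are averaged over folds. Diagonal
entries are self-connections: estimated, reported, but excluded from
network means.

Model order is selected beforehand by OLS VAR information criteria,
AIC = ln det(S) + 2pM²/n and BIC = ln det(S) + pM² ln(n)/n with S the
MLE residual covariance; the consensus is the smaller of the two
argmins (ties break toward smaller p, favouring parsimony).

### Surrogate significance

Each of the (default 100) surrogates circularly shifts every node and
trial independently by a uniform offset in [0.1·T, 0.9·T], preserving
each series' spectrum and internal dynamics while destroying
cross-node temporal relations, then reruns the full fit and extraction
with the identical configuration. An edge is significant when its
observed estimate exceeds the 95th percentile of its surrogate values.
Fewer than 20 surrogates triggers a warning (the upper quantile is
unstable). Calibration note: all edges of one fit share that fit's
stochastic-training luck, so edge-level false positives cluster within
datasets; configurations with very few folds make the empirical
false-positive rate over a small number of replicates unstable.
Validation studies therefore use at least 4 folds for surrogate
analyses, which brings the measured type-I rate close to the nominal
5% (pooled over many runs it is ≈ 0.05).

## Sensor statistics

The cluster-based permutation test takes per-subject, per-channel
band-power scalars for two paired conditions (power is averaged over
the band's frequencies and the analysis window first, so clustering is
purely spatial). Channels with |paired t| above the two-tailed
α = 0.05 threshold are clustered by spatial adjacency, separately by
sign; clusters need ≥ 2 channels; the cluster statistic is the
within-cluster t-sum. The null distribution is the maximum absolute
cluster mass over random within-subject condition sign flips (default
500), and p = (count ≥ observed + 1)/(n_perm + 1) — the +1 keeps the
estimator valid at any permutation count. An exhaustive mode
enumerates all 2^n flips for small n (used to verify the Monte-Carlo
p against exact enumeration). Channel adjacency is distance-based; the
neighbour threshold is a config parameter in the units of the supplied
positions.

## Source analysis

LCMV spatial filters are computed per voxel from the covariance C of
the concatenated time-locked condition averages (one common filter for
both conditions, so condition differences cannot arise from different
filters), regularized by adding reg_fraction·mean(eigenvalue)·I
(default 5% Tikhonov loading). Orientation is fixed to the max-power
direction — the dominant eigenvector of the 3×3 source covariance,
equivalently the minimum eigenvector of LᵀC⁻¹L — and the scalar filter
w = C⁻¹l/(lᵀC⁻¹l) satisfies unit gain wᵀl = 1 (checked to 1e-6). The
neural activity index is NAI(v) = (wᵀC_data w)/(wᵀC_noise w); the noise
covariance defaults to the identity scaled by the smallest eigenvalue
of C (a unit-noise floor), which leaves the argmax and the ranking
invariant to global sensor scaling.

Voxel selection takes the top 1% of the NAI distribution among
atlas-labeled voxels — implemented as exactly ceil(0.01·n_labeled)
voxels with ties broken by voxel index, so the candidate set is
deterministic even on degenerate (constant) maps. DBSCAN with
eps = 1.5 × voxel edge and minPts = 2 clusters the candidates; noise
points are discarded. The manual visual-curation step of cluster
selection is replaced by two deterministic rules (a minimum reported
cluster size and a centroid-distance merge rule for clusters sharing a
dominant label), both off by default, because reproducibility excludes
a human in the loop. Cluster activity is the arithmetic mean of member
voxel time courses per trial.

## Group statistics

Condition contrasts are one-sided paired t tests (direction declared
per contrast in config; the hypotheses are directional by design) with
Cohen's d = mean(diff)/sd(diff). Per-edge contrasts include only
subjects whose edge was surrogate-significant in both conditions, so
degrees of freedom vary across edges; edges with < 3 included subjects
are skipped with a notice. The network-mean contrast averages each
subject's included non-self edges. No multiple-comparison correction is
applied by default (matching the uncorrected per-edge reporting this
analysis style uses); Holm correction is available. Brain-behavior
association is a Pearson correlation with the two-sided t-transform p.

The display rule for connectivity graphs: one scalar threshold equal to
the mean over all non-self connections pooled across bands and
conditions; edges below it are suppressed and displayed values are
scaled ×100.

## Spectral analysis

Morlet wavelets with Gaussian envelope σ_t = n_cycles/(2πf), five
cycles by default; power is the squared magnitude of the per-trial
transform averaged over trials (induced and evoked together — no
evoked subtraction). The frequency grid defaults to 1 Hz steps over
2–30 Hz, covering theta (4–7 Hz), alpha (8–12 Hz) and beta (12–25 Hz).
Samples within half the wavelet support of an epoch edge are flagged
invalid and band-power windows may not touch them. Band-pass filtering
uses Hamming-windowed sinc FIR filters (≈53 dB stop-band attenuation),
transition width max(2 Hz, 0.25·f_lo), applied zero-phase by default.
Zero-phase filtering spreads energy backwards in time, which can in
principle distort a directed-causality estimate downstream; a causal
(minimum-phase) mode is exposed for sensitivity analyses, with
zero-phase kept as the default because phase delay would shift all
band-limited activity uniformly later.

## Synthetic generators: what they emulate and what they do not

All generators expand one integer seed into per-subject/per-trial
substreams (SeedSequence spawning), so datasets are bit-reproducible
and independent of evaluation order.

* **nMVAR systems** — known linear lag matrices plus nonlinear terms
  from {square, tanh, lagged cross-product}, spanning polynomial and
  saturating nonlinearities; Gaussian i.i.d. residuals (the weakest
  assumption consistent with an unspecified residual term); burn-in of
  max(10p, 100) samples; construction rejects linearly non-stationary
  systems (companion spectral radius ≥ 1). `oscillator_var_spec` builds
  coupled AR(2) resonators with poles near the unit circle — the
  high-R² regime band-limited cortical sources occupy.
* **Two-condition band-effect sensor data** — 1/f background noise on
  all channels plus narrowband oscillatory activity on designated
  channel groups. The per-band effect size d plants a deterministic
  relative amplitude contrast (×(1 + 0.4 d) in condition A); subject
  amplitude jitter multiplies both conditions and cancels in the
  contrast. This makes d = 0 an exact null (conditions identically
  distributed) and d > 0 produce a positive measured power difference
  in essentially every subject. The generator does not emulate
  artifacts, evoked transients or channel-covariance structure of real
  EEG, so passing cluster tests here demonstrates calibration and
  sensitivity of the statistics, not robustness to artifacts.
* **Source projection** — planted dipoles at known voxels of a
  synthetic lattice leadfield (smooth gain falloff; no head geometry)
  plus white sensor noise. Localization results on it validate the
  beamformer algebra, not forward-model accuracy.
* **Multi-subject condition study** — ring-coupled VAR subjects whose
  cross-coupling is lower in condition B; the per-edge, per-subject
  coupling difference is drawn with mean/SD = d (default 0.5), i.e.
  the planted standardized effect is per edge, and differences are
  independent across edges so a network-mean contrast aggregates them.
  Two scale choices matter and were fixed from measurement-regime
  considerations: trials are 128 samples (0.5 s at 256 Hz; real
  recordings of this kind are 2 s trials, so this is scaled down but
  long enough that estimator noise does not dominate) and the
  between-subject heterogeneity scale is 0.3 × base coupling, large
  enough that subject-level variance, not network-extraction noise,
  carries the planted effect to the observed level.
* **Behavioral scores** — Gaussian scores constructed to have an exact
  population correlation with a supplied connectivity summary.

## Validation studies and problem sizes

The studies in `ncreann.studies` (run by the test suite and
`scripts/acceptance.py`) use: 10 seeds × 20,000 samples for the linear
OLS-oracle comparison (fixtures assign distinct, evenly spaced
strengths 0.05–0.50 to all six off-diagonal edges, because rank
agreement is undefined between estimators on edges whose true
strengths tie at zero); 20 seeds for single-nonlinear-edge detection;
20 replicates × 100 surrogates (M = 3, 600 samples, 4-fold fits) for
surrogate calibration; 200 replicates × 500 permutations (20 subjects,
32 channels, Welch band power) for cluster-test calibration; a
10×10×10 grid at SNR 10 for beamformer recovery; and 10 replicates of
a 40-subject study for end-to-end recovery. These sizes keep each
study in the seconds-to-minutes range while leaving Monte-Carlo error
well inside the tolerances being checked.

## Known limitations

* The Taylor split attributes to "linear" whatever the network
  expresses through its first-order term at the origin; strongly
  saturating dynamics far from the origin blur the split.
* NC is a log error ratio: it detects nonlinear *dependence*, not its
  functional form, and mild negative values can occur on finite data.
* Zero-phase filtering before connectivity estimation is the
  documented default, not a verified-neutral choice; the causal mode
  exists for sensitivity checks.
* The surrogate test's edge decisions are correlated within a fit;
  with few folds and few replicates its empirical false-positive rate
  is noisy around the nominal level.
* The incremental trainer is stochastic; estimates carry fit-seed
  variability that fold-averaging reduces but does not remove.
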