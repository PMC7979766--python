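# Methods

## Problem and model

`metasurv` models the time to distant metastasis (DM) for head-and-neck
cancer patients from the planning CT restricted to the contoured tumor
(primary GTV plus nodal GTVs ≥ 2 cm³), optionally combined with seven
clinical covariates. Instead of a binary classifier that discards
follow-up information, the networks use a discrete-time survival
formulation: follow-up is cut into 10 half-year intervals and the final
sigmoid layer emits, per interval *j*, the conditional probability
*p<sub>j</sub>* of remaining DM-free through that interval given DM-free
at its start. The survival curve is the running product
*S<sub>j</sub> = ∏<sub>k≤j</sub> p<sub>k</sub>*, and the scalar risk used
everywhere downstream is *1 − S(3 y)* (for binary models, the sigmoid
score).

The likelihood treats censoring as non-informative. Each patient is
encoded as two indicator vectors: `survived[j] = 1` for intervals fully
lived through and `event_at[j] = 1` for the interval containing an
observed event. Censored patients receive survival credit for every
interval whose midpoint precedes the censoring time (half-interval
credit); events or censoring beyond the grid count as full survivors. The
loss is the mean over patients of
`−Σ_j (survived[j]·log p_j + event_at[j]·log(1−p_j))`, with *p* clamped to
`[1e−7, 1−1e−7]`. Clamped entries get zero gradient.

### Risk direction

The horizon concordance index (HCI) is computed between the risk
*1 − S(3 y)* and the observed time, so that higher risk pairs with shorter
event time and a perfect model scores 1.0. Standard Harrell permissibility
rules apply (pairs of two events, or one event preceding the other's
censoring time; tied risks credit 0.5); the implementation wraps
lifelines' concordance index with the risk negated, and the test suite
holds an independent O(n²) pair-counting oracle.

## Architectures

Four families, each in a binary (1 output unit) and a time-to-event
(10 output units) variant:

* **2D/3D CNN** — three blocks of (stride-1 "same" convolution,
  non-overlapping max-pool, per-channel PReLU), then flatten, two dense
  layers with PReLU, dropout (rate 0.25), dense output, sigmoid. The
  full-scale blocks (32 k5 / 64 k5 / 128 k3 kernels, pools 4/4/8) reduce a
  128-voxel crop to a single spatial cell with 128 channels. The per-block
  numbers and dense widths (64, 32) are package defaults — the reference
  description fixes only the block count, the 128-feature bottleneck and
  the head — and are fully configurable. A desk-scale set
  (8/16/32 kernels, pools 4/4/2, dense 32/16) covers 32-voxel crops.
* **Clinical ANN** — input of 20 features (age/100, total GTV volume/100,
  one-hot sex, site, overall stage, T-stage, N-stage), one 14-unit hidden
  ReLU layer, dropout, sigmoid head.
* **CNN+Clinical** — the CNN with the 20 clinical features concatenated
  onto the flattened 128-vector before the dense head.

The engine is a small NumPy implementation with explicit backprop
(convolutions via `sliding_window_view` + tensordot, pooling via blocked
argmax); all layer gradients are finite-difference checked in the tests.
Optimization is Adam with constant learning rate and L2 weight decay
(1e−4) applied to convolution/dense kernels only. Best-validation-metric
weights (AUC for binary, HCI for time-to-event) are retained; early
stopping monitors the same metric.

## Preprocessing

Images are resampled to an isotropic grid (linear interpolation); binary
masks are resampled shape-based: the 3D signed Euclidean distance map is
interpolated linearly and re-thresholded at zero. CT values are windowed
to [−500, +500] HU and mapped affinely to [−1, +1]; the image is then
masked with the union of primary and nodal GTVs (outside = −1). Nodal
volumes below 2 cm³ are excluded (inclusive boundary: exactly 2 cm³ is
kept). In the texture-ablating *binary* mode, every in-union voxel above
background is set to +1, leaving only volume and shape. The masked image
is embedded in a cubic canvas centred on the mask-union centroid — the
reference protocol does not state how the canvas is positioned, so
centroid centering is this package's convention, guaranteeing the tumor
survives the subsequent crop. 2D models use the axial slice with the
largest in-mask voxel count (ties: lowest index).

Training-time augmentation: random crop whose centre is shifted by at
most 20% of the canvas per axis, left-right mirroring (p = 0.5), and —
jointly with probability 0.1–0.5 depending on model — rotation (≤60°,
in-plane for 2D, about a uniformly random axis for 3D, out-of-grid voxels
filled with −1) plus a smooth random elastic deformation. The elastic
field is Gaussian-filtered noise with peak displacement drawn up to
`elastic_fraction × extent / 8`; the magnitude convention is ours, chosen
to stay in the mild-deformation regime. Evaluation uses a deterministic
central crop only.

## Synthetic cohorts

The generator emulates the structure of multicentric head-and-neck DM
cohorts without any anatomical pretension: a soft-tissue background, one
ellipsoidal primary (randomised semi-axes, uniform random orientation,
band-limited Gaussian texture inside) and 0–3 nodal blobs, some below the
2 cm³ filter. Semi-axes are drawn as 0.12–0.32 of the grid so total GTV
volumes land in the tens of cm³ on the 64 mm-scale canvas, matching the
median volumes of the emulated cohorts; desk-scale 32³ cohorts use 2 mm
voxels so physical sizes are preserved.

Three latent features drive outcome: log total GTV volume, primary
elongation (max/min semi-axis) and texture contrast (the texture field's
HU standard deviation). Standardized over the cohort, they enter a
per-interval logistic hazard; the baseline logit is calibrated by
bisection (with common random numbers) until the realized event
prevalence hits the target, 10% by default, within the 6–14% range typical
of DM in this disease. Event intervals are sampled from the discrete
hazard and realised at interval midpoints; censoring is independent,
uniform between the 2-year minimum follow-up and the grid end for a
configurable fraction of patients, and beyond the grid for the rest.
`true_risk` returns each patient's ground-truth 1 − S(3 y), making
parameter-recovery tests well-posed.

What the generator does **not** emulate: anatomy (no organs, bone or air
cavities), scanner effects, inter-observer contour variability,
covariate-dependent censoring, or clinical covariates that carry
independent prognostic signal (site, stage etc. are sampled independently
of the hazard). Passing recovery tests therefore demonstrates that the
pipeline can extract a known image-borne hazard signal under censoring —
not that it reproduces clinical performance on real cohorts.

## Evaluation protocol

Three event-stratified cross-validation folds (stratification is this
package's choice to avoid event-free folds at small n) each yield one
best-checkpoint model. Frozen fold models are applied to independent test
cohorts; their predictions are averaged pointwise (curves or scores) into
one model-averaged prediction per patient. Cohort metrics are summarised
as the bootstrap median with an 83% percentile interval (8.5th/91.5th
percentiles of 1000 patient resamples; replicates with an undefined
metric are redrawn and counted). Two non-overlapping 83% intervals
correspond to a difference at significance level ≈0.05; touching
endpoints count as overlap. The stratification threshold is, per fold,
the midpoint between the mean risk of event and non-event validation
patients, averaged over folds; high risk is strict `risk > threshold`.
Groups are compared with Kaplan–Meier curves and the two-group log-rank
test (lifelines). Patient-id leakage between cross-validation and test
cohorts aborts the run, and the threshold function receives validation
data only, by construction.

## Desk-scale study conditions

Full-scale defaults (256³ canvas, 128³ crop, 300–500 epochs) are
supported by configuration but are not what the tests run. The recovery
experiment uses: n = 400 patients, 32³ volumes at 2 mm, prevalence 0.30,
hazard coefficient 3.0 on standardized log-volume (0 on elongation and
texture), split 220 train / 80 validation / 100 test. The effect size is
chosen so the ground-truth risk attains HCI ≈ 0.91 on the test split:
the criteria then measure estimation quality rather than irreducible
noise. The 3D CNN trains 24 epochs (learning rate 1e−3, batch 8), the
ANN up to 3000 epochs (1e−2, batch 32, patience 1000). Under these conditions
the standard-input CNN and the ANN reach test HCI ≈ 0.86–0.90, and
discarding texture (binary mode) changes the CNN by well under 0.05 —
consistent with texture carrying no signal by construction.

## Numerical and degenerate-input conventions

* Conditional probabilities clamped to `[1e−7, 1−1e−7]` inside the loss.
* Maximal-slice ties resolved to the lowest axial index.
* A primary mask that vanishes under resampling excludes the record with
  a logged reason; vanished nodal masks are dropped individually.
* Bootstrap replicates with a single outcome class (AUC) or no
  permissible pairs (HCI) are redrawn; more than 50% such draws is an
  error.
* An empty risk group after thresholding is reported without a log-rank
  test.
* All randomness flows from one experiment seed expanded into named
  sub-seeds (split / per-fold init / per-fold training / bootstrap) via
  SHA-256, so reports are byte-identical across runs on one machine.

## Known limitations

* The NumPy engine is CPU-bound; full-scale 128³ training is supported in
  principle but impractically slow — the package targets method-level
  validation at desk scale.
* PReLU slopes are per-channel; the reference granularity is unstated.
* The elastic-deformation amplitude convention is package-specific.
* Binary-variant training and 2D families are exercised at unit scale in
  the tests; the deep recovery experiment covers the 3D time-to-event
  CNN and the ANN.
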