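# Methods

## Scope and data model

The package calibrates leaf-level SPAD (relative chlorophyll) against
325–1075 nm reflectance sampled at 1 nm. The unit of analysis is the
(stage, leaf position) group — apical leaves at the vegetative stages
V6/V8/V12, the three ear leaves at the reproductive stages R1/R2 —
because chlorophyll statistics, screening thresholds and calibration
models all vary across that grid. A `SampleSet` couples one shared
wavelength grid, a reflectance matrix, and per-leaf metadata (stage,
leaf position, variety, nitrogen rate, SPAD); every stage of the
pipeline consumes and returns this container. On disk the canonical
form is a wide spectra CSV (rows = samples, columns = integer nm) plus
a SPAD/metadata CSV joined on `sample_id`; records present on only one
side are dropped with a logged count, since an unpaired spectrum or
SPAD reading cannot enter a paired calibration. A long spectra dialect
is supported read-only. Raw reflectance must lie in [0, 1]; preprocessed
values are unrestricted.

## Synthetic study conditions

No public paired dataset exists for this design, so the generator is a
first-class module that defines the study conditions, with ground truth
retained for recovery benchmarks.

**SPAD distributions.** Each group draws SPAD from a normal
distribution truncated to the meter range (0, 100). The default group
grid uses nine (stage, leaf position) combinations with means 50.6–61.7
and SDs 3.0–5.8 — every generating CV below 10%, matching the
tight within-group clustering typical of managed field trials.

**Spectral model.** Reflectance is rendered as

    R(λ) = gain · (floor + (base(λ) − floor) · exp(−γ · chl · a(λ))) + offset + ε(λ)

with `base` a smooth sigmoid rising from a dim visible level (0.12) to
the NIR plateau (0.54) across the red edge (centre 715 nm, width 18 nm);
`a(λ)` a fixed nonnegative absorption kernel (blue and red Gaussian
lobes at 450/670 nm) that ramps linearly to zero over 700–750 nm;
`floor` = 0.05 the residual reflectance of a fully absorbing leaf; and
γ = 70 the absorptivity scale. Latent chlorophyll is an affine monotone
function of SPAD (chl = 0.0012·SPAD); only the monotone coupling
matters downstream. The Beer–Lambert exponential is deliberate: at
field-typical chlorophyll, γ·chl·a ≈ 4 in the blue/red troughs, so
those bands are optically saturated and nearly chlorophyll-insensitive,
while the red-edge shoulder (where `a` decays through ~0.2–0.7) stays
in its responsive regime. This reproduces the defining correlation
structure of real leaf spectra — near-zero r at 670 nm, the strongest
negative r on the red-edge shoulder (≈ 730 nm here), positive r on the
NIR plateau — and is why red-edge indices win the screening. A linear
depth model (R = gain·(base − chl·a) + offset) was evaluated first and
rejected: without saturation the visible-contrast indices (TGI, VARI,
VIG) dominate every group's correlation ranking, which contradicts the
empirical primacy of red-edge features this package is designed around.

**Artifacts.** Each leaf gets a multiplicative gain ~ N(1, 0.02) and an
additive offset ~ N(0, 0.008) — the scatter that SNV/MSC remove — plus
white noise ~ N(0, 0.003) per band, which SG smoothing suppresses. The
scales are free parameters of the emulation (chosen once): leaf-clip
contact measurements after white-reference correction and three-scan
averaging are reproducible to a few percent, and because gain scales
absorption depth directly, gain SD also sets an irreducible
SPAD-prediction noise floor of roughly gain_sd × SPAD ≈ 1 SPAD unit,
consistent with published leaf-level calibration RMSEs of 2–3.5.

**Planted anomalies.** Outlier flags are recorded in `SyntheticTruth`
*before* corruption. SPAD anomalies displace the recorded SPAD 5–8
group-SDs from the group mean (spectrum untouched) — centre-relative so
that "≥ 5 SD from centre" is guaranteed by construction, which is the
condition under which a centre-distance rule can be expected to flag
every planted case. Spectral anomalies keep their SPAD but re-render the
spectrum from a latent chlorophyll whose implied SPAD sits 3 group-SDs
toward the group mean (kind `"mismatch"`; physically glare, poor clip
contact or a target/file swap washing the pigment signature toward an
average-looking leaf). Two alternatives remain available
(`spectral_outlier_kind="gain"` — a gross ×2 gain — and `"spike"` — a
localized 0.3-reflectance Gaussian bump) but are not the default
because a residual-based detector is largely blind to them: a scaled
spectrum preserves the chlorophyll contrast so near-mean samples keep
small residuals, and coherent or high-leverage corruption is absorbed
by PLS components (self-masking and slope collapse). The mismatch kind
breaks X–y consistency for every planted sample at modest leverage; its
magnitude is fixed (not a range) so the benchmark measures sensitivity
at one calibrated effect size, and the toward-mean orientation keeps
the sample's own SPAD deviation from cancelling the planted residual.

**What the generator does not emulate.** Canopy/BRDF geometry,
variety- or nitrogen-specific spectral responses beyond their effect on
the SPAD distribution, instrument splice artifacts, wavelength
miscalibration, and real absorption fine structure (water bands,
carotenoids). Passing recovery and signal benchmarks therefore shows
the pipeline is correct and sensitive under its stated assumptions, not
that real field data will reach the same numbers — synthetic spectra
are cleaner than field spectra, and the model metrics here (test
R² ≈ 0.95) sit correspondingly above typical field results
(R² ≈ 0.6–0.7).

## Outlier screening

Both rules run per group, and the union of flags is removed as pairs.

*K-means SPAD rule.* K-means (Euclidean) on the univariate SPAD values,
default k = 1, where the rule degenerates to the distance-to-mean rule;
distances to assigned centres are pooled and a point is flagged if its
distance exceeds mean + 2·SD (SD with n−1). With all values equal the
SD is zero and the strict inequality flags nothing.

*Monte-Carlo PLSR rule.* The PLSR component count minimises 10-fold CV
RMSE, capped at 20. Per-fold predictions for every candidate count come
from a single maximal fit: NIPALS components are computed sequentially,
so the first k components of a 20-component model equal a k-component
model (coefficients rotations[:, :k] @ loadings[:, :k].T; verified to
machine precision against refits). Then 1000 iterations (tests and the
acceptance script use 200) each fit PLSR on a random 80% subset without
replacement and record every sample's absolute residual — all samples
by default; a `holdout_only` flag restricts to held-out samples. A
sample is flagged when its mean |residual| exceeds mean + 3·SD of the
per-sample statistic. If the largest statistic is below 1% of the
response SD the residuals are solver slop from a near-exact fit and
nothing is flagged. Fixed seed ⇒ fixed flags.

Under joint contamination, gross SPAD errors dominate the residual
spread and can mask subtler spectral mismatches (the SPAD screen still
removes them); the recovery benchmarks therefore plant one anomaly type
at a time, and re-screening after exclusion is the recommended practice
on real data.

## Preprocessing

SG smoothing (window 15, polyorder 2 — suited to 1 nm sampling of a
3 nm-resolution instrument; edge windows fit the truncated polynomial)
always leads a chain; SNV standardises each spectrum to mean 0 / SD 1
(n−1 denominator everywhere in this package); detrend subtracts a
degree-2 least-squares polynomial of wavelength (computed on a centred,
scaled axis for conditioning); MSC regresses each spectrum on a
reference over bands and returns (x − a)/b. The standard chains are SG,
SG-SNV, SG-SNV-DT and SG-MSC. MSC references default to the group mean
spectrum and are stored on the chain after fitting so held-out data can
be transformed with the calibration reference — avoiding leakage even
though scatter correction is nearly fit-free. SNV and MSC both remove
pure gain/offset corruption exactly in the noise-free case (SNV by
affine invariance, MSC by construction).

## Indices and screening

The 21 indices are computed from the (possibly preprocessed) spectra at
the nominal bands 450/550/670/720/800 nm (nearest grid point, ties to
the lower wavelength). Published formula variants are kept verbatim —
SAVI with the 2.5 factor and +0.5 term, CCI2 with +0.1, PVI as a
difference of sums — because screening results are defined by the
printed forms. Denominators with magnitude below 1e-10 yield NaN
(masked) rather than an exception, since SNV/detrended spectra
legitimately cross zero; masked entries are dropped listwise in
correlations and masked columns are dropped (and logged) before the
random forest. Pearson r uses the product-moment formula; strength
classes bin |r| at 0.3/0.5/0.8 with boundaries assigned to the lower
class; the classes are descriptive magnitude bins, not hypothesis
tests, so no p-values or multiplicity control are attached. Optimal
selection takes the argmax of |r| per group with deterministic
tie-breaks (fewer masked samples, then lexicographic feature name),
with ties recorded.

## Partitioning and models

*SPXY.* Normalised Euclidean distances in X and in y are summed
(d = dX/max dX + dY/max dY); the training set seeds with the pair at
maximum combined distance and grows by farthest-point selection
(maximin) until it holds round(0.8·n) samples. The sweep is
deterministic and permutation-invariant up to exact distance ties,
which break toward the lower index. A brute-force re-implementation
validates the full selection trace on small fixtures.

*Single-index fits.* Linear and quadratic by ordinary least squares;
exponential y = a·e^{bx} and power y = a·x^b by nonlinear least squares
initialised from the log-linearisation, keeping errors additive on the
SPAD scale rather than multiplicative on the log scale. The power form
returns a `not_fittable` status when the index takes non-positive
values (a real-exponent power law is undefined there), as does any NLS
convergence failure. Metrics are in-sample, matching how single-index
function fits are conventionally reported.

*Random forest.* ŷ = (1/T) Σ fₜ(x) over the 21 indices. The search
covers T ∈ {5, 10, 50, 100, 200, 500, 1000} × mtry ∈ 1…⌊2p/3⌋, scored
by out-of-bag R² on the SPXY training partition — OOB was chosen over
k-fold CV because it is RF-native, needs one fit per grid point, and
selects equivalent optima; very small forests that fail OOB coverage
simply score poorly. Ties break toward the smaller forest. Train and
test metrics are reported for the refitted winner; a fixed seed makes
the whole report reproducible.

## Evaluation statistics

R² is the squared Pearson correlation of predicted vs. actual — not
1 − SSE/SST. The two coincide for unbiased least-squares fits but the
correlation form is invariant to affine miscalibration of the
predictions; the difference is documented because it flatters
offset-biased predictors. RMSE uses the n denominator. RPD divides the
actual values' SD (n−1) by RMSE; capability classes are binned at
1.0/1.4/1.8/2.0/2.5 with boundary values assigned to the lower class
(the published class table uses strict inequalities and leaves
boundaries unassigned; a perfect fit with RMSE 0 maps to infinite RPD
in the top class). Group summaries report n, max, min, mean, SD and
CV% = 100·SD/mean, rounded to one decimal in presentation tables only.
Relative SPAD (plot ÷ high-nitrogen control) calls for topdressing
below 0.95 and declares sufficiency at or above it.

## Problem sizes and numerical choices

Tests and the acceptance script run the screening benchmarks at one
300-leaf group with 5% contamination and 200 Monte-Carlo iterations,
and the end-to-end screening/modelling at 120 leaves per group — sizes
chosen to exercise every code path at comfortable statistical power
while keeping a full run in seconds to minutes. Determinism is enforced
throughout: every stochastic step (generation, CV folds, Monte-Carlo
subsets, forests) takes an explicit seed, and re-running any stage with
the same inputs reproduces its outputs bit for bit.

## Known limitations

The MC-PLSR screen detects spectrum–SPAD inconsistency, not X-space
leverage; gross but y-consistent spectral corruption (pure gain errors)
calls for a complementary leverage/Mahalanobis screen, which is out of
scope here. Single-pass thresholding is vulnerable to masking at high
contamination (the per-sample statistic's SD is itself inflated by
outliers); the benchmarks stay at 5% per type, where the rule operates
comfortably. The squared-correlation R² can overstate accuracy for
biased predictors — RPD and RMSE are reported alongside for that
reason. The generator's cleanliness upper-bounds attainable metrics;
comparisons to field studies should be qualitative (which indices win,
which stages are sensitive), not numeric.
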