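# Methods

## Scope and data model

The package analyzes urinary CE-MS peptidome cohorts. The atomic
observation is a *signal* — one (m/z, charge, intensity) measurement in one
spectrum; a *peak* is one deconvoluted peptide in one sample (neutral
monoisotopic mass in Da, normalized CE migration time in min, normalized
amplitude); the central container is the *peptide matrix*, a peptide ×
sample amplitude table with consensus mass/time per peptide, in which an
amplitude of 0 (or a blank cell on disk) means "not detected". A peptide's
*frequency* in a sample group is the fraction of that group's samples in
which it is detected. All artifacts are plain TSV (CSV by flag), UTF-8,
`.` decimal point, and every writer/reader pair round-trips bit-exactly
(amplitudes and coordinates are serialized with shortest-repr formatting
and parsed with exact float conversion).

## Per-sample preprocessing

**Noise filter.** A signal is retained when its charge is ≥ 2, its
signal-to-noise ratio (intensity / noise level) is ≥ 4, and it belongs to a
trace of ≥ 3 consecutive spectrum indices at matching m/z (20 ppm trace
tolerance) and equal charge. Boundary readings are literal: S/N = 4.0 is
kept, a 2-spectrum trace is not.

**Charge deconvolution.** Neutral mass M = z·(m/z − 1.00728) with the
proton mass constant 1.00728 Da. Signals agreeing in M within 25 ppm
(charges ≤ 6; 100 ppm above, where isotopic resolution is lost) and in
migration time within 0.5 min merge into one peak; the merged amplitude is
the *sum* of intensities (total signal is conserved, which gives a testable
invariant), mass and time are intensity-weighted means. The merge sweeps
peaks in mass order against the running consensus of open clusters and is
idempotent. Probabilistic isotope-pattern scoring is intentionally out of
scope; the deconvolution operates on monoisotopic sticks.

**CE-time calibration.** Calibrant peptides with known migration times are
located by mass (50 ppm, nearest-time tie-break); a tricube-weighted local
*linear* regression (span 0.3 of the anchors, at least 2 per fit, 2
bisquare robustness iterations) maps observed to canonical time and is
applied to every peak. The smoother reproduces any globally affine
distortion exactly, so constant offsets and linear stretches are removed to
numerical precision; the mean absolute residual over calibrants is the QC
quantity. A robustness-iteration subtlety: when the fit is numerically
perfect the median residual is floating-point noise, so residual scales
below 1e-9 of the data scale skip the bisquare reweighting. Fewer than 5
matched calibrants raises a calibration error — the sample is flagged, not
silently passed.

**Amplitude normalization.** Housekeeping peptides — peptides with small
relative SD across subjects — anchor the intensity scale. The default
(global) mode multiplies every amplitude by the median of
canonical/observed over matched housekeeping peptides, which removes a
per-sample dilution factor exactly and is scale-equivariant. The lowess
mode regresses the log10 ratio on migration time with the same local
smoother and corrects pointwise (falling back to the global mode below 3
matches). No housekeeping match raises a normalization error.

**QC gate.** A sample passes when ≥ 950 peptides were detected over a
migration span of ≥ 10 min with a mean calibration residual strictly
< 0.35 min; failures carry explicit reasons. The 0.35-min rule is applied
per sample; cohort-level reporting simply aggregates the per-sample
residuals.

## Cross-sample clustering

Peaks of different samples are the same peptide when the mass deviation is
≤ 50 ppm for small peptides (≤ 4 kDa — the small/large boundary is not
fixed by the underlying technology description, so it is configuration with
a 4 kDa default near the center of the 0.8–20 kDa working range) or
≤ 75 ppm for larger ones, and the migration-time deviation is within a
relative half-window that widens linearly from 2% of the time at 19 min to
5% at 45 min (clamped outside), reflecting diffusion-driven CE peak
broadening. The algorithm pools all peaks, sorts by (mass, time,
−amplitude, sample) — making the result independent of sample order — and
sweeps once, assigning each peak to the nearest open cluster (normalized
Δmass/Δtime Euclidean distance) whose consensus window contains it, else
founding a new cluster; consensus mass/time are amplitude-weighted means.
One peak per sample per cluster: the largest amplitude wins and drops are
counted, so assigned + dropped = input (conservation invariant). The
deposit filter then keeps peptides with detection frequency strictly
> 20% (overall, or in any group by option).

## Statistics

**Discovery test.** Per peptide, a Welch two-sample statistic on the base-10
logarithms of the *detected* amplitudes, with p-values from the standard
normal — the Gaussian approximation to the t reference. Only peptides
detected in ≥ 50% of at least one diagnostic group are tested (both-groups
scope by option); a gated peptide with < 3 detected values in a group is
marked untestable rather than raising. Zero pooled variance with equal
means gives p = 1, with unequal means p = 0. An exact Welch–Satterthwaite
*t* reference is available (`reference="t"`). The normal reference is
mildly anti-conservative at double-digit group sizes: on replicate
synthetic discovery cohorts (68 + 42 subjects, 10% true effects,
independent peptides) it yields an empirical false-discovery proportion of
≈ 0.059 after Benjamini–Hochberg at 0.05, whereas the identical pipeline
with the t reference is calibrated (≈ 0.044, and a complete-null
any-discovery rate of ≈ 0.04). The package implements the normal reference
as the default because it is the procedure the pipeline models; the t
reference exists both as the statistically calibrated option and as the
dual-route check that localizes the inflation in the reference
distribution rather than in the BH machinery.

**Multiple testing.** Benjamini–Hochberg step-up adjustment (via
statsmodels) with monotone adjusted q-values; discoveries are q ≤ 0.05.
Report ordering is deterministic: ascending q, then p, then peptide id.

**Covariate exclusion.** Candidates whose abundance depends on a clinical
covariate (age, diabetes duration) are screened by a Kruskal–Wallis test
across covariate quartile bins (quantile binning is the minimal-assumption
way to feed a continuous covariate to a rank ANOVA; the bin count is
configuration). The test uses detected-sample amplitudes only, the same
convention as the discovery test — including non-detected zeros floods the
ranks with covariate-independent mass and collapses the screen's power
(measured: 64% vs 97% of designed age-correlated peptides caught at a 0.02
log10/yr slope, n = 110). Exclusion is p < 0.05 (strict, matching the
screening convention), and a constant covariate is a hard error.

*Confounding trade-off.* When the covariate is strongly confounded with the
diagnostic contrast — T1D subjects are ~20 years younger than T2D by study
design — the pooled screen also removes genuine type markers whose group
effect masquerades as an age trend: on the default synthetic design most
designed type-differential candidates are excluded along with all designed
age-correlated ones. This conservatism is inherent to covariate screening
under near-total confounding and is the reason the workflow reports
discovery recovery and exclusion rates separately; panels may equally come
from prior studies and be validated here, which sidesteps the screen.

**Validation test.** Panel peptides are re-tested in independent cohorts
with a two-sided Mann–Whitney U on amplitudes *including* zeros (rank
methods tolerate the point mass at the bottom rank). Exact p-values for
combined n ≤ 25 without ties; exact enumeration over group assignments
(extremeness by |U − mn/2|, ties counted half) for tied inputs with
combined n ≤ 14; tie-corrected normal approximation otherwise. All-equal
input returns p = 1. Significance is p ≤ 0.05 (inclusive, the reporting
convention for validation counts). The same engine backs between-group
score comparison.

**Regulation factor.** Signed fold change of group B relative to group A on
linear-scale means over detected samples: `F = mean_B/mean_A` if B is up,
`−mean_A/mean_B` if down, 1 at equality, NaN (flagged) at a zero mean. By
construction |F| ≥ 1 and F is antisymmetric under group swap.

**Logistic confounder assessment.** Maximum-likelihood logistic regression
(statsmodels, Newton, 100 iterations) of the binary diagnosis on clinical
covariates, jointly or one at a time; complete/quasi-separation and
non-convergence are flagged explicitly (detected via fit failure or
exploding coefficients) instead of reporting silently divergent estimates.
Rows with missing covariates are dropped and counted.

## Classification and evaluation

The panel classifier is a linear soft-margin SVM (scikit-learn SVC,
C = 1.0 default) on `log10(amplitude + 1)` features standardized with
training-set mean/SD; the transform constants live in the model so scores
reproduce bit-identically, including from the plain-text model file. A
peptide missing from a sample enters as amplitude 0. The *SVM score* is the
signed Euclidean distance `(w·x + b)/‖w‖` to the maximal-margin hyperplane
— invariant to uniform rescaling of (w, b); the alphabetically larger class
label sits on the positive side. Cross-validation is stratified k-fold,
seed-reproducible, each sample scored exactly once by a model that never
saw it.

ROC analysis enumerates all distinct thresholds; the AUC equals the
Mann–Whitney concordance probability with ties counted half (asserted as an
internal identity against trapezoidal integration). Confidence intervals
use the DeLong placement-value variance estimator with a normal-theory
interval clipped to [0, 1]; Hanley–McNeil is available as an alternative.
Over 500 simulated null cohorts (50 + 50) the 95% interval covers
AUC = 0.5 at the nominal rate (93–97% band). Degenerate all-equal scores
yield the uninformative [0, 1] interval with a warning. Score summaries use
the linear-interpolation quartile convention (numpy default), which matters
when medians/IQRs are compared against printed values.

Renal-status classification is the explicit rule ACR > 30 µg/mg or
GFR < 60 (strict inequalities: a subject at exactly 30 and 60 is
normoalbuminuric), with GFR estimated by Cockcroft–Gault,
`(140 − age)·weight / (72·creatinine)`, ×0.85 for women — a creatinine
clearance used as a GFR proxy, deliberately without body-surface-area
renormalization; negative estimates (age > 140) clamp to 0 with a warning.
Discovery/validation splitting is stratified with largest-remainder
rounding, exhaustive, disjoint and seed-reproducible.

## Synthetic cohorts

The generator emulates the study conditions end to end. Subjects: T1D age
~ N(43, 11²), T2D ~ N(63, 9²), controls ~ N(40, 10²) years; diabetes
duration N(27, 10²)/N(11, 8²) years (clipped), reproducing the
age/duration confounding the covariate screen must handle; ACR/GFR and the
remaining covariates are drawn at normoalbuminuric levels. Peptides: 1500
by default, masses log-uniform over 0.8–20 kDa, migration times uniform
over 19–45 min (the clustering window's domain), per-peptide baseline
log10-amplitude uniform in [2, 5]. Amplitudes are log10-normal with
per-peptide SD 0.4 — a mid-range inter-individual spread for urinary
peptides; designed differential peptides shift the group mean by ±0.5 log10
(sign Bernoulli 0.5), age-correlated peptides drift at 0.02 log10/yr around
the cohort mean age; 29 housekeeping peptides have 5% linear CV before
dilution and are always detected, as are the 10 calibrants. Detection is
Bernoulli thinning at a per-peptide frequency uniform in [0.5, 1.0] —
high-prevalence peptides, consistent with a matrix that has already passed
the > 20% deposit filter and feeds a ≥ 50% testing gate. Each sample
carries a shared dilution factor (SD 0.3 log10) and a constant
migration-time offset (SD 0.5 min) for the normalization and calibration
stages to remove; measurement noise is 10 ppm mass and 0.1 min time jitter
per peak. Raw signal tables emit each detected peptide as 1–3 charge
states in z ∈ {2..6} (concentrated-Dirichlet amplitude shares so no share
vanishes below the S/N gate) over 3 consecutive spectra with a triangular
intensity profile, at 20 spectra/min, plus injected sub-threshold and
singly charged contaminant signals. Everything derives from one integer
seed; identical seeds give byte-identical serialized outputs.

What the generator does *not* emulate: isotopic envelopes (monoisotopic
sticks only), intensity-dependent detection (optional stress mode is out of
the defaults; real non-detection correlates with low abundance),
heavy-tailed amplitude outliers, batch/center effects, and correlated
peptide families (fragments of one parent protein co-vary in real urine).
Passing tests therefore demonstrate correctness of the computational
pipeline under its stated model, not robustness to every artifact of real
instruments.

## Reproduction script

`scripts/acceptance.py --seed S --out results/acceptance.json` regenerates
the package's calibration headline from scratch: 200 replicate discovery
cohorts (110 subjects split 68/42, 1500 independent peptides — dilution off,
as independence requires — 150 truly differential at 0.5 log10), the
frequency-gated Gaussian-reference discovery test plus Benjamini–Hochberg
at 0.05 per cohort, and the false-discovery proportion averaged over
replicates with non-empty discovery sets (key `t10`). As discussed above,
this measured value sits near 0.059 — above the nominal 0.05 of the
Gaussian-reference procedure, by the reference-distribution approximation
alone; the calibrated t-reference variant of the same pipeline achieves
0.044. Problem sizes throughout the test suite (cohorts of 45–218 subjects,
120–1500 peptides, 200-replicate batteries) were chosen as the smallest
designs at which the studied contrasts and error rates are stable.

## Known limitations

- The de-novo sweep clustering can fragment a peptide whose time scatter
  approaches the 2% window at early migration times; at the default noise
  (0.1 min) recovery is 1:1, at 0.2 min a few percent of peptides split
  into a main cluster plus a satellite (the satellite still lies within the
  match window of the true peptide).
- Mann–Whitney exactness for tied inputs is limited to combined n ≤ 14 by
  enumeration cost; beyond that the tie-corrected normal approximation is
  used even below n = 25.
- The logistic separation flag is heuristic (fit failure or |coef| > 50);
  it has no false negatives on the tested designs but is not a formal
  separation test.
- Reproducing published AUC confidence intervals exactly depends on the
  original software's CI construction, which is not documented; DeLong is
  the package's default and Hanley–McNeil the alternative.
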