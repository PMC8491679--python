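# Methods

This package implements a longitudinal analysis that couples voxel-wise
BOLD signal variability, multivariate brain–behavior modeling, and a
spatial-PCA index of functional integration, exercised end to end on
synthetic cohorts with planted ground truth.  This note documents the
models, the generator, the numerical choices, and what the tests do and do
not establish.

## Signal conditioning and SD_BOLD

Each subject-occasion contributes a voxels × timepoints matrix sampled at
TR = 2.5 s (200 volumes by default).  Conditioning proceeds in a fixed
order:

1. **Volume discard** — the first 4 volumes (10 s) are dropped.
2. **Polynomial detrending** — a least-squares polynomial of order ≤ 2 is
   removed per voxel; the residual is orthogonal to the polynomial basis.
3. **Band-pass filtering** — a zero-phase (forward–backward) Butterworth
   band-pass at 0.01–0.10 Hz.  The `order` parameter (default 8) is the
   design order handed to `scipy.signal.butter`; note that a band-pass
   design of order N realizes 2N poles, and forward–backward application
   doubles the effective attenuation once more.  Zero-phase filtering was
   chosen so that the temporal dynamics entering the variability and
   integration measures carry no phase distortion; the cost is the doubled
   attenuation order, which is documented rather than hidden.  Edge
   transients are controlled by reflect padding (`padtype='even'`); series
   must exceed the pad length (49 samples at the default order).

**SD_BOLD** is the per-voxel standard deviation of the conditioned series,
with the population divisor N by default so that SD² equals the mean power
of the demeaned series exactly — SD_BOLD is then the square root of the
total non-DC spectral power under the matched normalization
Σ|X_k|²/N² (Parseval; verified to 1e−6 relative tolerance in the tests).
The divisor is a switch (`ddof`).  Longitudinal change is the Time 2 −
Time 1 difference per voxel.

The high-frequency noise screen computes, from a periodogram of the
demeaned series, the fraction of non-DC power above a cutoff (default
0.10 Hz); a series is flagged when the fraction reaches 0.75.  DC is
excluded from "total power" because a mean offset carries no dynamics;
the periodogram convention (demeaned, boxcar window) is fixed here since
reasonable alternatives move the fraction by far less than the 0.75
decision margin in practice.

Voxels with zero variance at either occasion are dropped from all
subjects' analyses — the stand-in for a common-activation mask.

## Cognitive and metabolic component scores

The battery has 16 indicators over five domains (fluid intelligence ×4,
vocabulary ×1, episodic memory ×3, working memory ×4, perceptual speed
×4); reaction-time and error indicators carry `lower_better` direction
flags and are never pre-negated — downstream code must (and does) handle
direction explicitly.  Per domain, the first principal component of the
**standardized** indicators is extracted (correlation-based PCA, the only
defensible scaling for mixed units of items, errors, and milliseconds),
separately for Time 1, Time 2, and Time 2 − Time 1 difference scores
(change scores are PCA'd directly, not differenced component scores).
Scores are unit-variance with sign fixed so that the mean
direction-aligned loading is positive (higher = better); the orientation
rule is deterministic.  Missing data are handled listwise within domain;
cross-domain assembly keeps the union with explicit missing markers, and
the PLS stage drops incomplete rows.

Metabolic risk uses five indicators (systolic blood pressure, fasting
glucose, fasting triglycerides, HDL cholesterol, waist-to-hip ratio):
one PC from baseline values, one from raw longitudinal change scores,
both oriented so that higher = higher risk (HDL, the protective
indicator, aligns negatively).  Subjects missing any indicator are
dropped listwise.

## Behavioral PLS

The longitudinal model correlates voxel-wise SD_BOLD change with the five
change-based domain scores plus the retest interval in years ("age
change"), across subjects:

    CORR[b, v] = Pearson r(behavior_b, ΔSD_BOLD_v),   CORR = U S V′.

Latent variables are ordered by singular value; the SVD sign
indeterminacy is resolved by making the largest-magnitude behavior
salience positive per LV.

* **Permutation test** — behavior rows are shuffled jointly over subjects
  (preserving inter-behavior correlation, the standard exchangeability
  argument), n_perm = 1000 by default; p_k = (1 + #{S_perm,k ≥ S_obs,k}) /
  (n_perm + 1) (add-one convention, so p never reaches 0).  Permuted
  singular values are compared per LV without rotation; under a true null
  LV1's statistic is exchangeable with its permutation distribution, so
  LV1 p-values are calibrated (verified over 200 null cohorts), while
  later LVs inherit the usual max-statistic conservatism.
* **Bootstrap** — subjects resampled with replacement (n_boot = 1000);
  each resample's SVD is aligned to the original by an orthogonal
  Procrustes rotation (identity when the resample equals the original);
  resamples with a constant column are redrawn and counted.  The
  bootstrap ratio is the original V element over the bootstrap SE of that
  element (a switch allows the bootstrap-mean numerator), thresholded at
  ±3.00 (beyond the two-sided 99.5% normal critical value 2.807);
  threshold inclusion is inclusive at the boundary.  Behavior weights get
  95% percentile CIs; a weight is "bootstrap-stable" when its CI excludes
  zero.
* **Scores** — brain scores P·V and behavior scores Q·U are computed from
  column-standardized blocks, consistent with the correlation-based
  decomposition; the latent correlation (Pearson and Spearman) between
  the two LV1 score vectors summarizes the coupling.  Both saliences and
  score-level correlations are emitted, since bar-plot conventions differ.

## Functional integration

Integration of a voxel set is the percent variance explained by the first
eigenvalue of the voxel × voxel Pearson correlation matrix over
timepoints ("spatial PCA"): 100·λ₁/p, bounded below by 100/p.  The
correlation (not covariance) matrix is used so that amplitude (SD_BOLD)
and integration are separable measurements.  When the set has more voxels
than timepoints the spectrum is computed from the temporal Gram matrix of
the standardized series (identical nonzero eigenvalues; both routes agree
to 1e−8 where feasible).  Change is the Time 2 − Time 1 difference in
that percentage.  The suprathreshold set defaults to the union of
positive and negative |BSR| ≥ 3 voxels (a `positive`-only switch exists,
and outputs are flagged with the choice).

Spatial specificity is probed by re-computing integration change on (a)
100 random subthreshold samples matched in size to the suprathreshold set
(equating estimable dimensionality), summarized by the sample with the
smallest cumulative |distance| to each subject's median change (ties →
lowest sample index; a squared-distance variant is a config switch), and
(b) the equally sized subthreshold set farthest from threshold, i.e. with
the smallest |BSR| (ties → lowest voxel id).  Correlations of integration
change with the cognition/age score share that score, so set-to-set
comparisons use Steiger's (1980) Z for dependent correlations with one
variable in common, in the mean-correlation (Z̄₁*) form:

    rbar = (r1 + r2)/2
    s    = [r12(1 − 2·rbar²) − rbar²(1 − 2·rbar² − r12²)/2] / (1 − rbar²)²
    Z    = (z1 − z2) · sqrt((n − 3) / (2(1 − s)))

with z the Fisher transform and a two-sided normal p.

## Covariate controls and coverage

The control analysis regresses the LV1 brain score on the LV1
cognition/age score plus baseline and change-in metabolic risk (OLS; a
robust-SE variant exists but is off by default, keeping the plain
construction).  Influence is screened with Cook's distance against the
4/n rule; flagged cases are held out and the model refit **once** (not
iteratively — the simplest reading of a single screen), with the
threshold displayed truncated to three decimals (4/68 → "0.058").
Cook's D from the leverage closed form equals the leave-one-out refit
definition to 1e−8 on toy problems.

Parcel coverage takes any integer label volume on the mask grid and
reports, per parcel, the count and percentage (nearest-integer display,
exact fraction retained) of its voxels present in the suprathreshold set.

## The synthetic cohort generator

The generator is first-class, tested code; its defaults define the study
conditions everywhere (tests, acceptance, analysis scripts).

* **Design** — 74 subjects × 2 occasions; 200 volumes at TR 2.5 s; retest
  interval uniform on 1.92–3.91 years; 16 cognitive indicators in five
  domains; 5 metabolic indicators; default mask of 1000 voxels with 250
  effect voxels (the effect fraction ≈ 25% mirrors a suprathreshold map
  covering roughly a fifth to a quarter of analyzed voxels); a 20-subject
  × 300-voxel preset (`fast_preset`) serves fast tests.
* **Imaging model** — x_v(t) = a_v·c(t) + e_v(t), where c(t) is white
  noise band-passed by the same zero-phase Butterworth design the
  pipeline uses (unit SD; < 5% of power outside 0.01–0.10 Hz), and e_v is
  white noise with SD `noise_sd` = 1.  Effect voxels have occasion-2
  loading a_v = 1 + 0.5·f (subject factor f ~ N(0,1)); all other loadings
  are 1.  SD change over the effect set is therefore (approximately
  linearly) tied to f, and pairwise effect-voxel correlation rises and
  falls with the same factor — amplitude change and integration change
  are two faces of one planted latent, mirroring the empirical coupling
  of variability loss with integration loss.  The default gain 0.5 puts
  the per-voxel change effect clearly above SD-estimation noise at 196
  retained volumes while keeping occasion-2 loadings positive over
  essentially the whole factor range.
* **Behavior model** — cognitive change factor g = ρ·f + √(1−ρ²)·ε with
  planted coupling ρ (`coupling_rho`, default 0.6).  Indicator change
  scores are g plus unit-SD indicator noise, scaled into each test's
  natural units (0.3 × its cross-sectional SD) and direction (RT/error
  indicators worsen upward).  Baseline levels load on a separate factor.
  Metabolic indicators follow their own baseline/change factors,
  independent of f and g — a true null covariate.  The equal-weight
  composite of p standardized change indicators correlates with g at the
  closed-form attenuation 1/√(1 + σ²/p) (≈ 0.97 at defaults).
* **Attenuation-adjusted recovery target** — `attenuated_latent_r`
  Monte-Carlos, at large n, the correlation between the mean effect-voxel
  SD change (through the real conditioning chain, so SD-estimation noise
  is included) and the equal-weight cognitive change composite.  No SVD
  or estimated weighting is involved, so the target is independent of the
  PLS path.  At defaults it is ≈ 0.57 for ρ = 0.6; the in-sample PLS
  latent r additionally carries a small optimistic bias (≈ +0.06 at
  n = 74) from fitting voxel weights on the same subjects, which the
  recovery tolerance absorbs.

**What the generator does not emulate** — scanner physics, head motion,
physiological noise spectra, spatial smoothness and autocorrelation,
manual ICA denoising inputs, site/sequence effects, and non-Gaussian
indicator distributions.  Passing tests therefore establish that the
estimators recover planted structure of this idealized form at realistic
sizes and noise levels — not that real acquisitions carry such structure.

## Problem sizes used in tests and acceptance runs

Simulation-heavy checks use, as this package's own study conditions:
permutation calibration on 200 null cohorts of the 20 × 300 preset with
200 permutations; parameter recovery on 50 cohorts of 74 subjects at the
300-voxel preset with 200 permutations/bootstraps; spatial specificity on
50 replicates of 30 subjects × 300 voxels with 10 matched random sets
each.  The acceptance script runs the full default cohort (74 × 1000)
with the study's 1000 permutations, 1000 bootstraps, and 100 random
voxel samples.

## Known limitations

* Latent correlations are in-sample and optimistically biased at small n;
  no cross-validated variant is provided.
* Permutation inference beyond LV1 is conservative (max-statistic).
* The linearization of SD change in the subject factor degrades for
  |gain·f| approaching the base loading.
* The generator's voxels are exchangeable within effect/null sets; there
  is no spatial structure, so parcel coverage on synthetic labels is a
  plumbing demonstration, not a spatial claim.
* Cook's screening is done once on the initial fit; an iterative screen
  would flag different cases in adversarial configurations.
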