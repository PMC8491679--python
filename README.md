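# boldvar

Longitudinal coupling of brain signal variability, functional integration,
and cognitive change — as a tested, reusable pipeline exercised end to end
on synthetic cohorts with planted ground truth.

## The problem

Moment-to-moment variability of the resting-state BOLD signal (SD_BOLD,
the per-voxel standard deviation of the conditioned time series) behaves
as a functional marker of brain aging: older, lower-performing adults tend
to express less of it.  Testing whether *changes* in SD_BOLD track
*changes* in cognition over a few years requires a longitudinal
change–change analysis: voxel-wise SD_BOLD change on one side, change-based
cognitive component scores (plus retest interval, i.e. "age change") on
the other, linked by multivariate behavioral partial least squares (PLS),
and complemented by a spatial-PCA index of functional integration over the
implicated voxels.  This package implements that full analysis — signal
conditioning, SD_BOLD, per-domain PCA component scores, behavioral PLS
with permutation and bootstrap inference, the integration index with its
spatial-specificity resampling analysis, metabolic-risk covariate
controls, and parcel-coverage reporting — for methodologists who want to
study the estimators' behavior under known ground truth, since cohort data
of this design are not openly deposited.

## The model

Given subjects × voxels SD_BOLD changes ΔP and subjects × behaviors
change scores Q, the between-subject correlation matrix is decomposed by
SVD:

    CORR[b, v] = r(Q_b, ΔP_v),      CORR = U S V′

Each latent variable (LV) pairs behavior saliences (column of U) with
voxel saliences (column of V) at strength S_k.  Inference:

* singular values are tested with 1000 joint-row permutations of the
  behavior block, p = (1 + #{S_perm ≥ S_obs}) / (n_perm + 1);
* robustness comes from 1000 subject-level bootstrap resamples,
  Procrustes-aligned to the original decomposition; each voxel's
  **bootstrap ratio** BSR = V element / bootstrap SE is thresholded at
  ±3.00 (beyond the 99.5% two-sided normal critical value ≈ 2.807);
* per-subject **brain scores** P·V and **cognition/age scores** Q·U yield
  the LV's latent correlation.

**Functional integration** of a voxel set is the percent variance
explained by the first principal component of the voxel × voxel
correlation matrix over timepoints (100·λ₁/p); its Time 2 − Time 1 change
is compared across the suprathreshold set, 100 size-matched random
subthreshold samples, and the subthreshold set farthest from threshold,
with Steiger's Z for dependent correlations.

The synthetic generator plants a subject-level change factor that jointly
drives effect-voxel SD change, effect-voxel co-fluctuation (integration)
change, and a cognitive change factor at a chosen coupling ρ, so every
stage has a recoverable target.  See `docs/methods.md` for details.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic cohort (74 subjects × 2 occasions, 1000 voxels of which 250
carry the planted effect, 200 volumes at TR 2.5 s, planted change–change
coupling ρ = 0.6):

```bash
python analysis/01_simulate_cohort.py --seed 0     # writes results/cohort/
python analysis/02_condition_and_sdbold.py
python analysis/03_cognitive_components.py
python analysis/04_pls_change_change.py --seed 0
python analysis/05_functional_integration.py --seed 0
python analysis/06_controls_and_coverage.py
```

Output of the PLS step:

```
LV1: singular value 20.236, permuted p = 0.000999
LV1 latent r = 0.673 (Pearson), 0.650 (Spearman)
bootstrap-stable behaviors: ['Gf_change', 'Gc_change', 'EpisodicMemory_change',
 'WorkingMemory_change', 'Speed_change', 'retest_interval_years']
|BSR| >= 3 voxels: 253 (recall of planted effect set: 1.00)
```

One latent variable dominates (permutation floor p = 1/1001): subjects
losing SD_BOLD in the effect voxels decline on the cognitive composite.
The |BSR| ≥ 3 map recovers all 250 planted voxels (plus 3 false alarms of
750 null voxels).  The latent r of 0.67 sits above the generator's
attenuation-adjusted population target (≈ 0.57) by the expected in-sample
optimism of PLS at n = 74.

Output of the integration step:

```
FI change vs SD_BOLD-change brain score: r = 0.964
FI change vs cognition/age score: suprathreshold r = 0.627,
  representative r = 0.035, farthest r = 0.112
Steiger Z (supra vs representative) = 3.87, p = 0.0001086
```

Integration change over the suprathreshold set moves almost in lockstep
with SD_BOLD change (both are driven by the planted factor), correlates
with cognitive change where the effect lives, and the association
collapses on matched random subthreshold voxel sets — the planted effect
is spatially specific, and Steiger's Z confirms the dependent-correlation
difference.  The control step shows metabolic-risk components (null by
construction) do not explain the coupling, with the Cook's D > 4/n screen
(printed as 0.054 at n = 74) holding out 2 high-leverage cases.

## Layout

```
src/boldvar/        library: synthgen, signalprep, components, pls,
                    integration, controls, pipeline, cli, io
analysis/           numbered narrative drivers over the library
scripts/            acceptance.py
tests/              pytest suite (unit, property, acceptance)
docs/methods.md     models, assumptions, numerical choices, limitations
```

A `boldvar` console script exposes `simulate` and `all` (plus per-stage)
subcommands over the same pipeline.
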