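"""End-to-end orchestration: conditioning -> components -> PLS -> integration -> controls.

Two analysis modes mirror the study design:

* ``longitudinal`` (the primary model): between-subject correlations of
  voxel-wise SD_BOLD change (Time 2 - Time 1) with change-based cognitive
  domain component scores plus the retest interval ("age change"), followed
  by the functional-integration specificity analysis and metabolic-risk
  controls.
* ``cross_sectional``: SD_BOLD levels at each occasion against occasion
  cognitive component scores and age, stacked over subject-occasions.

Every random draw derives from the run seed recorded in the manifest.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import components as comp
from . import controls as ctrl
from . import integration as integ
from . import io as bio
from . import pls as plsmod
from . import synthgen
from .signalprep import condition, sd_bold_map, sd_change_map, hf_power_fraction

COGNITIVE_DOMAINS = ("Gf", "Gc", "EpisodicMemory", "WorkingMemory", "Speed")


@dataclass
class RunConfig:
    """All pipeline settings; defaults equal the emulated study's values."""

    out_dir: str = "results/run"
    cohort_dir: str | None = None           # existing on-disk cohort; else simulate
    n_discard: int = 4
    detrend_order: int = 2
    low_hz: float = 0.01
    high_hz: float = 0.10
    filter_order: int = 8
    n_perm: int = 1000
    n_boot: int = 1000
    bsr_threshold: float = 3.0
    n_fi_samples: int = 100
    fi_sign: str = "union"                  # union | positive: suprathreshold pool
    seed: int = 0
    synth: dict = field(default_factory=dict)  # SynthConfig overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def synth_config(self) -> synthgen.SynthConfig:
        params = dict(self.synth)
        params.setdefault("seed", self.seed)
        return synthgen.SynthConfig(**params)


@dataclass
class PrepResult:
    """Conditioned SD maps and their longitudinal change."""

    sd_t1: pd.DataFrame            # subjects x voxels
    sd_t2: pd.DataFrame
    sd_change: pd.DataFrame
    analysis_voxels: np.ndarray    # voxels retained (nonzero variance at both occasions)
    n_hf_noise_flagged: int


def prep_stage(cohort: synthgen.Cohort, config: RunConfig) -> PrepResult:
    """Condition every subject-occasion series and build SD / SD-change tables.

    Voxels with (near-)zero variance at either occasion in any subject are
    dropped from all analyses, standing in for the usual common-activation
    mask.  Raw series are also screened with the high-frequency power
    criterion (>= 75% of non-DC power above the band's upper edge).
    """
    subjects = cohort.truth.subject_ids
    sd = {1: {}, 2: {}}
    n_flagged = 0
    for sid in subjects:
        for occ in (1, 2):
            ts = cohort.series[(sid, occ)]
            # Noise screen on the raw mean series (cheap whole-scan summary).
            if hf_power_fraction(ts.values.mean(axis=0), ts.tr_seconds, config.high_hz) >= 0.75:
                n_flagged += 1
            cond = condition(
                ts,
                n_discard=config.n_discard,
                detrend_order=config.detrend_order,
                low_hz=config.low_hz,
                high_hz=config.high_hz,
                filter_order=config.filter_order,
            )
            sd[occ][sid] = sd_bold_map(cond)
    voxel_ids = next(iter(sd[1].values())).voxel_ids
    sd_t1 = pd.DataFrame({s: sd[1][s].values for s in subjects}, index=voxel_ids).T
    sd_t2 = pd.DataFrame({s: sd[2][s].values for s in subjects}, index=voxel_ids).T
    tiny = 1e-12
    keep = (sd_t1.min(axis=0) > tiny) & (sd_t2.min(axis=0) > tiny)
    analysis_voxels = np.asarray(voxel_ids)[keep.to_numpy()]
    sd_t1 = sd_t1.loc[:, keep.to_numpy()]
    sd_t2 = sd_t2.loc[:, keep.to_numpy()]
    sd_change = sd_t2 - sd_t1
    return PrepResult(
        sd_t1=sd_t1,
        sd_t2=sd_t2,
        sd_change=sd_change,
        analysis_voxels=analysis_voxels,
        n_hf_noise_flagged=n_flagged,
    )


def behavior_change_block(cohort: synthgen.Cohort) -> tuple[pd.DataFrame, list[comp.ComponentScores]]:
    """Change-based domain component scores plus retest interval ("age change")."""
    change = comp.change_table(cohort.behavior.t1, cohort.behavior.t2)
    scores = [comp.domain_component_scores(change, d) for d in COGNITIVE_DOMAINS]
    block = comp.assemble_score_block(
        scores, extra={"retest_interval_years": cohort.behavior.retest_interval_years}
    )
    return block.dropna(axis=0, how="any"), scores


@dataclass
class IntegrationResult:
    """Integration changes per voxel set and their coupling to the PLS scores."""

    fi_change: pd.DataFrame                # subjects x {supra, representative, farthest}
    r_supra: float
    r_representative: float
    r_farthest: float
    r_fi_vs_brain_score: float
    steiger_supra_vs_representative: tuple[float, float]
    steiger_supra_vs_farthest: tuple[float, float]
    supra_set: integ.VoxelSampleSet
    representative_set: integ.VoxelSampleSet
    farthest_set: integ.VoxelSampleSet
    random_set_r: np.ndarray               # r(FI change, cognition score) per random sample


def _fi_change_for_set(
    cohort: synthgen.Cohort, subjects: list[str], voxel_set: integ.VoxelSampleSet
) -> np.ndarray:
    out = np.empty(len(subjects))
    for i, sid in enumerate(subjects):
        p1 = integ.integration_profile(cohort.series[(sid, 1)], voxel_set)
        p2 = integ.integration_profile(cohort.series[(sid, 2)], voxel_set)
        out[i] = integ.integration_change(p1, p2)
    return out


def integration_stage(
    cohort: synthgen.Cohort,
    model: plsmod.PLSModel,
    subjects: list[str],
    config: RunConfig,
) -> IntegrationResult:
    """Spatial-PCA integration change on suprathreshold, matched-random and
    farthest-from-threshold voxel sets, with dependent-correlation tests."""
    pos, neg = plsmod.threshold_map(model.bsr, model.voxel_ids, config.bsr_threshold)
    supra_ids = np.sort(np.concatenate([pos, neg])) if config.fi_sign == "union" else np.sort(pos)
    if supra_ids.size < 2:
        raise ValueError("fewer than 2 suprathreshold voxels; integration undefined")
    supra = integ.VoxelSampleSet("suprathreshold", supra_ids, "suprathreshold")
    bsr1 = model.bsr[:, 0]
    sub_mask = np.abs(bsr1) < config.bsr_threshold
    pool = model.voxel_ids[sub_mask]
    size = min(supra_ids.size, pool.size)
    samples = integ.sample_matched_voxel_sets(
        pool, size=size, n_samples=config.n_fi_samples, seed=config.seed + 7
    )

    behav_sc = model.behavior_scores[:, 0]
    brain_sc = model.brain_scores[:, 0]

    fi_supra = _fi_change_for_set(cohort, subjects, supra)
    fi_samples = np.stack([_fi_change_for_set(cohort, subjects, s) for s in samples])
    rep = integ.representative_sample(samples, fi_samples)
    fi_rep = fi_samples[int(rep.sample_id.split("_")[1])]
    far = integ.farthest_subthreshold_set(bsr1, model.voxel_ids, size, config.bsr_threshold)
    fi_far = _fi_change_for_set(cohort, subjects, far)

    def _r(a, b):
        return float(np.corrcoef(a, b)[0, 1])

    r_supra = _r(fi_supra, behav_sc)
    r_rep = _r(fi_rep, behav_sc)
    r_far = _r(fi_far, behav_sc)
    n = len(subjects)
    z_rep = integ.steiger_z(r_supra, r_rep, _r(fi_supra, fi_rep), n)
    z_far = integ.steiger_z(r_supra, r_far, _r(fi_supra, fi_far), n)
    random_r = np.array([_r(fi, behav_sc) for fi in fi_samples])

    fi_change = pd.DataFrame(
        {
            "suprathreshold": fi_supra,
            "representative": fi_rep,
            "farthest_from_threshold": fi_far,
        },
        index=pd.Index(subjects, name="subject_id"),
    )
    return IntegrationResult(
        fi_change=fi_change,
        r_supra=r_supra,
        r_representative=r_rep,
        r_farthest=r_far,
        r_fi_vs_brain_score=_r(fi_supra, brain_sc),
        steiger_supra_vs_representative=z_rep,
        steiger_supra_vs_farthest=z_far,
        supra_set=supra,
        representative_set=rep,
        farthest_set=far,
        random_set_r=random_r,
    )


@dataclass
class ControlsResult:
    initial: ctrl.ControlModel
    filtered: ctrl.ControlModel
    metabolic_baseline: comp.ComponentScores
    metabolic_change: comp.ComponentScores


def controls_stage(
    cohort: synthgen.Cohort, model: plsmod.PLSModel, subjects: list[str]
) -> ControlsResult:
    """Metabolic-risk components and the covariate-control regression."""
    change = comp.change_table(cohort.behavior.t1, cohort.behavior.t2)
    base_pc, change_pc = comp.metabolic_risk_scores(cohort.behavior.t1, change)
    table = pd.DataFrame(
        {
            "brain_change_score": pd.Series(model.brain_scores[:, 0], index=subjects),
            "cognition_age_change": pd.Series(model.behavior_scores[:, 0], index=subjects),
            "metabolic_baseline": base_pc.scores,
            "metabolic_change": change_pc.scores,
        }
    )
    initial = ctrl.fit_control_regression(table)
    filtered = ctrl.cooks_filter(initial)
    return ControlsResult(
        initial=initial,
        filtered=filtered,
        metabolic_baseline=base_pc,
        metabolic_change=change_pc,
    )


@dataclass
class LongitudinalResult:
    prep: PrepResult
    behavior_block: pd.DataFrame
    model: plsmod.PLSModel
    integration: IntegrationResult
    controls: ControlsResult
    coverage: pd.DataFrame | None
    subjects: list[str]


def run_longitudinal(
    cohort: synthgen.Cohort,
    config: RunConfig,
    parcels: np.ndarray | None = None,
) -> LongitudinalResult:
    prep = prep_stage(cohort, config)
    block, _ = behavior_change_block(cohort)
    subjects = [s for s in cohort.truth.subject_ids if s in block.index]
    brain = prep.sd_change.loc[subjects].to_numpy()
    model = plsmod.behavioral_pls(
        brain,
        block.loc[subjects].to_numpy(),
        behavior_labels=list(block.columns),
        voxel_ids=prep.analysis_voxels,
        n_perm=config.n_perm,
        n_boot=config.n_boot,
        seed=config.seed,
    )
    integration = integration_stage(cohort, model, subjects, config)
    controls = controls_stage(cohort, model, subjects)
    coverage = None
    if parcels is not None:
        coverage = ctrl.parcel_coverage(parcels, integration.supra_set.voxel_ids)
    return LongitudinalResult(
        prep=prep,
        behavior_block=block,
        model=model,
        integration=integration,
        controls=controls,
        coverage=coverage,
        subjects=subjects,
    )


@dataclass
class CrossSectionalResult:
    model: plsmod.PLSModel
    latent_r_t1: float
    latent_r_t2: float
    rows: pd.DataFrame


def run_cross_sectional(cohort: synthgen.Cohort, config: RunConfig) -> CrossSectionalResult:
    """Occasion-level PLS: SD_BOLD levels vs domain scores and age, stacked."""
    prep = prep_stage(cohort, config)
    blocks = []
    brains = []
    occ_tags = []
    for occ, sd_tab, occ_name in ((1, prep.sd_t1, "T1"), (2, prep.sd_t2, "T2")):
        table = cohort.behavior.t1 if occ == 1 else cohort.behavior.t2
        scores = [comp.domain_component_scores(table, d) for d in COGNITIVE_DOMAINS]
        age = cohort.behavior.age_years_t1
        if occ == 2:
            age = age + cohort.behavior.retest_interval_years
        block = comp.assemble_score_block(scores, extra={"age_years": age})
        block = block.dropna(axis=0, how="any")
        block.columns = [c.replace("_T1", "").replace("_T2", "") for c in block.columns]
        blocks.append(block)
        brains.append(sd_tab.loc[block.index].to_numpy())
        occ_tags.extend([occ_name] * block.shape[0])
    behavior = pd.concat(blocks, axis=0)
    brain = np.vstack(brains)
    model = plsmod.behavioral_pls(
        brain,
        behavior.to_numpy(),
        behavior_labels=list(behavior.columns),
        voxel_ids=prep.analysis_voxels,
        n_perm=config.n_perm,
        n_boot=config.n_boot,
        seed=config.seed,
    )
    tags = np.asarray(occ_tags)
    rows = pd.DataFrame(
        {
            "occasion": tags,
            "brain_score": model.brain_scores[:, 0],
            "behavior_score": model.behavior_scores[:, 0],
        }
    )
    def _occ_r(tag):
        sub = rows[rows["occasion"] == tag]
        return float(np.corrcoef(sub["brain_score"], sub["behavior_score"])[0, 1])
    return CrossSectionalResult(
        model=model, latent_r_t1=_occ_r("T1"), latent_r_t2=_occ_r("T2"), rows=rows
    )


def _write_model_tables(out: Path, res: LongitudinalResult) -> None:
    m = res.model
    pd.DataFrame(m.u, index=m.behavior_labels).to_csv(out / "behavior_saliences.tsv", sep="\t")
    pd.DataFrame(
        {
            "singular_value": m.s,
            "perm_p": m.perm_p,
            "latent_r_pearson": m.latent_pearson,
            "latent_r_spearman": m.latent_spearman,
        }
    ).to_csv(out / "latent_variables.tsv", sep="\t", index_label="lv")
    pd.DataFrame(
        {"voxel_id": m.voxel_ids, "salience": m.v[:, 0], "bsr": m.bsr[:, 0]}
    ).to_csv(out / "voxel_saliences_lv1.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "behavior": m.behavior_labels,
            "u_lv1": m.u[:, 0],
            "ci_low": m.u_ci_low[:, 0],
            "ci_high": m.u_ci_high[:, 0],
        }
    ).to_csv(out / "behavior_weights_ci_lv1.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "subject_id": res.subjects,
            "brain_score": m.brain_scores[:, 0],
            "behavior_score": m.behavior_scores[:, 0],
        }
    ).to_csv(out / "latent_scores_lv1.tsv", sep="\t", index=False)
    res.integration.fi_change.to_csv(out / "fi_change.tsv", sep="\t")
    reg = pd.DataFrame(
        {
            "coef_initial": res.controls.initial.params,
            "p_initial": res.controls.initial.pvalues,
            "coef_filtered": res.controls.filtered.params,
            "p_filtered": res.controls.filtered.pvalues,
        }
    )
    reg.to_csv(out / "control_regression.tsv", sep="\t")
    if res.coverage is not None:
        res.coverage.to_csv(out / "parcel_coverage.tsv", sep="\t")


def run_pipeline(config: RunConfig, mode: str = "longitudinal") -> Path:
    """Execute the full pipeline and write tables + manifest to ``out_dir``."""
    if mode not in ("longitudinal", "cross_sectional"):
        raise ValueError("mode must be 'longitudinal' or 'cross_sectional'")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.cohort_dir is not None:
        cohort = synthgen.load_cohort(config.cohort_dir)
    else:
        cohort = synthgen.simulate_cohort(config.synth_config())

    manifest = {
        "mode": mode,
        "config": asdict(config),
        "seed": config.seed,
        "n_subjects": cohort.config.n_subjects,
        "n_voxels": cohort.config.n_voxels,
        "python": platform.python_version(),
        "numpy": np.__version__,
    }
    if mode == "longitudinal":
        parcels = synthgen.generate_parcels(cohort.config)
        res = run_longitudinal(cohort, config, parcels=parcels)
        _write_model_tables(out, res)
        manifest.update(
            {
                "lv1_perm_p": float(res.model.perm_p[0]),
                "lv1_latent_r": float(res.model.latent_pearson[0]),
                "n_suprathreshold": int(res.integration.supra_set.size),
                "n_hf_noise_flagged": res.prep.n_hf_noise_flagged,
                "n_bootstrap_redrawn": res.model.n_redrawn,
                "cooks_excluded": res.controls.filtered.excluded_subjects,
            }
        )
    else:
        res = run_cross_sectional(cohort, config)
        res.rows.to_csv(out / "cross_sectional_scores.tsv", sep="\t", index=False)
        manifest.update(
            {
                "lv1_perm_p": float(res.model.perm_p[0]),
                "latent_r_t1": res.latent_r_t1,
                "latent_r_t2": res.latent_r_t2,
            }
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    return out
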