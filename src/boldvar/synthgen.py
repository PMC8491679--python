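"""Synthetic cohorts with planted brain-behavior coupling.

The generator emulates a two-occasion longitudinal resting-state study:
~74 adults scanned twice about 2.5 years apart (retest interval uniform on
1.92-3.91 years), 200 volumes at TR = 2.5 s per scan, a 16-test cognitive
battery over five domains, and five metabolic-risk indicators.

Planted structure
-----------------
Each subject carries a latent change factor ``f ~ N(0,1)``.  Voxel ``v`` at
occasion ``o`` is generated as

    x_v(t) = a_v(o) * c(t) + e_v(t)

where ``c(t)`` is a shared latent signal band-limited to the analysis band
(0.01-0.10 Hz, built by band-passing white noise with the same zero-phase
Butterworth filter the pipeline uses) and ``e_v`` is white noise.  Effect
voxels have occasion-2 loading ``a_v = base + integration_gain * f`` while
all other voxels keep ``a_v = base`` at both occasions.  Effect voxels
therefore jointly gain (or lose) both SD and inter-voxel correlation with
the subject factor: SD change and functional-integration change are two
faces of the same planted latent.

The cognitive change factor is ``g = rho * f + sqrt(1 - rho^2) * eps``, so
``corr(f, g) = rho`` (``coupling_rho``) by construction.  Indicator change
scores load on ``g`` with unit loading plus indicator noise; reaction-time
and error indicators are emitted in their natural (lower-is-better) units
with direction-of-goodness metadata, never pre-negated.  Metabolic
indicators are independent of ``f`` by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import io as bio
from .components import BehaviorTable
from .signalprep import VoxelTimeSeries, bandpass_array, condition, sd_bold_map

DOMAINS = ("Gf", "Gc", "EpisodicMemory", "WorkingMemory", "Speed")

#: The cognitive battery: (name, domain, direction, typical mean, typical SD).
#: Units are per test (items correct, errors, ms); the analysis standardizes.
COGNITIVE_BATTERY: tuple[tuple[str, str, str, float, float], ...] = (
    ("cfit1", "Gf", "higher_better", 9.0, 2.5),
    ("cfit2", "Gf", "higher_better", 10.0, 2.5),
    ("cfit3", "Gf", "higher_better", 9.5, 2.5),
    ("cfit4", "Gf", "higher_better", 6.5, 2.0),
    ("vocabulary", "Gc", "higher_better", 18.0, 5.0),
    ("mn_immediate", "EpisodicMemory", "higher_better", 30.0, 8.0),
    ("mn_delayed", "EpisodicMemory", "higher_better", 27.0, 8.0),
    ("spatial_recall", "EpisodicMemory", "higher_better", 4.5, 1.2),
    ("lspan", "WorkingMemory", "higher_better", 20.0, 7.0),
    ("size_judgment_span", "WorkingMemory", "higher_better", 25.0, 8.0),
    ("nb3_errors_verbal", "WorkingMemory", "lower_better", 8.0, 4.0),
    ("nb3_errors_nonverbal", "WorkingMemory", "lower_better", 9.0, 4.0),
    ("letter_comparison", "Speed", "higher_better", 22.0, 5.0),
    ("pattern_comparison", "Speed", "higher_better", 32.0, 6.0),
    ("nb1_rt_verbal", "Speed", "lower_better", 750.0, 150.0),
    ("nb1_rt_nonverbal", "Speed", "lower_better", 800.0, 160.0),
)

#: Metabolic-risk battery: (name, direction of goodness, mean, SD).
#: HDL cholesterol is protective (higher_better); the rest are risk-when-high.
METABOLIC_BATTERY: tuple[tuple[str, str, float, float], ...] = (
    ("systolic_bp", "lower_better", 128.0, 15.0),
    ("fasting_glucose", "lower_better", 96.0, 12.0),
    ("fasting_triglycerides", "lower_better", 120.0, 45.0),
    ("hdl_cholesterol", "higher_better", 55.0, 14.0),
    ("waist_hip_ratio", "lower_better", 0.90, 0.08),
)


def _default_domain_counts() -> dict[str, int]:
    counts: dict[str, int] = {d: 0 for d in DOMAINS}
    for _, domain, _, _, _ in COGNITIVE_BATTERY:
        counts[domain] += 1
    return counts


@dataclass
class SynthConfig:
    """Generative parameters of a synthetic cohort.

    Defaults mirror the emulated study design: 74 subjects, 200 volumes at
    TR 2.5 s (196 retained after discarding 4), retest interval uniform on
    1.92-3.91 years, 16 cognitive indicators across 5 domains and 5
    metabolic indicators.  ``coupling_rho`` is the planted correlation
    between the latent SD_BOLD-change factor and the cognitive-change
    factor; ``integration_gain`` scales how strongly effect-voxel loadings
    on the shared latent signal depend on the subject factor.
    """

    n_subjects: int = 74
    n_voxels: int = 1000
    n_timepoints: int = 200
    tr_seconds: float = 2.5
    n_effect_voxels: int = 250
    coupling_rho: float = 0.6
    integration_gain: float = 0.5
    base_loading: float = 1.0
    noise_sd: float = 1.0
    indicator_noise_sd: float = 1.0
    retest_interval_range: tuple[float, float] = (1.92, 3.91)
    n_indicators_per_domain: dict[str, int] = field(default_factory=_default_domain_counts)
    n_metabolic_indicators: int = 5
    band_hz: tuple[float, float] = (0.01, 0.10)
    filter_order: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_subjects", "n_voxels", "n_timepoints", "n_effect_voxels"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.n_voxels == 0 or self.n_timepoints == 0:
            raise ValueError("n_voxels and n_timepoints must be positive")
        if self.n_effect_voxels > self.n_voxels:
            raise ValueError("n_effect_voxels cannot exceed n_voxels")
        for name in ("tr_seconds", "noise_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite")
        for name in ("integration_gain", "indicator_noise_sd", "base_loading"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be nonnegative and finite")
        if not np.isfinite(self.coupling_rho) or not (-1.0 <= self.coupling_rho <= 1.0):
            raise ValueError("coupling_rho must lie in [-1, 1]")
        lo, hi = self.retest_interval_range
        if not (0 < lo < hi) or not np.isfinite(lo) or not np.isfinite(hi):
            raise ValueError("retest_interval_range must satisfy 0 < low < high")
        if any(c <= 0 for c in self.n_indicators_per_domain.values()):
            raise ValueError("every cognitive domain needs at least one indicator")
        if self.n_metabolic_indicators < 1:
            raise ValueError("need at least one metabolic indicator")


def fast_preset(**overrides) -> SynthConfig:
    """Small cohort (20 subjects x 300 voxels) for fast tests."""
    params = dict(n_subjects=20, n_voxels=300, n_effect_voxels=60)
    params.update(overrides)
    return SynthConfig(**params)


@dataclass
class SynthTruth:
    """Planted generative parameters against which recovery is tested."""

    effect_voxel_ids: np.ndarray
    subject_ids: list[str]
    subject_factor: np.ndarray
    cognitive_change_factor: np.ndarray
    planted_rho: float
    planted_integration_t1: np.ndarray
    planted_integration_t2: np.ndarray
    seed: int

    def to_dict(self) -> dict:
        return {
            "effect_voxel_ids": [int(v) for v in self.effect_voxel_ids],
            "subject_ids": list(self.subject_ids),
            "subject_factor": [float(v) for v in self.subject_factor],
            "cognitive_change_factor": [float(v) for v in self.cognitive_change_factor],
            "planted_rho": float(self.planted_rho),
            "planted_integration_t1": [float(v) for v in self.planted_integration_t1],
            "planted_integration_t2": [float(v) for v in self.planted_integration_t2],
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SynthTruth":
        return cls(
            effect_voxel_ids=np.asarray(d["effect_voxel_ids"], dtype=int),
            subject_ids=list(d["subject_ids"]),
            subject_factor=np.asarray(d["subject_factor"], dtype=float),
            cognitive_change_factor=np.asarray(d["cognitive_change_factor"], dtype=float),
            planted_rho=float(d["planted_rho"]),
            planted_integration_t1=np.asarray(d["planted_integration_t1"], dtype=float),
            planted_integration_t2=np.asarray(d["planted_integration_t2"], dtype=float),
            seed=int(d["seed"]),
        )


def effect_voxel_ids(config: SynthConfig) -> np.ndarray:
    """Deterministic effect-voxel set for a config (sorted mask indices)."""
    rng = np.random.default_rng(config.seed)
    ids = rng.permutation(config.n_voxels)[: config.n_effect_voxels]
    return np.sort(ids)


def subject_ids(config: SynthConfig) -> list[str]:
    return [f"sub-{i + 1:03d}" for i in range(config.n_subjects)]


def latent_signal(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Band-limited shared signal c(t) with unit population SD.

    White noise is band-passed with the same zero-phase Butterworth design
    used by the conditioning pipeline, guaranteeing spectral compliance with
    the analysis band.
    """
    raw = rng.standard_normal(config.n_timepoints)
    low, high = config.band_hz
    c = bandpass_array(raw, config.tr_seconds, low, high, config.filter_order)
    sd = c.std()
    if sd == 0:
        raise ValueError("degenerate latent signal (zero variance)")
    return c / sd


def _loadings(config: SynthConfig, subject_factor: float, occasion: int) -> np.ndarray:
    if occasion not in (1, 2):
        raise ValueError("occasion must be 1 or 2")
    a = np.full(config.n_voxels, config.base_loading, dtype=float)
    if occasion == 2:
        eff = effect_voxel_ids(config)
        a[eff] = config.base_loading + config.integration_gain * subject_factor
    return a


def planted_integration(config: SynthConfig, subject_factor: float, occasion: int) -> float:
    """Expected PC1-variance fraction (in [0,1]) over the effect set.

    For p equicorrelated voxels with pairwise correlation r the first
    eigenvalue of the correlation matrix is 1 + (p-1) r, so PC1 explains
    (1 + (p-1) r) / p of the variance.  Here r = a^2 / (a^2 + noise_sd^2)
    with a the occasion-specific effect-voxel loading (raw-series value,
    before band-pass reshaping of the noise).
    """
    a = config.base_loading
    if occasion == 2:
        a = config.base_loading + config.integration_gain * subject_factor
    r = a**2 / (a**2 + config.noise_sd**2)
    p = max(config.n_effect_voxels, 2)
    return (1.0 + (p - 1) * r) / p


def generate_timeseries(
    config: SynthConfig,
    subject_factor: float,
    occasion: int,
    subject_id: str = "sub-000",
    rng: np.random.Generator | None = None,
) -> VoxelTimeSeries:
    """One subject-occasion's raw voxel x timepoint matrix.

    ``x_v(t) = a_v c(t) + e_v(t)`` with the occasion-2 effect-voxel loading
    shifted by ``integration_gain * subject_factor``.  Deterministic given
    the generator state (default: derived from ``config.seed`` and the
    occasion).
    """
    config.validate()
    if not np.isfinite(subject_factor):
        raise ValueError("subject_factor must be finite")
    if occasion not in (1, 2):
        raise ValueError("occasion must be 1 or 2")
    if rng is None:
        rng = np.random.default_rng([config.seed, occasion, 0x7E5])
    c = latent_signal(config, rng)
    a = _loadings(config, subject_factor, occasion)
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_voxels, config.n_timepoints))
    values = a[:, None] * c[None, :] + noise
    return VoxelTimeSeries(
        values=values,
        tr_seconds=config.tr_seconds,
        voxel_ids=np.arange(config.n_voxels),
        subject_id=subject_id,
        occasion=occasion,
    )


def composite_attenuation(config: SynthConfig) -> float:
    """Closed-form attenuation of the cognitive-change composite.

    The direction-aligned mean of the p standardized indicator changes is
    ``g + (indicator_noise_sd / sqrt(p)) * zbar``, so its correlation with
    the change factor g is ``1 / sqrt(1 + sigma^2 / p)``.
    """
    p = sum(config.n_indicators_per_domain.values())
    sigma2 = config.indicator_noise_sd**2
    return 1.0 / np.sqrt(1.0 + sigma2 / p)


@dataclass
class BehaviorBundle:
    """Behavior tables for both occasions plus ancillary per-subject data."""

    t1: BehaviorTable
    t2: BehaviorTable
    retest_interval_years: pd.Series
    age_years_t1: pd.Series
    cognitive_change_factor: np.ndarray


def generate_behavior(
    config: SynthConfig,
    subject_factor: np.ndarray,
    rng: np.random.Generator | None = None,
) -> BehaviorBundle:
    """Cognitive + metabolic tables at both occasions.

    Indicator change scores load (unit loading, noise ``indicator_noise_sd``)
    on a single cognitive-change factor g with corr(f, g) = ``coupling_rho``.
    Lower-is-better indicators (errors, RTs) are emitted in natural units
    with direction metadata.  Metabolic indicators are driven by their own
    independent baseline/change factors.
    """
    config.validate()
    subject_factor = np.asarray(subject_factor, dtype=float)
    if not np.all(np.isfinite(subject_factor)):
        raise ValueError("subject factors must be finite")
    n = subject_factor.shape[0]
    if rng is None:
        rng = np.random.default_rng([config.seed, 0xBE4])
    subjects = [f"sub-{i + 1:03d}" for i in range(n)]

    rho = config.coupling_rho
    g = rho * subject_factor + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)
    u = rng.standard_normal(n)  # baseline (cross-sectional) cognition factor
    lam1 = 0.6  # baseline communality of each indicator with u

    battery = COGNITIVE_BATTERY
    counts = _default_domain_counts()
    if dict(config.n_indicators_per_domain) != counts:
        raise ValueError(
            "n_indicators_per_domain must match the built-in battery "
            f"({counts}); custom batteries are not supported"
        )

    t1_cols: dict[str, np.ndarray] = {}
    t2_cols: dict[str, np.ndarray] = {}
    domains: dict[str, str] = {}
    directions: dict[str, str] = {}
    for name, domain, direction, mu, scale in battery:
        sgn = 1.0 if direction == "higher_better" else -1.0
        t1_good = lam1 * u + np.sqrt(1.0 - lam1**2) * rng.standard_normal(n)
        delta_good = g + config.indicator_noise_sd * rng.standard_normal(n)
        t1_cols[name] = mu + scale * sgn * t1_good
        t2_cols[name] = t1_cols[name] + 0.3 * scale * sgn * delta_good
        domains[name] = domain
        directions[name] = direction

    # Metabolic indicators: independent of f and g by design (null covariates).
    h_base = rng.standard_normal(n)
    h_change = rng.standard_normal(n)
    for name, direction, mu, scale in METABOLIC_BATTERY[: config.n_metabolic_indicators]:
        sgn_risk = -1.0 if direction == "higher_better" else 1.0
        base_good = 0.6 * h_base + 0.8 * rng.standard_normal(n)
        change = 0.5 * h_change + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        t1_cols[name] = mu + scale * sgn_risk * base_good
        t2_cols[name] = t1_cols[name] + 0.25 * scale * sgn_risk * change
        domains[name] = "Metabolic"
        directions[name] = direction

    df1 = pd.DataFrame(t1_cols, index=pd.Index(subjects, name="subject_id"))
    df2 = pd.DataFrame(t2_cols, index=pd.Index(subjects, name="subject_id"))
    intervals = pd.Series(
        rng.uniform(*config.retest_interval_range, size=n), index=df1.index,
        name="retest_interval_years",
    )
    ages = pd.Series(rng.uniform(45.0, 80.0, size=n), index=df1.index, name="age_years_t1")

    t1 = BehaviorTable(data=df1, domains=domains, directions=directions, occasion="T1")
    t2 = BehaviorTable(data=df2, domains=domains, directions=directions, occasion="T2")
    return BehaviorBundle(
        t1=t1, t2=t2, retest_interval_years=intervals, age_years_t1=ages,
        cognitive_change_factor=g,
    )


@dataclass
class Cohort:
    """In-memory synthetic cohort: imaging + behavior + ground truth."""

    config: SynthConfig
    truth: SynthTruth
    series: dict[tuple[str, int], VoxelTimeSeries]
    behavior: BehaviorBundle


def simulate_cohort(config: SynthConfig) -> Cohort:
    """Generate a full cohort in memory, deterministically from the config seed."""
    config.validate()
    root = np.random.default_rng(config.seed)
    f = root.standard_normal(config.n_subjects)
    subjects = subject_ids(config)
    behavior = generate_behavior(config, f, rng=np.random.default_rng([config.seed, 0xBE4]))

    series: dict[tuple[str, int], VoxelTimeSeries] = {}
    for i, sid in enumerate(subjects):
        for occ in (1, 2):
            rng = np.random.default_rng([config.seed, i, occ])
            series[(sid, occ)] = generate_timeseries(
                config, f[i], occ, subject_id=sid, rng=rng
            )

    truth = SynthTruth(
        effect_voxel_ids=effect_voxel_ids(config),
        subject_ids=subjects,
        subject_factor=f,
        cognitive_change_factor=behavior.cognitive_change_factor,
        planted_rho=config.coupling_rho,
        planted_integration_t1=np.array(
            [planted_integration(config, fi, 1) for fi in f]
        ),
        planted_integration_t2=np.array(
            [planted_integration(config, fi, 2) for fi in f]
        ),
        seed=config.seed,
    )
    return Cohort(config=config, truth=truth, series=series, behavior=behavior)


def generate_cohort(config: SynthConfig, out_dir: str | Path) -> Path:
    """Write a cohort to disk as NIfTI + TSV + truth JSON; byte-stable given seed.

    Layout::

        out_dir/
          mask.nii.gz
          func/<subject>_ses-<occ>_bold.nii.gz
          behavior_t1.tsv, behavior_t2.tsv
          indicators.tsv          (indicator -> domain, direction)
          subjects.tsv            (retest interval, age)
          truth.json
    """
    out = Path(out_dir)
    (out / "func").mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)

    mask, affine = bio.grid_mask(config.n_voxels)
    bio.save_mask(out / "mask.nii.gz", mask, affine)
    for (sid, occ), ts in cohort.series.items():
        bio.save_series(out / "func" / f"{sid}_ses-{occ}_bold.nii.gz", ts, mask, affine)

    bio.save_behavior_table(out / "behavior_t1.tsv", cohort.behavior.t1)
    bio.save_behavior_table(out / "behavior_t2.tsv", cohort.behavior.t2)
    bio.save_indicator_metadata(out / "indicators.tsv", cohort.behavior.t1)
    subj = pd.DataFrame(
        {
            "retest_interval_years": cohort.behavior.retest_interval_years,
            "age_years_t1": cohort.behavior.age_years_t1,
        }
    )
    subj.to_csv(out / "subjects.tsv", sep="\t")
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out


def load_cohort(path: str | Path) -> Cohort:
    """Round-trip reader for :func:`generate_cohort` output."""
    path = Path(path)
    with open(path / "truth.json") as fh:
        truth = SynthTruth.from_dict(json.load(fh))
    mask, affine = bio.load_mask(path / "mask.nii.gz")
    series: dict[tuple[str, int], VoxelTimeSeries] = {}
    for sid in truth.subject_ids:
        for occ in (1, 2):
            series[(sid, occ)] = bio.load_series(
                path / "func" / f"{sid}_ses-{occ}_bold.nii.gz", mask, subject_id=sid, occasion=occ
            )
    meta = bio.load_indicator_metadata(path / "indicators.tsv")
    t1 = bio.load_behavior_table(path / "behavior_t1.tsv", meta, occasion="T1")
    t2 = bio.load_behavior_table(path / "behavior_t2.tsv", meta, occasion="T2")
    subj = pd.read_csv(path / "subjects.tsv", sep="\t", index_col="subject_id")
    n_vox = int(mask.sum())
    config = SynthConfig(
        n_subjects=len(truth.subject_ids),
        n_voxels=n_vox,
        n_timepoints=next(iter(series.values())).n_timepoints,
        n_effect_voxels=len(truth.effect_voxel_ids),
        coupling_rho=truth.planted_rho,
        seed=truth.seed,
    )
    behavior = BehaviorBundle(
        t1=t1,
        t2=t2,
        retest_interval_years=subj["retest_interval_years"],
        age_years_t1=subj["age_years_t1"],
        cognitive_change_factor=truth.cognitive_change_factor,
    )
    return Cohort(config=config, truth=truth, series=series, behavior=behavior)


def generate_parcels(config: SynthConfig, n_parcels: int = 7) -> np.ndarray:
    """Synthetic integer parcel labels over the mask (1..n_parcels).

    Parcel 1 is enriched for effect voxels, mimicking an anatomical parcel
    whose territory overlaps the planted system; the remainder of the mask is
    split evenly.  Deterministic given the config seed.
    """
    rng = np.random.default_rng([config.seed, 0xAC])
    labels = np.zeros(config.n_voxels, dtype=int)
    eff = effect_voxel_ids(config)
    # ~80% of effect voxels plus a sprinkle of others form parcel 1.
    take = rng.random(eff.size) < 0.8
    labels[eff[take]] = 1
    rest = np.where(labels == 0)[0]
    extra = rng.permutation(rest)[: max(1, eff.size // 10)]
    labels[extra] = 1
    rest = np.where(labels == 0)[0]
    chunks = np.array_split(rng.permutation(rest), n_parcels - 1)
    for k, chunk in enumerate(chunks, start=2):
        labels[chunk] = k
    return labels


def attenuated_latent_r(
    config: SynthConfig,
    n_subjects: int = 1500,
    seed: int | None = None,
    chunk: int = 200,
) -> float:
    """Attenuation-adjusted target for the recovered LV1 latent correlation.

    Monte-Carlo estimate, at large n, of the correlation between two plain
    composites of the planted model: the mean effect-voxel SD_BOLD change
    (computed through the real conditioning pipeline, so SD-estimation noise
    is included) and the equal-weight cognitive change composite (mean of
    direction-aligned standardized domain means).  No SVD or weighting is
    involved, so the estimate is independent of the PLS code path.  It
    reflects the planted coupling ``rho`` attenuated by measurement noise on
    both sides; finite-sample PLS estimates additionally carry a small
    optimistic bias from fitting the voxel weights.
    """
    if seed is None:
        seed = config.seed + 991
    rng = np.random.default_rng(seed)
    p_eff = max(config.n_effect_voxels, 1)

    f = rng.standard_normal(n_subjects)
    rho = config.coupling_rho
    g = rho * f + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n_subjects)

    # Brain side: effect voxels only, through the real conditioning chain.
    mean_dsd = np.empty(n_subjects)
    eff_cfg_voxels = p_eff
    for start in range(0, n_subjects, chunk):
        idx = np.arange(start, min(start + chunk, n_subjects))
        block = np.empty((idx.size, 2, eff_cfg_voxels))
        for occ_i, occ in enumerate((1, 2)):
            for j, i in enumerate(idx):
                raw = rng.standard_normal(config.n_timepoints)
                low, high = config.band_hz
                c = bandpass_array(raw, config.tr_seconds, low, high, config.filter_order)
                c /= c.std()
                a = config.base_loading + (
                    config.integration_gain * f[i] if occ == 2 else 0.0
                )
                noise = rng.normal(0.0, config.noise_sd, size=(eff_cfg_voxels, config.n_timepoints))
                ts = VoxelTimeSeries(a * c[None, :] + noise, config.tr_seconds)
                sd = sd_bold_map(condition(ts)).values
                block[j, occ_i] = sd
        mean_dsd[idx] = (block[:, 1] - block[:, 0]).mean(axis=1)

    # Behavior side: per-domain means of direction-aligned indicator changes.
    domain_scores = []
    for domain, count in _default_domain_counts().items():
        noise = config.indicator_noise_sd * rng.standard_normal((n_subjects, count))
        domain_scores.append((g[:, None] + noise).mean(axis=1))
    comp = np.mean(
        [(s - s.mean()) / s.std() for s in domain_scores], axis=0
    )
    return float(np.corrcoef(mean_dsd, comp)[0, 1])
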