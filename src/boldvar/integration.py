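"""Functional integration via spatial PCA, and its spatial-specificity analysis.

Functional integration of a voxel set is the percent variance explained by
the first principal component of the voxel x voxel Pearson correlation
matrix over timepoints: the higher the fraction, the more the voxels
co-fluctuate as one ("lower-dimensional") system.  Longitudinal change is
the Time 2 minus Time 1 difference in that percentage.

The spatial-specificity analysis asks whether integration change computed
on the suprathreshold (|BSR| >= 3) voxel set relates more strongly to
cognitive change than integration computed on (a) size-matched random
samples from the subthreshold pool and (b) the equally sized subthreshold
set farthest from threshold (smallest |BSR|).  Matching the set size
equates the total estimable dimensionality.  Dependent correlations sharing
the cognition variable are compared with Steiger's Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .signalprep import VoxelTimeSeries


@dataclass
class IntegrationProfile:
    """Per-subject, per-occasion PC1-variance percentage over a voxel set."""

    subject_id: str
    occasion: int
    voxel_set_id: str
    pc1_fraction: float  # percent in [100/|set|, 100]

    def __post_init__(self) -> None:
        if not (0.0 <= self.pc1_fraction <= 100.0 + 1e-9):
            raise ValueError("pc1_fraction must be a percentage in [0, 100]")


@dataclass
class VoxelSampleSet:
    """A named voxel set with provenance for the specificity analysis."""

    sample_id: str
    voxel_ids: np.ndarray
    provenance: str = "suprathreshold"

    def __post_init__(self) -> None:
        self.voxel_ids = np.asarray(self.voxel_ids, dtype=int)
        valid = {"suprathreshold", "random_subthreshold", "representative", "farthest_from_threshold"}
        if self.provenance not in valid:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def size(self) -> int:
        return int(self.voxel_ids.size)


def pc1_variance_fraction(
    ts: VoxelTimeSeries | np.ndarray, voxel_ids: np.ndarray | None = None
) -> float:
    """Percent variance explained by PC1 of the voxel correlation matrix.

    Equals ``100 * lambda_1 / p`` for the p x p Pearson correlation matrix of
    the selected voxel series.  When p exceeds the number of timepoints the
    spectrum is computed from the temporal Gram matrix of the standardized
    series (identical nonzero eigenvalues).
    """
    if isinstance(ts, VoxelTimeSeries):
        values = ts.values
        all_ids = ts.voxel_ids
    else:
        values = np.asarray(ts, dtype=float)
        all_ids = np.arange(values.shape[0])
    if voxel_ids is not None:
        pos = {int(v): i for i, v in enumerate(all_ids)}
        try:
            rows = [pos[int(v)] for v in voxel_ids]
        except KeyError as exc:
            raise ValueError(f"voxel id {exc} not present in series") from exc
        values = values[rows]
    p, t = values.shape
    if p < 2:
        raise ValueError("need at least 2 voxels for spatial PCA")
    sd = values.std(axis=1, ddof=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance voxel in the requested set")
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    if p <= t:
        mat = (z @ z.T) / t            # p x p correlation matrix
    else:
        mat = (z.T @ z) / t            # t x t Gram; same nonzero spectrum
    lam1 = float(np.linalg.eigvalsh(mat)[-1])
    return 100.0 * lam1 / p


def integration_profile(
    ts: VoxelTimeSeries, voxel_set: VoxelSampleSet
) -> IntegrationProfile:
    return IntegrationProfile(
        subject_id=ts.subject_id,
        occasion=ts.occasion,
        voxel_set_id=voxel_set.sample_id,
        pc1_fraction=pc1_variance_fraction(ts, voxel_set.voxel_ids),
    )


def integration_change(t1: IntegrationProfile, t2: IntegrationProfile) -> float:
    """Time 2 minus Time 1 PC1-variance percentage (percentage points)."""
    if t1.subject_id != t2.subject_id:
        raise ValueError("profiles belong to different subjects")
    if t1.voxel_set_id != t2.voxel_set_id:
        raise ValueError("profiles use different voxel sets")
    return t2.pc1_fraction - t1.pc1_fraction


def sample_matched_voxel_sets(
    pool: np.ndarray,
    size: int,
    n_samples: int = 100,
    seed: int | None = None,
) -> list[VoxelSampleSet]:
    """Random without-replacement samples of exactly ``size`` voxels from the pool."""
    pool = np.asarray(pool, dtype=int)
    if size > pool.size:
        raise ValueError(f"sample size {size} exceeds pool size {pool.size}")
    if size < 1 or n_samples < 1:
        raise ValueError("size and n_samples must be positive")
    rng = np.random.default_rng(seed)
    return [
        VoxelSampleSet(
            sample_id=f"random_{i:03d}",
            voxel_ids=np.sort(rng.choice(pool, size=size, replace=False)),
            provenance="random_subthreshold",
        )
        for i in range(n_samples)
    ]


def representative_sample(
    samples: list[VoxelSampleSet], fi_changes: np.ndarray, metric: str = "abs"
) -> VoxelSampleSet:
    """The sample minimizing cumulative distance to per-subject median changes.

    ``fi_changes`` is n_samples x n_subjects.  For each subject the median
    integration change across samples is taken; the selected sample minimizes
    the sum over subjects of |sample change - subject median| (ties broken by
    lowest sample index).  ``metric='squared'`` sums squared distances instead.
    """
    if not samples:
        raise ValueError("no samples provided")
    if metric not in ("abs", "squared"):
        raise ValueError("metric must be 'abs' or 'squared'")
    fi = np.asarray(fi_changes, dtype=float)
    if fi.shape[0] != len(samples):
        raise ValueError("fi_changes rows must match number of samples")
    medians = np.median(fi, axis=0)
    dev = np.abs(fi - medians[None, :])
    cumdist = (dev**2 if metric == "squared" else dev).sum(axis=1)
    best = int(np.argmin(cumdist))  # argmin returns the first (lowest) index on ties
    chosen = samples[best]
    return VoxelSampleSet(
        sample_id=chosen.sample_id,
        voxel_ids=chosen.voxel_ids,
        provenance="representative",
    )


def farthest_subthreshold_set(
    bsr: np.ndarray,
    voxel_ids: np.ndarray,
    size: int,
    threshold: float = 3.0,
) -> VoxelSampleSet:
    """The ``size`` subthreshold voxels with smallest |BSR| (ties by voxel id)."""
    bsr = np.asarray(bsr, dtype=float).ravel()
    voxel_ids = np.asarray(voxel_ids, dtype=int)
    sub = np.abs(bsr) < threshold
    pool_ids = voxel_ids[sub]
    pool_abs = np.abs(bsr[sub])
    if size > pool_ids.size:
        raise ValueError(f"requested {size} voxels but only {pool_ids.size} subthreshold")
    order = np.lexsort((pool_ids, pool_abs))
    chosen = np.sort(pool_ids[order[:size]])
    return VoxelSampleSet(
        sample_id="farthest_from_threshold",
        voxel_ids=chosen,
        provenance="farthest_from_threshold",
    )


def steiger_z(r1: float, r2: float, r12: float, n: int) -> tuple[float, float]:
    """Steiger's Z for two dependent correlations sharing one variable.

    Compares r1 = corr(x, y1) with r2 = corr(x, y2), where r12 = corr(y1, y2),
    over n subjects.  Fisher-z transforms both correlations and accounts for
    their covariance through the mean correlation (Steiger 1980, Z1* form):

        rbar = (r1 + r2) / 2
        s    = [r12 (1 - 2 rbar^2) - rbar^2 (1 - 2 rbar^2 - r12^2) / 2] / (1 - rbar^2)^2
        Z    = (z1 - z2) * sqrt((n - 3) / (2 (1 - s)))

    Returns (Z, two-sided p).
    """
    for name, r in (("r1", r1), ("r2", r2), ("r12", r12)):
        if not np.isfinite(r) or abs(r) >= 1:
            raise ValueError(f"|{name}| must be < 1 and finite")
    if n < 4:
        raise ValueError("need n >= 4")
    z1 = np.arctanh(r1)
    z2 = np.arctanh(r2)
    rbar = 0.5 * (r1 + r2)
    num = r12 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r12**2)
    s = num / (1 - rbar**2) ** 2
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - s)))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
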