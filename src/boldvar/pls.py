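"""Behavioral partial least squares (PLS) linking voxel maps to behavior.

The method decomposes the behaviors x voxels matrix of between-subject
Pearson correlations,

    CORR = corr(behavior_b, brain_v),    SVD: CORR = U S V'

into latent variables (LVs).  Column k of U holds the behavior saliences,
column k of V the voxel saliences, and S_k the singular value.  Inference:

* permutation test on each LV's singular value — behavior rows are
  shuffled jointly over subjects (preserving inter-behavior correlation),
  with the add-one convention p = (1 + #{S_perm >= S_obs}) / (n_perm + 1);
* bootstrap over subjects (resampled with replacement) — each resample's
  SVD is aligned to the original by an orthogonal Procrustes rotation, and
  each voxel's bootstrap ratio (BSR) is its original salience divided by
  the bootstrap standard error of that salience.  BSRs are conventionally
  thresholded at +/-3.00, which exceeds the two-sided 99.5% normal
  critical value.

Per-subject expressions of an LV are the brain score P V and the
cognition/behavior score Q U, whose correlation is the LV's latent r.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class CorrMatrix:
    """Behaviors x voxels between-subject correlation matrix."""

    values: np.ndarray
    behavior_labels: list[str]
    voxel_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_ids = np.asarray(self.voxel_ids, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("CORR must be 2-D (behaviors x voxels)")
        if len(self.behavior_labels) != self.values.shape[0]:
            raise ValueError("behavior label count does not match CORR rows")
        if self.voxel_ids.shape[0] != self.values.shape[1]:
            raise ValueError("voxel id count does not match CORR columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CORR contains non-finite entries")
        if np.any(np.abs(self.values) > 1 + 1e-10):
            raise ValueError("CORR entries must lie in [-1, 1]")


@dataclass
class PLSModel:
    """Fitted behavioral PLS decomposition with inference results."""

    u: np.ndarray                    # behaviors x LVs, unit-norm columns
    s: np.ndarray                    # singular values, descending
    v: np.ndarray                    # voxels x LVs, unit-norm columns
    behavior_labels: list[str]
    voxel_ids: np.ndarray
    perm_p: np.ndarray | None = None
    bsr: np.ndarray | None = None            # voxels x LVs
    u_ci_low: np.ndarray | None = None       # behaviors x LVs, 95% percentile CI
    u_ci_high: np.ndarray | None = None
    brain_scores: np.ndarray | None = None   # subjects x LVs
    behavior_scores: np.ndarray | None = None
    latent_pearson: np.ndarray | None = None
    latent_spearman: np.ndarray | None = None
    n_perm: int = 0
    n_boot: int = 0
    n_redrawn: int = 0
    seed: int | None = None

    @property
    def n_lv(self) -> int:
        return self.s.shape[0]

    def stable_behaviors(self, lv: int = 0) -> list[str]:
        """Behaviors whose bootstrap 95% CI excludes zero for this LV."""
        if self.u_ci_low is None:
            raise ValueError("bootstrap CIs not computed")
        keep = (self.u_ci_low[:, lv] > 0) | (self.u_ci_high[:, lv] < 0)
        return [b for b, k in zip(self.behavior_labels, keep) if k]


def _standardize_columns(x: np.ndarray, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=0, ddof=0)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise ValueError(f"zero-variance {what} column(s) at index {bad.tolist()}")
    return (x - x.mean(axis=0)) / sd


def correlation_matrix(
    brain: np.ndarray,
    behavior: np.ndarray,
    behavior_labels: list[str] | None = None,
    voxel_ids: np.ndarray | None = None,
) -> CorrMatrix:
    """Between-subject Pearson correlations: CORR[b, v] = r(behavior_b, brain_v)."""
    brain = np.asarray(brain, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    if brain.shape[0] != behavior.shape[0]:
        raise ValueError("brain and behavior must cover the same subjects (rows)")
    n = brain.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for correlations")
    zb = _standardize_columns(behavior, "behavior")
    zv = _standardize_columns(brain, "brain")
    corr = (zb.T @ zv) / n
    np.clip(corr, -1.0, 1.0, out=corr)
    if behavior_labels is None:
        behavior_labels = [f"b{i}" for i in range(behavior.shape[1])]
    if voxel_ids is None:
        voxel_ids = np.arange(brain.shape[1])
    return CorrMatrix(values=corr, behavior_labels=list(behavior_labels), voxel_ids=voxel_ids)


def _svd(corr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    u, s, vt = np.linalg.svd(corr, full_matrices=False)
    return u, s, vt.T


def _fix_signs(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per LV, make the largest-magnitude behavior salience positive."""
    u = u.copy()
    v = v.copy()
    for k in range(u.shape[1]):
        j = int(np.argmax(np.abs(u[:, k])))
        if u[j, k] < 0:
            u[:, k] = -u[:, k]
            v[:, k] = -v[:, k]
    return u, v


def pls_svd(corr: CorrMatrix) -> PLSModel:
    """SVD of CORR with deterministic sign convention; LVs ordered by S."""
    u, s, v = _svd(corr.values)
    u, v = _fix_signs(u, v)
    return PLSModel(
        u=u, s=s, v=v,
        behavior_labels=list(corr.behavior_labels),
        voxel_ids=corr.voxel_ids,
    )


def permutation_pvalues(
    brain: np.ndarray,
    behavior: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    procrustes: bool = False,
) -> np.ndarray:
    """Per-LV permutation p-values on the singular values.

    Behavior rows are permuted jointly (subject-label shuffle), preserving
    the inter-behavior correlation structure; p_k uses the add-one
    convention, so p in [1/(n_perm+1), 1].  By default permuted singular
    values are compared per LV without rotation; ``procrustes=True``
    instead aligns each permuted decomposition to the observed one and
    compares the rotation-corrected singular values.
    """
    if n_perm < 100:
        import warnings

        warnings.warn("n_perm < 100 gives coarse p-values", stacklevel=2)
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    brain = np.asarray(brain, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    u_obs, s_obs, _ = _svd(correlation_matrix(brain, behavior).values)
    n = brain.shape[0]
    count = np.zeros_like(s_obs)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        u_p, s_p, v_p = _svd(correlation_matrix(brain, behavior[perm]).values)
        if procrustes:
            rot = _procrustes_rotation(u_p, u_obs)
            s_perm = np.linalg.norm(v_p @ np.diag(s_p) @ rot, axis=0)
        else:
            s_perm = s_p
        count += s_perm >= s_obs
    return (1.0 + count) / (n_perm + 1.0)


def _procrustes_rotation(u_boot: np.ndarray, u_orig: np.ndarray) -> np.ndarray:
    """Orthogonal rotation aligning a resample's singular vectors to the original."""
    a, _, bt = np.linalg.svd(u_boot.T @ u_orig)
    return a @ bt


def bootstrap_ratios(
    brain: np.ndarray,
    behavior: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_redraws: int = 1000,
    numerator: str = "original",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Bootstrap over subjects: (BSR voxels x LVs, U CI low, U CI high, n_redrawn).

    Each resample's SVD is Procrustes-rotated to the original decomposition
    before accumulating.  BSR = original V element / bootstrap SE of that
    element (``numerator='mean'`` uses the bootstrap-mean salience instead).
    Behavior-weight 95% CIs use the percentile method.  Resamples producing
    a zero-variance column are redrawn (counted).
    """
    if numerator not in ("original", "mean"):
        raise ValueError("numerator must be 'original' or 'mean'")
    if n_boot < 100:
        import warnings

        warnings.warn("n_boot < 100 gives unstable standard errors", stacklevel=2)
    if rng is None:
        rng = np.random.default_rng(seed)
    brain = np.asarray(brain, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    n = brain.shape[0]
    corr = correlation_matrix(brain, behavior)
    u0, s0, v0 = _svd(corr.values)
    u0, v0 = _fix_signs(u0, v0)

    v_samples = np.empty((n_boot,) + v0.shape)
    u_samples = np.empty((n_boot,) + u0.shape)
    n_redrawn = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            corr_b = correlation_matrix(brain[idx], behavior[idx]).values
        except ValueError:
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise ValueError(
                    "too many degenerate bootstrap resamples (constant columns); "
                    "data may be duplicate-subject degenerate"
                )
            continue
        ub, sb, vb = _svd(corr_b)
        rot = _procrustes_rotation(ub, u0)
        v_samples[b] = vb @ rot
        u_samples[b] = ub @ rot
        b += 1

    se = v_samples.std(axis=0, ddof=1)
    num = v0 if numerator == "original" else v_samples.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = np.where(se > 0, num / se, np.inf * np.sign(num))
    ci_low = np.percentile(u_samples, 2.5, axis=0)
    ci_high = np.percentile(u_samples, 97.5, axis=0)
    return bsr, ci_low, ci_high, n_redrawn


def brain_scores(v: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Per-subject brain scores: score[s, k] = sum_v V[v, k] * P[s, v]."""
    v = np.asarray(v, dtype=float)
    p = np.asarray(p, dtype=float)
    if p.shape[1] != v.shape[0]:
        raise ValueError("voxel dimension of P does not match V")
    return p @ v


def behavior_scores(u: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Per-subject cognition/behavior scores: score[s, k] = sum_b U[b, k] * Q[s, b]."""
    u = np.asarray(u, dtype=float)
    q = np.asarray(q, dtype=float)
    if q.shape[1] != u.shape[0]:
        raise ValueError("behavior dimension of Q does not match U")
    return q @ u


def latent_correlation(
    brain_sc: np.ndarray, behavior_sc: np.ndarray, lv: int = 0
) -> tuple[float, float]:
    """(Pearson r, Spearman rho) between the two score vectors of one LV."""
    x = np.asarray(brain_sc, dtype=float)
    y = np.asarray(behavior_sc, dtype=float)
    if x.ndim == 2:
        x = x[:, lv]
    if y.ndim == 2:
        y = y[:, lv]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant score vector; latent correlation undefined")
    return (
        float(stats.pearsonr(x, y).statistic),
        float(stats.spearmanr(x, y).statistic),
    )


def threshold_map(
    bsr: np.ndarray, voxel_ids: np.ndarray, threshold: float = 3.0, lv: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """(positive, negative) suprathreshold voxel id sets; inclusive at +/-threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    b = np.asarray(bsr, dtype=float)
    if b.ndim == 2:
        b = b[:, lv]
    voxel_ids = np.asarray(voxel_ids, dtype=int)
    return voxel_ids[b >= threshold], voxel_ids[b <= -threshold]


def behavioral_pls(
    brain: np.ndarray,
    behavior: np.ndarray,
    behavior_labels: list[str] | None = None,
    voxel_ids: np.ndarray | None = None,
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int | None = None,
) -> PLSModel:
    """Full behavioral PLS: decomposition, permutation test, bootstrap, scores.

    Brain and behavior scores are computed from column-standardized blocks,
    consistent with the correlation-based decomposition (the latent r is
    unaffected by per-column affine rescaling).
    """
    rng = np.random.default_rng(seed)
    corr = correlation_matrix(brain, behavior, behavior_labels, voxel_ids)
    model = pls_svd(corr)
    model.seed = seed
    model.n_perm = n_perm
    model.n_boot = n_boot
    model.perm_p = permutation_pvalues(brain, behavior, n_perm=n_perm, rng=rng)
    model.bsr, model.u_ci_low, model.u_ci_high, model.n_redrawn = bootstrap_ratios(
        brain, behavior, n_boot=n_boot, rng=rng
    )
    zb = _standardize_columns(np.asarray(behavior, dtype=float), "behavior")
    zv = _standardize_columns(np.asarray(brain, dtype=float), "brain")
    model.brain_scores = brain_scores(model.v, zv)
    model.behavior_scores = behavior_scores(model.u, zb)
    n_lv = model.n_lv
    model.latent_pearson = np.empty(n_lv)
    model.latent_spearman = np.empty(n_lv)
    for k in range(n_lv):
        r_p, r_s = latent_correlation(model.brain_scores, model.behavior_scores, k)
        model.latent_pearson[k] = r_p
        model.latent_spearman[k] = r_s
    return model
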