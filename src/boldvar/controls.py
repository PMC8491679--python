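"""Covariate-control regression with influence diagnostics, and parcel coverage.

The control analysis asks whether the latent change-change association
survives adjustment for metabolic risk: the per-subject SD_BOLD-change brain
score is regressed (OLS) on the cognition/age change score plus baseline and
change-in metabolic-risk component scores.  High-leverage observations are
then screened with Cook's distance using the 4/n rule of thumb and the model
is refit once on the retained subjects.

Parcel coverage summarizes a suprathreshold voxel map against an integer
label volume: for each parcel, the fraction of its voxels present in the
suprathreshold set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

PREDICTORS = ("cognition_age_change", "metabolic_baseline", "metabolic_change")


@dataclass
class ControlModel:
    """OLS of the brain change score on cognition/age change + metabolic risk."""

    params: pd.Series
    pvalues: pd.Series
    rsquared: float
    n: int
    excluded_subjects: list[str] = field(default_factory=list)
    cooks_threshold: float | None = None
    _results: object | None = None
    _data: pd.DataFrame | None = None


def fit_control_regression(
    scores: pd.DataFrame,
    outcome: str = "brain_change_score",
    predictors: tuple[str, ...] = PREDICTORS,
    robust: bool = False,
) -> ControlModel:
    """OLS with intercept on complete cases of the given score table.

    ``robust=True`` reports heteroscedasticity-consistent (HC3) standard
    errors; the default is the plain OLS construction.
    """
    cols = [outcome, *predictors]
    missing = [c for c in cols if c not in scores.columns]
    if missing:
        raise ValueError(f"score table lacks columns: {missing}")
    data = scores[cols].dropna(axis=0, how="any")
    n = data.shape[0]
    if n <= len(predictors) + 2:
        raise ValueError(f"too few complete cases (n={n}) for {len(predictors)} predictors")
    x = sm.add_constant(data[list(predictors)])
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        raise ValueError("rank-deficient design matrix")
    res = sm.OLS(data[outcome], x).fit(cov_type="HC3" if robust else "nonrobust")
    return ControlModel(
        params=res.params,
        pvalues=res.pvalues,
        rsquared=float(res.rsquared),
        n=n,
        _results=res,
        _data=data,
    )


def cooks_distance_threshold(n: int) -> float:
    """The 4/n rule-of-thumb cutoff."""
    return 4.0 / n


def format_threshold(threshold: float, decimals: int = 3) -> str:
    """Display form of the cutoff, truncated (not rounded) to 3 decimals.

    4/68 = 0.0588... prints as "0.058".
    """
    factor = 10**decimals
    return f"{np.floor(threshold * factor) / factor:.{decimals}f}"

def cooks_filter(model: ControlModel) -> ControlModel:
    """Exclude observations with Cook's D > 4/n, refit once on the rest."""
    if model._results is None or model._data is None:
        raise ValueError("model must come from fit_control_regression")
    res = model._results
    if res.ssr <= 1e-10 * max(1.0, float(res.centered_tss)):
        # (Numerically) perfect fit: all influence distances are zero.
        d = np.zeros(model.n)
    else:
        d = OLSInfluence(res).cooks_distance[0]
    threshold = cooks_distance_threshold(model.n)
    keep = d <= threshold
    excluded = [str(s) for s in model._data.index[~keep]]
    if keep.sum() == 0:
        raise ValueError("Cook's filter would exclude every observation")
    refit = fit_control_regression(
        model._data.loc[keep],
        outcome=model._data.columns[0],
        predictors=tuple(model._data.columns[1:]),
    )
    refit.excluded_subjects = excluded
    refit.cooks_threshold = threshold
    return refit


def parcel_coverage(
    labels: np.ndarray,
    suprathreshold_ids: np.ndarray,
    label_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per-parcel coverage of the suprathreshold set.

    ``labels`` gives an integer parcel label per mask voxel (0 = background);
    ``suprathreshold_ids`` are flat mask indices.  Returns one row per
    nonzero label with covered count, total count, the exact fraction, and
    the display percentage rounded to the nearest integer.
    """
    labels = np.asarray(labels, dtype=int).ravel()
    if np.any(labels < 0):
        raise ValueError("parcel labels must be nonnegative")
    ids = np.asarray(suprathreshold_ids, dtype=int)
    if ids.size and (ids.min() < 0 or ids.max() >= labels.size):
        raise ValueError("suprathreshold voxel ids fall outside the label grid")
    in_set = np.zeros(labels.size, dtype=bool)
    in_set[ids] = True
    rows = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        members = labels == lab
        total = int(members.sum())
        covered = int((members & in_set).sum())
        fraction = covered / total
        rows.append(
            {
                "label": int(lab),
                "name": (label_names or {}).get(int(lab), f"parcel_{lab}"),
                "covered": covered,
                "total": total,
                "fraction": fraction,
                "percent": int(round(100.0 * fraction)),
            }
        )
    if not rows:
        raise ValueError("label volume contains no nonzero parcels")
    return pd.DataFrame(rows).set_index("label")
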