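"""Single-component scores per cognitive domain and for metabolic risk.

Each cognitive domain (fluid intelligence, crystallized intelligence,
episodic memory, working memory, perceptual speed) is reduced to the first
principal component of its standardized indicators — computed separately at
Time 1, Time 2, and on Time 2 - Time 1 difference scores.  Because the
battery mixes units (items correct, errors, milliseconds), PCA is always
correlation-based.  Scores are oriented so that higher = better using each
indicator's direction-of-goodness metadata; reaction-time and error
indicators carry ``lower_better`` flags and are never pre-negated in the
data itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_DIRECTIONS = ("higher_better", "lower_better")
VALID_DOMAINS = ("Gf", "Gc", "EpisodicMemory", "WorkingMemory", "Speed", "Metabolic")

METABOLIC_INDICATORS = (
    "systolic_bp",
    "fasting_glucose",
    "fasting_triglycerides",
    "hdl_cholesterol",
    "waist_hip_ratio",
)


@dataclass
class BehaviorTable:
    """Subjects x indicators table with domain and direction metadata.

    ``data`` is indexed by subject_id; ``domains`` and ``directions`` map
    every indicator column to its domain and direction of goodness.
    ``occasion`` is 'T1', 'T2' or 'change'.
    """

    data: pd.DataFrame
    domains: dict[str, str]
    directions: dict[str, str]
    occasion: str = "T1"

    def __post_init__(self) -> None:
        for col in self.data.columns:
            if col not in self.domains:
                raise ValueError(f"indicator {col!r} has no domain label")
            if self.domains[col] not in VALID_DOMAINS:
                raise ValueError(f"unknown domain {self.domains[col]!r} for {col!r}")
            if self.directions.get(col) not in VALID_DIRECTIONS:
                raise ValueError(f"indicator {col!r} needs a valid direction flag")
        if self.data.index.duplicated().any():
            raise ValueError("subject ids must be unique within an occasion")

    def indicators(self, domain: str) -> list[str]:
        return [c for c in self.data.columns if self.domains[c] == domain]

    @property
    def subjects(self) -> pd.Index:
        return self.data.index


@dataclass
class ComponentScores:
    """First-principal-component scores for one domain at one occasion."""

    domain: str
    occasion: str
    scores: pd.Series               # standardized (unit variance), higher = better
    loadings: pd.Series             # corr(indicator, component); |loading| <= 1
    explained_fraction: float       # PC1 eigenvalue / number of indicators
    dropped_subjects: list[str] = field(default_factory=list)


def change_table(t1: BehaviorTable, t2: BehaviorTable) -> BehaviorTable:
    """Elementwise Time 2 - Time 1 difference scores, metadata carried over."""
    if list(t1.data.columns) != list(t2.data.columns):
        raise ValueError("occasions have different indicator columns")
    if not t1.data.index.equals(t2.data.index):
        raise ValueError("occasions cover different subjects")
    return BehaviorTable(
        data=t2.data - t1.data,
        domains=dict(t1.domains),
        directions=dict(t1.directions),
        occasion="change",
    )


def _pc1(z: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """PC1 of already-standardized columns: (scores, loadings, var fraction)."""
    n, p = z.shape
    corr = (z.T @ z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    lam1 = eigvals[-1]
    v1 = eigvecs[:, -1]
    scores = z @ v1
    if lam1 <= 0:
        raise ValueError("degenerate correlation matrix (PC1 eigenvalue <= 0)")
    scores = scores / np.sqrt(lam1)          # unit-variance component scores
    loadings = v1 * np.sqrt(lam1)            # correlation of indicator with PC1
    return scores, loadings, float(lam1 / p)


def _oriented(scores, loadings, align: np.ndarray):
    """Flip sign so the mean direction-aligned loading is positive."""
    if float(np.mean(align * loadings)) < 0:
        return -scores, -loadings
    return scores, loadings


def domain_component_scores(table: BehaviorTable, domain: str) -> ComponentScores:
    """PC1 scores of the standardized indicators of one domain.

    Complete-case (listwise) within the domain; requires >= 3 complete
    subjects.  Sign is fixed so that, after aligning lower-is-better
    indicators, the mean loading is positive (higher score = better
    performance).  A single-indicator domain returns the standardized
    (direction-oriented) indicator itself.
    """
    cols = table.indicators(domain)
    if not cols:
        raise ValueError(f"domain {domain!r} has no indicators")
    sub = table.data[cols].dropna(axis=0, how="any")
    dropped = [s for s in table.data.index if s not in sub.index]
    if sub.shape[0] < 3:
        raise ValueError(f"domain {domain!r}: need >= 3 complete-case subjects")
    std = sub.std(axis=0, ddof=1)
    if (std == 0).any():
        bad = list(std.index[std == 0])
        raise ValueError(f"zero-variance indicator(s) in {domain!r}: {bad}")
    z = ((sub - sub.mean(axis=0)) / std).to_numpy()
    scores, loadings, frac = _pc1(z)
    align = np.array(
        [1.0 if table.directions[c] == "higher_better" else -1.0 for c in cols]
    )
    scores, loadings = _oriented(scores, loadings, align)
    return ComponentScores(
        domain=domain,
        occasion=table.occasion,
        scores=pd.Series(scores, index=sub.index, name=f"{domain}_{table.occasion}"),
        loadings=pd.Series(loadings, index=cols),
        explained_fraction=frac,
        dropped_subjects=dropped,
    )


def metabolic_risk_scores(
    baseline: BehaviorTable, change: BehaviorTable
) -> tuple[ComponentScores, ComponentScores]:
    """Baseline metabolic-risk PC1 and change-in-metabolic-risk PC1.

    Baseline risk comes from the Time 1 indicators, change-in-risk from the
    raw longitudinal change scores.  Orientation: higher score = higher risk,
    i.e. the mean loading of risk-when-high indicators is positive (HDL
    cholesterol, the protective indicator, aligns negatively).  Subjects
    missing any indicator are dropped listwise.
    """
    for tab in (baseline, change):
        missing = [c for c in METABOLIC_INDICATORS if c not in tab.data.columns]
        if missing:
            raise ValueError(f"missing metabolic indicator columns: {missing}")

    out = []
    for tab, occ in ((baseline, "T1"), (change, "change")):
        cols = list(METABOLIC_INDICATORS)
        sub = tab.data[cols].dropna(axis=0, how="any")
        dropped = [s for s in tab.data.index if s not in sub.index]
        if sub.shape[0] < 3:
            raise ValueError("need >= 3 subjects with complete metabolic data")
        std = sub.std(axis=0, ddof=1)
        if (std == 0).any():
            bad = list(std.index[std == 0])
            raise ValueError(f"zero-variance metabolic indicator(s): {bad}")
        z = ((sub - sub.mean(axis=0)) / std).to_numpy()
        scores, loadings, frac = _pc1(z)
        # Risk orientation is the inverse of goodness orientation.
        align = np.array(
            [-1.0 if tab.directions[c] == "higher_better" else 1.0 for c in cols]
        )
        scores, loadings = _oriented(scores, loadings, align)
        out.append(
            ComponentScores(
                domain="Metabolic",
                occasion=occ,
                scores=pd.Series(
                    scores, index=sub.index, name=f"metabolic_risk_{occ}"
                ),
                loadings=pd.Series(loadings, index=cols),
                explained_fraction=frac,
                dropped_subjects=dropped,
            )
        )
    return out[0], out[1]


def assemble_score_block(
    components: list[ComponentScores],
    extra: dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """Subjects x variables block for PLS (union of subjects, NaN if missing).

    Downstream PLS requires complete rows; callers should inspect and drop
    incomplete subjects explicitly (a drop report is their responsibility).
    """
    pieces = {c.scores.name: c.scores for c in components}
    if extra:
        pieces.update(extra)
    return pd.DataFrame(pieces)
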