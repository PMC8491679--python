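#!/usr/bin/env python
"""Reduce the cognitive battery to per-domain component scores.

Correlation-based PCA per domain, separately for Time 1, Time 2 and the
Time 2 - Time 1 difference scores; single-component models only, oriented
so that higher = better.  Writes loadings and score tables under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from boldvar import components as comp
from boldvar import synthgen
from boldvar.pipeline import COGNITIVE_DOMAINS


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = synthgen.load_cohort(args.cohort)
    tables = {
        "T1": cohort.behavior.t1,
        "T2": cohort.behavior.t2,
        "change": comp.change_table(cohort.behavior.t1, cohort.behavior.t2),
    }
    args.out.mkdir(parents=True, exist_ok=True)
    loadings_rows = []
    for occ, table in tables.items():
        scores = [comp.domain_component_scores(table, d) for d in COGNITIVE_DOMAINS]
        block = comp.assemble_score_block(scores)
        block.to_csv(args.out / f"component_scores_{occ}.tsv", sep="\t")
        for cs in scores:
            print(f"{occ:>6s} {cs.domain:<15s} PC1 explains "
                  f"{100 * cs.explained_fraction:5.1f}% of indicator variance")
            for ind, ld in cs.loadings.items():
                loadings_rows.append(
                    {"occasion": occ, "domain": cs.domain, "indicator": ind,
                     "loading": ld}
                )
    pd.DataFrame(loadings_rows).to_csv(
        args.out / "component_loadings.tsv", sep="\t", index=False
    )
    print(f"scores and loadings written under {args.out}")


if __name__ == "__main__":
    main()
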