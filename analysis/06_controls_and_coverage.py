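#!/usr/bin/env python
"""Metabolic-risk controls and parcel coverage of the suprathreshold map.

Builds baseline and change-in metabolic-risk PCA components, regresses the
SD_BOLD-change brain score on the cognition/age change score while
controlling for both, screens high-leverage cases with the Cook's 4/n rule
(refit once), and summarizes suprathreshold coverage of a synthetic parcel
volume.  Requires the tables written by 04_pls_change_change.py.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from boldvar import components as comp
from boldvar import controls as ctrl
from boldvar import synthgen


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = synthgen.load_cohort(args.cohort)
    scores = pd.read_csv(args.out / "pls_latent_scores_lv1.tsv", sep="\t",
                         index_col="subject_id")
    change = comp.change_table(cohort.behavior.t1, cohort.behavior.t2)
    base_pc, change_pc = comp.metabolic_risk_scores(cohort.behavior.t1, change)
    table = pd.DataFrame(
        {"brain_change_score": scores["brain_score"],
         "cognition_age_change": scores["behavior_score"],
         "metabolic_baseline": base_pc.scores,
         "metabolic_change": change_pc.scores}
    )
    initial = ctrl.fit_control_regression(table)
    filtered = ctrl.cooks_filter(initial)

    pd.DataFrame(
        {"coef_initial": initial.params, "p_initial": initial.pvalues,
         "coef_filtered": filtered.params, "p_filtered": filtered.pvalues}
    ).to_csv(args.out / "control_regression.tsv", sep="\t")

    print(f"control regression on n = {initial.n} complete cases:")
    for name in ("cognition_age_change", "metabolic_baseline", "metabolic_change"):
        print(f"  {name:<22s} coef {initial.params[name]:+.3f}  p = {initial.pvalues[name]:.3g}")
    thr = ctrl.format_threshold(filtered.cooks_threshold)
    print(f"Cook's screen (D > {thr}): {len(filtered.excluded_subjects)} cases held out; "
          f"refit metabolic p-values: baseline {filtered.pvalues['metabolic_baseline']:.2g}, "
          f"change {filtered.pvalues['metabolic_change']:.2g}")

    bsr_tab = pd.read_csv(args.out / "pls_voxel_bsr_lv1.tsv", sep="\t")
    supra = bsr_tab.loc[np.abs(bsr_tab["bsr"]) >= 3.0, "voxel_id"].to_numpy()
    labels = synthgen.generate_parcels(cohort.config)
    coverage = ctrl.parcel_coverage(labels, supra)
    coverage.to_csv(args.out / "parcel_coverage.tsv", sep="\t")
    print("parcel coverage by suprathreshold voxels:")
    for lab, row in coverage.iterrows():
        print(f"  {row['name']:<12s} {row['covered']:4d}/{row['total']:<4d} = {row['percent']}%")


if __name__ == "__main__":
    main()
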