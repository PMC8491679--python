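#!/usr/bin/env python
"""Functional-integration change and its spatial specificity.

Computes each subject's PC1-variance percentage (spatial PCA) over the
suprathreshold voxel set at both occasions, then over 100 size-matched
random subthreshold samples and the farthest-from-threshold set, and
compares how each set's integration change correlates with the latent
cognition/age change score (Steiger's Z for dependent correlations).
Requires the tables written by 04_pls_change_change.py.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from boldvar import integration as integ
from boldvar import synthgen


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--n-samples", type=int, default=100)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    cohort = synthgen.load_cohort(args.cohort)
    bsr_tab = pd.read_csv(args.out / "pls_voxel_bsr_lv1.tsv", sep="\t")
    scores = pd.read_csv(args.out / "pls_latent_scores_lv1.tsv", sep="\t")
    subjects = list(scores["subject_id"])
    behav_sc = scores["behavior_score"].to_numpy()
    brain_sc = scores["brain_score"].to_numpy()
    voxel_ids = bsr_tab["voxel_id"].to_numpy()
    bsr = bsr_tab["bsr"].to_numpy()

    supra_ids = voxel_ids[np.abs(bsr) >= 3.0]
    pool = voxel_ids[np.abs(bsr) < 3.0]
    size = min(supra_ids.size, pool.size)

    def fi_change(ids):
        out = np.empty(len(subjects))
        for i, sid in enumerate(subjects):
            f1 = integ.pc1_variance_fraction(cohort.series[(sid, 1)], ids)
            f2 = integ.pc1_variance_fraction(cohort.series[(sid, 2)], ids)
            out[i] = f2 - f1
        return out

    fi_supra = fi_change(supra_ids)
    samples = integ.sample_matched_voxel_sets(pool, size, args.n_samples, args.seed + 7)
    fi_samples = np.stack([fi_change(s.voxel_ids) for s in samples])
    rep = integ.representative_sample(samples, fi_samples)
    fi_rep = fi_samples[int(rep.sample_id.split("_")[1])]
    far = integ.farthest_subthreshold_set(bsr, voxel_ids, size)
    fi_far = fi_change(far.voxel_ids)

    r = lambda a, b: float(np.corrcoef(a, b)[0, 1])
    n = len(subjects)
    r_supra, r_rep, r_far = r(fi_supra, behav_sc), r(fi_rep, behav_sc), r(fi_far, behav_sc)
    z_rep, p_rep = integ.steiger_z(r_supra, r_rep, r(fi_supra, fi_rep), n)
    z_far, p_far = integ.steiger_z(r_supra, r_far, r(fi_supra, fi_far), n)

    pd.DataFrame(
        {"subject_id": subjects, "fi_change_suprathreshold": fi_supra,
         "fi_change_representative": fi_rep, "fi_change_farthest": fi_far}
    ).to_csv(args.out / "fi_change.tsv", sep="\t", index=False)

    per_subject_sd = fi_samples.std(axis=0, ddof=1)
    print(f"suprathreshold set: {supra_ids.size} voxels; matched sets: {size} voxels")
    print(f"random-sample FI-change SD per subject: median {np.median(per_subject_sd):.2f} "
          f"(range {per_subject_sd.min():.2f}-{per_subject_sd.max():.2f})")
    print(f"FI change vs SD_BOLD-change brain score: r = {r(fi_supra, brain_sc):.3f}")
    print(f"FI change vs cognition/age score: "
          f"suprathreshold r = {r_supra:.3f}, representative r = {r_rep:.3f}, "
          f"farthest r = {r_far:.3f}")
    print(f"Steiger Z (supra vs representative) = {z_rep:.2f}, p = {p_rep:.4g}")
    print(f"Steiger Z (supra vs farthest)       = {z_far:.2f}, p = {p_far:.4g}")


if __name__ == "__main__":
    main()
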