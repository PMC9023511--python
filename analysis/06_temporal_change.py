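#!/usr/bin/env python
"""Did the mixture of the two populations change through time?

Cross-tabulates inferred cluster labels against the region x birth-period
groups (collections with more than six sharks), tests every pair of
collections with a two-sided Fisher exact test, estimates the pooled
between-cluster Weir-Cockerham FST, and compares individual
heterozygosity between clusters.

Reads results/filtered.vcf, results/metadata_aged.csv and
results/cluster_assignments.tsv; writes composition and test tables under
results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from retropop import popgen, temporal
from retropop.genotypes import read_vcf


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--vcf", type=Path, default=Path("results/filtered.vcf"))
    ap.add_argument("--metadata", type=Path, default=Path("results/metadata_aged.csv"))
    ap.add_argument("--assignments", type=Path,
                    default=Path("results/cluster_assignments.tsv"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    assign = pd.read_csv(args.assignments, sep="\t").set_index("sample_id")
    geno = read_vcf(args.vcf)
    geno = geno.drop_samples([s for s in geno.samples if s not in assign.index])
    assign = assign.loc[geno.samples]
    meta = pd.read_csv(args.metadata).set_index("sample_id").loc[geno.samples]
    labels = assign.cluster.to_numpy()

    comp = temporal.composition_table(labels, meta.group.to_numpy())
    comp.data.to_csv(args.outdir / "composition.tsv", sep="\t", index=False)
    print("cluster composition (collections with > 6 sharks):")
    print(comp.data.round(3).to_string(index=False))

    tests = temporal.composition_change(comp)
    df = temporal.change_results_frame(tests)
    df.to_csv(args.outdir / "change_tests.tsv", sep="\t", index=False)
    tas = df[df.group_a.str.startswith("TAS") & df.group_b.str.startswith("TAS")]
    print("Tasman Sea temporal comparisons (two-sided Fisher exact):")
    print(tas.round(6).to_string(index=False))

    if set(labels) >= {1, 2}:
        est, per_locus = temporal.pooled_cluster_fst(
            geno, labels, n_resamples=1000, rng=np.random.default_rng(args.seed)
        )
        per_locus.to_csv(args.outdir / "pooled_fst_per_locus.tsv", sep="\t", index=False)
        print(f"pooled between-cluster FST = {est.theta:.4f} "
              f"(bootstrap p = {est.p_value}, 95% CI {est.ci_95[0]:.4f}-{est.ci_95[1]:.4f})")

        het = popgen.individual_heterozygosity(geno)
        miss = geno.missing_mask().mean(axis=1)
        hc = temporal.cluster_het_comparison(het.to_numpy(), labels, missing=miss)
        print(
            f"heterozygosity: cluster 1 {hc['mean_1']:.3f} +/- {hc['se_1']:.3f}, "
            f"cluster 2 {hc['mean_2']:.3f} +/- {hc['se_2']:.3f} (Welch p = {hc['p_value']:.3f})"
        )
        print(
            f"missing data: cluster 1 {100 * hc['missing_1']:.2f}%, "
            f"cluster 2 {100 * hc['missing_2']:.2f}%"
        )


if __name__ == "__main__":
    main()
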