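#!/usr/bin/env python
"""Diversity, relatedness and pairwise differentiation.

Removes the duplicate controls (and any residual identical genotypes found
by the relatedness scan), then computes per-sample heterozygosity, the
heterozygosity ~ missingness control regression, pairwise Weir-Cockerham
FST between birth periods and between region x period groups (bootstrap
significance over loci, FDR-adjusted), folded-SFS diversity per period, and
a PCoA of the group FST matrix.

Reads results/filtered.vcf + results/metadata_aged.csv; writes the stats
tables under results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from retropop import popgen, structure
from retropop.genotypes import read_vcf


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--vcf", type=Path, default=Path("results/filtered.vcf"))
    ap.add_argument("--metadata", type=Path, default=Path("results/metadata_aged.csv"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--resamples", type=int, default=1000)
    args = ap.parse_args()
    rng = np.random.default_rng(args.seed)

    geno = read_vcf(args.vcf)
    geno = geno.drop_samples([s for s in geno.samples if s.endswith("_dup")])
    A, flags = popgen.relatedness_ajk(geno)
    dups = sorted({r.sample_2 for r in flags.itertuples() if r.flag == "duplicate"})
    if dups:
        print(f"removing identical genotypes: {dups}")
        geno = geno.drop_samples(dups)
    flags.to_csv(args.outdir / "relatedness_flags.tsv", sep="\t", index=False)

    meta = pd.read_csv(args.metadata).set_index("sample_id").loc[geno.samples]
    het = popgen.individual_heterozygosity(geno)
    miss = pd.Series(geno.missing_mask().mean(axis=1), index=geno.samples)
    pd.DataFrame({"heterozygosity": het, "missing_fraction": miss}).to_csv(
        args.outdir / "per_sample_stats.tsv", sep="\t"
    )
    slope, r2, p = popgen.het_missingness_regression(het, miss)
    print(f"heterozygosity ~ missingness: R^2 = {r2:.3f}, p = {p:.2f} "
          "(no correlation expected if missingness is benign)")

    for label, groups in [("periods", meta.birth_period), ("groups", meta.group)]:
        pw = popgen.pairwise_fst_matrix(
            geno, groups.to_numpy(), n_resamples=args.resamples, rng=rng
        )
        pw.table().to_csv(args.outdir / f"fst_{label}.tsv", sep="\t")
        print(f"pairwise FST ({label}; theta lower triangle, FDR-adjusted p upper):")
        print(pw.table().round(4).to_string())
        if label == "groups":
            tested = [g for g in pw.groups if pw.theta.loc[g].notna().any()]
            D = pw.theta.loc[tested, tested].fillna(0.0).clip(lower=0.0)
            np.fill_diagonal(D.values, 0.0)
            pco = structure.pcoa(D)
            pco.to_dataframe().to_csv(args.outdir / "pcoa_groups.tsv", sep="\t")
            print(f"PCoA axis 1 explains {100 * pco.explained[0]:.1f}% of FST variation")

    rows = []
    for period, sub in meta.groupby("birth_period"):
        sfs = popgen.sfs_diversity(geno, sub.index.tolist())
        rows.append(dict(period=period, n_chrom=sfs.projection_n, S=sfs.S,
                         pi_per_snp=sfs.pi, theta_w=sfs.theta_w))
    div = pd.DataFrame(rows)
    div.to_csv(args.outdir / "diversity_by_period.tsv", sep="\t", index=False)
    print("diversity per period (per-SNP units):")
    print(div.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
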