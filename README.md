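# retropop

Retrospective population genomics of eastern-Australian tiger sharks
(*Galeocerdo cuvier*): a tested reimplementation of the analysis chain that
detects the decline of a cryptic historical population from archived and
contemporary SNP data.

Tiger sharks along Australia's east coast were long treated as one panmictic
stock. Genotyping historical specimens (trophy jaws, vertebrae) alongside
contemporary fin-clips and comparing samples by **back-calculated birth
year** — rather than catch year — reveals two weakly differentiated
populations whose mixture changed through time: the second cluster dominates
the oldest Tasman Sea collection and is nearly absent today. This package
implements every step of that analysis as a reusable, tested library, with a
synthetic-study generator standing in for the sequencing data (which were
never deposited).

## What is implemented

- **Ageing** (`retropop.growth`): inverse von Bertalanffy growth function
  `t = ln((L∞ − L_T)/(L∞ − L_0)) / (−k)` with sex-specific constants
  (males L∞ = 441.1 cm, k = 0.08, L0 = 123.4 cm; females 379.9/0.06/116.8;
  combined 433.7/0.06/121.5), fork-length (`L_T = 22.607 + 1.096 L_F`) and
  weight (`W_T = 2.5281×10⁻⁶ L_F^3.2603`) conversions, and binning of birth
  decades into the periods 1910–1960 / 1970–1990 / 2000.
- **Filtering** (`retropop.filtering`): the post-calling cascade — biallelic
  SNPs, QUAL > 30, minor allele count ≥ 3, locus missingness ≤ 20%, excess
  mean depth (> mean + 2 SD), LD pruning (r² < 0.25 within 800 bp),
  duplicate-control concordance > 80%, Hardy–Weinberg exact test (drop
  p < 0.05), sample call rate ≥ 70% — with a step-by-step audit report.
- **Population genetics** (`retropop.popgen`): Weir–Cockerham (1984)
  variance components (a, b, c) and multilocus θ = Σa/Σ(a+b+c), bootstrap /
  permutation significance with Benjamini–Hochberg FDR across pairs,
  per-individual heterozygosity, folded SFS via hypergeometric projection
  with π and Watterson θ_W = S/a_{n−1}, Yang-style relatedness A_jk, and the
  heterozygosity ~ missingness control regression.
- **Structure** (`retropop.structure`): genotype PCA, Gower-centred PCoA of
  FST matrices, DAPC-style cluster-number selection (k-means over retained
  PCs scored by BIC(K) = n ln(WSS_K/n) + K ln n, discriminant membership
  probabilities), and a PC-regression outlier scan with genomic-inflation
  correction.
- **Temporal inference** (`retropop.temporal`): cluster composition per
  region × birth-period collection, two-sided Fisher exact tests of
  composition change (exact integer enumeration), pooled between-cluster
  FST, and the between-cluster heterozygosity comparison.
- **Synthetic studies** (`retropop.simulate`): Balding–Nichols
  two-population draws (population frequencies Beta-distributed around an
  ancestral frequency with variance F·p(1−p)) arranged into the survey's
  seven collections, with realistic QUAL/depth artefacts, tissue-dependent
  missingness and duplicate-control pairs.

## Worked example

`analysis/` contains the numbered drivers; running them in order on the
default synthetic study (seed 1) reproduces the survey's qualitative result:

```bash
python analysis/01_simulate_study.py     # 110 samples x 1840 SNPs
python analysis/02_age_samples.py        # birth years 1917-2010
python analysis/03_filter_snps.py        # 1637/1840 SNPs retained
python analysis/04_popgen_stats.py
python analysis/05_structure_clusters.py
python analysis/06_temporal_change.py
```

The last two print:

```
BIC selects K = 2 (21 PCs retained)
...
        group  n_cluster1  n_cluster2  total  frac_cluster2
TAS_1910-1960           6          13     19          0.684
TAS_1970-1990           9           5     14          0.357
     TAS_2000          25           1     26          0.038
...
TAS_1910-1960      TAS_2000    13     6     1    25   54.17 0.000004
pooled between-cluster FST = 0.0135 (bootstrap p = 0.0, 95% CI 0.0117-0.0154)
```

Read: the clustering recovers exactly two populations; ~68% of the oldest
Tasman Sea sharks belong to cluster 2, which is essentially gone from
contemporary collections; the change is highly significant by Fisher's exact
test; and the pooled clusters are differentiated at FST ≈ 0.013, the
divergence the study was generated with. The same chain runs on any VCF +
metadata pair via the `retro` CLI (`retro report --vcf ... --metadata ...`).

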