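# Methods

## The question and the analysis design

Tiger sharks are long-lived (decades), so collections made in different
years mix generations. All temporal comparisons here are therefore made
between **birth cohorts**: each shark's age is back-calculated from its
size via the inverse von Bertalanffy growth function (VBGF),

    L(t) = L∞ − (L∞ − L0) e^(−k t)   ⇒   t = ln((L∞ − L_T)/(L∞ − L0)) / (−k),

its birth year is catch year minus the rounded age, and birth decades are
grouped into three periods (1910–1960, 1970–1990, 2000–). Sex-specific
growth constants are used where sex is known, otherwise the combined set.
Sharks recorded only with fork length or whole weight are converted to
total length first; the weight relationship is the inversion of
W_T = 2.5281×10⁻⁶ · L_F^3.2603 (W in kg, L in cm). The printed form of
that conversion in the source literature is ambiguous about where the 10⁻⁶
binds; the inversion used here is the only reading that produces realistic
sizes (80.3 kg ↔ 200 cm fork length), and it is exactly self-consistent
with the forward allometry. Ages are rounded half-up to whole years before
subtraction; births in 1961–1969 (none occur) would fold into the
historical bin.

## Synthetic studies

The genotype data behind the original survey are not deposited, so the
package ships a generator whose defaults *are* the study conditions, and
every downstream claim is tested against it.

- **Divergence model.** Balding–Nichols: per locus an ancestral frequency
  p ~ U(0.10, 0.50); each population's frequency is Beta(p(1−F)/F,
  (1−p)(1−F)/F), i.e. mean p and variance F·p(1−p); genotypes are
  Binomial(2, p_pop). Two populations drawn independently with the same F
  have expected Weir–Cockerham θ ≈ F; simulations at F ∈ {0.013, 0.05,
  0.2} recover the nominal value within 25% (property-tested). Loci are
  unlinked; loci monomorphic in the pooled sample are redrawn.
- **Design.** 1,840 loci; seven collections (region × birth period) with
  sizes 12/14/7/15/19/14/26 and population-2 counts 0/1/0/1/13/5/0 —
  the 13/19 historical Tasman Sea share is the signal the temporal tests
  must detect. Ages are uniform on [2, 30] years, truncated so catch years
  stay ≤ 2015; lengths are emitted with Gaussian noise (SD 2 cm,
  configurable to 0 for exact round-trip tests); configurable fractions of
  samples carry only fork length (15%) or only weight (17%, matching the
  20/115 weight-only sharks reported).
- **Artefacts.** Site QUAL is a shifted gamma placing 5% of sites at or
  below the QUAL-30 threshold; site depth is Gamma-distributed with 2% of
  sites inflated 4×, so the depth filter has known expected casualties.
  Genotypes are masked per sample at 1.14% (jaw/vertebra specimens, caught
  before 2000) or 0.35% (fin clips), the reported per-cluster means. Three
  duplicate-control pairs re-emit a sample's genotypes under an independent
  missingness mask. An optional historical-damage mode injects genotype
  errors (off by default).
- **What it does not emulate:** linkage and recombination, site-frequency
  spectra shaped by demography (the ancestral-MAF prior is flat, so
  singleton-heavy spectra never occur), sequencing-level error structure,
  and selection. Passing tests therefore demonstrate that the *methods*
  recover known inputs under the stated noise model, not that the original
  biological conclusions are certain.

## Filtering

The cascade applies, in order: biallelic SNPs only; QUAL > 30; minor
allele count ≥ 3 (the MAC filter that removes damage-inflated
singletons/doubletons); per-locus missingness ≤ 20%; excess mean site
depth; greedy left-to-right LD pruning (drop the later locus of any pair
closer than 800 bp with r² ≥ 0.25, r² = squared Pearson correlation of
dosages over jointly complete samples); duplicate-control concordance
(> 80% of informative pairs identical; loci with no informative pair are
kept but flagged); Hardy–Weinberg exact test on the pooled sample (drop
p < 0.05); and finally sample call rate ≥ 70%. Every step logs
before/after counts and its realized parameters.

Numerical/design notes:

- **Excess depth** is "mean site depth > cohort mean + 2 SD" (a paralog
  heuristic; no published threshold exists for this step). Because the
  threshold adapts to the cohort, a literal re-run on filtered output can
  trim further; the report records the realized threshold, and re-running
  with that frozen value is a no-op — that is the sense in which the
  cascade is idempotent.
- **HWE on pooled, structured samples** preferentially removes the most
  differentiated loci (Wahlund effect). The behaviour is reproduced
  deliberately, because the analysis being reimplemented did it; it is a
  conservative bias against the temporal signal, not in its favour.
- The HWE test enumerates heterozygote counts of the observed parity with
  exact integer weights (multinomial × 2^h), so tie handling is exact.

## Population-genetic statistics

- **FST.** Weir & Cockerham (1984) variance components per biallelic
  locus from population sample sizes, allele frequencies and observed
  heterozygote proportions (missing genotypes excluded per locus);
  multilocus θ is the ratio of sums Σa/Σ(a+b+c). Monomorphic or
  degenerate loci contribute zeros; negative estimates are reported as
  computed, not clamped. Significance defaults to bootstrap over loci
  (p = fraction of replicate θ ≤ 0, percentile CI); label permutation is
  available — the phrase "permutations over loci" in the source is
  ambiguous between the two, so both exist and the bootstrap is the
  default. Benjamini–Hochberg adjustment is applied across pairwise
  comparisons.
- **Diversity.** π and Watterson θ_W are reported **per SNP dataset**, not
  per base pair: capture data has no callable-site denominator, so only
  relative comparisons between groups are meaningful. The folded SFS is
  obtained by hypergeometric projection to a common chromosome count;
  each segregating site distributes one unit of mass over the projected
  polymorphic classes (renormalised, so the folded spectrum sums to S).
- **Relatedness.** Yang-style unadjusted A_jk with allele frequencies from
  the full sample; pairs with A_jk ≥ 0.25 are flagged as putative kin
  (second-degree threshold — the source states none) and pairs with
  IBS ≥ 0.99 as duplicates. Technical replicates and duplicate genotypes
  are removed before any diversity or structure statistic.

## Cluster-number selection

PCA scores (per-locus mean imputation, centring, SVD, deterministic sign
convention) feed k-means (20 deterministic restarts) for K = 1..6, scored
by BIC(K) = n ln(WSS_K/n) + K ln n; the selected K is the argmin, and a
linear discriminant on the selected clusters yields membership
probabilities. Cluster labels are ordered so cluster 2 is the one with the
smaller contemporary share, matching the convention that cluster 2 is the
fading population.

**How many PCs feed the k-means is the load-bearing choice.** Two failure
modes bracket it: in few dimensions (≲ n/8 PCs) a k-means split removes
≈ 2/π of the leading eigenvalue even from pure noise, which exceeds the
ln(n) BIC penalty and inflates K; in many dimensions (≳ n/4) accumulated
noise variance swamps a weak between-population signal and BIC collapses
to K = 1. The default retains round(n/5) PCs (21 of 107 samples), inside
the window where simulations at the study's divergence select K = 2 in
≥ 95% of seeds and a single simulated population selects K = 1 in 100%.
Cross-validated assignment accuracy — the usual DAPC tuning device — was
evaluated and rejected as the default: it prefers ~5 PCs (assignment is
already perfect there) where the BIC overfits. A fixed override (e.g. the
26 PCs suggested by cross-validated DAPC on the original data) is
available.

## Outlier scan

Standardised genotypes are regressed on the first K = 2 PCs; each locus's
vector of regression z-scores receives a Mahalanobis distance using the
ordinary covariance across loci, rescaled by the genomic inflation factor
median(D²)/median(χ²_K) and referred to χ²_K; q-values are
Benjamini–Hochberg, outliers at q < 0.1. Constant loci are excluded. This
is the ordinary-covariance variant of the robust-covariance scan; the
inflation rescaling absorbs most of the difference on simulated data
(GIF ≈ 1 under neutrality).

## Temporal inference

Cluster composition is tabulated per region × birth-period collection,
keeping collections with more than six sharks. Pairs of collections are
compared with a **two-sided Fisher exact test**: hypergeometric
enumeration with exact integer probabilities, summing all tables no more
probable than the observed one (ties exact by construction). The test of
the reported 5/14-vs-0/26 table gives p = 0.003043, matching the printed
0.003; the 13/19-vs-0/26 table gives p ≈ 3.7×10⁻⁷. The printed 0.041 for
the 13/19-vs-5/14 comparison does not match two-sided enumeration of those
counts (which gives ≈ 0.085) under any standard convention tried; that
value is documented as unreproducible from the stated counts and not used
as a check. Composition tests are reported unadjusted by default (BH
optional), mirroring how the original values were presented.

Pooled-cluster FST reuses the Weir–Cockerham machinery with clusters as
populations and emits a per-locus θ table: the diagnostic that
differentiation is spread across many loci (removing the top 1% leaves θ
above half its value) rather than driven by a few artefacts. The
between-cluster heterozygosity comparison uses Welch's t by default (the
source names no test); Mann–Whitney is available.

## Problem sizes and reproducibility

Simulated studies default to the survey's own dimensions (1,840 SNPs, 107
sharks + 3 duplicate controls); resampling defaults to 1,000 replicates,
with smaller replicate counts used in the test suite where only the sign
of a decision is at stake. All randomness flows from a single integer
seed through `numpy.random.default_rng`; k-means restarts are seeded, so
identical configurations reproduce byte-identical output tables.

## Known limitations

- Point back-calculated ages carry no uncertainty; a shark near a period
  boundary can be mis-binned by measurement noise (the survey has the
  same property).
- Per-SNP diversity units preclude comparison with per-bp estimates from
  other studies.
- The BIC window analysis above is specific to WSS-based k-means scoring;
  model-based clustering (e.g. admixture-coefficient estimation with
  cross-entropy selection) is out of scope, represented here only by the
  DAPC-style route.
- The generator draws unlinked loci, so the LD-pruning step is exercised
  mainly by the engineered fixtures, not by realistic linkage.
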