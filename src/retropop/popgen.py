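"""Core population-genetic statistics.

Implements the Weir & Cockerham (1984) FST estimator from per-locus variance
components, resampling significance with Benjamini-Hochberg correction
across pairwise comparisons, per-individual heterozygosity, the folded site
frequency spectrum with hypergeometric projection plus the Watterson and
pairwise-diversity estimators, Yang-style genomic relatedness, and the
heterozygosity ~ missingness control regression.

Diversity here is reported per SNP in the dataset, not per base pair:
capture data carries no callable-site denominator, so absolute per-bp rates
are not estimable and only relative comparisons between groups are
meaningful.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "FstEstimate",
    "PairwiseFst",
    "SfsSummary",
    "wc_fst",
    "wc_components",
    "pairwise_fst_matrix",
    "individual_heterozygosity",
    "sfs_diversity",
    "relatedness_ajk",
    "het_missingness_regression",
]


@dataclass
class FstEstimate:
    """Multilocus Weir-Cockerham theta with its per-locus components.

    theta = sum(a) / sum(a+b+c) over loci (ratio of sums); a is the
    among-population variance component, b between-individuals-within-
    population, c within-individuals.  Negative estimates are reported as
    computed.
    """

    theta: float
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    p_value: float | None = None
    n_resamples: int = 0
    ci_95: tuple[float, float] | None = None

    def per_locus_theta(self) -> np.ndarray:
        denom = self.a + self.b + self.c
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom != 0, self.a / denom, np.nan)


def _pop_summaries(dosage: np.ndarray, labels: np.ndarray):
    """Per-population sample size, alt frequency and het proportion, per locus."""
    pops = np.unique(labels)
    n = np.zeros((len(pops), dosage.shape[1]))
    p = np.zeros_like(n)
    h = np.zeros_like(n)
    for i, g in enumerate(pops):
        sub = dosage[labels == g]
        called = sub != MISSING
        n[i] = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p[i] = np.where(called, sub, 0).sum(axis=0) / np.maximum(2 * n[i], 1)
            h[i] = ((sub == 1) & called).sum(axis=0) / np.maximum(n[i], 1)
    return pops, n, p, h


def wc_components(
    geno: GenotypeMatrix | np.ndarray, labels
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham variance components (a, b, c).

    Loci where any population has no genotyped sample, where the pooled
    sample is monomorphic, or where the size corrections degenerate
    (n_bar <= 1 or n_c <= 0) contribute zeros to all three components.
    """
    dosage = geno.dosage if isinstance(geno, GenotypeMatrix) else np.asarray(geno)
    labels = np.asarray(labels)
    if dosage.shape[0] != labels.shape[0]:
        raise ValueError("labels must align with samples")
    pops, n, p, h = _pop_summaries(dosage, labels)
    r = len(pops)
    if r < 2:
        raise ValueError("need at least two populations")
    ok_pop = (n >= 2).any(axis=1)
    if not ok_pop.all():
        bad = [str(pops[i]) for i in np.flatnonzero(~ok_pop)]
        raise ValueError(f"population(s) with <2 genotyped samples at every locus: {bad}")

    valid = (n > 0).all(axis=0)
    n_bar = n.mean(axis=0)
    n_total = n.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (n_total - (n**2).sum(axis=0) / n_total) / (r - 1)
        p_bar = (n * p).sum(axis=0) / n_total
        s2 = (n * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n * h).sum(axis=0) / n_total

        a = (n_bar / n_c) * (
            s2 - (1.0 / (n_bar - 1)) * (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
        )
        c = h_bar / 2

    poly = (p_bar > 0) & (p_bar < 1)
    usable = valid & poly & (n_bar > 1) & (n_c > 0)
    a = np.where(usable, a, 0.0)
    b = np.where(usable, b, 0.0)
    c = np.where(usable, c, 0.0)
    return a, b, c


def wc_fst(
    geno: GenotypeMatrix | np.ndarray,
    labels,
    n_resamples: int = 0,
    method: str = "bootstrap",
    rng: np.random.Generator | None = None,
) -> FstEstimate:
    """Multilocus Weir-Cockerham theta, optionally with resampling inference.

    method="bootstrap" (default): resample loci with replacement; the
    p-value is the fraction of replicate thetas <= 0 and a percentile 95% CI
    is attached.  method="permutation": shuffle population labels; p is the
    (add-one) fraction of permuted thetas >= observed.
    """
    a, b, c = wc_components(geno, labels)
    denom_total = (a + b + c).sum()
    if denom_total == 0:
        raise ValueError("no usable polymorphic loci")
    theta = a.sum() / denom_total
    est = FstEstimate(theta=float(theta), a=a, b=b, c=c)
    if n_resamples <= 0:
        return est
    rng = rng or np.random.default_rng()
    if method == "bootstrap":
        L = len(a)
        idx = rng.integers(0, L, size=(n_resamples, L))
        num = a[idx].sum(axis=1)
        den = (a + b + c)[idx].sum(axis=1)
        reps = np.where(den != 0, num / den, 0.0)
        est.p_value = float((reps <= 0).mean())
        est.ci_95 = tuple(np.percentile(reps, [2.5, 97.5]))
    elif method == "permutation":
        labels = np.asarray(labels)
        count = 0
        for _ in range(n_resamples):
            perm = rng.permutation(labels)
            pa, pb, pc = wc_components(geno, perm)
            pd_ = (pa + pb + pc).sum()
            t = pa.sum() / pd_ if pd_ != 0 else 0.0
            count += t >= theta
        est.p_value = (count + 1) / (n_resamples + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    est.n_resamples = n_resamples
    return est


@dataclass
class PairwiseFst:
    """All pairwise thetas between groups, with raw and FDR-adjusted p."""

    groups: list
    theta: pd.DataFrame
    p_value: pd.DataFrame
    q_value: pd.DataFrame

    def table(self) -> pd.DataFrame:
        """Theta in the lower triangle, adjusted p in the upper."""
        out = self.theta.copy()
        for i, gi in enumerate(self.groups):
            for j, gj in enumerate(self.groups):
                if j > i:
                    out.loc[gi, gj] = self.q_value.loc[gi, gj]
                elif j == i:
                    out.loc[gi, gj] = np.nan
        return out


def pairwise_fst_matrix(
    geno: GenotypeMatrix,
    groups,
    n_resamples: int = 1000,
    method: str = "bootstrap",
    min_group_size: int = 2,
    rng: np.random.Generator | None = None,
) -> PairwiseFst:
    """Pairwise Weir-Cockerham theta between all groups.

    Groups below ``min_group_size`` are skipped with a warning (NaN cells);
    p-values are Benjamini-Hochberg adjusted across the tested pairs.
    """
    groups = np.asarray(groups)
    rng = rng or np.random.default_rng()
    names = [g for g in pd.unique(groups)]
    sizes = {g: int((groups == g).sum()) for g in names}
    usable = [g for g in names if sizes[g] >= min_group_size]
    for g in names:
        if g not in usable:
            warnings.warn(f"group {g!r} below minimum size {min_group_size}; skipped")
    theta = pd.DataFrame(np.nan, index=names, columns=names)
    pval = pd.DataFrame(np.nan, index=names, columns=names)
    tested, raw_p = [], []
    for ga, gb in itertools.combinations(usable, 2):
        sel = np.flatnonzero((groups == ga) | (groups == gb))
        sub = geno.take_samples(sel)
        est = wc_fst(sub, groups[sel], n_resamples=n_resamples, method=method, rng=rng)
        theta.loc[ga, gb] = theta.loc[gb, ga] = est.theta
        pval.loc[ga, gb] = pval.loc[gb, ga] = est.p_value
        tested.append((ga, gb))
        raw_p.append(est.p_value)
    qval = pval.copy()
    if raw_p:
        q = multipletests(raw_p, method="fdr_bh")[1]
        for (ga, gb), qv in zip(tested, q):
            qval.loc[ga, gb] = qval.loc[gb, ga] = qv
    return PairwiseFst(groups=names, theta=theta, p_value=pval, q_value=qval)


def individual_heterozygosity(geno: GenotypeMatrix) -> pd.Series:
    """Per-sample proportion of heterozygous loci among genotyped loci.

    Normalising by each sample's genotyped-locus count makes the measure
    comparable across samples with different missingness.  Samples with zero
    genotyped loci come back NaN with a warning.
    """
    called = geno.dosage != MISSING
    n_called = called.sum(axis=1)
    if (n_called == 0).any():
        warnings.warn("sample(s) with zero genotyped loci: heterozygosity undefined")
    with np.errstate(invalid="ignore"):
        het = (geno.dosage == 1).sum(axis=1) / np.where(n_called > 0, n_called, np.nan)
    return pd.Series(het, index=geno.samples, name="heterozygosity")


@dataclass
class SfsSummary:
    """Folded SFS at a projected sample size, with diversity estimators.

    folded : counts indexed by minor-allele class 1..floor(n/2); sums to S
    S : segregating sites in the subset
    pi : mean pairwise diversity per SNP
    theta_w : Watterson estimator per SNP dataset (S / a_{n-1})
    a_n : harmonic normaliser sum_{i=1}^{n-1} 1/i
    """

    projection_n: int
    folded: np.ndarray
    S: int
    pi: float
    theta_w: float
    a_n: float


def sfs_diversity(
    geno: GenotypeMatrix, subset: list[str] | np.ndarray | None = None, projection_n: int | None = None
) -> SfsSummary:
    """Folded SFS by hypergeometric projection, plus pi and Watterson theta.

    The subset's genotypes are projected down to ``projection_n`` chromosomes
    (default: twice the minimum genotyped-sample count across loci); each
    segregating site distributes one unit of mass over the projected allele-
    frequency classes, conditioned on remaining polymorphic, then folded.
    """
    if subset is not None:
        idx = geno.sample_index(list(subset)) if isinstance(subset[0], str) else np.asarray(subset)
        geno = geno.take_samples(idx)
    if geno.n_samples == 0:
        raise ValueError("empty sample subset")
    alt, total = geno.allele_counts()
    usable = total >= 2
    alt, total = alt[usable], total[usable]
    if projection_n is None:
        projection_n = int(total.min())
    n = int(projection_n)
    if n < 2:
        raise ValueError("projection_n must be >= 2")
    if n > total.min():
        raise ValueError(
            f"projection_n={n} exceeds the smallest genotyped chromosome count {int(total.min())}"
        )
    seg = (alt > 0) & (alt < total)
    S = int(seg.sum())

    # projection: P(j of n | d of m) hypergeometric, renormalised over the
    # polymorphic classes 1..n-1 so each site contributes exactly one unit
    d, m = alt[seg].astype(float), total[seg].astype(float)
    j = np.arange(1, n)
    log_p = (
        _log_comb(d[:, None], j[None, :])
        + _log_comb((m - d)[:, None], (n - j)[None, :])
        - _log_comb(m[:, None], float(n))
    )
    p = np.exp(log_p)
    row_sums = p.sum(axis=1, keepdims=True)
    p = np.divide(p, row_sums, out=np.zeros_like(p), where=row_sums > 0)
    unfolded = p.sum(axis=0)  # classes 1..n-1

    n_fold = n // 2
    folded = np.zeros(n_fold)
    for k in range(1, n_fold + 1):
        if k == n - k:
            folded[k - 1] = unfolded[k - 1]
        else:
            folded[k - 1] = unfolded[k - 1] + unfolded[n - k - 1]

    a_n = float(np.sum(1.0 / np.arange(1, n)))
    theta_w = S / a_n if S else 0.0
    with np.errstate(invalid="ignore"):
        pi_sites = 2.0 * alt * (total - alt) / (total * (total - 1))
    pi = float(pi_sites.mean()) if len(pi_sites) else 0.0
    return SfsSummary(projection_n=n, folded=folded, S=S, pi=pi, theta_w=theta_w, a_n=a_n)


def _log_comb(n, k):
    return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)


def relatedness_ajk(
    geno: GenotypeMatrix, kin_threshold: float = 0.25, ibs_duplicate: float = 0.99
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Yang-style unadjusted genomic relatedness A_jk for all sample pairs.

    A_jk = mean over loci of (x_j - 2p)(x_k - 2p) / (2p(1-p)) with allele
    frequencies estimated from the full sample; loci monomorphic in the
    sample are excluded.  Returns the relatedness matrix and a table of
    flagged pairs: putative kin (A_jk >= ``kin_threshold``) and duplicates
    (identity-by-state >= ``ibs_duplicate``).
    """
    X = geno.dosage_float()
    called = ~np.isnan(X)
    alt = np.nansum(X, axis=0)
    n2 = 2 * called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = alt / n2
    poly = (p > 0) & (p < 1) & (n2 > 0)
    if not poly.any():
        raise ValueError("no polymorphic loci for relatedness estimation")
    Xp = X[:, poly]
    pp = p[poly]
    Z = (Xp - 2 * pp) / np.sqrt(2 * pp * (1 - pp))
    Z = np.where(np.isnan(Z), 0.0, Z)
    V = (~np.isnan(Xp)).astype(float)
    num = Z @ Z.T
    cnt = V @ V.T
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(cnt > 0, num / cnt, np.nan)
    A_df = pd.DataFrame(A, index=geno.samples, columns=geno.samples)

    rows = []
    n = geno.n_samples
    for i in range(n):
        for jx in range(i + 1, n):
            both = ~np.isnan(Xp[i]) & ~np.isnan(Xp[jx])
            nb = both.sum()
            ibs = float((Xp[i, both] == Xp[jx, both]).mean()) if nb else np.nan
            ajk = A[i, jx]
            if (nb and ibs >= ibs_duplicate) or (np.isfinite(ajk) and ajk >= kin_threshold):
                rows.append(
                    dict(
                        sample_1=geno.samples[i],
                        sample_2=geno.samples[jx],
                        a_jk=ajk,
                        ibs=ibs,
                        flag="duplicate" if nb and ibs >= ibs_duplicate else "kin",
                    )
                )
    flags = pd.DataFrame(rows, columns=["sample_1", "sample_2", "a_jk", "ibs", "flag"])
    return A_df, flags


def het_missingness_regression(het, missing) -> tuple[float, float, float]:
    """OLS of individual heterozygosity on missing-data fraction.

    Returns (slope, R^2, two-sided p for the slope).  A heterozygosity
    vector with zero variance yields slope 0, R^2 0, p 1 (nothing to
    explain); a zero-variance predictor is an error.
    """
    het = np.asarray(het, dtype=float)
    missing = np.asarray(missing, dtype=float)
    if het.shape != missing.shape or het.size < 3:
        raise ValueError("need matched vectors of length >= 3")
    if np.std(missing) == 0:
        raise ValueError("missingness has zero variance; regression undefined")
    if np.std(het) == 0:
        return 0.0, 0.0, 1.0
    res = stats.linregress(missing, het)
    return float(res.slope), float(res.rvalue**2), float(res.pvalue)
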