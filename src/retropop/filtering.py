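"""Post-variant-calling SNP and sample filters.

The cascade reproduces a conservative capture-sequencing QC recipe, in
order: biallelic SNPs only; site quality above 30; minor allele count of at
least 3 (removes the singletons/doubletons that DNA damage inflates);
per-locus missingness at most 20%; excess mean site depth (paralog
heuristic); LD pruning within 800 bp at r^2 < 0.25; duplicate-control
concordance above 80%; Hardy-Weinberg exact-test survivors (p >= 0.05);
finally samples below 70% call rate are dropped.  Every step is logged in a
FilterReport so the locus accounting is auditable on any input.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "FilterConfig",
    "FilterReport",
    "hwe_exact",
    "ld_prune",
    "duplicate_concordance_filter",
    "find_duplicate_pairs",
    "run_filter_cascade",
]


@dataclass
class FilterConfig:
    min_qual: float = 30.0
    min_mac: int = 3
    max_locus_missing: float = 0.20
    depth_sd_multiplier: float = 2.0
    # a pre-computed absolute threshold overrides the adaptive mean + k*SD
    # rule; the cascade records the realized value in its report so a re-run
    # can be made exactly reproducible
    depth_threshold: float | None = None
    ld_window_bp: int = 800
    ld_r2_max: float = 0.25
    dup_min_concordance: float = 0.80
    hwe_alpha: float = 0.05
    min_sample_call_rate: float = 0.70


@dataclass
class FilterReport:
    """Ordered audit trail: one row per cascade step."""

    steps: list[dict] = field(default_factory=list)

    def add(self, name, loci_before, loci_after, samples_before, samples_after, **params):
        if loci_after > loci_before or samples_after > samples_before:
            raise ValueError("filter steps cannot add loci or samples")
        self.steps.append(
            dict(
                step=name,
                loci_before=loci_before,
                loci_after=loci_after,
                samples_before=samples_before,
                samples_after=samples_after,
                params=params,
            )
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            r = {k: v for k, v in s.items() if k != "params"}
            r["params"] = ";".join(f"{k}={v}" for k, v in s["params"].items())
            rows.append(r)
        return pd.DataFrame(rows)

    def realized_param(self, step: str, key: str):
        for s in self.steps:
            if s["step"] == step and key in s["params"]:
                return s["params"][key]
        return None


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test (two-sided, by probability order).

    Conditions on the observed minor-allele count: every heterozygote count
    of the same parity is enumerated, each weighted by its conditional
    probability, and the p-value sums all outcomes no more probable than the
    observed one.  Weights are exact integers (multinomial x 2^het), so ties
    are resolved exactly.  Monomorphic samples return 1.0.
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0 or int(c) != c:
            raise ValueError("genotype counts must be non-negative integers")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    n_a = 2 * n_aa + n_Aa
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0
    # weight(h) proportional to P(het = h | n, allele counts):
    #   n! * 2^h / (nAA! * h! * naa!)  -- common factors dropped
    weights = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        if hom_major < 0:
            continue
        w = (
            math.factorial(n)
            * 2**h
            // (math.factorial(hom_minor) * math.factorial(h) * math.factorial(hom_major))
        )
        weights[h] = w
    w_obs = weights[n_Aa]
    total = sum(weights.values())
    tail = sum(w for w in weights.values() if w <= w_obs)
    return tail / total


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over samples
    complete for both; undefined (no variance or <2 points) counts as 0."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xs, ys = x[ok].astype(float), y[ok].astype(float)
    if xs.std() == 0 or ys.std() == 0:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def ld_prune(
    geno: GenotypeMatrix, window_bp: int = 800, r2_max: float = 0.25
) -> np.ndarray:
    """Indices of loci kept by a greedy left-to-right prune.

    Within each scaffold, a locus is dropped when it sits closer than
    ``window_bp`` to an already-kept locus with which its genotype r^2
    reaches ``r2_max`` (the earlier locus wins).  Requires loci sorted by
    (scaffold, position).
    """
    chrom = geno.loci["chrom"].to_numpy()
    pos = geno.loci["pos"].to_numpy()
    for j in range(1, len(pos)):
        if chrom[j] == chrom[j - 1] and pos[j] < pos[j - 1]:
            raise ValueError("loci must be sorted by (scaffold, position)")
    kept: list[int] = []
    recent: list[int] = []  # kept loci on current scaffold, within reach
    cur_chrom = None
    for j in range(geno.n_loci):
        if chrom[j] != cur_chrom:
            cur_chrom = chrom[j]
            recent = []
        recent = [i for i in recent if pos[j] - pos[i] < window_bp]
        drop = any(
            _pairwise_r2(geno.dosage[:, i], geno.dosage[:, j]) >= r2_max for i in recent
        )
        if not drop:
            kept.append(j)
            recent.append(j)
    return np.array(kept, dtype=int)


# ---------------------------------------------------------------------------
# Duplicate-control concordance
# ---------------------------------------------------------------------------

def find_duplicate_pairs(samples: list[str]) -> list[tuple[int, int]]:
    """Duplicate-control pairs by the ``<id>_dup`` naming convention."""
    lookup = {s: i for i, s in enumerate(samples)}
    pairs = []
    for s, i in lookup.items():
        if s.endswith("_dup") and s[:-4] in lookup:
            pairs.append((lookup[s[:-4]], i))
    return sorted(pairs)


def duplicate_concordance_filter(
    geno: GenotypeMatrix,
    duplicate_pairs: list[tuple[int, int]],
    min_match: float = 0.80,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus keep mask from duplicate-pair genotype concordance.

    Concordance at a locus is the fraction of duplicate pairs with identical
    non-missing genotypes (pairs missing in either member are excluded from
    the denominator).  Loci with concordance > ``min_match`` are kept; loci
    with an empty denominator are kept but flagged (second return value).
    """
    if not duplicate_pairs:
        warnings.warn("no duplicate pairs available; concordance filter is a no-op")
        return np.ones(geno.n_loci, dtype=bool), np.zeros(geno.n_loci, dtype=bool)
    a_idx = np.array([p[0] for p in duplicate_pairs])
    b_idx = np.array([p[1] for p in duplicate_pairs])
    A, B = geno.dosage[a_idx], geno.dosage[b_idx]
    comparable = (A != MISSING) & (B != MISSING)
    n_cmp = comparable.sum(axis=0)
    n_match = (comparable & (A == B)).sum(axis=0)
    flagged = n_cmp == 0
    with np.errstate(invalid="ignore"):
        conc = np.where(n_cmp > 0, n_match / np.maximum(n_cmp, 1), np.nan)
    keep = flagged | (conc > min_match)
    return keep, flagged


# ---------------------------------------------------------------------------
# The cascade
# ---------------------------------------------------------------------------

def _is_biallelic_snp(loci: pd.DataFrame) -> np.ndarray:
    bases = {"A", "C", "G", "T"}
    ref_ok = loci["ref"].isin(bases)
    alt_ok = loci["alt"].isin(bases)
    return (ref_ok & alt_ok).to_numpy()


def run_filter_cascade(
    geno: GenotypeMatrix,
    config: FilterConfig | None = None,
    duplicate_pairs: list[tuple[int, int]] | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the full SNP/sample filter cascade; returns matrix + report.

    ``duplicate_pairs`` defaults to pairs inferred from the ``_dup`` id
    convention.  Raises if the input is empty or no locus survives.
    """
    config = config or FilterConfig()
    if geno.n_loci == 0 or geno.n_samples == 0:
        raise ValueError("empty genotype matrix")
    if duplicate_pairs is None:
        duplicate_pairs = find_duplicate_pairs(geno.samples)
    report = FilterReport()
    ns = geno.n_samples

    def apply(name, keep_mask, **params):
        nonlocal geno
        before = geno.n_loci
        geno = geno.take_loci(np.flatnonzero(keep_mask))
        report.add(name, before, geno.n_loci, ns, ns, **params)

    # 1. biallelic SNPs only
    apply("biallelic_snp", _is_biallelic_snp(geno.loci))

    # 2. site quality
    qual = geno.loci["qual"].to_numpy(dtype=float)
    apply("qual", qual > config.min_qual, min_qual=config.min_qual)

    # 3. minor allele count
    alt, total = geno.allele_counts()
    mac = np.minimum(alt, total - alt)
    apply("mac", mac >= config.min_mac, min_mac=config.min_mac)

    # 4. per-locus missingness
    apply(
        "locus_missingness",
        geno.locus_missingness() <= config.max_locus_missing,
        max_missing=config.max_locus_missing,
    )

    # 5. excess depth
    depth = geno.mean_site_depth()
    if config.depth_threshold is not None:
        thr = config.depth_threshold
    else:
        thr = float(np.nanmean(depth) + config.depth_sd_multiplier * np.nanstd(depth))
    with np.errstate(invalid="ignore"):
        keep = ~(depth > thr)
    apply("excess_depth", keep, threshold=round(thr, 6))

    # 6. LD prune
    before = geno.n_loci
    kept_idx = ld_prune(geno, config.ld_window_bp, config.ld_r2_max)
    geno = geno.take_loci(kept_idx)
    report.add(
        "ld_prune", before, geno.n_loci, ns, ns,
        window_bp=config.ld_window_bp, r2_max=config.ld_r2_max,
    )

    # 7. duplicate concordance
    if duplicate_pairs:
        keep, flagged = duplicate_concordance_filter(
            geno, duplicate_pairs, config.dup_min_concordance
        )
        apply(
            "duplicate_concordance", keep,
            min_match=config.dup_min_concordance,
            n_pairs=len(duplicate_pairs),
            n_flagged_empty=int(flagged.sum()),
        )
    else:
        report.add("duplicate_concordance", geno.n_loci, geno.n_loci, ns, ns, n_pairs=0)

    # 8. Hardy-Weinberg exact test on the pooled sample
    dos = geno.dosage
    called = dos != MISSING
    n_het = ((dos == 1) & called).sum(axis=0)
    n_hom_alt = (dos == 2).sum(axis=0)
    n_called = called.sum(axis=0)
    pvals = np.array(
        [
            hwe_exact(int(n - h - a), int(h), int(a)) if n > 0 else 1.0
            for n, h, a in zip(n_called, n_het, n_hom_alt)
        ]
    )
    apply("hwe", pvals >= config.hwe_alpha, alpha=config.hwe_alpha)

    if geno.n_loci == 0:
        raise ValueError(f"all loci removed by the cascade:\n{report.to_dataframe()}")

    # 9. sample call rate
    keep_samples = geno.sample_call_rate() >= config.min_sample_call_rate
    before_s = geno.n_samples
    geno = geno.take_samples(np.flatnonzero(keep_samples))
    report.add(
        "sample_call_rate", geno.n_loci, geno.n_loci, before_s, geno.n_samples,
        min_call_rate=config.min_sample_call_rate,
    )
    return geno, report
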