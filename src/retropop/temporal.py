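"""Temporal change in cluster composition.

The headline question: did the relative contribution of the two cryptic
populations to eastern-Australian collections change through time?  Inferred
cluster labels are cross-tabulated against the spatiotemporal groups, pairs
of collections are compared with two-sided Fisher exact tests, the pooled
clusters get a Weir-Cockerham FST, and individual heterozygosity is compared
between clusters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genotypes import GenotypeMatrix
from .popgen import FstEstimate, wc_fst

__all__ = [
    "fisher_exact_2x2",
    "CompositionTable",
    "composition_table",
    "ChangeTestResult",
    "composition_change",
    "pooled_cluster_fst",
    "cluster_het_comparison",
]


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Enumerates the hypergeometric distribution over tables with the observed
    margins and sums the probabilities of all tables no more probable than
    the observed one.  Probabilities are compared as exact integer
    numerators over the common denominator C(N, c1), so ties contribute
    exactly.  A zero margin leaves only one possible table: p = 1 with a
    warning.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if (t < 0).any() or (t != np.round(t)).any():
            raise ValueError("table entries must be non-negative integers")
        t = t.astype(int)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == N:
        warnings.warn("zero margin in 2x2 table; p = 1")
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    # integer numerators of the hypergeometric pmf over common denominator
    num = {x: math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)}
    obs = num[a]
    tail = sum(v for v in num.values() if v <= obs)
    return tail / math.comb(N, c1)


@dataclass
class CompositionTable:
    """Cluster composition per spatiotemporal group.

    ``data`` rows: group, n_cluster1, n_cluster2, total, frac_cluster2.
    Groups at or below ``min_total`` samples are excluded from ``data`` but
    retained in ``excluded`` for the audit trail.
    """

    data: pd.DataFrame
    excluded: pd.DataFrame
    min_total: int = 6

    def counts(self, group: str) -> tuple[int, int]:
        row = self.data.loc[self.data["group"] == group]
        if row.empty:
            raise KeyError(f"group {group!r} not in composition table")
        return int(row["n_cluster2"].iloc[0]), int(row["n_cluster1"].iloc[0])


def composition_table(
    assignments, groups, min_total: int = 6
) -> CompositionTable:
    """Cross-tabulate hard cluster assignments (1/2) against group labels."""
    assignments = np.asarray(assignments)
    groups = np.asarray(groups)
    rows = []
    for g in pd.unique(groups):
        sel = groups == g
        n2 = int((assignments[sel] == 2).sum())
        n1 = int((assignments[sel] != 2).sum())
        tot = n1 + n2
        rows.append(
            dict(group=g, n_cluster1=n1, n_cluster2=n2, total=tot,
                 frac_cluster2=n2 / tot if tot else np.nan)
        )
    df = pd.DataFrame(rows)
    keep = df["total"] > min_total
    return CompositionTable(
        data=df[keep].reset_index(drop=True),
        excluded=df[~keep].reset_index(drop=True),
        min_total=min_total,
    )


@dataclass
class ChangeTestResult:
    group_a: str
    group_b: str
    table: np.ndarray  # [[n2_a, n1_a], [n2_b, n1_b]]
    odds_ratio: float
    p_value: float
    q_value: float | None = None


def composition_change(
    table: CompositionTable,
    comparisons: list[tuple[str, str]] | None = None,
    adjust: bool = False,
) -> list[ChangeTestResult]:
    """Fisher exact tests of cluster composition between group pairs.

    ``comparisons`` defaults to all pairs of included groups.  Pairs naming
    a group excluded for small size are skipped with a warning; unknown
    groups raise.  Benjamini-Hochberg adjustment across the tested pairs is
    off by default (raw p-values are reported).
    """
    included = set(table.data["group"])
    known = included | set(table.excluded["group"])
    if comparisons is None:
        names = list(table.data["group"])
        comparisons = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    results = []
    for ga, gb in comparisons:
        for g in (ga, gb):
            if g not in known:
                raise KeyError(f"unknown group {g!r}")
        if ga not in included or gb not in included:
            warnings.warn(
                f"comparison ({ga}, {gb}) skipped: group at or below "
                f"{table.min_total} samples"
            )
            continue
        n2a, n1a = table.counts(ga)
        n2b, n1b = table.counts(gb)
        t = np.array([[n2a, n1a], [n2b, n1b]])
        with np.errstate(divide="ignore", invalid="ignore"):
            orat = (n2a * n1b) / (n1a * n2b) if n1a * n2b else np.inf
        results.append(
            ChangeTestResult(
                group_a=ga, group_b=gb, table=t,
                odds_ratio=float(orat), p_value=fisher_exact_2x2(t),
            )
        )
    if adjust and results:
        q = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    return results


def change_results_frame(results: list[ChangeTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                group_a=r.group_a, group_b=r.group_b,
                n2_a=r.table[0, 0], n1_a=r.table[0, 1],
                n2_b=r.table[1, 0], n1_b=r.table[1, 1],
                odds_ratio=r.odds_ratio, p_value=r.p_value, q_value=r.q_value,
            )
            for r in results
        ]
    )


def pooled_cluster_fst(
    geno: GenotypeMatrix,
    assignments,
    n_resamples: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[FstEstimate, pd.DataFrame]:
    """Weir-Cockerham FST between the pooled inferred clusters.

    Also returns a per-locus table (per-locus theta and heterozygosity) for
    the differentiation-vs-diversity diagnostic: differentiation spread over
    many loci argues against a handful of artefactual sites driving the
    signal.
    """
    assignments = np.asarray(assignments)
    for k in (1, 2):
        if (assignments == k).sum() < 2:
            raise ValueError(f"cluster {k} has fewer than 2 members")
    est = wc_fst(geno, assignments, n_resamples=n_resamples, rng=rng)
    denom = est.a + est.b + est.c
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = np.where(denom != 0, est.a / denom, np.nan)
    dos = geno.dosage_float()
    het = np.nanmean(dos == 1, axis=0)
    per_locus_df = pd.DataFrame(
        {
            "chrom": geno.loci["chrom"],
            "pos": geno.loci["pos"],
            "fst": per_locus,
            "heterozygosity": het,
        }
    )
    return est, per_locus_df


def cluster_het_comparison(
    het, assignments, missing=None, test: str = "welch"
) -> dict:
    """Mean individual heterozygosity per cluster, with a two-sample test.

    Returns means with standard errors, the two-sided p (Welch's t by
    default, Mann-Whitney with ``test='mannwhitney'``), and, when per-sample
    missing fractions are supplied, each cluster's mean missingness.
    Identical constant groups compare equal with p = 1.
    """
    het = np.asarray(het, dtype=float)
    assignments = np.asarray(assignments)
    g1 = het[assignments == 1]
    g2 = het[assignments == 2]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("both clusters need at least 2 members")
    out = {
        "mean_1": float(g1.mean()),
        "se_1": float(g1.std(ddof=1) / np.sqrt(len(g1))),
        "mean_2": float(g2.mean()),
        "se_2": float(g2.std(ddof=1) / np.sqrt(len(g2))),
        "n_1": int(len(g1)),
        "n_2": int(len(g2)),
    }
    if g1.std(ddof=1) == 0 and g2.std(ddof=1) == 0:
        out["p_value"] = 1.0 if g1.mean() == g2.mean() else 0.0
    elif test == "welch":
        out["p_value"] = float(stats.ttest_ind(g1, g2, equal_var=False).pvalue)
    elif test == "mannwhitney":
        out["p_value"] = float(stats.mannwhitneyu(g1, g2, alternative="two-sided").pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    if missing is not None:
        missing = np.asarray(missing, dtype=float)
        out["missing_1"] = float(missing[assignments == 1].mean())
        out["missing_2"] = float(missing[assignments == 2].mean())
    return out
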