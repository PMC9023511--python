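"""Synthetic two-population genotype studies with known ground truth.

The shark sequencing data behind the original survey are not deposited, so
every downstream stage is exercised on simulated studies that carry the same
statistical structure: two cryptic populations differentiated at a target
FST, sampled across seven region x birth-period groups, with realistic site
quality, depth and missing-data artefacts.

Divergence follows the Balding-Nichols drift model: per locus an ancestral
frequency p is drawn, and each population's frequency comes from
Beta(p(1-F)/F, (1-p)(1-F)/F), whose variance is F p (1-p).  Two populations
drawn independently with the same F have expected Weir-Cockerham theta ~= F.
Genotypes are Binomial(2, p_pop) draws: unlinked loci, Hardy-Weinberg within
populations, no selection.

The default study design mirrors the survey: 107 sharks in groups
GCA/CRS/TAS x birth periods, population-2 membership concentrated in the
historical Tasman Sea group (13 of 19), higher missingness for specimens
archived as jaws, and three duplicate-control pairs for the concordance
filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, LOCUS_COLUMNS, write_vcf
from .growth import (
    COMBINED_PARAMS,
    DEFAULT_COEFFS,
    PARAMS_BY_SEX,
    vbgf_forward,
)

__all__ = [
    "GroupSpec",
    "SimulationConfig",
    "SimulatedStudy",
    "DEFAULT_GROUP_DESIGN",
    "simulate_two_pops",
    "simulate_study",
    "write_study",
]


@dataclass(frozen=True)
class GroupSpec:
    """One spatiotemporal collection: region, birth period and the number of
    members drawn from each of the two source populations."""

    region: str
    birth_period: str
    n_pop1: int
    n_pop2: int

    @property
    def name(self) -> str:
        return f"{self.region}_{self.birth_period}"

    @property
    def total(self) -> int:
        return self.n_pop1 + self.n_pop2


#: The survey's seven collections with population-2 counts from the reported
#: cluster assignments (13/19 historical TAS, 5/14 1970-1990 TAS, one each in
#: the contemporary GCA and CRS collections).
DEFAULT_GROUP_DESIGN = (
    GroupSpec("GCA", "1970-1990", 12, 0),
    GroupSpec("GCA", "2000", 13, 1),
    GroupSpec("CRS", "1970-1990", 7, 0),
    GroupSpec("CRS", "2000", 14, 1),
    GroupSpec("TAS", "1910-1960", 6, 13),
    GroupSpec("TAS", "1970-1990", 9, 5),
    GroupSpec("TAS", "2000", 26, 0),
)

#: Birth-year windows samples are drawn from, per period (inclusive).
BIRTH_WINDOWS = {"1910-1960": (1917, 1960), "1970-1990": (1970, 1990), "2000": (2000, 2012)}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    n_loci: int = 1840
    divergence_F: float = 0.013
    ancestral_maf_range: tuple[float, float] = (0.10, 0.50)
    group_design: tuple[GroupSpec, ...] = DEFAULT_GROUP_DESIGN
    missing_rate_historical: float = 0.0114
    missing_rate_contemporary: float = 0.0035
    # site QUAL ~ shift + Gamma(shape, scale); shift places ~5% of sites at
    # QUAL <= 30 so the quality filter has known expected casualties
    qual_shape: float = 2.0
    qual_scale: float = 100.0
    qual_shift: float = 30.0 - 100.0 * 0.35536151069973424  # P(QUAL<=30)=0.05
    # site depth ~ Gamma(shape, mean/shape); a small fraction of sites gets
    # inflated depth (paralog mimic) caught by the excess-depth filter
    depth_mean: float = 40.0
    depth_shape: float = 30.0
    depth_inflated_frac: float = 0.02
    depth_inflation: float = 4.0
    n_duplicate_controls: int = 3
    length_noise_sd_cm: float = 2.0
    age_range_years: tuple[float, float] = (2.0, 30.0)
    catch_year_ceiling: int = 2015
    frac_fork_only: float = 0.15
    frac_weight_only: float = 0.17
    # optional historical-damage mode: random genotype errors in jaw samples
    historical_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not (0 <= self.divergence_F < 1):
            raise ValueError("divergence_F must lie in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("ancestral MAF range must sit inside (0, 0.5]")
        for r in (self.missing_rate_historical, self.missing_rate_contemporary):
            if not (0 <= r < 1):
                raise ValueError("missing rates must lie in [0, 1)")
        if self.n_duplicate_controls < 0:
            raise ValueError("n_duplicate_controls must be >= 0")


@dataclass
class SimulatedStudy:
    """A generated study: genotypes, sample metadata and the ground truth."""

    genotypes: GenotypeMatrix
    metadata: pd.DataFrame
    truth: pd.DataFrame  # sample_id, true_pop, true_birth_year, true_age


def _population_frequencies(
    n_loci: int, F: float, maf_range: tuple[float, float], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    p = rng.uniform(maf_range[0], maf_range[1], n_loci)
    if F == 0:
        return p.copy(), p.copy()
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    return rng.beta(a, b), rng.beta(a, b)


def simulate_two_pops(
    n1: int,
    n2: int,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw genotypes for two Balding-Nichols populations.

    Returns a complete (no missing data, no QC artefacts) GenotypeMatrix of
    n1+n2 samples plus a truth table of population labels.  Loci monomorphic
    across the pooled sample are redrawn so every locus is usable.
    """
    config = config or SimulationConfig()
    if n1 + n2 < 2:
        raise ValueError("need at least two samples in total")
    rng = rng or np.random.default_rng(config.seed)
    L = config.n_loci
    p1, p2 = _population_frequencies(L, config.divergence_F, config.ancestral_maf_range, rng)
    g1 = rng.binomial(2, p1, size=(n1, L))
    g2 = rng.binomial(2, p2, size=(n2, L))
    G = np.vstack([g1, g2])
    # redraw monomorphic columns until the pooled sample segregates everywhere
    for _ in range(200):
        mono = np.flatnonzero((G == G[0]).all(axis=0) & np.isin(G[0], [0, 2]))
        if mono.size == 0:
            break
        q1, q2 = _population_frequencies(
            mono.size, config.divergence_F, config.ancestral_maf_range, rng
        )
        G[:n1, mono] = rng.binomial(2, q1, size=(n1, mono.size))
        G[n1:, mono] = rng.binomial(2, q2, size=(n2, mono.size))
        p1[mono], p2[mono] = q1, q2

    samples = [f"P1_{i:03d}" for i in range(n1)] + [f"P2_{i:03d}" for i in range(n2)]
    loci = _locus_table(L, rng, config)
    geno = GenotypeMatrix(dosage=G.astype(np.int8), samples=samples, loci=loci)
    truth = pd.DataFrame({"sample_id": samples, "true_pop": [1] * n1 + [2] * n2})
    return geno, truth


def _locus_table(L: int, rng: np.random.Generator, config: SimulationConfig) -> pd.DataFrame:
    """Scaffold layout, QUAL and mean-depth draws for L loci.

    Loci are laid out ten per scaffold with spacings of 200-2000 bp, so the
    LD-pruning window (800 bp) contains genuine neighbour pairs.
    """
    per_scaffold = 10
    chroms, positions = [], []
    pos = 0
    for j in range(L):
        if j % per_scaffold == 0:
            pos = int(rng.integers(100, 1000))
        else:
            pos += int(rng.integers(200, 2001))
        chroms.append(f"scaffold_{j // per_scaffold + 1}")
        positions.append(pos)
    qual = config.qual_shift + rng.gamma(config.qual_shape, config.qual_scale, L)
    qual = np.maximum(qual, 1.0)
    depth = rng.gamma(config.depth_shape, config.depth_mean / config.depth_shape, L)
    inflated = rng.random(L) < config.depth_inflated_frac
    depth[inflated] *= config.depth_inflation
    ref = rng.choice(list("ACGT"), L)
    offsets = rng.integers(1, 4, L)
    bases = np.array(list("ACGT"))
    base_idx = np.searchsorted(bases, ref)
    alt = bases[(base_idx + offsets) % 4]
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "ref": ref,
            "alt": alt,
            "qual": qual,
            "mean_depth": depth,
        },
        columns=LOCUS_COLUMNS,
    )


def _draw_sample_metadata(
    spec: GroupSpec, pop: int, idx: int, rng: np.random.Generator, config: SimulationConfig
) -> dict:
    lo, hi = BIRTH_WINDOWS[spec.birth_period]
    for _ in range(1000):
        birth_year = int(rng.integers(lo, hi + 1))
        age = float(rng.uniform(*config.age_range_years))
        catch_year = birth_year + int(np.floor(age + 0.5))
        if catch_year <= config.catch_year_ceiling:
            break
    else:
        raise ValueError(
            f"infeasible design: no catch year <= {config.catch_year_ceiling} "
            f"for group {spec.name}"
        )
    tissue = "fin" if catch_year >= 2000 else ("jaw" if rng.random() < 0.8 else "vertebra")
    if tissue == "fin":
        sex = rng.choice(["M", "F", "U"], p=[0.45, 0.45, 0.10])
    else:
        sex = rng.choice(["M", "F", "U"], p=[0.10, 0.10, 0.80])
    params = PARAMS_BY_SEX.get(sex, COMBINED_PARAMS)
    lt_true = vbgf_forward(age, params)
    lt = lt_true + rng.normal(0.0, config.length_noise_sd_cm)
    lt = min(lt, params.l_inf_cm - 1e-6)
    u = rng.random()
    rec = {
        "sample_id": f"{spec.name}_{idx:03d}",
        "region": spec.region,
        "catch_year": catch_year,
        "sex": sex,
        "total_length_cm": np.nan,
        "fork_length_cm": np.nan,
        "weight_kg": np.nan,
        "tissue": tissue,
    }
    lf = (lt - DEFAULT_COEFFS.lt_intercept_cm) / DEFAULT_COEFFS.lt_slope
    if u < config.frac_weight_only:
        rec["weight_kg"] = DEFAULT_COEFFS.weight_a * lf**DEFAULT_COEFFS.weight_b
    elif u < config.frac_weight_only + config.frac_fork_only:
        rec["fork_length_cm"] = lf
    else:
        rec["total_length_cm"] = lt
    return rec, birth_year, age


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Generate a full spatiotemporal study under the default (or given) design.

    Samples are drawn as a mixture of the two populations per group; sizes
    and ages are emitted so the ageing module can re-derive each sample's
    birth period; genotypes are masked at tissue-dependent missing rates;
    duplicate-control pairs (id suffix ``_dup``) re-emit a sample's genotypes
    under an independent missingness mask.
    """
    config = config or SimulationConfig()
    if not config.group_design:
        raise ValueError("group_design must be non-empty")
    rng = np.random.default_rng(config.seed)

    n1 = sum(g.n_pop1 for g in config.group_design)
    n2 = sum(g.n_pop2 for g in config.group_design)
    geno, _ = simulate_two_pops(n1, n2, config, rng)
    # rows 0..n1-1 are population-1 draws, the rest population 2; deal them
    # out to groups in order
    i1, i2 = 0, n1
    rows, meta, truth = [], [], []
    for spec in config.group_design:
        pops = [1] * spec.n_pop1 + [2] * spec.n_pop2
        for k, pop in enumerate(pops):
            if pop == 1:
                rows.append(i1)
                i1 += 1
            else:
                rows.append(i2)
                i2 += 1
            rec, birth_year, age = _draw_sample_metadata(spec, pop, k, rng, config)
            meta.append(rec)
            truth.append(
                {
                    "sample_id": rec["sample_id"],
                    "true_pop": pop,
                    "true_birth_year": birth_year,
                    "true_age": age,
                    "group": spec.name,
                }
            )
    G = geno.dosage[rows].copy()
    meta = pd.DataFrame(meta)
    truth = pd.DataFrame(truth)

    # duplicate controls: same underlying genotypes, independent mask
    if config.n_duplicate_controls > 0:
        dup_src = rng.choice(len(meta), size=config.n_duplicate_controls, replace=False)
        for s in dup_src:
            G = np.vstack([G, G[s][None, :]])
            rec = meta.iloc[s].to_dict()
            rec["sample_id"] = rec["sample_id"] + "_dup"
            meta = pd.concat([meta, pd.DataFrame([rec])], ignore_index=True)
            trow = truth.iloc[s].to_dict()
            trow["sample_id"] = rec["sample_id"]
            truth = pd.concat([truth, pd.DataFrame([trow])], ignore_index=True)

    # tissue-dependent missingness, then optional historical genotype errors
    historical = (meta["tissue"] != "fin").to_numpy()
    rate = np.where(
        historical, config.missing_rate_historical, config.missing_rate_contemporary
    )
    mask = rng.random(G.shape) < rate[:, None]
    G = np.where(mask, MISSING, G).astype(np.int8)
    if config.historical_error_rate > 0:
        err = (rng.random(G.shape) < config.historical_error_rate) & historical[:, None]
        err &= G != MISSING
        G = np.where(err, rng.integers(0, 3, G.shape), G).astype(np.int8)

    # per-genotype depth around the site mean
    site_depth = geno.loci["mean_depth"].to_numpy()
    depth = rng.poisson(np.broadcast_to(site_depth, G.shape)).astype(np.int32)
    depth[G == MISSING] = 0

    out = GenotypeMatrix(
        dosage=G,
        samples=meta["sample_id"].tolist(),
        loci=geno.loci.copy(),
        depth=depth,
    )
    out.loci["mean_depth"] = out.mean_site_depth()
    return SimulatedStudy(genotypes=out, metadata=meta, truth=truth)


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write VCF + metadata CSV + truth CSV; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "study.vcf",
        "metadata": outdir / "metadata.csv",
        "truth": outdir / "truth.csv",
    }
    write_vcf(study.genotypes, paths["vcf"])
    study.metadata.to_csv(paths["metadata"], index=False, float_format="%.4f")
    study.truth.to_csv(paths["truth"], index=False, float_format="%.4f")
    return paths
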