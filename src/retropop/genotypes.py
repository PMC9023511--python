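"""Genotype container and VCF / metadata I/O.

The central in-memory object is :class:`GenotypeMatrix`: a samples x loci
matrix of alternate-allele dosages (0, 1, 2; -1 for missing) plus per-locus
metadata (scaffold, 1-based position, alleles, site QUAL, depth) and sample
ids.  Reading goes through cyvcf2; writing emits plain VCF v4.2 text with
GT:DP genotype fields so round trips are byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = ["GenotypeMatrix", "read_vcf", "write_vcf", "read_metadata", "MISSING"]

MISSING = -1

LOCUS_COLUMNS = ["chrom", "pos", "ref", "alt", "qual", "mean_depth"]


@dataclass
class GenotypeMatrix:
    """Samples x loci dosage matrix with locus metadata.

    dosage : int8 array, entries in {0, 1, 2, -1(missing)}
    samples : sample identifiers, one per row
    loci : DataFrame with columns chrom, pos, ref, alt, qual, mean_depth
    depth : optional per-genotype read depth (same shape as dosage)
    """

    dosage: np.ndarray
    samples: list[str]
    loci: pd.DataFrame
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x loci)")
        if self.dosage.shape[0] != len(self.samples):
            raise ValueError("sample count mismatch")
        if self.dosage.shape[1] != len(self.loci):
            raise ValueError("locus count mismatch")
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosages must be in {0,1,2,-1}")
        if (self.loci["pos"] <= 0).any():
            raise ValueError("positions must be positive (1-based)")
        self.loci = self.loci.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def dosage_float(self) -> np.ndarray:
        """Dosages as float with NaN for missing."""
        out = self.dosage.astype(float)
        out[self.dosage == MISSING] = np.nan
        return out

    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            dosage=self.dosage[:, index],
            loci=self.loci.iloc[index].reset_index(drop=True),
            depth=None if self.depth is None else self.depth[:, index],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            dosage=self.dosage[index],
            samples=[self.samples[i] for i in np.atleast_1d(index)],
            depth=None if self.depth is None else self.depth[index],
        )

    def drop_samples(self, ids: list[str]) -> "GenotypeMatrix":
        keep = np.array([s not in set(ids) for s in self.samples])
        return self.take_samples(np.flatnonzero(keep))

    def sample_index(self, ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[s] for s in ids])

    # --- per-locus summaries used throughout -------------------------------

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(alt allele count, total called alleles) per locus."""
        called = self.dosage != MISSING
        alt = np.where(called, self.dosage, 0).sum(axis=0)
        return alt, 2 * called.sum(axis=0)

    def locus_missingness(self) -> np.ndarray:
        return (self.dosage == MISSING).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return (self.dosage != MISSING).mean(axis=1)

    def mean_site_depth(self) -> np.ndarray:
        """Mean depth per locus over non-missing genotypes."""
        if self.depth is not None:
            called = self.dosage != MISSING
            with np.errstate(invalid="ignore"):
                tot = np.where(called, self.depth, 0).sum(axis=0)
                n = called.sum(axis=0)
                return np.where(n > 0, tot / np.maximum(n, 1), np.nan)
        return self.loci["mean_depth"].to_numpy(dtype=float)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write as uncompressed VCF v4.2 with GT:DP genotype fields."""
    path = Path(path)
    contigs = list(dict.fromkeys(geno.loci["chrom"]))
    lines = [
        "##fileformat=VCFv4.2",
        "##source=retropop",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">',
        *[f"##contig=<ID={c}>" for c in contigs],
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(geno.samples),
    ]
    dp = geno.depth
    for j, loc in enumerate(geno.loci.itertuples(index=False)):
        fields = [
            str(loc.chrom),
            str(int(loc.pos)),
            ".",
            loc.ref,
            loc.alt,
            f"{loc.qual:.2f}",
            "PASS",
            ".",
            "GT:DP",
        ]
        col = geno.dosage[:, j]
        if dp is not None:
            gts = [f"{_GT_STRINGS[int(g)]}:{int(d)}" for g, d in zip(col, dp[:, j])]
        else:
            gts = [_GT_STRINGS[int(g)] for g in col]
        lines.append("\t".join(fields + gts))
    path.write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load a VCF into a GenotypeMatrix.

    All records are loaded, including non-biallelic / non-SNP sites (the
    filter cascade removes those explicitly so the audit trail shows them);
    for multiallelic records any non-reference allele counts toward the
    dosage and the ALT column joins the alternates with commas.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosages, depths, loci = [], [], []
    has_depth = True
    for var in vcf:
        gt = var.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dos = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        dosages.append(dos.astype(np.int8))
        dp = var.format("DP")
        if dp is None:
            has_depth = False
        else:
            d = dp[:, 0].astype(np.int32)
            d[d < 0] = 0
            depths.append(d)
        alt = ",".join(var.ALT) if var.ALT else "."
        called = dos != MISSING
        loci.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": alt,
                "qual": float(var.QUAL) if var.QUAL is not None else np.nan,
                "mean_depth": np.nan,
            }
        )
    if not dosages:
        raise ValueError(f"empty VCF: {path}")
    dosage = np.column_stack(dosages)
    depth = np.column_stack(depths) if has_depth and depths else None
    loci_df = pd.DataFrame(loci, columns=LOCUS_COLUMNS)
    geno = GenotypeMatrix(dosage=dosage, samples=samples, loci=loci_df, depth=depth)
    geno.loci["mean_depth"] = geno.mean_site_depth()
    return geno


METADATA_COLUMNS = [
    "sample_id",
    "region",
    "catch_year",
    "sex",
    "total_length_cm",
    "fork_length_cm",
    "weight_kg",
    "tissue",
]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata CSV, checking the required schema."""
    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata file {path} lacks columns: {missing}")
    return df
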