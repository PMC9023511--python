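"""End-to-end orchestration: simulate/load -> age -> filter -> stats ->
cluster -> temporal, with every threshold and seed logged and all tables
written as TSV/JSON so any stage can be re-run from the previous stage's
outputs."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import popgen, structure, temporal
from .filtering import FilterConfig, find_duplicate_pairs, run_filter_cascade
from .genotypes import GenotypeMatrix, read_metadata, read_vcf, write_vcf
from .growth import assign_birth_periods
from .simulate import SimulationConfig, simulate_study, write_study

logger = logging.getLogger("retropop")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; serialised next to its outputs."""

    outdir: str = "results/pipeline"
    seed: int = 0
    # input: either a simulation config, or vcf + metadata paths
    simulation: SimulationConfig | None = None
    vcf: str | None = None
    metadata: str | None = None
    # stage toggles
    run_age: bool = True
    run_filter: bool = True
    run_stats: bool = True
    run_cluster: bool = True
    run_temporal: bool = True
    # thresholds
    filter: FilterConfig = field(default_factory=FilterConfig)
    n_resamples: int = 1000
    k_max: int = 6
    n_pcs: int | None = None
    min_group_size: int = 6
    pcadapt_k: int = 2
    pcadapt_q: float = 0.1

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return str(o)

        return json.dumps(dataclasses.asdict(self), default=enc, indent=2)


@dataclass
class PipelineResult:
    config: PipelineConfig
    metadata: pd.DataFrame
    genotypes: GenotypeMatrix
    summary: dict
    outputs: dict[str, Path]


def _write(df: pd.DataFrame, path: Path, **kw) -> Path:
    df.to_csv(path, sep="\t", float_format="%.6g", **kw)
    return path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the enabled stages in order; returns the result bundle.

    Outputs land under ``config.outdir``: the serialized config, the aged
    metadata, the filter report and filtered VCF, FST/heterozygosity/SFS
    tables, cluster assignments with BIC curve, composition tests and a
    single ``summary.json``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "pipeline_config.json").write_text(config.to_json())
    outputs: dict[str, Path] = {"config": out / "pipeline_config.json"}
    summary: dict = {"seed": config.seed}
    rng = np.random.default_rng(config.seed)

    # ---- input stage ------------------------------------------------------
    if config.simulation is not None:
        sim_conf = dataclasses.replace(config.simulation, seed=config.seed)
        study = simulate_study(sim_conf)
        paths = write_study(study, out / "simulated")
        outputs.update({f"sim_{k}": v for k, v in paths.items()})
        geno, meta = study.genotypes, study.metadata
        logger.info("simulated study: %d samples x %d loci", geno.n_samples, geno.n_loci)
    else:
        if config.vcf is None or config.metadata is None:
            raise ValueError("either a simulation config or vcf+metadata paths are required")
        for p in (config.vcf, config.metadata):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        geno = read_vcf(config.vcf)
        meta = read_metadata(config.metadata)
    meta = meta.set_index("sample_id", drop=False).loc[geno.samples].reset_index(drop=True)

    # ---- ageing -----------------------------------------------------------
    if config.run_age:
        meta = assign_birth_periods(meta)
        meta["group"] = meta["region"] + "_" + meta["birth_period"]
        outputs["metadata_aged"] = _write(meta, out / "metadata_aged.tsv", index=False)
        summary["birth_year_range"] = [int(meta.birth_year.min()), int(meta.birth_year.max())]
    elif "group" not in meta:
        raise ValueError("ageing disabled but metadata has no 'group' column")

    # ---- filtering --------------------------------------------------------
    if config.run_filter:
        dup_pairs = find_duplicate_pairs(geno.samples)
        geno, report = run_filter_cascade(geno, config.filter, dup_pairs)
        outputs["filter_report"] = _write(report.to_dataframe(), out / "filter_report.tsv", index=False)
        write_vcf(geno, out / "filtered.vcf")
        outputs["filtered_vcf"] = out / "filtered.vcf"
        summary["loci_after_filter"] = geno.n_loci
        summary["samples_after_filter"] = geno.n_samples
        logger.info("filter cascade: %d loci, %d samples retained", geno.n_loci, geno.n_samples)

    # remove duplicate controls and any residual identical genotypes before
    # statistics (technical replicates must not masquerade as kin)
    dup_ids = [s for s in geno.samples if s.endswith("_dup")]
    if dup_ids:
        geno = geno.drop_samples(dup_ids)
    A, flags = popgen.relatedness_ajk(geno)
    outputs["relatedness_flags"] = _write(flags, out / "relatedness_flags.tsv", index=False)
    drop = sorted({r.sample_2 for r in flags.itertuples() if r.flag == "duplicate"})
    if drop:
        logger.info("removing %d identical-genotype sample(s): %s", len(drop), drop)
        geno = geno.drop_samples(drop)
    meta = meta.set_index("sample_id", drop=False).loc[geno.samples].reset_index(drop=True)
    summary["n_samples_analysed"] = geno.n_samples
    summary["n_duplicates_removed"] = len(dup_ids) + len(drop)

    het = popgen.individual_heterozygosity(geno)
    missing = pd.Series(geno.missing_mask().mean(axis=1), index=geno.samples)

    # ---- popgen statistics ------------------------------------------------
    if config.run_stats:
        periods = meta["birth_period"].to_numpy()
        pw_period = popgen.pairwise_fst_matrix(
            geno, periods, n_resamples=config.n_resamples, rng=rng
        )
        outputs["fst_periods"] = _write(pw_period.table(), out / "fst_periods.tsv")
        pw_group = popgen.pairwise_fst_matrix(
            geno, meta["group"].to_numpy(), n_resamples=config.n_resamples,
            min_group_size=config.min_group_size, rng=rng,
        )
        outputs["fst_groups"] = _write(pw_group.table(), out / "fst_groups.tsv")

        tested = [g for g in pw_group.groups if pw_group.theta.loc[g].notna().any()]
        D = pw_group.theta.loc[tested, tested].fillna(0.0).clip(lower=0.0)
        np.fill_diagonal(D.values, 0.0)
        pco = structure.pcoa(D)
        outputs["pcoa_groups"] = _write(pco.to_dataframe(), out / "pcoa_groups.tsv")
        summary["pcoa_axis1_explained"] = float(pco.explained[0]) if len(pco.explained) else None

        per_sample = pd.DataFrame({"heterozygosity": het, "missing_fraction": missing})
        outputs["per_sample"] = _write(per_sample, out / "per_sample_stats.tsv")
        slope, r2, p = popgen.het_missingness_regression(het.to_numpy(), missing.to_numpy())
        summary["het_missingness"] = {"slope": slope, "r2": r2, "p_value": p}

        sfs_rows = []
        for period in pd.unique(periods):
            ids = meta.loc[meta.birth_period == period, "sample_id"].tolist()
            if len(ids) < 2:
                continue
            sfs = popgen.sfs_diversity(geno, ids, projection_n=None)
            sfs_rows.append(
                dict(group=period, n_chromosomes=sfs.projection_n, S=sfs.S,
                     pi_per_snp=sfs.pi, theta_w=sfs.theta_w)
            )
        outputs["diversity"] = _write(pd.DataFrame(sfs_rows), out / "diversity_by_period.tsv", index=False)

        pca = structure.pca_genotypes(geno, n_components=10)
        outputs["pca"] = _write(pca.to_dataframe(), out / "pca_samples.tsv")

        scan = structure.pcadapt_outliers(geno, K=config.pcadapt_k, q_cutoff=config.pcadapt_q)
        outputs["outlier_scan"] = _write(scan, out / "outlier_scan.tsv", index=False)
        summary["n_outlier_loci"] = int(scan["outlier"].sum())

    # ---- clustering -------------------------------------------------------
    model = None
    if config.run_cluster:
        contemporary = (meta["birth_period"] == "2000").to_numpy()
        model = structure.find_clusters(
            geno, k_max=config.k_max, n_pcs=config.n_pcs, seed=config.seed,
            contemporary_mask=contemporary,
        )
        assign_df = pd.DataFrame(
            {"sample_id": geno.samples, "cluster": model.assignment}
        ).join(model.membership_df().reset_index(drop=True))
        outputs["clusters"] = _write(assign_df, out / "cluster_assignments.tsv", index=False)
        bic_df = pd.DataFrame(sorted(model.bic_by_k.items()), columns=["K", "BIC"])
        outputs["bic"] = _write(bic_df, out / "bic_by_k.tsv", index=False)
        summary["selected_K"] = model.K
        summary["n_pcs_retained"] = model.n_pcs_retained
        logger.info("clustering: selected K=%d with %d PCs", model.K, model.n_pcs_retained)

    # ---- temporal inference -----------------------------------------------
    if config.run_temporal:
        if model is None:
            logger.warning("temporal stage skipped: clustering disabled or not run")
            summary["temporal"] = "skipped (clustering disabled)"
        else:
            assignment = model.assignment if model.K >= 2 else np.ones(geno.n_samples, int)
            comp = temporal.composition_table(
                assignment, meta["group"].to_numpy(), min_total=config.min_group_size
            )
            outputs["composition"] = _write(comp.data, out / "composition.tsv", index=False)
            tests = temporal.composition_change(comp)
            tests_df = temporal.change_results_frame(tests)
            outputs["change_tests"] = _write(tests_df, out / "change_tests.tsv", index=False)
            summary["composition_tests"] = {
                f"{r.group_a} vs {r.group_b}": r.p_value for r in tests
            }
            if model.K >= 2 and min((assignment == 1).sum(), (assignment == 2).sum()) >= 2:
                est, per_locus = temporal.pooled_cluster_fst(
                    geno, assignment, n_resamples=config.n_resamples, rng=rng
                )
                outputs["fst_per_locus"] = _write(per_locus, out / "pooled_fst_per_locus.tsv", index=False)
                summary["pooled_cluster_fst"] = est.theta
                summary["pooled_cluster_fst_p"] = est.p_value
                hc = temporal.cluster_het_comparison(
                    het.to_numpy(), assignment, missing=missing.to_numpy()
                )
                summary["cluster_heterozygosity"] = hc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    outputs["summary"] = out / "summary.json"
    return PipelineResult(
        config=config, metadata=meta, genotypes=geno, summary=summary, outputs=outputs
    )
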