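"""End-to-end orchestration: quantgen -> confounders -> eqtl -> context ->
network -> popgen -> integrate, with per-stage TSV/JSON outputs and a run
manifest recording seeds and parameters so any result is reproducible from
the manifest alone."""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import confounders as conf
from . import context as ctx
from . import eqtl as eq
from . import integrate as integ
from . import network as net
from . import popgen as pg
from . import quantgen as qg
from .data import ExpressionData, GeneAnnotation, GenotypeData
from .io import RunConfig

__all__ = ["run_pipeline", "PipelineResult", "stage_rng"]

log = logging.getLogger(__name__)

STAGES = ("quantgen", "confounders", "eqtl", "context", "network",
          "popgen", "integrate")


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Named substream per stage, derived from the master seed."""
    key = zlib.crc32(stage.encode()) % 2**31
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(key,)))


@dataclass
class PipelineResult:
    manifest: dict
    filter_report: qg.FilterReport | None = None
    h2: pd.DataFrame | None = None
    qst: pd.DataFrame | None = None
    confounders: conf.ConfounderResult | None = None
    associations: pd.DataFrame | None = None
    egenes: list[str] = field(default_factory=list)
    esnps: list[str] = field(default_factory=list)
    hotspots: pd.DataFrame | None = None
    contexts: list[ctx.ContextAssignment] = field(default_factory=list)
    context_density: pd.DataFrame | None = None
    network: net.NetworkModel | None = None
    node_stats: pd.DataFrame | None = None
    scale_free: tuple[float, float] | None = None
    diversity: pd.DataFrame | None = None
    summary: pd.DataFrame | None = None
    pca: integ.PcaResult | None = None
    partial_correlations: pd.DataFrame | None = None


def run_pipeline(
    config: RunConfig,
    genotypes: GenotypeData,
    expression: ExpressionData,
    annotation: GeneAnnotation,
    panels: dict[str, dict] | None = None,
    out_dir: str | Path | None = None,
    confounder_grid: range | None = None,
) -> PipelineResult:
    """Run every stage in order on an in-memory input bundle.

    ``panels`` (per-gene haplotype panels) are optional; without them the
    popgen stage is skipped and sequence statistics are absent from the
    integration table. Stage outputs are written under ``out_dir`` when
    given. Any stage failure aborts with the stage name; outputs of
    completed stages persist.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": [], "seed": config.seed}
    result = PipelineResult(manifest=manifest)
    grid = confounder_grid if confounder_grid is not None else range(
        0, config.confounder_grid_max + 1
    )

    def checkpoint(stage: str) -> None:
        manifest["stages"].append(stage)
        if out is not None:
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2, default=str)

    stage = "quantgen"
    try:
        means_all = qg.genotype_means(expression, genotypes.samples)
        report, retained = qg.filter_expression(
            means_all, config.expr_var_threshold, config.expr_median_threshold
        )
        result.filter_report = report
        result.h2 = qg.estimate_h2(
            expression, genotypes.samples,
            n_perm=config.quantgen_permutations,
            rng=stage_rng(config.seed, "h2"),
        )
        pops = (
            genotypes.samples.drop_duplicates("genotype")
            .set_index("genotype")["population"]
        )
        result.qst = qg.estimate_qst(
            means_all, pops,
            n_perm=config.quantgen_permutations,
            rng=stage_rng(config.seed, "qst"),
        )
        if out is not None:
            report.classes.rename("class").to_csv(out / "filter_report.tsv", sep="\t")
            result.h2.to_csv(out / "h2.tsv", sep="\t")
            result.qst.to_csv(out / "qst.tsv", sep="\t")
        checkpoint(stage)

        stage = "confounders"
        vstats, filtered = eq.filter_variants(
            genotypes, config.maf_min, config.mgf_max, config.max_missing
        )
        if filtered.n_variants == 0:
            raise RuntimeError("no variants after filtering")
        covariate = eq.structure_covariate(filtered)
        cres = conf.select_confounder_count(
            retained, filtered, covariate, grid=grid, alpha=config.bh_alpha
        )
        result.confounders = cres
        residuals = cres.residuals
        if out is not None:
            cres.eqtl_counts_by_k.rename("n_eqtls").to_csv(
                out / "eqtl_counts_by_k.tsv", sep="\t"
            )
            residuals.to_csv(out / "residual_expression.tsv", sep="\t")
        checkpoint(stage)

        stage = "eqtl"
        scan = eq.map_associations(residuals, filtered, covariate)
        records = eq.empirical_fdr(
            scan, residuals, filtered, covariate,
            n_perm=config.eqtl_permutations, fdr=config.fdr,
            rng=stage_rng(config.seed, "eqtl"),
        )
        records = eq.classify_local_distant(
            records, annotation, filtered.variants, window=config.local_window
        )
        result.associations = records
        sig = records[records["significant"]]
        result.egenes = sorted(sig["gene"].unique())
        result.esnps = sorted(sig["snp"].unique())
        result.hotspots = eq.hotspot_scan(
            records, filtered.variants,
            window=config.hotspot_window, nominal_p_max=config.hotspot_p,
        )
        if out is not None:
            records.drop(columns=["_gi", "_si"]).to_csv(
                out / "associations.tsv", sep="\t", index=False
            )
            result.hotspots.to_csv(out / "hotspots.tsv", sep="\t", index=False)
        checkpoint(stage)

        stage = "context"
        snp_pos = {
            r.id: (r.chrom, r.pos)
            for r in filtered.variants.itertuples(index=False)
        }
        esnp_egene = sig.groupby("snp")["gene"].first()
        assignments = []
        for snp in result.esnps:
            chrom, pos = snp_pos[snp]
            assignments.append(
                ctx.classify_genomic_context(
                    snp, chrom, pos, annotation,
                    flank=config.context_flank,
                    egene=esnp_egene.get(snp),
                )
            )
        result.contexts = assignments
        density, _profile = ctx.context_density_profile(
            assignments, annotation, snp_pos, flank=config.context_flank
        )
        result.context_density = density
        if out is not None:
            density.to_csv(out / "context_density.tsv", sep="\t", index=False)
        checkpoint(stage)

        stage = "network"
        model = net.build_network(residuals, beta=config.soft_power)
        labels = net.detect_modules(
            model.dissimilarity, min_module_size=config.min_module_size
        )
        stats = net.node_statistics(model, labels, peri_r=config.periphery_r)
        stats = net.define_cores_and_periphery(
            model, labels, stats,
            core_frac=config.core_fraction,
            kwithin_min=config.kwithin_min,
            peri_r=config.periphery_r,
        )
        model.labels = labels
        model.stats = stats
        result.network = model
        result.node_stats = stats
        try:
            result.scale_free = net.scale_free_fit(stats["kTotal"].to_numpy())
        except ValueError:
            result.scale_free = None
        if out is not None:
            stats.to_csv(out / "node_stats.tsv", sep="\t")
        checkpoint(stage)

        stage = "popgen"
        if panels is not None:
            diversity = pg.gene_category_stats(
                panels, min_sites=config.min_covered_sites
            )
            result.diversity = diversity
            if out is not None:
                diversity.to_csv(out / "diversity.tsv", sep="\t", index=False)
        checkpoint(stage)

        stage = "integrate"
        summary = stats[["kTotal", "core"]].copy()
        pre_means = means_all.loc[summary.index]
        summary["expr_level"] = pre_means.mean(axis=1)
        summary["expr_variance"] = pre_means.var(axis=1, ddof=1)
        summary["egene"] = summary.index.isin(result.egenes)
        summary["H2"] = result.h2.loc[summary.index, "H2"]
        if result.diversity is not None:
            gene_rows = result.diversity[
                result.diversity["category"] == "gene"
            ].set_index("gene")
            for col in ("theta_pi", "tajima_d", "theta0_theta4", "dNdS"):
                summary[col] = gene_rows[col].reindex(summary.index)
        result.summary = summary
        try:
            result.pca = integ.expression_measure_pca(summary)
        except ValueError as err:
            # e.g. no module cores in a small run -> constant flag variable
            log.warning("expression-measure PCA skipped: %s", err)
            result.pca = None
        if result.diversity is not None:
            rows = []
            metrics = ("theta_pi", "tajima_d", "theta0_theta4", "dNdS")
            for metric in metrics:
                for measure in integ.EXPRESSION_MEASURES:
                    others = [
                        m for m in integ.EXPRESSION_MEASURES if m != measure
                    ]
                    sub = summary[[measure, metric, *others]].dropna()
                    try:
                        rho, p = integ.partial_spearman(
                            sub[measure].astype(float).to_numpy(),
                            sub[metric].to_numpy(),
                            sub[others].astype(float).to_numpy(),
                        )
                    except ValueError:
                        rho = p = float("nan")  # degenerate controls
                    rows.append({"measure": measure, "metric": metric,
                                 "rho": rho, "p": p})
            result.partial_correlations = pd.DataFrame(rows)
            if out is not None:
                result.partial_correlations.to_csv(
                    out / "partial_spearman.tsv", sep="\t", index=False
                )
        if out is not None:
            summary.to_csv(out / "gene_summary.tsv", sep="\t")
        checkpoint(stage)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return result
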