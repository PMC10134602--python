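"""End-to-end orchestration: matrices -> rebound calls -> modules -> enrichment.

The analysis proceeds per cell type: preprocessing (probe/count filters,
normalization), per-feature differential testing of the during-pregnancy
(3rd-1st trimester) and post-partum (PP-3rd) windows in each group,
rebound and shared-rebound classification, DIAMOnD expansion of the
shared rebound genes into PPI modules per omic, cross-omics module
intersection, and enrichment of the resulting rebound module against
disease gene sets and pathway collections.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .containers import CpGAnnotation, OmicsMatrix, SampleTable, ValidationError
from . import differential as diff
from . import enrichment as enr
from . import network as net
from . import preprocess as pre
from . import rebound as reb

logger = logging.getLogger("reboundomics")


@dataclass
class Thresholds:
    """All tunable thresholds of the analysis, at their standard values."""

    p_max: float = 0.05
    db_min: float = 0.05
    ppi_min_score: int = 700
    n_added: int = 200
    cpm_min: float = 10.0
    cpm_frac: float = 0.7
    viz_score: int = 950
    pathway_adj_max: float = 0.05
    gwas_p_max: float = 1e-6
    tss_window: tuple[int, int] = (-3000, 3000)

    def validate(self) -> None:
        if not 0 < self.p_max <= 1 or not 0 < self.pathway_adj_max <= 1:
            raise ValidationError("p-value thresholds must lie in (0, 1]")
        if self.db_min < 0 or self.cpm_min < 0:
            raise ValidationError("db_min and cpm_min must be >= 0")
        if not 0 <= self.ppi_min_score <= 1000 or not 0 <= self.viz_score <= 1000:
            raise ValidationError("PPI score thresholds must lie in [0, 1000]")
        if self.n_added < 0:
            raise ValidationError("n_added must be >= 0")
        if not 0 < self.cpm_frac <= 1:
            raise ValidationError("cpm_frac must lie in (0, 1]")


@dataclass
class PipelineConfig:
    """File-based pipeline configuration (see ``run_pipeline``)."""

    beta_path: str
    counts_path: str
    samples_path: str
    annotation_path: str
    ppi_path: str
    gene_sets_path: str | None = None
    covariates: list[str] = field(
        default_factory=lambda: ["age", "memory_fraction", "viability"]
    )
    reference_time: str = "T1"
    thresholds: Thresholds = field(default_factory=Thresholds)
    out_dir: str = "results"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        thr = Thresholds(**raw.pop("thresholds", {}))
        if isinstance(thr.tss_window, list):
            thr.tss_window = tuple(thr.tss_window)
        return cls(thresholds=thr, **raw)


def _differential_windows(
    fits: diff.FeatureFits,
    design: diff.DesignMatrix,
    groups: list[str],
    beta: OmicsMatrix | None,
    samples: SampleTable | None,
) -> dict[str, dict[str, diff.DifferentialResult]]:
    """Test the (T3-T1) and (PP-T3) contrasts for every group.

    For methylation (``beta`` given) the per-CpG mean beta difference is
    attached to each result.
    """
    windows = {"w1": ("T3", "T1"), "w2": ("PP", "T3")}
    out: dict[str, dict[str, diff.DifferentialResult]] = {}
    for group in groups:
        out[group] = {}
        for wname, (tb, ta) in windows.items():
            c = design.contrast(group, tb, ta)
            res = diff.test_contrast(fits, c, name=f"{group}:{tb}-{ta}")
            if beta is not None and samples is not None:
                res.table["delta_beta"] = diff.mean_beta_difference(
                    beta, samples, group, ta, tb
                )
            out[group][wname] = res
    return out


@dataclass
class AnalysisResult:
    """Everything the end-to-end analysis produces, in memory."""

    manifest: dict
    meth_results: dict
    expr_results: dict
    rebound_meth: dict
    rebound_expr: dict
    shared_meth: "reb.SharedRebound"
    shared_expr: "reb.SharedRebound"
    shared_dmgs: set[str]
    module_meth: "net.ModuleResult | None"
    module_expr: "net.ModuleResult | None"
    rebound_module: set[str]
    module_overlap: "enr.EnrichmentResult | None"
    disease_enrichment: "enr.EnrichmentResult | None"
    pathway_table: pd.DataFrame | None
    contrast_correlations: pd.DataFrame


def run_analysis(
    beta: OmicsMatrix,
    counts: OmicsMatrix,
    samples: SampleTable,
    annotation: CpGAnnotation,
    ppi: nx.Graph | None = None,
    gene_sets: dict[str, set[str]] | None = None,
    covariates: list[str] | None = None,
    reference_time: str = "T1",
    thresholds: Thresholds | None = None,
) -> AnalysisResult:
    """Run the full in-memory analysis on one cell type.

    Inputs enter post array/count QC (use :mod:`reboundomics.preprocess`
    beforehand for probe filtering); this function performs count
    filtering and normalization, differential testing, rebound calling,
    module inference and enrichment.
    """
    thr = thresholds or Thresholds()
    thr.validate()
    covariates = covariates if covariates is not None else [
        c for c in ("age", "memory_fraction", "viability") if c in samples.data.columns
    ]
    manifest: dict = {"parameters": {**thr.__dict__, "covariates": covariates,
                                     "reference_time": reference_time},
                      "stages": {}}

    def stage(name: str, **counts_):
        manifest["stages"][name] = counts_
        logger.info("stage=%s %s", name, counts_)

    t0 = time.time()
    samples = samples.aligned_to(beta)
    groups = samples.groups
    if len(groups) != 2:
        raise ValidationError(f"expected 2 groups, found {groups}")

    # ---- preprocessing -------------------------------------------------
    counts_f = pre.filter_low_count_genes(counts, thr.cpm_min, thr.cpm_frac)
    factors = pre.tmm_factors(counts_f)
    logcpm = pre.log_cpm(counts_f, factors)
    m_vals = pre.beta_m_transform(beta, "m")
    stage("preprocess", n_cpgs=beta.shape[0], n_genes_in=counts.shape[0],
          n_genes_kept=counts_f.shape[0])

    # ---- differential --------------------------------------------------
    design_m = diff.build_design(samples, covariates, reference_time)
    rho_m = diff.estimate_block_correlation(m_vals, design_m)
    fits_m = diff.fit_feature_models(m_vals, design_m, rho=rho_m)
    diff.ebayes_moderate(fits_m)

    samples_e = samples.aligned_to(counts_f)
    design_e = diff.build_design(samples_e, covariates, reference_time)
    weights = diff.voom_weights(counts_f, design_e, factors)
    rho_e = diff.estimate_block_correlation(logcpm, design_e)
    fits_e = diff.fit_feature_models(logcpm, design_e, rho=rho_e, weights=weights)
    diff.ebayes_moderate(fits_e)

    meth_results = _differential_windows(fits_m, design_m, groups, beta, samples)
    expr_results = _differential_windows(fits_e, design_e, groups, None, None)
    stage("differential", rho_methylation=round(rho_m, 4), rho_expression=round(rho_e, 4))

    # ---- rebound -------------------------------------------------------
    rebound_meth, rebound_expr = {}, {}
    for group in groups:
        dmp_w1 = reb.call_dmps(meth_results[group]["w1"], thr.p_max, thr.db_min)
        dmp_w2 = reb.call_dmps(meth_results[group]["w2"], thr.p_max, thr.db_min)
        rebound_meth[group] = reb.find_rebound(dmp_w1, dmp_w2)
        deg_w1 = reb.call_degs(expr_results[group]["w1"], thr.p_max)
        deg_w2 = reb.call_degs(expr_results[group]["w2"], thr.p_max)
        rebound_expr[group] = reb.find_rebound(deg_w1, deg_w2)

    g1, g2 = groups
    shared_meth = reb.shared_rebound(rebound_meth[g1], rebound_meth[g2])
    shared_expr = reb.shared_rebound(rebound_expr[g1], rebound_expr[g2])
    shared_dmgs, n_unannotated = reb.map_cpgs_to_genes(shared_meth.shared_ids, annotation)
    stage(
        "rebound",
        **{f"rebound_meth_{g}": len(rebound_meth[g].rebound) for g in groups},
        **{f"rebound_expr_{g}": len(rebound_expr[g].rebound) for g in groups},
        shared_dmps=len(shared_meth.shared_ids),
        shared_degs=len(shared_expr.shared_ids),
        shared_dmgs=len(shared_dmgs),
        unannotated_shared_dmps=n_unannotated,
    )

    # ---- contrast correlations (during vs after pregnancy) -------------
    corr_rows = []
    for omic, results in (("methylation", meth_results), ("expression", expr_results)):
        for group in groups:
            r, p = reb.contrast_correlation(results[group]["w1"], results[group]["w2"])
            corr_rows.append({"omic": omic, "group": group, "window_pair": "w1_vs_w2",
                              "pearson_r": r, "p": p})
    contrast_correlations = pd.DataFrame(corr_rows)

    # ---- modules -------------------------------------------------------
    module_meth = module_expr = None
    rebound_module: set[str] = set()
    module_overlap = None
    seeds_expr = shared_expr.shared_ids
    seeds_meth = shared_dmgs
    if ppi is not None and seeds_expr and seeds_meth and \
            (seeds_expr & set(ppi.nodes)) and (seeds_meth & set(ppi.nodes)):
        module_expr = net.diamond_expand(ppi, seeds_expr, n_added=thr.n_added)
        module_meth = net.diamond_expand(ppi, seeds_meth, n_added=thr.n_added)
        rebound_module, module_overlap = net.intersect_modules(
            module_expr, module_meth, ppi.nodes
        )
        stage("modules",
              module_expr=len(module_expr.module_genes),
              module_meth=len(module_meth.module_genes),
              rebound_module=len(rebound_module))
    else:
        stage("modules", skipped=True,
              reason="no PPI network or empty shared rebound seed sets")

    # ---- enrichment ----------------------------------------------------
    disease_enrichment = None
    pathway_table = None
    measured = set(counts_f.feature_ids)
    if gene_sets and rebound_module:
        universe = measured | set(ppi.nodes)
        disease_enrichment = enr.fisher_enrichment(
            rebound_module, gene_sets.get("disease", set()), universe, name="disease"
        )
        pathway_table = enr.pathway_enrichment(
            rebound_module, gene_sets, measured,
            network_genes=set(ppi.nodes),
            universe_mode="measured_plus_network",
            p_adj_max=thr.pathway_adj_max,
        )
        stage("enrichment",
              disease_or=round(disease_enrichment.odds_ratio, 3)
              if np.isfinite(disease_enrichment.odds_ratio) else "inf",
              disease_p=disease_enrichment.p,
              n_significant_pathways=int(pathway_table["significant"].sum()))
    else:
        stage("enrichment", skipped=True, reason="no gene sets or empty module")

    manifest["runtime_seconds"] = round(time.time() - t0, 2)
    return AnalysisResult(
        manifest=manifest,
        meth_results=meth_results,
        expr_results=expr_results,
        rebound_meth=rebound_meth,
        rebound_expr=rebound_expr,
        shared_meth=shared_meth,
        shared_expr=shared_expr,
        shared_dmgs=shared_dmgs,
        module_meth=module_meth,
        module_expr=module_expr,
        rebound_module=rebound_module,
        module_overlap=module_overlap,
        disease_enrichment=disease_enrichment,
        pathway_table=pathway_table,
        contrast_correlations=contrast_correlations,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based end-to-end run; writes stage outputs and a JSON manifest.

    Returns the manifest. Any stage failure aborts with the stage name;
    outputs already produced are left on disk.
    """
    config.thresholds.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    beta = OmicsMatrix.read_tsv(config.beta_path, "beta")
    counts = OmicsMatrix.read_tsv(config.counts_path, "count")
    samples = SampleTable.read_tsv(config.samples_path)
    annotation = CpGAnnotation.read_tsv(config.annotation_path)
    ppi = net.load_ppi(config.ppi_path, config.thresholds.ppi_min_score)
    gene_sets = enr.read_gmt(config.gene_sets_path) if config.gene_sets_path else None

    result = run_analysis(
        beta, counts, samples, annotation, ppi, gene_sets,
        covariates=config.covariates,
        reference_time=config.reference_time,
        thresholds=config.thresholds,
    )

    for group, windows in result.meth_results.items():
        for wname, res in windows.items():
            res.write_tsv(out / f"differential_meth_{group}_{wname}.tsv")
    for group, windows in result.expr_results.items():
        for wname, res in windows.items():
            res.write_tsv(out / f"differential_expr_{group}_{wname}.tsv")
    for group in result.rebound_meth:
        result.rebound_meth[group].rebound.to_csv(
            out / f"rebound_meth_{group}.tsv", sep="\t", index_label="feature")
        result.rebound_expr[group].rebound.to_csv(
            out / f"rebound_expr_{group}.tsv", sep="\t", index_label="feature")
    result.shared_meth.shared.to_csv(out / "shared_rebound_dmps.tsv", sep="\t",
                                     index_label="feature")
    result.shared_expr.shared.to_csv(out / "shared_rebound_degs.tsv", sep="\t",
                                     index_label="feature")
    result.shared_meth.quadrant_table.to_csv(out / "quadrants_meth.tsv", sep="\t",
                                             index=False)
    result.shared_expr.quadrant_table.to_csv(out / "quadrants_expr.tsv", sep="\t",
                                             index=False)
    result.contrast_correlations.to_csv(out / "contrast_correlations.tsv", sep="\t",
                                        index=False)
    if result.module_expr is not None:
        result.module_expr.write_tsv(out / "module_expr.tsv")
        result.module_meth.write_tsv(out / "module_meth.tsv")
        viz = net.export_viz_subgraph(ppi, result.rebound_module,
                                      config.thresholds.viz_score)
        viz.to_csv(out / "rebound_module_edges.tsv", sep="\t", index=False)
        pd.Series(sorted(result.rebound_module)).to_csv(
            out / "rebound_module_genes.txt", index=False, header=False)
    if result.pathway_table is not None:
        result.pathway_table.to_csv(out / "pathway_enrichment.tsv", sep="\t")

    manifest = dict(result.manifest)
    manifest["seed"] = config.seed
    manifest["inputs"] = {
        "beta": config.beta_path, "counts": config.counts_path,
        "samples": config.samples_path, "annotation": config.annotation_path,
        "ppi": config.ppi_path, "gene_sets": config.gene_sets_path,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
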