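"""End-to-end pipeline orchestration, single-cell QC filter, and reporting.

Stages: (simulate | load) -> ssGSEA FRG scores -> FPI -> min-max
standardization -> maximally selected survival cutpoint -> group assignment
-> gene differential analysis between FPI groups -> immune infiltration
scores and FPI correlations -> GSVA pathway scores -> pathway differential
analysis -> per-group Kaplan-Meier curves.  Every intermediate table is
written out; the summary JSON records all seeds and parameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential, enrichment, fpi as fpi_mod, immune, surv
from .data import (
    CohortAnnotations,
    ExpressionMatrix,
    GeneSetCollection,
    InputError,
    align,
    read_annotations,
    read_expression,
    read_gmt,
    write_annotations,
    write_expression,
    write_gmt,
)
from .simulate import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "QCReport", "qc_filter_cells", "run_pipeline", "make_report"]


@dataclass
class QCReport:
    """Tally of a single-cell QC filtering pass (a cell may fail several rules)."""

    cells_in: int
    cells_out: int
    failed_min_genes: int
    failed_max_genes: int
    failed_mito: int


class QCError(InputError):
    def __init__(self, message: str, report: QCReport):
        super().__init__(message)
        self.report = report


def qc_filter_cells(
    expr: ExpressionMatrix,
    mito_prefix: str = "MT-",
    min_genes: int = 500,
    max_genes: int = 4000,
    mito_max: float = 0.05,
) -> tuple[ExpressionMatrix, QCReport]:
    """Filter cells (columns) of a count matrix by detected-gene count and
    mitochondrial fraction.

    A cell is kept when its detected-gene count lies in [min_genes,
    max_genes] and its mitochondrial count fraction is strictly below
    ``mito_max``.  Failure tallies count every rule a cell breaks.
    """
    if expr.scale_tag != "counts":
        raise InputError("qc_filter_cells expects a counts matrix (scale_tag='counts')")
    if np.any(expr.values < 0):
        raise InputError("counts must be non-negative")
    detected = (expr.values > 0).sum(axis=0)
    mito_rows = np.array([g.startswith(mito_prefix) for g in expr.gene_ids])
    totals = expr.values.sum(axis=0)
    mito_frac = np.divide(
        expr.values[mito_rows].sum(axis=0) if mito_rows.any() else np.zeros_like(totals),
        totals,
        out=np.zeros_like(totals),
        where=totals > 0,
    )
    fail_min = detected < min_genes
    fail_max = detected > max_genes
    fail_mito = mito_frac >= mito_max
    keep = ~(fail_min | fail_max | fail_mito)
    report = QCReport(
        cells_in=expr.n_samples,
        cells_out=int(keep.sum()),
        failed_min_genes=int(fail_min.sum()),
        failed_max_genes=int(fail_max.sum()),
        failed_mito=int(fail_mito.sum()),
    )
    if not keep.any():
        raise QCError("no cells pass QC", report)
    kept_ids = [s for s, k in zip(expr.sample_ids, keep) if k]
    return expr.subset_samples(kept_ids), report


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulation`` (a CohortConfig) or the triple of real
    input paths (expression/annotations/gene sets) must be provided.  All
    named thresholds default to the analysis' standard values.
    """

    simulation: CohortConfig | None = None
    expression_path: str | None = None
    annotations_path: str | None = None
    gmt_path: str | None = None
    frg_positive: str = "FRG_positive"
    frg_negative: str = "FRG_negative"
    ssgsea_alpha: float = 0.25
    gsva_tau: float = 1.0
    gsva_kcdf: str = "gaussian"
    min_set_size: int = 10
    max_set_size: int = 500
    minprop: float = 0.10
    effect_threshold: float = 1.5
    pathway_effect_threshold: float = 0.1
    alpha: float = 0.05
    qc_min_genes: int = 500
    qc_max_genes: int = 4000
    qc_mito_max: float = 0.05
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        real = [self.expression_path, self.annotations_path, self.gmt_path]
        has_real = any(p is not None for p in real)
        if has_real and self.simulation is not None:
            raise InputError("config must specify real inputs or a simulation block, not both")
        if has_real and not all(p is not None for p in real):
            raise InputError("real-input mode needs expression, annotations and gmt paths")
        if not has_real and self.simulation is None:
            raise InputError("config must specify real inputs or a simulation block")
        for name, value, lo, hi in (
            ("minprop", self.minprop, 0.0, 0.5),
            ("alpha", self.alpha, 0.0, 1.0),
            ("qc_mito_max", self.qc_mito_max, 0.0, 1.0),
        ):
            if not (lo < value <= hi):
                raise InputError(f"{name}={value} outside ({lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(simulation=CohortConfig(**sim) if sim is not None else None, **raw)
        return cfg

    def to_dict(self) -> dict:
        out = asdict(self)
        return out


def _load_inputs(
    config: PipelineConfig,
) -> tuple[ExpressionMatrix, CohortAnnotations, GeneSetCollection]:
    if config.simulation is not None:
        return generate_cohort(config.simulation)
    expr = read_expression(config.expression_path)
    ann = read_annotations(config.annotations_path)
    sets = read_gmt(config.gmt_path)
    return expr, ann, sets


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the in-memory report bundle.

    When ``config.outdir`` is set, every intermediate table, the summary
    JSON and a run log are written there; stage failures propagate with the
    stage name attached and partial outputs are retained.
    """
    outdir = Path(config.outdir) if config.outdir else None
    handler = None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
        logging.getLogger("ferroscore").addHandler(handler)
    try:
        return _run_pipeline_stages(config, outdir)
    finally:
        if handler is not None:
            logging.getLogger("ferroscore").removeHandler(handler)
            handler.close()


def _run_pipeline_stages(config: PipelineConfig, outdir: Path | None) -> dict:
    bundle: dict = {"config": config.to_dict()}
    stage = "load_inputs"
    try:
        expr, ann, sets = _load_inputs(config)
        expr, ann = align(expr, ann)
        bundle["n_genes"], bundle["n_samples"] = expr.n_genes, expr.n_samples
        logger.info("inputs: %d genes x %d samples, %d gene sets", expr.n_genes, expr.n_samples, len(sets))
        if outdir:
            write_expression(expr, outdir / "expression.tsv")
            write_annotations(ann, outdir / "annotations.tsv")
            write_gmt(sets, outdir / "sets.gmt")

        stage = "frg_scores"
        frg = fpi_mod.FRGConfig(sets[config.frg_positive], sets[config.frg_negative])
        frg_scores = enrichment.ssgsea_scores(
            expr, frg.as_collection(), alpha=config.ssgsea_alpha, normalize=True
        )
        if outdir:
            frg_scores.to_frame().to_csv(outdir / "frg_scores.tsv", sep="\t")

        stage = "fpi"
        raw_fpi = fpi_mod.compute_fpi(frg_scores, frg)
        std_fpi = fpi_mod.standardize_fpi(raw_fpi)
        logger.info("FPI standardized before cutpoint selection (min-max to [0,1])")

        stage = "optimal_cutpoint"
        cut = surv.optimal_cutpoint(std_fpi.fpi, ann, minprop=config.minprop)
        grouped = fpi_mod.assign_groups(std_fpi, cut.cutoff)
        bundle["fpi_cutoff"] = cut.cutoff
        bundle["cutpoint_statistic"] = cut.statistic
        bundle["cutpoint_candidates"] = cut.candidates_evaluated
        if outdir:
            grouped.to_frame().to_csv(outdir / "fpi.tsv", sep="\t")

        stage = "km_logrank"
        fpi_ann = CohortAnnotations(
            pd.DataFrame(
                {"group": grouped.group, "time": ann.time, "event": ann.event},
                index=pd.Index(list(ann.sample_ids), name="sample_id"),
            )
        )
        lr = surv.logrank_test(fpi_ann, ("low", "high"))
        km_low = surv.km_estimate(fpi_ann, "low")
        km_high = surv.km_estimate(fpi_ann, "high")
        horizon = float(np.median(ann.time))
        bundle["logrank_p"] = lr.pvalue
        bundle["worse_survival_group"] = (
            "low" if km_low.survival_at(horizon) < km_high.survival_at(horizon) else "high"
        )
        if outdir:
            for name, curve in (("low", km_low), ("high", km_high)):
                pd.DataFrame(
                    {
                        "time": curve.times,
                        "survival": curve.survival,
                        "at_risk": curve.at_risk,
                        "events": curve.events,
                    }
                ).to_csv(outdir / f"km_{name}.tsv", sep="\t", index=False)

        stage = "gene_differential"
        degs = differential.moderated_t_test(expr, grouped.group)
        degs = differential.select_features(degs, config.effect_threshold, config.alpha)
        bundle["n_degs_selected"] = int(degs["selected"].sum())
        if outdir:
            degs.to_csv(outdir / "degs.tsv", sep="\t", index=False)

        stage = "immune"
        marker_names = [n for n in sets.names if n not in (frg.positive.name, frg.negative.name)]
        bundle["n_correlated_celltypes"] = 0
        corr = None
        if marker_names:
            markers = sets.subset(marker_names)
            infil = immune.infiltration_scores(expr, markers, alpha=config.ssgsea_alpha)
            corr = immune.correlate_fpi_infiltration(grouped, infil)
            edges = immune.network_edges(corr, padj_cutoff=config.alpha)
            bundle["n_correlated_celltypes"] = len(edges)
            bundle["top_celltypes"] = corr.head(5)[["cell_type", "r", "padj"]].to_dict("records")
            if outdir:
                infil.to_frame().to_csv(outdir / "infiltration.tsv", sep="\t")
                corr.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
                edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)

        stage = "pathway_gsva"
        bundle["n_pathways_selected"] = 0
        if marker_names:
            pathways = sets.subset(marker_names)
            gsva = enrichment.gsva_scores(
                expr, pathways, tau=config.gsva_tau, kcdf=config.gsva_kcdf
            )
            path_diff = differential.moderated_t_test(gsva, grouped.group)
            path_diff = differential.select_features(
                path_diff, config.pathway_effect_threshold, config.alpha
            )
            bundle["n_pathways_selected"] = int(path_diff["selected"].sum())
            if outdir:
                gsva.to_frame().to_csv(outdir / "gsva_scores.tsv", sep="\t")
                path_diff.to_csv(outdir / "pathway_diff.tsv", sep="\t", index=False)

        bundle["correlations"] = corr
    except InputError as exc:
        raise InputError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = {k: v for k, v in bundle.items() if k != "correlations"}
    bundle["summary_json"] = json.dumps(summary, indent=2, sort_keys=True, default=str)
    if outdir:
        (outdir / "summary.json").write_text(bundle["summary_json"])
        (outdir / "report.md").write_text(make_report(bundle))
    return bundle


def make_report(bundle: dict) -> str:
    """Render the bundle as a short human-readable markdown summary."""
    lines = [
        "# Ferroptosis-index analysis report",
        "",
        f"- Samples: {bundle.get('n_samples')}  Genes: {bundle.get('n_genes')}",
        f"- FPI survival cutoff: {bundle.get('fpi_cutoff'):.4f} "
        f"(log-rank statistic {bundle.get('cutpoint_statistic'):.3f}, "
        f"{bundle.get('cutpoint_candidates')} candidate splits)",
        f"- Log-rank p (low vs high FPI): {bundle.get('logrank_p'):.3g}",
        f"- Worse-survival group: {bundle.get('worse_survival_group')} FPI",
        f"- Differential genes selected: {bundle.get('n_degs_selected', 0)}",
        f"- Pathways selected: {bundle.get('n_pathways_selected', 0)}",
        "",
    ]
    corr = bundle.get("correlations")
    if corr is not None and len(corr):
        lines.append("Cell types by |correlation with FPI| (descending):")
        for _, row in corr.iterrows():
            lines.append(
                f"- {row['cell_type']}: r = {row['r']:+.3f} (padj = {row['padj']:.3g})"
            )
    else:
        lines.append("No immune marker sets provided; correlation stage skipped.")
    if bundle.get("n_degs_selected", 0) == 0:
        lines.append("")
        lines.append("Zero differential features passed the selection rule.")
    lines.append("")
    return "\n".join(lines)
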