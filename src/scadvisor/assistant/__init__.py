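"""The ten advisor tasks: gather metrics, render the augmented prompt,
dispatch to the backend, parse the response, and optionally apply the
result back onto the dataset."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Any, Callable

import numpy as np
import pandas as pd

from .._errors import MetricError, ParseError, ScAdvisorError, UserError
from .. import metrics as M
from ..backends import BackendConfig, complete
from ..dataio import (
    CELL_TYPE_COLUMN,
    CellDataset,
    GeneSetCollection,
    RecommendationRecord,
    attach_labels,
)
from ..prompt_engine import format_number, get_template, render_prompt
from . import parsers
from .network import NetworkGraph, graph_from_text, write_html
from .ora import EnrichmentTable, format_enrichment_block, run_ora
from .parsers import (
    AnnotationTable,
    FilterCutoffs,
    ResolutionRange,
    extract_metric_echoes,
    parse_annotations,
    parse_cutoffs,
    parse_seq_range,
)

__all__ = [
    "TaskSpec",
    "TASK_REGISTRY",
    "run_task",
    "analyze_and_annotate",
    "analyze_enrichment",
    "summary_network",
    "run_ora",
    "EnrichmentTable",
    "NetworkGraph",
    "FilterCutoffs",
    "ResolutionRange",
    "AnnotationTable",
    "parse_seq_range",
    "parse_cutoffs",
    "parse_annotations",
    "extract_metric_echoes",
]

DEFAULT_NORMALIZATION_MENU = ["LogNormalize", "SCTransform", "CLR", "RC"]
DEFAULT_MAX_PADJ = 0.05
DEFAULT_TOP_MARKERS = 10


@dataclass
class TaskSpec:
    """Binds one advisor task to its metric gatherer, template and parser."""

    task_id: str
    gather: Callable[[CellDataset, dict], dict]
    parser: Callable[[str, dict], Any]
    applier: Callable[[CellDataset, Any, dict], CellDataset] | None = None


# ---------------------------------------------------------------------------
# gatherers: CellDataset (+ task inputs) -> placeholder values
# ---------------------------------------------------------------------------

def _fmt_quantiles(qs: dict[int, float]) -> str:
    return ", ".join(f"{k}%: {format_number(v)}" for k, v in qs.items())


def _gather_quality(ds: CellDataset, inputs: dict) -> dict:
    names = inputs.get("metric_names") or M.default_qc_metric_names(ds)
    bundle = M.summarize_qc(ds, names)
    blocks = []
    for name, s in bundle.metrics.items():
        blocks.append(
            f"{name}: mean={format_number(s.mean)}, "
            f"median={format_number(s.median)}, sd={format_number(s.sd)}, "
            f"min={format_number(s.min)}, max={format_number(s.max)};"
            f" quantiles: {_fmt_quantiles(s.quantiles)}"
        )
    inputs["_metric_names"] = names
    return {"n_cells": bundle.n_cells, "qc_stats_block": "\n".join(blocks)}


def _gather_normalization(ds: CellDataset, inputs: dict) -> dict:
    stats = M.library_size_stats(ds)
    menu = inputs.get("method_menu") or DEFAULT_NORMALIZATION_MENU
    inputs["_method_menu"] = menu
    return {
        "n_cells": stats.n_cells,
        "library_size_mean": format_number(stats.library_size_mean),
        "library_size_median": format_number(stats.library_size_median),
        "library_size_cv": format_number(stats.library_size_cv),
        "zero_fraction": format_number(stats.zero_fraction),
        "gene_mean_quantiles": _fmt_quantiles(stats.gene_mean_quantiles),
        "method_menu": "\n".join(f"- {m}" for m in menu),
    }


def _gather_variable_features(ds: CellDataset, inputs: dict) -> dict:
    flags = M.ensure_hvg(ds, inputs.get("n_hvg", M.DEFAULT_N_HVG))
    genes = [g for g, f in zip(ds.gene_names, flags) if f]
    limit = inputs.get("max_genes_in_prompt", 100)
    return {"hvg_genes": ", ".join(genes[:limit])}


def _gather_recommend_pcs(ds: CellDataset, inputs: dict) -> dict:
    profile = M.variance_explained(ds)
    lines = [
        f"PC{i + 1}: {format_number(float(f))} "
        f"(cumulative {format_number(float(c))})"
        for i, (f, c) in enumerate(zip(profile.fractions, profile.cumulative))
    ]
    return {"variance_table": "\n".join(lines)}


def _gather_analyze_pcs(ds: CellDataset, inputs: dict) -> dict:
    n_pcs = inputs.get("n_pcs", 5)
    n_genes = inputs.get("n_genes", 10)
    M.ensure_pca(ds, max(n_pcs, M.DEFAULT_N_PCS))
    n_pcs = min(n_pcs, ds.pc_loadings.shape[1])
    table = M.top_pc_genes(ds, n_pcs, min(n_genes, ds.n_genes))
    lines = []
    for pc, (pos, neg) in table.per_pc.items():
        pos_s = ", ".join(f"{g} ({format_number(v)})" for g, v in pos)
        neg_s = ", ".join(f"{g} ({format_number(v)})" for g, v in neg)
        lines.append(f"PC{pc} positive: {pos_s}\nPC{pc} negative: {neg_s}")
    return {"pc_gene_table": "\n".join(lines)}


def _gather_recommend_k(ds: CellDataset, inputs: dict) -> dict:
    M.ensure_pca(ds, inputs.get("n_pcs", M.DEFAULT_N_PCS))
    return {
        "n_cells": ds.n_cells,
        "n_pcs_used": min(inputs.get("n_pcs", M.DEFAULT_N_PCS),
                          ds.pc_embedding.shape[1]),
        "clustering_goals": inputs.get(
            "clustering_goals", "general-purpose cluster discovery"
        ),
    }


def _gather_recommend_res(ds: CellDataset, inputs: dict) -> dict:
    cm = M.clustering_metrics(
        ds,
        k=inputs.get("k", M.DEFAULT_K) if inputs.get("k", M.DEFAULT_K) < ds.n_cells
        else max(1, ds.n_cells - 1),
        n_pcs=inputs.get("n_pcs", M.DEFAULT_N_PCS),
    )
    return {
        "n_cells": cm.n_cells,
        "n_hvg": cm.n_hvg,
        "mean_expression_variability": format_number(
            cm.mean_expression_variability
        ),
        "median_neighbor_distance": format_number(cm.median_neighbor_distance),
    }


def _marker_block(bundle: M.ClusterMarkerBundle) -> str:
    lines = []
    for cluster, rows in bundle.per_cluster.items():
        if not rows:
            lines.append(f"Cluster {cluster}: (no significant markers)")
            continue
        genes = ", ".join(
            f"{g} (lfc={format_number(lfc)}, padj={format_number(p)})"
            for g, lfc, p in rows
        )
        lines.append(f"Cluster {cluster}: {genes}")
    return "\n".join(lines)


def _gather_annotate(ds: CellDataset, inputs: dict) -> dict:
    table = inputs.get("marker_table")
    if table is None:
        table = M.marker_table_from_dataset(ds)
    if table is None:
        raise MetricError("analyze_and_annotate requires a marker table")
    bundle = M.top_markers(
        table,
        inputs.get("top_n", DEFAULT_TOP_MARKERS),
        inputs.get("max_padj", DEFAULT_MAX_PADJ),
    )
    clusters = sorted(bundle.per_cluster)
    if ds.cluster_labels is not None:
        observed = sorted(set(ds.cluster_labels))
        extra = set(clusters) - set(observed)
        if extra:
            raise MetricError(
                f"marker table has clusters absent from dataset: {sorted(extra)}"
            )
        clusters = sorted(set(clusters) | set(observed))
    inputs["_clusters"] = clusters
    return {
        "marker_block": _marker_block(bundle),
        "clusters": ", ".join(clusters),
    }


def _compute_enrichment_table(
    ds: CellDataset | None, inputs: dict
) -> EnrichmentTable:
    query = inputs.get("query_genes")
    sets: GeneSetCollection | None = inputs.get("gene_sets")
    if query is None or sets is None:
        raise MetricError(
            "analyze_enrichment requires query_genes and gene_sets inputs"
        )
    universe = inputs.get("universe_genes")
    if universe is None:
        if ds is None:
            raise MetricError(
                "analyze_enrichment needs universe_genes or a dataset"
            )
        # default universe: all genes detected in >= 1 cell
        detected = np.asarray((ds.counts > 0).sum(axis=0)).ravel()
        universe = [g for g, d in zip(ds.gene_names, detected) if d > 0]
    return run_ora(query, universe, sets, inputs.get("max_q", 0.05))


def _gather_enrichment(ds: CellDataset | None, inputs: dict) -> dict:
    table = inputs.get("_enrichment_table")
    if table is None:
        table = _compute_enrichment_table(ds, inputs)
        inputs["_enrichment_table"] = table
    return {"enrichment_block": format_enrichment_block(table)}


def _gather_network(ds: CellDataset | None, inputs: dict) -> dict:
    summary = inputs.get("enrichment_summary")
    if not summary:
        record = inputs.get("enrichment_record")
        if record is not None:
            summary = record.raw_response
    if not summary:
        raise MetricError(
            "summary_network requires an enrichment summary or record"
        )
    return {"enrichment_summary": summary}


# ---------------------------------------------------------------------------
# parsers: raw text (+ inputs) -> payload
# ---------------------------------------------------------------------------

def _parse_quality(text: str, inputs: dict) -> FilterCutoffs:
    names = inputs.get("_metric_names") or inputs.get("metric_names") or []
    return parse_cutoffs(text, names)


def _parse_normalization(text: str, inputs: dict) -> dict:
    menu = inputs.get("_method_menu") or DEFAULT_NORMALIZATION_MENU
    return {
        "method": parsers.parse_method_choice(text, menu),
        "reasoning": parsers._reasoning_tail(text),
    }


def _parse_free_text(text: str, inputs: dict) -> dict:
    if not text.strip():
        raise ParseError("empty response")
    return {"summary": text.strip()}


def _parse_recommend_pcs(text: str, inputs: dict) -> dict:
    return {"n_pcs": parsers.parse_n_pcs(text)}


def _parse_recommend_k(text: str, inputs: dict) -> dict:
    lo, hi = parsers.parse_int_range(text)
    return {"k_min": lo, "k_max": hi}


def _parse_recommend_res(text: str, inputs: dict) -> ResolutionRange:
    return parse_seq_range(text)


def _parse_annotations(text: str, inputs: dict) -> AnnotationTable:
    return parse_annotations(text, inputs.get("_clusters") or [])


def _parse_network(text: str, inputs: dict) -> NetworkGraph:
    return graph_from_text(text)


# ---------------------------------------------------------------------------
# appliers
# ---------------------------------------------------------------------------

def _apply_annotations(
    ds: CellDataset, payload: AnnotationTable, inputs: dict
) -> CellDataset:
    return attach_labels(
        ds,
        inputs.get("label_column", CELL_TYPE_COLUMN),
        payload.labels,
        overwrite=inputs.get("overwrite", True),
    )


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

TASK_REGISTRY: dict[str, TaskSpec] = {
    spec.task_id: spec
    for spec in [
        TaskSpec("analyze_quality", _gather_quality, _parse_quality),
        TaskSpec("recommend_normalization", _gather_normalization,
                 _parse_normalization),
        TaskSpec("analyze_variable_features", _gather_variable_features,
                 _parse_free_text),
        TaskSpec("recommend_pcs", _gather_recommend_pcs, _parse_recommend_pcs),
        TaskSpec("analyze_pcs", _gather_analyze_pcs, _parse_free_text),
        TaskSpec("recommend_k", _gather_recommend_k, _parse_recommend_k),
        TaskSpec("recommend_res", _gather_recommend_res, _parse_recommend_res),
        TaskSpec("analyze_and_annotate", _gather_annotate, _parse_annotations,
                 _apply_annotations),
        TaskSpec("analyze_enrichment", _gather_enrichment, _parse_free_text),
        TaskSpec("summary_network", _gather_network, _parse_network),
    ]
}


def run_task(
    task_id: str,
    ds: CellDataset | None,
    cfg: BackendConfig,
    experiment_description: str = "",
    template_dir=None,
    record_timestamp: bool = True,
    **inputs,
) -> RecommendationRecord:
    """Run one advisor task end to end and return its record.

    Metric precondition failures propagate with task context; a parser
    failure returns a record flagged unparsed with the raw text preserved.
    """
    if task_id not in TASK_REGISTRY:
        raise UserError(
            f"unknown task {task_id!r}; valid tasks: "
            f"{', '.join(sorted(TASK_REGISTRY))}"
        )
    spec = TASK_REGISTRY[task_id]
    try:
        values = spec.gather(ds, inputs)
    except ScAdvisorError as exc:
        raise type(exc)(f"[{task_id}] {exc}") from exc
    template = get_template(task_id, template_dir)
    prompt = render_prompt(template, values, experiment_description or None)
    response = complete(cfg, prompt)
    record = RecommendationRecord(
        task_id=task_id,
        rendered_prompt=prompt.text,
        raw_response=response.text,
        model_id=response.model_id,
        backend_name=cfg.server,
        timestamp=(
            datetime.now(timezone.utc).isoformat() if record_timestamp else ""
        ),
        provenance={
            "substitutions": sorted(prompt.substitutions),
            "derived_layers": list((ds.provenance.get("derived", []) if ds else [])),
        },
    )
    try:
        record.parsed_payload = spec.parser(response.text, inputs)
    except ParseError as exc:
        record.parse_error = str(exc)
    return record


# ---------------------------------------------------------------------------
# composite operations
# ---------------------------------------------------------------------------

def analyze_and_annotate(
    ds: CellDataset,
    marker_table: pd.DataFrame,
    cfg: BackendConfig,
    apply: bool = False,
    experiment_description: str = "",
    **inputs,
) -> tuple[RecommendationRecord, CellDataset]:
    """Annotate clusters from markers; write-back is atomic — on any parse
    error the dataset is returned unchanged."""
    record = run_task(
        "analyze_and_annotate",
        ds,
        cfg,
        experiment_description,
        marker_table=marker_table,
        **inputs,
    )
    if not apply or record.parse_error is not None:
        return record, ds
    updated = _apply_annotations(ds, record.parsed_payload, inputs)
    return record, updated


def analyze_enrichment(
    query_genes,
    gene_sets: GeneSetCollection,
    cfg: BackendConfig,
    ds: CellDataset | None = None,
    universe_genes=None,
    experiment_description: str = "",
    **inputs,
) -> tuple[RecommendationRecord, EnrichmentTable]:
    """Native ORA feeding an LLM summary; the table survives LLM failures."""
    inputs.update(
        query_genes=query_genes,
        gene_sets=gene_sets,
        universe_genes=universe_genes,
    )
    table = _compute_enrichment_table(ds, inputs)
    record = run_task(
        "analyze_enrichment",
        ds,
        cfg,
        experiment_description,
        _enrichment_table=table,
        **inputs,
    )
    return record, table


def summary_network(
    enrichment_record: RecommendationRecord,
    cfg: BackendConfig,
    html_out=None,
    **inputs,
) -> tuple[RecommendationRecord, NetworkGraph | None]:
    """Second-round LLM call: extract a typed network from the enrichment
    summary and optionally write a self-contained HTML view."""
    record = run_task(
        "summary_network",
        None,
        cfg,
        enrichment_record=enrichment_record,
        **inputs,
    )
    if record.parse_error is not None:
        raise ParseError(
            f"summary_network: {record.parse_error}; raw text preserved in record"
        )
    net: NetworkGraph = record.parsed_payload
    if html_out is not None:
        write_html(net, html_out)
    return record, net
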