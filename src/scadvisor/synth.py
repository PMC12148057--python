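"""Synthetic single-cell datasets with known structure, marker tables and
canned LLM responses, so every stage is testable offline.

Counts are negative-binomial with log-normal library-size factors; each
population's marker genes are up-regulated by a fixed fold-change.  No
attempt is made to mimic droplet artifacts (doublets, ambient RNA).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from ._errors import DataError, UserError
from .assistant.ora import benjamini_hochberg
from .dataio import CLUSTER_COLUMN, CellDataset
from .metrics import MARKER_COLUMNS, ensure_lognorm
from .prompt_engine import TASK_IDS

__all__ = [
    "SynthConfig",
    "generate_counts",
    "generate_marker_table",
    "build_fixture_store",
    "DEFAULT_RESPONSES",
]


@dataclass
class SynthConfig:
    n_cells: int = 500
    n_genes: int = 1000
    n_populations: int = 3
    markers_per_population: int = 10
    marker_fold_change: float = 8.0
    nb_mean: float = 0.5
    nb_dispersion: float = 0.5
    libsize_sigma: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        positives = dict(
            n_cells=self.n_cells,
            n_genes=self.n_genes,
            n_populations=self.n_populations,
            markers_per_population=self.markers_per_population,
            marker_fold_change=self.marker_fold_change,
            nb_mean=self.nb_mean,
            nb_dispersion=self.nb_dispersion,
            libsize_sigma=self.libsize_sigma,
        )
        for name, value in positives.items():
            if value <= 0:
                raise UserError(f"{name} must be positive, got {value}")
        if self.n_populations > self.n_cells:
            raise UserError("more populations than cells")
        if self.markers_per_population * self.n_populations > self.n_genes:
            raise UserError("marker genes exceed total genes")


def planted_markers(cfg: SynthConfig) -> dict[str, list[str]]:
    """Gene names planted as markers of each population, by construction."""
    out: dict[str, list[str]] = {}
    for p in range(cfg.n_populations):
        start = p * cfg.markers_per_population
        out[str(p)] = [
            _gene_name(i, cfg.n_genes)
            for i in range(start, start + cfg.markers_per_population)
        ]
    return out


def _gene_name(i: int, n_genes: int) -> str:
    width = len(str(n_genes))
    return f"G{i + 1:0{width}d}"


def generate_counts(cfg: SynthConfig) -> CellDataset:
    """Seed-reproducible NB counts with planted population markers.

    True population labels are stored as string cluster labels.
    """
    rng = np.random.default_rng(cfg.seed)
    # per-gene baseline means spread over ~2 orders of magnitude
    base = cfg.nb_mean * rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    lib = rng.lognormal(mean=0.0, sigma=cfg.libsize_sigma, size=cfg.n_cells)
    pops = rng.integers(0, cfg.n_populations, size=cfg.n_cells)

    mu = np.outer(lib, base)
    for p in range(cfg.n_populations):
        start = p * cfg.markers_per_population
        cols = slice(start, start + cfg.markers_per_population)
        mu[pops == p, cols] *= cfg.marker_fold_change

    r = 1.0 / cfg.nb_dispersion  # NB size; var = mu + dispersion * mu^2
    p_nb = r / (r + mu)
    counts = rng.negative_binomial(r, p_nb)

    gene_names = [_gene_name(i, cfg.n_genes) for i in range(cfg.n_genes)]
    barcodes = [f"C{i + 1:05d}" for i in range(cfg.n_cells)]
    meta = pd.DataFrame(index=barcodes)
    ds = CellDataset.from_counts(counts, gene_names, meta)
    ds.cell_meta[CLUSTER_COLUMN] = pops.astype(str)
    ds.provenance["synth_config"] = {
        k: getattr(cfg, k) for k in cfg.__dataclass_fields__
    }
    return ds


def generate_marker_table(ds: CellDataset, min_lfc: float = 0.0) -> pd.DataFrame:
    """Rank-sum marker table (cluster, gene, avg_log2FC, p_val_adj) from the
    stored true labels; deterministic given the dataset."""
    labels = ds.cluster_labels
    if labels is None:
        raise DataError("dataset has no true labels; run generate_counts first")
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise DataError("marker table needs at least two populations")
    logn = np.asarray(ensure_lognorm(ds))
    eps = 1e-9
    rows = []
    for cluster in clusters:
        mask = (labels == cluster).to_numpy()
        inside, outside = logn[mask], logn[~mask]
        mean_in = np.expm1(inside).mean(axis=0)
        mean_out = np.expm1(outside).mean(axis=0)
        lfc = np.log2((mean_in + eps) / (mean_out + eps))
        p = mannwhitneyu(inside, outside, alternative="greater", axis=0).pvalue
        padj = benjamini_hochberg(p)
        keep = lfc > min_lfc
        for g, l, q in zip(
            np.array(ds.gene_names)[keep], lfc[keep], padj[keep]
        ):
            rows.append((cluster, g, float(l), float(q)))
    return pd.DataFrame(rows, columns=list(MARKER_COLUMNS))


# ---------------------------------------------------------------------------
# canned LLM responses
# ---------------------------------------------------------------------------

# Canned recommend_res response with realistic full-precision reasoning so
# the range parser and the metric-echo audit have a stable, lifelike fixture.
_RECOMMEND_RES_EXAMPLE = """\
## Based on the data characteristics, I recommend:
## **Recommended Resolution:** seq(0.2, 1.2, 0.1)
##
## **Reasoning:**
## The mean expression variability of 0.868717336264306 suggests a moderate level of heterogeneity in your dataset. This indicates that there are likely distinct cell populations, but they may not be drastically different from each other. The median neighbor distance of 2.50502443313599 in the k-nearest neighbor graph further supports this notion, as it implies a moderate level of separation between cells.
## Therefore, a resolution range of 0.2 to 1.2 with increments of 0.1 is recommended. This range allows for the identification of both distinct and subtle cell populations. Lower resolutions (closer to 0.2) will capture broader, more general cell types, while higher resolutions (closer to 1.2) will reveal finer distinctions within those populations. By exploring this range, you can effectively identify the optimal resolution for your specific analysis goals.
"""

DEFAULT_RESPONSES: dict[str, str] = {
    "analyze_quality": (
        "Recommended filtering cutoffs:\n"
        "- total_counts above 500 and below 30000\n"
        "- n_genes_detected above 200 and below 5000\n"
        "Reasoning: the lower tails of both distributions indicate empty or "
        "low-quality droplets, while the upper tails are consistent with "
        "doublets; the quantile structure supports these boundaries."
    ),
    "recommend_normalization": (
        "Recommended normalization: LogNormalize\n"
        "Reasoning: the library size coefficient of variation is moderate "
        "and the expression distribution is typical of UMI counts, so "
        "global scaling with log transformation is appropriate."
    ),
    "analyze_variable_features": (
        "The highly variable genes are consistent with immune cell "
        "identity programs, suggesting enrichment of lymphocyte activation "
        "and cytokine signaling pathways relevant to the experiment."
    ),
    "recommend_pcs": (
        "Recommended number of PCs: 10\n"
        "Reasoning: the cumulative variance explained plateaus after the "
        "first ten components; later components contribute mostly noise."
    ),
    "analyze_pcs": (
        "PC1 separates cells by activation state, driven by its top "
        "positive-loading genes; PC2 reflects cell-cycle related "
        "variation. Together the leading components capture the dominant "
        "biological programs in the data."
    ),
    "recommend_k": (
        "Recommended k.param range: 10 to 30\n"
        "Reasoning: with this number of cells and PCs, neighborhoods of "
        "10-30 cells balance local structure against noise."
    ),
    "recommend_res": _RECOMMEND_RES_EXAMPLE,
    "analyze_and_annotate": (
        "Cluster 0: NK cells - strong expression of canonical cytotoxic "
        "markers.\n"
        "Cluster 1: CD8 T cells - dominated by T-cell receptor and "
        "cytotoxic effector genes.\n"
        "Cluster 2: B cells - immunoglobulin and B-lineage markers are "
        "the top features."
    ),
    "analyze_enrichment": (
        "The enrichment results highlight TNF signaling as the central "
        "pathway. TNF acts as a potential regulator upstream of NFKB1, "
        "which in turn drives IL6 expression; IL6 engages STAT3 as a key "
        "target. Together these form a coherent inflammatory signaling "
        "module."
    ),
    "summary_network": (
        "TNF|activates|NFKB1\n"
        "NFKB1|regulates|IL6\n"
        "IL6|induces|STAT3"
    ),
}


def build_fixture_store(
    responses: dict[str, str] | None = None, path: str | Path | None = None
) -> dict:
    """Build (and optionally write) a replay fixture store.

    Ships defaults for all ten tasks; ``responses`` overrides or pins
    per-task entries.  Unknown task keys are an error.
    """
    store: dict[str, dict] = {
        task: {"default": text} for task, text in DEFAULT_RESPONSES.items()
    }
    for task, entry in (responses or {}).items():
        if task not in TASK_IDS:
            raise UserError(
                f"unknown task key {task!r}; valid tasks: {', '.join(TASK_IDS)}"
            )
        if isinstance(entry, str):
            store[task] = {"default": entry}
        else:
            store[task].update(entry)
    if path is not None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(store, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return store
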