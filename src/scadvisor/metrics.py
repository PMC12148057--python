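"""Data metrics injected into task prompts.

Conventions fixed package-wide: sample variance (ddof=1), quantiles by
linear interpolation between order statistics, quantile grid
{1,5,10,25,50,75,90,95,99}%.  Log-normalization scales each cell to
10,000 counts then applies log1p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from ._errors import MetricError
from .dataio import CLUSTER_COLUMN, CellDataset

QUANTILE_GRID = (1, 5, 10, 25, 50, 75, 90, 95, 99)
DEFAULT_N_HVG = 2000
DEFAULT_N_PCS = 10
DEFAULT_K = 20
LOGNORM_TARGET_SUM = 10_000.0


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

@dataclass
class MetricSummary:
    mean: float
    median: float
    sd: float
    min: float
    max: float
    quantiles: dict[int, float]


@dataclass
class QCMetricBundle:
    n_cells: int
    metrics: dict[str, MetricSummary]


@dataclass
class NormalizationMetrics:
    n_cells: int
    library_size_mean: float
    library_size_median: float
    library_size_cv: float
    zero_fraction: float
    gene_mean_quantiles: dict[int, float]


@dataclass
class PCVarianceProfile:
    fractions: np.ndarray
    cumulative: np.ndarray


@dataclass
class PCGeneTable:
    # per PC: ([(gene, loading) descending], [(gene, loading) ascending])
    per_pc: dict[int, tuple[list[tuple[str, float]], list[tuple[str, float]]]]


@dataclass
class ClusteringMetrics:
    n_cells: int
    n_pcs_used: int
    n_hvg: int
    k: int
    mean_expression_variability: float
    median_neighbor_distance: float


@dataclass
class ClusterMarkerBundle:
    # per cluster: [(gene, effect size, adjusted p)] top-n by effect size
    per_cluster: dict[str, list[tuple[str, float, float]]] = field(
        default_factory=dict
    )


# ---------------------------------------------------------------------------
# QC summaries
# ---------------------------------------------------------------------------

def _summary(values: np.ndarray) -> MetricSummary:
    values = np.asarray(values, dtype=float)
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    qs = np.quantile(values, [q / 100.0 for q in QUANTILE_GRID])
    return MetricSummary(
        mean=float(np.mean(values)),
        median=float(np.median(values)),
        sd=sd,
        min=float(np.min(values)),
        max=float(np.max(values)),
        quantiles={q: float(v) for q, v in zip(QUANTILE_GRID, qs)},
    )


def summarize_qc(ds: CellDataset, metric_names: list[str]) -> QCMetricBundle:
    """Summary statistics + quantile grid per QC metric column."""
    out: dict[str, MetricSummary] = {}
    for name in metric_names:
        if name not in ds.cell_meta.columns:
            raise MetricError(
                f"unknown QC metric {name!r}; available: "
                f"{sorted(ds.cell_meta.columns)}"
            )
        out[name] = _summary(ds.cell_meta[name].to_numpy())
    return QCMetricBundle(n_cells=ds.n_cells, metrics=out)


def default_qc_metric_names(ds: CellDataset) -> list[str]:
    names = ["total_counts", "n_genes_detected"]
    names += sorted(c for c in ds.cell_meta.columns if c.startswith("percent_"))
    return names


# ---------------------------------------------------------------------------
# normalization metrics
# ---------------------------------------------------------------------------

def library_size_stats(ds: CellDataset) -> NormalizationMetrics:
    totals = ds.cell_meta["total_counts"].to_numpy(dtype=float)
    if totals.sum() == 0:
        raise MetricError("all-zero count matrix: nothing to normalize")
    mean = float(np.mean(totals))
    sd = float(np.std(totals, ddof=1)) if totals.size > 1 else 0.0
    counts = ds.counts
    if sp.issparse(counts):
        n_nonzero = counts.nnz
    else:
        n_nonzero = int(np.count_nonzero(counts))
    total_entries = ds.n_cells * ds.n_genes
    gene_means = np.asarray(counts.mean(axis=0)).ravel()
    qs = np.quantile(gene_means, [q / 100.0 for q in QUANTILE_GRID])
    return NormalizationMetrics(
        n_cells=ds.n_cells,
        library_size_mean=mean,
        library_size_median=float(np.median(totals)),
        library_size_cv=sd / mean,
        zero_fraction=1.0 - n_nonzero / total_entries,
        gene_mean_quantiles={q: float(v) for q, v in zip(QUANTILE_GRID, qs)},
    )


# ---------------------------------------------------------------------------
# derived layers (computed on demand when not supplied by the container)
# ---------------------------------------------------------------------------

def ensure_lognorm(ds: CellDataset) -> np.ndarray:
    if ds.lognorm is None:
        dense = ds.counts_dense().astype(float)
        totals = dense.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        ds.lognorm = np.log1p(dense / totals * LOGNORM_TARGET_SUM)
        ds.provenance.setdefault("derived", []).append("lognorm")
    return ds.lognorm


def ensure_hvg(ds: CellDataset, n_top: int = DEFAULT_N_HVG) -> np.ndarray:
    """Flag the top-n genes by dispersion (variance/mean of lognorm)."""
    if ds.hvg_flags is None:
        logn = ensure_lognorm(ds)
        disp = _gene_dispersion(logn)
        n_top = min(n_top, ds.n_genes)
        order = np.argsort(-disp, kind="stable")
        flags = np.zeros(ds.n_genes, dtype=bool)
        flags[order[:n_top]] = True
        ds.hvg_flags = flags
        ds.provenance.setdefault("derived", []).append("hvg_flags")
    return ds.hvg_flags


def ensure_pca(ds: CellDataset, n_pcs: int = DEFAULT_N_PCS) -> np.ndarray:
    if ds.pc_embedding is None or ds.pc_embedding.shape[1] < min(
        n_pcs, ds.n_cells - 1
    ):
        logn = ensure_lognorm(ds)
        n_comp = min(n_pcs, ds.n_cells - 1, ds.n_genes)
        pca = PCA(n_components=n_comp, svd_solver="full")
        ds.pc_embedding = pca.fit_transform(logn)
        ds.pc_variance = pca.explained_variance_
        ds.pc_loadings = pca.components_.T  # genes x PCs
        ds.provenance.setdefault("derived", []).append(f"pca:{n_comp}")
    return ds.pc_embedding


def _gene_dispersion(matrix: np.ndarray) -> np.ndarray:
    means = matrix.mean(axis=0)
    if matrix.shape[0] > 1:
        variances = matrix.var(axis=0, ddof=1)
    else:
        variances = np.zeros(matrix.shape[1])
    disp = np.zeros_like(means)
    nz = means > 0
    disp[nz] = variances[nz] / means[nz]
    return disp


# ---------------------------------------------------------------------------
# PCA metrics
# ---------------------------------------------------------------------------

def variance_explained(ds: CellDataset) -> PCVarianceProfile:
    if ds.pc_variance is None:
        if ds.pc_embedding is not None:
            ds.pc_variance = np.var(ds.pc_embedding, axis=0, ddof=1)
        else:
            ensure_pca(ds)
    var = np.asarray(ds.pc_variance, dtype=float)
    if var.size == 0:
        raise MetricError("no principal components available")
    fractions = var / var.sum()
    return PCVarianceProfile(fractions=fractions, cumulative=np.cumsum(fractions))


def top_pc_genes(ds: CellDataset, n_pcs: int, n_genes: int) -> PCGeneTable:
    """Per PC, the ``n_genes`` highest- and lowest-loading genes.

    Ties in loading are broken by gene-name lexicographic order.
    """
    if ds.pc_loadings is None:
        ensure_pca(ds, n_pcs)
    loadings = np.asarray(ds.pc_loadings, dtype=float)
    if n_pcs > loadings.shape[1]:
        raise MetricError(
            f"requested {n_pcs} PCs but only {loadings.shape[1]} stored"
        )
    if n_genes > ds.n_genes:
        raise MetricError(
            f"requested {n_genes} genes per list but only {ds.n_genes} genes"
        )
    table: dict[int, tuple[list, list]] = {}
    for pc in range(n_pcs):
        pairs = list(zip(ds.gene_names, loadings[:, pc]))
        pos = sorted(pairs, key=lambda p: (-p[1], p[0]))[:n_genes]
        neg = sorted(pairs, key=lambda p: (p[1], p[0]))[:n_genes]
        table[pc + 1] = (
            [(g, float(v)) for g, v in pos],
            [(g, float(v)) for g, v in neg],
        )
    return PCGeneTable(per_pc=table)


# ---------------------------------------------------------------------------
# clustering metrics
# ---------------------------------------------------------------------------

def expression_variability(ds: CellDataset) -> float:
    """Mean HVG dispersion (sample variance / mean on log-normalized data).

    Genes with zero mean contribute 0.  Invariant to gene and cell order.
    """
    logn = ensure_lognorm(ds)
    flags = ensure_hvg(ds)
    if not flags.any():
        raise MetricError("no highly variable genes flagged")
    disp = _gene_dispersion(np.asarray(logn)[:, flags])
    return float(disp.mean())


def median_neighbor_distance(
    ds: CellDataset, k: int = DEFAULT_K, n_pcs: int = DEFAULT_N_PCS
) -> float:
    """Median over all cells x k of Euclidean k-NN distances in PC space.

    Self-neighbors are excluded; exact brute-force under 5,000 cells,
    tree-based above.
    """
    if k >= ds.n_cells:
        raise MetricError(f"k={k} must be < n_cells={ds.n_cells}")
    if k < 1:
        raise MetricError("k must be >= 1")
    emb = ensure_pca(ds, n_pcs)
    emb = np.asarray(emb, dtype=float)[:, : min(n_pcs, emb.shape[1])]
    algorithm = "brute" if ds.n_cells < 5000 else "auto"
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm=algorithm)
    nn.fit(emb)
    dists, _ = nn.kneighbors(emb)
    return float(np.median(dists[:, 1:]))


def clustering_metrics(
    ds: CellDataset, k: int = DEFAULT_K, n_pcs: int = DEFAULT_N_PCS
) -> ClusteringMetrics:
    ensure_pca(ds, n_pcs)
    return ClusteringMetrics(
        n_cells=ds.n_cells,
        n_pcs_used=min(n_pcs, ds.pc_embedding.shape[1]),
        n_hvg=int(ensure_hvg(ds).sum()),
        k=k,
        mean_expression_variability=expression_variability(ds),
        median_neighbor_distance=median_neighbor_distance(ds, k=k, n_pcs=n_pcs),
    )


# ---------------------------------------------------------------------------
# marker tables
# ---------------------------------------------------------------------------

MARKER_COLUMNS = ("cluster", "gene", "avg_log2FC", "p_val_adj")


def top_markers(
    marker_table: pd.DataFrame, n: int, max_padj: float = 0.05
) -> ClusterMarkerBundle:
    """Per cluster, top-n genes by descending effect size at adjusted p
    below ``max_padj``.  Ties broken by gene-name lexicographic order."""
    if n < 1:
        raise MetricError("n must be >= 1")
    missing = [c for c in MARKER_COLUMNS if c not in marker_table.columns]
    if missing:
        raise MetricError(f"marker table missing columns: {missing}")
    bundle = ClusterMarkerBundle()
    for cluster, grp in marker_table.groupby(
        marker_table["cluster"].astype(str), sort=True
    ):
        sig = grp[grp["p_val_adj"] < max_padj]
        if sig.empty:
            warnings.warn(
                f"cluster {cluster}: no markers below adjusted p {max_padj}",
                stacklevel=2,
            )
            bundle.per_cluster[cluster] = []
            continue
        ranked = sig.sort_values(
            ["avg_log2FC", "gene"], ascending=[False, True], kind="stable"
        ).head(n)
        bundle.per_cluster[cluster] = [
            (str(r.gene), float(r.avg_log2FC), float(r.p_val_adj))
            for r in ranked.itertuples()
        ]
    return bundle


def read_marker_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table = pd.read_csv(path, sep=sep)
    missing = [c for c in MARKER_COLUMNS if c not in table.columns]
    if missing:
        raise MetricError(f"marker table {path}: missing columns {missing}")
    return table


def marker_table_from_dataset(ds: CellDataset) -> pd.DataFrame | None:
    """Hook for datasets that already carry a marker table in provenance."""
    tbl = ds.provenance.get("marker_table")
    if isinstance(tbl, pd.DataFrame):
        return tbl
    return None
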