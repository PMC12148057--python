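import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scadvisor._errors import MetricError
from scadvisor.dataio import CellDataset
from scadvisor import metrics as M


def _ds_with_meta(values, name="metric"):
    counts = np.ones((len(values), 2), dtype=int)
    ds = CellDataset.from_counts(counts, ["a", "b"])
    ds.cell_meta[name] = values
    return ds


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def quantile_oracle(values, prob):
    """Sort-and-interpolate quantile, written independently of numpy."""
    xs = sorted(values)
    n = len(xs)
    h = (n - 1) * prob
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def knn_median_oracle(points, k):
    """Full pairwise-distance brute force."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    dists = []
    for i in range(n):
        d = sorted(
            np.linalg.norm(pts[i] - pts[j]) for j in range(n) if j != i
        )
        dists.extend(d[:k])
    return float(np.median(dists))


# ---------------------------------------------------------------------------
# summarize_qc
# ---------------------------------------------------------------------------

def test_summary_basic():
    ds = _ds_with_meta([1, 2, 3, 4, 5])
    b = M.summarize_qc(ds, ["metric"])
    s = b.metrics["metric"]
    assert (s.mean, s.median, s.min, s.max) == (3, 3, 1, 5)
    assert b.n_cells == 5


def test_summary_quantile_linear_interpolation():
    ds = _ds_with_meta([1, 2, 3, 4, 5])
    s = M.summarize_qc(ds, ["metric"]).metrics["metric"]
    assert s.quantiles[25] == pytest.approx(2.0, abs=1e-12)
    assert s.quantiles[25] == pytest.approx(
        quantile_oracle([1, 2, 3, 4, 5], 0.25), abs=1e-12
    )


def test_summary_constant_column():
    ds = _ds_with_meta([7, 7, 7])
    s = M.summarize_qc(ds, ["metric"]).metrics["metric"]
    assert s.sd == 0.0
    assert all(v == 7 for v in s.quantiles.values())


def test_summary_unknown_metric():
    ds = _ds_with_meta([1, 2])
    with pytest.raises(MetricError, match="unknown"):
        M.summarize_qc(ds, ["nope"])


def test_quantiles_match_oracle_on_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(100):
        values = rng.normal(size=rng.integers(5, 40)) * 100
        ds = _ds_with_meta(values)
        s = M.summarize_qc(ds, ["metric"]).metrics["metric"]
        for q, v in s.quantiles.items():
            assert v == pytest.approx(quantile_oracle(values, q / 100), abs=1e-9)


def test_quantile_bundle_invariants(synth_ds):
    b = M.summarize_qc(synth_ds, ["total_counts"])
    s = b.metrics["total_counts"]
    qs = [s.quantiles[q] for q in sorted(s.quantiles)]
    assert all(s.min <= v <= s.max for v in qs)
    assert qs == sorted(qs)


# ---------------------------------------------------------------------------
# library_size_stats
# ---------------------------------------------------------------------------

def test_cv_zero_for_equal_totals():
    counts = np.array([[5, 5], [5, 5], [5, 5]])
    ds = CellDataset.from_counts(counts, ["a", "b"])
    assert M.library_size_stats(ds).library_size_cv == 0.0


def test_cv_hand_computed():
    # totals [10, 20, 30]: sample sd 10, mean 20 -> CV 0.5
    counts = np.array([[10, 0], [20, 0], [30, 0]])
    ds = CellDataset.from_counts(counts, ["a", "b"])
    assert M.library_size_stats(ds).library_size_cv == pytest.approx(0.5, abs=1e-12)


def test_zero_fraction():
    counts = np.array([[1, 0, 0, 0], [0, 2, 0, 3], [4, 0, 5, 6]])
    ds = CellDataset.from_counts(counts, ["a", "b", "c", "d"])
    assert M.library_size_stats(ds).zero_fraction == pytest.approx(0.5)


def test_all_zero_matrix_errors():
    ds = CellDataset.from_counts(np.zeros((3, 2), dtype=int), ["a", "b"])
    with pytest.raises(MetricError, match="nothing to normalize"):
        M.library_size_stats(ds)


# ---------------------------------------------------------------------------
# variance_explained
# ---------------------------------------------------------------------------

def _ds_with_pc_variance(var):
    ds = CellDataset.from_counts(np.ones((3, 2), dtype=int), ["a", "b"])
    ds.pc_variance = np.asarray(var, dtype=float)
    return ds


def test_variance_fractions():
    p = M.variance_explained(_ds_with_pc_variance([4, 3, 2, 1]))
    assert np.allclose(p.fractions, [0.4, 0.3, 0.2, 0.1])
    assert np.allclose(p.cumulative, [0.4, 0.7, 0.9, 1.0])


def test_variance_single_pc():
    p = M.variance_explained(_ds_with_pc_variance([2.5]))
    assert np.allclose(p.fractions, [1.0])


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0.01, 100), min_size=1, max_size=20))
def test_variance_fractions_sum_to_one(var):
    p = M.variance_explained(_ds_with_pc_variance(var))
    assert p.fractions.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(p.cumulative) >= -1e-12)
    assert p.cumulative[-1] <= 1 + 1e-9


# ---------------------------------------------------------------------------
# top_pc_genes
# ---------------------------------------------------------------------------

def _ds_with_loadings(genes, loadings):
    ds = CellDataset.from_counts(
        np.ones((3, len(genes)), dtype=int), genes
    )
    ds.pc_loadings = np.asarray(loadings, dtype=float)
    return ds


def test_top_pc_genes_basic():
    ds = _ds_with_loadings(["A", "B", "C"], [[0.9], [-0.8], [0.1]])
    t = M.top_pc_genes(ds, 1, 1)
    pos, neg = t.per_pc[1]
    assert pos == [("A", 0.9)]
    assert neg == [("B", -0.8)]


def test_top_pc_genes_tie_lexicographic():
    ds = _ds_with_loadings(["B", "A", "C"], [[0.5], [0.5], [-1.0]])
    pos, _ = M.top_pc_genes(ds, 1, 2).per_pc[1]
    assert [g for g, _ in pos] == ["A", "B"]


def test_top_pc_genes_all_genes_once():
    ds = _ds_with_loadings(["A", "B", "C"], [[0.9], [-0.8], [0.1]])
    pos, neg = M.top_pc_genes(ds, 1, 3).per_pc[1]
    assert sorted(g for g, _ in pos) == ["A", "B", "C"]
    assert sorted(g for g, _ in neg) == ["A", "B", "C"]


def test_top_pc_genes_too_many():
    ds = _ds_with_loadings(["A", "B"], [[0.9], [-0.8]])
    with pytest.raises(MetricError):
        M.top_pc_genes(ds, 1, 3)


# ---------------------------------------------------------------------------
# expression_variability
# ---------------------------------------------------------------------------

def _ds_with_lognorm(logn, hvg=None):
    logn = np.asarray(logn, dtype=float)
    ds = CellDataset.from_counts(
        np.ones(logn.shape, dtype=int), [f"g{i}" for i in range(logn.shape[1])]
    )
    ds.lognorm = logn
    ds.hvg_flags = (
        np.ones(logn.shape[1], dtype=bool) if hvg is None else np.asarray(hvg)
    )
    return ds


def test_expression_variability_stated_definition():
    # gene A [0,2]: var 2 / mean 1 -> 2; gene B [1,1] -> 0; mean -> 1.0
    ds = _ds_with_lognorm([[0, 1], [2, 1]])
    assert M.expression_variability(ds) == pytest.approx(1.0, abs=1e-12)


def test_expression_variability_constant():
    ds = _ds_with_lognorm([[3, 3], [3, 3]])
    assert M.expression_variability(ds) == 0.0


def test_expression_variability_no_hvg():
    ds = _ds_with_lognorm([[0, 1], [2, 1]], hvg=[False, False])
    with pytest.raises(MetricError, match="variable"):
        M.expression_variability(ds)


def test_expression_variability_matches_loop_oracle(synth_ds):
    logn = M.ensure_lognorm(synth_ds)
    flags = M.ensure_hvg(synth_ds)
    per_gene = []
    for j in np.flatnonzero(flags):
        col = logn[:, j]
        m = col.mean()
        per_gene.append(col.var(ddof=1) / m if m > 0 else 0.0)
    assert M.expression_variability(synth_ds) == pytest.approx(
        np.mean(per_gene), abs=1e-12
    )


def test_expression_variability_order_invariant(synth_ds):
    base = M.expression_variability(synth_ds)
    rng = np.random.default_rng(3)
    gene_order = rng.permutation(synth_ds.n_genes)
    cell_order = rng.permutation(synth_ds.n_cells)
    shuffled = CellDataset.from_counts(
        synth_ds.counts_dense()[np.ix_(cell_order, gene_order)],
        [synth_ds.gene_names[i] for i in gene_order],
    )
    shuffled.lognorm = np.asarray(synth_ds.lognorm)[np.ix_(cell_order, gene_order)]
    shuffled.hvg_flags = np.asarray(synth_ds.hvg_flags)[gene_order]
    assert M.expression_variability(shuffled) == pytest.approx(base, abs=1e-12)


# ---------------------------------------------------------------------------
# median_neighbor_distance
# ---------------------------------------------------------------------------

def _ds_with_embedding(points):
    pts = np.asarray(points, dtype=float)
    ds = CellDataset.from_counts(
        np.ones((pts.shape[0], 2), dtype=int), ["a", "b"]
    )
    ds.pc_embedding = pts
    ds.pc_variance = np.var(pts, axis=0, ddof=1)
    return ds


def test_knn_median_1d_k1():
    ds = _ds_with_embedding([[0.0], [1.0], [3.0]])
    assert M.median_neighbor_distance(ds, k=1, n_pcs=1) == 1.0


def test_knn_median_1d_k2():
    ds = _ds_with_embedding([[0.0], [1.0], [3.0]])
    assert M.median_neighbor_distance(ds, k=2, n_pcs=1) == 2.0


def test_knn_median_k_too_large():
    ds = _ds_with_embedding([[0.0], [1.0]])
    with pytest.raises(MetricError, match="k="):
        M.median_neighbor_distance(ds, k=2, n_pcs=1)


def test_knn_median_matches_bruteforce_oracle():
    rng = np.random.default_rng(11)
    pts = rng.normal(size=(50, 5))
    ds = _ds_with_embedding(pts)
    for k in (1, 3, 10):
        assert M.median_neighbor_distance(ds, k=k, n_pcs=5) == pytest.approx(
            knn_median_oracle(pts, k), abs=1e-12
        )


def test_knn_median_oracle_on_synth(synth_ds):
    emb = M.ensure_pca(synth_ds, 10)
    expected = knn_median_oracle(np.asarray(emb)[:, :10], 20)
    assert M.median_neighbor_distance(synth_ds, k=20, n_pcs=10) == pytest.approx(
        expected, abs=1e-9
    )


# ---------------------------------------------------------------------------
# top_markers
# ---------------------------------------------------------------------------

def test_top_markers_basic(marker_frame):
    b = M.top_markers(marker_frame, 2)
    assert [g for g, _, _ in b.per_cluster["0"]] == ["A", "B"]
    assert [g for g, _, _ in b.per_cluster["1"]] == ["D", "E"]


def test_top_markers_padj_filter(marker_frame):
    b = M.top_markers(marker_frame, 5, max_padj=5e-5)
    assert [g for g, _, _ in b.per_cluster["0"]] == ["A"]


def test_top_markers_all_filtered_warns(marker_frame):
    with pytest.warns(UserWarning, match="no markers"):
        b = M.top_markers(marker_frame, 2, max_padj=1e-12)
    assert b.per_cluster["0"] == []


def test_top_markers_tie_break():
    table = pd.DataFrame(
        {
            "cluster": ["0", "0"],
            "gene": ["Z", "A"],
            "avg_log2FC": [1.0, 1.0],
            "p_val_adj": [0.01, 0.01],
        }
    )
    b = M.top_markers(table, 1)
    assert b.per_cluster["0"][0][0] == "A"


def test_top_markers_missing_column(marker_frame):
    with pytest.raises(MetricError, match="missing"):
        M.top_markers(marker_frame.drop(columns=["gene"]), 2)


# ---------------------------------------------------------------------------
# purity
# ---------------------------------------------------------------------------

def test_metrics_pure(synth_ds):
    a = M.clustering_metrics(synth_ds, k=10, n_pcs=5)
    b = M.clustering_metrics(synth_ds, k=10, n_pcs=5)
    assert a == b
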