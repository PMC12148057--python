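"""Read/write the standard formats the advisor touches and hold the
single-cell dataset container shared by every stage.

The container keeps counts cells-by-genes (10x MTX files store genes as
rows and are transposed on load).  Cluster labels are stored as strings to
match marker-table conventions.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._errors import DataError

__all__ = [
    "CellDataset",
    "GeneSetCollection",
    "RecommendationRecord",
    "load_counts",
    "write_counts",
    "read_gene_sets",
    "write_record",
    "read_record",
    "attach_labels",
]

CLUSTER_COLUMN = "cluster"
CELL_TYPE_COLUMN = "cell_type"


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------

@dataclass
class CellDataset:
    """Counts plus per-cell metadata and optional derived layers.

    ``counts`` is cells x genes, non-negative integral (dense ndarray or
    scipy sparse).  ``cell_meta`` always carries ``total_counts`` and
    ``n_genes_detected``; percent-feature columns (``percent_*``) live on a
    0..100 scale.  Derived layers are filled lazily by :mod:`.metrics`.
    """

    counts: Any
    gene_names: list[str]
    cell_meta: pd.DataFrame
    lognorm: Any | None = None
    hvg_flags: np.ndarray | None = None
    pc_embedding: np.ndarray | None = None
    pc_variance: np.ndarray | None = None
    pc_loadings: np.ndarray | None = None
    neighbor_distances: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_counts(
        cls,
        counts: Any,
        gene_names: list[str],
        cell_meta: pd.DataFrame | None = None,
    ) -> "CellDataset":
        """Build a dataset, computing total_counts / n_genes_detected."""
        counts = _as_matrix(counts)
        n_cells = counts.shape[0]
        if cell_meta is None:
            cell_meta = pd.DataFrame(index=pd.RangeIndex(n_cells).astype(str))
        else:
            cell_meta = cell_meta.copy()
        cell_meta["total_counts"] = np.asarray(
            counts.sum(axis=1)
        ).ravel().astype(np.int64)
        cell_meta["n_genes_detected"] = np.asarray(
            (counts > 0).sum(axis=1)
        ).ravel().astype(np.int64)
        ds = cls(counts=counts, gene_names=list(gene_names), cell_meta=cell_meta)
        ds.validate()
        return ds

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        counts = self.counts
        n_cells, n_genes = counts.shape
        if len(self.gene_names) != n_genes:
            raise DataError(
                f"gene_names length {len(self.gene_names)} != {n_genes} columns"
            )
        dupes = _duplicates(self.gene_names)
        if dupes:
            raise DataError(f"duplicated gene names: {sorted(dupes)}")
        if len(self.cell_meta) != n_cells:
            raise DataError(
                f"cell_meta has {len(self.cell_meta)} rows for {n_cells} cells"
            )
        data = counts.data if sp.issparse(counts) else np.asarray(counts)
        if data.size and (data < 0).any():
            raise DataError("negative entries in counts")
        if data.size and not np.allclose(data, np.round(data)):
            raise DataError("non-integer entries in counts")
        stored_tc = self.cell_meta["total_counts"].to_numpy()
        stored_ng = self.cell_meta["n_genes_detected"].to_numpy()
        recomputed_tc = np.asarray(counts.sum(axis=1)).ravel()
        recomputed_ng = np.asarray((counts > 0).sum(axis=1)).ravel()
        if not np.array_equal(stored_tc, recomputed_tc):
            raise DataError("stored total_counts disagree with counts")
        if not np.array_equal(stored_ng, recomputed_ng):
            raise DataError("stored n_genes_detected disagree with counts")
        for col in self.cell_meta.columns:
            if col.startswith("percent_"):
                vals = self.cell_meta[col].to_numpy(dtype=float)
                if ((vals < 0) | (vals > 100)).any():
                    raise DataError(f"{col} outside [0, 100]")

    # -- convenience --------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cluster_labels(self) -> pd.Series | None:
        if CLUSTER_COLUMN not in self.cell_meta.columns:
            return None
        return self.cell_meta[CLUSTER_COLUMN].astype(str)

    def counts_dense(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return np.asarray(self.counts)

    def copy(self) -> "CellDataset":
        return dataclasses.replace(
            self,
            counts=self.counts.copy(),
            cell_meta=self.cell_meta.copy(),
            provenance=dict(self.provenance),
        )


def _as_matrix(counts: Any) -> Any:
    if sp.issparse(counts):
        return counts.tocsr()
    arr = np.asarray(counts)
    if arr.ndim != 2:
        raise DataError(f"counts must be 2-D, got shape {arr.shape}")
    return arr


def _duplicates(names: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for n in names:
        if n in seen:
            dup.add(n)
        seen.add(n)
    return dup


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-set descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise DataError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>members...``.

    Members duplicated within a line are deduplicated; duplicate set names
    are an error; an empty file yields an empty (but valid) collection with
    a warning.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{path.name}:{lineno}: GMT line needs >= 3 tab-separated "
                    f"fields (name, description, members), got {len(fields)}"
                )
            name, desc, *members = fields
            if name in sets:
                raise DataError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            members = {m for m in members if m}
            if not members:
                raise DataError(f"{path.name}:{lineno}: set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    if not sets:
        warnings.warn(f"{path} contained no gene sets", stacklevel=2)
    return GeneSetCollection(sets=sets, descriptions=descriptions)


# ---------------------------------------------------------------------------
# counts I/O
# ---------------------------------------------------------------------------

def load_counts(path: str | Path, format: str | None = None,
                allow_float: bool = False) -> CellDataset:
    """Load a count matrix from an MTX triplet directory, H5AD, or CSV.

    ``format`` is one of ``{"mtx_dir", "h5ad", "csv"}``; when omitted it is
    inferred from the path.  Non-integer matrices are rejected unless
    ``allow_float`` is set (then rounded with a warning).
    """
    path = Path(path)
    if format is None:
        format = _infer_format(path)
    if format == "mtx_dir":
        return _load_mtx_dir(path, allow_float)
    if format == "h5ad":
        return _load_h5ad(path, allow_float)
    if format == "csv":
        return _load_csv(path, allow_float)
    raise DataError(
        f"unknown counts format {format!r}; expected mtx_dir, h5ad or csv"
    )


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "mtx_dir"
    if path.suffix == ".h5ad":
        return "h5ad"
    if path.suffix in {".csv", ".tsv"}:
        return "csv"
    raise DataError(f"cannot infer counts format from {path}")


def _load_mtx_dir(path: Path, allow_float: bool) -> CellDataset:
    matrix_file = path / "matrix.mtx"
    if not matrix_file.exists():
        raise DataError(f"missing {matrix_file}")
    features = path / "features.tsv"
    if not features.exists():
        features = path / "genes.tsv"
    if not features.exists():
        raise DataError(f"missing features.tsv/genes.tsv in {path}")
    barcodes = path / "barcodes.tsv"
    if not barcodes.exists():
        raise DataError(f"missing {barcodes}")
    mat = scipy.io.mmread(matrix_file).tocsr().T.tocsr()  # disk: genes x cells
    feat = pd.read_csv(features, sep="\t", header=None)
    gene_names = feat.iloc[:, 0].astype(str).tolist()
    codes = pd.read_csv(barcodes, sep="\t", header=None).iloc[:, 0].astype(str)
    mat = _coerce_integer(mat, allow_float, source=str(matrix_file))
    meta = pd.DataFrame(index=codes.tolist())
    ds = CellDataset.from_counts(mat, gene_names, meta)
    ds.provenance["source"] = str(path)
    _maybe_read_labels(path, ds)
    return ds


def _maybe_read_labels(path: Path, ds: CellDataset) -> None:
    labels = path / "labels.tsv"
    if labels.exists():
        tbl = pd.read_csv(labels, sep="\t")
        if CLUSTER_COLUMN in tbl.columns and len(tbl) == ds.n_cells:
            ds.cell_meta[CLUSTER_COLUMN] = tbl[CLUSTER_COLUMN].astype(str).to_numpy()


def _load_h5ad(path: Path, allow_float: bool, layer: str | None = None) -> CellDataset:
    import anndata

    adata = anndata.read_h5ad(path)
    mat = adata.layers[layer] if layer else adata.X
    if sp.issparse(mat):
        mat = mat.tocsr()
    else:
        mat = np.asarray(mat)
    mat = _coerce_integer(mat, allow_float, source=str(path))
    meta = adata.obs.copy()
    meta.index = meta.index.astype(str)
    ds = CellDataset.from_counts(mat, adata.var_names.astype(str).tolist(), meta)
    ds.provenance["source"] = str(path)
    return ds


def _load_csv(path: Path, allow_float: bool) -> CellDataset:
    sep = "\t" if path.suffix == ".tsv" else ","
    table = pd.read_csv(path, sep=sep, index_col=0)
    values = table.to_numpy()
    if not allow_float:
        bad = np.argwhere(values != np.floor(values))
        if bad.size:
            r, c = bad[0]
            raise DataError(
                f"non-integer count {values[r, c]!r} at row {table.index[r]!r}, "
                f"column {table.columns[c]!r} in {path}"
            )
    mat = _coerce_integer(values, allow_float, source=str(path))
    meta = pd.DataFrame(index=table.index.astype(str))
    return CellDataset.from_counts(mat, [str(c) for c in table.columns], meta)


def _coerce_integer(mat: Any, allow_float: bool, source: str) -> Any:
    data = mat.data if sp.issparse(mat) else np.asarray(mat)
    if data.size and not np.allclose(data, np.round(data)):
        if not allow_float:
            raise DataError(
                f"{source}: matrix has non-integer entries; pass allow_float "
                "to round them"
            )
        warnings.warn(f"{source}: rounding non-integer counts", stacklevel=3)
        if sp.issparse(mat):
            mat = mat.copy()
            mat.data = np.round(mat.data)
        else:
            mat = np.round(data)
    if sp.issparse(mat):
        mat = mat.astype(np.int64)
    else:
        mat = np.asarray(mat).astype(np.int64)
    return mat


def write_counts(ds: CellDataset, out_dir: str | Path) -> Path:
    """Write an MTX triplet (genes x cells on disk) plus a labels TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mat = ds.counts
    if not sp.issparse(mat):
        mat = sp.csr_matrix(mat)
    scipy.io.mmwrite(out_dir / "matrix.mtx", mat.T.tocoo(), field="integer")
    with open(out_dir / "features.tsv", "w", encoding="utf-8") as fh:
        for g in ds.gene_names:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(out_dir / "barcodes.tsv", "w", encoding="utf-8") as fh:
        for b in ds.cell_meta.index:
            fh.write(f"{b}\n")
    if ds.cluster_labels is not None:
        ds.cell_meta[[CLUSTER_COLUMN]].astype(str).to_csv(
            out_dir / "labels.tsv", sep="\t", index=False
        )
    return out_dir


# ---------------------------------------------------------------------------
# recommendation records
# ---------------------------------------------------------------------------

@dataclass
class RecommendationRecord:
    """One advisor run: prompt, raw response, parsed payload, provenance."""

    task_id: str
    rendered_prompt: str
    raw_response: str
    parsed_payload: Any = None
    model_id: str = ""
    backend_name: str = ""
    timestamp: str = ""
    parse_error: str | None = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        payload = self.parsed_payload
        if dataclasses.is_dataclass(payload) and not isinstance(payload, type):
            payload = dataclasses.asdict(payload)
        return {
            "task_id": self.task_id,
            "rendered_prompt": self.rendered_prompt,
            "raw_response": self.raw_response,
            "parsed_payload": payload,
            "model_id": self.model_id,
            "backend_name": self.backend_name,
            "timestamp": self.timestamp,
            "parse_error": self.parse_error,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RecommendationRecord":
        required = {"task_id", "rendered_prompt", "raw_response"}
        missing = required - set(d)
        if missing:
            raise DataError(f"record missing fields: {sorted(missing)}")
        return cls(
            task_id=d["task_id"],
            rendered_prompt=d["rendered_prompt"],
            raw_response=d["raw_response"],
            parsed_payload=d.get("parsed_payload"),
            model_id=d.get("model_id", ""),
            backend_name=d.get("backend_name", ""),
            timestamp=d.get("timestamp", ""),
            parse_error=d.get("parse_error"),
            provenance=dict(d.get("provenance", {})),
        )


def write_record(record: RecommendationRecord, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(record.to_dict(), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_record(path: str | Path) -> RecommendationRecord:
    try:
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise DataError(f"{path}: truncated or invalid record file: {exc}") from exc
    if not isinstance(payload, dict):
        raise DataError(f"{path}: record file must hold a JSON object")
    return RecommendationRecord.from_dict(payload)


# ---------------------------------------------------------------------------
# label attachment
# ---------------------------------------------------------------------------

def attach_labels(
    ds: CellDataset,
    column: str,
    mapping: Mapping[str, str],
    overwrite: bool = False,
) -> CellDataset:
    """Return a copy of ``ds`` with a per-cell column mapped from clusters.

    The mapping must cover every observed cluster; an existing column is
    only replaced when ``overwrite`` is set.
    """
    clusters = ds.cluster_labels
    if clusters is None:
        raise DataError("dataset has no cluster labels to map from")
    mapping = {str(k): v for k, v in mapping.items()}
    observed = set(clusters.unique())
    missing = sorted(observed - set(mapping))
    if missing:
        raise DataError(f"mapping missing clusters, missing: {', '.join(missing)}")
    if column in ds.cell_meta.columns and not overwrite:
        raise DataError(
            f"column {column!r} already exists; pass overwrite to replace it"
        )
    out = ds.copy()
    out.cell_meta[column] = clusters.map(mapping).to_numpy()
    return out
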