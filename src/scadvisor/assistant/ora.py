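"""Native over-representation analysis: one-sided hypergeometric tail per
gene set plus Benjamini-Hochberg adjustment over all tested sets.

Gene identifiers are matched case-insensitively (mixed human/mouse symbol
conventions); the reported overlap genes keep the query's original casing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .._errors import DataError
from ..dataio import GeneSetCollection

ORA_COLUMNS = (
    "set_name",
    "overlap_k",
    "set_size_K",
    "query_size_n",
    "universe_size_N",
    "p_value",
    "q_value",
    "overlap_genes",
)


@dataclass
class EnrichmentTable:
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ORA_COLUMNS if c not in self.rows.columns]
        if missing:
            raise DataError(f"enrichment table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.rows)

    def to_tsv(self, path) -> None:
        out = self.rows.copy()
        out["overlap_genes"] = out["overlap_genes"].map(",".join)
        out.to_csv(path, sep="\t", index=False)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjustment: q_i = min over j>=i of p_(j) * m / j."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    q = np.empty_like(adjusted)
    q[order] = adjusted
    return q


def run_ora(
    query_genes: Iterable[str],
    universe_genes: Iterable[str],
    sets: GeneSetCollection,
    max_q: float = 0.05,
) -> EnrichmentTable:
    """Hypergeometric ORA of a query list against named sets in a universe.

    Per set, ``p = P[X >= k]`` under Hypergeometric(N, K, n); BH q over all
    tested sets; rows with ``q <= max_q`` retained, sorted by (q, p).
    Query genes outside the universe are dropped with a warning; sets are
    intersected with the universe and empty intersections skipped.
    """
    universe = {}
    for g in universe_genes:
        universe.setdefault(str(g).casefold(), str(g))
    n_universe = len(universe)
    if n_universe == 0:
        raise DataError("empty gene universe")

    query = {}
    dropped = []
    for g in query_genes:
        key = str(g).casefold()
        if key in universe:
            query.setdefault(key, str(g))
        else:
            dropped.append(str(g))
    if dropped:
        warnings.warn(
            f"{len(dropped)} query genes outside the universe dropped: "
            f"{sorted(dropped)[:10]}",
            stacklevel=2,
        )
    if not query:
        raise DataError("no query genes remain after universe filtering")
    n_query = len(query)

    records = []
    for name in sets:
        members = {str(g).casefold() for g in sets[name]}
        members &= universe.keys()
        if not members:
            continue
        overlap_keys = sorted(members & query.keys())
        k = len(overlap_keys)
        K = len(members)
        # P[X >= k]; sf(k-1) is the exact upper tail
        p = float(hypergeom.sf(k - 1, n_universe, K, n_query))
        records.append(
            {
                "set_name": name,
                "overlap_k": k,
                "set_size_K": K,
                "query_size_n": n_query,
                "universe_size_N": n_universe,
                "p_value": min(p, 1.0),
                "overlap_genes": [query[key] for key in overlap_keys],
            }
        )
    if not records:
        table = pd.DataFrame(columns=list(ORA_COLUMNS))
        return EnrichmentTable(rows=table)
    table = pd.DataFrame.from_records(records)
    table["q_value"] = benjamini_hochberg(table["p_value"].to_numpy())
    table = table[table["q_value"] <= max_q]
    table = table.sort_values(
        ["q_value", "p_value", "set_name"], kind="stable"
    ).reset_index(drop=True)
    return EnrichmentTable(rows=table[list(ORA_COLUMNS)])


def format_enrichment_block(table: EnrichmentTable, max_rows: int = 30) -> str:
    """Serialize significant rows for the enrichment prompt; an empty table
    states so explicitly rather than seeding hallucination."""
    if len(table) == 0:
        return "No significant enrichment was found."
    lines = []
    for row in table.rows.head(max_rows).itertuples():
        genes = ", ".join(row.overlap_genes)
        lines.append(
            f"- {row.set_name} (q={row.q_value:.3g}, "
            f"{row.overlap_k}/{row.set_size_K} genes): {genes}"
        )
    return "\n".join(lines)
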