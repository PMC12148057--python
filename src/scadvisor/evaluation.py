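"""Evaluation statistics: groundedness of responses against ground-truth
term sets, and chunked-embedding semantic similarity.

The embedder is pluggable; :class:`BagOfWordsEmbedder` is a deterministic
stand-in so no model weights are needed offline.
"""

from __future__ import annotations

import hashlib
import math
import re
from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

import numpy as np

from ._errors import UserError
from .dataio import RecommendationRecord

__all__ = [
    "TokenSet",
    "GroundednessScore",
    "DocumentEmbedding",
    "BagOfWordsEmbedder",
    "tokenize_terms",
    "groundedness",
    "embed_document",
    "semantic_similarity",
    "ground_truth_from_records",
]

#: minimal stopword list; gene/pathway tokens are never this generic
STOPWORDS = frozenset(
    """a an and are as at be but by for from has have in into is it its of on
    or that the their then this to was were will with your you we our they
    not may can which these those there here also more most very such each
    based using between within per""".split()
)

_TOKEN_RE = re.compile(r"[0-9A-Za-z](?:[0-9A-Za-z_-]*[0-9A-Za-z])?")


TokenSet = set  # set of normalized term strings


@dataclass
class GroundednessScore:
    value: float
    intersection: int
    response_size: int


@dataclass
class DocumentEmbedding:
    vector: np.ndarray
    chunk_count: int
    pooling: str = "mean"


class Embedder(Protocol):
    dim: int

    def embed(self, tokens: Sequence[str]) -> np.ndarray: ...


def tokenize_terms(text: str) -> TokenSet:
    """Normalize text into a term set.

    Split on non-alphanumerics (hyphen/underscore kept inside tokens),
    case-fold, drop stopwords and tokens shorter than two characters.
    """
    out: TokenSet = set()
    for m in _TOKEN_RE.finditer(text or ""):
        token = m.group(0).casefold()
        if len(token) < 2 or token in STOPWORDS:
            continue
        out.add(token)
    return out


def groundedness(gt: TokenSet, resp: TokenSet) -> GroundednessScore:
    """G = |GT ∩ RESP| / |RESP| — an indirect hallucination measure."""
    if not resp:
        raise UserError("groundedness undefined for an empty response set")
    inter = len(gt & resp)
    return GroundednessScore(
        value=inter / len(resp), intersection=inter, response_size=len(resp)
    )


def ground_truth_from_records(
    records: Iterable[RecommendationRecord],
) -> TokenSet:
    """Assemble a ground-truth term set from a run's records: everything the
    advisor actually supplied to the model (prompts hold the metrics, gene
    lists and enrichment rows)."""
    gt: TokenSet = set()
    for rec in records:
        gt |= tokenize_terms(rec.rendered_prompt)
    return gt


class BagOfWordsEmbedder:
    """Deterministic hashed bag-of-words embedder (no weights, no network)."""

    def __init__(self, dim: int = 256):
        self.dim = dim

    def embed(self, tokens: Sequence[str]) -> np.ndarray:
        vec = np.zeros(self.dim, dtype=float)
        for token in tokens:
            digest = hashlib.sha1(token.casefold().encode("utf-8")).digest()
            vec[int.from_bytes(digest[:4], "big") % self.dim] += 1.0
        return vec


def _document_tokens(text: str) -> list[str]:
    return [m.group(0) for m in _TOKEN_RE.finditer(text)]


def embed_document(
    text: str, embedder: Embedder, chunk_limit: int = 512
) -> DocumentEmbedding:
    """Chunk, embed and mean-pool a document.

    ``chunk_limit`` counts the two boundary marker slots per chunk, so each
    chunk carries ``chunk_limit - 2`` content tokens and the chunk count is
    ``ceil(L / (chunk_limit - 2))``.
    """
    if chunk_limit < 3:
        raise UserError("chunk_limit must be >= 3 (two slots are markers)")
    tokens = _document_tokens(text)
    if not tokens:
        raise UserError("cannot embed an empty document")
    usable = chunk_limit - 2
    n_chunks = math.ceil(len(tokens) / usable)
    vectors = [
        np.asarray(embedder.embed(tokens[i * usable : (i + 1) * usable]),
                   dtype=float)
        for i in range(n_chunks)
    ]
    pooled = np.mean(vectors, axis=0)
    if not np.isfinite(pooled).all():
        raise UserError("embedding produced non-finite values")
    return DocumentEmbedding(vector=pooled, chunk_count=n_chunks)


def semantic_similarity(
    doc_a: str, doc_b: str, embedder: Embedder, chunk_limit: int = 512
) -> float:
    """Cosine similarity of the pooled chunk embeddings of two documents."""
    va = embed_document(doc_a, embedder, chunk_limit).vector
    vb = embed_document(doc_b, embedder, chunk_limit).vector
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise UserError("zero-norm embedding; cannot compute cosine")
    return float(np.dot(va, vb) / (na * nb))
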