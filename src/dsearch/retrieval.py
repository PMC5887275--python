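"""Fielded BM25 scoring with field weights and query-term boosting.

A document's score for a weighted query is

    score(d, q) = sum_t w(t) * sum_f lambda_f * BM25(t, d, f)

where ``w(t)`` is the query-term boost (1.0 for ordinary terms, higher
for detected keywords, fractional for expansion terms), ``lambda_f``
the field weight for TITLE/TEXT/METADATA, and BM25 the per-field
Okapi score with the smoothed non-negative idf

    idf(t, f) = ln(1 + (N - df + 0.5) / (df + 0.5)).

The cross-field combination is a weighted sum of per-field BM25 scores
(each field keeps its own length statistics), matching per-field
indexing; the shipped default weights and k1/b are the tuned values
for biomedical dataset descriptions (TITLE 0.1, TEXT 0.3, METADATA 0.5,
k1 = 1.8, b = 0.7).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

from .index_core import FIELDS, FieldedIndex, EmptyIndexError

#: Provenance labels for query terms.
ORIGINS = ("original", "wig_boosted", "brf", "external")


@dataclass
class RetrievalConfig:
    """BM25 and field-combination parameters.

    Defaults are the tuned best values for the dataset-description
    retrieval task (grid ranges: weights {0.1,0.3,0.5,0.7}, k1
    {0.6,1,1.4,1.8}, b {0.3,0.5,0.7,0.9}).
    """

    k1: float = 1.8
    b: float = 0.7
    field_weights: dict[str, float] = dc_field(
        default_factory=lambda: {"title": 0.1, "text": 0.3, "metadata": 0.5}
    )
    top_k: int = 100

    def __post_init__(self) -> None:
        if not self.k1 > 0:
            raise ValueError(f"k1 must be positive, got {self.k1}")
        if not 0 <= self.b <= 1:
            raise ValueError(f"b must be in [0, 1], got {self.b}")
        unknown = set(self.field_weights) - set(FIELDS)
        if unknown:
            raise ValueError(f"unknown fields in field_weights: {sorted(unknown)}")
        if any(w < 0 for w in self.field_weights.values()):
            raise ValueError("field weights must be non-negative")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass(frozen=True)
class QueryTerm:
    term: str
    weight: float
    origin: str = "original"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.weight) and self.weight >= 0):
            raise ValueError(f"term weight must be finite and >= 0, got {self.weight}")
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown term origin {self.origin!r}")


@dataclass
class WeightedQuery:
    """Query terms with boosts and origin provenance."""

    qid: str
    terms: list[QueryTerm]

    @classmethod
    def from_tokens(cls, qid: str, tokens: Sequence[str],
                    weight: float = 1.0) -> "WeightedQuery":
        """Uniformly-weighted query over unique tokens (first-seen order)."""
        seen: dict[str, None] = {}
        for t in tokens:
            seen.setdefault(t)
        return cls(qid, [QueryTerm(t, weight) for t in seen])

    def original_terms(self) -> list[str]:
        """Unique original-query terms (original or boosted), in order."""
        return [t.term for t in self.terms if t.origin in ("original", "wig_boosted")]


@dataclass
class RankedList:
    """Ordered (docno, score) retrieval results for one query."""

    qid: str
    items: list[tuple[str, float]]

    @property
    def docnos(self) -> list[str]:
        return [d for d, _ in self.items]

    def __len__(self) -> int:
        return len(self.items)

    def top(self, n: int) -> list[str]:
        return [d for d, _ in self.items[:n]]


def bm25_term_field_score(tf: int, df: int, doclen: int, avgdoclen: float,
                          n_docs: int, k1: float, b: float) -> float:
    """Okapi BM25 score of one term in one field of one document.

    Uses the smoothed non-negative idf ln(1 + (N - df + 0.5)/(df + 0.5));
    zero tf scores zero; the result is always >= 0.
    """
    if tf < 0 or df < 0 or df > n_docs or doclen < 0:
        raise ValueError("invalid tf/df/doclen for BM25")
    if not k1 > 0 or not 0 <= b <= 1:
        raise ValueError("invalid BM25 parameters")
    if tf == 0:
        return 0.0
    if avgdoclen <= 0:
        raise ValueError("avgdoclen must be positive when tf > 0")
    idf = math.log(1.0 + (n_docs - df + 0.5) / (df + 0.5))
    return idf * tf * (k1 + 1.0) / (tf + k1 * (1.0 - b + b * doclen / avgdoclen))


def score_document(index: FieldedIndex, wq: WeightedQuery, docno: str,
                   cfg: RetrievalConfig) -> float:
    """Weighted-sum fielded BM25 score of one document for one query."""
    if docno not in index:
        raise KeyError(f"unknown docno {docno!r}")
    n = index.n_docs
    score = 0.0
    for qt in wq.terms:
        if qt.weight == 0.0:
            continue
        term_score = 0.0
        for f, fw in cfg.field_weights.items():
            if fw == 0.0:
                continue
            tf = index.tf(qt.term, docno, f)
            if tf == 0:
                continue
            term_score += fw * bm25_term_field_score(
                tf, index.df(qt.term, f), index.doc_len(docno, f),
                index.avg_doc_length(f), n, cfg.k1, cfg.b,
            )
        score += qt.weight * term_score
    return score


def search(index: FieldedIndex, wq: WeightedQuery,
           cfg: RetrievalConfig | None = None) -> RankedList:
    """Rank the top_k documents for a weighted query.

    Documents scoring zero are excluded; ties are broken by ascending
    docno for determinism. An empty query yields an empty list with a
    warning.
    """
    cfg = cfg or RetrievalConfig()
    if index.n_docs == 0:
        raise EmptyIndexError("cannot search an empty index")
    if not wq.terms:
        warnings.warn(f"query {wq.qid!r} is empty after normalization", stacklevel=2)
        return RankedList(wq.qid, [])
    candidates: set[str] = set()
    for qt in wq.terms:
        if qt.weight == 0.0:
            continue
        for f, fw in cfg.field_weights.items():
            if fw > 0.0:
                candidates.update(index.postings[f].get(qt.term, ()))
    scored = []
    for docno in candidates:
        s = score_document(index, wq, docno, cfg)
        if s > 0.0:
            scored.append((docno, s))
    scored.sort(key=lambda item: (-item[1], item[0]))
    return RankedList(wq.qid, scored[: cfg.top_k])
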