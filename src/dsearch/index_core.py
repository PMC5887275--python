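"""Text normalization and the fielded inverted index.

Documents are dataset descriptions with three text sections -- TITLE,
TEXT and METADATA -- which are indexed separately, plus a materialized
WHOLE pseudo-field holding their concatenation (in that order). The
index keeps, per field: postings (term -> docno -> term frequency),
document lengths and average lengths, document frequencies, and for the
WHOLE field the collection term frequencies used by the language-model
probabilities. Repository (web-domain) document counts are kept for the
DomainWeight ranking feature. Word-bigram sets per field and first-token
positions in TEXT are stored for the re-ranking features; full
positional search is out of scope.

Normalization is: lowercase, split on runs of non-alphanumeric
characters, remove the 33 standard Lucene English stopwords, then apply
the classic Porter stemmer (stopword removal happens on the surface
form, before stemming).
"""

from __future__ import annotations

import json
import math
import re
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping

from .corpus_io import DatasetRecord
from .porter import stem

#: The 33-word English stopword list used by Lucene's StandardAnalyzer.
STOPWORDS = frozenset(
    """a an and are as at be but by for if in into is it no not of on or
    such that the their then there these they this to was will with""".split()
)

#: Real record fields, in WHOLE concatenation order.
FIELDS = ("title", "text", "metadata")
WHOLE = "whole"
ALL_FIELDS = FIELDS + (WHOLE,)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Normalize free text to an ordered list of index terms.

    Lowercases, splits on maximal runs of non-alphanumeric characters
    (digits are retained, so gene symbols like ``tp53`` survive),
    removes stopwords and Porter-stems the remainder. Deterministic;
    empty input yields an empty list.
    """
    return [stem(t) for t in _TOKEN_RE.findall(text.lower()) if t not in STOPWORDS]


class EmptyIndexError(ValueError):
    """Raised when an operation requires a non-empty index."""


class FieldedIndex:
    """Per-field postings and collection statistics for a record corpus.

    Built with :func:`build_index`; treat instances as immutable.
    """

    SCHEMA_VERSION = 1

    def __init__(self) -> None:
        self.postings: dict[str, dict[str, dict[str, int]]] = {f: {} for f in ALL_FIELDS}
        self.doc_length: dict[str, dict[str, int]] = {f: {} for f in ALL_FIELDS}
        self.doc_vectors: dict[str, dict[str, Counter]] = {f: {} for f in ALL_FIELDS}
        self.bigrams: dict[str, dict[str, set[tuple[str, str]]]] = {f: {} for f in ALL_FIELDS}
        self.text_first_pos: dict[str, dict[str, int]] = {}
        self.repo_of: dict[str, str] = {}
        self.domain_counts: Counter = Counter()
        self.collection_tf: Counter = Counter()  # WHOLE-field term frequencies
        self.total_tokens: int = 0  # WHOLE-field token count

    # -- statistics -------------------------------------------------------

    @property
    def n_docs(self) -> int:
        return len(self.repo_of)

    @property
    def docnos(self) -> list[str]:
        return sorted(self.repo_of)

    def df(self, term: str, field: str) -> int:
        return len(self.postings[field].get(term, ()))

    def tf(self, term: str, docno: str, field: str) -> int:
        return self.postings[field].get(term, {}).get(docno, 0)

    def doc_len(self, docno: str, field: str) -> int:
        return self.doc_length[field].get(docno, 0)

    def avg_doc_length(self, field: str) -> float:
        if not self.repo_of:
            raise EmptyIndexError("empty index has no average document length")
        return sum(self.doc_length[field].values()) / self.n_docs

    def doc_terms(self, docno: str, field: str = WHOLE) -> Mapping[str, int]:
        """Term -> tf vector of one document in one field."""
        return self.doc_vectors[field].get(docno, Counter())

    def bigram_set(self, docno: str, field: str) -> set[tuple[str, str]]:
        return self.bigrams[field].get(docno, set())

    def first_positions(self, docno: str) -> Mapping[str, int]:
        """First 0-based token position of each term in the TEXT field."""
        return self.text_first_pos.get(docno, {})

    def __contains__(self, docno: str) -> bool:
        return docno in self.repo_of

    # -- persistence ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {
            "schema_version": self.SCHEMA_VERSION,
            "fields": list(ALL_FIELDS),
            "n_docs": self.n_docs,
            "total_tokens": self.total_tokens,
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
        payload = {
            "postings": self.postings,
            "doc_length": self.doc_length,
            "text_first_pos": self.text_first_pos,
            "repo_of": self.repo_of,
            "collection_tf": dict(self.collection_tf),
            "bigrams": {
                f: {doc: sorted(" ".join(b) for b in bs) for doc, bs in per.items()}
                for f, per in self.bigrams.items()
            },
        }
        (d / "index.json").write_text(json.dumps(payload))

    @classmethod
    def load(cls, directory: str | Path) -> "FieldedIndex":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        if manifest["schema_version"] != cls.SCHEMA_VERSION:
            raise ValueError(f"unsupported index schema {manifest['schema_version']}")
        payload = json.loads((d / "index.json").read_text())
        idx = cls()
        idx.postings = {f: dict(payload["postings"].get(f, {})) for f in ALL_FIELDS}
        idx.doc_length = {f: dict(payload["doc_length"].get(f, {})) for f in ALL_FIELDS}
        idx.text_first_pos = payload["text_first_pos"]
        idx.repo_of = payload["repo_of"]
        idx.collection_tf = Counter(payload["collection_tf"])
        idx.total_tokens = sum(idx.collection_tf.values())
        idx.domain_counts = Counter(idx.repo_of.values())
        idx.bigrams = {
            f: {doc: {tuple(s.split(" ")) for s in bs} for doc, bs in per.items()}
            for f, per in payload["bigrams"].items()
        }
        for f in ALL_FIELDS:
            for term, posting in idx.postings[f].items():
                for doc, tf in posting.items():
                    idx.doc_vectors[f].setdefault(doc, Counter())[term] = tf
        return idx


def build_index(records: Iterable[DatasetRecord]) -> FieldedIndex:
    """Build a :class:`FieldedIndex` from a record stream.

    WHOLE-field statistics are computed from the concatenation of
    title, text and metadata, in that order. Duplicate docnos are an
    error. The result depends only on the multiset of records, not on
    their order.
    """
    idx = FieldedIndex()
    for rec in records:
        if rec.docno in idx.repo_of:
            raise ValueError(f"duplicate docno {rec.docno!r}")
        idx.repo_of[rec.docno] = rec.repository
        idx.domain_counts[rec.repository] += 1
        whole: list[str] = []
        for field in FIELDS:
            tokens = tokenize(getattr(rec, field))
            whole.extend(tokens)
            _add_field(idx, rec.docno, field, tokens)
            if field == "text":
                firsts: dict[str, int] = {}
                for pos, tok in enumerate(tokens):
                    firsts.setdefault(tok, pos)
                idx.text_first_pos[rec.docno] = firsts
        _add_field(idx, rec.docno, WHOLE, whole)
        idx.collection_tf.update(whole)
        idx.total_tokens += len(whole)
    return idx


def _add_field(idx: FieldedIndex, docno: str, field: str, tokens: list[str]) -> None:
    counts = Counter(tokens)
    idx.doc_length[field][docno] = len(tokens)
    idx.doc_vectors[field][docno] = counts
    for term, tf in counts.items():
        idx.postings[field].setdefault(term, {})[docno] = tf
    idx.bigrams[field][docno] = set(zip(tokens, tokens[1:]))


def collection_prob(index: FieldedIndex, term: str) -> float:
    """Collection language-model probability F_i / sum_j F_j (WHOLE field).

    Unseen terms have probability 0. Raises on an empty index.
    """
    if index.total_tokens == 0:
        raise EmptyIndexError("collection probability undefined for an empty index")
    return index.collection_tf.get(term, 0) / index.total_tokens
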