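"""Query reformulation: WIG keyword boosting and query expansion.

The verbose free-text queries of dataset search (~15 terms) mix a few
discriminative keywords with filler vocabulary. Three reformulation
steps build a weighted query from the original one:

1. *Weighted Information Gain* (WIG) keyword detection. For each query
   term q_i with positive collection frequency,

       wig(q_i) = [ mean_{d in T_N(q_i)} log p(q_i|d) - log p(q_i|C) ]
                  / ( -log p(q_i|C) )

   where T_N(q_i) are the top N documents retrieved for the single-term
   query q_i, p(q_i|d) is the Dirichlet-smoothed document language
   model and p(q_i|C) the collection probability. Terms whose wig
   exceeds the mean over the query's (finite-wig) terms are boosted by
   a multiplicative weight.

2. *Blind relevance feedback* (BRF): the most frequent non-query,
   non-stopword terms of the top initially-retrieved documents are
   added with a small weight.

3. *External expansion*: query keywords gated by a medical-term list
   are looked up in offline resource providers; the returned snippets
   are concatenated into a pseudo-document and its most frequent terms
   -- restricted to terms that occur in the initial top documents, to
   limit query drift -- are added with their own weight.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Protocol, Sequence
import json

from .index_core import STOPWORDS, WHOLE, FieldedIndex, collection_prob, tokenize
from .retrieval import (QueryTerm, RankedList, RetrievalConfig, WeightedQuery,
                        search)

logger = logging.getLogger(__name__)


@dataclass
class ReformConfig:
    """Tuned reformulation parameters.

    Defaults are the tuned best values (grid ranges {5,10,30} for
    counts and {0.1,0.3,0.5} for expansion-term weights). The same
    top-document count is shared by WIG, BRF and external expansion.
    """

    n_top_datasets: int = 5
    n_internal_terms: int = 5
    internal_weight: float = 0.1
    n_external_terms: int = 10
    external_weight: float = 0.5
    smoothing_mu: float = 2000.0
    boost_factor: float = 3.0
    drop_low_wig: bool = False

    def __post_init__(self) -> None:
        for name in ("n_top_datasets", "n_internal_terms", "n_external_terms"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("internal_weight", "external_weight", "smoothing_mu", "boost_factor"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class TermWeight:
    term: str
    wig: float          # -inf for terms absent from the collection
    weight: float       # 1.0 or the boost factor
    selected: bool      # True when boosted


@dataclass
class TermWeightReport:
    """Per-term WIG scores and the weights they induced for one query."""

    qid: str
    terms: list[TermWeight]

    def weights(self) -> dict[str, float]:
        return {t.term: t.weight for t in self.terms}

    def selected_terms(self) -> list[str]:
        return [t.term for t in self.terms if t.selected]


class ResourceProvider(Protocol):
    """Offline stand-in for an external knowledge source (KEGG, HGNC,
    vertical web search). ``lookup`` must be a pure function of the
    provider's fixture data; no network access."""

    name: str

    def lookup(self, key: str) -> list[str]: ...


class FixtureProvider:
    """Resource provider backed by an in-memory key -> snippets mapping."""

    def __init__(self, name: str, mapping: dict[str, list[str]],
                 category: str | None = None) -> None:
        self.name = name
        self.category = category  # optional resource category tag
        self._mapping = {k.lower(): list(v) for k, v in mapping.items()}

    def lookup(self, key: str) -> list[str]:
        return list(self._mapping.get(key.lower(), []))

    @classmethod
    def from_file(cls, path: str | Path) -> "FixtureProvider":
        """Load a provider fixture: JSON ``{"name": ..., "snippets": {key: [..]}}``."""
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(obj["name"], obj["snippets"], obj.get("category"))


def load_medical_terms(path: str | Path) -> set[str]:
    """Load a medical-term gate list, one lowercase surface term per line."""
    terms = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        term = line.strip().lower()
        if term:
            terms.add(term)
    return terms


# -- language-model probabilities ----------------------------------------

def doc_prob(index: FieldedIndex, term: str, docno: str, mu: float) -> float:
    """Dirichlet-smoothed probability of observing ``term`` in a document.

        p(t|d) = (tf(t, d) + mu * p(t|C)) / (|d| + mu)

    over the WHOLE field. Raises for terms absent from the collection:
    the WIG computation handles those with a -inf sentinel instead.
    """
    if mu <= 0:
        raise ValueError("smoothing parameter mu must be positive")
    if docno not in index:
        raise KeyError(f"unknown docno {docno!r}")
    p_c = collection_prob(index, term)
    if p_c == 0.0:
        raise ValueError(f"term {term!r} has zero collection probability")
    tf = index.tf(term, docno, WHOLE)
    return (tf + mu * p_c) / (index.doc_len(docno, WHOLE) + mu)


# -- WIG keyword detection ------------------------------------------------

def wig_weights(index: FieldedIndex, query: Sequence[str], cfg: ReformConfig,
                retrieval_cfg: RetrievalConfig | None = None,
                qid: str = "") -> TermWeightReport:
    """Score each unique query term with WIG and assign boost weights.

    Terms absent from the collection get wig = -inf and weight 1.0.
    Terms with wig strictly above the mean over finite-wig terms get
    ``boost_factor``; if all finite wigs are equal no term is boosted.
    """
    if not query:
        raise ValueError("cannot weight an empty query")
    retrieval_cfg = retrieval_cfg or RetrievalConfig()
    unique_terms = list(dict.fromkeys(query))
    wigs: dict[str, float] = {}
    for term in unique_terms:
        p_c = collection_prob(index, term)
        if p_c == 0.0:
            wigs[term] = -math.inf
            continue
        single = WeightedQuery.from_tokens(f"{qid}:{term}", [term])
        top = search(index, single, retrieval_cfg).top(cfg.n_top_datasets)
        if not top:  # positive collection frequency but zero-weighted fields
            wigs[term] = -math.inf
            continue
        log_pc = math.log(p_c)
        mean_log_pd = sum(
            math.log(doc_prob(index, term, d, cfg.smoothing_mu)) for d in top
        ) / len(top)
        wigs[term] = (mean_log_pd - log_pc) / (-log_pc)
    finite = [w for w in wigs.values() if math.isfinite(w)]
    threshold = sum(finite) / len(finite) if finite else math.inf
    all_equal = len(set(finite)) <= 1
    terms = []
    for term in unique_terms:
        selected = (not all_equal) and wigs[term] > threshold
        weight = cfg.boost_factor if selected else 1.0
        terms.append(TermWeight(term, wigs[term], weight, selected))
    return TermWeightReport(qid, terms)


# -- expansion ------------------------------------------------------------

def _top_doc_term_counts(index: FieldedIndex, initial: RankedList,
                         n_docs: int) -> Counter:
    counts: Counter = Counter()
    for docno in initial.top(n_docs):
        counts.update(index.doc_terms(docno, WHOLE))
    return counts


def brf_expand(index: FieldedIndex, initial: RankedList,
               original_terms: Iterable[str],
               cfg: ReformConfig) -> list[tuple[str, float]]:
    """Blind relevance feedback expansion from the top retrieved docs.

    Candidates are all WHOLE-field terms of the top documents minus
    stopwords and original query terms, ranked by total term frequency
    across those documents (ties lexicographic). Returns at most
    ``n_internal_terms`` pairs (term, internal_weight).
    """
    exclude = set(original_terms) | STOPWORDS
    counts = _top_doc_term_counts(index, initial, cfg.n_top_datasets)
    ranked = sorted(
        ((t, c) for t, c in counts.items() if t not in exclude),
        key=lambda item: (-item[1], item[0]),
    )
    return [(t, cfg.internal_weight) for t, _ in ranked[: cfg.n_internal_terms]]


def external_expand(index: FieldedIndex, query, initial: RankedList,
                    providers: Sequence[ResourceProvider],
                    med_terms: set[str],
                    cfg: ReformConfig) -> list[tuple[str, float]]:
    """Pseudo-document expansion from offline external resources.

    Only query words whose lowercase surface form is in ``med_terms``
    are sent to the providers. All returned snippets are concatenated
    into one pseudo-document; candidate terms must not be original
    query terms or stopwords and must occur at least once in the WHOLE
    field of the initial top documents (query-drift gate). Ranked by
    pseudo-document frequency, ties lexicographic; at most
    ``n_external_terms`` pairs (term, external_weight). A failing
    provider is skipped with a warning, never fatal.

    ``query`` may be a :class:`~dsearch.corpus_io.Query` or a raw
    string; gating uses surface forms, before stemming.
    """
    raw_text = getattr(query, "raw_text", query)
    surface = [w for w in _surface_words(raw_text)]
    keys = [w for w in dict.fromkeys(surface) if w in med_terms]
    snippets: list[str] = []
    for provider in providers:
        for key in keys:
            try:
                snippets.extend(provider.lookup(key))
            except Exception:  # noqa: BLE001 - provider quality is not our contract
                logger.warning("provider %r failed for key %r; skipped",
                               getattr(provider, "name", provider), key)
                break
    if not snippets:
        return []
    pseudo_counts = Counter(tokenize(" ".join(snippets)))
    original = set(tokenize(raw_text))
    top_counts = _top_doc_term_counts(index, initial, cfg.n_top_datasets)
    ranked = sorted(
        ((t, c) for t, c in pseudo_counts.items()
         if t not in original and t in top_counts),
        key=lambda item: (-item[1], item[0]),
    )
    return [(t, cfg.external_weight) for t, _ in ranked[: cfg.n_external_terms]]


def _surface_words(text: str) -> list[str]:
    import re

    return re.findall(r"[a-z0-9]+", text.lower())


# -- composition ----------------------------------------------------------

_ORIGIN_PRIORITY = {"original": 0, "wig_boosted": 0, "external": 1, "brf": 2}


def compose_query(qid: str, report: TermWeightReport,
                  brf_terms: Sequence[tuple[str, float]] = (),
                  ext_terms: Sequence[tuple[str, float]] = (),
                  drop_low_wig: bool = False) -> WeightedQuery:
    """Merge WIG-weighted original terms with expansion terms.

    A term appearing in several sources is kept once with its maximum
    weight and the highest-priority origin (original > external > brf).
    With ``drop_low_wig`` the unboosted original terms are discarded
    entirely (keyword-only querying).
    """
    merged: dict[str, QueryTerm] = {}

    def _offer(term: str, weight: float, origin: str) -> None:
        prev = merged.get(term)
        if prev is None:
            merged[term] = QueryTerm(term, weight, origin)
            return
        best_weight = max(prev.weight, weight)
        best_origin = min((prev.origin, origin), key=_ORIGIN_PRIORITY.__getitem__)
        merged[term] = QueryTerm(term, best_weight, best_origin)

    for tw in report.terms:
        if drop_low_wig and not tw.selected:
            continue
        _offer(tw.term, tw.weight, "wig_boosted" if tw.selected else "original")
    for term, weight in ext_terms:
        _offer(term, weight, "external")
    for term, weight in brf_terms:
        _offer(term, weight, "brf")
    return WeightedQuery(qid, list(merged.values()))


def render_annotated(wq: WeightedQuery) -> str:
    """Human-readable reformulated query using the marker convention:
    boosted keywords get a trailing '+', external expansion terms are
    enclosed in '[]' and BRF terms in '<>'."""
    parts = []
    ext = [t.term for t in wq.terms if t.origin == "external"]
    brf = [t.term for t in wq.terms if t.origin == "brf"]
    for t in wq.terms:
        if t.origin == "wig_boosted":
            parts.append(t.term + "+")
        elif t.origin == "original":
            parts.append(t.term)
    if ext:
        parts.append("[" + " ".join(ext) + "]")
    if brf:
        parts.append("<" + " ".join(brf) + ">")
    return " ".join(parts)


def reformulate(index: FieldedIndex, query, cfg: ReformConfig | None = None,
                retrieval_cfg: RetrievalConfig | None = None,
                providers: Sequence[ResourceProvider] = (),
                med_terms: set[str] | None = None,
                use_brf: bool = True, use_external: bool = True) -> WeightedQuery:
    """Full reformulation pipeline for one query.

    Retrieves the initial list with the uniformly-weighted original
    query, detects keywords with WIG, optionally expands internally
    (BRF) and externally, and composes the weighted query.
    """
    cfg = cfg or ReformConfig()
    retrieval_cfg = retrieval_cfg or RetrievalConfig()
    tokens = tokenize(query.raw_text)
    report = wig_weights(index, tokens, cfg, retrieval_cfg, qid=query.qid)
    initial = search(index, WeightedQuery.from_tokens(query.qid, tokens), retrieval_cfg)
    brf_terms: list[tuple[str, float]] = []
    ext_terms: list[tuple[str, float]] = []
    if initial.items:
        if use_brf:
            brf_terms = brf_expand(index, initial, tokens, cfg)
        if use_external and providers:
            ext_terms = external_expand(index, query, initial, providers,
                                        med_terms or set(), cfg)
    return compose_query(query.qid, report, brf_terms, ext_terms,
                         drop_low_wig=cfg.drop_low_wig)
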