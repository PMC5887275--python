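"""Synthetic corpora with the statistical structure the pipeline assumes.

The generator emulates, with symbolic vocabulary, the structure of a
dataset-description retrieval task so that every stage of the engine is
testable offline:

* verbose queries (~15 terms) mixing a few discriminative topic
  keywords with high-frequency filler terms drawn from the background
  vocabulary -- the separation WIG keyword detection relies on;
* graded relevance: grade-2 documents carry their topic's terms densely
  in TITLE/TEXT; grade-1 documents carry them either only in the
  repository-level METADATA field (the metadata "bridge") or sparsely
  in TEXT; grade-0 documents are pure background;
* planted expansion terms that co-occur with topic terms in relevant
  documents but never appear in queries, recoverable by blind relevance
  feedback and served by offline provider fixtures for external
  expansion;
* multiple source repositories of unequal size (for DomainWeight);
* optional label noise for noisy-training experiments.

Terms are synthetic symbols ending in digits (``t3top1``, ``bg17``),
which pass unchanged through the Porter stemmer and are not stopwords,
so surface forms equal index terms by construction. Generation is a
pure function of the configuration (including its seed).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path
from typing import Sequence
import json

import numpy as np

from .corpus_io import (DatasetRecord, QrelsTable, Query, write_corpus,
                        write_qrels, write_queries)
from .ltr import FEATURE_NAMES, FeatureTable
from .query_reform import FixtureProvider


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic retrieval task.

    Defaults model a small but structurally faithful corpus: 600
    documents over 5 repositories of unequal size, 20 query topics,
    a 300-term zipf-distributed background vocabulary whose 30 most
    frequent terms form the query filler pool, 4 topic + 4 expansion
    terms per topic, 6 grade-2 and 4 grade-1 documents per topic, and
    15-term queries carrying 3 topic keywords.
    """

    n_docs: int = 600
    n_queries: int = 20
    n_repositories: int = 5
    topic_terms_per_topic: int = 4
    expansion_term_count: int = 4
    background_vocab: int = 300
    filler_pool: int = 30
    zipf_exponent: float = 0.5
    query_length: int = 15
    query_topic_terms: int = 3
    grade2_per_topic: int = 6
    grade1_per_topic: int = 4
    metadata_bridge_rate: float = 0.8
    label_noise_rate: float = 0.0
    judged_irrelevant_per_query: int = 20
    n_medical_decoys: int = 30
    seed: int = 7

    def __post_init__(self) -> None:
        planted = self.n_queries * (self.grade2_per_topic + self.grade1_per_topic)
        if planted > self.n_docs:
            raise ValueError(
                f"{planted} graded documents exceed n_docs={self.n_docs}")
        if self.query_topic_terms > min(self.topic_terms_per_topic, self.query_length):
            raise ValueError("query_topic_terms exceeds topic terms or query length")
        for name in ("metadata_bridge_rate", "label_noise_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.filler_pool > self.background_vocab:
            raise ValueError("filler pool larger than background vocabulary")


@dataclass
class PlantedTruth:
    """Ground truth exposed for assertions against the generator."""

    topic_terms: dict[str, list[str]]       # qid -> topic keywords
    expansion_terms: dict[str, list[str]]   # qid -> planted co-occurring terms
    grades: dict[str, dict[str, int]]       # qid -> docno -> planted grade
    filler_terms: dict[str, list[str]]      # qid -> filler terms in the query


@dataclass
class SyntheticBundle:
    records: list[DatasetRecord]
    queries: list[Query]
    qrels: QrelsTable
    providers: list[FixtureProvider]
    medical_terms: set[str]
    truth: PlantedTruth


def _background_sampler(cfg: GeneratorConfig, rng: np.random.Generator):
    vocab = [f"bg{i}" for i in range(cfg.background_vocab)]
    weights = 1.0 / np.arange(1, cfg.background_vocab + 1) ** cfg.zipf_exponent
    probs = weights / weights.sum()

    def draw(n: int) -> list[str]:
        return [vocab[i] for i in rng.choice(cfg.background_vocab, size=n, p=probs)]

    return vocab, draw


def generate(cfg: GeneratorConfig) -> SyntheticBundle:
    """Generate corpus, queries, qrels, provider fixtures and the
    medical-term gate list. Deterministic given ``cfg`` (incl. seed)."""
    rng = np.random.default_rng(cfg.seed)
    bg_vocab, draw_bg = _background_sampler(cfg, rng)
    filler_terms = bg_vocab[: cfg.filler_pool]

    qids = [f"q{i + 1}" for i in range(cfg.n_queries)]
    topic_terms = {
        qid: [f"t{i + 1}top{j + 1}" for j in range(cfg.topic_terms_per_topic)]
        for i, qid in enumerate(qids)
    }
    expansion_terms = {
        qid: [f"t{i + 1}exp{j + 1}" for j in range(cfg.expansion_term_count)]
        for i, qid in enumerate(qids)
    }

    repos = [f"repo{r + 1}" for r in range(cfg.n_repositories)]
    repo_weights = 0.5 ** np.arange(cfg.n_repositories)
    repo_probs = repo_weights / repo_weights.sum()

    def draw_repo() -> str:
        return repos[rng.choice(cfg.n_repositories, p=repo_probs)]

    def lengths() -> tuple[int, int, int]:
        title = max(3, int(rng.lognormal(math.log(5), 0.3)))
        text = max(20, int(rng.lognormal(math.log(50), 0.3)))
        meta = max(6, int(rng.lognormal(math.log(12), 0.3)))
        return title, text, meta

    records: list[DatasetRecord] = []
    grades: dict[str, dict[str, int]] = {qid: {} for qid in qids}
    doc_counter = 0

    def new_docno() -> str:
        nonlocal doc_counter
        doc_counter += 1
        return f"d{doc_counter:05d}"

    def shuffled(tokens: list[str]) -> str:
        arr = np.array(tokens, dtype=object)
        rng.shuffle(arr)
        return " ".join(arr.tolist())

    for qid in qids:
        topics = topic_terms[qid]
        expans = expansion_terms[qid]
        for _ in range(cfg.grade2_per_topic):
            docno = new_docno()
            t_len, x_len, m_len = lengths()
            title = [topics[int(rng.integers(len(topics)))]] + draw_bg(t_len - 1)
            planted = topics * 2 + expans * 2
            text = planted + draw_bg(max(0, x_len - len(planted)))
            meta = topics[:2] + draw_bg(max(0, m_len - 2))
            records.append(DatasetRecord(docno, shuffled(title), draw_repo(),
                                         shuffled(text), shuffled(meta)))
            grades[qid][docno] = 2
        for _ in range(cfg.grade1_per_topic):
            docno = new_docno()
            t_len, x_len, m_len = lengths()
            if rng.random() < cfg.metadata_bridge_rate:
                # topic terms reachable only through the METADATA field
                title = draw_bg(t_len)
                text = draw_bg(x_len)
                meta = topics[:] + draw_bg(max(0, m_len - len(topics)))
            else:
                title = draw_bg(t_len)
                text = topics[:1] + draw_bg(x_len - 1)
                meta = draw_bg(m_len)
            records.append(DatasetRecord(docno, shuffled(title), draw_repo(),
                                         shuffled(text), shuffled(meta)))
            grades[qid][docno] = 1

    n_background = cfg.n_docs - doc_counter
    background_docnos = []
    for _ in range(n_background):
        docno = new_docno()
        t_len, x_len, m_len = lengths()
        records.append(DatasetRecord(docno, shuffled(draw_bg(t_len)), draw_repo(),
                                     shuffled(draw_bg(x_len)),
                                     shuffled(draw_bg(m_len))))
        background_docnos.append(docno)

    queries: list[Query] = []
    filler_by_qid: dict[str, list[str]] = {}
    for qid in qids:
        kw = topic_terms[qid][: cfg.query_topic_terms]
        n_filler = cfg.query_length - len(kw)
        fillers = [filler_terms[i]
                   for i in rng.integers(cfg.filler_pool, size=n_filler)]
        filler_by_qid[qid] = fillers
        queries.append(Query(qid, shuffled(kw + fillers)))

    qrels = QrelsTable()
    for qid in qids:
        for docno, grade in grades[qid].items():
            qrels.add(qid, docno, _maybe_noisy(grade, cfg.label_noise_rate, rng))
        n_judged0 = min(cfg.judged_irrelevant_per_query, len(background_docnos))
        sample = rng.choice(len(background_docnos), size=n_judged0, replace=False)
        for i in sample:
            qrels.add(qid, background_docnos[i],
                      _maybe_noisy(0, cfg.label_noise_rate, rng))

    providers = _make_providers(cfg, rng, qids, topic_terms, expansion_terms, draw_bg)
    decoys = {f"med{i + 1}x" for i in range(cfg.n_medical_decoys)}
    medical_terms = {t for terms in topic_terms.values() for t in terms} | decoys

    truth = PlantedTruth(topic_terms, expansion_terms, grades, filler_by_qid)
    return SyntheticBundle(records, queries, qrels, providers, medical_terms, truth)


def _maybe_noisy(grade: int, rate: float, rng: np.random.Generator) -> int:
    if rate > 0.0 and rng.random() < rate:
        grade += int(rng.choice([-1, 1]))
    return min(2, max(0, grade))


def _make_providers(cfg, rng, qids, topic_terms, expansion_terms, draw_bg):
    """Two provider fixtures keyed by topic-term surface forms; the
    snippets embed the planted expansion terms in background text."""
    mappings: list[dict[str, list[str]]] = [{}, {}]
    for qid in qids:
        for k, term in enumerate(topic_terms[qid]):
            snippets = []
            for _ in range(2):
                tokens = expansion_terms[qid] * 3 + topic_terms[qid] + draw_bg(4)
                arr = np.array(tokens, dtype=object)
                rng.shuffle(arr)
                snippets.append(" ".join(arr.tolist()))
            mappings[k % 2][term] = snippets
    return [
        FixtureProvider("refdb", mappings[0], category="knowledge_base"),
        FixtureProvider("websearch", mappings[1], category="vertical_search"),
    ]


def planted_truth(cfg: GeneratorConfig) -> PlantedTruth:
    """Ground truth for the given configuration (same seed semantics
    as :func:`generate`)."""
    return generate(cfg).truth


def write_fixture_dir(bundle: SyntheticBundle, outdir: str | Path) -> None:
    """Write a bundle as plain-text fixture files: corpus (canonical
    dialect), queries, qrels, provider JSON files, the medical-term
    list and the planted-truth report."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_corpus(bundle.records, out / "corpus.jsonl")
    write_queries(bundle.queries, out / "queries.tsv")
    write_qrels(bundle.qrels, out / "qrels.txt")
    providers_dir = out / "providers"
    providers_dir.mkdir(exist_ok=True)
    for provider in bundle.providers:
        (providers_dir / f"{provider.name}.json").write_text(json.dumps({
            "name": provider.name,
            "category": provider.category,
            "snippets": provider._mapping,
        }, indent=1))
    (out / "medterms.txt").write_text(
        "\n".join(sorted(bundle.medical_terms)) + "\n")
    (out / "planted_truth.json").write_text(json.dumps({
        "topic_terms": bundle.truth.topic_terms,
        "expansion_terms": bundle.truth.expansion_terms,
        "grades": bundle.truth.grades,
        "filler_terms": bundle.truth.filler_terms,
    }, indent=1))


# -- planted-linear ranking task -----------------------------------------

def planted_linear_task(n_queries: int = 20, docs_per_query: int = 30,
                        seed: int = 7,
                        noise: float = 0.1) -> tuple[FeatureTable, QrelsTable,
                                                     np.ndarray]:
    """A ranking task whose grades follow a hidden linear utility.

    Feature vectors are standard normal; a fixed hidden weight vector
    (mixed signs) defines a utility whose per-query quantiles set the
    grades (top 20% grade 2, next 30% grade 1). Used to check that the
    coordinate-ascent learner recovers enough of the utility to beat a
    uniform-weight ranking on held-out queries.
    """
    rng = np.random.default_rng(seed)
    n_features = len(FEATURE_NAMES)
    true_w = rng.normal(size=n_features)
    table = FeatureTable()
    qrels = QrelsTable()
    for qi in range(n_queries):
        qid = f"s{qi + 1}"
        x = rng.normal(size=(docs_per_query, n_features))
        utility = x @ true_w + noise * rng.normal(size=docs_per_query)
        order = np.argsort(-utility)
        grade = np.zeros(docs_per_query, dtype=int)
        n2 = max(1, int(0.2 * docs_per_query))
        n1 = max(1, int(0.3 * docs_per_query))
        grade[order[:n2]] = 2
        grade[order[n2:n2 + n1]] = 1
        for di in range(docs_per_query):
            docno = f"{qid}d{di + 1}"
            table.add(qid, docno, x[di])
            qrels.add(qid, docno, int(grade[di]))
    return table, qrels, true_w
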