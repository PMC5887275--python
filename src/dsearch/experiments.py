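"""End-to-end experiment drivers over the synthetic retrieval task.

These functions wire the full pipeline together -- generate a corpus,
index it, run the retrieval variants (uniform weights, WIG boosting,
BRF and external expansion, METADATA ablation), and train/evaluate the
learning-to-rank stage -- and report the direction-of-effect
comparisons the engine is designed around. They are used both by the
test suite and by the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .evaluation import evaluate_run, make_cv_plan, mean_ndcg, run_cv, ndcg
from .index_core import FieldedIndex, build_index, tokenize
from .ltr import (FeatureTable, LinearRankModel, RankedList,
                  extract_features, rerank, train_coordinate_ascent)
from .query_reform import (ReformConfig, brf_expand, compose_query,
                           external_expand, wig_weights)
from .retrieval import RetrievalConfig, WeightedQuery, search
from .synthdata import (GeneratorConfig, SyntheticBundle, generate,
                        planted_linear_task)


@dataclass
class ReformulationOutcome:
    """Mean NDCG of each retrieval variant plus BRF recovery."""

    ndcg_by_variant: dict[str, float]
    per_query_ndcg: dict[str, dict[str, float]]
    brf_recovery_rate: float
    n_queries: int


def run_reformulation_experiment(
    cfg: GeneratorConfig,
    retrieval_cfg: RetrievalConfig | None = None,
    reform_cfg: ReformConfig | None = None,
    bundle: SyntheticBundle | None = None,
    index: FieldedIndex | None = None,
) -> ReformulationOutcome:
    """Run the retrieval variants over a synthetic task.

    Variants: ``uniform`` (plain fielded BM25), ``no_metadata``
    (METADATA field weight zeroed), ``wig`` (WIG-boosted terms),
    ``wig_brf`` and ``wig_ext`` (boosting plus internal / external
    expansion), ``iropt`` (boosting plus both). BRF recovery is the
    fraction of queries for which blind relevance feedback returns at
    least one planted expansion term.
    """
    retrieval_cfg = retrieval_cfg or RetrievalConfig()
    reform_cfg = reform_cfg or ReformConfig()
    bundle = bundle or generate(cfg)
    index = index or build_index(bundle.records)

    no_meta_cfg = RetrievalConfig(
        k1=retrieval_cfg.k1, b=retrieval_cfg.b,
        field_weights={**retrieval_cfg.field_weights, "metadata": 0.0},
        top_k=retrieval_cfg.top_k,
    )

    lists: dict[str, list[RankedList]] = {
        v: [] for v in ("uniform", "no_metadata", "wig", "wig_brf",
                        "wig_ext", "iropt")
    }
    recovered = 0
    for query in bundle.queries:
        tokens = tokenize(query.raw_text)
        uniform_wq = WeightedQuery.from_tokens(query.qid, tokens)
        initial = search(index, uniform_wq, retrieval_cfg)
        lists["uniform"].append(initial)
        lists["no_metadata"].append(search(index, uniform_wq, no_meta_cfg))

        report = wig_weights(index, tokens, reform_cfg, retrieval_cfg,
                             qid=query.qid)
        brf_terms = brf_expand(index, initial, tokens, reform_cfg)
        ext_terms = external_expand(index, query, initial, bundle.providers,
                                    bundle.medical_terms, reform_cfg)
        planted = set(bundle.truth.expansion_terms[query.qid])
        if any(t in planted for t, _ in brf_terms):
            recovered += 1

        lists["wig"].append(search(index, compose_query(query.qid, report),
                                   retrieval_cfg))
        lists["wig_brf"].append(search(
            index, compose_query(query.qid, report, brf_terms=brf_terms),
            retrieval_cfg))
        lists["wig_ext"].append(search(
            index, compose_query(query.qid, report, ext_terms=ext_terms),
            retrieval_cfg))
        lists["iropt"].append(search(
            index, compose_query(query.qid, report, brf_terms=brf_terms,
                                 ext_terms=ext_terms),
            retrieval_cfg))

    per_query = {
        variant: evaluate_run(ls, bundle.qrels).per_query["ndcg"]
        for variant, ls in lists.items()
    }
    means = {v: sum(p.values()) / len(p) for v, p in per_query.items()}
    return ReformulationOutcome(means, per_query, recovered / len(bundle.queries),
                                len(bundle.queries))


@dataclass
class LtrOutcome:
    """Held-out comparison of the learned model vs a uniform-weight
    baseline on the planted-linear ranking task."""

    learned_heldout_ndcg: float
    uniform_heldout_ndcg: float
    trace_non_decreasing: bool
    training_ndcg: float


def run_planted_linear_ltr(n_queries: int = 20, docs_per_query: int = 30,
                           seed: int = 7, n_folds: int = 4,
                           n_restarts: int = 3, ndcg_k: int = 100) -> LtrOutcome:
    """Cross-validated coordinate-ascent training on the planted-linear
    task, compared with ranking by the unweighted feature sum."""
    table, qrels, _ = planted_linear_task(n_queries, docs_per_query, seed=seed)
    plan = make_cv_plan(table.qids, "kfold", k=n_folds, seed=seed)

    traces_ok: list[bool] = []
    training_scores: list[float] = []

    def train_fn(train_qids):
        model = train_coordinate_ascent(table.subset_queries(train_qids), qrels,
                                        seed=seed, n_restarts=n_restarts,
                                        ndcg_k=ndcg_k)
        trace = model.metadata["trace"]
        traces_ok.append(all(b >= a for a, b in zip(trace, trace[1:])))
        training_scores.append(model.metadata["training_ndcg"])
        return model

    def eval_with(model) -> dict[str, float]:
        def eval_fn(m, test_qids):
            out = {}
            for qid in test_qids:
                candidates = RankedList(qid, [(d, 0.0) for d in table.docnos(qid)])
                out[qid] = ndcg(rerank(m if m is not None else model,
                                       candidates, table), qrels, ndcg_k)
            return out
        return eval_fn

    learned = run_cv(plan, train_fn, lambda m, qs: eval_with(None)(m, qs))
    uniform_model = LinearRankModel({n: 1.0 for n in table.feature_names})
    uniform = {
        qid: ndcg(rerank(uniform_model,
                         RankedList(qid, [(d, 0.0) for d in table.docnos(qid)]),
                         table), qrels, ndcg_k)
        for qid in table.qids
    }
    return LtrOutcome(
        learned_heldout_ndcg=sum(learned.values()) / len(learned),
        uniform_heldout_ndcg=sum(uniform.values()) / len(uniform),
        trace_non_decreasing=all(traces_ok),
        training_ndcg=max(training_scores),
    )
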