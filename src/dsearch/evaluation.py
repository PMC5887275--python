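"""Graded and binary retrieval metrics, cross-validation and tuning.

Metrics follow the common graded formulation: NDCG with gain
2^grade - 1 and discount log2(rank + 1), evaluated at depth k = 100 by
default (the retrieval depth of the task); MAP and P@10 binarize at
grade >= 1. Unjudged documents count as grade 0 throughout.

The harness reproduces the experimental protocol of the task: 4-fold
and leave-one-out cross-validation over query ids, exhaustive grid
search by mean NDCG, paired t-tests on per-query metric values, and
11-point interpolated precision-recall curves. A two-stage tuning
protocol is supported by composing these pieces: tune the initial
retrieval grid on a designated query set first, freeze it, then tune
the reformulation grid inside CV folds.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .corpus_io import QrelsTable
from .retrieval import RankedList

#: Grade threshold for binary relevance (MAP, P@10, PR curves).
RELEVANT_GRADE = 1

#: Default tuning grid for the initial retrieval stage (BM25 + field
#: weights); the full cartesian product has 4^5 = 1024 points.
INITIAL_RETRIEVAL_GRID: dict[str, list[float]] = {
    "title_weight": [0.1, 0.3, 0.5, 0.7],
    "text_weight": [0.1, 0.3, 0.5, 0.7],
    "metadata_weight": [0.1, 0.3, 0.5, 0.7],
    "k1": [0.6, 1.0, 1.4, 1.8],
    "b": [0.3, 0.5, 0.7, 0.9],
}

#: Default tuning grid for the query-reformulation stage.
REFORM_GRID: dict[str, list[float]] = {
    "n_top_datasets": [5, 10, 30],
    "n_internal_terms": [5, 10, 30],
    "internal_weight": [0.1, 0.3, 0.5],
    "n_external_terms": [5, 10, 30],
    "external_weight": [0.1, 0.3, 0.5],
}


def _gain(grade: int) -> float:
    return float(2 ** grade - 1)


def ndcg(ranked: RankedList, qrels: QrelsTable, k: int = 100) -> float:
    """Normalized discounted cumulative gain at depth k.

    The ideal DCG is computed from the grade-sorted list of *all*
    judged documents for the query (truncated at k). Queries with no
    judged relevant document (IDCG = 0) score 0.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    dcg = sum(
        _gain(qrels.grade(ranked.qid, docno)) / math.log2(rank + 1)
        for rank, (docno, _) in enumerate(ranked.items[:k], start=1)
    )
    ideal = sorted(qrels.judged(ranked.qid).values(), reverse=True)
    idcg = sum(_gain(g) / math.log2(r + 1) for r, g in enumerate(ideal[:k], start=1))
    return dcg / idcg if idcg > 0 else 0.0


def average_precision(ranked: RankedList, qrels: QrelsTable) -> float:
    """Average precision with binary relevance (grade >= 1).

    AP = (1/R) * sum over retrieved relevant docs at rank r of
    precision@r, with R the total number of relevant judged documents.
    Queries with R = 0 score 0.
    """
    total_relevant = sum(
        1 for g in qrels.judged(ranked.qid).values() if g >= RELEVANT_GRADE
    )
    if total_relevant == 0:
        return 0.0
    hits = 0
    ap = 0.0
    for rank, (docno, _) in enumerate(ranked.items, start=1):
        if qrels.grade(ranked.qid, docno) >= RELEVANT_GRADE:
            hits += 1
            ap += hits / rank
    return ap / total_relevant


def p_at_k(ranked: RankedList, qrels: QrelsTable, k: int = 10) -> float:
    """Fraction of relevant documents among the top k results."""
    if k < 1:
        raise ValueError("k must be >= 1")
    hits = sum(
        1 for docno, _ in ranked.items[:k]
        if qrels.grade(ranked.qid, docno) >= RELEVANT_GRADE
    )
    return hits / k


def pr_curve(lists: Sequence[RankedList], qrels: QrelsTable) -> np.ndarray:
    """11-point interpolated precision at recall 0.0, 0.1, ..., 1.0,
    averaged over queries. Queries with no relevant judged document
    contribute zeros."""
    if not lists:
        raise ValueError("need at least one ranked list")
    recall_levels = np.linspace(0.0, 1.0, 11)
    curves = []
    for ranked in lists:
        total_relevant = sum(
            1 for g in qrels.judged(ranked.qid).values() if g >= RELEVANT_GRADE
        )
        if total_relevant == 0:
            curves.append(np.zeros(11))
            continue
        precisions, recalls = [], []
        hits = 0
        for rank, (docno, _) in enumerate(ranked.items, start=1):
            if qrels.grade(ranked.qid, docno) >= RELEVANT_GRADE:
                hits += 1
                precisions.append(hits / rank)
                recalls.append(hits / total_relevant)
        prec = np.asarray(precisions)
        rec = np.asarray(recalls)
        interp = np.array([
            prec[rec >= level].max() if np.any(rec >= level) else 0.0
            for level in recall_levels
        ])
        curves.append(interp)
    return np.mean(curves, axis=0)


def paired_ttest(per_query_a: Mapping[str, float],
                 per_query_b: Mapping[str, float]) -> float:
    """Two-sided paired t-test p-value over matched per-query values.

    The two mappings must cover the same qids (>= 2). Zero-variance
    differences (e.g. identical runs) yield p = 1.0 with a warning.
    """
    qids = sorted(per_query_a)
    if qids != sorted(per_query_b):
        raise ValueError("per-query values must cover the same qids")
    if len(qids) < 2:
        raise ValueError("need at least two queries for a paired test")
    a = np.array([per_query_a[q] for q in qids])
    b = np.array([per_query_b[q] for q in qids])
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        warnings.warn("zero-variance differences; p-value reported as 1.0",
                      stacklevel=2)
        return 1.0
    return float(stats.ttest_rel(a, b).pvalue)


@dataclass
class EvalResult:
    """Per-query metric values and their means for one run."""

    per_query: dict[str, dict[str, float]]  # metric -> qid -> value
    metadata: dict = dc_field(default_factory=dict)

    def mean(self, metric: str) -> float:
        values = self.per_query[metric]
        return sum(values.values()) / len(values) if values else 0.0

    @property
    def metrics(self) -> list[str]:
        return list(self.per_query)


def evaluate_run(lists: Sequence[RankedList], qrels: QrelsTable,
                 k: int = 100, tag: str = "") -> EvalResult:
    """NDCG@k, MAP and P@10 for a set of ranked lists."""
    per: dict[str, dict[str, float]] = {"ndcg": {}, "map": {}, "p10": {}}
    for ranked in lists:
        per["ndcg"][ranked.qid] = ndcg(ranked, qrels, k)
        per["map"][ranked.qid] = average_precision(ranked, qrels)
        per["p10"][ranked.qid] = p_at_k(ranked, qrels, 10)
    return EvalResult(per, {"k": k, "relevant_grade": RELEVANT_GRADE, "tag": tag})


def mean_ndcg(lists: Sequence[RankedList], qrels: QrelsTable, k: int = 100) -> float:
    return evaluate_run(lists, qrels, k).mean("ndcg")


# -- cross-validation -----------------------------------------------------

@dataclass
class CvPlan:
    """Fold assignment over query ids."""

    folds: dict[str, int]  # qid -> fold index
    mode: str              # "kfold(k)" or "loo"

    @property
    def n_folds(self) -> int:
        return max(self.folds.values()) + 1 if self.folds else 0

    def fold_qids(self, fold: int) -> list[str]:
        return sorted(q for q, f in self.folds.items() if f == fold)

    def fold_sizes(self) -> list[int]:
        return [len(self.fold_qids(f)) for f in range(self.n_folds)]


def make_cv_plan(qids: Sequence[str], mode: str = "kfold",
                 k: int = 4, seed: int = 0) -> CvPlan:
    """Deterministic fold assignment.

    ``kfold``: qids are sorted, shuffled with a seeded generator and
    dealt round-robin, so 21 queries in 4 folds yield sizes 6/5/5/5.
    ``loo``: one fold per query.
    """
    ordered = sorted(qids)
    if len(set(ordered)) != len(ordered):
        raise ValueError("duplicate qids in CV plan")
    if mode == "loo":
        return CvPlan({q: i for i, q in enumerate(ordered)}, "loo")
    if mode != "kfold":
        raise ValueError(f"unknown CV mode {mode!r}")
    if k > len(ordered):
        raise ValueError(f"cannot make {k} folds from {len(ordered)} queries")
    rng = np.random.default_rng(seed)
    shuffled = list(ordered)
    rng.shuffle(shuffled)
    return CvPlan({q: i % k for i, q in enumerate(shuffled)}, f"kfold({k})")


def run_cv(plan: CvPlan,
           train_fn: Callable[[list[str]], object],
           eval_fn: Callable[[object, list[str]], Mapping[str, float]],
           ) -> dict[str, float]:
    """Train on out-of-fold queries, evaluate in-fold, pool per-query.

    ``train_fn(train_qids)`` returns a model; ``eval_fn(model,
    test_qids)`` returns per-query metric values. The pooled qid ->
    value mapping over all folds is returned.
    """
    pooled: dict[str, float] = {}
    for fold in range(plan.n_folds):
        test_qids = plan.fold_qids(fold)
        train_qids = sorted(q for q in plan.folds if plan.folds[q] != fold)
        model = train_fn(train_qids)
        for qid, value in eval_fn(model, test_qids).items():
            pooled[qid] = value
    return pooled


# -- tuning ---------------------------------------------------------------

def grid_points(param_grid: Mapping[str, Sequence]) -> list[dict]:
    """Cartesian product of a parameter grid, in first-in-grid order."""
    if not param_grid or any(len(v) == 0 for v in param_grid.values()):
        raise ValueError("empty parameter grid")
    names = list(param_grid)
    return [dict(zip(names, combo))
            for combo in itertools.product(*(param_grid[n] for n in names))]


def grid_search(param_grid: Mapping[str, Sequence],
                objective: Callable[[dict], float]) -> tuple[dict, float]:
    """Exhaustive maximization of ``objective`` (mean NDCG by convention)
    over the grid; ties are resolved by first-in-grid order."""
    best_params: dict | None = None
    best_score = -math.inf
    for params in grid_points(param_grid):
        score = objective(params)
        if score > best_score:
            best_params, best_score = params, score
    assert best_params is not None
    return best_params, best_score


def percent_change(new_value: float, original_value: float) -> float:
    """Percentage change 100 * (new - original) / original.

    A degradation comes out negative; report its magnitude with
    ``abs``. Zero original value is an error.
    """
    if original_value == 0:
        raise ValueError("percent change undefined for original value 0")
    return 100.0 * (new_value - original_value) / original_value
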