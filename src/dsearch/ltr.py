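"""Learning to rank: 22 query-document features and re-rankers.

The feature vector for a (query, document) pair has eight groups:

1. BM25 scores (whole document, TITLE, TEXT, METADATA);
2. summed term frequencies of matched query terms per field;
3. summed inverse document frequencies per field, with
   idf(t, f) = ln(N / (n_t + 1)) + 1;
4. summed tf*idf per field;
5. the group 2-4 statistics on the concatenated (WHOLE) document;
6. distinct word bigrams shared between query and field;
7. DistanceFromStart: token position of the first query term in TEXT
   (TEXT length when no query term occurs);
8. DomainWeight: the fraction of the corpus contributed by the
   document's source repository.

Sums run over the unique original query terms present in the given
field of the document; features are computed from the original query,
not its expansion terms. The trainable re-rankers are a from-scratch
listwise coordinate-ascent linear model optimizing mean NDCG, and a
pointwise gradient-boosted-tree learner behind a registry of uniform
fit/score adapters. Either re-ranks a top-100 candidate list; the
output is always a permutation of the input.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .corpus_io import QrelsTable
from .index_core import FIELDS, WHOLE, FieldedIndex, EmptyIndexError
from .retrieval import (RankedList, RetrievalConfig, WeightedQuery,
                        bm25_term_field_score)

FEATURE_NAMES: tuple[str, ...] = (
    "BM25", "BM25Title", "BM25Text", "BM25Meta",
    "1GramTFTitle", "1GramTFText", "1GramTFMeta",
    "1GramIDFTitle", "1GramIDFText", "1GramIDFMeta",
    "1GramTFIDFTitle", "1GramTFIDFText", "1GramTFIDFMeta",
    "1GramTFWhole", "1GramIDFWhole", "1GramTFIDFWhole",
    "2GramsTitle", "2GramsText", "2GramsMeta", "2GramsWhole",
    "DistanceFromStart", "DomainWeight",
)

FEATURE_GROUPS: dict[int, tuple[str, ...]] = {
    1: ("BM25", "BM25Title", "BM25Text", "BM25Meta"),
    2: ("1GramTFTitle", "1GramTFText", "1GramTFMeta"),
    3: ("1GramIDFTitle", "1GramIDFText", "1GramIDFMeta"),
    4: ("1GramTFIDFTitle", "1GramTFIDFText", "1GramTFIDFMeta"),
    5: ("1GramTFWhole", "1GramIDFWhole", "1GramTFIDFWhole"),
    6: ("2GramsTitle", "2GramsText", "2GramsMeta", "2GramsWhole"),
    7: ("DistanceFromStart",),
    8: ("DomainWeight",),
}


def idf_feature(index: FieldedIndex, term: str, field: str) -> float:
    """Inverse document frequency ln(N / (n_i + 1)) + 1 in one field.

    Unseen terms get ln(N) + 1. The df = N edge case dips slightly
    below 1 and is accepted as written.
    """
    n = index.n_docs
    if n < 1:
        raise EmptyIndexError("idf undefined for an empty index")
    return math.log(n / (index.df(term, field) + 1)) + 1.0


def extract_features(index: FieldedIndex, query: WeightedQuery | Sequence[str],
                     docno: str,
                     cfg: RetrievalConfig | None = None) -> dict[str, float]:
    """The 22-feature vector for one query-document pair.

    ``query`` is a weighted query (its unique original-origin terms are
    used, in order) or an ordered token sequence. BM25 features reuse
    the retrieval scoring per field, unweighted.
    """
    cfg = cfg or RetrievalConfig()
    if docno not in index:
        raise KeyError(f"unknown docno {docno!r}")
    if isinstance(query, WeightedQuery):
        tokens = query.original_terms()
    else:
        tokens = list(dict.fromkeys(query))
    n = index.n_docs
    feats: dict[str, float] = {}

    field_key = {"title": "Title", "text": "Text", "metadata": "Meta", WHOLE: "Whole"}
    for f in FIELDS + (WHOLE,):
        bm25 = tf_sum = idf_sum = tfidf_sum = 0.0
        avg_len = index.avg_doc_length(f)
        for term in tokens:
            tf = index.tf(term, docno, f)
            if tf == 0:
                continue
            idf = idf_feature(index, term, f)
            tf_sum += tf
            idf_sum += idf
            tfidf_sum += tf * idf
            bm25 += bm25_term_field_score(
                tf, index.df(term, f), index.doc_len(docno, f),
                avg_len, n, cfg.k1, cfg.b,
            )
        key = field_key[f]
        feats["BM25" if f == WHOLE else f"BM25{key}"] = bm25
        if f == WHOLE:
            feats["1GramTFWhole"] = tf_sum
            feats["1GramIDFWhole"] = idf_sum
            feats["1GramTFIDFWhole"] = tfidf_sum
        else:
            feats[f"1GramTF{key}"] = tf_sum
            feats[f"1GramIDF{key}"] = idf_sum
            feats[f"1GramTFIDF{key}"] = tfidf_sum

    query_bigrams = set(zip(tokens, tokens[1:]))
    for f in FIELDS + (WHOLE,):
        shared = query_bigrams & index.bigram_set(docno, f)
        feats[f"2Grams{field_key[f]}"] = float(len(shared))

    firsts = index.first_positions(docno)
    positions = [firsts[t] for t in tokens if t in firsts]
    feats["DistanceFromStart"] = float(
        min(positions) if positions else index.doc_len(docno, "text")
    )
    feats["DomainWeight"] = index.domain_counts[index.repo_of[docno]] / n
    return {name: feats[name] for name in FEATURE_NAMES}


# -- feature table --------------------------------------------------------

class FeatureTable:
    """Feature vectors keyed by (qid, docno), in insertion order."""

    def __init__(self, feature_names: Sequence[str] = FEATURE_NAMES) -> None:
        self.feature_names = tuple(feature_names)
        self._rows: dict[str, dict[str, np.ndarray]] = {}

    def add(self, qid: str, docno: str,
            features: Mapping[str, float] | Sequence[float]) -> None:
        if isinstance(features, Mapping):
            vec = np.array([features[n] for n in self.feature_names], dtype=float)
        else:
            vec = np.asarray(features, dtype=float)
            if vec.shape != (len(self.feature_names),):
                raise ValueError("feature vector length mismatch")
        if not np.all(np.isfinite(vec)):
            raise ValueError(f"non-finite features for ({qid}, {docno})")
        self._rows.setdefault(qid, {})[docno] = vec

    @property
    def qids(self) -> list[str]:
        return list(self._rows)

    def docnos(self, qid: str) -> list[str]:
        return list(self._rows[qid])

    def vector(self, qid: str, docno: str) -> np.ndarray:
        return self._rows[qid][docno]

    def matrix(self, qid: str) -> np.ndarray:
        return np.vstack([self._rows[qid][d] for d in self._rows[qid]])

    def __contains__(self, key: tuple[str, str]) -> bool:
        qid, docno = key
        return qid in self._rows and docno in self._rows[qid]

    def subset_queries(self, qids: Iterable[str]) -> "FeatureTable":
        out = FeatureTable(self.feature_names)
        for qid in qids:
            for docno, vec in self._rows[qid].items():
                out.add(qid, docno, vec)
        return out

    def drop_features(self, names: Iterable[str]) -> "FeatureTable":
        drop = set(names)
        keep_idx = [i for i, n in enumerate(self.feature_names) if n not in drop]
        out = FeatureTable([self.feature_names[i] for i in keep_idx])
        for qid, docs in self._rows.items():
            for docno, vec in docs.items():
                out.add(qid, docno, vec[keep_idx])
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"qid": qid, "docno": docno,
             **dict(zip(self.feature_names, vec))}
            for qid, docs in self._rows.items() for docno, vec in docs.items()
        ]
        return pd.DataFrame(rows, columns=["qid", "docno", *self.feature_names])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FeatureTable":
        frame = pd.read_csv(path, sep="\t", dtype={"qid": str, "docno": str})
        names = [c for c in frame.columns if c not in ("qid", "docno")]
        table = cls(names)
        for row in frame.itertuples(index=False):
            table.add(str(row.qid), str(row.docno),
                      np.array(row[2:], dtype=float))
        return table

    def write_letor(self, qrels: QrelsTable, path: str | Path) -> None:
        """Write the de-facto LTR text format
        ``grade qid:<qid> 1:v ... 22:v # docno``."""
        with open(path, "w", encoding="utf-8") as out:
            for qid, docs in self._rows.items():
                for docno, vec in docs.items():
                    feats = " ".join(f"{i}:{v:g}" for i, v in enumerate(vec, 1))
                    out.write(f"{qrels.grade(qid, docno)} qid:{qid} {feats} # {docno}\n")


def extract_feature_table(index: FieldedIndex, queries: Mapping[str, WeightedQuery],
                          lists: Sequence[RankedList],
                          cfg: RetrievalConfig | None = None) -> FeatureTable:
    """Features for every document of every ranked list."""
    table = FeatureTable()
    for ranked in lists:
        wq = queries[ranked.qid]
        for docno, _ in ranked.items:
            table.add(ranked.qid, docno, extract_features(index, wq, docno, cfg))
    return table


# -- models ---------------------------------------------------------------

class RankModel(Protocol):
    """Uniform scorer contract used by :func:`rerank`."""

    def scores(self, matrix: np.ndarray) -> np.ndarray: ...


@dataclass
class LinearRankModel:
    """Linear scorer with one weight per feature."""

    weights: dict[str, float]
    metadata: dict = dc_field(default_factory=dict)

    def weight_vector(self, feature_names: Sequence[str]) -> np.ndarray:
        return np.array([self.weights[n] for n in feature_names])

    def scores(self, matrix: np.ndarray) -> np.ndarray:
        return matrix @ np.array(list(self.weights.values()))

    def save(self, path: str | Path) -> None:
        import json

        Path(path).write_text(json.dumps(
            {"weights": self.weights, "metadata": self.metadata}, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "LinearRankModel":
        import json

        obj = json.loads(Path(path).read_text())
        return cls(obj["weights"], obj.get("metadata", {}))


def _ndcg_from_order(grades_in_order: np.ndarray, idcg: float, k: int) -> float:
    if idcg <= 0:
        return 0.0
    top = grades_in_order[:k]
    discounts = np.log2(np.arange(2, len(top) + 2))
    return float((((2.0 ** top) - 1.0) / discounts).sum() / idcg)


def _mean_ndcg_for_weights(weights: np.ndarray, mats: list[np.ndarray],
                           grades: list[np.ndarray], idcgs: list[float],
                           k: int) -> float:
    total = 0.0
    for mat, grade, idcg in zip(mats, grades, idcgs):
        order = np.argsort(-(mat @ weights), kind="stable")
        total += _ndcg_from_order(grade[order], idcg, k)
    return total / len(mats)


def train_coordinate_ascent(features: FeatureTable, qrels: QrelsTable,
                            seed: int = 0, n_restarts: int = 5,
                            grid: Sequence[float] | None = None,
                            ndcg_k: int = 100,
                            max_sweeps: int = 50) -> LinearRankModel:
    """Listwise coordinate ascent maximizing mean training NDCG.

    Cyclic one-dimensional line search per weight over ``grid``
    (default 21 points in [-5, 5]); a move is accepted only if mean
    NDCG strictly increases; sweeps repeat until no weight changes.
    The best of ``n_restarts`` randomly initialized restarts is
    returned, with its accepted-NDCG trace (non-decreasing within a
    restart) in ``metadata``. Ties in the induced ranking keep the
    feature-table insertion order. Unjudged documents count grade 0.
    """
    qids = features.qids
    if len(qids) < 2:
        raise ValueError("need at least two training queries")
    grid_vals = list(grid) if grid is not None else list(np.linspace(-5.0, 5.0, 21))
    names = features.feature_names
    mats, grades, idcgs = [], [], []
    for qid in qids:
        mats.append(features.matrix(qid))
        grades.append(np.array([qrels.grade(qid, d) for d in features.docnos(qid)],
                               dtype=float))
        ideal = sorted(qrels.judged(qid).values(), reverse=True)[:ndcg_k]
        idcgs.append(sum((2.0 ** g - 1) / math.log2(r + 1)
                         for r, g in enumerate(ideal, start=1)))
    if all(idcg == 0 for idcg in idcgs) or all(len(set(g)) <= 1 for g in grades):
        warnings.warn("degenerate training data: all documents share one grade",
                      stacklevel=2)

    rng = np.random.default_rng(seed)
    best_weights: np.ndarray | None = None
    best_score = -math.inf
    best_trace: list[float] = []
    n_iterations = 0
    for _ in range(n_restarts):
        w = rng.uniform(-1.0, 1.0, size=len(names))
        score = _mean_ndcg_for_weights(w, mats, grades, idcgs, ndcg_k)
        trace = [score]
        for _sweep in range(max_sweeps):
            changed = False
            for j in range(len(names)):
                current = w[j]
                best_local = score
                best_val = current
                for val in grid_vals:
                    if val == current:
                        continue
                    w[j] = val
                    cand = _mean_ndcg_for_weights(w, mats, grades, idcgs, ndcg_k)
                    n_iterations += 1
                    if cand > best_local:
                        best_local, best_val = cand, val
                w[j] = best_val
                if best_local > score:
                    score = best_local
                    trace.append(score)
                    changed = True
            if not changed:
                break
        if score > best_score:
            best_score, best_weights, best_trace = score, w.copy(), trace
    assert best_weights is not None
    return LinearRankModel(
        dict(zip(names, map(float, best_weights))),
        metadata={
            "training_ndcg": best_score, "trace": best_trace, "seed": seed,
            "n_restarts": n_restarts, "iterations": n_iterations,
            "ndcg_k": ndcg_k,
        },
    )


def rerank(model: RankModel, ranked: RankedList,
           features: FeatureTable) -> RankedList:
    """Reorder a candidate list by model score (stable: ties keep the
    input rank). The output docno set always equals the input set."""
    if not ranked.items:
        return RankedList(ranked.qid, [])
    rows = []
    for docno, _ in ranked.items:
        if (ranked.qid, docno) not in features:
            raise KeyError(f"missing feature vector for docno {docno!r}")
        rows.append(features.vector(ranked.qid, docno))
    scores = np.asarray(model.scores(np.vstack(rows)), dtype=float)
    order = np.argsort(-scores, kind="stable")
    return RankedList(ranked.qid,
                      [(ranked.items[i][0], float(scores[i])) for i in order])


# -- ablation -------------------------------------------------------------

def ablate_groups(features: FeatureTable, qrels: QrelsTable, cv_plan,
                  seed: int = 0, ndcg_k: int = 100,
                  **train_kwargs) -> pd.DataFrame:
    """Mean held-out NDCG after omitting each feature group.

    Each of the 8 groups is dropped in turn and the coordinate-ascent
    model is retrained under the same CV plan and seed. The result is
    sorted ascending by NDCG, so the most important group (largest
    degradation when removed) comes first.
    """
    from .evaluation import run_cv

    rows = []
    for group, names in FEATURE_GROUPS.items():
        reduced = features.drop_features(names)

        def train_fn(train_qids: list[str]):
            return train_coordinate_ascent(
                reduced.subset_queries(train_qids), qrels,
                seed=seed, ndcg_k=ndcg_k, **train_kwargs)

        def eval_fn(model, test_qids: list[str]) -> dict[str, float]:
            out = {}
            for qid in test_qids:
                candidates = RankedList(qid, [(d, 0.0) for d in reduced.docnos(qid)])
                from .evaluation import ndcg as _ndcg

                out[qid] = _ndcg(rerank(model, candidates, reduced), qrels, ndcg_k)
            return out

        pooled = run_cv(cv_plan, train_fn, eval_fn)
        rows.append({"group": group, "omitted": ", ".join(names),
                     "mean_ndcg": sum(pooled.values()) / len(pooled)})
    frame = pd.DataFrame(rows).sort_values("mean_ndcg", kind="stable")
    return frame.reset_index(drop=True)


# -- external learner adapters -------------------------------------------

class TreeRankModel:
    """Pointwise gradient-boosted regression trees fit on grades."""

    def __init__(self, seed: int = 0, **params) -> None:
        from sklearn.ensemble import GradientBoostingRegressor

        defaults = {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1}
        defaults.update(params)
        self._model = GradientBoostingRegressor(random_state=seed, **defaults)

    def fit(self, features: FeatureTable, qrels: QrelsTable) -> "TreeRankModel":
        xs, ys = [], []
        for qid in features.qids:
            for docno in features.docnos(qid):
                xs.append(features.vector(qid, docno))
                ys.append(qrels.grade(qid, docno))
        self._model.fit(np.vstack(xs), np.array(ys, dtype=float))
        return self

    def scores(self, matrix: np.ndarray) -> np.ndarray:
        return self._model.predict(matrix)


def _fit_ca(features: FeatureTable, qrels: QrelsTable, seed: int,
            **params) -> LinearRankModel:
    return train_coordinate_ascent(features, qrels, seed=seed, **params)


def _fit_gbrt(features: FeatureTable, qrels: QrelsTable, seed: int,
              **params) -> TreeRankModel:
    return TreeRankModel(seed=seed, **params).fit(features, qrels)


#: Registered learners for :func:`external_learner_adapter`. ``gbrt``
#: (boosted regression trees) is the default MART-style analog.
LEARNERS: dict[str, Callable[..., RankModel]] = {
    "ca": _fit_ca,
    "gbrt": _fit_gbrt,
}


def external_learner_adapter(features: FeatureTable, qrels: QrelsTable,
                             spec: str | dict, seed: int = 0) -> RankModel:
    """Fit a registered learner under the uniform fit/score contract.

    ``spec`` is a learner name or ``{"name": ..., <params>}``. The
    returned model is usable by :func:`rerank` interchangeably with
    :class:`LinearRankModel`.
    """
    if isinstance(spec, str):
        name, params = spec, {}
    else:
        params = dict(spec)
        name = params.pop("name")
    if name not in LEARNERS:
        raise ValueError(
            f"unknown learner {name!r}; registered: {sorted(LEARNERS)}")
    return LEARNERS[name](features, qrels, seed=seed, **params)
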