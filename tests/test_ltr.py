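import math

import numpy as np
import pytest

import oracles
from dsearch.corpus_io import QrelsTable
from dsearch.index_core import build_index, tokenize
from dsearch.ltr import (FEATURE_GROUPS, FEATURE_NAMES, FeatureTable,
                         LinearRankModel, TreeRankModel, ablate_groups,
                         extract_features, external_learner_adapter,
                         idf_feature, rerank, train_coordinate_ascent)
from dsearch.evaluation import make_cv_plan
from dsearch.retrieval import RankedList, RetrievalConfig, WeightedQuery
from dsearch.synthdata import planted_linear_task


class TestIdfFeature:
    def test_hand_value(self):
        # ln(N / (n_i + 1)) + 1 with N=9, n_i=2 -> ln(3) + 1
        from dsearch.corpus_io import DatasetRecord

        records = [DatasetRecord(f"d{i}", "marker" if i < 2 else "x", "r", "y")
                   for i in range(9)]
        idx = build_index(records)
        assert idf_feature(idx, "marker", "title") == \
            pytest.approx(2.09861228866811, rel=1e-12)

    def test_ubiquitous_term_dips_below_one(self):
        # df = N makes ln(N/(N+1)) slightly negative
        from dsearch.corpus_io import DatasetRecord

        records = [DatasetRecord(f"d{i}", "common", "r", "") for i in range(50)]
        idx = build_index(records)
        value = idf_feature(idx, "common", "title")
        assert 0.9 < value < 1.0

    def test_monotone_decreasing_in_df(self, small_index):
        terms = sorted(small_index.postings["text"],
                       key=lambda t: small_index.df(t, "text"))
        rare, common = terms[0], terms[-1]
        assert small_index.df(rare, "text") < small_index.df(common, "text")
        assert idf_feature(small_index, rare, "text") > \
            idf_feature(small_index, common, "text")

    def test_unseen_term_value(self, tiny_index):
        n = tiny_index.n_docs
        assert idf_feature(tiny_index, "zebrafish", "title") == \
            pytest.approx(math.log(n) + 1)


class TestExtractFeatures:
    def test_feature_vector_is_complete_and_finite(self, tiny_index):
        wq = WeightedQuery.from_tokens("q", tokenize("gene expression"))
        feats = extract_features(tiny_index, wq, "d1")
        assert tuple(feats) == FEATURE_NAMES
        assert all(math.isfinite(v) for v in feats.values())

    def test_no_shared_terms_zeroes_match_features(self, tiny_index):
        feats = extract_features(tiny_index, ["zebrafish"], "d2")
        for name in FEATURE_NAMES:
            if name.startswith(("1Gram", "2Grams", "BM25")):
                assert feats[name] == 0.0
        assert feats["DistanceFromStart"] == tiny_index.doc_len("d2", "text")

    def test_hand_counted_distance_and_bigrams(self):
        from dsearch.corpus_io import DatasetRecord

        records = [DatasetRecord("A", "other", "r", "cell gene express data"),
                   DatasetRecord("B", "x", "r", "unrelated")]
        idx = build_index(records)
        feats = extract_features(idx, ["gene", "express"], "A")
        assert feats["DistanceFromStart"] == 1.0
        assert feats["2GramsText"] == 1.0  # shared bigram "gene express"
        assert feats["2GramsTitle"] == 0.0

    def test_domain_weight_is_repository_share(self, tiny_index):
        feats = extract_features(tiny_index, ["gene"], "d1")
        assert feats["DomainWeight"] == pytest.approx(3 / 5)  # geo has 3 of 5

    def test_sums_use_unique_matched_terms(self, tiny_index):
        once = extract_features(tiny_index, ["gene", "express"], "d1")
        dup = extract_features(tiny_index, ["gene", "express", "gene"], "d1")
        assert once == dup

    def test_agrees_with_single_pass_oracle(self, small_bundle, small_index):
        rng = np.random.default_rng(3)
        cfg = RetrievalConfig()
        docnos = [r.docno for r in small_bundle.records]
        for _ in range(20):
            query = small_bundle.queries[rng.integers(len(small_bundle.queries))]
            docno = docnos[rng.integers(len(docnos))]
            tokens = tokenize(query.raw_text)
            got = extract_features(small_index, tokens, docno, cfg)
            expected = oracles.brute_force_features(
                small_bundle.records, tokens, docno, cfg)
            for name in FEATURE_NAMES:
                assert got[name] == pytest.approx(expected[name], abs=1e-9), name


class TestFeatureTable:
    def test_tsv_round_trip(self, tmp_path, tiny_index):
        table = FeatureTable()
        wq = WeightedQuery.from_tokens("q1", tokenize("gene expression"))
        for docno in ("d1", "d3"):
            table.add("q1", docno, extract_features(tiny_index, wq, docno))
        table.write_tsv(tmp_path / "f.tsv")
        loaded = FeatureTable.read_tsv(tmp_path / "f.tsv")
        assert loaded.feature_names == table.feature_names
        np.testing.assert_allclose(loaded.matrix("q1"), table.matrix("q1"))

    def test_letor_format(self, tmp_path):
        table = FeatureTable(["f1", "f2"])
        table.add("q1", "d1", [1.0, 2.0])
        qrels = QrelsTable({("q1", "d1"): 2})
        table.write_letor(qrels, tmp_path / "letor.txt")
        line = (tmp_path / "letor.txt").read_text().strip()
        assert line == "2 qid:q1 1:1 2:2 # d1"

    def test_non_finite_features_rejected(self):
        table = FeatureTable(["f1"])
        with pytest.raises(ValueError):
            table.add("q1", "d1", [float("nan")])

    def test_drop_features_by_group(self):
        table = FeatureTable()
        table.add("q1", "d1", dict.fromkeys(FEATURE_NAMES, 1.0))
        reduced = table.drop_features(FEATURE_GROUPS[1])
        assert len(reduced.feature_names) == 18
        assert not set(FEATURE_GROUPS[1]) & set(reduced.feature_names)


class TestCoordinateAscent:
    def test_perfectly_separating_feature_reaches_ndcg_one(self):
        table = FeatureTable(["good", "noise"])
        qrels = QrelsTable()
        rng = np.random.default_rng(0)
        for qi in range(4):
            qid = f"q{qi}"
            for di, grade in enumerate([2, 1, 0, 0]):
                table.add(qid, f"{qid}d{di}", [float(grade), rng.normal()])
                qrels.add(qid, f"{qid}d{di}", grade)
        model = train_coordinate_ascent(table, qrels, seed=0, n_restarts=2)
        assert model.metadata["training_ndcg"] == pytest.approx(1.0)

    def test_trace_non_decreasing(self, ltr_outcome):
        assert ltr_outcome.trace_non_decreasing

    def test_learned_model_beats_uniform_on_heldout(self, ltr_outcome):
        assert ltr_outcome.learned_heldout_ndcg > ltr_outcome.uniform_heldout_ndcg

    def test_degenerate_grades_warn(self):
        table = FeatureTable(["f"])
        qrels = QrelsTable()
        for qi in range(2):
            for di in range(3):
                table.add(f"q{qi}", f"q{qi}d{di}", [float(di)])
                qrels.add(f"q{qi}", f"q{qi}d{di}", 1)
        with pytest.warns(UserWarning, match="degenerate"):
            train_coordinate_ascent(table, qrels, seed=0, n_restarts=1,
                                    max_sweeps=2)

    def test_needs_two_queries(self):
        table = FeatureTable(["f"])
        table.add("q1", "d1", [1.0])
        with pytest.raises(ValueError):
            train_coordinate_ascent(table, QrelsTable(), seed=0)


class TestRerank:
    @pytest.fixture
    def table_and_list(self):
        table = FeatureTable(["f1", "f2"])
        items = []
        rng = np.random.default_rng(5)
        for di in range(10):
            table.add("q1", f"d{di}", rng.normal(size=2))
            items.append((f"d{di}", 10.0 - di))
        return table, RankedList("q1", items)

    def test_output_is_permutation_of_input(self, table_and_list):
        table, ranked = table_and_list
        model = LinearRankModel({"f1": 2.0, "f2": -1.0})
        out = rerank(model, ranked, table)
        assert sorted(out.docnos) == sorted(ranked.docnos)
        assert len(out) == len(ranked)
        scores = [s for _, s in out.items]
        assert scores == sorted(scores, reverse=True)

    def test_zero_model_preserves_input_order(self, table_and_list):
        table, ranked = table_and_list
        out = rerank(LinearRankModel({"f1": 0.0, "f2": 0.0}), ranked, table)
        assert out.docnos == ranked.docnos

    def test_single_doc_unchanged(self, table_and_list):
        table, ranked = table_and_list
        single = RankedList("q1", ranked.items[:1])
        out = rerank(LinearRankModel({"f1": 1.0, "f2": 1.0}), single, table)
        assert out.docnos == single.docnos

    def test_missing_feature_vector_names_docno(self, table_and_list):
        table, ranked = table_and_list
        ranked.items.append(("dMissing", 0.0))
        with pytest.raises(KeyError, match="dMissing"):
            rerank(LinearRankModel({"f1": 1.0, "f2": 1.0}), ranked, table)


@pytest.fixture(scope="module")
def planted_group1_task():
    """Only the BM25 features (group 1) carry signal."""
    rng = np.random.default_rng(2)
    table = FeatureTable()
    qrels = QrelsTable()
    group1 = set(FEATURE_GROUPS[1])
    for qi in range(8):
        qid = f"q{qi}"
        for di in range(12):
            grade = int(di < 2) * 2 + int(2 <= di < 5)
            vec = {
                name: (3.0 * grade + rng.normal(scale=0.1)
                       if name in group1 else rng.normal())
                for name in FEATURE_NAMES
            }
            table.add(qid, f"{qid}d{di}", vec)
            qrels.add(qid, f"{qid}d{di}", grade)
    return table, qrels


class TestAblation:
    def test_eight_rows_sorted_ascending(self, planted_group1_task):
        table, qrels = planted_group1_task
        plan = make_cv_plan(table.qids, "kfold", k=2, seed=0)
        frame = ablate_groups(table, qrels, plan, seed=0, n_restarts=1,
                              max_sweeps=5)
        assert len(frame) == 8
        assert list(frame["mean_ndcg"]) == sorted(frame["mean_ndcg"])

    def test_planted_signal_group_ranks_first(self, planted_group1_task):
        table, qrels = planted_group1_task
        plan = make_cv_plan(table.qids, "kfold", k=2, seed=0)
        frame = ablate_groups(table, qrels, plan, seed=0, n_restarts=1,
                              max_sweeps=5)
        assert frame.iloc[0]["group"] == 1

    def test_null_group_omission_changes_nothing(self):
        # DomainWeight (group 8) all zero -> removing it is a no-op
        rng = np.random.default_rng(4)
        table = FeatureTable()
        qrels = QrelsTable()
        for qi in range(4):
            qid = f"q{qi}"
            for di in range(6):
                grade = int(di < 2)
                vec = {name: (2.0 * grade + rng.normal(scale=0.2)
                              if name == "BM25" else 0.0)
                       for name in FEATURE_NAMES}
                table.add(qid, f"{qid}d{di}", vec)
                qrels.add(qid, f"{qid}d{di}", grade)
        plan = make_cv_plan(table.qids, "kfold", k=2, seed=0)
        frame = ablate_groups(table, qrels, plan, seed=0, n_restarts=1,
                              max_sweeps=3)
        by_group = frame.set_index("group")["mean_ndcg"]
        full_equivalent = by_group[8]  # zero features removed
        assert by_group[6] == pytest.approx(full_equivalent)  # also all-zero


class TestLearnerAdapters:
    def test_unknown_learner_lists_registered(self):
        table, qrels, _ = planted_linear_task(4, 8, seed=0)
        with pytest.raises(ValueError, match="ca"):
            external_learner_adapter(table, qrels, "ranknet")

    def test_gbrt_deterministic_given_seed(self):
        table, qrels, _ = planted_linear_task(6, 10, seed=1)
        x = table.matrix(table.qids[0])
        a = external_learner_adapter(table, qrels, "gbrt", seed=3).scores(x)
        b = external_learner_adapter(table, qrels, "gbrt", seed=3).scores(x)
        np.testing.assert_array_equal(a, b)

    def test_tree_model_interchangeable_with_linear_in_rerank(self):
        table, qrels, _ = planted_linear_task(6, 10, seed=1)
        qid = table.qids[0]
        ranked = RankedList(qid, [(d, 0.0) for d in table.docnos(qid)])
        model = external_learner_adapter(table, qrels, "gbrt", seed=0)
        out = rerank(model, ranked, table)
        assert sorted(out.docnos) == sorted(ranked.docnos)

    def test_gbrt_beats_random_order_on_planted_task(self):
        from dsearch.evaluation import ndcg

        table, qrels, _ = planted_linear_task(10, 20, seed=2)
        train = table.subset_queries(table.qids[:7])
        model = external_learner_adapter(train, qrels, "gbrt", seed=0)
        rng = np.random.default_rng(0)
        learned, random_order = [], []
        for qid in table.qids[7:]:
            docs = table.docnos(qid)
            ranked = RankedList(qid, [(d, 0.0) for d in docs])
            learned.append(ndcg(rerank(model, ranked, table), qrels))
            shuffled = list(docs)
            rng.shuffle(shuffled)
            random_order.append(ndcg(RankedList(qid, [(d, 0.0) for d in shuffled]),
                                     qrels))
        assert np.mean(learned) >= np.mean(random_order)
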