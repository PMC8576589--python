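import numpy as np
import pytest

from confkg.ade import (ClassifierSpec, LabeledPair, LabeledTriple,
                        build_pair_features, build_triple_features,
                        compute_metrics, compute_occurrence_scores,
                        cross_dataset_eval, filter_missing, make_cv_splits,
                        per_side_effect_eval, polypharmacy_records,
                        read_pairs, read_triples, sample_negative_triples,
                        train_eval, write_pairs, write_triples)
from confkg.embeddings import EmbeddingTable


def table_of(ids, dim=4, seed=0):
    rng = np.random.default_rng(seed)
    return EmbeddingTable(list(ids), rng.normal(size=(len(ids), dim)))


class TestFilterMissing:
    def test_all_present_is_identity(self):
        pairs = [LabeledPair("D1", "Z1", 1), LabeledPair("D2", "Z2", -1)]
        table = table_of(["D1", "D2", "Z1", "Z2"])
        kept, removed = filter_missing(pairs, table)
        assert kept == pairs and removed == []

    def test_missing_drugs_removed_and_reported(self):
        pairs = [LabeledPair(f"D{i}", "Z", 1 if i % 2 else -1) for i in range(10)]
        table = table_of(["Z"] + [f"D{i}" for i in range(8)])
        kept, removed = filter_missing(pairs, table)
        assert len(kept) == 8
        assert removed == ["D8", "D9"]

    def test_empty_table_removes_all(self):
        pairs = [LabeledPair("D", "Z", 1)]
        kept, removed = filter_missing(pairs, table_of(["X"]))
        assert kept == [] and set(removed) == {"D", "Z"}


class TestFeatures:
    def test_pair_concatenation_order(self):
        table = EmbeddingTable.from_dict(
            {"drug": np.array([1.0, 0.0]), "disease": np.array([0.0, 2.0])}
        )
        feat = build_pair_features(table, LabeledPair("drug", "disease", 1))
        np.testing.assert_array_equal(feat, [1.0, 0.0, 0.0, 2.0])

    def test_pair_feature_is_order_sensitive(self):
        table = table_of(["A", "B"], dim=3)
        f_ab = build_pair_features(table, LabeledPair("A", "B", 1))
        f_ba = build_pair_features(table, LabeledPair("B", "A", 1))
        assert (f_ab != f_ba).any()

    def test_triple_feature_length_and_zeros(self):
        dim = 5
        table = EmbeddingTable(["d1", "d2", "se"], np.zeros((3, dim)))
        feat = build_triple_features(table, LabeledTriple("d1", "se", "d2", 1))
        assert feat.shape == (3 * dim,)
        assert not feat.any()


class TestCVSplits:
    def test_loo_yields_n_folds(self):
        # a 43-positive / 50-negative benchmark composition
        y = [1] * 43 + [-1] * 50
        folds = make_cv_splits(y, "LOO")
        assert len(folds) == 93
        assert all(len(test) == 1 for _, test in folds)

    def test_s5f_exactly_stratified(self):
        y = np.array([1] * 10 + [-1] * 10)
        folds = make_cv_splits(y, "S5F", seed=0)
        assert len(folds) == 5
        for _, test in folds:
            assert (y[test] == 1).sum() == 2
            assert (y[test] == -1).sum() == 2

    @pytest.mark.parametrize("scheme", ["LOO", "S5F"])
    def test_folds_partition_index_set(self, scheme):
        y = [1] * 12 + [-1] * 9
        folds = make_cv_splits(y, scheme, seed=1)
        tests = [set(test.tolist()) for _, test in folds]
        assert set().union(*tests) == set(range(21))
        assert sum(len(t) for t in tests) == 21
        for train, test in folds:
            assert set(train.tolist()) == set(range(21)) - set(test.tolist())

    def test_s5f_small_class_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            make_cv_splits([1] * 4 + [-1] * 10, "S5F")

    def test_s5f_proportionality_within_one(self):
        y = [1] * 17 + [-1] * 29
        for _, test in make_cv_splits(y, "S5F", seed=3):
            pos = sum(1 for i in test if y[i] == 1)
            assert abs(pos - 17 * len(test) / 46) <= 1


class TestNegativeTriples:
    def test_forced_last_candidate(self):
        drugs, ses = ["A", "B"], ["S"]
        known = []
        rng = np.random.default_rng(0)
        out = sample_negative_triples(known, 1, drugs, ses, rng)
        assert out == [LabeledTriple("A", "S", "B", 0)]

    def test_no_overlap_with_known_exhaustive(self):
        drugs = [f"D{i}" for i in range(12)]
        ses = [f"S{i}" for i in range(20)]
        rng = np.random.default_rng(1)
        known = [
            LabeledTriple(drugs[i], ses[j], drugs[i + 1], 1)
            for i in range(10) for j in range(5)
        ]
        out = sample_negative_triples(known, 1000, drugs, ses, rng)
        assert len(out) == 1000
        keys = {t.key for t in out}
        assert len(keys) == 1000
        assert not keys & {t.key for t in known}

    def test_infeasible_request_rejected(self):
        with pytest.raises(ValueError):
            sample_negative_triples([], 3, ["A", "B"], ["S"], np.random.default_rng(0))


class TestOccurrenceScores:
    def test_unique_pair_scores_one(self):
        t = [LabeledTriple("A", "S", "B", 1)]
        np.testing.assert_array_equal(compute_occurrence_scores(t), [1])

    def test_shared_pair_counts_all_side_effects(self):
        t = [LabeledTriple("A", f"S{i}", "B", 1) for i in range(3)]
        t.append(LabeledTriple("A", "S0", "C", 1))
        np.testing.assert_array_equal(compute_occurrence_scores(t), [3, 3, 3, 1])

    def test_permutation_invariant(self):
        t = [LabeledTriple("A", f"S{i}", "B", 1) for i in range(3)]
        rev = compute_occurrence_scores(t[::-1])
        np.testing.assert_array_equal(rev, compute_occurrence_scores(t)[::-1])

    def test_polypharmacy_records_convention(self):
        t = [LabeledTriple("A", f"S{i}", "B", 1) for i in range(3)]
        recs = polypharmacy_records(t)
        assert all(r.subject_score == 1.0 and r.object_score == 1.0 for r in recs)
        assert all(r.cooccurrence == 3 for r in recs)


class TestMetrics:
    def test_printed_toy_case_matches_brute_force(self):
        y = [1, 0, 1, 0]
        s = [0.9, 0.8, 0.7, 0.1]
        m = compute_metrics(y, s, threshold=0.5)
        # concordant-pair brute force
        pairs = [(i, j) for i in range(4) for j in range(4) if y[i] == 1 and y[j] == 0]
        conc = sum(s[i] > s[j] for i, j in pairs) / len(pairs)
        assert m["AUC"] == pytest.approx(conc) == pytest.approx(0.75)
        # confusion-matrix arithmetic at threshold 0.5: preds [1,1,1,0]
        assert m["F1"] == pytest.approx(0.8)

    def test_perfect_ranking(self):
        y = [1, 1, 0, 0]
        s = [0.9, 0.8, 0.2, 0.1]
        m = compute_metrics(y, s)
        assert m["AUC"] == m["AUPRC"] == m["AP@50"] == 1.0

    def test_reversed_scores_complement_auc(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.random(50)  # continuous, no ties
        a = compute_metrics(y, s)["AUC"]
        b = compute_metrics(y, -s)["AUC"]
        assert a + b == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([1, 1], [0.4, 0.6])

    def test_metrics_bounded(self):
        rng = np.random.default_rng(5)
        y = np.array([1] * 20 + [0] * 30)
        s = rng.random(50)
        m = compute_metrics(y, s)
        assert all(0.0 <= v <= 1.0 for v in m.values())


def _separable(n=40, dim=4, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, dim))
    y = np.where(X[:, 0] > 0, 1, -1)
    X[:, 0] += np.where(y > 0, 3.0, -3.0)
    return X, y


class TestTrainEval:
    @pytest.mark.parametrize("family", ["LR", "KNN", "RF"])
    def test_separable_data_is_perfect(self, family):
        X, y = _separable()
        folds = make_cv_splits(y, "S5F", seed=0)
        report = train_eval(X, y, ClassifierSpec(family), folds, seed=0)
        assert report.mean["F1"] == 1.0
        assert report.mean["AUC"] == 1.0

    def test_label_permutation_gives_chance_auc(self):
        rng = np.random.default_rng(0)
        X, y = _separable(n=60)
        aucs = []
        for rep in range(20):
            yp = rng.permutation(y)
            folds = make_cv_splits(yp, "S5F", seed=rep)
            report = train_eval(X, yp, ClassifierSpec("LR"), folds, seed=rep)
            aucs.append(report.mean["AUC"])
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_deterministic_report(self):
        X, y = _separable(seed=3)
        folds = make_cv_splits(y, "S5F", seed=1)
        r1 = train_eval(X, y, ClassifierSpec("RF"), folds, seed=1)
        r2 = train_eval(X, y, ClassifierSpec("RF"), folds, seed=1)
        assert r1.to_dict() == r2.to_dict()

    def test_single_class_training_fold_named(self):
        X = np.zeros((6, 2))
        y = [1, 1, 1, 1, 1, -1]
        folds = [(np.array([0, 1, 2]), np.array([3, 4, 5]))]
        with pytest.raises(ValueError, match="fold 0"):
            train_eval(X, y, ClassifierSpec("LR"), folds)

    def test_loo_reports_pooled_metrics(self):
        X, y = _separable(n=20)
        folds = make_cv_splits(y, "LOO")
        report = train_eval(X, y, ClassifierSpec("KNN"), folds)
        assert report.scheme == "LOO"
        assert report.sd["AUC"] == 0.0
        assert report.mean["AUC"] == 1.0

    def test_cross_dataset_protocol(self):
        X1, y1 = _separable(n=40, seed=0)
        X2, y2 = _separable(n=40, seed=7)
        report = cross_dataset_eval(X1, y1, X2, y2, ClassifierSpec("LR"), seed=0)
        assert report.scheme == "cross_dataset"
        assert len(report.per_fold) == 5
        assert report.mean["AUC"] > 0.9


class TestPerSideEffect:
    def test_groups_and_bounds(self):
        rng = np.random.default_rng(0)
        triples, y, s = [], [], []
        for se in ("S0", "S1"):
            for i in range(20):
                triples.append(LabeledTriple(f"A{i}", se, f"B{i}", 1))
                label = int(i < 10)
                y.append(label)
                s.append(label * 0.6 + rng.random() * 0.4)
        df = per_side_effect_eval(triples, y, s)
        assert set(df["side_effect"]) == {"S0", "S1"}
        assert ((df[["AUC", "AUPRC", "AP@50"]] >= 0).all() ).all()


class TestBenchmarkIO:
    def test_pair_round_trip(self, tmp_path):
        pairs = [LabeledPair("D1", "Z1", 1), LabeledPair("D2", "Z2", -1)]
        path = tmp_path / "pairs.csv"
        write_pairs(pairs, path)
        assert read_pairs(path) == pairs

    def test_triple_round_trip_canonicalizes(self, tmp_path):
        triples = [LabeledTriple("B", "S", "A", 1)]
        path = tmp_path / "triples.csv"
        write_triples(triples, path)
        back = read_triples(path)
        assert back[0].drug1_id == "A" and back[0].drug2_id == "B"
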