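import numpy as np
import pytest

from confkg.embeddings import EmbeddingTable
from confkg.transe import (TrainingTriplet, TransEParams, corrupt, energy,
                           margin_loss, mean_rank, train_transe,
                           training_triplets)
from confkg.io import build_graph
from confkg.weighting import score_graph

from conftest import random_triplet_kg


class TestEnergy:
    def test_perfect_translation_is_zero(self):
        h, l = np.array([1.0, 2.0]), np.array([0.5, -1.0])
        assert energy(h, l, h + l) == 0.0

    def test_hand_arithmetic(self):
        h, l, t = np.array([1.0, 0.0]), np.array([0.0, 1.0]), np.array([0.0, 0.0])
        assert energy(h, l, t, "L2") == pytest.approx(np.sqrt(2))
        assert energy(h, l, t, "L1") == pytest.approx(2.0)

    def test_nonnegative_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            h, l, t = rng.normal(size=(3, 5))
            assert energy(h, l, t) >= 0.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            energy(np.zeros(3), np.zeros(2), np.zeros(3))


class TestCorrupt:
    def test_exactly_one_side_replaced(self):
        pool = [f"E{i}" for i in range(10)]
        rng = np.random.default_rng(0)
        base = TrainingTriplet("E0", "r", "E1")
        head_replaced = 0
        for _ in range(10_000):
            c = corrupt(base, pool, rng)
            assert c.relation == "r"
            changed_head = c.head != base.head
            changed_tail = c.tail != base.tail
            assert changed_head != changed_tail  # exactly one
            head_replaced += changed_head
        assert head_replaced / 10_000 == pytest.approx(0.5, abs=0.02)

    def test_two_entity_pool_forced(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            c = corrupt(TrainingTriplet("A", "r", "B"), ["A", "B"], rng)
            assert (c.head, c.tail) in {("B", "B"), ("A", "A")}

    def test_singleton_pool_rejected(self):
        with pytest.raises(ValueError):
            corrupt(TrainingTriplet("A", "r", "B"), ["A"], np.random.default_rng(0))


def _plain_transe_loss(positives, negatives, ent, rel, margin, norm):
    """Independent unweighted reference: the textbook margin-ranking loss."""
    total = 0.0
    for pos, neg in zip(positives, negatives):
        d = energy(ent[pos.head], rel[pos.relation], ent[pos.tail], norm)
        dn = energy(ent[neg.head], rel[neg.relation], ent[neg.tail], norm)
        total += max(margin + d - dn, 0.0)
    return total


class TestMarginLoss:
    @pytest.fixture
    def tables(self):
        rng = np.random.default_rng(0)
        ent = EmbeddingTable([f"E{i}" for i in range(10)], rng.normal(size=(10, 4)))
        rel = EmbeddingTable(["r0", "r1"], rng.normal(size=(2, 4)))
        return ent, rel

    def test_hand_computed_weighted_case(self, tables):
        # gamma=1, d=0.5, f=0.5, d'=1 -> [1 + 1 - 1]_+ = 1, built from
        # vectors engineered to give those energies
        ent = EmbeddingTable.from_dict({
            "h": np.array([0.0, 0.0]), "t": np.array([0.5, 0.0]),
            "t2": np.array([1.0, 0.0]),
        })
        rel = EmbeddingTable.from_dict({"r": np.array([0.0, 0.0])})
        pos = [TrainingTriplet("h", "r", "t", confidence=0.5)]
        neg = [TrainingTriplet("h", "r", "t2")]
        loss = margin_loss(pos, neg, (ent, rel), TransEParams(margin=1.0, dimension=2))
        assert loss == pytest.approx(1.0, abs=1e-12)

    def test_inactive_hinge_is_zero(self, tables):
        ent = EmbeddingTable.from_dict({
            "h": np.array([0.0, 0.0]), "t": np.array([0.2, 0.0]),
            "t2": np.array([5.0, 0.0]),
        })
        rel = EmbeddingTable.from_dict({"r": np.array([0.0, 0.0])})
        pos = [TrainingTriplet("h", "r", "t", confidence=1.0)]
        neg = [TrainingTriplet("h", "r", "t2")]
        assert margin_loss(pos, neg, (ent, rel), TransEParams(margin=1.0)) == 0.0

    def test_zero_margin_boundary(self):
        ent = EmbeddingTable.from_dict({"h": np.array([0.0]), "t": np.array([1.0])})
        rel = EmbeddingTable.from_dict({"r": np.array([0.0])})
        pos = [TrainingTriplet("h", "r", "t", confidence=1.0)]
        neg = [TrainingTriplet("h", "r", "t")]
        with pytest.raises(ValueError):
            TransEParams(margin=0.0)  # margin must stay positive
        # boundary emulated with the smallest legal margin: d/f == d' gives loss == margin
        loss = margin_loss(pos, neg, (ent, rel), TransEParams(margin=1e-9))
        assert loss == pytest.approx(1e-9)

    @pytest.mark.parametrize("norm", ["L1", "L2"])
    def test_unit_confidence_equals_unweighted_bitwise(self, tables, norm):
        ent, rel = tables
        rng = np.random.default_rng(7)
        params = TransEParams(margin=1.0, norm=norm)
        for _ in range(100):
            idx = rng.integers(0, 10, size=(8, 4))
            rels = rng.integers(0, 2, size=8)
            pos = [
                TrainingTriplet(f"E{a}", f"r{r}", f"E{b}", confidence=1.0)
                for (a, b, *_), r in zip(idx, rels)
            ]
            neg = [
                TrainingTriplet(f"E{c}", f"r{r}", f"E{d}")
                for (_, _, c, d), r in zip(idx, rels)
            ]
            weighted = margin_loss(pos, neg, (ent, rel), params)
            reference = _plain_transe_loss(pos, neg, ent, rel, 1.0, norm)
            assert weighted == reference  # bit-for-bit

    def test_lowering_confidence_weakly_increases_loss(self, tables):
        ent, rel = tables
        pos_hi = [TrainingTriplet("E0", "r0", "E1", confidence=1.0)]
        pos_lo = [TrainingTriplet("E0", "r0", "E1", confidence=0.2)]
        neg = [TrainingTriplet("E2", "r0", "E1")]
        params = TransEParams(margin=1.0)
        assert margin_loss(pos_lo, neg, (ent, rel), params) >= margin_loss(
            pos_hi, neg, (ent, rel), params
        )

    def test_misaligned_lists_rejected(self, tables):
        pos = [TrainingTriplet("E0", "r0", "E1")]
        with pytest.raises(ValueError):
            margin_loss(pos, [], tables, TransEParams())


class TestTrainTransE:
    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_transe([], TransEParams())

    def test_loss_decreases_and_norms_unit(self):
        _, _, trips = random_triplet_kg(0)
        model = train_transe(
            trips, TransEParams(dimension=16, epochs=50, alpha=0.01, batch_size=16, seed=0)
        )
        assert model.loss_history[-1] < model.loss_history[0]
        norms = np.linalg.norm(model.entity_table.matrix, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-6)

    def test_deterministic_given_seed(self):
        _, _, trips = random_triplet_kg(1)
        p = TransEParams(dimension=8, epochs=10, alpha=0.01, batch_size=16, seed=4)
        m1, m2 = train_transe(trips, p), train_transe(trips, p)
        np.testing.assert_array_equal(m1.entity_table.matrix, m2.entity_table.matrix)
        assert m1.loss_history == m2.loss_history

    def test_trained_rank_beats_untrained(self):
        _, _, trips = random_triplet_kg(2)
        model = train_transe(
            trips, TransEParams(dimension=16, epochs=100, alpha=0.01, batch_size=16, seed=0)
        )
        rng = np.random.default_rng(99)
        ents = model.entity_table.tokens
        E0 = rng.normal(size=(len(ents), 16))
        E0 /= np.linalg.norm(E0, axis=1, keepdims=True)
        base = mean_rank(trips, EmbeddingTable(ents, E0), model.relation_table)
        assert mean_rank(trips, *model) < base


class TestTrainingTriplets:
    def test_confidence_defaults_to_one_without_scores(self, toy_graph):
        trips = training_triplets(toy_graph)
        assert all(t.confidence == 1.0 for t in trips)
        assert len(trips) == toy_graph.num_triplets

    def test_scores_map_to_clipped_confidences(self, toy_records):
        g = build_graph(toy_records)
        scores = score_graph(g)
        trips = training_triplets(g, scores, f_min=1e-3)
        for t, rec in zip(trips, g.records):
            expected = max(scores[rec.key].normalized, 1e-3)
            assert t.confidence == pytest.approx(expected)
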