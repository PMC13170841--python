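"""Scoring-function algebra, training determinism, filtered evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cmkg.embeddings import (
    EmbeddingTable,
    TrainConfig,
    evaluate_filtered,
    sample_negatives,
    score_complex,
    score_distmult,
    score_rotate,
    score_transe,
    split_triples,
    train,
)
from cmkg.embeddings import _init_table
from cmkg.errors import CMKGError, ConstraintError, ShapeError
from cmkg.synth import generate_antisymmetric_kg

from conftest import make_store

vec = arrays(np.float64, 4, elements=st.floats(-3, 3, allow_nan=False))


class TestScoringFunctions:
    def test_transe_perfect_translation_scores_zero(self):
        h, r = np.array([1.0, 2.0]), np.array([0.5, -1.0])
        assert score_transe(h, r, h + r) == 0.0

    def test_transe_hand_norm(self):
        assert score_transe([1, 0], [0, 1], [0, 0]) == pytest.approx(-np.sqrt(2))
        assert score_transe([1, 0], [0, 1], [0, 0], norm="L1") == -2.0

    def test_transe_translation_invariance(self):
        h, r, t, c = (np.array(x, dtype=float) for x in ([1, 2], [3, 4], [0, 1], [7, -2]))
        assert score_transe(h + c, r, t + c) == pytest.approx(score_transe(h, r, t))

    def test_distmult_hand_sum(self):
        assert score_distmult([1, 2], [1, 1], [3, 1]) == 5.0
        assert score_distmult([1, 2], [0, 0], [3, 1]) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(vec, vec, vec)
    def test_distmult_symmetry_exact(self, h, r, t):
        assert score_distmult(h, r, t) == score_distmult(t, r, h)

    @settings(max_examples=50, deadline=None)
    @given(vec, vec, vec)
    def test_complex_reduces_to_distmult_on_real_vectors(self, h, r, t):
        assert score_complex(h + 0j, r + 0j, t + 0j) == pytest.approx(
            score_distmult(h, r, t), abs=1e-12
        )

    def test_complex_hand_product(self):
        assert score_complex([1 + 0j], [1j], [1j]) == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None)
    @given(vec, vec, vec)
    def test_complex_antisymmetric_under_imaginary_relation(self, h, r, t):
        ri = 1j * r
        assert score_complex(h + 0j, ri, t + 0j) == pytest.approx(
            -score_complex(t + 0j, ri, h + 0j), abs=1e-9
        )

    def test_rotate_exact_rotation_scores_zero(self):
        h = np.array([1 + 2j, 0.5 - 1j])
        r = np.exp(1j * np.array([0.3, -1.2]))
        assert score_rotate(h, r, h * r) == pytest.approx(0.0, abs=1e-12)

    def test_rotate_identity_rotation_is_distance(self):
        h, t = np.array([1 + 1j, 2 + 0j]), np.array([0 + 1j, 1 + 0j])
        ones = np.ones(2, dtype=complex)
        assert score_rotate(h, ones, t) == pytest.approx(-np.sqrt(np.sum(np.abs(h - t) ** 2)))

    def test_rotate_quarter_turn_hand_case(self):
        assert score_rotate([1 + 0j], [1j], [1j]) == pytest.approx(0.0)

    def test_rotate_rejects_non_unit_modulus(self):
        with pytest.raises(ConstraintError):
            score_rotate([1 + 0j], [2 + 0j], [1j])

    @pytest.mark.parametrize("fn", [score_transe, score_distmult, score_complex])
    def test_dimension_mismatch_raises(self, fn):
        with pytest.raises(ShapeError):
            fn([1.0, 2.0], [1.0], [1.0, 2.0])


@pytest.fixture(scope="module")
def ring_store():
    return generate_antisymmetric_kg(n_entities=20, offsets=(1, 3))


class TestNegativeSampling:
    def test_corruptions_differ_in_exactly_one_slot(self, ring_store):
        triple = ring_store.triples[0]
        negs = sample_negatives(triple, 200, ring_store, seed=0)
        assert len(negs) == 200
        for n in negs:
            same_head = n.head_id == triple.head_id
            same_tail = n.tail_id == triple.tail_id
            assert n.relation == triple.relation
            assert same_head != same_tail or (same_head and not same_tail)
            assert same_head + same_tail == 1

    def test_deterministic_given_seed(self, ring_store):
        t = ring_store.triples[3]
        assert sample_negatives(t, 50, ring_store, seed=9) == sample_negatives(
            t, 50, ring_store, seed=9
        )

    def test_two_entity_store_always_takes_other_entity(self):
        store = make_store([("A", "Gene"), ("B", "Gene")], [("A", "experiments", "B")])
        for n in sample_negatives(store.triples[0], 30, store, seed=1):
            # head corruption must yield B, tail corruption must yield A
            assert n in (
                type(n)("B", "experiments", "B", "negative"),
                type(n)("A", "experiments", "A", "negative"),
            )

    def test_nonpositive_count_rejected(self, ring_store):
        with pytest.raises(CMKGError):
            sample_negatives(ring_store.triples[0], 0, ring_store)


class TestTraining:
    CFG = dict(dimension=16, batch_size=32, negatives_per_positive=8, learning_rate=1.0)

    def test_zero_epochs_returns_seeded_initialization(self, ring_store):
        cfg = TrainConfig(epochs=0, seed=5, **self.CFG)
        table, trace = train(ring_store, "complEx", cfg)
        init = _init_table(ring_store, "complEx", cfg)
        assert trace == []
        np.testing.assert_array_equal(table.entity_vecs, init.entity_vecs)

    def test_same_seed_gives_identical_loss_trace(self, ring_store):
        cfg = TrainConfig(epochs=4, seed=5, **self.CFG)
        _, t1 = train(ring_store, "transE", cfg)
        _, t2 = train(ring_store, "transE", cfg)
        assert t1 == t2

    def test_training_improves_planted_bijection_rank(self, ring_store):
        """On a graph whose relations are bijections, trained embeddings must
        rank true tails far better than the random initialization."""
        cfg = TrainConfig(epochs=60, seed=7, **self.CFG)
        trained, _ = train(ring_store, "complEx", cfg)
        untrained = _init_table(ring_store, "complEx", cfg)
        test = ring_store.triples[:20]

        def mean_rank(table):
            res = evaluate_filtered(table, test, ring_store)
            return res.mrr

        assert mean_rank(trained) > 2 * mean_rank(untrained)

    def test_rotate_phases_stay_unit_modulus(self, ring_store):
        cfg = TrainConfig(epochs=3, seed=2, **self.CFG)
        table, _ = train(ring_store, "rotatE", cfg)
        mods = np.abs(table._complex_relations())
        np.testing.assert_allclose(mods, 1.0, atol=1e-9)

    def test_loss_trace_has_epoch_per_entry(self, ring_store):
        cfg = TrainConfig(epochs=5, seed=3, **self.CFG)
        _, trace = train(ring_store, "distMult", cfg)
        assert len(trace) == 5 and all(np.isfinite(x) for x in trace)

    def test_checkpoint_round_trip(self, ring_store, tmp_path):
        cfg = TrainConfig(epochs=2, seed=3, **self.CFG)
        table, _ = train(ring_store, "rotatE", cfg)
        table.save(tmp_path / "ckpt")
        back = EmbeddingTable.load(tmp_path / "ckpt")
        np.testing.assert_array_equal(back.entity_vecs, table.entity_vecs)
        assert back.model_kind == "rotatE" and back.relation_ids == table.relation_ids


class TestSplit:
    def test_fractions_and_determinism(self, ring_store):
        tr, va, te = split_triples(ring_store, seed=1)
        assert len(tr) + len(va) + len(te) == len(ring_store)
        assert abs(len(tr) - 0.9 * len(ring_store)) <= 1
        tr2, _, _ = split_triples(ring_store, seed=1)
        assert tr == tr2

    def test_bad_fractions_rejected(self, ring_store):
        with pytest.raises(CMKGError):
            split_triples(ring_store, fractions=(0.8, 0.1, 0.2))


class _OracleTable(EmbeddingTable):
    """Scores known-true triples strictly highest, everything else by a fixed
    pseudo-random key — used to pin down the ranking protocol itself."""

    def __init__(self, store):
        ids = sorted(store.entities)
        rels = sorted(store.relation_vocabulary)
        super().__init__(
            "distMult", 2, ids, rels,
            np.zeros((len(ids), 2)), np.zeros((len(rels), 2)),
        )
        self._store = store

    def score_triples(self, h_idx, r_idx, t_idx):
        h_idx, r_idx, t_idx = np.broadcast_arrays(h_idx, r_idx, t_idx)
        out = np.empty(h_idx.shape)
        for pos in np.ndindex(h_idx.shape):
            key = (
                self.entity_ids[h_idx[pos]],
                self.relation_ids[r_idx[pos]],
                self.entity_ids[t_idx[pos]],
            )
            out[pos] = 100.0 if key in self._store else (hash(key) % 997) / 1000.0
        return out


class TestFilteredEvaluation:
    def test_oracle_model_achieves_perfect_metrics(self):
        store = make_store(
            [(f"G{i}", "Gene") for i in range(8)],
            [(f"G{i}", "experiments", f"G{(i+1) % 8}") for i in range(8)],
        )
        res = evaluate_filtered(_OracleTable(store), store.triples, store)
        assert res.mrr == 1.0 and res.hits_at[1] == 1.0

    def test_ranks_match_brute_force_sort(self, ring_store):
        cfg = TrainConfig(epochs=2, seed=11, **TestTraining.CFG)
        table, _ = train(ring_store, "complEx", cfg)
        test = ring_store.triples[:10]
        res = evaluate_filtered(table, test, ring_store, ks=(1, 3, 10))

        known = {(t.head_id, t.relation, t.tail_id) for t in ring_store.triples}
        inv_ranks = []
        for tr in test:
            for slot in ("tail", "head"):
                scored = []
                for cand in table.entity_ids:
                    key = (
                        (tr.head_id, tr.relation, cand)
                        if slot == "tail"
                        else (cand, tr.relation, tr.tail_id)
                    )
                    truth = cand == (tr.tail_id if slot == "tail" else tr.head_id)
                    if key in known and not truth:
                        continue
                    scored.append((table.score(*key), truth))
                s_true = [s for s, truth in scored if truth][0]
                higher = sum(1 for s, _ in scored if s > s_true)
                ties = sum(1 for s, _ in scored if s == s_true)
                inv_ranks.append(1.0 / (higher + (ties + 1) / 2))
        assert res.mrr == pytest.approx(np.mean(inv_ranks), abs=1e-12)

    def test_filtered_mrr_at_least_raw(self, ring_store):
        cfg = TrainConfig(epochs=4, seed=13, **TestTraining.CFG)
        table, _ = train(ring_store, "complEx", cfg)
        test = ring_store.triples[:15]
        filt = evaluate_filtered(table, test, ring_store, filtered=True)
        raw = evaluate_filtered(table, test, ring_store, filtered=False)
        assert filt.mrr >= raw.mrr - 1e-12

    def test_hits_monotone_and_bound_mrr(self, ring_store):
        cfg = TrainConfig(epochs=4, seed=13, **TestTraining.CFG)
        table, _ = train(ring_store, "distMult", cfg)
        res = evaluate_filtered(table, ring_store.triples[:15], ring_store)
        assert res.hits_at[1] <= res.hits_at[3] <= res.hits_at[10]
        assert res.hits_at[1] <= res.mrr <= 1.0

    def test_empty_test_set_rejected(self, ring_store):
        table = _init_table(ring_store, "distMult", TrainConfig(epochs=0, **TestTraining.CFG))
        with pytest.raises(CMKGError):
            evaluate_filtered(table, [], ring_store)
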