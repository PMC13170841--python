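"""Unified path scoring: components, DFS enumeration, hybrid ranking."""

import math
from dataclasses import replace

import networkx as nx
import numpy as np
import pytest

from cmkg.errors import CMKGError, ConfigurationError
from cmkg.paths import (
    IngredientFrequencyIndex,
    MechanisticPath,
    ScoringConfig,
    base_score,
    bonus,
    decay,
    dfs_paths,
    effective_confidence,
    entity_weight,
    isi_factor,
    isi_weight,
    rank_paths,
    relation_weight,
    score_path,
)

from conftest import make_store


def chain4_path():
    return MechanisticPath(
        ("H1", "G1", "G2", "G3", "D1"),
        ("act_on", "synergizewith", "synergizewith", "act in pathway"),
    )


class TestComponentWeights:
    @pytest.mark.parametrize(
        "relation,types,expected",
        [
            ("experiments", ("Gene", "Gene"), 1.0),
            ("experiments_transferred", ("Gene", "Gene"), 1.0),
            ("synergizewith", ("Gene", "Gene"), 0.9),
            ("act_on", ("Herb", "Gene"), 0.7),
            ("dysregulate", ("Gene", "DiseaseMM"), 0.7),
        ],
    )
    def test_relation_weight_tiers(self, relation, types, expected):
        assert relation_weight(relation, types) == expected

    def test_entity_weight_tiers(self):
        idx = IngredientFrequencyIndex(100, {"I1": 9})
        assert entity_weight("G1", "Gene") == 1.0
        assert entity_weight("D1", "DiseaseMM") == 0.7
        assert entity_weight("I1", "Ingredient", index=idx) == pytest.approx(0.5)

    def test_isi_anchors(self, config):
        assert isi_weight(1.0, IngredientFrequencyIndex(50, {}), "new") == 1.0
        assert isi_weight(1.0, IngredientFrequencyIndex(100, {"i": 9}), "i") == pytest.approx(0.5)
        assert isi_weight(1.0, IngredientFrequencyIndex(100, {"i": 99}), "i") == pytest.approx(0.01)

    def test_isi_monotone_and_bounded(self, config):
        idx_n = 200
        factors = [
            isi_factor(IngredientFrequencyIndex(idx_n, {"i": df}), "i", config)
            for df in range(idx_n)
        ]
        assert all(a >= b for a, b in zip(factors, factors[1:]))
        assert all(config.isi_floor <= f <= 1.0 for f in factors)

    def test_isi_requires_two_herbs(self, config):
        with pytest.raises(ConfigurationError):
            isi_factor(IngredientFrequencyIndex(1, {}), "i", config)

    @pytest.mark.parametrize("length,expected", [(1, 1.0), (2, 1.0), (3, 0.9), (4, 0.81)])
    def test_decay_schedule(self, length, expected):
        assert decay(length) == pytest.approx(expected)

    def test_decay_out_of_range(self):
        with pytest.raises(CMKGError):
            decay(5)

    def test_effective_confidence_clamps(self, chain4_store, config):
        p = chain4_path()
        rule = replace_origin(p, "Rule", 0.75)
        assert effective_confidence(rule, 0.9, config) == 0.75
        assert effective_confidence(replace_origin(p, "Rule", 1.3), 0.9, config) == 1.0
        assert effective_confidence(p, 0.7260, config) == pytest.approx(0.14520)
        with pytest.raises(CMKGError):
            effective_confidence(replace_origin(p, "Rule", None), 0.9, config)


def replace_origin(p, origin, c_rule):
    return MechanisticPath(p.nodes, p.relations, origin=origin, c_rule=c_rule)


class TestBonus:
    def test_no_trigger_path_gets_unity(self):
        store = make_store(
            [("H1", "Herb"), ("S1", "SymptomTCM"), ("D1", "DiseaseMM")],
            [("H1", "is_associated_with", "S1"), ("S1", "is_associated_with", "D1")],
        )
        p = MechanisticPath(("H1", "S1", "D1"), ("is_associated_with",) * 2)
        assert bonus(p, store) == 1.0

    def test_gene_node_triggers_structural_tier(self, chain4_store):
        p = MechanisticPath(("H1", "G1", "D1"), ("act_on", "dysregulate"))
        assert bonus(p, chain4_store) == 1.2

    def test_gene_plus_evidence_capped(self):
        store = make_store(
            [("H1", "Herb"), ("G1", "Gene"), ("G2", "Gene"), ("D1", "DiseaseMM")],
            [("H1", "act_on", "G1"), ("G1", "experiments", "G2"), ("G2", "dysregulate", "D1")],
        )
        p = MechanisticPath(("H1", "G1", "G2", "D1"), ("act_on", "experiments", "dysregulate"))
        assert bonus(p, store) == pytest.approx(1.8)  # min(cap, 1.2 * 1.5)

    def test_specific_but_not_ubiquitous_ingredient_triggers(self):
        store = make_store(
            [("H1", "Herb"), ("I1", "Ingredient"), ("I2", "Ingredient"), ("D1", "DiseaseMM")],
            [("H1", "includes", "I1"), ("I1", "act_on", "D1")],
        )
        idx = IngredientFrequencyIndex(100, {"I1": 0, "I2": 99})
        rare = MechanisticPath(("H1", "I1", "D1"), ("act_on", "act_on"))
        ubiq = MechanisticPath(("H1", "I2", "D1"), ("act_on", "act_on"))
        assert bonus(rare, store, index=idx) == 1.2
        assert bonus(ubiq, store, index=idx) == 1.0


class TestScorePath:
    def test_neutral_configuration_scores_one(self):
        store = make_store(
            [("H1", "Herb"), ("G1", "Gene"), ("C1", "Compound")],
            [("H1", "act_on", "G1"), ("G1", "bind", "C1")],
        )
        cfg = ScoringConfig(
            w_base=1.0, other_gene_gene_weight=1.0, lambda_dfs=1.0,
            bonus_structural=1.0, bonus_evidence=1.0, bonus_cap=1.0,
        )
        p = MechanisticPath(("H1", "G1", "C1"), ("act_on", "bind"))
        b = score_path(p, store, cfg)
        assert (b.base_score, b.decay, b.c_effective, b.bonus, b.final_score) == (1.0,) * 5

    def test_hand_worked_four_hop_chain(self, chain4_store, config):
        b = score_path(chain4_path(), chain4_store, config)
        assert round(b.base_score, 4) == 0.7260
        assert b.decay == pytest.approx(0.81)
        assert round(b.c_effective, 4) == 0.1452
        assert b.bonus == 1.2
        assert round(b.final_score, 4) == 0.1025

    def test_random_paths_match_log_domain_oracle(self, synth_store, synth_index, config):
        rng = np.random.default_rng(5)
        paths = _random_paths(synth_store, rng, n=300)
        for p in paths:
            b = score_path(p, synth_store, config, synth_index)
            logs = []
            for i in range(p.length):
                tp = (synth_store.entity_type(p.nodes[i]), synth_store.entity_type(p.nodes[i + 1]))
                logs.append(math.log(relation_weight(p.relations[i], tp, config)))
                logs.append(math.log(entity_weight(p.nodes[i + 1], tp[1], config, synth_index)))
            assert b.base_score == pytest.approx(math.exp(sum(logs) / p.length), abs=1e-12)
            assert b.final_score == pytest.approx(
                b.base_score * b.decay * b.c_effective * b.bonus, abs=1e-12
            )
            assert 0.0 < b.final_score <= config.bonus_cap

    def test_scores_invariant_under_entity_renaming(self, synth_store, synth_index, config):
        rng = np.random.default_rng(6)
        mapping = {e: f"N{i:05d}" for i, e in enumerate(sorted(synth_store.entities))}
        from cmkg.kg_core import apply_id_mapping

        renamed_store = apply_id_mapping(synth_store, mapping)
        renamed_index = IngredientFrequencyIndex(
            synth_index.n_herbs, {mapping[k]: v for k, v in synth_index.df.items()}
        )
        for p in _random_paths(synth_store, rng, n=40):
            q = MechanisticPath(tuple(mapping[n] for n in p.nodes), p.relations, p.origin, p.c_rule)
            a = score_path(p, synth_store, config, synth_index).final_score
            b = score_path(q, renamed_store, config, renamed_index).final_score
            assert a == pytest.approx(b, abs=1e-14)

    def test_dfs_score_monotone_in_lambda(self, chain4_store):
        p = chain4_path()
        scores = [
            score_path(p, chain4_store, ScoringConfig(lambda_dfs=lam)).final_score
            for lam in (0.05, 0.2, 0.5, 1.0)
        ]
        assert scores == sorted(scores)

    def test_isi_floor_one_erases_df_sensitivity(self, synth_store, synth_index):
        cfg = ScoringConfig(isi_floor=1.0)
        for ing, df in list(synth_index.df.items())[:5]:
            assert isi_factor(synth_index, ing, cfg) == 1.0


def _random_paths(store, rng, n):
    """Random walks over the store's edges, labelled as DFS or rule paths."""
    out = []
    triples = store.triples
    while len(out) < n:
        t0 = triples[rng.integers(len(triples))]
        nodes, rels = [t0.head_id, t0.tail_id], [t0.relation]
        for _ in range(int(rng.integers(0, 3))):
            nxt = [t for t in store.out_triples(nodes[-1]) if t.tail_id not in nodes]
            if not nxt:
                break
            t = nxt[rng.integers(len(nxt))]
            nodes.append(t.tail_id)
            rels.append(t.relation)
        origin = "Rule" if rng.random() < 0.4 else "DFS"
        c_rule = float(rng.uniform(0.05, 1.0)) if origin == "Rule" else None
        out.append(MechanisticPath(tuple(nodes), tuple(rels), origin, c_rule))
    return out


class TestDfsEnumeration:
    def test_direct_edge_single_path(self):
        store = make_store(
            [("A", "Herb"), ("B", "DiseaseMM")], [("A", "treat", "B")]
        )
        paths = dfs_paths(store, "A", "B")
        assert len(paths) == 1 and paths[0].length == 1

    def test_disconnected_pair_empty(self):
        store = make_store([("A", "Herb"), ("B", "DiseaseMM"), ("C", "Gene")], [("A", "act_on", "C")])
        assert dfs_paths(store, "A", "B") == []

    def test_matches_networkx_enumeration(self, config):
        rng = np.random.default_rng(17)
        n = 25
        ents = [(f"E{i:02d}", "Gene") for i in range(n)]
        triples = set()
        while len(triples) < 70:
            a, b = rng.integers(n, size=2)
            if a != b:
                triples.add((f"E{a:02d}", "experiments", f"E{b:02d}"))
        store = make_store(ents, sorted(triples))
        g = nx.MultiDiGraph()
        for h, r, t in sorted(triples):
            g.add_edge(h, t, relation=r)
            g.add_edge(t, h, relation=r)  # 'experiments' is symmetric in config
        mine = {
            (p.nodes, p.relations) for p in dfs_paths(store, "E00", "E01", config)
        }
        theirs = set()
        for ep in nx.all_simple_edge_paths(g, "E00", "E01", cutoff=config.max_hops):
            nodes = tuple([ep[0][0]] + [e[1] for e in ep])
            rels = tuple(g.edges[e]["relation"] for e in ep)
            theirs.add((nodes, rels))
        assert mine == theirs

    def test_deterministic_order(self, synth_store, synth_manifest, config):
        src = synth_manifest["planted_paths"][0]["nodes"][0]
        dst = synth_manifest["target_disease"]
        a = dfs_paths(synth_store, src, dst, config)
        b = dfs_paths(synth_store, src, dst, config)
        assert [(p.nodes, p.relations) for p in a] == [(p.nodes, p.relations) for p in b]

    def test_source_equal_target_rejected(self, synth_store):
        with pytest.raises(CMKGError):
            dfs_paths(synth_store, "HEB0001", "HEB0001")


class TestRankPaths:
    def test_rule_path_with_higher_score_ranks_first(self, chain4_store, config):
        dfs = MechanisticPath(("H1", "G1", "D1"), ("act_on", "dysregulate"))
        rule = replace_origin(dfs, "Rule", 0.9)
        two_hop = make_store(
            [("H1", "Herb"), ("G1", "Gene"), ("D1", "DiseaseMM")],
            [("H1", "act_on", "G1"), ("G1", "dysregulate", "D1")],
        )
        ranked = rank_paths([rule], [], two_hop, config, k=5)
        dfs_only = rank_paths([], [dfs], two_hop, config, k=5)
        assert ranked[0][1].final_score > dfs_only[0][1].final_score

    def test_duplicate_signature_keeps_rule_origin(self, config):
        store = make_store(
            [("H1", "Herb"), ("G1", "Gene"), ("D1", "DiseaseMM")],
            [("H1", "act_on", "G1"), ("G1", "dysregulate", "D1")],
        )
        p = MechanisticPath(("H1", "G1", "D1"), ("act_on", "dysregulate"))
        ranked = rank_paths([replace_origin(p, "Rule", 0.8)], [p], store, config, k=5)
        assert len(ranked) == 1 and ranked[0][0].origin == "Rule"

    def test_matches_brute_force_sort(self, synth_store, synth_index, config):
        rng = np.random.default_rng(9)
        pool = _random_paths(synth_store, rng, n=60)
        rules = [p for p in pool if p.origin == "Rule"]
        dfs = [p for p in pool if p.origin == "DFS"]
        ranked = rank_paths(rules, dfs, synth_store, config, synth_index, k=15)
        merged = {p.signature: p for p in dfs}
        merged.update({p.signature: p for p in rules})
        oracle = sorted(
            (
                (p, score_path(p, synth_store, config, synth_index))
                for p in merged.values()
            ),
            key=lambda it: (-it[1].final_score, it[0].length, it[0].nodes),
        )[:15]
        assert [p.signature for p, _ in ranked] == [p.signature for p, _ in oracle]
        scores = [b.final_score for _, b in ranked]
        assert scores == sorted(scores, reverse=True)

    def test_k_must_be_positive(self, synth_store, config):
        with pytest.raises(CMKGError):
            rank_paths([], [], synth_store, config, k=0)
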