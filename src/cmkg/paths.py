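"""Unified mechanistic path scoring: DFS enumeration, ISI, calibration, decay.

A mechanistic path is an alternating entity/relation chain from a candidate
drug to a target disease. Each path receives

    score = BaseScore x Decay(L) x C_effective x Bonus

where BaseScore is the geometric mean of per-edge relation weights and
per-entity weights along the path, Decay penalises paths longer than two
hops, C_effective puts rule-derived confidences and search-derived paths on
one scale through the calibration factor lambda_DFS, and Bonus rewards paths
carrying molecular-mechanism signal (gene nodes, specific ingredients,
experimentally evidenced edges).

The Ingredient Specificity Index (ISI) down-weights ubiquitous herb
ingredients the way inverse document frequency down-weights stop-words: an
ingredient found in df of N herbs keeps a fraction
max(floor, ln(N / (df + 1)) / ln N) of its mechanism weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

from .errors import CMKGError, ConfigurationError, EntityLookupError
from .kg_core import KnowledgeGraphStore

Origin = Literal["DFS", "Rule"]

#: Types whose nodes carry full molecular-mechanism weight.
MECHANISM_TYPES = frozenset({"Herb", "Ingredient", "Gene", "Compound"})
#: Gene-gene relations backed by direct or transferred experimental evidence.
EVIDENCE_RELATIONS = frozenset({"experiments", "experiments_transferred"})


@dataclass(frozen=True)
class MechanisticPath:
    """Entity/relation chain e0 -r1-> e1 ... -rL-> eL with its origin."""

    nodes: tuple[str, ...]
    relations: tuple[str, ...]
    origin: Origin = "DFS"
    c_rule: float | None = None

    def __post_init__(self) -> None:
        if len(self.nodes) != len(self.relations) + 1:
            raise CMKGError("node count must be relation count + 1")
        if len(self.relations) < 1:
            raise CMKGError("a path has at least one edge")

    @property
    def length(self) -> int:
        return len(self.relations)

    @property
    def signature(self) -> tuple:
        """Identity for deduplication: nodes and relations, not origin."""
        return (self.nodes, self.relations)

    def arrow_string(self, store: KnowledgeGraphStore | None = None) -> str:
        """Human-readable ``e0 -> r1 -> e1 -> ...`` rendering (entity names
        when a store is given, ids otherwise)."""

        def label(eid: str) -> str:
            if store is not None and eid in store.entities:
                return store.entities[eid].name
            return eid

        parts = [label(self.nodes[0])]
        for rel, node in zip(self.relations, self.nodes[1:]):
            parts += [rel, label(node)]
        return " -> ".join(parts)


@dataclass(frozen=True)
class ScoringConfig:
    """All tunable weights of the unified path score.

    Defaults are the baseline configuration: baseline weight 0.7,
    non-evidence gene-gene weight 0.9, decay base 0.9 beyond two hops,
    ISI floor 0.01, bonus tiers 1.2 (structural) and 1.5 (evidence) capped
    at 1.8, lambda_DFS 0.2, at most 4 hops.
    """

    w_base: float = 0.7
    mech_entity_types: frozenset[str] = MECHANISM_TYPES
    mech_weight: float = 1.0
    evidence_relations: frozenset[str] = EVIDENCE_RELATIONS
    evidence_weight: float = 1.0
    other_gene_gene_weight: float = 0.9
    lambda_dfs: float = 0.2
    decay_base: float = 0.9
    max_hops: int = 4
    isi_floor: float = 0.01
    bonus_structural: float = 1.2
    bonus_evidence: float = 1.5
    bonus_cap: float = 1.8
    specific_ingredient_threshold: float = 0.5
    bonus_trigger_relations: frozenset[str] = EVIDENCE_RELATIONS | {"includes"}
    #: Relations traversable against edge direction during DFS (undirected
    #: sources such as gene-gene interaction networks).
    symmetric_relations: frozenset[str] = frozenset(
        {"synergizewith", "experiments", "experiments_transferred"}
    )

    def __post_init__(self) -> None:
        for name in ("w_base", "mech_weight", "evidence_weight", "other_gene_gene_weight"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1], got {v}")
        if not 0.0 < self.lambda_dfs <= 1.0:
            raise ConfigurationError("lambda_dfs must be in (0, 1]")
        if not 0.0 < self.decay_base <= 1.0:
            raise ConfigurationError("decay_base must be in (0, 1]")
        if not 0.0 < self.isi_floor <= 1.0:
            raise ConfigurationError("isi_floor must be in (0, 1]")
        if self.max_hops < 1:
            raise ConfigurationError("max_hops must be >= 1")
        if not 1.0 <= self.bonus_structural <= self.bonus_cap:
            raise ConfigurationError("bonus_structural outside [1, bonus_cap]")
        if not 1.0 <= self.bonus_evidence:
            raise ConfigurationError("bonus_evidence must be >= 1")


@dataclass(frozen=True)
class IngredientFrequencyIndex:
    """Herb-document frequency of each ingredient: df_i of N herbs."""

    n_herbs: int
    df: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.n_herbs < 1:
            raise ConfigurationError("n_herbs must be >= 1")

    @classmethod
    def from_store(cls, store: KnowledgeGraphStore) -> "IngredientFrequencyIndex":
        """Count, for each ingredient, the distinct herbs linked to it by any
        Herb->Ingredient edge, regardless of relation name."""
        herbs_of: dict[str, set[str]] = {}
        for t in store.triples:
            if (
                store.entity_type(t.head_id) == "Herb"
                and store.entity_type(t.tail_id) == "Ingredient"
            ):
                herbs_of.setdefault(t.tail_id, set()).add(t.head_id)
        n = len(store.entities_of_type("Herb"))
        return cls(max(n, 1), {ing: len(h) for ing, h in herbs_of.items()})


@dataclass(frozen=True)
class PathScoreBreakdown:
    base_score: float
    decay: float
    c_effective: float
    bonus: float
    final_score: float

    def rounded(self, ndigits: int = 4) -> "PathScoreBreakdown":
        return PathScoreBreakdown(
            *(round(x, ndigits) for x in (self.base_score, self.decay, self.c_effective, self.bonus, self.final_score))
        )


# -- component functions --------------------------------------------------


def isi_factor(index: IngredientFrequencyIndex, ingredient: str, config: ScoringConfig) -> float:
    """max(floor, ln(N / (df_i + 1)) / ln N); df of unseen ingredients is 0."""
    n = index.n_herbs
    if n < 2:
        raise ConfigurationError("ISI needs at least 2 herbs (ln N > 0)")
    df_i = index.df.get(ingredient, 0)
    return max(config.isi_floor, math.log(n / (df_i + 1)) / math.log(n))


def isi_weight(
    weight: float,
    index: IngredientFrequencyIndex,
    ingredient: str,
    config: ScoringConfig = ScoringConfig(),
) -> float:
    """Scale ``weight`` by the ingredient's specificity factor."""
    return weight * isi_factor(index, ingredient, config)


def relation_weight(
    relation: str,
    endpoint_types: tuple[str, str],
    config: ScoringConfig = ScoringConfig(),
) -> float:
    """Evidence gene-gene edges get 1.0, other gene-gene edges 0.9, and
    everything else the 0.7 baseline (defaults)."""
    if endpoint_types == ("Gene", "Gene"):
        if relation in config.evidence_relations:
            return config.evidence_weight
        return config.other_gene_gene_weight
    return config.w_base


def entity_weight(
    entity_id: str,
    entity_type: str,
    config: ScoringConfig = ScoringConfig(),
    index: IngredientFrequencyIndex | None = None,
) -> float:
    """Mechanism types weigh 1.0 (ingredients scaled by ISI), others 0.7."""
    if entity_type == "Ingredient" and index is not None:
        return isi_weight(config.mech_weight, index, entity_id, config)
    if entity_type in config.mech_entity_types:
        return config.mech_weight
    return config.w_base


def base_score(
    path: MechanisticPath,
    store: KnowledgeGraphStore,
    config: ScoringConfig = ScoringConfig(),
    index: IngredientFrequencyIndex | None = None,
) -> float:
    """Geometric mean of w_ri * w_ei over i = 1..L (head entity excluded)."""
    product = 1.0
    for i in range(path.length):
        e_prev, e_next = path.nodes[i], path.nodes[i + 1]
        types = (store.entity_type(e_prev), store.entity_type(e_next))
        w_r = relation_weight(path.relations[i], types, config)
        w_e = entity_weight(e_next, types[1], config, index)
        product *= w_r * w_e
    return product ** (1.0 / path.length)


def decay(length: int, config: ScoringConfig = ScoringConfig()) -> float:
    """1.0 up to two hops, then decay_base per extra hop, capped at max_hops."""
    if not 1 <= length <= config.max_hops:
        raise CMKGError(f"path length {length} outside [1, {config.max_hops}]")
    if length <= 2:
        return 1.0
    return config.decay_base ** (length - 2)


def effective_confidence(
    path: MechanisticPath,
    base: float,
    config: ScoringConfig = ScoringConfig(),
) -> float:
    """min(1, C_rule) for rule paths; min(1, BaseScore * lambda_DFS) for DFS."""
    if path.origin == "Rule":
        if path.c_rule is None:
            raise CMKGError("rule-derived path lacks a rule confidence")
        return min(1.0, path.c_rule)
    return min(1.0, base * config.lambda_dfs)


def bonus(
    path: MechanisticPath,
    store: KnowledgeGraphStore,
    config: ScoringConfig = ScoringConfig(),
    index: IngredientFrequencyIndex | None = None,
) -> float:
    """Mechanism bonus in [1.0, bonus_cap].

    The structural tier fires when the path contains a Gene node or a
    *specific* ingredient (ISI factor at least the configured threshold of
    its pre-ISI weight); the evidence tier fires when any relation is an
    evidence relation or the herb-composition relation ``includes``. Tiers
    multiply and the product is capped.
    """
    factor = 1.0
    structural = False
    for node in path.nodes:
        etype = store.entity_type(node)
        if etype == "Gene":
            structural = True
            break
        if etype == "Ingredient":
            f = isi_factor(index, node, config) if index is not None else 1.0
            if f >= config.specific_ingredient_threshold:
                structural = True
                break
    if structural:
        factor *= config.bonus_structural
    if any(r in config.bonus_trigger_relations for r in path.relations):
        factor *= config.bonus_evidence
    return min(factor, config.bonus_cap)


def score_path(
    path: MechanisticPath,
    store: KnowledgeGraphStore,
    config: ScoringConfig = ScoringConfig(),
    index: IngredientFrequencyIndex | None = None,
) -> PathScoreBreakdown:
    """Full breakdown; final score is the exact product of the four parts."""
    b = base_score(path, store, config, index)
    d = decay(path.length, config)
    c = effective_confidence(path, b, config)
    bo = bonus(path, store, config, index)
    return PathScoreBreakdown(b, d, c, bo, b * d * c * bo)


# -- DFS enumeration ------------------------------------------------------


def dfs_paths(
    store: KnowledgeGraphStore,
    source: str,
    target: str,
    config: ScoringConfig = ScoringConfig(),
) -> list[MechanisticPath]:
    """All simple paths from source to target of length <= max_hops.

    Edges are traversed head-to-tail; relations listed in
    ``config.symmetric_relations`` may also be traversed tail-to-head.
    Enumeration order is deterministic (sorted successor expansion).
    """
    for eid in (source, target):
        if eid not in store.entities:
            raise EntityLookupError(eid)
    if source == target:
        raise CMKGError("source and target must differ")

    succ_cache: dict[str, list[tuple[str, str]]] = {}

    def successors(eid: str) -> list[tuple[str, str]]:
        if eid not in succ_cache:
            pairs = {(t.relation, t.tail_id) for t in store.out_triples(eid)}
            pairs |= {
                (t.relation, t.head_id)
                for t in store.in_triples(eid)
                if t.relation in config.symmetric_relations
            }
            succ_cache[eid] = sorted(pairs)
        return succ_cache[eid]

    out: list[MechanisticPath] = []
    stack_nodes = [source]
    stack_rels: list[str] = []
    visiting = {source}

    def walk(eid: str) -> None:
        depth = len(stack_rels)
        if depth >= config.max_hops:
            return
        for rel, nxt in successors(eid):
            if nxt == target:
                out.append(
                    MechanisticPath(tuple(stack_nodes) + (nxt,), tuple(stack_rels) + (rel,))
                )
                continue
            if nxt in visiting:
                continue
            stack_nodes.append(nxt)
            stack_rels.append(rel)
            visiting.add(nxt)
            walk(nxt)
            visiting.discard(nxt)
            stack_nodes.pop()
            stack_rels.pop()

    walk(source)
    return out


# -- hybrid merge and ranking ---------------------------------------------


def rank_paths(
    rule_paths: Iterable[MechanisticPath],
    dfs_paths_: Iterable[MechanisticPath],
    store: KnowledgeGraphStore,
    config: ScoringConfig = ScoringConfig(),
    index: IngredientFrequencyIndex | None = None,
    k: int = 10,
) -> list[tuple[MechanisticPath, PathScoreBreakdown]]:
    """Merge, dedup (rule provenance preferred), score, and take the top k.

    Sorting is by final score descending; ties break toward shorter paths,
    then lexicographic node ids.
    """
    if k <= 0:
        raise CMKGError("k must be positive")
    merged: dict[tuple, MechanisticPath] = {}
    for p in dfs_paths_:
        merged.setdefault(p.signature, p)
    for p in rule_paths:
        merged[p.signature] = p  # rule origin wins duplicate signatures
    scored = [(p, score_path(p, store, config, index)) for p in merged.values()]
    scored.sort(key=lambda it: (-it[1].final_score, it[0].length, it[0].nodes))
    return scored[:k]


def write_path_report(
    ranked: Sequence[tuple[MechanisticPath, PathScoreBreakdown]],
    path: str,
    store: KnowledgeGraphStore | None = None,
) -> None:
    """TSV report mirroring the arrow notation of published path tables."""
    import pandas as pd

    rows = [
        (
            i + 1,
            p.arrow_string(store),
            p.origin,
            round(b.base_score, 4),
            round(b.decay, 4),
            round(b.c_effective, 4),
            round(b.bonus, 4),
            round(b.final_score, 4),
        )
        for i, (p, b) in enumerate(ranked)
    ]
    pd.DataFrame(
        rows,
        columns=["rank", "path", "origin", "base", "decay", "c_eff", "bonus", "score"],
    ).to_csv(path, sep="\t", index=False)
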