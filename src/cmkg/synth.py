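"""Seeded generators of schema-faithful toy cross-medicine graphs.

The main generator emulates the CMKG schema — herb -> ingredient -> gene ->
disease chains, gene-gene edges with and without experimental-evidence
labels, ubiquitous versus rare ingredients with exact document frequencies,
planted mechanistic paths, and planted Horn rules with exact confidences —
so every other module is testable without any external download. A second
generator builds a deliberately antisymmetric graph (successor rings and a
strict hierarchy) on which direction-aware embedding models separate from
symmetric ones.

Planted rules use relation-name triples reserved for planting (noise never
draws them), which keeps manifest support / body-count / confidence exact
under arbitrary noise densities.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import CMKGError
from .kg_core import (
    EntityRecord,
    KnowledgeGraphStore,
    TripleRecord,
    write_entity_table,
    write_triple_table,
)
from .paths import MechanisticPath
from .rules import Atom, HornRule, write_rules

SOURCE = "synthetic"

#: (head_relation, body_relation_1, body_relation_2) triples reserved for
#: planted rules; noise generation never uses these names.
RESERVED_RULE_RELATIONS: tuple[tuple[str, str, str], ...] = (
    ("treat", "regulate", "elevate"),
    ("alleviate", "inhibit", "induce"),
    ("prevent", "affect", "degrade"),
)


@dataclass(frozen=True)
class SynthesisParams:
    """Study conditions for the toy CMKG.

    Sizes are desk-scale but keep the schema's shape: tens of herbs sharing
    ingredients of very different ubiquity, a gene-gene interaction layer of
    which roughly a third carries experimental-evidence labels, and a handful
    of diseases each anchored by several genes.
    """

    n_herbs: int = 30
    n_ingredients: int = 40
    n_compounds: int = 20
    n_genes: int = 60
    n_diseases: int = 4
    n_symptoms: int = 10
    ubiquitous_fraction: float = 0.1  # ingredients present in nearly all herbs
    rare_df_max: int = 3
    ingredient_gene_edges: int = 2
    herb_gene_edges: int = 2
    gene_gene_edges: int = 120
    evidence_fraction: float = 0.3
    gene_disease_edges: int = 8  # per disease
    compound_gene_edges: int = 3  # per compound
    herb_symptom_edges: int = 1  # per herb
    planted_mechanism_lengths: tuple[int, ...] = (2, 3, 4)
    planted_rule_counts: tuple[tuple[int, int], ...] = ((2, 4), (3, 3))
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_herbs, self.n_ingredients, self.n_genes, self.n_diseases) < 1:
            raise CMKGError("entity counts must be >= 1")
        if not 0.0 <= self.ubiquitous_fraction <= 1.0:
            raise CMKGError("ubiquitous_fraction must be in [0, 1]")
        if any(length < 2 or length > 4 for length in self.planted_mechanism_lengths):
            raise CMKGError("planted mechanism lengths must be within [2, 4] hops")
        if len(self.planted_rule_counts) > len(RESERVED_RULE_RELATIONS):
            raise CMKGError(
                f"at most {len(RESERVED_RULE_RELATIONS)} rules can be planted"
            )
        for s, b in self.planted_rule_counts:
            if not 0 < s <= b:
                raise CMKGError("each planted rule needs 0 < support <= body_count")


def _ids(prefix: str, n: int, width: int) -> list[str]:
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def generate_cmkg(params: SynthesisParams) -> tuple[KnowledgeGraphStore, dict]:
    """Build the toy graph and its ground-truth manifest.

    The manifest records every planted mechanistic path, every planted rule
    with its exact support / body count / confidence, and each ingredient's
    true herb document frequency. Identical parameters (including the seed)
    reproduce the store and manifest exactly.
    """
    rng = np.random.default_rng(params.seed)
    herbs = _ids("HEB", params.n_herbs, 4)
    ingredients = _ids("INT", params.n_ingredients, 5)
    compounds = _ids("DCP", params.n_compounds, 5)
    genes = _ids("GEE", params.n_genes, 5)
    diseases = _ids("DM", params.n_diseases, 2)
    symptoms = _ids("TS", params.n_symptoms, 4)

    entities = (
        [EntityRecord(e, f"herb {e}", "Herb", SOURCE) for e in herbs]
        + [EntityRecord(e, f"ingredient {e}", "Ingredient", SOURCE) for e in ingredients]
        + [EntityRecord(e, f"compound {e}", "Compound", SOURCE) for e in compounds]
        + [EntityRecord(e, f"gene {e}", "Gene", SOURCE) for e in genes]
        + [EntityRecord(e, f"disease {e}", "DiseaseMM", SOURCE) for e in diseases]
        + [EntityRecord(e, f"symptom {e}", "SymptomTCM", SOURCE) for e in symptoms]
    )
    triples: list[TripleRecord] = []

    def add(h: str, r: str, t: str) -> None:
        triples.append(TripleRecord(h, r, t, SOURCE))

    # -- ingredient ubiquity: exact document frequencies ------------------
    n_ubiq = int(round(params.ubiquitous_fraction * params.n_ingredients))
    df_truth: dict[str, int] = {}
    for k, ing in enumerate(ingredients):
        if k < n_ubiq and params.n_herbs > 1:
            df = params.n_herbs - 1
        else:
            df = int(rng.integers(1, min(params.rare_df_max, params.n_herbs) + 1))
        df_truth[ing] = df
        for herb in rng.choice(herbs, size=df, replace=False):
            add(str(herb), "includes", ing)

    # -- planted mechanistic chains ---------------------------------------
    planted_paths: list[MechanisticPath] = []
    target = diseases[0]
    for j, length in enumerate(params.planted_mechanism_lengths):
        gs = [genes[(7 * j + i) % params.n_genes] for i in range(length)]
        if length == 2:
            herb = herbs[j % params.n_herbs]
            nodes = (herb, gs[0], target)
            rels = ("act_on", "dysregulate")
        elif length == 3:
            herb = herbs[(j + 1) % params.n_herbs]
            nodes = (herb, gs[0], gs[1], target)
            rels = ("act_on", "synergizewith", "dysregulate")
        else:  # 4 hops through an ingredient
            ing = ingredients[min(n_ubiq + j, params.n_ingredients - 1)]
            # reuse an existing includes edge so the ingredient's df stays exact
            owners = [t.head_id for t in triples if t.relation == "includes" and t.tail_id == ing]
            herb = owners[0]
            nodes = (herb, ing, gs[0], gs[1], target)
            rels = ("includes", "act_on", "synergizewith", "dysregulate")
        for a, r, b in zip(nodes, rels, nodes[1:]):
            if (a, r, b) not in {(t.head_id, t.relation, t.tail_id) for t in triples}:
                add(a, r, b)
        planted_paths.append(MechanisticPath(nodes, rels))

    # -- planted Horn rules with exact statistics --------------------------
    planted_rules: list[HornRule] = []
    gene_cursor = 0
    for i, (support, body_count) in enumerate(params.planted_rule_counts):
        head_rel, b1, b2 = RESERVED_RULE_RELATIONS[i]
        if body_count > params.n_compounds * params.n_diseases:
            raise CMKGError("not enough (compound, disease) pairs for planted rule")
        if body_count > params.n_genes - gene_cursor:
            raise CMKGError("not enough dedicated genes for planted rule bodies")
        pairs = [
            (compounds[k % params.n_compounds], diseases[k // params.n_compounds])
            for k in range(body_count)
        ]
        for k, (x, y) in enumerate(pairs):
            bridge = genes[gene_cursor]
            gene_cursor += 1
            add(x, b1, bridge)
            add(bridge, b2, y)
            if k < support:
                add(x, head_rel, y)
        planted_rules.append(
            HornRule(
                head=Atom(head_rel, "X", "Y"),
                body=(Atom(b1, "X", "A"), Atom(b2, "A", "Y")),
                support=support,
                body_count=body_count,
                confidence=support / body_count,
            )
        )

    # -- noise layers (planted structure already fixed) --------------------
    for ing in ingredients:
        for g in rng.choice(genes, size=params.ingredient_gene_edges, replace=False):
            add(ing, "act_on", str(g))
    for herb in herbs:
        for g in rng.choice(genes, size=params.herb_gene_edges, replace=False):
            add(herb, "act_on", str(g))
        for s in rng.choice(symptoms, size=params.herb_symptom_edges, replace=False):
            add(herb, "is_associated_with", str(s))
    gg_relations = ["experiments", "experiments_transferred", "synergizewith"]
    for _ in range(params.gene_gene_edges):
        a, b = rng.choice(params.n_genes, size=2, replace=False)
        if rng.random() < params.evidence_fraction:
            rel = gg_relations[int(rng.integers(2))]
        else:
            rel = "synergizewith"
        add(genes[a], rel, genes[b])
    for dis in diseases:
        for g in rng.choice(genes, size=min(params.gene_disease_edges, params.n_genes), replace=False):
            rel = "dysregulate" if rng.random() < 0.5 else "act in pathway"
            add(str(g), rel, dis)
    for comp in compounds:
        for g in rng.choice(genes, size=params.compound_gene_edges, replace=False):
            rel = ("bind", "upregulate", "downregulate")[int(rng.integers(3))]
            add(comp, rel, str(g))
    for s in symptoms:
        add(s, "is_associated_with", diseases[int(rng.integers(params.n_diseases))])

    store = KnowledgeGraphStore(entities, triples, strict=True)
    manifest = {
        "params": asdict(params),
        "planted_paths": [
            {"nodes": list(p.nodes), "relations": list(p.relations)}
            for p in planted_paths
        ],
        "planted_rules": [
            {
                "head": r.head.relation,
                "body_relations": list(r.body_relations),
                "support": r.support,
                "body_count": r.body_count,
                "confidence": r.confidence,
            }
            for r in planted_rules
        ],
        "ingredient_df": df_truth,
        "target_disease": target,
    }
    return store, manifest


def planted_rules_from_manifest(manifest: dict) -> list[HornRule]:
    rules = []
    for r in manifest["planted_rules"]:
        b1, b2 = r["body_relations"]
        rules.append(
            HornRule(
                head=Atom(r["head"], "X", "Y"),
                body=(Atom(b1, "X", "A"), Atom(b2, "A", "Y")),
                support=r["support"],
                body_count=r["body_count"],
                confidence=r["confidence"],
            )
        )
    return rules


def write_fixture(
    store: KnowledgeGraphStore, manifest: dict, directory: str | Path
) -> dict[str, Path]:
    """Write entity/triple TSVs, the planted-rule file, and the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {
        "entities": directory / "entities.tsv",
        "triples": directory / "triples.tsv",
        "rules": directory / "rules.tsv",
        "manifest": directory / "manifest.json",
    }
    write_entity_table(store.entities.values(), files["entities"])
    write_triple_table(store.triples, files["triples"])
    write_rules(planted_rules_from_manifest(manifest), files["rules"])
    files["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return files


# -- antisymmetric benchmark graph ----------------------------------------


def generate_antisymmetric_kg(
    n_entities: int = 200,
    offsets: Sequence[int] = (1, 2, 3, 4, 5, 7, 9, 11, 13, 17),
    seed: int = 0,
) -> KnowledgeGraphStore:
    """Cyclic-offset graph: relation ``plus_k`` links i to (i + k) mod n.

    Every relation is an antisymmetric bijection (for k != n/2, (a, b) in
    plus_k implies (b, a) is not), and the whole family is exactly
    representable by rotations of entities placed on a circle. A symmetric
    scorer is forced to give (h, t) and (t, h) equal scores and cannot rank
    these relations, while direction-aware models can; the ``seed`` argument
    is kept for interface symmetry (the construction is deterministic).
    """
    del seed  # deterministic construction
    ids = _ids("GEE", n_entities, 5)
    entities = [EntityRecord(e, f"gene {e}", "Gene", SOURCE) for e in ids]
    triples = [
        TripleRecord(ids[i], f"plus_{k}", ids[(i + k) % n_entities], SOURCE)
        for k in offsets
        for i in range(n_entities)
    ]
    return KnowledgeGraphStore(entities, triples, strict=True)
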