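"""Entity alignment, relation fusion, and graph-level audit statistics.

Relation fusion merges semantically redundant relation types by comparing the
(head, tail) pair sets they cover: two relations are merged when their Jaccard
similarity is at least 0.8, or when Jaccard is at most 0.2 while the Overlap
coefficient is at least 0.6 (the small-set-inside-large-set case). Entity
alignment merges same-name, same-type records from different sources. The
audit routines recompute per-source triple contributions and the shared
gene-target statistics that justify gene-bridged integration of traditional
and modern medicine.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import pandas as pd

from .errors import CMKGError, ConfigurationError, IntegrityError
from .kg_core import EntityRecord, KnowledgeGraphStore, TripleRecord


@dataclass(frozen=True)
class FusionThresholds:
    """Decision thresholds: merge if J >= j_hi, or (J <= j_lo and O >= o_hi)."""

    j_hi: float = 0.8
    j_lo: float = 0.2
    o_hi: float = 0.6


@dataclass(frozen=True)
class RelationProfile:
    """The set of (head, tail) pairs occurring under one relation."""

    relation: str
    pair_set: frozenset[tuple[str, str]]

    @classmethod
    def from_store(cls, store: KnowledgeGraphStore, relation: str) -> "RelationProfile":
        pairs = frozenset(
            (t.head_id, t.tail_id) for t in store.triples if t.relation == relation
        )
        if not pairs:
            raise CMKGError(f"relation {relation!r} has no triples in the store")
        return cls(relation, pairs)


@dataclass(frozen=True)
class FusionDecision:
    relation_a: str
    relation_b: str
    jaccard: float
    overlap: float
    action: str  # "merge" | "keep"
    survivor: str | None = None


def jaccard(a: frozenset | set, b: frozenset | set) -> float:
    """|A ∩ B| / |A ∪ B| for two sets of (head, tail) pairs."""
    if not a and not b:
        raise CMKGError("jaccard undefined for two empty sets")
    return len(a & b) / len(a | b)


def overlap(a: frozenset | set, b: frozenset | set) -> float:
    """|A ∩ B| / min(|A|, |B|); requires both sets non-empty."""
    if not a or not b:
        raise CMKGError("overlap undefined when either set is empty")
    return len(a & b) / min(len(a), len(b))


def fusion_decision(
    pa: RelationProfile,
    pb: RelationProfile,
    thresholds: FusionThresholds = FusionThresholds(),
) -> FusionDecision:
    """Apply the threshold rule to one relation pair.

    The survivor of a merge is the relation covering more pairs, ties broken
    lexicographically (the store-level rule; the merged relation's triples are
    renamed to the survivor).
    """
    j = jaccard(pa.pair_set, pb.pair_set)
    o = overlap(pa.pair_set, pb.pair_set)
    merge = j >= thresholds.j_hi or (j <= thresholds.j_lo and o >= thresholds.o_hi)
    survivor = None
    if merge:
        # larger pair set survives; lexicographically smaller name wins a tie
        survivor = min(
            (pa, pb), key=lambda p: (-len(p.pair_set), p.relation)
        ).relation
    return FusionDecision(pa.relation, pb.relation, j, o, "merge" if merge else "keep", survivor)


def relation_type_signature(store: KnowledgeGraphStore, relation: str) -> set[tuple[str, str]]:
    return {
        (store.entity_type(t.head_id), store.entity_type(t.tail_id))
        for t in store.triples
        if t.relation == relation
    }


def propose_fusions(
    store: KnowledgeGraphStore,
    thresholds: FusionThresholds = FusionThresholds(),
) -> list[FusionDecision]:
    """Pairwise decisions over relations sharing a head/tail type signature.

    Only relation pairs whose (head type, tail type) signatures intersect are
    compared; comparing across signatures is meaningless.
    """
    relations = sorted(store.relation_vocabulary)
    profiles = {r: RelationProfile.from_store(store, r) for r in relations}
    signatures = {r: relation_type_signature(store, r) for r in relations}
    decisions = []
    for i, ra in enumerate(relations):
        for rb in relations[i + 1 :]:
            if signatures[ra] & signatures[rb]:
                decisions.append(fusion_decision(profiles[ra], profiles[rb], thresholds))
    return decisions


def fuse_relations(
    store: KnowledgeGraphStore,
    decisions: Iterable[FusionDecision],
) -> tuple[KnowledgeGraphStore, pd.DataFrame]:
    """Rename merged relations to their survivors and drop duplicate triples.

    Merge decisions are combined by union-find; a chain with conflicting
    survivors raises :class:`IntegrityError`. Returns the fused store and a
    report with one row per decision plus the triple-count delta.
    """
    parent: dict[str, str] = {}

    def find(r: str) -> str:
        parent.setdefault(r, r)
        while parent[r] != r:
            parent[r] = parent[parent[r]]
            r = parent[r]
        return r

    merges = [d for d in decisions if d.action == "merge"]
    for d in merges:
        if d.survivor not in (d.relation_a, d.relation_b):
            raise IntegrityError(
                f"survivor {d.survivor!r} is neither side of ({d.relation_a}, {d.relation_b})"
            )
        loser = d.relation_a if d.survivor == d.relation_b else d.relation_b
        ra, rb = find(loser), find(d.survivor)
        if ra != rb:
            parent[ra] = rb

    # A merge chain must resolve to exactly one declared survivor.
    declared = {d.survivor for d in merges}
    for d in merges:
        root = find(d.survivor)
        if root != d.survivor and root not in declared:
            raise IntegrityError(
                f"conflicting survivors in merge chain through {d.survivor!r}"
            )

    renamed = [
        TripleRecord(t.head_id, find(t.relation), t.tail_id, t.source_db)
        for t in store.triples
    ]
    fused = store.subset_with_triples(renamed)
    report = pd.DataFrame(
        [
            (d.relation_a, d.relation_b, round(d.jaccard, 4), round(d.overlap, 4), d.action, d.survivor or "")
            for d in decisions
        ],
        columns=["relation_a", "relation_b", "jaccard", "overlap", "action", "survivor"],
    )
    report.attrs["triples_before"] = len(store)
    report.attrs["triples_after"] = len(fused)
    report.attrs["removed_relations"] = sorted(
        store.relation_vocabulary - fused.relation_vocabulary
    )
    return fused, report


# -- entity alignment -----------------------------------------------------

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Case-fold, collapse internal whitespace, strip edge punctuation."""
    s = _WS.sub(" ", name.strip()).casefold()
    return s.strip(" .,;:-_'\"()[]")


def align_entities(
    tables: Sequence[Sequence[EntityRecord]],
) -> tuple[list[EntityRecord], pd.DataFrame]:
    """Merge same-name, same-type records across per-source entity tables.

    Records whose normalized names and entity types match become one entity;
    the first-seen id wins and provenance labels are concatenated with ``;``.
    Returns the aligned records and a per-type merge-count report.
    """
    by_key: dict[tuple[str, str], EntityRecord] = {}
    merge_counts: Counter[str] = Counter()
    for table in tables:
        for rec in table:
            key = (normalize_name(rec.name), rec.entity_type)
            if key not in by_key:
                by_key[key] = rec
            else:
                prev = by_key[key]
                sources = list(dict.fromkeys(prev.source_db.split(";") + rec.source_db.split(";")))
                by_key[key] = EntityRecord(
                    prev.entity_id, prev.name, prev.entity_type, ";".join(sources)
                )
                merge_counts[rec.entity_type] += 1
    report = pd.DataFrame(
        sorted(merge_counts.items()), columns=["entity_type", "merged_records"]
    )
    return list(by_key.values()), report


# -- audit statistics -----------------------------------------------------


def percentage(count: int, total: int, decimals: int = 2) -> float:
    """A printed-table percentage: 100 * count / total, rounded."""
    if total <= 0:
        raise ConfigurationError("total must be positive")
    return round(100.0 * count / total, decimals)


def source_contribution(
    counts: Mapping[str, int] | KnowledgeGraphStore,
) -> pd.DataFrame:
    """Per-source triple counts and two-decimal percentage contributions.

    Accepts either a store (counts taken from triple provenance) or a
    precomputed {source: count} mapping, e.g. a published distribution table.
    """
    if isinstance(counts, KnowledgeGraphStore):
        tally = Counter(t.source_db for t in counts.triples)
    else:
        tally = Counter(counts)
    total = sum(tally.values())
    rows = [
        (src, n, percentage(n, total, 2))
        for src, n in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    df = pd.DataFrame(rows, columns=["source_db", "triples", "percentage"])
    df.attrs["total"] = total
    return df


#: Default system type sets for shared-gene-target analysis.
TCM_TYPES = frozenset({"Herb", "Ingredient", "SymptomTCM", "Syndrome"})
MM_TYPES = frozenset({"Compound", "DiseaseMM", "SymptomMM", "Anatomy"})


def shared_target_stats(
    store: KnowledgeGraphStore,
    tcm_types: frozenset[str] = TCM_TYPES,
    mm_types: frozenset[str] = MM_TYPES,
) -> dict:
    """Genes bridging the two medical systems, with intersection percentages.

    A gene is *shared* when it is adjacent (either direction, any relation) to
    at least one entity of a TCM-system type and at least one of an MM-system
    type. For each system, the intersection counts genes among the shared set
    that touch *every* type of that system; percentages are relative to the
    shared count, one decimal.
    """
    if not tcm_types or not mm_types:
        raise ConfigurationError("system type sets must be non-empty")
    if tcm_types & mm_types:
        raise ConfigurationError("system type sets must be disjoint")

    gene_types: dict[str, set[str]] = defaultdict(set)
    for t in store.triples:
        ht, tt = store.entity_type(t.head_id), store.entity_type(t.tail_id)
        if ht == "Gene":
            gene_types[t.head_id].add(tt)
        if tt == "Gene":
            gene_types[t.tail_id].add(ht)

    shared = {
        g for g, types in gene_types.items() if types & tcm_types and types & mm_types
    }
    tcm_full = {g for g in shared if tcm_types <= gene_types[g]}
    mm_full = {g for g in shared if mm_types <= gene_types[g]}
    n = len(shared)
    return {
        "shared_genes": n,
        "tcm_intersection": len(tcm_full),
        "mm_intersection": len(mm_full),
        "tcm_percentage": percentage(len(tcm_full), n, 1) if n else 0.0,
        "mm_percentage": percentage(len(mm_full), n, 1) if n else 0.0,
    }
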