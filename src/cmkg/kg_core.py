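"""Typed knowledge-graph substrate: records, TSV I/O, indices, custom IDs.

A cross-medicine knowledge graph (CMKG) is a directed multigraph whose nodes
are typed biomedical entities (herbs, ingredients, genes, diseases, ...) and
whose edges are (head, relation, tail) triples carrying a provenance label.
This module holds the in-memory store every other module operates on, plus the
tab-separated interchange format and the per-type custom-ID scheme used to
give entities globally unique, human-readable identifiers.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, EntityLookupError, FormatError, IntegrityError

#: Closed vocabulary of entity types in the CMKG schema.
ENTITY_TYPES = frozenset(
    {
        "DiseaseMM",
        "SymptomMM",
        "SymptomTCM",
        "Herb",
        "Ingredient",
        "Compound",
        "Gene",
        "Pathway",
        "MolecularFunction",
        "CellularComponent",
        "BiologicalProcess",
        "SideEffect",
        "Anatomy",
        "PharmacologicalClassification",
        "Syndrome",
    }
)

ENTITY_COLUMNS = ("entity_id", "name", "entity_type", "source_db")
TRIPLE_COLUMNS = ("head_id", "relation", "tail_id", "source_db")

#: Sentinel for assign_custom_ids: keep the source-database identifier.
RETAIN_SOURCE_ID = "RETAIN"


@dataclass(frozen=True)
class EntityRecord:
    """One typed entity with provenance.

    ``source_db`` may carry several provenance labels joined by ``;`` after
    entity alignment.
    """

    entity_id: str
    name: str
    entity_type: str
    source_db: str

    def __post_init__(self) -> None:
        if not self.name:
            raise IntegrityError(f"entity {self.entity_id!r} has an empty name")
        if self.entity_type not in ENTITY_TYPES:
            raise FormatError(
                f"unknown entity_type {self.entity_type!r} for entity "
                f"{self.entity_id!r}; expected one of {sorted(ENTITY_TYPES)}"
            )


@dataclass(frozen=True)
class TripleRecord:
    """A directed (head, relation, tail) assertion with provenance."""

    head_id: str
    relation: str
    tail_id: str
    source_db: str

    @property
    def key(self) -> tuple[str, str, str]:
        """Identity used for deduplication: provenance is not part of it."""
        return (self.head_id, self.relation, self.tail_id)


class KnowledgeGraphStore:
    """Deduplicated triples over a typed entity table, with adjacency indices.

    Parameters
    ----------
    entities
        Entity records; ids must be unique.
    triples
        Triple records. Exact (head, relation, tail) duplicates are dropped,
        keeping the first occurrence's provenance.
    strict
        If True (default), a triple referencing an unknown entity raises
        :class:`IntegrityError`. If False, such triples are skipped and
        counted in :attr:`skipped_dangling`.
    """

    def __init__(
        self,
        entities: Iterable[EntityRecord],
        triples: Iterable[TripleRecord] = (),
        strict: bool = True,
    ) -> None:
        self.entities: dict[str, EntityRecord] = {}
        for rec in entities:
            if rec.entity_id in self.entities:
                raise IntegrityError(f"duplicate entity_id {rec.entity_id!r}")
            self.entities[rec.entity_id] = rec

        self.triples: list[TripleRecord] = []
        self.skipped_dangling = 0
        self._seen: set[tuple[str, str, str]] = set()
        self.out_index: dict[str, list[int]] = defaultdict(list)
        self.in_index: dict[str, list[int]] = defaultdict(list)
        self.relation_vocabulary: set[str] = set()
        for t in triples:
            self._add_triple(t, strict=strict)

    def _add_triple(self, t: TripleRecord, strict: bool = True) -> bool:
        if t.head_id not in self.entities or t.tail_id not in self.entities:
            if strict:
                missing = t.head_id if t.head_id not in self.entities else t.tail_id
                raise IntegrityError(
                    f"triple {t.key} references unknown entity {missing!r}"
                )
            self.skipped_dangling += 1
            return False
        if t.key in self._seen:
            return False
        self._seen.add(t.key)
        idx = len(self.triples)
        self.triples.append(t)
        self.out_index[t.head_id].append(idx)
        self.in_index[t.tail_id].append(idx)
        self.relation_vocabulary.add(t.relation)
        return True

    # -- queries ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.triples)

    def __contains__(self, key: tuple[str, str, str]) -> bool:
        return key in self._seen

    def entity_type(self, entity_id: str) -> str:
        try:
            return self.entities[entity_id].entity_type
        except KeyError:
            raise EntityLookupError(entity_id) from None

    def entities_of_type(self, entity_type: str) -> list[str]:
        return sorted(
            eid for eid, rec in self.entities.items() if rec.entity_type == entity_type
        )

    def out_triples(self, entity_id: str) -> list[TripleRecord]:
        return [self.triples[i] for i in self.out_index.get(entity_id, ())]

    def in_triples(self, entity_id: str) -> list[TripleRecord]:
        return [self.triples[i] for i in self.in_index.get(entity_id, ())]

    def subset_with_triples(self, triples: Iterable[TripleRecord]) -> "KnowledgeGraphStore":
        """New store over the same entities with a replacement triple list."""
        return KnowledgeGraphStore(self.entities.values(), triples, strict=True)


def neighbors(
    store: KnowledgeGraphStore,
    entity_id: str,
    direction: Literal["out", "in", "both"] = "both",
) -> list[tuple[str, str]]:
    """Incident (relation, neighbor_id) pairs in deterministic order.

    ``out`` follows triples where the entity is the head, ``in`` where it is
    the tail; ``both`` is their multiset union. Pairs are sorted by
    (relation, neighbor_id).
    """
    if entity_id not in store.entities:
        raise EntityLookupError(entity_id)
    pairs: list[tuple[str, str]] = []
    if direction in ("out", "both"):
        pairs += [(t.relation, t.tail_id) for t in store.out_triples(entity_id)]
    if direction in ("in", "both"):
        pairs += [(t.relation, t.head_id) for t in store.in_triples(entity_id)]
    return sorted(pairs)


# -- tab-separated I/O ---------------------------------------------------


def _read_tsv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in columns:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def read_entity_table(path: str | Path) -> list[EntityRecord]:
    """Read a 4-column entity TSV (entity_id, name, entity_type, source_db)."""
    df = _read_tsv(path, ENTITY_COLUMNS)
    records = [
        EntityRecord(r.entity_id, r.name, r.entity_type, r.source_db)
        for r in df.itertuples(index=False)
    ]
    seen: dict[str, int] = {}
    dupes = []
    for rec in records:
        if rec.entity_id in seen:
            dupes.append(rec.entity_id)
        seen[rec.entity_id] = 1
    if dupes:
        raise IntegrityError(f"duplicate entity ids: {sorted(set(dupes))}")
    return records


def read_triples(
    path: str | Path,
    entities: Iterable[EntityRecord],
    strict: bool = True,
) -> KnowledgeGraphStore:
    """Read a triple TSV against an already-loaded entity table.

    Exact duplicates are dropped. In strict mode a dangling reference raises;
    in lenient mode it is skipped and counted on the returned store.
    """
    df = _read_tsv(path, TRIPLE_COLUMNS)
    triples = (
        TripleRecord(r.head_id, r.relation, r.tail_id, r.source_db)
        for r in df.itertuples(index=False)
    )
    return KnowledgeGraphStore(entities, triples, strict=strict)


def write_entity_table(records: Iterable[EntityRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.entity_id, r.name, r.entity_type, r.source_db) for r in records],
        columns=list(ENTITY_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def write_triple_table(triples: Iterable[TripleRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(t.head_id, t.relation, t.tail_id, t.source_db) for t in triples],
        columns=list(TRIPLE_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


# -- custom ID assignment -------------------------------------------------


@dataclass(frozen=True)
class IdScheme:
    """Per-type prefix and zero-pad width, e.g. Herb -> HEB + 4 digits."""

    prefix: str
    width: int


#: Default CMKG naming scheme (Herb -> HEB0001..., Gene -> GEE00001..., etc.).
DEFAULT_ID_SCHEMES: Mapping[str, IdScheme | str] = {
    "DiseaseMM": IdScheme("DIMM", 5),
    "SymptomMM": IdScheme("MS", 4),
    "SymptomTCM": IdScheme("TS", 4),
    "Herb": IdScheme("HEB", 4),
    "Ingredient": IdScheme("INT", 5),
    "Compound": IdScheme("DCP", 5),
    "Gene": IdScheme("GEE", 5),
    "Pathway": IdScheme("PW", 4),
    "Syndrome": IdScheme("ZH", 3),
    "MolecularFunction": RETAIN_SOURCE_ID,
    "CellularComponent": RETAIN_SOURCE_ID,
    "BiologicalProcess": RETAIN_SOURCE_ID,
    "SideEffect": RETAIN_SOURCE_ID,
    "Anatomy": RETAIN_SOURCE_ID,
    "PharmacologicalClassification": RETAIN_SOURCE_ID,
}


def assign_custom_ids(
    entities: Sequence[EntityRecord],
    schemes: Mapping[str, IdScheme | str] = DEFAULT_ID_SCHEMES,
) -> dict[str, str]:
    """Deterministic old-id -> new-id mapping under a per-type prefix scheme.

    Within each type, entities are ordered by case-insensitive name, breaking
    ties by source_db then by original id, and numbered from 1 with zero
    padding (``HEB`` + width 4 -> ``HEB0001``). Types mapped to
    :data:`RETAIN_SOURCE_ID` keep their original identifiers.
    """
    prefixes: dict[str, str] = {}
    for etype, scheme in schemes.items():
        if isinstance(scheme, IdScheme):
            if scheme.prefix in prefixes.values():
                raise ConfigurationError(
                    f"prefix {scheme.prefix!r} assigned to more than one type"
                )
            prefixes[etype] = scheme.prefix

    present = {rec.entity_type for rec in entities}
    missing = present - set(schemes)
    if missing:
        raise ConfigurationError(f"no ID scheme for entity types {sorted(missing)}")

    mapping: dict[str, str] = {}
    by_type: dict[str, list[EntityRecord]] = defaultdict(list)
    for rec in entities:
        by_type[rec.entity_type].append(rec)
    for etype, recs in by_type.items():
        scheme = schemes[etype]
        if scheme == RETAIN_SOURCE_ID:
            for rec in recs:
                mapping[rec.entity_id] = rec.entity_id
            continue
        assert isinstance(scheme, IdScheme)
        ordered = sorted(recs, key=lambda r: (r.name.casefold(), r.source_db, r.entity_id))
        for i, rec in enumerate(ordered, start=1):
            mapping[rec.entity_id] = f"{scheme.prefix}{i:0{scheme.width}d}"
    if len(set(mapping.values())) != len(mapping):
        raise ConfigurationError("ID scheme produced colliding identifiers")
    return mapping


def apply_id_mapping(
    store: KnowledgeGraphStore, mapping: Mapping[str, str]
) -> KnowledgeGraphStore:
    """Rebuild a store with entity ids rewritten through ``mapping``."""
    ents = [
        EntityRecord(mapping.get(r.entity_id, r.entity_id), r.name, r.entity_type, r.source_db)
        for r in store.entities.values()
    ]
    trips = [
        TripleRecord(
            mapping.get(t.head_id, t.head_id),
            t.relation,
            mapping.get(t.tail_id, t.tail_id),
            t.source_db,
        )
        for t in store.triples
    ]
    return KnowledgeGraphStore(ents, trips, strict=True)
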