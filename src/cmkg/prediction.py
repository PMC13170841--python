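"""Gene-bridged, meta-path-constrained ranking of drug candidates.

A target disease is first expanded to its bridge genes (every gene adjacent
to the disease in either direction). Each candidate of an allowed type (herb
or compound) is then scored against the bridge genes under a fixed set of
drug-gene meta-path relations using the trained embedding scorer, and the
top candidates per type are retained. The score of a candidate aggregates
its (relation, gene) score grid as the mean of the top-m cells, rewarding
multi-target support while resisting single-pair outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CMKGError, EntityLookupError
from .embeddings import EmbeddingTable
from .kg_core import KnowledgeGraphStore

#: Drug-to-gene meta-path relations; a gene-headed relation here means the
#: candidate is scored in the tail slot.
DEFAULT_BRIDGE_RELATIONS: tuple[str, ...] = (
    "bind",
    "downregulate",
    "upregulate",
    "act_on",
    "is_associated_with",
)
GENE_HEADED_RELATIONS = frozenset({"is_associated_with"})


@dataclass(frozen=True)
class BridgeSpec:
    """Prediction task: disease, meta-path relations, candidate scope."""

    disease_id: str
    bridge_relations: tuple[str, ...] = DEFAULT_BRIDGE_RELATIONS
    candidate_types: tuple[str, ...] = ("Herb", "Compound")
    top_k: int = 100
    top_m: int = 5  # grid cells averaged per candidate; None/inf = plain mean
    aggregate: str = "top_m_mean"  # "top_m_mean" | "mean" | "max"

    def __post_init__(self) -> None:
        if not self.bridge_relations:
            raise CMKGError("bridge_relations must be non-empty")
        if self.top_k < 1:
            raise CMKGError("top_k must be >= 1")


def disease_gene_bridge(store: KnowledgeGraphStore, disease_id: str) -> set[str]:
    """All Gene entities adjacent to the disease, either direction."""
    if disease_id not in store.entities:
        raise EntityLookupError(disease_id)
    genes = {
        t.tail_id for t in store.out_triples(disease_id)
        if store.entity_type(t.tail_id) == "Gene"
    }
    genes |= {
        t.head_id for t in store.in_triples(disease_id)
        if store.entity_type(t.head_id) == "Gene"
    }
    return genes


def _aggregate(grid: np.ndarray, spec: BridgeSpec) -> float:
    flat = grid.ravel()
    if spec.aggregate == "max":
        return float(flat.max())
    if spec.aggregate == "mean" or spec.top_m is None or spec.top_m >= flat.size:
        return float(flat.mean())
    top = np.sort(flat)[-spec.top_m :]
    return float(top.mean())


def rank_candidates(
    table: EmbeddingTable,
    store: KnowledgeGraphStore,
    spec: BridgeSpec,
    exclude_known: bool = False,
) -> pd.DataFrame:
    """Rank candidates of each allowed type against the disease's bridge genes.

    Each candidate's score grid holds f(candidate, r, gene) for every bridge
    relation r present in the embedding vocabulary and every bridge gene
    (candidate in the tail slot for gene-headed relations). With
    ``exclude_known`` the cells whose triple already exists in the store are
    masked out of the aggregation.
    Returns a frame (rank, entity_id, name, entity_type, score) with at most
    top_k rows per type; ties break by entity_id.
    """
    genes = sorted(disease_gene_bridge(store, spec.disease_id))
    if not genes:
        raise CMKGError(f"disease {spec.disease_id!r} has no bridge genes")
    gene_idx = np.array([table.entity_index[g] for g in genes])
    relations = [r for r in spec.bridge_relations if r in table.relation_index]
    if not relations:
        raise CMKGError("no bridge relation present in the embedding vocabulary")

    frames = []
    for ctype in spec.candidate_types:
        cands = store.entities_of_type(ctype)
        if not cands:
            warnings.warn(f"no candidates of type {ctype!r} in the store")
            continue
        rows = []
        for cand in cands:
            ci = table.entity_index[cand]
            grids = []
            for rel in relations:
                ri = table.relation_index[rel]
                if rel in GENE_HEADED_RELATIONS:
                    h = gene_idx
                    t = np.full(len(genes), ci)
                else:
                    h = np.full(len(genes), ci)
                    t = gene_idx
                scores = table.score_triples(h, np.full(len(genes), ri), t)
                if exclude_known:
                    mask = np.array(
                        [
                            (table.entity_ids[hh], rel, table.entity_ids[tt]) in store
                            for hh, tt in zip(h, t)
                        ]
                    )
                    scores = np.where(mask, -np.inf, scores)
                grids.append(scores)
            grid = np.stack(grids)
            finite = grid[np.isfinite(grid)]
            if finite.size == 0:
                continue
            rows.append((cand, store.entities[cand].name, ctype,
                         _aggregate(finite, spec)))
        rows.sort(key=lambda r: (-r[3], r[0]))
        rows = rows[: spec.top_k]
        frames.append(
            pd.DataFrame(
                [(i + 1, *r) for i, r in enumerate(rows)],
                columns=["rank", "entity_id", "name", "entity_type", "score"],
            )
        )
    if not frames:
        return pd.DataFrame(columns=["rank", "entity_id", "name", "entity_type", "score"])
    return pd.concat(frames, ignore_index=True)
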