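"""Knowledge-graph embeddings: four scoring functions, training, evaluation.

Implements the translational model TransE (f = -||h + r - t||), the bilinear
diagonal model DistMult (f = sum_i h_i r_i t_i), and the two complex-space
models ComplEx (f = Re<h, r, conj(t)>) and RotatE (f = -||h o r - t|| with
unit-modulus relation rotations). Training minimises a pairwise margin
ranking loss with uniform negative sampling by plain SGD with analytic
gradients; evaluation follows the filtered link-prediction protocol
(other known-true triples are removed from the candidate set) and reports
MRR and Hits@K with an average tie policy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import CMKGError, ConstraintError, ShapeError, TrainingError
from .kg_core import KnowledgeGraphStore, TripleRecord

ModelKind = Literal["transE", "distMult", "complEx", "rotatE"]
MODEL_KINDS: tuple[str, ...] = ("transE", "distMult", "complEx", "rotatE")
_COMPLEX_MODELS = {"complEx", "rotatE"}


# -- scoring functions (single-triple, public contract) -------------------


def _check_dims(*vecs: np.ndarray) -> None:
    dims = {np.asarray(v).shape[-1] for v in vecs}
    if len(dims) != 1:
        raise ShapeError(f"mismatched embedding dimensions: {sorted(dims)}")


def score_transe(h: np.ndarray, r: np.ndarray, t: np.ndarray, norm: str = "L2") -> float:
    """-||h + r - t|| (higher is better); L1 or L2 norm."""
    h, r, t = (np.asarray(x, dtype=float) for x in (h, r, t))
    _check_dims(h, r, t)
    diff = h + r - t
    if norm == "L1":
        return float(-np.abs(diff).sum())
    if norm == "L2":
        return float(-np.sqrt((diff**2).sum()))
    raise CMKGError(f"unknown norm {norm!r}")


def score_distmult(h: np.ndarray, r: np.ndarray, t: np.ndarray) -> float:
    """sum_i h_i r_i t_i — symmetric in h and t by commutativity."""
    h, r, t = (np.asarray(x, dtype=float) for x in (h, r, t))
    _check_dims(h, r, t)
    # grouped as (h * t) * r so that swapping h and t is bitwise exact
    return float((h * t * r).sum())


def score_complex(h: np.ndarray, r: np.ndarray, t: np.ndarray) -> float:
    """Re(sum_i h_i r_i conj(t_i)) over complex vectors."""
    h, r, t = (np.asarray(x, dtype=complex) for x in (h, r, t))
    _check_dims(h, r, t)
    return float(np.real((h * r * np.conj(t)).sum()))


def score_rotate(
    h: np.ndarray, r: np.ndarray, t: np.ndarray, tol: float = 1e-6
) -> float:
    """-||h o r - t|| where o rotates h by the unit-modulus relation r."""
    h, r, t = (np.asarray(x, dtype=complex) for x in (h, r, t))
    _check_dims(h, r, t)
    if np.any(np.abs(np.abs(r) - 1.0) > tol):
        raise ConstraintError("rotatE relation coordinates must have |r_i| = 1")
    return float(-np.sqrt((np.abs(h * r - t) ** 2).sum()))


# -- configuration and table ----------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    Defaults document the full-scale protocol (dimension 400, batch 1024,
    200 negatives per positive, L2 penalty 1e-9); tests and examples pass
    desk-scale overrides (d=32, batch 128, 16 negatives).
    """

    dimension: int = 400
    batch_size: int = 1024
    negatives_per_positive: int = 200
    margin: float = 6.0
    learning_rate: float = 0.05
    l2_penalty: float = 1e-9
    epochs: int = 30
    seed: int = 42
    early_stopping: bool = False
    patience: int = 3
    transe_norm: str = "L2"

    def __post_init__(self) -> None:
        for name in ("dimension", "batch_size", "negatives_per_positive", "patience"):
            if getattr(self, name) <= 0:
                raise CMKGError(f"{name} must be positive")
        if self.margin <= 0 or self.learning_rate <= 0:
            raise CMKGError("margin and learning_rate must be positive")
        if self.epochs < 0:
            raise CMKGError("epochs must be >= 0")


@dataclass
class EmbeddingTable:
    """Entity and relation vectors plus the model kind selecting the scorer.

    Real-channel models store (n, d) float arrays. ComplEx stores (n, 2d)
    with real and imaginary channels concatenated. RotatE stores entities as
    (n, 2d) channels and relations as (n_r, d) phase angles, so the
    unit-modulus constraint holds by construction.
    """

    model_kind: str
    dimension: int
    entity_ids: list[str]
    relation_ids: list[str]
    entity_vecs: np.ndarray
    relation_vecs: np.ndarray
    seed: int = 0
    config: TrainConfig | None = None

    def __post_init__(self) -> None:
        self.entity_index = {e: i for i, e in enumerate(self.entity_ids)}
        self.relation_index = {r: i for i, r in enumerate(self.relation_ids)}

    # channel views -------------------------------------------------------

    def _complex_entities(self) -> np.ndarray:
        d = self.dimension
        return self.entity_vecs[:, :d] + 1j * self.entity_vecs[:, d:]

    def _complex_relations(self) -> np.ndarray:
        d = self.dimension
        if self.model_kind == "rotatE":
            return np.exp(1j * self.relation_vecs)
        return self.relation_vecs[:, :d] + 1j * self.relation_vecs[:, d:]

    def entity_vector(self, entity_id: str) -> np.ndarray:
        i = self.entity_index[entity_id]
        if self.model_kind in _COMPLEX_MODELS:
            return self._complex_entities()[i]
        return self.entity_vecs[i]

    def relation_vector(self, relation: str) -> np.ndarray:
        i = self.relation_index[relation]
        if self.model_kind in _COMPLEX_MODELS:
            return self._complex_relations()[i]
        return self.relation_vecs[i]

    # batch scoring -------------------------------------------------------

    def score_triples(
        self, h_idx: np.ndarray, r_idx: np.ndarray, t_idx: np.ndarray
    ) -> np.ndarray:
        """Scores for index arrays of equal (broadcastable) shape."""
        kind = self.model_kind
        norm = (self.config.transe_norm if self.config else "L2")
        if kind in _COMPLEX_MODELS:
            E, R = self._complex_entities(), self._complex_relations()
            h, r, t = E[h_idx], R[r_idx], E[t_idx]
            if kind == "complEx":
                return np.real((h * r * np.conj(t)).sum(axis=-1))
            return -np.sqrt((np.abs(h * r - t) ** 2).sum(axis=-1))
        h, r, t = self.entity_vecs[h_idx], self.relation_vecs[r_idx], self.entity_vecs[t_idx]
        if kind == "transE":
            diff = h + r - t
            if norm == "L1":
                return -np.abs(diff).sum(axis=-1)
            return -np.sqrt((diff**2).sum(axis=-1))
        return (h * t * r).sum(axis=-1)

    def score_all(self, fixed_idx: int, r_idx: int, slot: str) -> np.ndarray:
        """Score every entity substituted into ``slot`` ('head' or 'tail')."""
        n = len(self.entity_ids)
        cand = np.arange(n)
        fixed = np.full(n, fixed_idx)
        if slot == "tail":
            return self.score_triples(fixed, np.full(n, r_idx), cand)
        if slot == "head":
            return self.score_triples(cand, np.full(n, r_idx), fixed)
        raise CMKGError(f"unknown slot {slot!r}")

    def score(self, head_id: str, relation: str, tail_id: str) -> float:
        h = np.array([self.entity_index[head_id]])
        r = np.array([self.relation_index[relation]])
        t = np.array([self.entity_index[tail_id]])
        return float(self.score_triples(h, r, t)[0])

    # persistence ---------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "model_kind": self.model_kind,
            "dimension": self.dimension,
            "seed": self.seed,
            "entity_ids": self.entity_ids,
            "relation_ids": self.relation_ids,
            "config": (self.config.__dict__ if self.config else None),
        }
        (directory / "metadata.json").write_text(json.dumps(meta, indent=1))
        np.save(directory / "entities.npy", self.entity_vecs)
        np.save(directory / "relations.npy", self.relation_vecs)

    @classmethod
    def load(cls, directory: str | Path) -> "EmbeddingTable":
        directory = Path(directory)
        meta = json.loads((directory / "metadata.json").read_text())
        cfg = TrainConfig(**meta["config"]) if meta.get("config") else None
        return cls(
            model_kind=meta["model_kind"],
            dimension=meta["dimension"],
            entity_ids=meta["entity_ids"],
            relation_ids=meta["relation_ids"],
            entity_vecs=np.load(directory / "entities.npy"),
            relation_vecs=np.load(directory / "relations.npy"),
            seed=meta.get("seed", 0),
            config=cfg,
        )


# -- splits and negative sampling -----------------------------------------


def split_triples(
    store: KnowledgeGraphStore,
    fractions: tuple[float, float, float] = (0.9, 0.05, 0.05),
    seed: int = 42,
) -> tuple[list[TripleRecord], list[TripleRecord], list[TripleRecord]]:
    """Random train/validation/test split by triple with a recorded seed."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise CMKGError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(store.triples))
    n_train = int(round(fractions[0] * len(order)))
    n_valid = int(round(fractions[1] * len(order)))
    triples = [store.triples[i] for i in order]
    return (
        triples[:n_train],
        triples[n_train : n_train + n_valid],
        triples[n_train + n_valid :],
    )


def sample_negatives(
    triple: TripleRecord,
    n: int,
    store: KnowledgeGraphStore,
    seed: int = 0,
) -> list[TripleRecord]:
    """n corruptions of one triple, replacing head or tail uniformly.

    The replacement entity is drawn uniformly from all entities other than
    the one it replaces, so each corruption differs from the positive in
    exactly one slot.
    """
    if n <= 0:
        raise CMKGError("n must be positive")
    entity_ids = sorted(store.entities)
    if len(entity_ids) < 2:
        raise CMKGError("need at least 2 entities to corrupt a triple")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        corrupt_head = bool(rng.integers(2))
        current = triple.head_id if corrupt_head else triple.tail_id
        pool = [e for e in entity_ids if e != current]
        repl = pool[rng.integers(len(pool))]
        if corrupt_head:
            out.append(TripleRecord(repl, triple.relation, triple.tail_id, "negative"))
        else:
            out.append(TripleRecord(triple.head_id, triple.relation, repl, "negative"))
    return out


# -- training -------------------------------------------------------------


def _init_table(
    store: KnowledgeGraphStore, model_kind: str, config: TrainConfig
) -> EmbeddingTable:
    if model_kind not in MODEL_KINDS:
        raise CMKGError(f"unknown model kind {model_kind!r}")
    rng = np.random.default_rng(config.seed)
    entity_ids = sorted(store.entities)
    relation_ids = sorted(store.relation_vocabulary)
    d = config.dimension
    bound = 6.0 / np.sqrt(d)
    n_channels = 2 if model_kind in _COMPLEX_MODELS else 1
    ent = rng.uniform(-bound, bound, size=(len(entity_ids), n_channels * d))
    if model_kind == "rotatE":
        rel = rng.uniform(-np.pi, np.pi, size=(len(relation_ids), d))
    else:
        rel = rng.uniform(-bound, bound, size=(len(relation_ids), n_channels * d))
    return EmbeddingTable(model_kind, d, entity_ids, relation_ids, ent, rel,
                          seed=config.seed, config=config)


def _score_and_grads(
    table: EmbeddingTable,
    h: np.ndarray,
    r: np.ndarray,
    t: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Scores and per-parameter gradients df/dH, df/dR, df/dT.

    Index arrays share one shape S; gradient arrays have shape S + (width,)
    matching the stored parameter width of each embedding matrix.
    """
    kind = table.model_kind
    d = table.dimension
    E, R = table.entity_vecs, table.relation_vecs
    eps = 1e-12
    if kind == "transE":
        H, Rv, T = E[h], R[r], E[t]
        diff = H + Rv - T
        if (table.config.transe_norm if table.config else "L2") == "L1":
            f = -np.abs(diff).sum(axis=-1)
            g = -np.sign(diff)
        else:
            nrm = np.sqrt((diff**2).sum(axis=-1)) + eps
            f = -nrm + eps
            g = -diff / nrm[..., None]
        return f, g, g, -g
    if kind == "distMult":
        H, Rv, T = E[h], R[r], E[t]
        return (H * Rv * T).sum(axis=-1), Rv * T, H * T, H * Rv
    if kind == "complEx":
        hr, hi = E[h][..., :d], E[h][..., d:]
        rr, ri = R[r][..., :d], R[r][..., d:]
        tr, ti = E[t][..., :d], E[t][..., d:]
        f = (hr * rr * tr + hr * ri * ti + hi * rr * ti - hi * ri * tr).sum(axis=-1)
        dH = np.concatenate([rr * tr + ri * ti, rr * ti - ri * tr], axis=-1)
        dR = np.concatenate([hr * tr + hi * ti, hr * ti - hi * tr], axis=-1)
        dT = np.concatenate([hr * rr - hi * ri, hr * ri + hi * rr], axis=-1)
        return f, dH, dR, dT
    # rotatE: entities as channel pairs, relations as phases
    hr, hi = E[h][..., :d], E[h][..., d:]
    tr, ti = E[t][..., :d], E[t][..., d:]
    theta = R[r]
    c, s = np.cos(theta), np.sin(theta)
    rot_r = hr * c - hi * s
    rot_i = hr * s + hi * c
    dr_, di_ = rot_r - tr, rot_i - ti
    nrm = np.sqrt((dr_**2 + di_**2).sum(axis=-1)) + eps
    f = -nrm + eps
    gr, gi = -dr_ / nrm[..., None], -di_ / nrm[..., None]
    dH = np.concatenate([gr * c + gi * s, -gr * s + gi * c], axis=-1)
    dT = np.concatenate([-gr, -gi], axis=-1)
    dR = gr * (-rot_i) + gi * rot_r
    return f, dH, dR, dT


def train(
    store: KnowledgeGraphStore,
    model_kind: str,
    config: TrainConfig,
    triples: Sequence[TripleRecord] | None = None,
    valid: Sequence[TripleRecord] | None = None,
) -> tuple[EmbeddingTable, list[float]]:
    """SGD on the pairwise margin ranking loss, fully seeded.

    ``triples`` defaults to every triple in the store (pass a train split for
    evaluation work). With ``early_stopping`` and a validation split, training
    stops when validation loss has not improved for ``patience`` epochs.
    Returns the table and the per-epoch training-loss trace.
    """
    table = _init_table(store, model_kind, config)
    data = list(triples if triples is not None else store.triples)
    if not data:
        raise CMKGError("training requires a non-empty triple collection")
    rng = np.random.default_rng(config.seed + 1)
    h_all = np.array([table.entity_index[t.head_id] for t in data])
    r_all = np.array([table.relation_index[t.relation] for t in data])
    t_all = np.array([table.entity_index[t.tail_id] for t in data])
    n_ent = len(table.entity_ids)
    n_neg = config.negatives_per_positive
    trace: list[float] = []
    best_valid, stale = np.inf, 0

    for epoch in range(config.epochs):
        order = rng.permutation(len(data))
        epoch_loss, n_pairs = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            h, r, t = h_all[idx], r_all[idx], t_all[idx]
            B = len(idx)
            corrupt_head = rng.integers(2, size=(B, n_neg)).astype(bool)
            repl = rng.integers(n_ent, size=(B, n_neg))
            hn = np.where(corrupt_head, repl, h[:, None])
            tn = np.where(corrupt_head, t[:, None], repl)
            rn = np.broadcast_to(r[:, None], (B, n_neg))

            f_pos, dHp, dRp, dTp = _score_and_grads(table, h, r, t)
            f_neg, dHn, dRn, dTn = _score_and_grads(table, hn, rn, tn)
            active = (config.margin - f_pos[:, None] + f_neg) > 0
            loss = np.where(active, config.margin - f_pos[:, None] + f_neg, 0.0)
            epoch_loss += float(loss.sum())
            n_pairs += loss.size

            scale = 1.0 / loss.size
            w_pos = -active.sum(axis=1) * scale  # dL/df_pos
            w_neg = active * scale  # dL/df_neg

            gE = np.zeros_like(table.entity_vecs)
            gR = np.zeros_like(table.relation_vecs)
            np.add.at(gE, h, w_pos[:, None] * dHp)
            np.add.at(gE, t, w_pos[:, None] * dTp)
            np.add.at(gR, r, w_pos[:, None] * dRp)
            np.add.at(gE, hn.ravel(), (w_neg[..., None] * dHn).reshape(-1, dHn.shape[-1]))
            np.add.at(gE, tn.ravel(), (w_neg[..., None] * dTn).reshape(-1, dTn.shape[-1]))
            np.add.at(gR, rn.ravel(), (w_neg[..., None] * dRn).reshape(-1, dRn.shape[-1]))

            table.entity_vecs -= config.learning_rate * (
                gE + config.l2_penalty * table.entity_vecs
            )
            table.relation_vecs -= config.learning_rate * (
                gR + config.l2_penalty * table.relation_vecs
            )
            if model_kind == "rotatE":
                # keep phases wrapped; |r_i| = 1 holds by parametrisation
                np.mod(table.relation_vecs + np.pi, 2 * np.pi, out=table.relation_vecs)
                table.relation_vecs -= np.pi

        mean_loss = epoch_loss / max(n_pairs, 1)
        if not np.isfinite(mean_loss):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        trace.append(mean_loss)

        if config.early_stopping and valid:
            v = _validation_loss(table, valid, config, seed=config.seed + 2)
            if v < best_valid - 1e-6:
                best_valid, stale = v, 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
    return table, trace


def _validation_loss(
    table: EmbeddingTable,
    valid: Sequence[TripleRecord],
    config: TrainConfig,
    seed: int,
) -> float:
    rng = np.random.default_rng(seed)
    h = np.array([table.entity_index[t.head_id] for t in valid])
    r = np.array([table.relation_index[t.relation] for t in valid])
    t = np.array([table.entity_index[t.tail_id] for t in valid])
    n_ent = len(table.entity_ids)
    n_neg = min(config.negatives_per_positive, 16)
    corrupt_head = rng.integers(2, size=(len(valid), n_neg)).astype(bool)
    repl = rng.integers(n_ent, size=(len(valid), n_neg))
    hn = np.where(corrupt_head, repl, h[:, None])
    tn = np.where(corrupt_head, t[:, None], repl)
    rn = np.broadcast_to(r[:, None], (len(valid), n_neg))
    f_pos = table.score_triples(h, r, t)
    f_neg = table.score_triples(hn, rn, tn)
    return float(np.maximum(0.0, config.margin - f_pos[:, None] + f_neg).mean())


# -- filtered evaluation --------------------------------------------------


@dataclass(frozen=True)
class EvalResult:
    """Filtered-protocol metrics, averaged over both ranking directions."""

    mrr: float
    hits_at: dict[int, float]
    n_test: int

    def as_dict(self) -> dict:
        return {"mrr": self.mrr, **{f"hits@{k}": v for k, v in self.hits_at.items()}, "n": self.n_test}


def _average_rank(scores: np.ndarray, true_idx: int) -> float:
    s = scores[true_idx]
    higher = int((scores > s).sum())
    ties = int((scores == s).sum())  # includes the true candidate
    return higher + (ties + 1) / 2.0


def evaluate_filtered(
    table: EmbeddingTable,
    test: Sequence[TripleRecord],
    store: KnowledgeGraphStore,
    ks: Iterable[int] = (1, 3, 10),
    filtered: bool = True,
) -> EvalResult:
    """Rank each test triple's head and tail against all entities.

    Under the filtered protocol, candidate entities forming other known-true
    triples (anywhere in the store) are removed before ranking; the test
    triple itself is kept. Ranks use the average tie policy.
    """
    if not test:
        raise CMKGError("test set must be non-empty")
    ks = sorted(ks)
    known_tails: dict[tuple[int, int], set[int]] = {}
    known_heads: dict[tuple[int, int], set[int]] = {}
    ei, ri = table.entity_index, table.relation_index
    for tr in store.triples:
        h, r, t = ei[tr.head_id], ri[tr.relation], ei[tr.tail_id]
        known_tails.setdefault((h, r), set()).add(t)
        known_heads.setdefault((r, t), set()).add(h)

    ranks: list[float] = []
    for tr in test:
        h, r, t = ei[tr.head_id], ri[tr.relation], ei[tr.tail_id]
        tail_scores = table.score_all(h, r, "tail").copy()
        if filtered:
            drop = known_tails.get((h, r), set()) - {t}
            tail_scores[list(drop)] = -np.inf
        ranks.append(_average_rank(tail_scores, t))
        head_scores = table.score_all(t, r, "head").copy()
        if filtered:
            drop = known_heads.get((r, t), set()) - {h}
            head_scores[list(drop)] = -np.inf
        ranks.append(_average_rank(head_scores, h))

    arr = np.array(ranks)
    return EvalResult(
        mrr=float((1.0 / arr).mean()),
        hits_at={k: float((arr <= k).mean()) for k in ks},
        n_test=len(test),
    )


def evaluate_seeds(
    store: KnowledgeGraphStore,
    model_kind: str,
    config: TrainConfig,
    seeds: Sequence[int] = (42, 123, 2026),
    split_seed: int = 42,
) -> dict:
    """Multi-seed stability run: train/evaluate per seed, report mean and sd."""
    per_seed = []
    for seed in seeds:
        cfg = replace(config, seed=seed)
        train_t, valid_t, test_t = split_triples(store, seed=split_seed)
        table, _ = train(store, model_kind, cfg, triples=train_t, valid=valid_t)
        per_seed.append((seed, evaluate_filtered(table, test_t, store)))
    mrrs = np.array([r.mrr for _, r in per_seed])
    hits10 = np.array([r.hits_at[10] for _, r in per_seed])
    return {
        "per_seed": [(s, r.as_dict()) for s, r in per_seed],
        "mrr_mean": float(mrrs.mean()),
        "mrr_std": float(mrrs.std()),
        "hits10_mean": float(hits10.mean()),
        "hits10_std": float(hits10.std()),
    }
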