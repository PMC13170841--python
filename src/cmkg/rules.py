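"""Horn chain rules: AnyBURL-dialect I/O, path-sampling mining, grounding.

A chain rule ``head(X, Y) <= b1(X, A1), ..., bL(A_{L-1}, Y)`` asserts that a
relation is implied by a relation path between the same endpoints. Its
confidence is support / body_count, where body_count is the number of
distinct (X, Y) pairs connected by the body chain and support counts those
pairs for which the head triple is actually present.

The miner follows the random-path-sampling recipe: draw a bounded random walk
whose endpoints are also joined by a direct edge, generalise the walk to a
variable chain, then compute exact support and body counts by brute-force
grounding. Body atoms may traverse an edge against its direction; such atoms
carry the ``^-1`` suffix on the relation name.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import CMKGError, EntityLookupError, RuleParseError
from .kg_core import KnowledgeGraphStore
from .paths import MechanisticPath

INVERSE_SUFFIX = "^-1"


def invert(relation: str) -> str:
    if relation.endswith(INVERSE_SUFFIX):
        return relation[: -len(INVERSE_SUFFIX)]
    return relation + INVERSE_SUFFIX


def is_inverse(relation: str) -> bool:
    return relation.endswith(INVERSE_SUFFIX)


@dataclass(frozen=True)
class Atom:
    """relation(arg1, arg2); args are variables (X, Y, A, B, ...) or constants."""

    relation: str
    arg1: str
    arg2: str

    def __str__(self) -> str:
        return f"{self.relation}({self.arg1},{self.arg2})"


_VARIABLES = ("X", "A", "B", "C", "D", "E", "F", "Y")


@dataclass(frozen=True)
class HornRule:
    """Chain rule with exact counting statistics.

    ``confidence == support / body_count`` holds exactly in integer
    arithmetic for mined rules; parsed rules are cross-checked within 1e-4.
    """

    head: Atom
    body: tuple[Atom, ...]
    support: int
    body_count: int
    confidence: float

    def __post_init__(self) -> None:
        if not self.body:
            raise CMKGError("rule body must be non-empty")
        if not 0.0 < self.confidence <= 1.0:
            raise CMKGError(f"confidence {self.confidence} outside (0, 1]")

    @property
    def body_relations(self) -> tuple[str, ...]:
        return tuple(a.relation for a in self.body)

    def is_chain(self) -> bool:
        """True when the body is a connected X -> ... -> Y variable chain."""
        if self.head.arg1 != "X" or self.head.arg2 != "Y":
            return False
        expected_first = "X"
        for i, atom in enumerate(self.body):
            if atom.arg1 != expected_first:
                return False
            last = i == len(self.body) - 1
            if last:
                if atom.arg2 != "Y":
                    return False
            else:
                if atom.arg2 in ("X", "Y") or not atom.arg2.isupper():
                    return False
                expected_first = atom.arg2
        return True

    def format_line(self) -> str:
        body = ", ".join(str(a) for a in self.body)
        return f"{self.support}\t{self.body_count}\t{self.confidence:.6g}\t{self.head} <= {body}"


# -- parsing --------------------------------------------------------------

_ATOM_RE = re.compile(r"\s*([^\s(,]+)\(\s*([^,()\s]+)\s*,\s*([^,()\s]+)\s*\)\s*")


def _parse_atom(text: str, lineno: int) -> Atom:
    m = _ATOM_RE.fullmatch(text)
    if not m:
        raise RuleParseError(f"line {lineno}: malformed atom {text!r}")
    return Atom(m.group(1), m.group(2), m.group(3))


def parse_rules(
    path: str | Path,
    max_hops: int = 4,
    strict_confidence: bool = False,
) -> list[HornRule]:
    """Parse the 4-field tab-separated dialect.

    Each line is ``support<TAB>body_count<TAB>confidence<TAB>head <= body``.
    A body longer than ``max_hops`` atoms is a length error. A confidence
    drifting more than 1e-4 from support/body_count raises when
    ``strict_confidence`` else is repaired to the exact ratio.
    """
    rules: list[HornRule] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise RuleParseError(f"line {lineno}: expected 4 tab-separated fields")
        try:
            support, body_count = int(fields[0]), int(fields[1])
            confidence = float(fields[2])
        except ValueError as exc:
            raise RuleParseError(f"line {lineno}: bad numeric field: {exc}") from None
        if "<=" not in fields[3]:
            raise RuleParseError(f"line {lineno}: missing '<=' implication")
        head_text, body_text = fields[3].split("<=", 1)
        head = _parse_atom(head_text, lineno)
        # atoms contain commas between their arguments, so split on ")," and
        # restore the closing paren
        parts = [p.strip() for p in body_text.split("),")]
        parts = [p if p.endswith(")") else p + ")" for p in parts]
        body = tuple(_parse_atom(a, lineno) for a in parts)
        if len(body) > max_hops:
            raise RuleParseError(
                f"line {lineno}: body of {len(body)} atoms exceeds max_hops={max_hops}"
            )
        exact = support / body_count if body_count else 0.0
        if abs(exact - confidence) > 1e-4:
            if strict_confidence:
                raise RuleParseError(
                    f"line {lineno}: confidence {confidence} != support/body_count {exact:.6g}"
                )
            confidence = exact
        rules.append(HornRule(head, body, support, body_count, confidence))
    return rules


def write_rules(rules: Iterable[HornRule], path: str | Path) -> None:
    Path(path).write_text("".join(r.format_line() + "\n" for r in rules))


# -- grounding ------------------------------------------------------------


def _step(
    store: KnowledgeGraphStore, entity: str, relation: str
) -> list[str]:
    """Entities reachable from ``entity`` via one body atom (handles ^-1)."""
    if is_inverse(relation):
        base = invert(relation)
        return sorted({t.head_id for t in store.in_triples(entity) if t.relation == base})
    return sorted({t.tail_id for t in store.out_triples(entity) if t.relation == relation})


def _chain_groundings(
    store: KnowledgeGraphStore,
    relations: Sequence[str],
    start: str,
    end: str | None = None,
) -> list[tuple[str, ...]]:
    """All entity sequences instantiating the relation chain from ``start``;
    restricted to those ending at ``end`` when given."""
    seqs: list[tuple[str, ...]] = [(start,)]
    for rel in relations:
        nxt: list[tuple[str, ...]] = []
        for seq in seqs:
            for e in _step(store, seq[-1], rel):
                nxt.append(seq + (e,))
        seqs = nxt
        if not seqs:
            return []
    if end is not None:
        seqs = [s for s in seqs if s[-1] == end]
    return seqs


def count_rule_statistics(
    store: KnowledgeGraphStore, head_relation: str, body_relations: Sequence[str]
) -> tuple[int, int]:
    """Exact (support, body_count) over distinct (X, Y) endpoint pairs."""
    pairs: set[tuple[str, str]] = set()
    for start in store.entities:
        for seq in _chain_groundings(store, body_relations, start):
            if seq[-1] != start:
                pairs.add((start, seq[-1]))
    support = sum(1 for x, y in pairs if (x, head_relation, y) in store)
    return support, len(pairs)


def ground_rule(
    rule: HornRule,
    store: KnowledgeGraphStore,
    source: str,
    target: str,
) -> list[MechanisticPath]:
    """Instantiate the rule body with X=source, Y=target.

    Each grounding becomes a rule-origin mechanistic path carrying the rule's
    confidence. Inverse atoms contribute their base relation name to the path
    (the path states which edge was used, not the traversal direction).
    """
    for eid in (source, target):
        if eid not in store.entities:
            raise EntityLookupError(eid)
    if not rule.is_chain():
        return []
    out: dict[tuple, MechanisticPath] = {}
    display = tuple(invert(r) if is_inverse(r) else r for r in rule.body_relations)
    for seq in _chain_groundings(store, rule.body_relations, source, end=target):
        p = MechanisticPath(seq, display, origin="Rule", c_rule=rule.confidence)
        out.setdefault(p.signature, p)
    return list(out.values())


# -- mining ---------------------------------------------------------------


def mine_rules(
    store: KnowledgeGraphStore,
    n_samples: int,
    max_len: int = 4,
    seed: int = 0,
) -> list[HornRule]:
    """Random-path-sampling chain-rule miner with exact confidences.

    Each sample draws a known-true triple (h, r, t) and a walk length in
    [1, max_len], then probes for a random simple path from h to t of that
    length over forward and inverse edges (a single-edge body identical to
    the head atom is not evidence and is skipped). A found path generalises
    to a candidate chain rule; support and body counts are then computed
    exactly by brute-force grounding. Deterministic given ``seed``; the rule
    set grows monotonically with ``n_samples`` under the same seed stream.
    """
    if n_samples <= 0:
        raise CMKGError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    if not store.entities or not store.triples:
        return []

    def random_path(start: str, end: str, length: int, budget: int = 200) -> list[str] | None:
        """Randomised depth-first probe for a simple path of exact length."""
        expansions = [budget]

        def probe(node: str, depth: int, visited: set[str], rels: list[str]) -> list[str] | None:
            if depth == length:
                return list(rels) if node == end else None
            if expansions[0] <= 0:
                return None
            expansions[0] -= 1
            options = [(t.relation, t.tail_id) for t in store.out_triples(node)]
            options += [(invert(t.relation), t.head_id) for t in store.in_triples(node)]
            options = sorted({o for o in options if o[1] not in visited or (o[1] == end and depth == length - 1)})
            if not options:
                return None
            for k in rng.permutation(len(options)):
                rel, nxt = options[k]
                if depth == length - 1 and nxt != end:
                    continue
                if length == 1 and rel in head_exclude:
                    continue
                rels.append(rel)
                visited.add(nxt)
                hit = probe(nxt, depth + 1, visited, rels)
                visited.discard(nxt)
                rels.pop()
                if hit is not None:
                    return hit
            return None

        return probe(start, 0, {start}, [])

    found: dict[tuple[str, tuple[str, ...]], HornRule] = {}
    for _ in range(n_samples):
        tr = store.triples[rng.integers(len(store.triples))]
        start, head_rel, end = tr.head_id, tr.relation, tr.tail_id
        if start == end:
            continue
        length = int(rng.integers(1, max_len + 1))
        head_exclude = {head_rel}
        walk_rels = random_path(start, end, length)
        if walk_rels is None:
            continue
        key = (head_rel, tuple(walk_rels))
        if key not in found:
            support, body_count = count_rule_statistics(store, head_rel, walk_rels)
            if support == 0 or body_count == 0:
                continue
            atoms = []
            for i, rel in enumerate(walk_rels):
                a1 = _VARIABLES[0] if i == 0 else _VARIABLES[i]
                a2 = "Y" if i == len(walk_rels) - 1 else _VARIABLES[i + 1]
                atoms.append(Atom(rel, a1, a2))
            found[key] = HornRule(
                head=Atom(head_rel, "X", "Y"),
                body=tuple(atoms),
                support=support,
                body_count=body_count,
                confidence=support / body_count,
            )
    return sorted(found.values(), key=lambda r: (-r.confidence, str(r.head), r.body_relations))
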