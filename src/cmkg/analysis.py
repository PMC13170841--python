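"""Sensitivity and ablation harnesses for the unified path score.

Three instruments: the lambda_DFS sweep (how the calibration factor shifts
the rule/search composition of the top-k explanation list), rank-consistency
robustness (intersection-over-union of top-k lists under perturbed scoring
configurations, averaged over a panel of drugs), and the ablation metrics
(average path specificity via the ISI, the fraction of experimentally
evidenced edges, and the rule contribution of the top-k list).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CMKGError
from .kg_core import KnowledgeGraphStore
from .paths import (
    IngredientFrequencyIndex,
    MechanisticPath,
    PathScoreBreakdown,
    ScoringConfig,
    dfs_paths,
    isi_factor,
    rank_paths,
)
from .rules import HornRule, ground_rule

RankedList = Sequence[tuple[MechanisticPath, PathScoreBreakdown]]


def rule_ratio(topk: RankedList | Sequence[MechanisticPath]) -> float:
    """Fraction of paths in the list whose origin is a mined rule."""
    paths = [p[0] if isinstance(p, tuple) else p for p in topk]
    if not paths:
        raise CMKGError("rule_ratio of an empty list is undefined")
    return sum(1 for p in paths if p.origin == "Rule") / len(paths)


DEFAULT_LAMBDA_GRID: tuple[float, ...] = (0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0)


def lambda_sweep(
    rule_paths: Sequence[MechanisticPath],
    dfs_paths_: Sequence[MechanisticPath],
    store: KnowledgeGraphStore,
    config: ScoringConfig = ScoringConfig(),
    index: IngredientFrequencyIndex | None = None,
    grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    k: int = 10,
) -> pd.DataFrame:
    """Re-rank the hybrid pool at each lambda and report the composition.

    Returns a frame (lambda, rule_ratio, mean_topk_score). The rule ratio is
    non-increasing in lambda because only DFS path scores scale with it.
    """
    if not grid:
        raise CMKGError("lambda grid must be non-empty")
    rows = []
    for lam in grid:
        cfg = replace(config, lambda_dfs=lam)
        ranked = rank_paths(rule_paths, dfs_paths_, store, cfg, index, k=k)
        scores = [b.final_score for _, b in ranked]
        rows.append((lam, rule_ratio(ranked), float(np.mean(scores)) if scores else 0.0))
    return pd.DataFrame(rows, columns=["lambda", "rule_ratio", "mean_topk_score"])


def iou(list_a: RankedList | Sequence[MechanisticPath],
        list_b: RankedList | Sequence[MechanisticPath]) -> float:
    """Intersection over union of two top-k lists by path signature."""
    a = {(p[0] if isinstance(p, tuple) else p).signature for p in list_a}
    b = {(p[0] if isinstance(p, tuple) else p).signature for p in list_b}
    if not a and not b:
        raise CMKGError("IoU of two empty lists is undefined")
    return len(a & b) / len(a | b)


@dataclass(frozen=True)
class AblationReport:
    avg_isi: float
    evidence_ratio: float
    rule_contribution: float


def ablation_metrics(
    topk: RankedList,
    store: KnowledgeGraphStore,
    config: ScoringConfig = ScoringConfig(),
    index: IngredientFrequencyIndex | None = None,
) -> AblationReport:
    """Specificity, evidence, and rule-provenance summary of a top-k list.

    avg_isi averages the ISI factor over Ingredient node occurrences across
    all listed paths (0.0 when no path carries an ingredient);
    evidence_ratio is the fraction of edges whose relation carries
    experimental evidence; rule_contribution is the rule-origin fraction.
    """
    if not topk:
        raise CMKGError("ablation metrics of an empty list are undefined")
    isi_values: list[float] = []
    n_edges = 0
    n_evidence = 0
    for path, _ in topk:
        for node in path.nodes:
            if store.entity_type(node) == "Ingredient" and index is not None:
                isi_values.append(isi_factor(index, node, config))
        for rel in path.relations:
            n_edges += 1
            if rel in config.evidence_relations:
                n_evidence += 1
    return AblationReport(
        avg_isi=float(np.mean(isi_values)) if isi_values else 0.0,
        evidence_ratio=n_evidence / n_edges if n_edges else 0.0,
        rule_contribution=rule_ratio(topk),
    )


# -- configuration variants -----------------------------------------------


@dataclass(frozen=True)
class VariantConfig:
    """Named overrides of the scoring configuration."""

    name: str
    overrides: Mapping[str, float]

    def apply(self, base: ScoringConfig) -> ScoringConfig:
        return replace(base, **dict(self.overrides))


def sensitivity_variants() -> list[VariantConfig]:
    """The standard sensitivity panel around the baseline configuration:
    weight flattening/sharpening, decay off/strong, bonus off/high, ISI off."""
    return [
        VariantConfig("baseline", {}),
        VariantConfig("weight_no_distinction", {"w_base": 1.0, "other_gene_gene_weight": 1.0}),
        VariantConfig("weight_strong_distinction", {"w_base": 0.2}),
        VariantConfig("no_decay", {"decay_base": 1.0}),
        VariantConfig("strong_decay", {"decay_base": 0.5}),
        VariantConfig("no_bonus", {"bonus_structural": 1.0, "bonus_evidence": 1.0, "bonus_cap": 1.0}),
        VariantConfig("high_bonus", {"bonus_cap": 5.0}),
        VariantConfig("no_isi", {"isi_floor": 1.0}),
    ]


def hybrid_paths_for_drug(
    store: KnowledgeGraphStore,
    drug: str,
    target: str,
    rules: Sequence[HornRule],
    config: ScoringConfig,
) -> tuple[list[MechanisticPath], list[MechanisticPath]]:
    """Rule groundings and DFS paths for one (drug, disease) pair."""
    rp: list[MechanisticPath] = []
    for rule in rules:
        rp.extend(ground_rule(rule, store, drug, target))
    dp = dfs_paths(store, drug, target, config)
    return rp, dp


def run_variants(
    base_config: ScoringConfig,
    variants: Sequence[VariantConfig],
    drugs: Sequence[str],
    target: str,
    store: KnowledgeGraphStore,
    rules: Sequence[HornRule] = (),
    index: IngredientFrequencyIndex | None = None,
    k: int = 10,
) -> pd.DataFrame:
    """Mean IoU against the baseline per variant, plus ablation metrics.

    For each drug, the hybrid path pool is ranked under the baseline and
    under each variant; the IoU of the two top-k lists is averaged over
    drugs (drugs with no paths are skipped and counted in ``attrs``).
    """
    pools = {}
    for drug in drugs:
        rp, dp = hybrid_paths_for_drug(store, drug, target, rules, base_config)
        if rp or dp:
            pools[drug] = (rp, dp)
    skipped = len(drugs) - len(pools)
    if not pools:
        raise CMKGError("no drug in the panel has any path to the target")

    baseline = {
        drug: rank_paths(rp, dp, store, base_config, index, k=k)
        for drug, (rp, dp) in pools.items()
    }
    rows = []
    for variant in variants:
        cfg = variant.apply(base_config)
        ious = []
        all_paths: list[tuple[MechanisticPath, PathScoreBreakdown]] = []
        for drug, (rp, dp) in pools.items():
            ranked = rank_paths(rp, dp, store, cfg, index, k=k)
            ious.append(iou(ranked, baseline[drug]))
            all_paths.extend(ranked)
        report = ablation_metrics(all_paths, store, cfg, index)
        rows.append(
            (
                variant.name,
                float(np.mean(ious)),
                report.avg_isi,
                report.evidence_ratio,
                report.rule_contribution,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["variant", "mean_iou", "avg_isi", "evidence_ratio", "rule_contribution"],
    )
    df.attrs["skipped_drugs"] = skipped
    return df
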