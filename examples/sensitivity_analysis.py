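"""Sensitivity of the path ranking to lambda_DFS and the scoring weights.

Sweeps the DFS calibration factor over [0.05, 1.0] and reports how the
rule/search composition of the top-10 list shifts, then re-ranks a panel of
drugs under perturbed scoring configurations and reports rank consistency
(IoU with the baseline) plus the ablation metrics.
"""

import numpy as np

from cmkg import (
    IngredientFrequencyIndex,
    ScoringConfig,
    SynthesisParams,
    dfs_paths,
    generate_cmkg,
    ground_rule,
    lambda_sweep,
    mine_rules,
    run_variants,
    sensitivity_variants,
)

store, manifest = generate_cmkg(SynthesisParams(seed=42))
config = ScoringConfig()
index = IngredientFrequencyIndex.from_store(store)
disease = manifest["target_disease"]
rules = mine_rules(store, n_samples=5000, max_len=4, seed=42)

drug = "DCP00001"
rule_paths = [p for r in rules for p in ground_rule(r, store, drug, disease)]
search_paths = dfs_paths(store, drug, disease, config)
print("lambda_DFS sweep (rule share of the top-10 list and its mean score):")
print(lambda_sweep(rule_paths, search_paths, store, config, index).to_string(index=False))
print(
    "\nAt lambda = 1 search paths drown out the rules; small lambda hands the"
    " list to rule-grounded paths."
)

rng = np.random.default_rng(42)
pool = store.entities_of_type("Herb") + store.entities_of_type("Compound")
panel = [str(d) for d in rng.choice(pool, size=20, replace=False)]
report = run_variants(config, sensitivity_variants(), panel, disease, store, rules, index)
print("\nVariant robustness over a 20-drug panel (IoU of top-10 vs baseline):")
print(report.round(3).to_string(index=False))
print(
    "\navg_isi is the mean ingredient specificity in the retained paths,"
    " evidence_ratio the share of experimentally evidenced edges, and"
    " rule_contribution the share of rule-derived paths."
)
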