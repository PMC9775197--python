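"""Extract interpretable activity rules from descriptors.

Fits a depth-capped decision tree on a library where a two-group
conjunction (thiol AND sulfonamide present) drives activity, then extracts
anchor-style rules at a 0.80 precision threshold and scores feature
interactions with Friedman's H statistic.
"""

from ureascape import profiling, rules
from ureascape.curation import curate
from ureascape.synthetic import SyntheticConfig, evaluate_recovery, generate_library

records, truth = generate_library(SyntheticConfig.rule_planted(seed=1))
curated, _, _ = curate(records)

X = profiling.descriptor_table(curated["canonical_smiles"])
y = curated["activity_class"].to_numpy()
model = rules.train_activity_tree(X, y, max_depth=10, seed=17)
extracted = rules.extract_rules(model, X, y, precision_threshold=0.80)
interactions = rules.interaction_table(model, X, features=["fr_SH", "fr_sulfonamd", "MolWt"])

print(f"training accuracy: {model.training_accuracy:.3f}")
print(f"rules extracted:   {len(extracted)}\n")
for rule in extracted:
    print(f"  {rule}  [N={rule.n_total}, precision {rule.precision_pct}%]")
print()
print(f"planted rule recovered verbatim: "
      f"{evaluate_recovery(truth, rules=extracted)['rule_recovered']}")
print()
print("feature interaction (one-vs-all H):")
print(interactions.to_string(index=False))
print()
print("The planted conjunction surfaces as its own rule; high H for the two")
print("rule descriptors reflects that neither acts additively on its own.")
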