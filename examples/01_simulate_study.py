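"""Generate a synthetic multi-platform study with planted ground truth.

Prints the study dimensions and what was planted: the DE genes the DEA
stage should recover, the dense hub community the centrality stage should
select, and the drug the matching stage should rank first.
"""

from hubdrug.simulate import (
    SimulationConfig,
    simulate_drug_table,
    simulate_expression,
    simulate_interactions,
)

config = SimulationConfig(seed=1)
matrices, annotation, truth = simulate_expression(config)
interactions = simulate_interactions(config, truth)
drug_table = simulate_drug_table(config, truth)

for m in matrices:
    print(f"{m.platform}: {m.shape[0]} genes x {m.shape[1]} samples")
print(f"planted DE genes: {len(truth.de_genes)} "
      f"({sum(v > 0 for v in truth.de_genes.values())} up, "
      f"{sum(v < 0 for v in truth.de_genes.values())} down)")
print(f"planted hub community: {len(truth.hub_genes)} genes")
print(f"interaction table: {len(interactions)} edges")
print(f"planted drug {truth.true_drug} inhibits {sorted(truth.true_drug_targets)}")
# Each platform carries ~70% shared genes plus a platform-specific slice;
# batch offsets shift both groups equally, so only pooled analysis suffers.
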