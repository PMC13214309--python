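"""Per-platform moderated-t differential expression and the merge step.

Flags genes with adjusted p < 0.05 and |log2FC| > 1 on each platform,
then merges across platforms (union of flagged genes, mean logFC,
direction-discordant genes dropped).
"""

from hubdrug.dea import dea_table, flag_degs, merge_platforms
from hubdrug.expression import normalize
from hubdrug.simulate import SimulationConfig, simulate_expression

matrices, annotation, truth = simulate_expression(SimulationConfig(seed=1))
flagged = []
for m in matrices:
    table = dea_table(normalize(m, "quantile"), annotation)
    degs = flag_degs(table, alpha=0.05, lfc_min=1.0)
    flagged.append(degs)
    print(f"{m.platform}: {len(degs)} DEGs of {len(table)} genes tested")

merged = merge_platforms(flagged)
print(f"merged: {len(merged)} DEGs "
      f"({(merged.direction == 'up').sum()} up, {(merged.direction == 'down').sum()} down)")
recovered = len(set(merged.gene) & set(truth.de_genes)) / len(truth.de_genes)
print(f"planted-DE recovery: {recovered:.1%}")
print(merged.sort_values("mean_logFC", ascending=False).head(3).to_string(index=False))
# mean_logFC is the average over the platforms where the gene was flagged;
# values near +/-2 match the planted effect size.
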