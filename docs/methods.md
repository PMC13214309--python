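# Methods

This note documents the statistical model behind each pipeline stage, the
synthetic-data design, the numerical choices, and the known limitations.

## Differential expression

Each platform is analyzed separately.  The estimand is the log2
fold-change between metastatic and primary groups per gene.  The test is
an empirical-Bayes moderated t: with per-gene pooled variance s²_g on
d = n₁ + n₂ − 2 degrees of freedom, the prior (d₀, s₀²) of a scaled
inverse-chi-square hierarchy is fitted by method of moments on
z = log s²_g — the mean and variance of z are digamma/trigamma
expressions in d and d₀, and the trigamma equation is inverted by Newton
iteration.  The posterior variance is s²_post = (d₀s₀² + d·s²_g)/(d₀+d)
and t = logFC / (s_post·√(1/n₁+1/n₂)) on d₀ + d degrees of freedom.
When the observed spread of log-variances is no larger than sampling
noise the prior degrees of freedom go to infinity and every gene uses
s₀².  With d₀ = 0 (exposed via `prior_df`) the statistic reduces exactly
to the classical pooled-variance t, which the tests exploit as an oracle.
Moment fitting rather than marginal maximum likelihood is a deliberate
simplification: at the simulated scales the two agree to well within the
decision thresholds, and the moment fit has no convergence failure modes.

Multiplicity is controlled by Benjamini–Hochberg step-up (configurable:
Bonferroni, none).  DEG flagging uses strict inequalities — adj. p < 0.05
AND |logFC| > 1 — mirroring the conventional printed thresholds.

Missing values are excluded pairwise per gene; a gene with fewer than two
observations in either group on a platform receives p = 1 there with a
warning rather than failing the run.

**Merge.** Flagged lists are merged as a union: a gene flagged anywhere
is kept, with mean logFC averaged over the platforms where it was
flagged.  Union (rather than intersection) semantics match workflows
whose merged DEG count exceeds individual platform counts.  Genes flagged
with opposite signs on different platforms are contradictory evidence and
are excluded with a logged warning.

**Normalization.** Quantile normalization (all samples share the mean
sorted value vector) is the default, emulating force-normalized
re-analysis; median centering and identity are alternatives.  Inputs
whose maximum exceeds 50 are assumed linear-scale and log2(x+1)
transformed first, with a log message.

## Network construction

Interaction tables carry scores in [0, 1]; STRING-style integer scores in
(1, 1000] are divided by 1000 on load, duplicate undirected pairs
collapse to the maximum score, and self-loops are dropped.  The seed
network is the induced graph on the merged DEGs with edges strictly above
`score_min` = 0.8 (isolated seeds retained).  Expansion adds, per seed
node, at most `max_new_per_node` = 2 non-seed interactors above the
cutoff, ranked by score descending with gene-id ascending as the
tie-break (the ranking is otherwise arbitrary; score order is the only
principled choice).  After additions, every qualifying edge among the
final node set is included, making expansion idempotent and bounding the
node count by |seeds|·3.

Hub analysis runs on the "interconnected core": by default the largest
connected component (ties broken by smallest member id), with a k-core
alternative exposed in configuration, since closeness ranks on isolates
are degenerate.

## Centrality and hub selection

- **Degree** is reported raw (integer neighbor counts).
- **Betweenness** is Brandes' algorithm, computed and pair-normalized
  within each connected component ((n_c−1)(n_c−2)/2 with component-local
  n_c); components smaller than 3 score 0.  The implementation is checked
  against exhaustive shortest-path enumeration on hundreds of small
  random graphs.
- **Closeness** is component-normalized, (r−1)/Σd over the r reachable
  nodes, so every node of a small complete component scores exactly 1.0;
  the Wasserman–Faust cross-component scaling is available via
  configuration.

Hubs per measure are the top ceil(0.15·n) nodes, ordered score descending
then id ascending, with every node tied at the cut included (inclusive
tie policy, documented rather than silent).  The hub set is the union
over the three measures; bookkeeping keeps the (gene, measure) selections
so that a gene topping several measures counts once in the union.
For the drug query, hubs must additionally carry |mean logFC| > 1
(strict); hubs without a merged DEG record — expansion-added non-seeds —
are excluded with a log entry.

## Enrichment

Terms are tested by the hypergeometric upper tail P(X ≥ k) for k query
genes in a term of size K against a universe of N genes, with a minimum
of 3 query genes per testable term.  The universe defaults to the union
of platform panels — the single most consequential analysis choice, so it
is an explicit argument.  Results keep raw p < 0.05 (sorted by p, ties by
term id) and carry BH-adjusted values.  Significant terms are linked into
a term network wherever Cohen's kappa of their 2×2 gene-membership table
exceeds 0.4 (the conventional functional-grouping default); degenerate
tables with chance agreement 1 define κ = 0 with a warning.

## Drug matching

Raw action strings map case-insensitively to three classes
(inhibitory: inhibitor, antagonist, blocker, suppressor, negative
modulator; activating: agonist, activator, inducer, stimulator,
potentiator, positive modulator; anything else: other).  A (drug, gene)
pair matches iff the gene is an up-regulated hub (mean logFC > 1) with an
inhibitory action or a down-regulated hub (mean logFC < −1) with an
activating action; "other" never matches.  Candidates rank by matched-hub
count, then Σ|mean logFC| of matched genes, then drug id — a transparent
mechanical ordering standing in for the literature-guided final choice a
human analyst would make.

## qPCR quantification

ΔCt = mean Ct(target) − mean Ct(reference) per group (arithmetic mean
over replicate wells, the common convention), ΔΔCt = ΔCt(treated) −
ΔCt(control), fold change 2^(−ΔΔCt).  The Pfaffl ratio
E_t^ΔCt_t / E_r^ΔCt_r (ΔCt = control − treated per gene, E = 1 +
efficiency) generalizes this to imperfect amplification and collapses to
2^(−ΔΔCt) at unit efficiencies; efficiencies are validated to be
positive, with a warning above 1.0.  Significance uses a REST-style
fixed-reallocation randomization test: group labels of per-sample ΔCt
values are permuted (default 2,000 times), and the two-sided p-value is
the tie-inclusive fraction of permuted |mean differences| at least the
observed one, with an add-one correction bounding p below by
1/(n_perm+1).  Bootstrap confidence intervals of the proprietary tool are
out of scope.

## Synthetic-data design

The generator emulates a three-platform case-control microarray study.
Defaults: 2,000 genes, 30 + 30 samples per platform, 100 planted DE genes
with |log2FC| = 2 and random sign, within-group SD 0.5, panel overlap
0.7 (each platform carries the shared 70% plus a private slice of the
rest), per-platform per-gene batch offsets with SD 2 added identically to
both groups.  The balanced additive batch design is the minimal
confounder that leaves per-platform analysis clean while inflating
pooled within-group variance — the failure mode that motivates
per-platform DEA followed by a merge.  It deliberately omits
probe-level artifacts, intensity-dependent (non-additive) effects and
unbalanced group-platform confounding.

The interaction network is preferential attachment (2 edges per added
node, giving the heavy-tailed degree distribution of real PPI networks)
with background scores uniform in [0.4, 1.0].  A planted community of 25
genes, drawn from the planted DE genes, receives within-community edges
with probability 0.9 and scores in [0.8, 1.0].  Two design points matter:
the community is drawn from DE genes because the workflow can only
surface hubs that enter the network as differentially expressed seeds,
and its size is commensurate with the distinct-hub yield of a top-15%
selection on the resulting core (3 lists with partial overlap), mirroring
published studies where the selected hubs themselves form the dense local
community.  Recovery of the community is intentionally partial:
betweenness also rewards bridge nodes outside any dense community, which
caps the selected-vs-planted Jaccard well below 1 — the recovery
experiments assert ≥ 0.5.

The gene-set collection has one planted set (20 genes, 75% drawn from the
DE genes) and 50 uniform background sets of 10–50 genes.  The drug table
has one planted drug with inhibitor actions on 3 up-regulated planted
hubs and 19 decoys with 2–5 random targets and random actions; one decoy
always inhibits a down-regulated gene so the direction filter is
exercised.  qPCR wells place the reference gene at 20 cycles and targets
at 25 (control) and 25 − log2(ratio) (treated), so the expected
2^(−ΔΔCt) equals the planted ratio exactly.

All randomness derives from a single integer seed through named
per-operation streams; identical configurations reproduce byte-identical
outputs, which the tests assert at the file level.

What passing recovery tests show — and what they do not: the pipeline
correctly inverts data generated under its own assumptions (additive
batch effects, Gaussian noise, a single dense community, action
vocabularies that map cleanly).  Real microarray data violate several of
these (probe effects, correlated noise, overlapping communities,
free-text drug actions), so recovery rates here are upper bounds, not
forecasts.

## Problem sizes and runtime

Recovery experiments use 20 seeds of the default study; the null control
uses 10 seeds plus 500 simulated qPCR datasets at 2,000 permutations
each.  The full test suite runs in ~10 s and the acceptance script in
~10 s on one CPU, so the experiments are comfortably repeatable at larger
sizes by raising the constants.

## Known limitations

- No probe-to-gene collapsing, surrogate-variable correction, or GEO
  format parsing: inputs are gene-level TSV matrices.
- Per-platform DEG counts and the published network's node counts depend
  on the original data and database releases and are not reproduction
  targets; the bundled worked examples cover the hub bookkeeping and the
  drug query, which are release-independent.
- Tissue-specific gene removal (a pre-filter in some studies) has no
  stated criterion and is not modeled.
- The enrichment module does no ontology traversal; terms are flat sets.
- The final drug choice among top candidates is a human, literature-based
  step; the ranking here is mechanical and transparent.
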