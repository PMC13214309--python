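"""Synthetic multi-platform studies with planted ground truth.

The generator emulates the statistical structure the pipeline assumes:
several microarray platforms with partially overlapping gene panels and
additive per-platform, per-gene batch offsets (shared by both groups, so
per-platform analysis is clean while naive pooling inflates within-group
variance); a primary-vs-metastatic contrast with planted log2
fold-changes; a scale-free background interaction network carrying a
dense planted community enriched for planted DE genes; a gene-set
collection with one planted enriched set; and a drug-target table whose
planted drug inhibits several up-regulated planted hubs.

All randomness flows from ``SimulationConfig.seed``; per-operation
streams are derived deterministically, so identical configs reproduce
identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from hubdrug.enrichment import GeneSet
from hubdrug.expression import ExpressionMatrix

BASELINE_MEAN = 7.0  # log2 intensity center of non-DE genes
BASELINE_SD = 1.0
# The planted community is drawn from the DE genes (falling back to non-DE
# genes only when n_de is smaller than the community): the workflow can only
# surface hubs that enter the network as differentially expressed seeds, and
# its size is commensurate with the distinct-hub count a top-15% selection
# on the resulting core yields.
HUB_DE_FRACTION = 1.0
DECOY_ACTIONS = ("inhibitor", "antagonist", "agonist", "activator", "binder", "ligand")


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic generator.

    Defaults describe a desk-scale three-platform case-control microarray
    study: 2,000 genes, 30 primary + 30 metastatic samples per platform,
    100 planted DE genes at |log2FC| = 2 with within-group SD 0.5 and
    platform offsets of SD 2, a 25-gene planted hub community (edge
    probability 0.9, drawn from the DE genes) on a preferential-attachment
    background, and a 20-drug table whose planted drug inhibits 3
    up-regulated hubs.
    """

    n_genes: int = 2000
    n_platforms: int = 3
    panel_overlap: float = 0.7
    n_primary: int = 30
    n_metastatic: int = 30
    n_de: int = 100
    effect_size: float = 2.0
    noise_sd: float = 0.5
    batch_sd: float = 2.0
    net_attach: int = 2
    hub_community_size: int = 25
    hub_community_p: float = 0.9
    n_drugs: int = 20
    planted_drug_targets: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_platforms < 1:
            raise ValueError("n_genes and n_platforms must be positive")
        if self.n_primary <= 0 or self.n_metastatic <= 0:
            raise ValueError("sample counts must be positive")
        if not 0 <= self.panel_overlap <= 1:
            raise ValueError("panel_overlap must lie in [0, 1]")
        if self.n_de > self.n_genes:
            raise ValueError("n_de exceeds n_genes")
        if self.hub_community_size > self.n_genes:
            raise ValueError("hub_community_size exceeds n_genes")
        if min(self.n_de, self.effect_size, self.noise_sd, self.batch_sd,
               self.net_attach, self.hub_community_size, self.n_drugs,
               self.planted_drug_targets) < 0:
            raise ValueError("counts and scales must be nonnegative")
        if not 0 <= self.hub_community_p <= 1:
            raise ValueError("hub_community_p must lie in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic per-operation random stream."""
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class GroundTruth:
    """Planted signal: DE genes with true log2FC, hub community, drug."""

    de_genes: dict[str, float] = field(default_factory=dict)
    hub_genes: set[str] = field(default_factory=set)
    true_drug: str = ""
    true_drug_targets: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        up = {g for g, lfc in self.de_genes.items() if lfc > 0}
        if not self.true_drug_targets <= (self.hub_genes & up) and self.true_drug_targets:
            raise ValueError("drug targets must be up-regulated planted hubs")

    def to_json(self, path) -> None:
        payload = {
            "de_genes": dict(sorted(self.de_genes.items())),
            "hub_genes": sorted(self.hub_genes),
            "true_drug": self.true_drug,
            "true_drug_targets": sorted(self.true_drug_targets),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            de_genes=dict(payload["de_genes"]),
            hub_genes=set(payload["hub_genes"]),
            true_drug=payload["true_drug"],
            true_drug_targets=set(payload["true_drug_targets"]),
        )


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def _plant_truth(config: SimulationConfig, rng: np.random.Generator) -> GroundTruth:
    genes = _gene_ids(config.n_genes)
    de = [str(g) for g in rng.choice(genes, size=config.n_de, replace=False)]
    signs = rng.choice([1.0, -1.0], size=config.n_de)
    de_map = {g: float(s * config.effect_size) for g, s in zip(de, signs)}
    up = [g for g in de if de_map[g] > 0]

    targets: list[str] = []
    hub: list[str] = []
    if config.hub_community_size > 0:
        if config.planted_drug_targets > len(up):
            raise ValueError(
                "planted_drug_targets exceeds the number of up-regulated planted DE genes"
            )
        targets = [str(g) for g in rng.choice(up, size=config.planted_drug_targets, replace=False)]
        n_from_de = min(round(HUB_DE_FRACTION * config.hub_community_size), config.n_de)
        n_from_de = max(n_from_de, len(targets))
        pool = sorted(set(de) - set(targets))
        extra_de = [str(g) for g in rng.choice(pool, size=n_from_de - len(targets), replace=False)]
        non_de = sorted(set(genes) - set(de))
        n_fill = config.hub_community_size - n_from_de
        fill = [str(g) for g in rng.choice(non_de, size=max(n_fill, 0), replace=False)]
        hub = targets + extra_de + fill
    elif config.planted_drug_targets > 0:
        raise ValueError("planted_drug_targets requires a hub community")

    drug_idx = int(rng.integers(1, config.n_drugs + 1)) if config.n_drugs > 0 else 0
    return GroundTruth(
        de_genes=de_map,
        hub_genes=set(hub),
        true_drug=f"D{drug_idx:03d}" if drug_idx else "",
        true_drug_targets=set(targets),
    )


def _platform_panels(config: SimulationConfig, rng: np.random.Generator) -> list[list[str]]:
    genes = _gene_ids(config.n_genes)
    n_shared = round(config.panel_overlap * config.n_genes)
    shared = set(rng.choice(genes, size=n_shared, replace=False))
    rest = [g for g in genes if g not in shared]
    rest = list(rng.permutation(rest))
    chunks = np.array_split(np.array(rest, dtype=object), config.n_platforms)
    return [sorted(shared | set(chunk.tolist())) for chunk in chunks]


def simulate_expression(
    config: SimulationConfig,
) -> tuple[list[ExpressionMatrix], pd.DataFrame, GroundTruth]:
    """Generate per-platform expression matrices, annotation and truth.

    Each gene's metastatic-group mean differs from its primary-group mean
    by the planted log2FC (0 for non-DE genes); a per-platform, per-gene
    offset (SD ``batch_sd``) shifts both groups identically.
    """
    config.validate()
    truth = _plant_truth(config, config.rng(0))
    panels = _platform_panels(config, config.rng(1))
    rng = config.rng(2)
    base = dict(zip(_gene_ids(config.n_genes),
                    rng.normal(BASELINE_MEAN, BASELINE_SD, config.n_genes)))

    matrices, ann_rows = [], []
    for p, panel in enumerate(panels):
        platform = f"PLT{p + 1}"
        offsets = rng.normal(0.0, config.batch_sd, len(panel)) if config.batch_sd > 0 else np.zeros(len(panel))
        primary = [f"{platform}_P{i:03d}" for i in range(1, config.n_primary + 1)]
        metastatic = [f"{platform}_M{i:03d}" for i in range(1, config.n_metastatic + 1)]
        samples = primary + metastatic
        mean = np.empty((len(panel), len(samples)))
        for i, gene in enumerate(panel):
            mu = base[gene] + offsets[i]
            lfc = truth.de_genes.get(gene, 0.0)
            mean[i, : len(primary)] = mu
            mean[i, len(primary):] = mu + lfc
        noise = (
            rng.normal(0.0, config.noise_sd, mean.shape)
            if config.noise_sd > 0
            else np.zeros_like(mean)
        )
        values = pd.DataFrame(mean + noise, index=panel, columns=samples)
        matrices.append(ExpressionMatrix(values=values, platform=platform))
        ann_rows += [
            {"sample": s, "group": "primary" if s in set(primary) else "metastatic",
             "platform": platform}
            for s in samples
        ]
    annotation = pd.DataFrame(ann_rows, columns=["sample", "group", "platform"])
    return matrices, annotation, truth


def simulate_interactions(config: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """Scored undirected edge list: preferential-attachment background plus
    a dense planted community (scores >= 0.8) on the hub genes."""
    config.validate()
    if config.hub_community_size < 2:
        raise ValueError("hub_community_size must be at least 2")
    rng = config.rng(3)
    genes = _gene_ids(config.n_genes)
    bg = nx.barabasi_albert_graph(
        config.n_genes, config.net_attach, seed=int(rng.integers(2**31))
    )
    edges: dict[tuple[str, str], float] = {}
    for i, j in bg.edges():
        a, b = sorted((genes[i], genes[j]))
        edges[(a, b)] = float(rng.uniform(0.4, 1.0))
    hub = sorted(truth.hub_genes)
    for i in range(len(hub)):
        for j in range(i + 1, len(hub)):
            if rng.random() < config.hub_community_p:
                key = (hub[i], hub[j])
                score = float(rng.uniform(0.8, 1.0))
                edges[key] = max(edges.get(key, 0.0), score)
    rows = [(a, b, s) for (a, b), s in sorted(edges.items())]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])


def simulate_gene_sets(
    config: SimulationConfig,
    truth: GroundTruth,
    n_background: int = 50,
    planted_size: int = 20,
    planted_de_fraction: float = 0.75,
    size_range: tuple[int, int] = (10, 50),
) -> list[GeneSet]:
    """Gene-set collection with one planted set enriched for DE genes.

    The planted set draws ``planted_de_fraction`` of its members from the
    planted DE genes (at least 50%); background sets are uniform draws
    from the gene universe.  All set sizes are >= 3.
    """
    config.validate()
    if size_range[0] < 3 or planted_size < 3:
        raise ValueError("gene sets need at least 3 genes")
    rng = config.rng(4)
    genes = _gene_ids(config.n_genes)
    de = sorted(truth.de_genes)
    n_from_de = min(round(planted_de_fraction * planted_size), len(de))
    members = list(rng.choice(de, size=n_from_de, replace=False)) if n_from_de else []
    others = sorted(set(genes) - set(members))
    members += list(rng.choice(others, size=planted_size - len(members), replace=False))
    collection = [GeneSet("T00000", "planted_process", frozenset(members))]
    for i in range(1, n_background + 1):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        collection.append(
            GeneSet(f"T{i:05d}", f"background_process_{i}",
                    frozenset(rng.choice(genes, size=size, replace=False)))
        )
    return collection


def simulate_drug_table(config: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """Drug-target table: a planted inhibitor of up-regulated hubs + decoys.

    Decoy drugs target random genes with random actions; at least one
    decoy inhibits a down-regulated DE gene so the direction filter is
    exercised.
    """
    config.validate()
    if config.n_drugs < 1:
        raise ValueError("need at least one drug (the planted one)")
    if len(truth.true_drug_targets) != config.planted_drug_targets:
        raise ValueError("truth does not carry the configured planted drug targets")
    rng = config.rng(5)
    genes = _gene_ids(config.n_genes)
    rows = [(truth.true_drug, g, "inhibitor") for g in sorted(truth.true_drug_targets)]
    decoys = [f"D{i:03d}" for i in range(1, config.n_drugs + 1) if f"D{i:03d}" != truth.true_drug]
    down = sorted(g for g, lfc in truth.de_genes.items() if lfc < 0)
    for idx, drug in enumerate(decoys):
        n_targets = int(rng.integers(2, 6))
        targets = list(rng.choice(genes, size=n_targets, replace=False))
        actions = list(rng.choice(DECOY_ACTIONS, size=n_targets))
        if idx == 0 and down:
            targets[0], actions[0] = down[0], "inhibitor"
        rows += list(zip([drug] * n_targets, targets, actions))
    return pd.DataFrame(rows, columns=["drug", "gene", "action"])


def simulate_qpcr(
    fold_changes: dict[str, float],
    n_reps: int = 3,
    noise_sd: float = 0.1,
    seed: int = 0,
    reference_gene: str = "REF",
) -> pd.DataFrame:
    """Ct wells whose expected 2^(-ddCt) equals each planted ratio.

    The reference gene sits at 20 cycles in both groups; each target's
    control Ct sits at 25 and its treated Ct at 25 - log2(ratio), plus
    independent Gaussian noise per well.
    """
    for gene, ratio in fold_changes.items():
        if ratio <= 0:
            raise ValueError(f"non-positive ratio for {gene}: {ratio}")
    rng = np.random.default_rng(seed)
    rows = []
    for group, prefix in (("control", "C"), ("treated", "T")):
        for r in range(1, n_reps + 1):
            sample = f"{prefix}{r:03d}"
            rows.append((sample, reference_gene, group, "reference",
                         20.0 + rng.normal(0.0, noise_sd) if noise_sd > 0 else 20.0))
            for gene, ratio in fold_changes.items():
                base = 25.0 if group == "control" else 25.0 - float(np.log2(ratio))
                ct = base + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append((sample, gene, group, "target", ct))
    return pd.DataFrame(rows, columns=["sample", "gene", "group", "role", "ct"])


def config_to_json(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(config), fh, indent=1, sort_keys=True)
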