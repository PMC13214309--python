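"""Centrality measures and top-fraction hub selection.

Hubs are the union of the top 15% of nodes under each of three
centralities: raw degree, pair-normalized betweenness (Brandes, computed
and normalized within each connected component) and component-normalized
closeness ((r-1)/sum of distances, so every node of a small complete
component scores exactly 1.0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

MEASURES = ("degree", "betweenness", "closeness")
CLOSENESS_VARIANTS = ("component", "wasserman_faust")


def degree_centrality(graph: nx.Graph) -> dict[str, int]:
    """Raw neighbor counts (integers, not normalized)."""
    return {n: int(d) for n, d in graph.degree()}


def betweenness_centrality(graph: nx.Graph) -> dict[str, float]:
    """Pair-normalized shortest-path betweenness, component-local.

    Each connected component is normalized by (n_c-1)(n_c-2)/2 with its
    own size n_c; components smaller than 3 contribute zeros.
    """
    out: dict[str, float] = {}
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        if len(comp) < 3:
            out.update({n: 0.0 for n in comp})
        else:
            out.update(nx.betweenness_centrality(sub, normalized=True))
    return out


def closeness_centrality(graph: nx.Graph, variant: str = "component") -> dict[str, float]:
    """Closeness in [0, 1]; isolates get 0.

    ``component`` normalizes within the node's component as (r-1)/sum(d);
    ``wasserman_faust`` applies the additional (r-1)/(n-1) cross-component
    scaling.
    """
    if variant not in CLOSENESS_VARIANTS:
        raise ValueError(f"unknown closeness variant: {variant!r}")
    return nx.closeness_centrality(graph, wf_improved=(variant == "wasserman_faust"))


def top_fraction(scores: dict, fraction: float = 0.15) -> list[str]:
    """Top-``fraction`` genes by score, descending, ties at the cut included.

    k = ceil(fraction * n); every gene tied with the k-th score is kept.
    Ordering is score descending then gene id ascending.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if not scores:
        raise ValueError("empty score map")
    items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    k = math.ceil(fraction * len(items))
    cutoff = items[k - 1][1]
    return [g for g, s in items if s >= cutoff]


@dataclass
class HubSelection:
    """Bookkeeping of per-measure top lists.

    ``selections`` concatenates (gene, measure) pairs over the measures;
    ``union_genes`` is the distinct gene set.  A gene top-ranked under all
    three measures contributes three selections but one union member.
    """

    per_measure: dict[str, list[str]]
    selections: list[tuple[str, str]] = field(init=False)
    union_genes: set[str] = field(init=False)

    def __post_init__(self) -> None:
        self.selections = [
            (g, m) for m in self.per_measure for g in self.per_measure[m]
        ]
        self.union_genes = {g for g, _ in self.selections}


def selection_from_lists(per_measure: dict[str, list[str]]) -> HubSelection:
    """Hub bookkeeping from externally supplied per-measure gene lists."""
    return HubSelection(per_measure=dict(per_measure))


def select_hubs(
    graph: nx.Graph, fraction: float = 0.15, closeness_variant: str = "component"
) -> HubSelection:
    """Union of the top-``fraction`` genes per centrality measure."""
    maps = {
        "degree": degree_centrality(graph),
        "betweenness": betweenness_centrality(graph),
        "closeness": closeness_centrality(graph, variant=closeness_variant),
    }
    return HubSelection(
        per_measure={m: top_fraction(maps[m], fraction) for m in MEASURES}
    )


def centrality_table(graph: nx.Graph, selection: HubSelection | None = None) -> pd.DataFrame:
    """Per-node centrality table with per-measure hub flags."""
    deg = degree_centrality(graph)
    btw = betweenness_centrality(graph)
    clo = closeness_centrality(graph)
    hubs = {m: set(selection.per_measure.get(m, [])) for m in MEASURES} if selection else None
    rows = []
    for n in sorted(graph.nodes):
        row = {"gene": n, "degree": deg[n], "betweenness": btw[n], "closeness": clo[n]}
        if hubs is not None:
            for m in MEASURES:
                row[f"is_hub_{m}"] = n in hubs[m]
        rows.append(row)
    return pd.DataFrame(rows)


def attach_logfc(
    hubs: HubSelection, merged: pd.DataFrame, lfc_min: float = 1.0
) -> pd.DataFrame:
    """Hub genes with |mean_logFC| strictly > lfc_min, carrying sign.

    Hub genes without a merged DEG record (typically expansion-added
    non-seeds) are excluded and logged, as are hubs below the threshold.
    Returns columns gene, mean_logFC, direction, measures.
    """
    lfc = merged.set_index("gene")["mean_logFC"]
    measures: dict[str, list[str]] = {}
    for gene, measure in hubs.selections:
        measures.setdefault(gene, []).append(measure)
    rows = []
    for gene in sorted(hubs.union_genes):
        if gene not in lfc.index:
            logger.info("hub %s has no merged DEG record: excluded from drug query", gene)
            continue
        value = float(lfc[gene])
        if abs(value) <= lfc_min:
            continue
        rows.append(
            {
                "gene": gene,
                "mean_logFC": value,
                "direction": "up" if value > 0 else "down",
                "measures": ",".join(measures[gene]),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "mean_logFC", "direction", "measures"])
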