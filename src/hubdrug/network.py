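"""PPI graph construction with score thresholding and constrained expansion.

Seeds (merged DEGs) form the initial network; edges require an interaction
score strictly above ``score_min`` (default 0.8, the conventional
high-confidence cutoff).  Each seed may then pull in at most
``max_new_per_node`` non-seed interactors, ranked by score, after which
every qualifying edge among the final node set is included.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

CORE_MODES = ("largest_component", "kcore")


def load_interactions(path) -> pd.DataFrame:
    """Load a 3-column interaction TSV (gene_a, gene_b, score).

    Scores may be fractions in [0, 1] or STRING-style integers in
    [0, 1000] (values > 1 are divided by 1000).  Self-loops are skipped
    with a warning; duplicate undirected pairs collapse to the max score.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", names=["gene_a", "gene_b", "score"], dtype=str
    )
    # tolerate a header row
    first = df.iloc[0]["score"] if len(df) else None
    if first is not None:
        try:
            float(first)
        except (TypeError, ValueError):
            df = df.iloc[1:].reset_index(drop=True)
    scores = pd.to_numeric(df["score"], errors="coerce")
    bad = scores.isna() | df["gene_a"].isna() | df["gene_b"].isna()
    if bad.any():
        line = int(bad.idxmax()) + 1
        raise ValueError(f"malformed interaction row at line {line}")
    df["score"] = scores
    return normalize_interactions(df)


def normalize_interactions(df: pd.DataFrame) -> pd.DataFrame:
    """Canonicalize an interaction table (dialect, loops, duplicates)."""
    df = df.copy()
    over = df["score"] > 1.0
    if over.any():
        df.loc[over, "score"] = df.loc[over, "score"] / 1000.0
    if (df["score"] < 0).any() or (df["score"] > 1).any():
        raise ValueError("interaction scores outside [0, 1] after normalization")
    loops = df["gene_a"] == df["gene_b"]
    if loops.any():
        logger.warning("skipping %d self-loop interaction rows", int(loops.sum()))
        df = df.loc[~loops]
    a = df["gene_a"].astype(str).to_numpy()
    b = df["gene_b"].astype(str).to_numpy()
    swap = a > b
    lo, hi = a.copy(), b.copy()
    lo[swap], hi[swap] = b[swap], a[swap]
    df = pd.DataFrame({"gene_a": lo, "gene_b": hi, "score": df["score"].to_numpy()})
    df = (
        df.groupby(["gene_a", "gene_b"], as_index=False, sort=True)["score"]
        .max()
        .reset_index(drop=True)
    )
    return df


def _adjacency(interactions: pd.DataFrame) -> dict[str, list[tuple[str, float]]]:
    adj: dict[str, list[tuple[str, float]]] = defaultdict(list)
    for a, b, s in interactions.itertuples(index=False):
        adj[a].append((b, float(s)))
        adj[b].append((a, float(s)))
    return adj


def build_seed_network(
    seeds, interactions: pd.DataFrame, score_min: float = 0.8
) -> nx.Graph:
    """Graph on the seed genes; edges need score strictly > score_min.

    Isolated seeds are retained as nodes.
    """
    seeds = list(dict.fromkeys(seeds))
    if not seeds:
        raise ValueError("seed list is empty")
    g = nx.Graph()
    g.add_nodes_from(seeds, is_seed=True)
    seed_set = set(seeds)
    for a, b, s in interactions.itertuples(index=False):
        if a in seed_set and b in seed_set and s > score_min and a != b:
            g.add_edge(a, b, score=float(s))
    return g


def expand_network(
    graph: nx.Graph,
    interactions: pd.DataFrame,
    score_min: float = 0.8,
    max_new_per_node: int = 2,
) -> nx.Graph:
    """Add up to ``max_new_per_node`` high-scoring non-seed interactors per seed.

    Candidates are ranked by (score descending, gene id ascending); after
    all additions every edge with score > score_min among the final node
    set is included.  Expansion is idempotent.
    """
    adj = _adjacency(interactions)
    seed_nodes = {n for n, d in graph.nodes(data=True) if d.get("is_seed", True)}
    added: set[str] = set(graph.nodes) - seed_nodes
    for seed in sorted(seed_nodes):
        cands = [(nbr, s) for nbr, s in adj.get(seed, ()) if nbr not in seed_nodes and s > score_min]
        cands.sort(key=lambda item: (-item[1], item[0]))
        for nbr, _ in cands[:max_new_per_node]:
            added.add(nbr)
    final = seed_nodes | added
    g = nx.Graph()
    g.add_nodes_from((n, {"is_seed": n in seed_nodes}) for n in final)
    for a, b, s in interactions.itertuples(index=False):
        if a in final and b in final and s > score_min and a != b:
            g.add_edge(a, b, score=float(s))
    return g


def largest_component(graph: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Ties break by the lexicographically smallest node id in the component;
    an empty graph maps to an empty graph.
    """
    if graph.number_of_nodes() == 0:
        return graph.copy()
    comps = sorted(nx.connected_components(graph), key=lambda c: (-len(c), min(c)))
    return graph.subgraph(comps[0]).copy()


def analysis_core(graph: nx.Graph, mode: str = "largest_component", k: int = 2) -> nx.Graph:
    """The 'highly interconnected' core the hub analysis runs on."""
    if mode not in CORE_MODES:
        raise ValueError(f"unknown core mode: {mode!r}")
    if mode == "kcore":
        core = nx.k_core(graph, k)
        return core.copy() if core.number_of_nodes() else largest_component(graph)
    return largest_component(graph)


def write_graph(graph: nx.Graph, edges_path, nodes_path) -> None:
    """Write edge-list TSV (gene_a, gene_b, score) and node TSV (gene, is_seed)."""
    edges = pd.DataFrame(
        [(min(a, b), max(a, b), d.get("score", float("nan"))) for a, b, d in graph.edges(data=True)],
        columns=["gene_a", "gene_b", "score"],
    ).sort_values(["gene_a", "gene_b"])
    edges.to_csv(edges_path, sep="\t", index=False)
    nodes = pd.DataFrame(
        [(n, bool(d.get("is_seed", False))) for n, d in sorted(graph.nodes(data=True))],
        columns=["gene", "is_seed"],
    )
    nodes.to_csv(nodes_path, sep="\t", index=False)


def read_graph(edges_path, nodes_path) -> nx.Graph:
    g = nx.Graph()
    nodes = pd.read_csv(nodes_path, sep="\t")
    for gene, is_seed in nodes.itertuples(index=False):
        g.add_node(str(gene), is_seed=bool(is_seed))
    edges = pd.read_csv(edges_path, sep="\t")
    for a, b, s in edges.itertuples(index=False):
        g.add_edge(str(a), str(b), score=float(s))
    return g
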