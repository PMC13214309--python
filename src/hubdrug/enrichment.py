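"""Hypergeometric gene-set enrichment and kappa term networks.

A term of size K is tested against a query of size n drawn from a
universe of N genes; the p-value is the upper tail P(X >= k) of the
hypergeometric distribution.  Significant terms are linked into a term
network wherever Cohen's kappa of their gene memberships exceeds a
cutoff, mimicking functional-grouping tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy import stats

from hubdrug.dea import adjust_pvalues

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.term_id} is empty")


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT file: term, description, genes, tab-separated."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(parts[0], parts[1], frozenset(g for g in parts[2:] if g)))
    return sets


def write_gmt(collection: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.term_id, gs.term_name, *sorted(gs.genes)]) + "\n")


def hypergeometric_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    k = query/set overlap, K = set size, n = query size, N = universe size.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query,
    collection: list[GeneSet],
    universe,
    alpha: float = 0.05,
    min_genes: int = 3,
    adjust_method: str = "bh",
) -> pd.DataFrame:
    """Test every term with >= min_genes query overlap; keep p < alpha.

    Query genes outside the universe are dropped with a warning; set
    membership is likewise restricted to the universe.  Results are
    sorted by p ascending, ties by term_id.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    outside = query - universe
    if outside:
        logger.warning("%d query genes outside universe dropped", len(outside))
        query &= universe
    n, N = len(query), len(universe)
    rows = []
    for gs in collection:
        genes = gs.genes & universe
        k = len(genes & query)
        if k < min_genes or not genes:
            continue
        rows.append(
            {
                "term_id": gs.term_id,
                "term_name": gs.term_name,
                "k": k,
                "K": len(genes),
                "n": n,
                "N": N,
                "p": hypergeometric_test(k, len(genes), n, N),
            }
        )
    if not rows:
        return pd.DataFrame(columns=["term_id", "term_name", "k", "K", "n", "N", "p", "adj_p"])
    res = pd.DataFrame(rows)
    res["adj_p"] = adjust_pvalues(res["p"].to_numpy(), adjust_method)
    res = res[res["p"] < alpha].sort_values(["p", "term_id"]).reset_index(drop=True)
    return res


def kappa_score(set_a, set_b, universe) -> float:
    """Cohen's kappa of two gene memberships over a universe.

    Built from the 2x2 membership table; degenerate tables with chance
    agreement 1 (both sets empty or both equal to the universe) return 0
    with a warning.
    """
    universe = set(universe)
    a = set(set_a) & universe
    b = set(set_b) & universe
    if (set(set_a) - universe) or (set(set_b) - universe):
        raise ValueError("gene sets must be subsets of the universe")
    N = len(universe)
    if N == 0:
        raise ValueError("empty universe")
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = N - both - only_a - only_b
    p_o = (both + neither) / N
    p_e = ((both + only_a) * (both + only_b) + (only_b + neither) * (only_a + neither)) / N**2
    if p_e >= 1.0:
        logger.warning("degenerate membership table (chance agreement 1): kappa set to 0")
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def term_network(
    results: pd.DataFrame,
    collection: list[GeneSet],
    universe,
    kappa_min: float = 0.4,
) -> nx.Graph:
    """Graph of significant terms; edges where membership kappa > kappa_min."""
    universe = set(universe)
    by_id = {gs.term_id: gs.genes & universe for gs in collection}
    terms = list(results["term_id"])
    g = nx.Graph()
    g.add_nodes_from(terms)
    for i, t1 in enumerate(terms):
        for t2 in terms[i + 1 :]:
            kappa = kappa_score(by_id[t1], by_id[t2], universe)
            if kappa > kappa_min:
                g.add_edge(t1, t2, kappa=kappa)
    return g
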