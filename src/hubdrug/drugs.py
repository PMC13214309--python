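"""Direction-aware drug-target matching and candidate ranking.

Up-regulated hub genes (mean logFC > 1) are matched to inhibitory drug
actions, down-regulated hubs (mean logFC < -1) to activating actions;
any other action class never matches.  Candidates rank by matched-hub
count, then total |mean logFC| of matched genes, then drug id.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

INHIBITORY = frozenset(
    {"inhibitor", "antagonist", "blocker", "suppressor", "negative modulator"}
)
ACTIVATING = frozenset(
    {"agonist", "activator", "inducer", "stimulator", "potentiator", "positive modulator"}
)


def classify_action(action: str) -> str:
    """Map a raw action string to 'inhibitory', 'activating' or 'other'."""
    key = str(action).strip().lower()
    if key in INHIBITORY:
        return "inhibitory"
    if key in ACTIVATING:
        return "activating"
    return "other"


@dataclass
class DrugCandidate:
    """A drug with direction-concordant hub-gene matches."""

    drug: str
    matched: list[tuple[str, float, str]]  # (gene, mean_logFC, action_class)

    @property
    def n_matched(self) -> int:
        return len(self.matched)

    @property
    def sum_abs_logfc(self) -> float:
        return float(sum(abs(lfc) for _, lfc, _ in self.matched))


def match_drugs(hubs: pd.DataFrame, table: pd.DataFrame) -> list[DrugCandidate]:
    """Match filtered hub genes against a drug-target table.

    ``hubs`` carries columns gene and mean_logFC (all |mean_logFC| > 1
    after :func:`hubdrug.centrality.attach_logfc`); ``table`` carries
    drug, gene, action.  A pair matches iff the hub is up-regulated and
    the action is inhibitory, or down-regulated and activating.
    """
    lfc = hubs.set_index("gene")["mean_logFC"]
    by_drug: dict[str, list[tuple[str, float, str]]] = {}
    for row in table.itertuples(index=False):
        gene = str(row.gene)
        if gene not in lfc.index:
            continue
        value = float(lfc[gene])
        cls = classify_action(row.action)
        if (value > 1.0 and cls == "inhibitory") or (value < -1.0 and cls == "activating"):
            by_drug.setdefault(str(row.drug), []).append((gene, value, cls))
    candidates = []
    for drug in sorted(by_drug):
        matched = sorted(set(by_drug[drug]))
        candidates.append(DrugCandidate(drug=drug, matched=matched))
    return candidates


def rank_drugs(candidates: list[DrugCandidate]) -> list[DrugCandidate]:
    """Deterministic ranking: n_matched desc, sum |logFC| desc, drug id asc."""
    return sorted(candidates, key=lambda c: (-c.n_matched, -c.sum_abs_logfc, c.drug))


def candidates_table(candidates: list[DrugCandidate]) -> pd.DataFrame:
    rows = [
        {
            "drug": c.drug,
            "n_matched": c.n_matched,
            "sum_abs_logFC": c.sum_abs_logfc,
            "matched_genes": ",".join(g for g, _, _ in c.matched),
        }
        for c in candidates
    ]
    return pd.DataFrame(rows, columns=["drug", "n_matched", "sum_abs_logFC", "matched_genes"])


def read_drug_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"drug", "gene", "action"} - set(table.columns)
    if missing:
        raise ValueError(f"drug table missing columns: {sorted(missing)}")
    return table
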