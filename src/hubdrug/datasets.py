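"""Bundled worked-example data from a published metastatic prostate-cancer
hub-gene study.

Two small tables are included: the per-measure hub lists (top 15% of a
120-node PPI core by closeness, betweenness and degree; 33 selections
over 29 distinct genes) and the drug-repositioning query result (two
candidate drugs with the mean log2 fold-changes of their matched hub
genes).  They drive the README example and serve as fixed end-to-end
checks of the hub bookkeeping and the direction-aware drug match.
"""

from __future__ import annotations

import pandas as pd

# Per-measure hub lists: (gene, centrality value), already ordered.
CLOSENESS_HUBS = [
    ("S100A8", 1.000000), ("ME3", 1.000000), ("CSRP1", 1.000000),
    ("GLUD2", 1.000000), ("AKR1C3", 1.000000), ("MAOB", 1.000000),
    ("PDE5A", 1.000000), ("ATP1A2", 1.000000), ("RAB27B", 1.000000),
    ("AZGP1", 1.000000), ("ACP3", 1.000000),
]
BETWEENNESS_HUBS = [
    ("GSTM2", 0.166667), ("GSTM4", 0.166667), ("KRT5", 0.166667),
    ("AR", 0.031131), ("FN1", 0.022844), ("TPM1", 0.022270),
    ("FGG", 0.021918), ("APOE", 0.017243), ("HBB", 0.016385),
    ("FLNA", 0.015037), ("FOS", 0.014410),
]
DEGREE_HUBS = [
    ("FGG", 44), ("FN1", 44), ("UBE2C", 37), ("MYL9", 36), ("IGF1", 34),
    ("TPM1", 33), ("MYH11", 32), ("APOE", 31), ("UBE2Z", 30),
    ("VCAN", 28), ("SPP1", 27),
]

# Mean log2 fold-change (metastatic vs primary, averaged over platforms
# where flagged) of the hub genes that passed the |mean logFC| > 1 filter.
HUB_MEAN_LOGFC = {
    "TPM1": 2.466474,
    "FLNA": 2.678756,
    "CSRP1": 3.086534,
    "APOE": -2.033000,
    "FN1": -2.718200,
    "FGG": -2.132180,
    "KRT5": 3.703653,
    "HBB": -3.501800,
    "S100A8": -2.387650,
}

# Drug-target actions behind the query result: Artenimol (artesunate's
# active metabolite) inhibits three up-regulated hubs; zinc salts act on
# the remaining six (agonist for the down-regulated, inhibitor for KRT5).
DRUG_TARGET_ROWS = [
    ("Artenimol", "TPM1", "inhibitor"),
    ("Artenimol", "FLNA", "inhibitor"),
    ("Artenimol", "CSRP1", "inhibitor"),
    ("Zinc", "APOE", "agonist"),
    ("Zinc", "FN1", "agonist"),
    ("Zinc", "FGG", "agonist"),
    ("Zinc", "KRT5", "inhibitor"),
    ("Zinc", "HBB", "agonist"),
    ("Zinc", "S100A8", "agonist"),
]


def hub_measure_lists() -> dict[str, list[str]]:
    """The three per-measure hub gene lists (ordered by centrality)."""
    return {
        "degree": [g for g, _ in DEGREE_HUBS],
        "betweenness": [g for g, _ in BETWEENNESS_HUBS],
        "closeness": [g for g, _ in CLOSENESS_HUBS],
    }


def hub_logfc_table() -> pd.DataFrame:
    """Filtered hub genes with mean_logFC, as fed to the drug query."""
    return pd.DataFrame(
        [{"gene": g, "mean_logFC": v, "direction": "up" if v > 0 else "down"}
         for g, v in HUB_MEAN_LOGFC.items()]
    )


def drug_target_table() -> pd.DataFrame:
    """Drug-target actions of the two candidate drugs."""
    return pd.DataFrame(DRUG_TARGET_ROWS, columns=["drug", "gene", "action"])
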