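"""Relative qPCR quantification: 2^(-ddCt), Pfaffl ratio, randomization test.

Wells are rows of (sample, gene, group, role, ct).  The target's mean Ct
is normalized against a reference gene within each group (dCt), the
treated group's dCt against the control group's (ddCt), and relative
expression is 2^(-ddCt).  The Pfaffl variant corrects for per-gene
amplification efficiency E = 1 + eff.  Significance comes from a
fixed-reallocation randomization test on per-sample dCt values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WELL_COLUMNS = ("sample", "gene", "group", "role", "ct")


@dataclass
class RelativeExpression:
    gene: str
    fold_change: float
    delta_delta_ct: float
    p_randomization: float | None = None


def _mean_ct(wells: pd.DataFrame, gene: str, group: str) -> float:
    sel = wells[(wells["gene"] == gene) & (wells["group"] == group)]
    if sel.empty:
        raise ValueError(f"no wells for gene {gene!r} in group {group!r}")
    return float(sel["ct"].mean())


def _check_ct_range(wells: pd.DataFrame) -> None:
    ct = wells["ct"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ct)):
        raise ValueError("non-finite Ct values")
    odd = np.sum((ct < 5) | (ct > 40))
    if odd:
        logger.info("%d Ct values outside the typical 5-40 cycle range", int(odd))


def delta_delta_ct(wells: pd.DataFrame, target_gene: str, reference_gene: str) -> RelativeExpression:
    """Relative expression of ``target_gene`` by the 2^(-ddCt) method.

    dCt = mean Ct(target) - mean Ct(reference) per group;
    ddCt = dCt(treated) - dCt(control); fold = 2^(-ddCt).
    """
    _check_ct_range(wells)
    d_ct = {
        group: _mean_ct(wells, target_gene, group) - _mean_ct(wells, reference_gene, group)
        for group in ("treated", "control")
    }
    ddct = d_ct["treated"] - d_ct["control"]
    return RelativeExpression(
        gene=target_gene, fold_change=float(2.0 ** (-ddct)), delta_delta_ct=float(ddct)
    )


def pfaffl_ratio(
    wells: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    e_target: float = 1.0,
    e_ref: float = 1.0,
) -> RelativeExpression:
    """Efficiency-corrected expression ratio (Pfaffl).

    Efficiencies are fractions (1.0 = perfect doubling, base E = 2);
    values above 1.0 up to 1.1 are accepted with a warning.  The ratio is
    E_t^dCt_t / E_r^dCt_r with dCt = control - treated per gene, and
    collapses to 2^(-ddCt) when both efficiencies are 1.
    """
    for name, eff in (("target", e_target), ("reference", e_ref)):
        if eff <= 0:
            raise ValueError(f"non-positive {name} efficiency: {eff}")
        if eff > 1.0:
            logger.warning("%s efficiency %.3f exceeds 1.0 (super-efficient primer)", name, eff)
    _check_ct_range(wells)
    dct_t = _mean_ct(wells, target_gene, "control") - _mean_ct(wells, target_gene, "treated")
    dct_r = _mean_ct(wells, reference_gene, "control") - _mean_ct(wells, reference_gene, "treated")
    ratio = (1.0 + e_target) ** dct_t / (1.0 + e_ref) ** dct_r
    return RelativeExpression(
        gene=target_gene, fold_change=float(ratio), delta_delta_ct=float(-(dct_t - dct_r))
    )


def _per_sample_dct(wells: pd.DataFrame, target_gene: str, reference_gene: str):
    # technical replicates within a (sample, gene) average before pairing
    target = (
        wells[wells["gene"] == target_gene]
        .groupby("sample")
        .agg(ct=("ct", "mean"), group=("group", "first"))
    )
    ref = wells[wells["gene"] == reference_gene].groupby("sample")["ct"].mean()
    samples = sorted(set(target.index) & set(ref.index))
    if not samples:
        raise ValueError("no samples with both target and reference measurements")
    dct = np.array([float(target.loc[s, "ct"]) - float(ref.loc[s]) for s in samples])
    groups = np.array([str(target.loc[s, "group"]) for s in samples])
    return dct, groups


def randomization_test(
    wells: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    n_perm: int = 2000,
    seed: int | None = None,
) -> float:
    """Fixed-reallocation randomization p-value for the expression ratio.

    Group labels of the per-sample dCt values are permuted ``n_perm``
    times; the two-sided p-value is the tie-inclusive fraction of
    permuted |mean dCt difference| at least the observed one, with an
    add-one correction (so p >= 1/(n_perm+1)).
    """
    dct, groups = _per_sample_dct(wells, target_gene, reference_gene)
    treated = groups == "treated"
    n_t, n_c = int(treated.sum()), int((~treated).sum())
    if n_t < 2 or n_c < 2:
        raise ValueError("need at least 2 samples per group for the randomization test")
    observed = dct[treated].mean() - dct[~treated].mean()
    rng = np.random.default_rng(seed)
    labels = np.tile(treated, (n_perm, 1))
    labels = rng.permuted(labels, axis=1)
    sums_t = (labels * dct).sum(axis=1)
    stats = sums_t / n_t - (dct.sum() - sums_t) / n_c
    exceed = np.sum(np.abs(stats) >= abs(observed) - 1e-12)
    return float((1 + exceed) / (n_perm + 1))


def read_wells_tsv(path) -> pd.DataFrame:
    wells = pd.read_csv(path, sep="\t")
    missing = set(WELL_COLUMNS) - set(wells.columns)
    if missing:
        raise ValueError(f"wells table missing columns: {sorted(missing)}")
    return wells
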