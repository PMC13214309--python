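"""Per-platform differential expression and cross-platform merging.

The test statistic is an empirical-Bayes moderated t: the per-gene pooled
variance s2_g (d degrees of freedom) is shrunk toward a prior variance
s0^2 with prior degrees of freedom d0, both fitted by method of moments
on log s2_g across genes.  The posterior variance is

    s2_post = (d0 * s0^2 + d * s2_g) / (d0 + d)

and the moderated t = logFC / (s_post * sqrt(1/n1 + 1/n2)) is referred to
a t distribution on d0 + d degrees of freedom.  With d0 = 0 this reduces
to the ordinary equal-variance two-sample t.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import special, stats

from hubdrug.expression import ExpressionMatrix

logger = logging.getLogger(__name__)

ADJUST_METHODS = ("bh", "bonferroni", "none")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-fit (d0, s0^2) of the scaled inverse-chi-square variance prior.

    Works on z = log s2_g, whose mean/variance under the hierarchical model
    are digamma/trigamma expressions in d and d0; the trigamma equation is
    inverted numerically.  Returns ``d0 = inf`` when the observed spread of
    log-variances is no larger than expected from sampling alone.
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        return math.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if evar <= 0:
        return math.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def _group_columns(matrix: ExpressionMatrix, annotation: pd.DataFrame) -> tuple[list[str], list[str]]:
    ann = annotation.set_index("sample")
    if ann.index.has_duplicates:
        raise ValueError("duplicate sample ids in annotation")
    missing = [s for s in matrix.sample_ids if s not in ann.index]
    if missing:
        raise ValueError(f"sample '{missing[0]}' missing from annotation")
    groups = ann.loc[matrix.sample_ids, "group"]
    primary = [s for s in matrix.sample_ids if groups[s] == "primary"]
    metastatic = [s for s in matrix.sample_ids if groups[s] == "metastatic"]
    if len(primary) < 2 or len(metastatic) < 2:
        raise ValueError("each group needs at least 2 samples")
    return primary, metastatic


def moderated_t(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Moderated two-group t test, metastatic minus primary, per gene.

    Returns a DataFrame with columns gene, logFC, t, p, platform (no
    multiplicity adjustment; see :func:`bh_adjust`).  Missing values are
    excluded per gene; a gene with fewer than 2 non-missing values in
    either group gets p = 1 and a NaN statistic, with a warning.

    ``prior_df``/``prior_var`` override the moment fit (``prior_df=0``
    yields the classical pooled-variance t).
    """
    primary, metastatic = _group_columns(matrix, annotation)
    x1 = matrix.values[primary].to_numpy(dtype=float)
    x2 = matrix.values[metastatic].to_numpy(dtype=float)
    n1 = np.sum(~np.isnan(x1), axis=1)
    n2 = np.sum(~np.isnan(x2), axis=1)
    with np.errstate(invalid="ignore"):
        m1 = np.nanmean(np.where(np.isnan(x1), np.nan, x1), axis=1)
        m2 = np.nanmean(np.where(np.isnan(x2), np.nan, x2), axis=1)
        ss1 = np.nansum((x1 - m1[:, None]) ** 2, axis=1)
        ss2 = np.nansum((x2 - m2[:, None]) ** 2, axis=1)
    logfc = m2 - m1
    df = n1 + n2 - 2.0
    ok = (n1 >= 2) & (n2 >= 2)
    n_bad = int(np.sum(~ok))
    if n_bad:
        logger.warning("%d genes with <2 observations in a group: p set to 1", n_bad)
    s2 = np.full(len(df), np.nan)
    s2[ok] = (ss1[ok] + ss2[ok]) / df[ok]

    if prior_df is None:
        d0, s0_sq = fit_variance_prior(s2[ok], df[ok])
    else:
        d0 = float(prior_df)
        s0_sq = float(prior_var) if prior_var is not None else float(np.nanmean(s2))

    t = np.full(len(df), np.nan)
    p = np.ones(len(df))
    if math.isinf(d0):
        s2_post = np.full(len(df), s0_sq)
        total_df = np.full(len(df), 1e6)
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        total_df = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2_post * (1.0 / np.maximum(n1, 1) + 1.0 / np.maximum(n2, 1)))
        t[ok] = logfc[ok] / se[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), total_df[ok])
    return pd.DataFrame(
        {
            "gene": matrix.gene_ids,
            "logFC": logfc,
            "t": t,
            "p": p,
            "platform": matrix.platform,
        }
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def adjust_pvalues(p_values, method: str = "bh") -> np.ndarray:
    """Multiplicity adjustment: 'bh' (default), 'bonferroni' or 'none'."""
    if method not in ADJUST_METHODS:
        raise ValueError(f"unknown adjustment method: {method!r}")
    p = np.asarray(p_values, dtype=float)
    if method == "bh":
        return bh_adjust(p)
    if method == "bonferroni":
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("p-values must lie in [0, 1]")
        return np.minimum(p * p.size, 1.0)
    return p.copy()


def dea_table(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    adjust_method: str = "bh",
    **kwargs,
) -> pd.DataFrame:
    """Moderated t plus adjusted p-values for one platform."""
    table = moderated_t(matrix, annotation, **kwargs)
    table["adj_p"] = adjust_pvalues(table["p"].to_numpy(), adjust_method)
    return table


def flag_degs(records: pd.DataFrame, alpha: float = 0.05, lfc_min: float = 1.0) -> pd.DataFrame:
    """Flag differentially expressed genes: adj_p < alpha AND |logFC| > lfc_min.

    Both inequalities are strict.
    """
    if "adj_p" not in records.columns:
        raise ValueError("records must carry an adj_p column (run adjustment first)")
    keep = (records["adj_p"] < alpha) & (records["logFC"].abs() > lfc_min)
    return records.loc[keep].reset_index(drop=True)


def merge_platforms(per_platform: list[pd.DataFrame]) -> pd.DataFrame:
    """Merge flagged DEG lists across platforms.

    The union of flagged genes is kept; mean_logFC averages logFC over the
    platforms where the gene was flagged.  Genes flagged with opposite
    signs on different platforms are direction-discordant and excluded
    (logged).  Returns columns gene, mean_logFC, n_platforms, direction.
    """
    if not per_platform:
        raise ValueError("need at least one platform DEG list")
    combined = pd.concat(per_platform, ignore_index=True)
    rows = []
    for gene, grp in combined.groupby("gene", sort=True):
        signs = set(np.sign(grp["logFC"]))
        if 1.0 in signs and -1.0 in signs:
            logger.warning("gene %s direction-discordant across platforms: excluded", gene)
            continue
        mean_lfc = float(grp["logFC"].mean())
        rows.append(
            {
                "gene": gene,
                "mean_logFC": mean_lfc,
                "n_platforms": int(len(grp)),
                "direction": "up" if mean_lfc > 0 else "down",
            }
        )
    return pd.DataFrame(rows, columns=["gene", "mean_logFC", "n_platforms", "direction"])
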