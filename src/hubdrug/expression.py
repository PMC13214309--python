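"""Expression-matrix container, annotation handling and normalization.

Matrices hold log2-scale intensities, genes in rows and samples in
columns, mirroring the gene-level tables exported from microarray
re-analysis tools.  Sample annotations assign each sample to a study
group (``primary`` or ``metastatic``) and a platform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_GROUPS = ("primary", "metastatic")
NORMALIZATION_METHODS = ("quantile", "median", "none")


@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes x samples) for one platform.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by unique gene ids, columns by unique sample ids.
        Entries are log2 intensities; missing values may be NaN.
    platform : str
        Platform identifier shared with the sample annotation.
    """

    values: pd.DataFrame
    platform: str = ""

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        self.values = self.values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def read_expression_tsv(path, platform: str = "") -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return ExpressionMatrix(values=df, platform=platform)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_annotation_tsv(path) -> pd.DataFrame:
    """Read a sample annotation TSV with columns sample, group, platform."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "group", "platform"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    bad = set(ann["group"]) - set(VALID_GROUPS)
    if bad:
        raise ValueError(f"unknown groups in annotation: {sorted(bad)}")
    return ann


def write_annotation_tsv(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def _ensure_log_scale(values: np.ndarray) -> np.ndarray:
    # Values above ~50 are implausible on a log2 scale; assume linear input.
    if np.nanmax(values) > 50:
        logger.info("max value > 50: applying log2(x+1) before normalization")
        values = np.log2(values + 1.0)
    return values


def normalize(matrix: ExpressionMatrix, method: str = "quantile") -> ExpressionMatrix:
    """Normalize samples within one platform.

    ``quantile`` forces every sample to share the identical sorted value
    vector (the mean of per-rank values across samples); ``median``
    subtracts each sample's median; ``none`` returns the input unchanged.
    """
    if method not in NORMALIZATION_METHODS:
        raise ValueError(f"unknown normalization method: {method!r}")
    if method == "none":
        return matrix
    vals = _ensure_log_scale(matrix.values.to_numpy(dtype=float))
    if method == "median":
        vals = vals - np.nanmedian(vals, axis=0, keepdims=True)
    else:  # quantile
        if np.isnan(vals).any():
            raise ValueError("quantile normalization requires complete data")
        order = np.argsort(vals, axis=0, kind="stable")
        mean_sorted = np.take_along_axis(vals, order, axis=0).mean(axis=1)
        out = np.empty_like(vals)
        for j in range(vals.shape[1]):
            out[order[:, j], j] = mean_sorted
        vals = out
    values = pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns)
    return replace(matrix, values=values)
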