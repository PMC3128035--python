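"""Matrix preprocessing: duplicate-probe averaging, flooring, log2,
probe-to-gene collapsing.

Order of operations for platforms with duplicate probe IDs follows the
narrative: average duplicates on the natural scale, substitute a floor,
then log2-transform.  Probe-to-gene collapsing operates on the log2 data
used for functional analysis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .matrix import LOG2, NATURAL, ExpressionMatrix

logger = logging.getLogger(__name__)

#: floor constant used for the GEH-style preprocessing
DEFAULT_FLOOR = 0.169


def average_duplicate_probes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse rows sharing a probe ID to their arithmetic per-sample mean.

    Row order of the result follows first occurrence.  Idempotent.
    """
    if matrix.scale != NATURAL:
        raise DataError("duplicate averaging expects a natural-scale matrix")
    if matrix.values.index.is_unique:
        return matrix.copy()
    grouped = matrix.values.groupby(level=0, sort=False).mean()
    # groupby(sort=False) preserves first-occurrence order already
    logger.info(
        "averaged duplicates: %d probes -> %d unique",
        matrix.n_probes,
        grouped.shape[0],
    )
    return matrix.with_values(grouped)


def floor_values(matrix: ExpressionMatrix, floor: float = DEFAULT_FLOOR) -> ExpressionMatrix:
    """Replace every value below ``floor`` by ``floor`` (natural scale)."""
    if floor <= 0:
        raise ConfigurationError(f"floor must be positive, got {floor}")
    if matrix.scale != NATURAL:
        raise DataError("flooring expects a natural-scale matrix")
    vals = matrix.values
    n_below = int((vals.to_numpy() < floor).sum())
    logger.info(
        "floor %.4g substituted %d / %d values (%.2f%%)",
        floor,
        n_below,
        vals.size,
        100.0 * n_below / vals.size if vals.size else 0.0,
    )
    return matrix.with_values(vals.clip(lower=floor))


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2; requires strictly positive natural-scale values."""
    if matrix.scale != NATURAL:
        raise DataError("matrix is already on the log2 scale")
    if (matrix.values.to_numpy() <= 0).any():
        raise DataError("nonpositive values: apply floor_values first")
    return matrix.with_values(np.log2(matrix.values), scale=LOG2)


def clean_probe_gene_map(annotation: pd.DataFrame) -> pd.DataFrame:
    """Drop probes associated with more than one gene symbol.

    Returns a map where each retained probe occurs exactly once.
    """
    ann = annotation.drop_duplicates()
    counts = ann.groupby(ann.columns[0])[ann.columns[1]].nunique()
    multi = set(counts.index[counts > 1])
    if multi:
        logger.info("dropped %d multi-mapping probes", len(multi))
        ann = ann[~ann.iloc[:, 0].isin(multi)]
    return ann.reset_index(drop=True)


def collapse_probes_to_genes(
    matrix: ExpressionMatrix, annotation: pd.DataFrame
) -> ExpressionMatrix:
    """Average log2 signals of all probes mapped to the same gene symbol.

    Probes absent from the (cleaned) map are dropped.  The result has one
    row per gene, ordered by first appearance of the gene in the matrix.
    """
    if matrix.scale != LOG2:
        raise DataError("collapsing expects a log2 matrix")
    if not matrix.values.index.is_unique:
        raise DataError("collapse requires unique probe IDs; average duplicates first")
    ann = clean_probe_gene_map(annotation)
    gene_of = dict(zip(ann.iloc[:, 0], ann.iloc[:, 1]))
    keep = matrix.values.index.to_series().map(gene_of).dropna()
    if keep.empty:
        raise DataError("no probe of the matrix appears in the annotation map")
    sub = matrix.values.loc[keep.index]
    collapsed = sub.groupby(keep.to_numpy(), sort=False).mean()
    collapsed.index.name = "gene"
    return matrix.with_values(collapsed)


def preprocess(
    matrix: ExpressionMatrix,
    floor: float | None = DEFAULT_FLOOR,
    average_duplicates: bool = True,
) -> ExpressionMatrix:
    """Standard chain: average duplicates -> floor -> log2."""
    out = matrix
    if average_duplicates:
        out = average_duplicate_probes(out)
    if floor is not None:
        out = floor_values(out, floor)
    return log2_transform(out)
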