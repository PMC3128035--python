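"""True-DEG definition from RT-PCR-style reference data.

Three rules: Benjamini-Hochberg FDR on two-sample t p-values (strict
FDR < alpha), absolute average-difference threshold (strict |AD| > cutoff),
and top-X by a stated ordering key.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError, EvaluationError
from .matrix import ExpressionMatrix
from .ranking import ClassDesign, _class_arrays, _pooled

logger = logging.getLogger(__name__)

TRUTH_METRICS = ("fdr", "ad", "topx")


@dataclass
class TruthSet:
    """Binary DEG labels over an assayed gene subset."""

    name: str
    labels: pd.Series  # bool, indexed by gene
    stats: pd.DataFrame  # per-gene p, fdr, ad

    @property
    def deg_genes(self) -> set[str]:
        return set(self.labels.index[self.labels])

    @property
    def n_deg(self) -> int:
        return int(self.labels.sum())

    def frame(self) -> pd.DataFrame:
        out = self.stats.copy()
        out["is_deg"] = self.labels
        return out


def two_sample_t_pvalues(
    matrix: ExpressionMatrix, design: ClassDesign, welch: bool = False
) -> pd.Series:
    """Two-sided two-sample t p-values per gene (pooled by default).

    Genes with zero variance in both classes get p = 1 when the class
    means are equal and p = 0 otherwise.
    """
    if design.n1 < 2 or design.n2 < 2:
        raise DataError("t-test needs >= 2 replicates per class")
    x1, x2 = _class_arrays(matrix, design)
    if welch:
        res = stats.ttest_ind(x2, x1, axis=1, equal_var=False)
        p = np.asarray(res.pvalue)
        diff = x2.mean(axis=1) - x1.mean(axis=1)
    else:
        diff, s2, df = _pooled(x1, x2)
        se = np.sqrt(s2 * (1.0 / design.n1 + 1.0 / design.n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    zero = ~np.isfinite(p)
    if zero.any():
        logger.info("%d genes with zero variance; p set by difference", int(zero.sum()))
        p = np.where(zero, np.where(diff == 0.0, 1.0, 0.0), p)
    return pd.Series(p, index=matrix.probe_ids, name="p")


def bh_adjust(pvalues: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DataError("p-values must lie in [0,1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")[::-1]  # descending
    ranked = p[order] * m / np.arange(m, 0, -1)
    adj = np.minimum.accumulate(ranked)
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    if isinstance(pvalues, pd.Series):
        return pd.Series(out, index=pvalues.index, name="fdr")
    return out


def truth_statistics(
    matrix: ExpressionMatrix, design: ClassDesign, welch: bool = False
) -> pd.DataFrame:
    """Per-gene p, BH FDR and AD for one comparison."""
    p = two_sample_t_pvalues(matrix, design, welch=welch)
    x1, x2 = _class_arrays(matrix, design)
    ad = pd.Series(x2.mean(axis=1) - x1.mean(axis=1), index=matrix.probe_ids, name="ad")
    return pd.DataFrame({"p": p, "fdr": bh_adjust(p), "ad": ad})


def define_truth(
    matrix: ExpressionMatrix,
    design: ClassDesign,
    metric: str,
    threshold: float,
    name: str | None = None,
    topx_key: str = "ad",
    welch: bool = False,
) -> TruthSet:
    """Label assayed genes as DEG / non-DEG by one of the three rules.

    metric "fdr": DEG iff FDR < threshold (strict).
    metric "ad":  DEG iff |AD| > threshold (strict).
    metric "topx": the ``threshold`` (= X) top genes by ``topx_key``
    ("fdr" family: smallest p first; "ad" family: largest |AD| first),
    with a stable gene-name tie-break.
    """
    if metric not in TRUTH_METRICS:
        raise ConfigurationError(f"unknown truth metric {metric!r}")
    st = truth_statistics(matrix, design, welch=welch)
    genes = st.index
    if metric == "fdr":
        labels = st["fdr"] < threshold
    elif metric == "ad":
        labels = st["ad"].abs() > threshold
    else:
        x = int(threshold)
        if x > len(genes):
            raise ConfigurationError(f"topX X={x} exceeds assayed count {len(genes)}")
        if topx_key == "fdr":
            key = st["p"].to_numpy()
        elif topx_key == "ad":
            key = -st["ad"].abs().to_numpy()
        else:
            raise ConfigurationError(f"unknown topx_key {topx_key!r}")
        order = np.lexsort((genes.to_numpy(dtype=str), key))
        labels = pd.Series(False, index=genes)
        labels.iloc[order[:x]] = True
    if name is None:
        name = f"truth_{metric}_{threshold:g}"
    if labels.sum() == 0:
        logger.warning("%s: empty truth set", name)
    return TruthSet(name, labels.astype(bool), st)


def require_nonempty(truth: TruthSet) -> TruthSet:
    if truth.n_deg == 0 or truth.n_deg == len(truth.labels):
        raise EvaluationError(
            f"truth set {truth.name!r} has no {'DEGs' if truth.n_deg == 0 else 'non-DEGs'}"
        )
    return truth
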