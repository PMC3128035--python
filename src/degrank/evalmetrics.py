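"""Evaluation of ranked gene lists: AUC against a truth set, percentage of
overlapping genes (POG), Spearman rank correlation and average-linkage
clustering of lists on 1 - correlation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .errors import DataError, DegenerateInputError, EvaluationError
from .ranking import ScoreTable, rank_genes
from .truth import TruthSet


def auc_from_ranks(ranks: pd.Series, labels: pd.Series) -> float:
    """Probability a random positive outranks a random negative.

    ``ranks`` follow the 1 = strongest convention; tied ranks contribute
    1/2 via the rank-sum formulation.
    """
    common = ranks.index.intersection(labels.index)
    r = ranks.loc[common].to_numpy(dtype=float)
    y = labels.loc[common].to_numpy(dtype=bool)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUC needs at least one DEG and one non-DEG")
    goodness = rankdata(-r, method="average")
    return float((goodness[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auc(
    scores: ScoreTable,
    truth: TruthSet,
    annotation: pd.DataFrame | None = None,
) -> float:
    """AUC of a score table against a truth set.

    When ``annotation`` (probe -> gene) is given, each probe inherits the
    label of its gene; evaluation is restricted to probes whose gene is
    assayed in the truth set.  Ranks are recomputed over the full list
    (average ties) before restriction, so the statistic's global ordering
    is what is evaluated.
    """
    ranks = rank_genes(scores, ties="average")
    if annotation is not None:
        gene_of = dict(zip(annotation.iloc[:, 0], annotation.iloc[:, 1]))
        genes = ranks.index.to_series().map(gene_of)
        keep = genes.isin(truth.labels.index)
        if not keep.any():
            raise EvaluationError(
                f"no probe maps to a gene assayed in truth set {truth.name!r}"
            )
        ranks = ranks[keep.to_numpy()]
        labels = genes[keep.to_numpy()].map(truth.labels).astype(bool)
        labels.index = ranks.index
    else:
        labels = truth.labels
    try:
        return auc_from_ranks(ranks, labels)
    except EvaluationError as exc:
        raise EvaluationError(f"{exc} (truth set {truth.name!r})") from None


def top_x_set(ranks: pd.Series, x: int) -> set:
    """Members ranked in the top X (ranks must be the stable flavour)."""
    if x > len(ranks):
        raise DataError(f"X={x} exceeds list length {len(ranks)}")
    return set(ranks.nsmallest(x).index)


def pog(rank_lists: Sequence[pd.Series], x: int) -> float:
    """100 * |intersection of top-X sets| / X over two or more lists."""
    if len(rank_lists) < 2:
        raise DataError("POG needs at least two lists")
    universe = set(rank_lists[0].index)
    for r in rank_lists[1:]:
        if set(r.index) != universe:
            raise DataError("POG lists must share one probe universe")
    tops = [top_x_set(r, x) for r in rank_lists]
    return 100.0 * len(set.intersection(*tops)) / x


def pairwise_pog(rank_lists: Sequence[pd.Series], x: int) -> np.ndarray:
    """Matrix of pairwise POG values."""
    k = len(rank_lists)
    out = np.full((k, k), 100.0)
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = pog([rank_lists[i], rank_lists[j]], x)
    return out


def spearman(list1: pd.Series, list2: pd.Series) -> float:
    """Pearson correlation of two (average-tie) rank vectors."""
    if set(list1.index) != set(list2.index):
        raise DataError("Spearman lists must share one probe universe")
    r1 = list1.to_numpy(dtype=float)
    r2 = list2.loc[list1.index].to_numpy(dtype=float)
    if np.ptp(r1) == 0 or np.ptp(r2) == 0:
        raise DegenerateInputError("constant rank vector; correlation undefined")
    return float(np.corrcoef(r1, r2)[0, 1])


@dataclass
class ClusterResult:
    """Average-linkage agglomeration of ranked lists on d = 1 - rho."""

    labels: list[str]
    merges: np.ndarray  # scipy linkage matrix (n-1, 4)
    distances: pd.DataFrame

    def newick(self) -> str:
        """Text rendering of the dendrogram with branch lengths."""
        from scipy.cluster.hierarchy import to_tree

        tree = to_tree(self.merges)

        def render(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.labels[node.id]}:{length:.6f}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{max(length, 0.0):.6f}"

        return render(tree, tree.dist).rsplit(":", 1)[0] + ";"


def correlation_matrix(lists: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Spearman correlation matrix of named rank lists."""
    labels = list(lists)
    if len(labels) < 2:
        raise DataError("need at least two lists")
    k = len(labels)
    rho = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            rho[i, j] = rho[j, i] = spearman(lists[labels[i]], lists[labels[j]])
    return pd.DataFrame(rho, index=labels, columns=labels)


def cluster_lists(lists: Mapping[str, pd.Series]) -> ClusterResult:
    """Average-linkage hierarchical clustering of rank lists on 1 - rho."""
    rho = correlation_matrix(lists)
    d = 1.0 - rho.to_numpy()
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    merges = linkage(condensed, method="average")
    return ClusterResult(list(rho.index), merges, 1.0 - rho)
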