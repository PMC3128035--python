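"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive (per-gene loops, exhaustive pair
counting, quadratic adjustment, O(n^3) agglomeration) and shares no code
with the package implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np


# -- statistics, one gene at a time -----------------------------------------

def ad_gene(x1: np.ndarray, x2: np.ndarray) -> float:
    return float(sum(x2) / len(x2) - sum(x1) / len(x1))


def fc_gene(x1: np.ndarray, x2: np.ndarray) -> float:
    m1 = sum(2.0**v for v in x1) / len(x1)
    m2 = sum(2.0**v for v in x2) / len(x2)
    return math.log2(m2 / m1)


def wad_all(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    m = x1.shape[0]
    ad = np.array([ad_gene(x1[g], x2[g]) for g in range(m)])
    xbar = np.array(
        [
            (sum(x1[g]) + sum(x2[g])) / (len(x1[g]) + len(x2[g]))
            for g in range(m)
        ]
    )
    w = (xbar - xbar.min()) / (xbar.max() - xbar.min())
    return ad * w


def _rank_average(values):
    """Average ranks of `values`, rank 1 = smallest, naive O(n^2)."""
    n = len(values)
    ranks = []
    for i in range(n):
        less = sum(1 for v in values if v < values[i])
        equal = sum(1 for v in values if v == values[i])
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def rank_products_all(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(rp_up, rp_down) via explicit per-pair loops."""
    m, n1 = x1.shape
    n2 = x2.shape[1]
    up_logs = [[] for _ in range(m)]
    down_logs = [[] for _ in range(m)]
    for i in range(n1):
        for j in range(n2):
            diffs = [x2[g, j] - x1[g, i] for g in range(m)]
            up = _rank_average([-d for d in diffs])
            down = _rank_average(diffs)
            for g in range(m):
                up_logs[g].append(math.log(up[g]))
                down_logs[g].append(math.log(down[g]))
    rp_up = np.array([math.exp(sum(v) / len(v)) for v in up_logs])
    rp_down = np.array([math.exp(sum(v) / len(v)) for v in down_logs])
    return rp_up, rp_down


def pooled_t_gene(x1: np.ndarray, x2: np.ndarray) -> float:
    n1, n2 = len(x1), len(x2)
    m1, m2 = sum(x1) / n1, sum(x2) / n2
    ss1 = sum((v - m1) ** 2 for v in x1)
    ss2 = sum((v - m2) ** 2 for v in x2)
    s2 = (ss1 + ss2) / (n1 + n2 - 2)
    return (m2 - m1) / math.sqrt(s2 * (1 / n1 + 1 / n2))


def moderated_t_gene(
    x1: np.ndarray, x2: np.ndarray, d0: float, s02: float
) -> float:
    n1, n2 = len(x1), len(x2)
    m1, m2 = sum(x1) / n1, sum(x2) / n2
    ss1 = sum((v - m1) ** 2 for v in x1)
    ss2 = sum((v - m2) ** 2 for v in x2)
    df = n1 + n2 - 2
    s2 = (ss1 + ss2) / df
    if math.isinf(d0):
        s2_post = s02
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
    return (m2 - m1) / math.sqrt(s2_post * (1 / n1 + 1 / n2))


def sam_t_gene(x1: np.ndarray, x2: np.ndarray, s0: float) -> float:
    n1, n2 = len(x1), len(x2)
    m1, m2 = sum(x1) / n1, sum(x2) / n2
    ss1 = sum((v - m1) ** 2 for v in x1)
    ss2 = sum((v - m2) ** 2 for v in x2)
    s2 = (ss1 + ss2) / (n1 + n2 - 2)
    se = math.sqrt(s2 * (1 / n1 + 1 / n2))
    return (m2 - m1) / (se + s0)


def shrinkage_t_all(x1: np.ndarray, x2: np.ndarray, lam: float) -> np.ndarray:
    m = x1.shape[0]
    n1, n2 = x1.shape[1], x2.shape[1]
    df = n1 + n2 - 2
    v = []
    diff = []
    for g in range(m):
        m1 = sum(x1[g]) / n1
        m2 = sum(x2[g]) / n2
        ss1 = sum((val - m1) ** 2 for val in x1[g])
        ss2 = sum((val - m2) ** 2 for val in x2[g])
        v.append((ss1 + ss2) / df)
        diff.append(m2 - m1)
    v_med = float(np.median(v))
    out = []
    for g in range(m):
        v_star = lam * v_med + (1 - lam) * v[g]
        out.append(diff[g] / math.sqrt(v_star * (1 / n1 + 1 / n2)))
    return np.array(out)


# -- evaluation metrics ------------------------------------------------------

def auc_pairs(ranks: np.ndarray, labels: np.ndarray) -> float:
    """Exhaustive DEG x non-DEG pair counting; ties count 1/2."""
    pos = [r for r, y in zip(ranks, labels) if y]
    neg = [r for r, y in zip(ranks, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            if p < q:  # smaller rank = stronger evidence
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def bh_quadratic(p: np.ndarray) -> np.ndarray:
    """Quadratic-time BH: adj_i = min over {j: p_j >= p_i} of m*p_j/rank_j."""
    m = len(p)
    sorted_p = sorted(p)
    out = []
    for pi in p:
        candidates = []
        for pj in p:
            if pj >= pi:
                rank_j = sum(1 for q in sorted_p if q <= pj)
                candidates.append(min(1.0, m * pj / rank_j))
        out.append(min(candidates))
    return np.array(out)


def spearman_pearson(r1: np.ndarray, r2: np.ndarray) -> float:
    """Pearson correlation of the rank vectors, from first principles."""
    n = len(r1)
    m1 = sum(r1) / n
    m2 = sum(r2) / n
    cov = sum((a - m1) * (b - m2) for a, b in zip(r1, r2))
    v1 = sum((a - m1) ** 2 for a in r1)
    v2 = sum((b - m2) ** 2 for b in r2)
    return cov / math.sqrt(v1 * v2)


def average_linkage_naive(dist: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """O(n^3) agglomeration; returns (cluster1, cluster2, height) merges.

    Inter-cluster distance = mean of all original pairwise distances.
    """
    n = dist.shape[0]
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean(
                    [dist[i, j] for i in clusters[a] for j in clusters[b]]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append((clusters[a], clusters[b], float(d)))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return merges
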