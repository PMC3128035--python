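"""Eight two-class associative statistics and their ranking conventions.

All statistics are oriented class2 - class1 on log2 data.  Each operation
returns a :class:`ScoreTable` carrying the per-probe statistic, its ordering
convention (descending absolute value for all methods except the rank
product, which orders ascending by its net value) and any auxiliary
per-probe quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import special
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import DataError, DegenerateInputError
from .matrix import LOG2, ExpressionMatrix

DESCENDING_ABS = "descending_abs"
ASCENDING = "ascending"

METHODS = ("wad", "ad", "fc", "rp", "modt", "samt", "shrt", "ibmt")


@dataclass(frozen=True)
class ClassDesign:
    """Assignment of samples to the two compared classes."""

    class1: tuple[str, ...]
    class2: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.class1 or not self.class2:
            raise DataError("both classes need at least one sample")
        if set(self.class1) & set(self.class2):
            raise DataError("classes overlap")

    @property
    def n1(self) -> int:
        return len(self.class1)

    @property
    def n2(self) -> int:
        return len(self.class2)

    @classmethod
    def from_samples(
        cls, samples: pd.DataFrame, type1: str, type2: str
    ) -> "ClassDesign":
        """Build a design from sample metadata, class1 = ``type1``."""
        c1 = tuple(samples.index[samples["type"] == type1])
        c2 = tuple(samples.index[samples["type"] == type2])
        if not c1 or not c2:
            raise DataError(f"no samples of type {type1!r} or {type2!r}")
        return cls(c1, c2)


@dataclass
class ScoreTable:
    """Per-probe statistic values with their ordering convention."""

    method: str
    scores: pd.Series
    ordering: str
    aux: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ordering not in (DESCENDING_ABS, ASCENDING):
            raise DataError(f"unknown ordering {self.ordering!r}")
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise DataError(f"{self.method}: non-finite statistic values")


def _class_arrays(
    matrix: ExpressionMatrix, design: ClassDesign
) -> tuple[np.ndarray, np.ndarray]:
    if matrix.scale != LOG2:
        raise DataError("ranking statistics expect log2 data")
    missing = (set(design.class1) | set(design.class2)) - set(matrix.sample_ids)
    if missing:
        raise DataError(f"design samples absent from matrix: {sorted(missing)}")
    x1 = matrix.values[list(design.class1)].to_numpy(dtype=float)
    x2 = matrix.values[list(design.class2)].to_numpy(dtype=float)
    return x1, x2


def _require_reps(design: ClassDesign) -> None:
    if design.n1 < 2 or design.n2 < 2:
        raise DataError("variance-based statistics need >= 2 replicates per class")


def _pooled(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean difference, pooled variance and its degrees of freedom."""
    n1, n2 = x1.shape[1], x2.shape[1]
    diff = x2.mean(axis=1) - x1.mean(axis=1)
    ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)
    df = n1 + n2 - 2
    return diff, ss / df, df


# ---------------------------------------------------------------------------
# simple fold-change family
# ---------------------------------------------------------------------------

def ad_statistic(matrix: ExpressionMatrix, design: ClassDesign) -> ScoreTable:
    """Average difference: difference of log2 class means."""
    x1, x2 = _class_arrays(matrix, design)
    s = x2.mean(axis=1) - x1.mean(axis=1)
    return ScoreTable("ad", pd.Series(s, index=matrix.probe_ids), DESCENDING_ABS)


def fc_statistic(matrix: ExpressionMatrix, design: ClassDesign) -> ScoreTable:
    """log2 ratio of natural-scale arithmetic class means."""
    x1, x2 = _class_arrays(matrix, design)
    m1 = np.exp2(x1).mean(axis=1)
    m2 = np.exp2(x2).mean(axis=1)
    s = np.log2(m2 / m1)
    return ScoreTable("fc", pd.Series(s, index=matrix.probe_ids), DESCENDING_ABS)


def wad_statistic(matrix: ExpressionMatrix, design: ClassDesign) -> ScoreTable:
    """Weighted average difference: AD times a min-max intensity weight.

    The weight of probe g is its mean log2 signal over both classes,
    rescaled so the dimmest probe gets 0 and the brightest 1.
    """
    x1, x2 = _class_arrays(matrix, design)
    if matrix.n_probes < 2:
        raise DegenerateInputError("WAD needs >= 2 probes for min-max scaling")
    ad = x2.mean(axis=1) - x1.mean(axis=1)
    xbar = np.hstack([x1, x2]).mean(axis=1)
    lo, hi = xbar.min(), xbar.max()
    if hi == lo:
        raise DegenerateInputError("all probe mean intensities equal; weight undefined")
    w = (xbar - lo) / (hi - lo)
    aux = pd.DataFrame({"weight": w, "ad": ad}, index=matrix.probe_ids)
    return ScoreTable("wad", pd.Series(ad * w, index=matrix.probe_ids), DESCENDING_ABS, aux)


# ---------------------------------------------------------------------------
# rank products
# ---------------------------------------------------------------------------

def rank_products(matrix: ExpressionMatrix, design: ClassDesign) -> ScoreTable:
    """Rank product over all n1*n2 between-class sample pairs.

    For each pair, genes are ranked by the pairwise log2 difference, once
    with rank 1 = most up-regulated and once with rank 1 = most
    down-regulated; the two per-gene values are the geometric means of the
    ranks across pairs and the net value is the smaller of the two.
    """
    x1, x2 = _class_arrays(matrix, design)
    m = x1.shape[0]
    # m x (n1*n2) pairwise differences, class2 minus class1
    diffs = (x2[:, None, :] - x1[:, :, None]).reshape(m, -1)
    up_logsum = np.zeros(m)
    down_logsum = np.zeros(m)
    n_pairs = diffs.shape[1]
    for j in range(n_pairs):
        up_logsum += np.log(rankdata(-diffs[:, j], method="average"))
        down_logsum += np.log(rankdata(diffs[:, j], method="average"))
    rp_up = np.exp(up_logsum / n_pairs)
    rp_down = np.exp(down_logsum / n_pairs)
    net = np.minimum(rp_up, rp_down)
    aux = pd.DataFrame({"rp_up": rp_up, "rp_down": rp_down}, index=matrix.probe_ids)
    return ScoreTable("rp", pd.Series(net, index=matrix.probe_ids), ASCENDING, aux)


# ---------------------------------------------------------------------------
# moderated t family
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = float(special.polygamma(1, y))
        step = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += step
        if abs(step) < 1e-10 * y:
            break
    return y


def _log_var_pseudo(s2: np.ndarray, df: int) -> np.ndarray:
    """Bias-corrected log sample variances (zeros clamped to the smallest
    positive variance for the estimation step only)."""
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise DegenerateInputError("zero pooled variance for every gene")
    s2_safe = np.where(s2 > 0, s2, positive.min())
    return np.log(s2_safe) - float(special.digamma(df / 2.0)) + np.log(df / 2.0)


def _fit_prior(e: np.ndarray, df: int) -> tuple[float, float | np.ndarray]:
    """Moment-matching fit of prior df d0 and prior variance s0^2.

    ``e`` are the bias-corrected log variances (possibly residuals about a
    trend, in which case the returned scale applies to the trend).
    """
    evar = float(np.var(e, ddof=1)) if e.size > 1 else 0.0
    target = evar - float(special.polygamma(1, df / 2.0))
    if target > 0:
        d0 = 2.0 * _trigamma_inverse(target)
    else:
        d0 = np.inf
    return d0, _prior_scale(float(np.mean(e)), d0)


def _prior_scale(elocation: float | np.ndarray, d0: float) -> float | np.ndarray:
    if np.isinf(d0):
        return np.exp(elocation)
    return np.exp(elocation + float(special.digamma(d0 / 2.0)) - np.log(d0 / 2.0))


def _moderated_denominator(
    s2: np.ndarray, df: int, d0: float, s02: float | np.ndarray
) -> np.ndarray:
    if np.isinf(d0):
        return np.broadcast_to(np.asarray(s02, dtype=float), s2.shape).copy()
    if d0 == 0:
        return s2.copy()
    return (d0 * s02 + df * s2) / (d0 + df)


def moderated_t(
    matrix: ExpressionMatrix, design: ClassDesign, prior_df: float | None = None
) -> ScoreTable:
    """Empirical-Bayes moderated t with a single shared prior variance.

    The prior (d0, s0^2) is estimated by moment matching on the log sample
    variances; ``prior_df`` overrides the estimate (0 recovers the ordinary
    pooled t, infinity uses the prior variance alone).
    """
    _require_reps(design)
    x1, x2 = _class_arrays(matrix, design)
    diff, s2, df = _pooled(x1, x2)
    e = _log_var_pseudo(s2, df)
    if prior_df is None:
        d0, s02 = _fit_prior(e, df)
    else:
        d0 = float(prior_df)
        s02 = _prior_scale(float(np.mean(e)), d0) if d0 != 0 else 0.0
    s2_post = _moderated_denominator(s2, df, d0, s02)
    if (s2_post <= 0).any():
        raise DegenerateInputError("zero posterior variance; input degenerate")
    t = diff / np.sqrt(s2_post * (1.0 / design.n1 + 1.0 / design.n2))
    aux = pd.DataFrame({"s2": s2, "s2_post": s2_post}, index=matrix.probe_ids)
    return ScoreTable(
        "modt",
        pd.Series(t, index=matrix.probe_ids),
        DESCENDING_ABS,
        aux,
        params={"d0": d0, "s02": float(np.asarray(s02).mean())},
    )


def choose_sam_s0(
    r: np.ndarray, se: np.ndarray, n_windows: int = 100
) -> float:
    """Fudge factor minimising the coefficient of variation of windowed MADs.

    Candidates are the percentiles 0, 5, ..., 100 of the per-gene standard
    errors; genes are partitioned into ``n_windows`` quantile windows of
    the standard error and, for each candidate, the CV of the window-wise
    median absolute deviations of the modified statistic is evaluated.
    """
    m = len(se)
    k = int(min(n_windows, max(1, m // 3)))
    order = np.argsort(se, kind="mergesort")
    windows = np.array_split(order, k)
    candidates = np.percentile(se, np.arange(0, 101, 5))
    best_s0, best_cv = 0.0, np.inf
    for s0 in candidates:
        d = r / (se + s0)
        mads = np.array(
            [np.median(np.abs(d[w] - np.median(d[w]))) * 1.4826 for w in windows]
        )
        mean = mads.mean()
        if mean <= 0:
            continue
        cv = mads.std(ddof=1) / mean if k > 1 else 0.0
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def sam_t(
    matrix: ExpressionMatrix,
    design: ClassDesign,
    s0: float | None = None,
    n_windows: int = 100,
) -> ScoreTable:
    """SAM-style t with an additive fudge factor in the denominator."""
    _require_reps(design)
    x1, x2 = _class_arrays(matrix, design)
    diff, s2, _ = _pooled(x1, x2)
    if not (s2 > 0).any():
        raise DegenerateInputError("zero pooled variance for every gene")
    se = np.sqrt(s2 * (1.0 / design.n1 + 1.0 / design.n2))
    if s0 is None:
        s0 = choose_sam_s0(diff, se, n_windows=n_windows)
    denom = se + s0
    if (denom <= 0).any():
        raise DegenerateInputError("zero denominator in SAM statistic")
    t = diff / denom
    aux = pd.DataFrame({"se": se}, index=matrix.probe_ids)
    return ScoreTable(
        "samt", pd.Series(t, index=matrix.probe_ids), DESCENDING_ABS, aux,
        params={"s0": float(s0)},
    )


def shrinkage_t(
    matrix: ExpressionMatrix,
    design: ClassDesign,
    shrink_lambda: float | None = None,
) -> ScoreTable:
    """t with per-gene variances shrunk toward the median gene variance.

    lambda* = min(1, sum Var^(v_g) / sum (v_g - v_median)^2), with the
    chi-square variance estimate Var^(v_g) = 2 v_g^2 / df; lambda* = 1 when
    the variances have no spread.
    """
    _require_reps(design)
    x1, x2 = _class_arrays(matrix, design)
    diff, s2, df = _pooled(x1, x2)
    v_med = float(np.median(s2))
    if shrink_lambda is None:
        denom = float(np.sum((s2 - v_med) ** 2))
        if denom == 0.0:
            lam = 1.0
        else:
            lam = min(1.0, float(np.sum(2.0 * s2**2 / df)) / denom)
    else:
        lam = float(shrink_lambda)
    v_star = lam * v_med + (1.0 - lam) * s2
    if (v_star <= 0).any():
        raise DegenerateInputError("zero shrunken variance; input degenerate")
    t = diff / np.sqrt(v_star * (1.0 / design.n1 + 1.0 / design.n2))
    aux = pd.DataFrame({"s2": s2, "v_star": v_star}, index=matrix.probe_ids)
    return ScoreTable(
        "shrt", pd.Series(t, index=matrix.probe_ids), DESCENDING_ABS, aux,
        params={"lambda": lam},
    )


def ibm_t(
    matrix: ExpressionMatrix,
    design: ClassDesign,
    span: float = 0.5,
    prior_df: float | None = None,
) -> ScoreTable:
    """Intensity-based moderated t.

    Like :func:`moderated_t` but the prior variance is an intensity-
    dependent trend: a lowess fit (tricube weights, fraction ``span``) of
    the bias-corrected log variances on the mean log2 intensity, with the
    prior degrees of freedom estimated from the residuals about the fit.
    """
    _require_reps(design)
    x1, x2 = _class_arrays(matrix, design)
    diff, s2, df = _pooled(x1, x2)
    abar = np.hstack([x1, x2]).mean(axis=1)
    e = _log_var_pseudo(s2, df)
    efit = lowess(e, abar, frac=span, return_sorted=False)
    resid = e - efit
    if prior_df is None:
        evar = float(np.var(resid, ddof=1)) if resid.size > 1 else 0.0
        target = evar - float(special.polygamma(1, df / 2.0))
        d0 = 2.0 * _trigamma_inverse(target) if target > 0 else np.inf
    else:
        d0 = float(prior_df)
    s02 = _prior_scale(efit, d0) if d0 != 0 else np.zeros_like(efit)
    s2_post = _moderated_denominator(s2, df, d0, s02)
    if (s2_post <= 0).any():
        raise DegenerateInputError("zero posterior variance; input degenerate")
    t = diff / np.sqrt(s2_post * (1.0 / design.n1 + 1.0 / design.n2))
    aux = pd.DataFrame(
        {
            "s2": s2,
            "s2_post": s2_post,
            "s02": np.broadcast_to(np.asarray(s02, dtype=float), s2.shape),
            "mean_intensity": abar,
        },
        index=matrix.probe_ids,
    )
    return ScoreTable(
        "ibmt", pd.Series(t, index=matrix.probe_ids), DESCENDING_ABS, aux,
        params={"d0": d0},
    )


_DISPATCH: dict[str, Callable[[ExpressionMatrix, ClassDesign], ScoreTable]] = {
    "wad": wad_statistic,
    "ad": ad_statistic,
    "fc": fc_statistic,
    "rp": rank_products,
    "modt": moderated_t,
    "samt": sam_t,
    "shrt": shrinkage_t,
    "ibmt": ibm_t,
}


def compute_statistic(
    method: str, matrix: ExpressionMatrix, design: ClassDesign
) -> ScoreTable:
    """Dispatch one of the eight methods by name."""
    try:
        fn = _DISPATCH[method]
    except KeyError:
        raise DataError(f"unknown method {method!r}; choose from {METHODS}") from None
    return fn(matrix, design)


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def rank_genes(table: ScoreTable, ties: str = "average") -> pd.Series:
    """Convert statistics to ranks (1 = strongest evidence).

    ``ties="average"`` assigns tied statistics their average rank (for
    correlation and enrichment use); ``ties="stable"`` breaks ties by probe
    ID so top-X truncation is deterministic.
    """
    s = table.scores.to_numpy(dtype=float)
    if not np.isfinite(s).all():
        raise DataError("non-finite statistic; upstream error")
    key = s if table.ordering == ASCENDING else -np.abs(s)
    if ties == "average":
        ranks = rankdata(key, method="average")
    elif ties == "stable":
        ids = table.scores.index.to_numpy(dtype=str)
        order = np.lexsort((ids, key))
        ranks = np.empty(len(key), dtype=float)
        ranks[order] = np.arange(1, len(key) + 1)
    else:
        raise DataError(f"unknown tie mode {ties!r}")
    return pd.Series(ranks, index=table.scores.index, name="rank")


def score_frame(table: ScoreTable) -> pd.DataFrame:
    """TSV-ready frame: statistic, both rank flavours, auxiliary columns."""
    out = pd.DataFrame({"statistic": table.scores})
    out["rank"] = rank_genes(table, ties="stable").astype(int)
    out["rank_avg"] = rank_genes(table, ties="average")
    if table.aux is not None:
        for col in table.aux.columns:
            out[col] = table.aux[col]
    return out
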