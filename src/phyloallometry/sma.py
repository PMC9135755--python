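"""Standardized major axis (SMA) line fitting and multi-group inference.

SMA fits a scaling line symmetric in x and y — appropriate when both
variables carry biological variation — with slope
``b = sign(s_xy) * sqrt(s_yy / s_xx)`` and elevation ``a = ybar - b*xbar``.
For several groups (species) sharing a bivariate scaling relationship the
module provides, in the tradition of the SMATR tool:

* a likelihood-ratio test of a common slope across groups
  (chi-square, df = g - 1), with the common slope estimated by minimizing
  the LR statistic;
* a Wald test of equal elevations at the common slope
  (chi-square, df = g - 1), accounting for the shared uncertainty in the
  common slope;
* pairwise elevation-shift matrices: the signed elevation difference and a
  df = 1 Wald test for every species pair, the raw material for
  inverse-shift (trade-off) classification.

The common-slope machinery follows Warton & Weber's grouped-SMA
methodology, including the small-sample weight (n_i - 2.5) in the LR
statistic. A ``method="ma"`` switch selects the (unstandardized) major
axis estimator instead; SMA is the default throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

logger = logging.getLogger(__name__)

__all__ = ["SMAFit", "GroupStats", "MultiGroupSMA", "MultiGroupSMAResults",
           "PairwiseShiftMatrix", "sma_fit", "common_slope_test",
           "elevation_test", "pairwise_elevation"]


# ---------------------------------------------------------------------------
# per-group sufficient statistics
# ---------------------------------------------------------------------------

@dataclass
class GroupStats:
    """Sufficient statistics of one group's (x, y) sample."""
    label: str
    n: int
    xbar: float
    ybar: float
    sxx: float
    sxy: float
    syy: float

    @classmethod
    def from_xy(cls, x, y, label="group"):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-d arrays of equal length")
        n = len(x)
        if n < 3:
            raise ValueError(f"group {label!r}: need n >= 3, have {n}")
        sxx = float(np.var(x, ddof=1))
        syy = float(np.var(y, ddof=1))
        if sxx <= 0 or syy <= 0:
            raise ValueError(f"group {label!r}: zero variance in x or y")
        sxy = float(np.cov(x, y, ddof=1)[0, 1])
        return cls(label, n, float(x.mean()), float(y.mean()), sxx, sxy, syy)

    @property
    def r(self) -> float:
        return self.sxy / np.sqrt(self.sxx * self.syy)

    def resid_var(self, b: float) -> float:
        """Variance of y - b*x within the group."""
        return self.syy - 2 * b * self.sxy + b * b * self.sxx

    def elevation(self, b: float) -> float:
        return self.ybar - b * self.xbar


@dataclass
class SMAFit:
    """Single-group SMA (or MA) line fit."""
    group: str
    slope: float
    elevation: float
    n: int
    r: float
    slope_ci: tuple
    method: str = "sma"
    minimal_n: bool = False   # n == 3: estimable but fragile

    def summary(self) -> str:
        flag = "  [minimal-n]" if self.minimal_n else ""
        return (f"{self.method.upper()} [{self.group}]: slope = "
                f"{self.slope:.4f} ({self.slope_ci[0]:.4f}, "
                f"{self.slope_ci[1]:.4f}), elevation = {self.elevation:.4f}, "
                f"n = {self.n}, r = {self.r:.3f}{flag}")


def _sma_slope(st: GroupStats, method: str = "sma") -> float:
    if method == "sma":
        sign = np.sign(st.sxy)
        if sign == 0:
            warnings.warn(f"group {st.label!r}: zero covariance; slope sign "
                          "set positive", stacklevel=3)
            sign = 1.0
        return float(sign * np.sqrt(st.syy / st.sxx))
    if method == "ma":
        d = st.syy - st.sxx
        return float((d + np.sqrt(d * d + 4 * st.sxy ** 2)) / (2 * st.sxy)) \
            if st.sxy != 0 else (1.0 if st.syy >= st.sxx else 0.0)
    raise ValueError(f"unknown line-fit method {method!r}")


def sma_fit(x, y, group: str = "group", alpha: float = 0.05,
            method: str = "sma") -> SMAFit:
    """Fit a standardized major axis line to one group.

    The slope confidence interval uses the standard F-based construction
    ``b * (sqrt(B + 1) +/- sqrt(B))`` with
    ``B = F(1-alpha; 1, n-2) * (1 - r^2) / (n - 2)``.
    """
    st = GroupStats.from_xy(x, y, group)
    b = _sma_slope(st, method)
    a = st.elevation(b)
    r = st.r
    B = scipy.stats.f.ppf(1 - alpha, 1, st.n - 2) \
        * max(1 - r * r, 0.0) / (st.n - 2)
    lo = b * (np.sqrt(B + 1) - np.sqrt(B))
    hi = b * (np.sqrt(B + 1) + np.sqrt(B))
    ci = (min(lo, hi), max(lo, hi))
    return SMAFit(group, b, a, st.n, r, ci, method=method,
                  minimal_n=st.n == 3)


# ---------------------------------------------------------------------------
# multi-group inference
# ---------------------------------------------------------------------------

def _as_group_stats(groups) -> list:
    """Accept a dict label -> (x, y) or a list of (x, y) pairs."""
    if isinstance(groups, dict):
        return [GroupStats.from_xy(x, y, label)
                for label, (x, y) in groups.items()]
    out = []
    for i, item in enumerate(groups):
        if isinstance(item, GroupStats):
            out.append(item)
        else:
            x, y = item
            out.append(GroupStats.from_xy(x, y, f"group{i}"))
    return out


def _lr_statistic(stats, b: float) -> float:
    """Grouped-SMA likelihood-ratio statistic at candidate common slope b.

    Each group contributes -(n_i - 2.5) * log(1 - r_rf^2) where r_rf is the
    within-group correlation between residual scores (y - b x) and fitted
    axis scores (y + b x); it vanishes at the group's own SMA slope.
    """
    total = 0.0
    for st in stats:
        num = st.syy - b * b * st.sxx
        var_r = st.syy - 2 * b * st.sxy + b * b * st.sxx
        var_f = st.syy + 2 * b * st.sxy + b * b * st.sxx
        r2 = num * num / (var_r * var_f)
        r2 = min(r2, 1.0 - 1e-15)
        total += -(st.n - 2.5) * np.log1p(-r2)
    return total


def _pooled_slope(stats) -> float:
    w = np.array([st.n - 1 for st in stats], dtype=float)
    sxx = float(np.dot(w, [st.sxx for st in stats]) / w.sum())
    syy = float(np.dot(w, [st.syy for st in stats]) / w.sum())
    sxy = float(np.dot(w, [st.sxy for st in stats]) / w.sum())
    sign = np.sign(sxy) or 1.0
    return float(sign * np.sqrt(syy / sxx))


def _estimate_common_slope(stats, max_iter: int = 200):
    """Minimize the LR statistic over the common slope.

    Parametrized as b = sign * exp(t) around the pooled SMA slope so the
    search stays on one sign; bounded Brent with tight tolerance.
    """
    b0 = _pooled_slope(stats)
    sign = np.sign(b0) or 1.0
    t0 = np.log(abs(b0))
    opt = scipy.optimize.minimize_scalar(
        lambda t: _lr_statistic(stats, sign * np.exp(t)),
        bounds=(t0 - 6.0, t0 + 6.0), method="bounded",
        options={"xatol": 1e-12, "maxiter": max_iter})
    if not opt.success:
        raise RuntimeError(
            f"common-slope estimation did not converge; last iterate "
            f"b = {sign * np.exp(opt.x):.6g}, statistic = {opt.fun:.6g}")
    b_c = float(sign * np.exp(opt.x))
    stat = float(_lr_statistic(stats, b_c))
    return b_c, stat


def _common_slope_variance(stats, b_c: float) -> float:
    """Observed-information variance of the common slope.

    The LR profile behaves as -2 log-likelihood, so
    var(b) ~= 2 / (d^2 LR / d b^2) at the minimum (central differences).
    """
    h = max(1e-5 * abs(b_c), 1e-8)
    f0 = _lr_statistic(stats, b_c)
    fp = _lr_statistic(stats, b_c + h)
    fm = _lr_statistic(stats, b_c - h)
    curv = (fp - 2 * f0 + fm) / (h * h)
    if curv <= 0:
        raise RuntimeError("non-positive curvature at the common slope; "
                           "slope not identified")
    return 2.0 / curv


def common_slope_test(groups, max_iter: int = 200):
    """Estimate a common SMA slope and test slope homogeneity.

    Returns ``(b_c, statistic, df, p)``; the statistic is compared to
    chi-square with df = g - 1.
    """
    stats = _as_group_stats(groups)
    if len(stats) < 2:
        raise ValueError("need at least 2 groups")
    b_c, stat = _estimate_common_slope(stats, max_iter)
    df = len(stats) - 1
    p = float(scipy.stats.chi2.sf(stat, df))
    return b_c, stat, df, p


def _elevation_wald(stats, b_c: float, var_b: float):
    """Wald statistic for equal elevations at a given common slope."""
    a = np.array([st.elevation(b_c) for st in stats])
    xbar = np.array([st.xbar for st in stats])
    # residual variance about a fitted line has n - 2 df
    dvar = np.array([st.resid_var(b_c) * (st.n - 1) / (st.n - 2) / st.n
                     for st in stats])
    V = np.diag(dvar) + var_b * np.outer(xbar, xbar)
    Vi = np.linalg.inv(V)
    one = np.ones_like(a)
    W = float(a @ Vi @ a - (one @ Vi @ a) ** 2 / (one @ Vi @ one))
    return max(W, 0.0), a


def elevation_test(groups, b_c: float | None = None,
                   var_b: float | None = None, slope_p: float | None = None):
    """Wald test of equal elevations across groups at the common slope.

    ``b_c``/``var_b`` default to the estimates from
    :func:`common_slope_test` on the same groups. If ``slope_p`` is given
    and below 0.05 a warning is emitted — elevation comparisons presume a
    common slope — but the test still runs.

    Returns ``(W, df, p)``.
    """
    stats = _as_group_stats(groups)
    if any(st.n < 3 for st in stats):
        raise ValueError("every group needs n >= 3 for the elevation test")
    if b_c is None:
        b_c, stat, df_s, slope_p = common_slope_test(stats)
    if var_b is None:
        var_b = _common_slope_variance(stats, b_c)
    if slope_p is not None and slope_p < 0.05:
        warnings.warn("common slope rejected (p = %.3g); elevation "
                      "comparisons assume slope homogeneity" % slope_p,
                      stacklevel=2)
    W, _ = _elevation_wald(stats, b_c, var_b)
    df = len(stats) - 1
    return W, df, float(scipy.stats.chi2.sf(W, df))


# ---------------------------------------------------------------------------
# pairwise elevation shifts
# ---------------------------------------------------------------------------

def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment of a flat vector of p values."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


@dataclass
class PairwiseShiftMatrix:
    """All pairwise elevation comparisons for one structure.

    ``delta_elevation[i, j] = a_i - a_j`` (antisymmetric) at the pair's
    common slope; ``W`` and ``p`` are the df = 1 Wald tests; ``p_holm``
    the Holm-adjusted p values across the g(g-1)/2 comparisons.
    """
    groups: list
    delta_elevation: np.ndarray
    W: np.ndarray
    p: np.ndarray
    p_holm: np.ndarray
    common_slope: float | None = None   # global slope, if one was used

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_pairs(self) -> int:
        g = self.n_groups
        return g * (g - 1) // 2

    def pair_index(self):
        g = self.n_groups
        return [(i, j) for i in range(g) for j in range(i + 1, g)]

    def upper_triangle(self, which: str = "delta_elevation") -> np.ndarray:
        mat = getattr(self, which)
        return np.array([mat[i, j] for i, j in self.pair_index()])

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, j in self.pair_index():
            rows.append({
                "group_i": self.groups[i], "group_j": self.groups[j],
                "delta_elevation": self.delta_elevation[i, j],
                "W": self.W[i, j], "p": self.p[i, j],
                "p_holm": self.p_holm[i, j],
            })
        return pd.DataFrame(rows)

    def to_square_frame(self) -> pd.DataFrame:
        """Square layout: elevation differences above the diagonal, Wald p
        values below."""
        g = self.n_groups
        out = pd.DataFrame(np.full((g, g), np.nan), index=self.groups,
                           columns=self.groups)
        for i, j in self.pair_index():
            out.iloc[i, j] = self.delta_elevation[i, j]
            out.iloc[j, i] = self.p[i, j]
        return out


def pairwise_elevation(groups, use_global_slope: bool = False,
                       labels=None) -> PairwiseShiftMatrix:
    """Pairwise elevation-shift tests for every unordered group pair.

    By default each pair re-estimates its own common slope (the behaviour
    of grouped-SMA tools); ``use_global_slope=True`` reuses the slope
    estimated from all groups jointly.
    """
    stats = _as_group_stats(groups)
    if labels is not None:
        for st, lbl in zip(stats, labels):
            st.label = lbl
    if any(st.n < 3 for st in stats):
        raise ValueError("every group needs n >= 3 for pairwise tests")
    g = len(stats)
    names = [st.label for st in stats]
    delta = np.zeros((g, g))
    W = np.zeros((g, g))
    p = np.zeros((g, g))
    np.fill_diagonal(p, 1.0)
    b_global = var_global = None
    if use_global_slope:
        b_global, _ = _estimate_common_slope(stats)
        var_global = _common_slope_variance(stats, b_global)
    for i in range(g):
        for j in range(i + 1, g):
            pair = [stats[i], stats[j]]
            if use_global_slope:
                b_c, var_b = b_global, var_global
            else:
                b_c, _ = _estimate_common_slope(pair)
                var_b = _common_slope_variance(pair, b_c)
            w_ij, a = _elevation_wald(pair, b_c, var_b)
            delta[i, j] = a[0] - a[1]
            delta[j, i] = -delta[i, j]
            W[i, j] = W[j, i] = w_ij
            p[i, j] = p[j, i] = float(scipy.stats.chi2.sf(w_ij, 1))
    flat_p = np.array([p[i, j] for i in range(g) for j in range(i + 1, g)])
    holm = _holm(flat_p)
    p_holm = np.zeros((g, g))
    np.fill_diagonal(p_holm, 1.0)
    for (k, (i, j)) in enumerate([(i, j) for i in range(g)
                                  for j in range(i + 1, g)]):
        p_holm[i, j] = p_holm[j, i] = holm[k]
    return PairwiseShiftMatrix(names, delta, W, p, p_holm,
                               common_slope=b_global)


# ---------------------------------------------------------------------------
# model / results facade
# ---------------------------------------------------------------------------

@dataclass
class MultiGroupSMAResults:
    fits: dict                       # label -> SMAFit
    common_slope: float
    slope_stat: float
    slope_df: int
    slope_p: float
    elevation_W: float
    elevation_df: int
    elevation_p: float
    pairwise: PairwiseShiftMatrix
    var_common_slope: float = np.nan
    group_stats: list = field(default_factory=list)

    @property
    def groups(self) -> list:
        return list(self.fits)

    def elevations_at_common_slope(self) -> pd.Series:
        return pd.Series({st.label: st.elevation(self.common_slope)
                          for st in self.group_stats})

    def summary(self) -> str:
        lines = ["Multi-group SMA"]
        lines += ["  " + f.summary() for f in self.fits.values()]
        lines.append(
            f"Common slope b_c = {self.common_slope:.4f}; slope homogeneity "
            f"LR = {self.slope_stat:.3f}, df = {self.slope_df}, "
            f"P = {self.slope_p:.4g}")
        lines.append(
            f"Elevation Wald W = {self.elevation_W:.3f}, "
            f"df = {self.elevation_df}, P = {self.elevation_p:.4g}")
        return "\n".join(lines)


class MultiGroupSMA:
    """Grouped SMA model: per-group lines, common slope, elevation shifts.

    Build from arrays (``x``, ``y``, ``groups``) or from a
    :class:`~phyloallometry.traits.TraitTable` via :meth:`from_table`;
    ``fit()`` returns a :class:`MultiGroupSMAResults`.
    """

    def __init__(self, x, y, groups, method: str = "sma"):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        if not (len(x) == len(y) == len(groups)):
            raise ValueError("x, y and groups must have equal length")
        self.method = method
        self.labels = sorted(pd.unique(groups).tolist())
        self._xy = {lbl: (x[groups == lbl], y[groups == lbl])
                    for lbl in self.labels}
        for lbl, (xs, _) in self._xy.items():
            if len(xs) < 3:
                raise ValueError(f"group {lbl!r} has n = {len(xs)} < 3")

    @classmethod
    def from_table(cls, table, x: str, y: str, method: str = "sma"):
        sub = table.complete_rows([x, y])
        return cls(sub.column(x).to_numpy(), sub.column(y).to_numpy(),
                   sub.species.to_numpy(), method=method)

    def fit(self, use_global_slope_pairwise: bool = False) -> MultiGroupSMAResults:
        fits = {lbl: sma_fit(xs, ys, group=lbl, method=self.method)
                for lbl, (xs, ys) in self._xy.items()}
        stats = [GroupStats.from_xy(xs, ys, lbl)
                 for lbl, (xs, ys) in self._xy.items()]
        b_c, stat = _estimate_common_slope(stats)
        df = len(stats) - 1
        slope_p = float(scipy.stats.chi2.sf(stat, df))
        var_b = _common_slope_variance(stats, b_c)
        W, _ = _elevation_wald(stats, b_c, var_b)
        elev_p = float(scipy.stats.chi2.sf(W, df))
        pw = pairwise_elevation(stats, use_global_slope=use_global_slope_pairwise)
        return MultiGroupSMAResults(
            fits=fits, common_slope=b_c, slope_stat=stat, slope_df=df,
            slope_p=slope_p, elevation_W=W, elevation_df=df,
            elevation_p=elev_p, pairwise=pw, var_common_slope=var_b,
            group_stats=stats)
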