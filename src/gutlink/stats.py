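"""Statistical primitives used by every stage of the pipeline.

All tests are two-sided. Pearson p-values come from the exact t
transform r·sqrt(n−2)/sqrt(1−r²); at n=6 (df=4) this admits the closed
form p = 1 − (3/2)|r| + (1/2)|r|³, which small cross-diet screens hit
constantly and which the unit tests pin down.

The two-way ANOVA uses type-II sums of squares (groups in these designs
are unbalanced, n=4 or 7 per cell) via an ordinary least-squares fit;
Tukey's post-hoc p comes from the studentized-range distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from gutlink.errors import (
    DegenerateFitError,
    InputError,
    UndefinedCorrelationError,
    UnsupportedLayoutError,
)

__all__ = [
    "CorrelationResult",
    "AncovaResult",
    "AnovaTable",
    "pearson",
    "pearson_pvalue",
    "ols_line",
    "ancova_compare",
    "welch_test",
    "bh_adjust",
    "two_way_anova",
    "tukey_hsd",
    "bonferroni",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its exact two-sided p-value.

    ``degenerate`` is set when |r| = 1 (noiseless data), in which case
    p = 0 by convention rather than raising.
    """

    r: float
    n: int
    df: int | None = None
    t_stat: float | None = None
    p_two_sided: float | None = None
    degenerate: bool = False


@dataclass(frozen=True)
class AncovaResult:
    """Nested-model comparison of two regression lines.

    ``F_slope``/``p_slope`` test homogeneity of slopes (separate lines
    vs common slope); ``F_elev``/``p_elev`` test equal elevation under
    the common-slope model (common slope vs a single line). ``p_elev``
    is meaningful only when the slopes are homogeneous.
    """

    slope_A: float
    slope_B: float
    F_slope: float
    p_slope: float
    df_slope: tuple[int, int]
    F_elev: float
    p_elev: float
    df_elev: tuple[int, int]


@dataclass(frozen=True)
class AnovaTable:
    """Two-way ANOVA decomposition (type-II SS)."""

    table: pd.DataFrame = field(repr=False)

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]

    @property
    def p_values(self) -> pd.Series:
        return self.table["p"]


# ---------------------------------------------------------------------------
# correlation


def _as_float_array(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InputError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise InputError(f"{name} contains non-finite values")
    return arr


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation of two paired sequences.

    Returns the coefficient plus the exact two-sided p-value from the
    t transform when n ≥ 3; for n = 2 only r is defined. Zero variance
    in either input raises :class:`UndefinedCorrelationError` so the
    caller can decide whether to exclude the record.
    """
    xa = _as_float_array(x, "x")
    ya = _as_float_array(y, "y")
    if xa.size != ya.size:
        raise InputError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < 2:
        raise InputError("need at least 2 pairs")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        raise UndefinedCorrelationError(
            "zero variance in " + ("x" if sxx == 0.0 else "y")
        )
    r = float(xc @ yc / math.sqrt(sxx * syy))
    r = max(-1.0, min(1.0, r))
    n = int(xa.size)
    if n < 3:
        return CorrelationResult(r=r, n=n)
    df = n - 2
    if abs(r) >= 1.0:
        return CorrelationResult(
            r=r, n=n, df=df, t_stat=math.inf, p_two_sided=0.0, degenerate=True
        )
    t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
    p = 2.0 * sps.t.sf(abs(t), df)
    return CorrelationResult(r=r, n=n, df=df, t_stat=t, p_two_sided=p)


def pearson_pvalue(r: float, n: int) -> float:
    """Exact two-sided p-value for a Pearson coefficient at n pairs.

    p = 2·SF_t(|r|·sqrt(n−2)/sqrt(1−r²), df = n−2). For df = 4 this
    equals 1 − (3/2)|r| + (1/2)|r|³ in closed form. |r| = 1 returns 0
    (degenerate, noiseless data).
    """
    if n < 3:
        raise InputError("p-value requires n >= 3")
    if not -1.0 <= r <= 1.0:
        raise InputError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1.0:
        return 0.0
    df = n - 2
    t = abs(r) * math.sqrt(df) / math.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(t, df))


# ---------------------------------------------------------------------------
# least squares and ANCOVA


def ols_line(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float, float]:
    """Simple least-squares line y = slope·x + intercept.

    Returns (slope, intercept, residual sum of squares, slope SE).
    The slope SE is NaN when there are no residual degrees of freedom.
    """
    xa = _as_float_array(x, "x")
    ya = _as_float_array(y, "y")
    if xa.size != ya.size:
        raise InputError(f"length mismatch: {xa.size} vs {ya.size}")
    n = xa.size
    if n < 2:
        raise InputError("need at least 2 points")
    xc = xa - xa.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise InputError("x is constant; slope undefined")
    slope = float(xc @ (ya - ya.mean()) / sxx)
    intercept = float(ya.mean() - slope * xa.mean())
    resid = ya - (slope * xa + intercept)
    rss = float(resid @ resid)
    if n > 2:
        slope_se = math.sqrt(rss / (n - 2) / sxx)
    else:
        slope_se = math.nan
    return slope, intercept, rss, slope_se


def _rss_line(x: np.ndarray, y: np.ndarray) -> float:
    slope, intercept, rss, _ = ols_line(x, y)
    return rss


def _rss_common_slope(
    xa: np.ndarray, ya: np.ndarray, xb: np.ndarray, yb: np.ndarray
) -> float:
    # ANCOVA pooled within-group slope: separate intercepts, one slope.
    xca = xa - xa.mean()
    xcb = xb - xb.mean()
    sxx = float(xca @ xca + xcb @ xcb)
    sxy = float(xca @ (ya - ya.mean()) + xcb @ (yb - yb.mean()))
    slope = sxy / sxx
    ra = ya - ya.mean() - slope * xca
    rb = yb - yb.mean() - slope * xcb
    return float(ra @ ra + rb @ rb)


def ancova_compare(
    group_a: tuple[Sequence[float], Sequence[float]],
    group_b: tuple[Sequence[float], Sequence[float]],
) -> AncovaResult:
    """Compare two regression lines by nested F tests (ANCOVA).

    Fits three nested models — separate lines, common slope with
    separate intercepts (elevations), single line — and tests slope
    homogeneity then elevation equality:

        F_slope = (RSS_common − RSS_separate) / (RSS_separate/(N−4))
        F_elev  = (RSS_single − RSS_common)   / (RSS_common/(N−3))
    """
    xa = _as_float_array(group_a[0], "x_A")
    ya = _as_float_array(group_a[1], "y_A")
    xb = _as_float_array(group_b[0], "x_B")
    yb = _as_float_array(group_b[1], "y_B")
    if xa.size != ya.size or xb.size != yb.size:
        raise InputError("x/y length mismatch within a group")
    if xa.size < 3 or xb.size < 3:
        raise InputError("each group needs at least 3 points")
    n = xa.size + xb.size
    if n - 4 < 1:
        raise InputError("combined residual df < 1")

    slope_a, _, rss_a, _ = ols_line(xa, ya)
    slope_b, _, rss_b, _ = ols_line(xb, yb)
    rss_sep = rss_a + rss_b
    rss_common = _rss_common_slope(xa, ya, xb, yb)
    rss_single = _rss_line(np.concatenate([xa, xb]), np.concatenate([ya, yb]))

    if rss_sep <= 0.0:
        raise DegenerateFitError("zero residual variance under separate-lines model")

    df_slope = (1, n - 4)
    f_slope = max(0.0, rss_common - rss_sep) / (rss_sep / (n - 4))
    p_slope = float(sps.f.sf(f_slope, *df_slope))

    df_elev = (1, n - 3)
    f_elev = max(0.0, rss_single - rss_common) / (rss_common / (n - 3))
    p_elev = float(sps.f.sf(f_elev, *df_elev))

    return AncovaResult(
        slope_A=slope_a,
        slope_B=slope_b,
        F_slope=f_slope,
        p_slope=p_slope,
        df_slope=df_slope,
        F_elev=f_elev,
        p_elev=p_elev,
        df_elev=df_elev,
    )


# ---------------------------------------------------------------------------
# two-group and multiple testing


def welch_test(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Welch's unequal-variance t test, two-sided.

    Returns (t, Welch–Satterthwaite df, p). Degenerate zero-variance
    cases are resolved by convention: equal means → (0, nan, 1);
    different means → (±inf, nan, 0).
    """
    xa = _as_float_array(x, "x")
    ya = _as_float_array(y, "y")
    if xa.size < 2 or ya.size < 2:
        raise InputError("each group needs at least 2 observations")
    vx = float(xa.var(ddof=1))
    vy = float(ya.var(ddof=1))
    dm = float(xa.mean() - ya.mean())
    if vx == 0.0 and vy == 0.0:
        if dm == 0.0:
            return 0.0, math.nan, 1.0
        return math.copysign(math.inf, dm), math.nan, 0.0
    sx2 = vx / xa.size
    sy2 = vy / ya.size
    t = dm / math.sqrt(sx2 + sy2)
    df = (sx2 + sy2) ** 2 / (
        sx2**2 / (xa.size - 1) + sy2**2 / (ya.size - 1)
    )
    p = float(2.0 * sps.t.sf(abs(t), df))
    return float(t), float(df), p


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j ≥ i} m·p_(j)/j, clipped to 1; monotone in p and
    idempotent on its own output.
    """
    pa = _as_float_array(p, "p")
    if pa.size == 0:
        return pa.copy()
    if np.any(pa < 0.0) or np.any(pa > 1.0):
        raise InputError("p-values must lie in [0, 1]")
    m = pa.size
    order = np.argsort(pa, kind="stable")
    ranked = pa[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bonferroni(p: float | Sequence[float], m: int) -> float | np.ndarray:
    """Bonferroni adjustment p' = min(1, m·p)."""
    if m < 1:
        raise InputError("m must be >= 1")
    if np.isscalar(p):
        if not 0.0 <= float(p) <= 1.0:  # type: ignore[arg-type]
            raise InputError("p must lie in [0, 1]")
        return min(1.0, m * float(p))  # type: ignore[arg-type]
    pa = _as_float_array(p, "p")
    if np.any(pa < 0.0) or np.any(pa > 1.0):
        raise InputError("p-values must lie in [0, 1]")
    return np.minimum(1.0, m * pa)


# ---------------------------------------------------------------------------
# factorial ANOVA and post-hoc tests


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
) -> AnovaTable:
    """Two-way ANOVA with interaction, type-II sums of squares.

    Handles unbalanced layouts; empty cells in the A×B grid raise
    :class:`UnsupportedLayoutError`.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    va = _as_float_array(values, "values")
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (va.size == fa.size == fb.size):
        raise InputError("values and factor labels must have equal length")
    if np.unique(fa).size < 2 or np.unique(fb).size < 2:
        raise InputError("each factor needs at least 2 levels")
    counts = pd.crosstab(pd.Series(fa), pd.Series(fb))
    if (counts == 0).any().any():
        raise UnsupportedLayoutError("empty cells in the two-way layout")

    df = pd.DataFrame({"y": va, "A": fa.astype(str), "B": fb.astype(str)})
    if va.var() == 0.0:
        # All-equal response: every effect explains nothing.
        effects = ["A", "B", "A:B", "Residual"]
        n_a = df["A"].nunique()
        n_b = df["B"].nunique()
        dfs = [n_a - 1, n_b - 1, (n_a - 1) * (n_b - 1)]
        dfs.append(va.size - 1 - sum(dfs))
        table = pd.DataFrame(
            {
                "sum_sq": [0.0, 0.0, 0.0, 0.0],
                "df": dfs,
                "F": [0.0, 0.0, 0.0, np.nan],
                "p": [1.0, 1.0, 1.0, np.nan],
            },
            index=effects,
        )
        return AnovaTable(table=table)

    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    raw = sm.stats.anova_lm(model, typ=2)
    table = raw.rename(
        columns={"PR(>F)": "p"},
        index={"C(A)": "A", "C(B)": "B", "C(A):C(B)": "A:B"},
    )
    table["df"] = table["df"].astype(int)
    return AnovaTable(table=table[["sum_sq", "df", "F", "p"]])


def tukey_hsd(values: Sequence[float], groups: Sequence) -> pd.DataFrame:
    """Tukey–Kramer pairwise comparisons after a one-way layout.

    p-values come from the studentized-range distribution with k groups
    and the pooled residual df; unequal group sizes use the Kramer
    harmonic form.
    """
    va = _as_float_array(values, "values")
    ga = np.asarray(groups)
    if va.size != ga.size:
        raise InputError("values and group labels must have equal length")
    levels = sorted(pd.unique(ga).tolist())
    k = len(levels)
    if k < 2:
        raise InputError("need at least 2 groups")
    by = {lev: va[ga == lev] for lev in levels}
    ns = {lev: arr.size for lev, arr in by.items()}
    if min(ns.values()) < 2:
        raise InputError("each group needs at least 2 observations")
    df_resid = va.size - k
    mse = sum(float(((arr - arr.mean()) ** 2).sum()) for arr in by.values()) / df_resid
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            diff = float(by[a].mean() - by[b].mean())
            se = math.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            if se == 0.0:
                p = 1.0 if diff == 0.0 else 0.0
                q = math.inf if diff != 0.0 else 0.0
            else:
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, df_resid))
            rows.append(
                {"group1": a, "group2": b, "mean_diff": diff, "q_stat": q, "p_adj": p}
            )
    return pd.DataFrame(rows)
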