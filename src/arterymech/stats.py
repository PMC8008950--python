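"""Group summaries and the statistical comparisons used on myograph cohorts.

Curves are compared pointwise on a matched grid (pressure step or stretch
bin) by classic fixed-effects two-way ANOVA with interaction (factors:
group x grid point); pairs of scalar datasets (e.g. per-sample IVS) are
compared by two-tailed Mann-Whitney tests, exact by full enumeration at
small sample sizes; families of post-test p-values are adjusted by the
step-down Holm-Sidak procedure.  Significance stars: * P<0.05, ** P<0.01,
*** P<0.001.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

EXACT_MW_MAX_N = 16


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class EffectResult:
    """One ANOVA effect: F statistic, degrees of freedom, p-value."""

    f_stat: float
    df_num: float
    df_den: float
    p: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one statistical test."""

    test: str
    p: float
    statistic: float | None = None
    effects: dict[str, EffectResult] = field(default_factory=dict)
    adjusted_p: float | None = None
    note: str = ""

    @property
    def stars(self) -> str:
        return significance_stars(self.adjusted_p if self.adjusted_p is not None else self.p)


def summarize_group_curves(
    curves: pd.DataFrame,
    dispersion: str = "se",
    group_col: str = "group",
    x_col: str = "x",
    y_col: str = "y",
) -> pd.DataFrame:
    """Pointwise group mean and dispersion of per-sample curves.

    ``curves`` is tidy: one row per (sample, grid point) with a group
    label.  Returns one row per (group, x) with mean, sd, se, n, the
    chosen dispersion, and a flag for points with n < 2 (dispersion
    undefined there).
    """
    if dispersion not in ("se", "sd"):
        raise ValueError("dispersion must be 'se' or 'sd'")
    if curves.empty:
        raise ValueError("no curves to summarize")
    g = curves.groupby([group_col, x_col])[y_col]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out["dispersion"] = out[dispersion]
    out["n_lt_2"] = out["n"] < 2
    return out


def two_way_anova_curves(
    data: pd.DataFrame,
    group_col: str = "group",
    x_col: str = "x",
    y_col: str = "y",
) -> ComparisonResult:
    """Fixed-effects two-factor ANOVA with interaction on pointwise responses.

    Each pressure-matched (or stretch-matched) point of each sample's
    curve is one observation; factors are the group and the grid point.
    Repeated points within a sample are treated as independent
    observations of the second factor, matching the curve-wise two-way
    ANOVA convention of myography studies (no subject random effect; see
    the methods note for the limitation this implies).

    Raises
    ------
    ValueError
        If any group x point cell is empty (naming the cell), or a factor
        has < 2 levels.
    """
    df = data[[group_col, x_col, y_col]].copy()
    df.columns = ["g", "x", "y"]
    df["g"] = df["g"].astype(str)
    df["x"] = df["x"].astype(str)
    if df["g"].nunique() < 2 or df["x"].nunique() < 2:
        raise ValueError("both factors need >= 2 levels")
    counts = df.groupby(["g", "x"], sort=True).size()
    full = pd.MultiIndex.from_product([df["g"].unique(), df["x"].unique()])
    missing = full.difference(counts.index)
    if len(missing) > 0:
        raise ValueError(f"empty cell(s) in group x point layout: {list(missing)[:5]}")
    model = ols("y ~ C(g) * C(x)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    df_den = float(table.loc["Residual", "df"])
    effects = {}
    for row, name in (("C(g)", "group"), ("C(x)", "point"), ("C(g):C(x)", "interaction")):
        effects[name] = EffectResult(
            f_stat=float(table.loc[row, "F"]),
            df_num=float(table.loc[row, "df"]),
            df_den=df_den,
            p=float(table.loc[row, "PR(>F)"]),
        )
    grp = effects["group"]
    return ComparisonResult(
        test="two-way ANOVA",
        p=grp.p,
        statistic=grp.f_stat,
        effects=effects,
    )


def _exact_mw_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-tailed exact Mann-Whitney p by full enumeration of rank splits.

    Mid-ranks handle ties; the two-tailed p is the null probability of a
    U at least as far from its mean m*n/2 as the observed one (capped at
    1 by construction).
    """
    m, n = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    mu = m * n / 2.0
    dev = abs(u_obs - mu) - 1e-12  # tolerate float fuzz in midrank sums
    hits = 0
    for idx in combinations(range(m + n), m):
        u = ranks[list(idx)].sum() - m * (m + 1) / 2.0
        if abs(u - mu) >= dev:
            hits += 1
    return hits / comb(m + n, m)


def mann_whitney(x, y, mode: str = "auto") -> ComparisonResult:
    """Two-tailed Mann-Whitney U test.

    mode="exact": full enumeration of all C(m+n, m) rank splits (mid-ranks
    for ties), feasible for m+n <= 16.  mode="approx": normal
    approximation with tie and continuity corrections.  mode="auto" picks
    exact when m+n <= 16 (with a log note when ties force mid-ranks),
    approximate otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if x.size + y.size <= EXACT_MW_MAX_N else "approx"
        if mode == "exact" and has_ties:
            log.info("mann_whitney: ties present; exact enumeration uses mid-ranks")
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)
    if mode == "exact":
        if x.size + y.size > EXACT_MW_MAX_N:
            raise ValueError(f"exact enumeration limited to m+n <= {EXACT_MW_MAX_N}")
        p = _exact_mw_p(x, y, u_obs)
        note = "exact enumeration" + (", mid-ranks for ties" if has_ties else "")
    elif mode == "approx":
        _, p = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(min(p, 1.0))
        note = "normal approximation with tie/continuity correction"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ComparisonResult(test="Mann-Whitney", p=p, statistic=u_obs, note=note)


def holm_sidak(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Step-down Holm-Sidak adjusted p-values, in the input order.

    Sorted ascending, p_(i) -> 1 - (1 - p_(i))^(m - i) for i = 0..m-1,
    then enforced monotone nondecreasing and mapped back.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, alpha=alpha, method="holm-sidak")
    return adjusted
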