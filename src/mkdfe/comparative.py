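"""Comparative statistics across species and taxonomic groups.

OLS regressions of adaptive-rate estimates on (log-transformed) diversity
and life-history traits, Spearman rank tests, within-group ANCOVA (parallel
lines, one per group: common-slope, intercept and interaction tests), and
the meta-analysis correlating per-group slopes with group mean diversity.
Missing values are dropped listwise per test; no multiple-testing
correction is applied.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm


@dataclass(frozen=True)
class OLSResult:
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


@dataclass(frozen=True)
class AncovaResult:
    common_slope: float
    p_slope: float
    p_intercepts: float
    p_interaction: float
    n: int
    n_groups: int


def _clean_xy(x, y, log10_x=False):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if log10_x:
        if np.any(x <= 0):
            raise ValueError("log10 transform requires positive x")
        x = np.log10(x)
    return x, y


def ols_regression(x, y, log10_x: bool = False) -> OLSResult:
    """Simple OLS of y on x with a two-sided t-test on the slope."""
    x, y = _clean_xy(x, y, log10_x)
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return OLSResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        n=len(x),
    )


def _exact_spearman_p(rho_obs: float, xr: np.ndarray, yr: np.ndarray) -> float:
    """Two-sided exact permutation p-value of |rho| >= |rho_obs| (small n)."""
    n = len(xr)
    yc = yr - yr.mean()
    xc = xr - xr.mean()
    denom = math.sqrt((xc**2).sum() * (yc**2).sum())
    count = total = 0
    target = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        rho = float((xc[list(perm)] * yc).sum() / denom)
        total += 1
        if abs(rho) >= target:
            count += 1
    return count / total


def spearman_test(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rank correlation with tie-corrected ranks.

    p-value via the t approximation, or exact permutation enumeration for
    n <= ``exact_max_n``.  Returns (nan, nan) for constant input.
    """
    x, y = _clean_xy(x, y)
    if len(x) < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    rho, p = stats.spearmanr(x, y)
    if len(x) <= exact_max_n:
        xr = stats.rankdata(x)
        yr = stats.rankdata(y)
        p = _exact_spearman_p(float(rho), xr, yr)
    return float(rho), float(p)


def ancova(
    table: pd.DataFrame,
    response: str,
    covariate: str,
    group_col: str = "group",
    log10_cov: bool = False,
) -> AncovaResult:
    """Parallel-lines ANCOVA of ``response`` on ``covariate`` across groups.

    Fits the additive model response ~ covariate + C(group); reports the
    common slope and its two-sided p-value, an F-test of the group factor
    (distinct intercepts) against the covariate-only model, and an F-test of
    the covariate x group interaction added to the additive model.
    """
    df = table[[response, covariate, group_col]].dropna().copy()
    df.columns = ["y", "x", "g"]
    if log10_cov:
        if (df["x"] <= 0).any():
            raise ValueError("log10 transform requires positive covariate")
        df["x"] = np.log10(df["x"])
    sizes = df.groupby("g").size()
    small = sizes[sizes < 2]
    if len(sizes) >= 2 and len(small):
        raise ValueError(f"groups with < 2 species: {list(small.index)}")
    if df["x"].nunique() < 2:
        raise ValueError("covariate has zero variance")
    if df["g"].nunique() == 1:
        res = ols_regression(df["x"], df["y"])
        return AncovaResult(res.slope, res.p_value, float("nan"), float("nan"), res.n, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m_cov = smf.ols("y ~ x", df).fit()
        m_add = smf.ols("y ~ x + C(g)", df).fit()
        m_int = smf.ols("y ~ x + C(g) + x:C(g)", df).fit()
        p_intercepts = float(anova_lm(m_cov, m_add).iloc[1]["Pr(>F)"])
        p_interaction = float(anova_lm(m_add, m_int).iloc[1]["Pr(>F)"])
    return AncovaResult(
        common_slope=float(m_add.params["x"]),
        p_slope=float(m_add.pvalues["x"]),
        p_intercepts=p_intercepts,
        p_interaction=p_interaction,
        n=len(df),
        n_groups=int(df["g"].nunique()),
    )


def slopes_vs_group_pi(
    table: pd.DataFrame,
    response: str = "omega_a",
    covariate: str = "pi_s",
    group_col: str = "group",
    min_species: int = 3,
) -> tuple[pd.DataFrame, float, float]:
    """Per-group OLS slopes of response on covariate vs group mean covariate.

    Groups with fewer than ``min_species`` complete species are flagged and
    excluded from the Spearman meta-correlation.  Returns (per-group frame
    with columns group/slope/group_pi/n/used, rho, p).
    """
    rows = []
    for g, sub in table.groupby(group_col):
        sub = sub[[response, covariate]].dropna()
        mean_pi = float(sub[covariate].mean()) if len(sub) else float("nan")
        if len(sub) < min_species:
            rows.append({"group": g, "slope": float("nan"), "group_pi": mean_pi,
                         "n": len(sub), "used": False})
            continue
        res = ols_regression(sub[covariate], sub[response])
        rows.append({"group": g, "slope": res.slope, "group_pi": mean_pi,
                     "n": len(sub), "used": True})
    frame = pd.DataFrame(rows)
    used = frame[frame["used"]]
    if len(used) < 4:
        raise ValueError("need at least 4 groups with enough species")
    rho, p = spearman_test(used["slope"], used["group_pi"])
    return frame, rho, p


def regression_suite(
    table: pd.DataFrame,
    response: str = "omega_a",
    covariates=("pi_s", "longevity", "fecundity", "propagule_size", "adult_size", "body_mass"),
    log10: bool = True,
) -> pd.DataFrame:
    """OLS of a response against each covariate (log10-transformed traits)."""
    rows = []
    for cov in covariates:
        if cov not in table.columns:
            continue
        sub = table[[response, cov]].dropna()
        try:
            res = ols_regression(sub[cov], sub[response], log10_x=log10)
        except ValueError:
            continue
        rows.append({"covariate": cov, "slope": res.slope, "r2": res.r2,
                     "p_value": res.p_value, "n": res.n})
    return pd.DataFrame(rows)
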