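"""Choice summaries and age-trend statistics.

Developmental analyses regress a subject-level outcome (risky-choice
proportion, asymmetry index, learning rates) on z-scored age, compare the
linear model against linear + quadratic with a nested F test, and report
Cohen's f-squared with noncentral-F confidence intervals. A significant
quadratic term is certified as u-shaped with the two-lines approach:
separate linear segments on either side of a breakpoint must both be
significant with opposite signs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import sessions, task

__all__ = [
    "risky_choice_proportion",
    "AgeRegressionResult",
    "quadratic_age_regression",
    "TwoLinesResult",
    "two_lines_test",
    "cohens_f2_ci",
]


def risky_choice_proportion(session: sessions.Session, pair_filter: str = "equal_ev") -> float:
    """Proportion of risky trials where the probabilistic machine was chosen.

    pair_filter selects equal-EV risky trials, unequal-EV risky trials, or
    both; missed trials are excluded.
    """
    wanted = {
        "equal_ev": {"risky_equal"},
        "unequal_ev": {"risky_unequal"},
        "all": {"risky_equal", "risky_unequal"},
    }.get(pair_filter)
    if wanted is None:
        raise ValueError(f"unknown pair_filter {pair_filter!r}")
    probabilistic = {"P40", "P80"}
    picked = total = 0
    for spec, rec in zip(session.sequence, session.records):
        if spec.trial_type not in wanted or rec.missed:
            continue
        total += 1
        picked += rec.chosen in probabilistic
    if total == 0:
        raise ValueError("no risky trials matched the filter")
    return picked / total


def cohens_f2_ci(f2: float, df_num: int, df_den: int, level: float = 0.95) -> tuple[float, float]:
    """CI for Cohen's f2 by inverting the noncentral-F distribution.

    The observed F is df_den/df_num * f2; the CI bounds are the
    noncentralities under which that F sits at the outer quantiles,
    rescaled back to the f2 scale (lambda / (df_num + df_den + 1)).
    """
    f_obs = f2 * df_den / df_num
    alpha = 1.0 - level
    n_eff = df_num + df_den + 1

    def coverage(nc: float, q: float) -> float:
        return stats.ncf.cdf(f_obs, df_num, df_den, nc) - q

    def solve(q: float) -> float:
        if coverage(0.0, q) <= 0.0:
            return 0.0
        hi = 10.0
        while coverage(hi, q) > 0.0 and hi < 1e6:
            hi *= 2.0
        from scipy.optimize import brentq

        return float(brentq(lambda nc: coverage(nc, q), 0.0, hi))

    lo = solve(1.0 - alpha / 2.0) / n_eff
    hi = solve(alpha / 2.0) / n_eff
    return (lo, hi)


@dataclass
class AgeRegressionResult:
    """Linear vs linear+quadratic age fits with the nested-model F test."""

    linear: pd.DataFrame  # term, estimate, t, p, f2, f2_ci_low, f2_ci_high
    quadratic: pd.DataFrame
    f_stat: float
    f_df: tuple[int, int]
    f_p: float
    preferred: str  # "linear" | "quadratic"
    n: int

    def quadratic_term(self) -> pd.Series:
        return self.quadratic[self.quadratic["term"] == "age_z2"].iloc[0]


def _term_table(fit, reduced_r2_by_term: dict[str, float]) -> pd.DataFrame:
    rows = []
    n = int(fit.nobs)
    k_full = len(fit.params)
    df_den = n - k_full
    for term in fit.params.index:
        f2 = math.nan
        ci = (math.nan, math.nan)
        if term in reduced_r2_by_term:
            r2_red = reduced_r2_by_term[term]
            denom = 1.0 - fit.rsquared
            f2 = max((fit.rsquared - r2_red) / denom, 0.0) if denom > 0 else math.inf
            if math.isfinite(f2):
                ci = cohens_f2_ci(f2, 1, df_den)
        rows.append(
            {
                "term": term,
                "estimate": fit.params[term],
                "t": fit.tvalues[term],
                "p": fit.pvalues[term],
                "f2": f2,
                "f2_ci_low": ci[0],
                "f2_ci_high": ci[1],
            }
        )
    return pd.DataFrame(rows)


def quadratic_age_regression(age: np.ndarray, y: np.ndarray) -> AgeRegressionResult:
    """Fit y ~ z(age) and y ~ z(age) + z(age)^2; arbitrate with a nested F.

    The quadratic model is preferred only when the F test is significant at
    0.05. Effect sizes are Cohen's f2 per term (change in R2 against the
    model dropping that term) with noncentral-F CIs.
    """
    age = np.asarray(age, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(age) != len(y):
        raise ValueError("age and outcome lengths differ")
    if len(y) < 10:
        raise ValueError("need at least 10 observations")
    if np.std(y) == 0.0:
        raise ValueError("constant outcome")
    age_z = (age - age.mean()) / age.std(ddof=0)
    data = pd.DataFrame({"y": y, "age_z": age_z, "age_z2": age_z**2})

    lin = sm.OLS(data["y"], sm.add_constant(data[["age_z"]])).fit()
    quad = sm.OLS(data["y"], sm.add_constant(data[["age_z", "age_z2"]])).fit()
    null = sm.OLS(data["y"], np.ones((len(y), 1))).fit()

    n = len(y)
    rss_red, rss_full = lin.ssr, quad.ssr
    df_den = n - 3
    f_stat = ((rss_red - rss_full) / 1.0) / (rss_full / df_den)
    f_p = float(stats.f.sf(f_stat, 1, df_den))

    lin_table = _term_table(lin, {"age_z": null.rsquared})
    quad_no_lin = sm.OLS(data["y"], sm.add_constant(data[["age_z2"]])).fit()
    quad_table = _term_table(
        quad, {"age_z": quad_no_lin.rsquared, "age_z2": lin.rsquared}
    )
    return AgeRegressionResult(
        linear=lin_table,
        quadratic=quad_table,
        f_stat=float(f_stat),
        f_df=(1, df_den),
        f_p=f_p,
        preferred="quadratic" if f_p < 0.05 else "linear",
        n=n,
    )


@dataclass
class TwoLinesResult:
    breakpoint: float
    left_slope: float
    left_z: float
    left_p: float
    right_slope: float
    right_z: float
    right_p: float
    u_shaped: bool  # both segments significant with opposite signs


def _segment_fit(x: np.ndarray, y: np.ndarray, robust: bool) -> tuple[float, float, float]:
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit(cov_type="HC3" if robust else "nonrobust")
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    if se == 0.0:
        z = math.inf if slope != 0 else 0.0
        p = 0.0 if slope != 0 else 1.0
    else:
        z = slope / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    return slope, z, p


def two_lines_test(
    x: np.ndarray,
    y: np.ndarray,
    breakpoint: float | str = "grid",
    robust: bool = True,
) -> TwoLinesResult:
    """Segmented regression on either side of a breakpoint.

    A u-shape (in either orientation) is certified only when both segment
    slopes are individually significant (two-sided, robust SEs by default)
    with opposite signs. ``breakpoint="grid"`` searches interior x values
    for the split maximizing summed segment R2; the breakpoint observation
    is included in the left segment.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if breakpoint == "grid":
        candidates = np.unique(x)[1:-1]
        best_bp, best_score = None, -math.inf
        for bp in candidates:
            left, right = x <= bp, x > bp
            if left.sum() < 5 or right.sum() < 5:
                continue
            score = 0.0
            for mask in (left, right):
                fit = sm.OLS(y[mask], sm.add_constant(x[mask])).fit()
                score += fit.rsquared
            if score > best_score:
                best_bp, best_score = float(bp), score
        if best_bp is None:
            raise ValueError("no breakpoint leaves >= 5 points on each side")
        breakpoint = best_bp
    left, right = x <= breakpoint, x > breakpoint
    if left.sum() < 5 or right.sum() < 5:
        raise ValueError("need at least 5 points on each side of the breakpoint")
    ls, lz, lp = _segment_fit(x[left], y[left], robust)
    rs, rz, rp = _segment_fit(x[right], y[right], robust)
    u_shaped = lp < 0.05 and rp < 0.05 and ls * rs < 0
    return TwoLinesResult(float(breakpoint), ls, lz, lp, rs, rz, rp, u_shaped)
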