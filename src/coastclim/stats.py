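"""Comparative statistics: country-random-effect means, paired sector
differences, Cohen's D, and the wealth-impact mixed regression.

Communities are nested in countries, so every reported average is the fixed
intercept of a random-intercept-by-country linear mixed model rather than a
raw mean.  Denominator degrees of freedom use a Satterthwaite-style
two-component approximation: the intercept variance splits into a
between-country share (with k - 1 df) and a residual share (with N - k df),
and the usual Welch-Satterthwaite combination gives a fractional df that
approaches k - 1 when countries dominate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)


@dataclass
class ComparisonResult:
    estimate: float
    se: float
    t: float
    df: float
    p: float
    tau2: float
    sigma2: float
    n: int
    n_groups: int
    method: str = "mixed"


def _satterthwaite_df(tau2: float, sigma2: float, k: int, n: int) -> float:
    """Fractional df for the intercept of a random-intercept model.

    Var(intercept) ~ tau2/k + sigma2/N in the balanced case; the two
    components carry k-1 and N-k df respectively.
    """
    if k <= 1:
        return max(n - 1, 1)
    a = tau2 / k
    b = sigma2 / max(n, 1)
    denom = 0.0
    if a > 0:
        denom += a**2 / (k - 1)
    if b > 0 and n > k:
        denom += b**2 / (n - k)
    if denom == 0:
        return float(k - 1)
    return float((a + b) ** 2 / denom)


def mixed_mean(values: pd.Series | np.ndarray, groups: pd.Series | np.ndarray,
               ) -> ComparisonResult:
    """Population mean of community values with a country random intercept.

    Returns the fixed-intercept estimate, its SE, and a one-sample test of
    the intercept against zero.  A singular or non-converging fit falls
    back to the mean of country means with a warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups differ in length")
    uniq = pd.unique(groups)
    k, n = len(uniq), len(values)
    if k < 2:
        raise ValueError("need at least 2 countries for a random effect")
    if np.allclose(values, values[0]):
        return ComparisonResult(
            estimate=float(values[0]), se=0.0, t=np.inf if values[0] != 0 else 0.0,
            df=float(k - 1), p=0.0 if values[0] != 0 else 1.0,
            tau2=0.0, sigma2=0.0, n=n, n_groups=k,
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(values, np.ones((n, 1)), groups=groups)
            fit = model.fit(reml=True)
        est = float(fit.params[0])
        se = float(fit.bse[0])
        tau2 = float(np.asarray(fit.cov_re)[0, 0])
        sigma2 = float(fit.scale)
        if not np.isfinite(se) or se <= 0:
            raise ValueError("degenerate SE from mixed fit")
        method = "mixed"
    except Exception as exc:  # singular fit
        logger.warning("mixed fit failed (%s); using country-mean fallback", exc)
        gm = pd.Series(values).groupby(pd.Series(groups)).mean()
        est = float(gm.mean())
        se = float(gm.std(ddof=1) / np.sqrt(k))
        tau2 = float(gm.var(ddof=1))
        sigma2 = float(
            pd.Series(values).groupby(pd.Series(groups)).var(ddof=1).mean()
        )
        method = "country-means"
    df = _satterthwaite_df(tau2, sigma2, k, n)
    t = est / se if se > 0 else np.inf
    p = float(2 * sps.t.sf(abs(t), df))
    return ComparisonResult(est, se, float(t), df, p, tau2, sigma2, n, k, method)


def paired_sector_difference(
    e_f: pd.Series | np.ndarray,
    e_a: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
) -> ComparisonResult:
    """Paired comparison of sector exposures per community.

    The response is the per-community difference (fisheries minus
    agriculture), keeping the pairing while the country random effect
    absorbs between-country scatter.
    """
    diff = np.asarray(e_f, dtype=float) - np.asarray(e_a, dtype=float)
    return mixed_mean(diff, groups)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardised mean difference (mean_a - mean_b) / pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = len(a), len(b)
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled <= 0:
        raise ValueError("pooled standard deviation is zero")
    return float((a.mean() - b.mean()) / np.sqrt(pooled))


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    se_boot: float
    t: float
    p: float
    marginal_r2: float
    conditional_r2: float
    n_boot: int
    slope_model_se: float


def _fit_slope(df: pd.DataFrame):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("y ~ x", df, groups=df["g"])
        fit = model.fit(reml=True)
    return fit


def _nakagawa_r2(fit, df: pd.DataFrame) -> tuple[float, float]:
    """Marginal and conditional R2 by the variance-decomposition formulas."""
    fixed = fit.params["Intercept"] + fit.params["x"] * df["x"]
    var_f = float(np.var(fixed, ddof=0))
    tau2 = float(np.asarray(fit.cov_re)[0, 0])
    sigma2 = float(fit.scale)
    total = var_f + tau2 + sigma2
    return var_f / total, (var_f + tau2) / total


def mixed_regression(
    x: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> RegressionResult:
    """Random-intercept regression of y on x with bootstrap slope SE.

    The nonparametric bootstrap resamples communities within country
    (stratified), refitting the model per replicate; resamples that end up
    with a single country are redrawn.  p is a normal-approximation test of
    the slope against zero using the bootstrap SE.
    """
    df = pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float),
                       "g": np.asarray(groups)})
    if df["g"].nunique() < 2:
        raise ValueError("need at least 2 countries")
    if len(df) < 10:
        raise ValueError("need at least 10 communities")
    fit = _fit_slope(df)
    slope = float(fit.params["x"])
    intercept = float(fit.params["Intercept"])
    marg, cond = _nakagawa_r2(fit, df)
    rng = np.random.default_rng(seed)
    groups_list = [g.reset_index(drop=True) for _, g in df.groupby("g")]
    slopes = np.empty(n_boot)
    b = 0
    attempts = 0
    while b < n_boot:
        attempts += 1
        if attempts > 50 * n_boot:
            raise RuntimeError("bootstrap failed to produce valid resamples")
        parts = []
        for g in groups_list:
            idx = rng.integers(0, len(g), size=len(g))
            parts.append(g.iloc[idx])
        boot = pd.concat(parts, ignore_index=True)
        if boot["g"].nunique() < 2 or boot["x"].nunique() < 2:
            continue
        try:
            bf = _fit_slope(boot)
        except Exception:
            continue
        s = float(bf.params["x"])
        if not np.isfinite(s):
            continue
        slopes[b] = s
        b += 1
    se_boot = float(slopes.std(ddof=1))
    t = slope / se_boot if se_boot > 0 else np.inf
    p = float(2 * sps.norm.sf(abs(t)))
    return RegressionResult(
        slope=slope, intercept=intercept, se_boot=se_boot, t=float(t), p=p,
        marginal_r2=marg, conditional_r2=cond, n_boot=n_boot,
        slope_model_se=float(fit.bse["x"]),
    )
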