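"""Dose-response fitting and comparison across radiation qualities.

Two response shapes cover the endpoints handled here:

* foci induction is linear in dose, ``y = intercept + slope * D``; the
  quality comparison is a t-test on the difference of fitted slopes;
* relative gene expression (fold change) rises to a plateau,
  ``y(D) = P - (P - 1) * exp(-k * D)``, anchored at ``y(0) = 1``
  because the fold change of the unirradiated control is 1 by
  definition.  Curve families are compared with an
  extra-sum-of-squares F-test (pooled vs per-group parameters).

Fit observations are per-dose group means, weighted by ``1/SE**2`` when
standard errors are supplied, matching how mean +/- SD dose-response
data are usually presented and fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "LinearFit",
    "PlateauFit",
    "SlopeComparison",
    "FComparison",
    "TTestResult",
    "FitError",
    "fit_linear",
    "compare_slopes",
    "fit_plateau",
    "compare_plateau_fits",
    "compare_groups",
    "two_way_anova",
]


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries diagnostics."""


@dataclass
class LinearFit:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    df_resid: int
    cov: np.ndarray
    n_points: int

    def predict(self, dose):
        return self.intercept + self.slope * np.asarray(dose, dtype=float)


@dataclass
class PlateauFit:
    """Saturating-exponential fit ``y = P - (P - 1) exp(-k D)``."""

    plateau: float
    rate: float
    plateau_se: float
    rate_se: float
    df_resid: int
    rss: float
    n_points: int
    rate_unidentifiable: bool = False

    def predict(self, dose):
        d = np.asarray(dose, dtype=float)
        return self.plateau - (self.plateau - 1.0) * np.exp(-self.rate * d)


@dataclass
class SlopeComparison:
    t: float
    df: float
    p: float
    slope_diff: float


@dataclass
class FComparison:
    f: float
    df_num: int
    df_den: int
    p: float
    rss_pooled: float
    rss_separate: float


@dataclass
class TTestResult:
    statistic: float
    df: float
    p: float
    mean_diff: float


def _series_arrays(series: pd.DataFrame):
    d = series["dose_gy"].to_numpy(dtype=float)
    y = series["response"].to_numpy(dtype=float)
    se = None
    if "se" in series.columns:
        s = series["se"].to_numpy(dtype=float)
        if np.all(np.isfinite(s)) and np.all(s > 0):
            se = s
    return d, y, se


def fit_linear(series: pd.DataFrame, through_origin: bool = False) -> LinearFit:
    """(Weighted) least-squares line through a dose-response series.

    ``series`` needs columns ``dose_gy, response`` and optionally
    ``se``; weights are ``1/se**2`` when every SE is finite and
    positive.  A free intercept is fitted by default even for
    background-subtracted data; ``through_origin=True`` forces the line
    through zero.
    """
    d, y, se = _series_arrays(series)
    if len(np.unique(d)) < 3:
        raise ValueError("need >= 3 distinct doses")
    if np.var(d) == 0:
        raise ValueError("zero dose variance")
    X = d[:, None] if through_origin else sm.add_constant(d)
    w = 1.0 / se**2 if se is not None else 1.0
    res = sm.WLS(y, X, weights=w).fit()
    if through_origin:
        slope, slope_se = float(res.params[0]), float(res.bse[0])
        intercept, intercept_se = 0.0, 0.0
        cov = np.zeros((2, 2))
        cov[1, 1] = res.cov_params().to_numpy()[0, 0] if hasattr(res.cov_params(), "to_numpy") \
            else np.asarray(res.cov_params())[0, 0]
    else:
        params = np.asarray(res.params)
        bse = np.asarray(res.bse)
        intercept, slope = float(params[0]), float(params[1])
        intercept_se, slope_se = float(bse[0]), float(bse[1])
        cov = np.asarray(res.cov_params())
    return LinearFit(
        slope=slope,
        intercept=intercept,
        slope_se=slope_se,
        intercept_se=intercept_se,
        df_resid=int(res.df_resid),
        cov=cov,
        n_points=int(len(y)),
    )


def compare_slopes(fit_a: LinearFit, fit_b: LinearFit) -> SlopeComparison:
    """Two-sided t-test on the difference of two fitted slopes.

    ``t = (slope_a - slope_b) / sqrt(se_a**2 + se_b**2)`` with
    Welch-Satterthwaite degrees of freedom built from the two slope
    variances and their residual dfs.  Antisymmetric in its arguments.
    """
    if fit_a.df_resid < 1 or fit_b.df_resid < 1:
        raise ValueError("both fits need residual df >= 1")
    va, vb = fit_a.slope_se**2, fit_b.slope_se**2
    if va + vb == 0:
        raise ValueError("zero combined slope SE")
    diff = fit_a.slope - fit_b.slope
    t = diff / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / fit_a.df_resid + vb**2 / fit_b.df_resid)
    p = 2.0 * stats.t.sf(abs(t), df)
    return SlopeComparison(t=float(t), df=float(df), p=float(p), slope_diff=float(diff))


def _plateau_model(d, plateau, rate):
    return plateau - (plateau - 1.0) * np.exp(-rate * d)


def fit_plateau(series: pd.DataFrame) -> PlateauFit:
    """Fit the saturating exponential ``y = P - (P - 1) exp(-k D)``.

    The curve is anchored at ``y(0) = 1`` by construction.  Starting
    values: P from the mean response at the largest dose, and a small
    grid of rates spanning the dose range; the best converged start
    wins.  A flat series at 1 leaves the rate unidentifiable and is
    returned as ``P = 1, k = 0`` with a flag rather than an error.
    """
    d, y, se = _series_arrays(series)
    if len(np.unique(d)) < 3 or 0.0 not in d:
        raise ValueError("need >= 3 distinct doses including 0 Gy")
    if np.ptp(y) < 1e-12 and abs(y.mean() - 1.0) < 1e-9:
        return PlateauFit(
            plateau=1.0, rate=0.0, plateau_se=0.0, rate_se=0.0,
            df_resid=len(y) - 2, rss=float(np.sum((y - 1.0) ** 2)),
            n_points=len(y), rate_unidentifiable=True,
        )
    dmax = d.max()
    p0_plateau = float(np.mean(y[d == dmax]))
    if abs(p0_plateau - 1.0) < 1e-9:
        p0_plateau = 1.0 + 0.1
    best = None
    errors = []
    for k0 in (0.5 / dmax, 2.0 / dmax, 8.0 / dmax):
        try:
            popt, pcov = curve_fit(
                _plateau_model, d, y, p0=(p0_plateau, k0),
                sigma=se, bounds=([-np.inf, 0.0], [np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:  # no convergence from this start
            errors.append(f"k0={k0:g}: {exc}")
            continue
        rss = float(np.sum((y - _plateau_model(d, *popt)) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise FitError(
            "plateau fit did not converge from any starting value: " + "; ".join(errors)
        )
    popt, pcov, rss = best
    ses = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return PlateauFit(
        plateau=float(popt[0]),
        rate=float(popt[1]),
        plateau_se=float(ses[0]),
        rate_se=float(ses[1]),
        df_resid=len(y) - 2,
        rss=rss,
        n_points=len(y),
    )


def compare_plateau_fits(series_a: pd.DataFrame, series_b: pd.DataFrame) -> FComparison:
    """Extra-sum-of-squares F-test: one shared curve vs one per group.

    The null model fits a single (P, k) pair to the pooled data; the
    alternative fits each group separately.  ``F = ((RSS_pooled -
    RSS_sep) / 2) / (RSS_sep / (n - 4))``.
    """
    pooled = pd.concat([series_a, series_b], ignore_index=True)
    # drop SEs for the pooled/separate comparison so both models minimise
    # the same unweighted RSS (nested by construction)
    cols = ["dose_gy", "response"]
    fp = fit_plateau(pooled[cols])
    fa = fit_plateau(series_a[cols])
    fb = fit_plateau(series_b[cols])
    rss_sep = fa.rss + fb.rss
    n = fp.n_points
    df_num, df_den = 2, n - 4
    if df_den < 1:
        raise ValueError("not enough points for the separate-fits model")
    # below numerical-noise floor both models fit perfectly: no evidence
    # against the shared curve
    noise_floor = 1e-12 * float(np.sum(pooled["response"].to_numpy() ** 2))
    if fp.rss <= noise_floor:
        f = 0.0
    elif rss_sep <= noise_floor:
        f = np.inf
    else:
        f = max((fp.rss - rss_sep) / df_num / (rss_sep / df_den), 0.0)
    p = float(stats.f.sf(f, df_num, df_den)) if np.isfinite(f) else 0.0
    return FComparison(
        f=float(f), df_num=df_num, df_den=df_den, p=p,
        rss_pooled=float(fp.rss), rss_separate=float(rss_sep),
    )


def compare_groups(samples_a, samples_b) -> TTestResult:
    """Unpaired two-tailed Welch t-test between two samples.

    Degenerate variances are handled by convention: identical constant
    samples give t = 0, p = 1; constant samples with different means
    give p = 0.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0 and vb == 0:
        if diff == 0:
            return TTestResult(0.0, float(len(a) + len(b) - 2), 1.0, 0.0)
        return TTestResult(np.inf if diff > 0 else -np.inf,
                           float(len(a) + len(b) - 2), 0.0, float(diff))
    t, p = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return TTestResult(float(t), float(df), float(p), float(diff))


def two_way_anova(
    data: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way ANOVA with interaction plus Tukey HSD on cell means.

    Returns the type-II ANOVA table and the Tukey multiple-comparison
    table over the crossed factor levels.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = data[[response, factor_a, factor_b]].copy()
    df.columns = ["y", "fa", "fb"]
    model = smf.ols("y ~ C(fa) * C(fb)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    cell = df["fa"].astype(str) + ":" + df["fb"].astype(str)
    tk = pairwise_tukeyhsd(df["y"], cell)
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=tk.summary().data[0]
    )
    return table, tukey
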