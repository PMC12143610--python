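"""Clonogenic survival: surviving fractions, linear-quadratic fit, RBE.

The linear-quadratic (LQ) model describes clonogenic cell killing as
``S(D) = exp(-alpha*D - beta*D**2)``.  Fitting is done in log space
(``ln SF`` is linear in ``D`` and ``D**2``) with both coefficients
constrained non-negative, the common radiobiology convention.  Relative
biological effectiveness (RBE) at an iso-survival level is the ratio of
the reference-radiation dose to the test-radiation dose producing that
survival, here computed from the fitted curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "LQFit",
    "surviving_fractions",
    "fit_lq",
    "dose_at_survival",
    "rbe",
]


@dataclass
class LQFit:
    """Fitted LQ parameters; alpha in 1/Gy, beta in 1/Gy^2."""

    alpha: float
    beta: float
    alpha_se: float
    beta_se: float
    cov: np.ndarray
    df_resid: int
    n_points: int
    excluded_rows: int = 0

    def survival(self, dose):
        d = np.asarray(dose, dtype=float)
        return np.exp(-(self.alpha * d + self.beta * d * d))


def surviving_fractions(data: pd.DataFrame) -> pd.DataFrame:
    """Per-dose surviving fractions from colony counts.

    Plating efficiency is computed per replicate (each replicate is an
    experiment with its own 0 Gy flask) and each replicate's dose series
    normalised to its own PE before pooling, so inter-experiment
    plating variation cancels.  Input columns: ``dose_gy, quality,
    replicate, cells_seeded, colonies``.  Output: one row per
    (quality, dose) with ``sf_mean, sf_se, n``.
    """
    required = {"dose_gy", "quality", "replicate", "cells_seeded", "colonies"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing survival columns: {sorted(missing)}")
    rows = []
    for (quality, rep), sub in data.groupby(["quality", "replicate"]):
        zero = sub[sub["dose_gy"] == 0.0]
        if zero.empty:
            raise ValueError(f"no 0 Gy rows for quality {quality!r} replicate {rep}")
        pe = float((zero["colonies"] / zero["cells_seeded"]).mean())
        if pe <= 0:
            raise ValueError(f"plating efficiency is 0 for quality {quality!r} replicate {rep}")
        for _, r in sub.iterrows():
            rows.append(
                dict(
                    quality=quality,
                    replicate=rep,
                    dose_gy=float(r["dose_gy"]),
                    sf=(r["colonies"] / r["cells_seeded"]) / pe,
                )
            )
    per_rep = pd.DataFrame(rows)
    g = per_rep.groupby(["quality", "dose_gy"])["sf"]
    out = g.agg(sf_mean="mean", sf_sd="std", n="size").reset_index()
    out["sf_sd"] = out["sf_sd"].fillna(0.0)
    out["sf_se"] = out["sf_sd"] / np.sqrt(out["n"])
    return out


def fit_lq(sf: pd.DataFrame) -> LQFit:
    """Constrained least squares of ``ln SF = -(alpha*D + beta*D**2)``.

    Expects the per-dose summary from :func:`surviving_fractions` (or
    any frame with ``dose_gy, sf_mean`` and optionally ``sf_se``).
    The 0 Gy point (SF = 1 by construction) carries no information and
    is dropped; non-positive SF values cannot enter the log and are
    excluded with a warning.  Weights are ``1/SE(ln SF)**2`` when SEs
    are available and positive.  alpha and beta are constrained >= 0
    via non-negative least squares; when a parameter sits on the
    boundary its SE is reported from the unconstrained covariance and
    should be read with care.
    """
    sub = sf[sf["dose_gy"] > 0].copy()
    bad = sub["sf_mean"] <= 0
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} non-positive surviving fractions from log-space fit"
        )
        sub = sub[~bad]
    if sub["dose_gy"].nunique() < 3:
        raise ValueError("need >= 3 distinct positive doses with SF > 0")

    d = sub["dose_gy"].to_numpy(dtype=float)
    y = -np.log(sub["sf_mean"].to_numpy(dtype=float))
    X = np.column_stack([d, d * d])

    if "sf_se" in sub.columns and (sub["sf_se"] > 0).all():
        se_ln = sub["sf_se"].to_numpy(dtype=float) / sub["sf_mean"].to_numpy(dtype=float)
        w = 1.0 / se_ln
    else:
        w = np.ones_like(y)
    Xw = X * w[:, None]
    yw = y * w
    coef, rnorm = nnls(Xw, yw)
    n = len(y)
    df_resid = max(n - 2, 1)
    s2 = (rnorm**2) / df_resid
    xtx = Xw.T @ Xw
    try:
        cov = s2 * np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    return LQFit(
        alpha=float(coef[0]),
        beta=float(coef[1]),
        alpha_se=float(np.sqrt(max(cov[0, 0], 0.0))),
        beta_se=float(np.sqrt(max(cov[1, 1], 0.0))),
        cov=cov,
        df_resid=int(n - 2),
        n_points=int(n),
        excluded_rows=int(bad.sum()),
    )


def dose_at_survival(fit: LQFit, level: float) -> float:
    """Dose (Gy) at which the fitted curve crosses a survival level.

    Positive root of ``beta*D**2 + alpha*D + ln(level) = 0``; reduces to
    ``-ln(level)/alpha`` for a pure-exponential fit (beta = 0).
    """
    if not (0 < level <= 1):
        raise ValueError("survival level must lie in (0, 1]")
    if level == 1.0:
        return 0.0
    if fit.alpha <= 0 and fit.beta <= 0:
        raise ValueError("alpha + beta must be positive to reach the level")
    c = np.log(level)
    if fit.beta == 0:
        return float(-c / fit.alpha)
    disc = fit.alpha**2 - 4.0 * fit.beta * c
    if disc < 0:
        raise ValueError("no positive root: level unreachable for this fit")
    return float((-fit.alpha + np.sqrt(disc)) / (2.0 * fit.beta))


def rbe(fit_reference: LQFit, fit_test: LQFit, level: float = 0.1) -> float:
    """Relative biological effectiveness at an iso-survival level.

    ``RBE = D_reference(level) / D_test(level)``: how many times less
    test-radiation dose is needed for the same survival.  The reference
    is conventionally the sparsely ionising quality (X-rays).
    """
    return dose_at_survival(fit_reference, level) / dose_at_survival(fit_test, level)
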