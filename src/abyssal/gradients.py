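"""Metric-versus-environment regressions with AICc model selection,
and the environmental-factor correlation screen.

Each ecological metric (density, richness, exp H') is regressed on one
environmental predictor (depth or POC flux) under three transformation
families of a simple linear model:

* ``linear``:  y ~ x
* ``log``:     y ~ ln(x)        (requires x > 0)
* ``exp``:     ln(y) ~ x        (requires y > 0; exponential response)

Families are compared on a common response scale with AICc: for the exp
family the Gaussian log-likelihood of ln(y) is adjusted by the
log-Jacobian sum(ln 1/y_i) so that it is a likelihood for y itself.
F, p and R^2 are reported on the transformed scale. Because depth is
strongly collinear with longitude (and POC flux with latitude) across the
study region, only depth and POC flux are offered as predictors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionFit",
    "CorrelationScreen",
    "FAMILIES",
    "fit_gradient",
    "select_model",
    "correlation_screen",
]

FAMILIES = ("linear", "log", "exp")
_K_PARAMS = 3  # intercept, slope, residual variance


@dataclass(frozen=True)
class RegressionFit:
    metric: str
    predictor: str
    family: str
    intercept: float
    slope: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    r_squared: float
    aicc: float
    n: int


@dataclass(frozen=True)
class CorrelationScreen:
    variables: tuple[str, ...]
    matrix: pd.DataFrame  # Pearson r, unit diagonal (NaN rows for zero variance)
    flagged: list[tuple[str, str, float]]  # |r| >= threshold: unusable predictor pairs
    undefined: list[tuple[str, str]]  # zero-variance pairs
    threshold: float


def _transform(y: np.ndarray, x: np.ndarray, family: str) -> tuple[np.ndarray, np.ndarray]:
    if family == "linear":
        return y, x
    if family == "log":
        if (x <= 0).any():
            bad = np.flatnonzero(x <= 0)[:5]
            raise ValueError(f"log family requires x > 0; offending indices {bad.tolist()}")
        return y, np.log(x)
    if family == "exp":
        if (y <= 0).any():
            bad = np.flatnonzero(y <= 0)[:5]
            raise ValueError(f"exp family requires y > 0; offending indices {bad.tolist()}")
        return np.log(y), x
    raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")


def fit_gradient(
    y: Sequence[float],
    x: Sequence[float],
    family: str = "linear",
    metric: str = "metric",
    predictor: str = "depth",
) -> RegressionFit:
    """OLS fit of one metric against one predictor under a named family."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be 1-D and aligned")
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    Y, X = _transform(y, x, family)
    model = sm.OLS(Y, sm.add_constant(X)).fit()
    intercept, slope = model.params
    if np.var(Y) == 0:  # constant response: F is 0 by convention, not 0/0
        f, p, r2 = 0.0, 1.0, 0.0
        slope = 0.0
    else:
        f = float(model.fvalue)
        p = float(model.f_pvalue)
        r2 = float(model.rsquared)
    llf = float(model.llf)
    if family == "exp":
        llf -= float(np.log(y).sum())  # Jacobian of the ln response
    aic = 2 * _K_PARAMS - 2 * llf
    if n > _K_PARAMS + 1:
        aicc = aic + 2 * _K_PARAMS * (_K_PARAMS + 1) / (n - _K_PARAMS - 1)
    else:
        aicc = float("inf")  # AICc undefined at n <= k+1
    return RegressionFit(
        metric=metric,
        predictor=predictor,
        family=family,
        intercept=float(intercept),
        slope=float(slope),
        f_statistic=f,
        df=(1, n - 2),
        p_value=p,
        r_squared=r2,
        aicc=float(aicc),
        n=n,
    )


def select_model(
    y: Sequence[float],
    x: Sequence[float],
    families: Sequence[str] = FAMILIES,
    metric: str = "metric",
    predictor: str = "depth",
) -> tuple[RegressionFit, pd.DataFrame]:
    """Fit every applicable family and select the minimum-AICc fit.

    Families whose domain preconditions fail are skipped with a note in the
    ranking table. When AICc is undefined for every family (tiny n), plain
    AIC ordering decides (identical offsets cancel). Returns (best fit,
    ranking table with delta_aicc).
    """
    fits: list[RegressionFit] = []
    rows = []
    for fam in families:
        try:
            fit = fit_gradient(y, x, fam, metric=metric, predictor=predictor)
        except ValueError as err:
            rows.append({"family": fam, "aicc": np.nan, "note": str(err)})
            continue
        fits.append(fit)
        rows.append({"family": fam, "aicc": fit.aicc, "note": ""})
    if not fits:
        raise ValueError("no fittable family for these data")
    finite = [f for f in fits if np.isfinite(f.aicc)]
    pool = finite if finite else fits
    best = min(pool, key=lambda f: f.aicc)
    ranking = pd.DataFrame(rows)
    base = np.nanmin(ranking["aicc"].to_numpy(dtype=float))
    ranking["delta_aicc"] = ranking["aicc"] - base
    ranking = ranking.sort_values("aicc", na_position="last").reset_index(drop=True)
    return best, ranking


def correlation_screen(
    data: pd.DataFrame,
    variables: Sequence[str] = ("depth", "latitude", "longitude", "poc_flux"),
    threshold: float = 0.7,
) -> CorrelationScreen:
    """Pairwise Pearson correlations among environmental variables.

    Pairs with |r| >= ``threshold`` are flagged as unusable predictor pairs;
    zero-variance variables yield undefined correlations, flagged
    separately.
    """
    cols = [v for v in variables if v in data.columns]
    if len(data) < 3:
        raise ValueError("need at least 3 units for a correlation screen")
    sub = data[cols].astype(float)
    r = sub.corr()
    np.fill_diagonal(r.values, 1.0)
    flagged = []
    undefined = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            val = r.loc[a, b]
            if np.isnan(val):
                undefined.append((a, b))
            elif abs(val) >= threshold:
                flagged.append((a, b, float(val)))
    return CorrelationScreen(
        variables=tuple(cols),
        matrix=r,
        flagged=flagged,
        undefined=undefined,
        threshold=threshold,
    )
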