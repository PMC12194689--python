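"""Univariable weighted linear regression with percentile-bounded weights.

The estimator regresses one dependent variable (e.g. 1-year BCVA in logMAR,
or injection count) on one independent variable, down-weighting far outliers
of either variable via the percentile-bounded Gaussian scheme in
:mod:`mnvquant.weights`. The slope is reported per ``unit`` of the predictor
(the predictor is divided by ``unit`` before fitting, e.g. 200 for a
"per 200 µm" slope), with a classical WLS 95% confidence interval and
two-sided t-test p-value on n-2 degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .weights import observation_weights

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionSpec",
    "RegressionResult",
    "PercentileWeightedLinearRegression",
    "fit_weighted_univariable",
    "run_regression_battery",
]


@dataclass(frozen=True)
class RegressionSpec:
    """One (IV, DV) pair of a regression battery.

    ``unit`` is the scaling divisor applied to the IV before the fit so the
    slope reads "per unit" (200 for 200 µm, 20 for 20 mm, 10 for 10%, 1 for
    unitless or 0/1 presence indicators); ``unit_label`` is what the report
    prints.
    """

    iv_name: str
    dv_name: str
    unit: float = 1.0
    unit_label: str = ""

    def __post_init__(self) -> None:
        if not self.unit > 0:
            raise ValueError("unit must be positive")


@dataclass(frozen=True)
class RegressionResult:
    iv_name: str
    dv_name: str
    unit_label: str
    n: int
    beta: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("confidence interval must bracket beta")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


class PercentileWeightedLinearRegression(RegressorMixin, BaseEstimator):
    """Weighted univariable linear regression with outlier down-weighting.

    Parameters
    ----------
    unit : float, default 1.0
        Scaling divisor for the predictor; the fitted slope is per ``unit``.
    weighted : bool, default True
        If False, all observation weights are 1 and the fit reduces exactly
        to ordinary least squares.

    Attributes
    ----------
    coef_ : ndarray of shape (1,)
        Slope per ``unit`` of the predictor.
    intercept_ : float
    n_ : int
        Number of observations used.
    se_ : float
        Standard error of the slope (classical WLS, ``df = n - 2``).
    ci_ : tuple of float
        95% confidence interval for the slope.
    p_value_ : float
        Two-sided t-test p-value for the slope.
    weights_ : ndarray
        Per-observation geometric-mean weights actually used.

    Notes
    -----
    Weights are computed on the *raw* predictor and response samples; the
    ``unit`` scaling is affine, so the weights are invariant to it. The
    linear solve is delegated to :class:`statsmodels.regression.linear_model.WLS`
    with weights treated as precision weights and the residual variance
    estimated on n-2 degrees of freedom.
    """

    def __init__(self, unit: float = 1.0, weighted: bool = True):
        self.unit = unit
        self.weighted = weighted

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("exactly one predictor column is required")
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values; drop incomplete cases first")
        if not self.unit > 0:
            raise ValueError("unit must be positive")
        n = y.shape[0]
        if n < 3:
            raise ValueError(f"need at least 3 complete cases, got {n}")
        x_raw = X[:, 0]
        if np.ptp(x_raw) == 0:
            raise ValueError("degenerate predictor (constant IV)")

        if self.weighted:
            w = observation_weights(x_raw, y)
        else:
            w = np.ones(n)

        logger.debug(
            "weights: min=%.4f mean=%.4f downweighted=%d/%d",
            float(w.min()), float(w.mean()), int(np.sum(w < 1.0)), n,
        )
        design = sm.add_constant(x_raw / self.unit)
        fit = sm.WLS(y, design, weights=w).fit()

        self.n_ = int(n)
        self.weights_ = w
        self.intercept_ = float(fit.params[0])
        self.coef_ = np.array([fit.params[1]])
        self.se_ = float(fit.bse[1])
        tcrit = stats.t.ppf(0.975, n - 2)
        self.ci_ = (
            float(fit.params[1] - tcrit * self.se_),
            float(fit.params[1] + tcrit * self.se_),
        )
        self.p_value_ = float(fit.pvalues[1])
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + self.coef_[0] * (X[:, 0] / self.unit)

    def result_(self, spec: RegressionSpec) -> RegressionResult:
        """Package the fitted attributes as a :class:`RegressionResult`."""
        check_is_fitted(self, "coef_")
        return RegressionResult(
            iv_name=spec.iv_name,
            dv_name=spec.dv_name,
            unit_label=spec.unit_label,
            n=self.n_,
            beta=float(self.coef_[0]),
            ci_low=self.ci_[0],
            ci_high=self.ci_[1],
            p_value=self.p_value_,
        )


def fit_weighted_univariable(iv, dv, spec: RegressionSpec) -> RegressionResult:
    """Fit one weighted univariable regression and return its table row."""
    model = PercentileWeightedLinearRegression(unit=spec.unit)
    model.fit(np.asarray(iv, dtype=float), np.asarray(dv, dtype=float))
    return model.result_(spec)


def run_regression_battery(
    cohort: pd.DataFrame, specs: list[RegressionSpec]
) -> pd.DataFrame:
    """Run every (IV, DV) spec against a cohort table, complete-case per spec.

    Returns one row per spec with columns
    ``dv, iv, unit_label, n, beta, ci_low, ci_high, p_value``. Rows whose IV
    column exists but has fewer than 3 complete cases or is constant raise;
    an unknown column raises immediately, naming the spec.
    """
    rows = []
    for spec in specs:
        for col in (spec.iv_name, spec.dv_name):
            if col not in cohort.columns:
                raise KeyError(
                    f"column {col!r} required by spec "
                    f"({spec.iv_name} -> {spec.dv_name}) not in cohort"
                )
        sub = cohort[[spec.iv_name, spec.dv_name]].dropna()
        res = fit_weighted_univariable(
            sub[spec.iv_name].to_numpy(float),
            sub[spec.dv_name].to_numpy(float),
            spec,
        )
        rows.append(
            {
                "dv": res.dv_name,
                "iv": res.iv_name,
                "unit_label": res.unit_label,
                "n": res.n,
                "beta": res.beta,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["dv", "iv", "unit_label", "n", "beta", "ci_low", "ci_high", "p_value"],
    )
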