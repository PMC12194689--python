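"""Percentile-bounded Gaussian observation weights.

Far outliers are down-weighted relative to the bulk of a variable's sample.
The admissible band is anchored at the empirical 10th and 90th percentiles
(p10, p90) and widened by 1.5 times their spread:

    t_low  = p10 - 1.5 * (p90 - p10)
    t_high = p90 + 1.5 * (p90 - p10)

Inside [t_low, t_high] an observation gets weight 1; outside, the weight
decays as a Gaussian in the exceedance measured in units of half the band
width, s = 0.5 * (t_high - t_low):

    w(x) = exp(-0.5 * (max(0, t_low - x, x - t_high) / s)**2)

Per-observation weights for a bivariate fit are the geometric mean of the
two variables' univariate weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WeightBounds",
    "percentile",
    "weight_bounds",
    "tail_weight",
    "observation_weights",
]


def _as_finite_array(values, name: str = "values") -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError(f"empty sample: {name}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite value in {name}")
    return arr


@dataclass(frozen=True)
class WeightBounds:
    """Percentile anchors and the derived weighting band for one variable.

    Attributes
    ----------
    p10, p90 : float
        Empirical 10th/90th percentiles of the sample.
    t_low, t_high : float
        Band edges ``p10 - 1.5*(p90-p10)`` and ``p90 + 1.5*(p90-p10)``.
    s : float
        Half band width, ``0.5*(t_high - t_low) = 2*(p90 - p10)``.
    """

    p10: float
    p90: float
    t_low: float
    t_high: float
    s: float

    def __post_init__(self) -> None:
        if not (self.t_low <= self.p10 <= self.p90 <= self.t_high):
            raise ValueError("invalid bounds ordering")
        if self.s < 0:
            raise ValueError("negative band half-width")


def percentile(values, q: float) -> float:
    """Empirical quantile with linear interpolation between order statistics.

    Uses the "type 7" rule (index ``q/100 * (n-1)``), the default of
    mainstream numerical environments.
    """
    arr = _as_finite_array(values)
    if not 0 <= q <= 100:
        raise ValueError("q must be in [0, 100]")
    return float(np.percentile(arr, q, method="linear"))


def weight_bounds(values) -> WeightBounds:
    """Compute the percentile-anchored weighting band for a sample."""
    arr = _as_finite_array(values)
    p10 = float(np.percentile(arr, 10, method="linear"))
    p90 = float(np.percentile(arr, 90, method="linear"))
    iqr = p90 - p10
    t_low = p10 - 1.5 * iqr
    t_high = p90 + 1.5 * iqr
    return WeightBounds(p10=p10, p90=p90, t_low=t_low, t_high=t_high, s=2.0 * iqr)


def tail_weight(x, bounds: WeightBounds):
    """Gaussian tail weight of value(s) ``x`` under ``bounds``.

    Returns 1 inside ``[t_low, t_high]``; decays smoothly outside. When the
    band is degenerate (``s == 0``, i.e. p10 == p90) there is no dispersion
    to measure outliers against and every weight is 1.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite x")
    if bounds.s == 0:
        w = np.ones_like(arr)
    else:
        exceed = np.maximum(0.0, np.maximum(bounds.t_low - arr, arr - bounds.t_high))
        w = np.exp(-0.5 * (exceed / bounds.s) ** 2)
    if arr.ndim == 0:
        return float(w)
    return w


def observation_weights(iv_values, dv_values) -> np.ndarray:
    """Geometric-mean weights over the two variables involved in a fit.

    ``w_i = sqrt(w_IV(x_i) * w_DV(y_i))`` with each factor's band computed
    on its own variable's sample.
    """
    x = _as_finite_array(iv_values, "iv_values")
    y = _as_finite_array(dv_values, "dv_values")
    if x.shape != y.shape:
        raise ValueError("length mismatch between IV and DV samples")
    wx = tail_weight(x, weight_bounds(x))
    wy = tail_weight(y, weight_bounds(y))
    return np.sqrt(np.asarray(wx) * np.asarray(wy))
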