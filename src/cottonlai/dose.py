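"""Quadratic dose-response of canopy and water-use traits to conditioner rate.

Both the seasonal maximum LAI and the water-use efficiency (WUE, yield
per mm of water consumed) respond to the application rate I of a soil
conditioner as a concave quadratic

    response(I) = c2*I^2 + c1*I + c0,        c2 < 0,

whose vertex I* = -c1 / (2*c2) is the agronomic optimum: the rate beyond
which additional conditioner no longer raises the trait.  The control
(rate 0) anchors each conditioner's curve at c0.

WUE and maximum LAI are themselves linearly related across treatments
under a fixed irrigation schedule, which `wue_laim_line` quantifies.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from ._exceptions import ValidationError
from .metrics import r_squared as _r2

__all__ = [
    "Optimum",
    "QuadraticDoseResponse",
    "fit_quadratic",
    "optimum",
    "wue",
    "wue_laim_line",
]


class Optimum(NamedTuple):
    """Vertex of a concave dose-response quadratic."""

    rate_star: float  # g m-2
    value_star: float  # response units


class QuadraticDoseResponse(RegressorMixin, BaseEstimator):
    """Exact linear least-squares quadratic in application rate.

    Attributes (after ``fit`` or ``from_coefficients``)
    ---------------------------------------------------
    coef_ : (c2, c1, c0) with value = c2*I^2 + c1*I + c0.
    r_squared_ : coefficient of determination on the training points
        (NaN when built from known coefficients).
    """

    def __init__(self, response_name: str = "LAI_m"):
        self.response_name = response_name

    @classmethod
    def from_coefficients(cls, c2: float, c1: float, c0: float, response_name: str = "LAI_m"):
        model = cls(response_name=response_name)
        model.coef_ = (float(c2), float(c1), float(c0))
        model.r_squared_ = float("nan")
        return model

    def fit(self, X, y):
        rate = np.asarray(X, dtype=float).ravel()
        resp = np.asarray(y, dtype=float).ravel()
        if rate.shape != resp.shape:
            raise ValidationError("rate and response lengths differ")
        if np.unique(rate).size < 3:
            raise ValidationError("need >= 3 distinct rates for a quadratic")
        c2, c1, c0 = np.polyfit(rate, resp, 2)
        self.coef_ = (float(c2), float(c1), float(c0))
        self.r_squared_ = _r2(resp, self.predict(rate))
        return self

    def predict(self, X):
        if not hasattr(self, "coef_"):
            raise ValidationError("model is not fitted")
        rate = np.asarray(X, dtype=float)
        c2, c1, c0 = self.coef_
        out = c2 * rate**2 + c1 * rate + c0
        return float(out) if np.ndim(X) == 0 else out

    def optimum(self) -> Optimum:
        """Vertex of the parabola; only defined for a concave fit (c2 < 0)."""
        c2, c1, _ = self.coef_
        if c2 >= 0:
            raise ValidationError(f"no interior maximum: c2 = {c2} >= 0")
        rate_star = -c1 / (2.0 * c2)
        return Optimum(rate_star=float(rate_star), value_star=self.predict(rate_star))


def fit_quadratic(points: Sequence[tuple[float, float]], response_name="LAI_m") -> QuadraticDoseResponse:
    """Fit a quadratic to (rate, response) pairs."""
    pts = np.asarray(points, dtype=float)
    return QuadraticDoseResponse(response_name=response_name).fit(pts[:, 0], pts[:, 1])


def optimum(q: QuadraticDoseResponse) -> Optimum:
    return q.optimum()


def wue(yield_kg_per_ha: float, water_mm: float) -> float:
    """Water-use efficiency: yield (kg/ha) per unit water consumed (mm)."""
    if water_mm <= 0:
        raise ValidationError("water consumption must be positive")
    if yield_kg_per_ha < 0:
        raise ValidationError("yield must be nonnegative")
    return yield_kg_per_ha / water_mm


def wue_laim_line(points: Sequence[tuple[float, float]]) -> tuple[float, float, float]:
    """Ordinary least-squares line LAI_m = slope*WUE + intercept.

    Returns (slope, intercept, r_squared).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValidationError("need >= 2 (wue, lai_m) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.allclose(x, x[0]):
        raise ValidationError("WUE values are constant; line undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
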