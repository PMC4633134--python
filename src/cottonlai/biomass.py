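"""Saturating LAI-dry-matter link, harvest index, and yield prediction.

Canopy expansion saturates with aboveground dry matter M in a
Michaelis-Menten form

    LAI = P*M / (1 + Q*M),

with asymptote P/Q.  The default fit linearizes to the double-reciprocal
line 1/LAI = (1/P)*(1/M) + Q/P and solves by ordinary least squares,
exactly as practised for this relation; the known error-weighting bias
of the reciprocal transform can be avoided with ``method="nonlinear"``
(direct least squares on the original scale), and reports state which
was used.  Inverting the link gives the peak dry matter a treatment can
produce from its maximum LAI:

    M_m = LAI_m / (P - Q*LAI_m),        LAI_m < P/Q.

The harvest index HI = Y / (M_m + Y) partitions total biomass between
yield and vegetative dry matter; it is near-constant across treatments,
so yield follows from maximum LAI alone:

    Y = HI/(1 - HI) * M_m(LAI_m).

Canonical mass-area unit throughout is kg m-2 (use
``t_per_ha_to_kg_per_m2`` at the I/O boundary for t/ha tables).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from ._exceptions import FitError, ValidationError

__all__ = [
    "MichaelisMentenRelation",
    "YieldModel",
    "fit_mm",
    "mm_lai",
    "mm_dry_matter",
    "harvest_index",
    "mean_hi",
    "predict_yield",
    "t_per_ha_to_kg_per_m2",
]


def t_per_ha_to_kg_per_m2(x):
    """Convert t/ha to kg/m^2 (x0.1)."""
    return np.asarray(x, dtype=float) * 0.1


class MichaelisMentenRelation(RegressorMixin, BaseEstimator):
    """Saturating LAI = P*M/(1 + Q*M) link between dry matter and LAI.

    Parameters
    ----------
    method : "linearized" (default) fits the double-reciprocal line by
        ordinary least squares; "nonlinear" minimizes squared error on
        the original scale.

    Attributes (after ``fit`` / ``from_parameters``)
    ------------------------------------------------
    p_, q_ : the gain and saturation parameters, both positive.
    asymptote_ : P/Q, the LAI ceiling.
    """

    def __init__(self, method: str = "linearized"):
        self.method = method

    @classmethod
    def from_parameters(cls, p: float, q: float) -> "MichaelisMentenRelation":
        if p <= 0 or q <= 0:
            raise ValidationError("P and Q must be positive")
        model = cls()
        model.p_, model.q_ = float(p), float(q)
        model.asymptote_ = model.p_ / model.q_
        return model

    def fit(self, X, y):
        m = np.asarray(X, dtype=float).ravel()
        lai = np.asarray(y, dtype=float).ravel()
        if m.shape != lai.shape or m.size < 2:
            raise ValidationError("need >= 2 matched (dry_matter, lai) points")
        if np.any(m <= 0) or np.any(lai <= 0):
            raise ValidationError("dry matter and LAI must be positive for fitting")
        if self.method == "linearized":
            # 1/LAI = (1/P)*(1/M) + Q/P
            slope, intercept = np.polyfit(1.0 / m, 1.0 / lai, 1)
            if slope <= 0:
                raise FitError(
                    "linearized fit gave nonpositive 1/P",
                    diagnostics={"slope": slope, "intercept": intercept},
                )
            p = 1.0 / slope
            q = intercept * p
        elif self.method == "nonlinear":
            slope, intercept = np.polyfit(1.0 / m, 1.0 / lai, 1)
            p0 = [1.0 / slope if slope > 0 else 1.0, max(intercept / slope, 0.01)]
            sol = least_squares(
                lambda t: t[0] * m / (1.0 + t[1] * m) - lai, p0, bounds=([1e-9, 1e-9], [np.inf, np.inf])
            )
            if not sol.success:
                raise FitError("nonlinear MM fit did not converge", diagnostics={"status": sol.status})
            p, q = sol.x
        else:
            raise ValidationError(f"unknown method {self.method!r}")
        if p <= 0 or q <= 0:
            raise FitError(
                "recovered nonpositive MM parameters", diagnostics={"p": p, "q": q}
            )
        self.p_, self.q_ = float(p), float(q)
        self.asymptote_ = self.p_ / self.q_
        return self

    def predict(self, X):
        """LAI at dry matter M: P*M/(1 + Q*M); increasing, bounded by P/Q."""
        self._check_fitted()
        m = np.asarray(X, dtype=float)
        if np.any(m < 0):
            raise ValidationError("dry matter must be nonnegative")
        out = self.p_ * m / (1.0 + self.q_ * m)
        return float(out) if np.ndim(X) == 0 else out

    def dry_matter(self, lai_m):
        """Invert the link: peak dry matter from maximum LAI.

        Defined for 0 <= LAI_m < P/Q; beyond the asymptote no finite dry
        matter can produce the requested canopy.
        """
        self._check_fitted()
        lm = np.asarray(lai_m, dtype=float)
        if np.any(lm < 0):
            raise ValidationError("lai_m must be nonnegative")
        if np.any(lm >= self.asymptote_):
            raise ValidationError(
                f"lai_m beyond the LAI asymptote P/Q = {self.asymptote_:.4g}"
            )
        out = lm / (self.p_ - self.q_ * lm)
        return float(out) if np.ndim(lai_m) == 0 else out

    def _check_fitted(self):
        if not hasattr(self, "p_"):
            raise ValidationError("MM relation is not fitted")


class YieldModel:
    """Yield from maximum LAI through the MM link and the harvest index.

    Y(LAI_m) = HI/(1-HI) * LAI_m / (P - Q*LAI_m), in kg m-2.
    """

    def __init__(self, harvest_index: float, mm: MichaelisMentenRelation):
        if not 0.0 < harvest_index < 1.0:
            raise ValidationError("harvest index must lie in (0, 1)")
        mm._check_fitted()
        self.harvest_index = float(harvest_index)
        self.mm = mm

    def predict_dry_matter(self, lai_m):
        return self.mm.dry_matter(lai_m)

    def predict(self, lai_m):
        factor = self.harvest_index / (1.0 - self.harvest_index)
        dm = self.mm.dry_matter(lai_m)
        return factor * dm


# ---------------------------------------------------------------- wrappers


def fit_mm(points: Sequence[tuple[float, float]], method="linearized") -> MichaelisMentenRelation:
    """Fit the MM link to (dry_matter, lai) pairs."""
    pts = np.asarray(points, dtype=float)
    return MichaelisMentenRelation(method=method).fit(pts[:, 0], pts[:, 1])


def mm_lai(mm: MichaelisMentenRelation, dry_matter):
    return mm.predict(dry_matter)


def mm_dry_matter(mm: MichaelisMentenRelation, lai_m):
    return mm.dry_matter(lai_m)


def harvest_index(yield_, total_biomass) -> float:
    """HI = yield / total aboveground biomass, strictly inside (0, 1)."""
    if yield_ <= 0 or total_biomass <= 0:
        raise ValidationError("yield and biomass must be positive")
    if yield_ >= total_biomass:
        raise ValidationError("yield must be below total biomass")
    return float(yield_) / float(total_biomass)


def mean_hi(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample (n-1) SD of per-treatment harvest indices."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValidationError("need >= 2 harvest indices")
    return float(v.mean()), float(v.std(ddof=1))


def predict_yield(model: YieldModel, lai_m):
    return model.predict(lai_m)


def results_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-treatment results table and derive HI and total biomass.

    Expects columns treatment_id, yield_, dry_biomass (kg m-2); fills in
    total_biomass = dry_biomass + yield_ and harvest_index = yield_/total
    when absent, and checks both identities when present.
    """
    out = df.copy()
    if "total_biomass" not in out.columns:
        out["total_biomass"] = out["dry_biomass"] + out["yield_"]
    if "harvest_index" not in out.columns:
        out["harvest_index"] = out["yield_"] / out["total_biomass"]
    bad = ~np.isclose(
        out["total_biomass"], out["dry_biomass"] + out["yield_"], atol=1e-4
    )
    if bad.any():
        raise ValidationError(
            f"total biomass != dry + yield for {out.loc[bad, 'treatment_id'].tolist()}"
        )
    return out
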