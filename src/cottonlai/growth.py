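"""Single-peak growth-curve models of relative LAI against thermal time.

Five functional forms describe the rise, plateau and decline of the
relative leaf area index over growing degree days g:

- ``modified_logistic``:  A / (1 + exp(a + b*g + c*g^2))
- ``gaussian``:           A * exp(-0.5 * ((g - a)/b)^2)
- ``modified_gaussian``:  A * exp(-0.5 * (|g - a|/b)^c)
- ``log_normal``:         A * exp(-0.5 * (ln(g/a)/b)^2)   (g > 0)
- ``cubic_polynomial``:   a0 + a1*g + a2*g^2 + a3*g^3

For the three exponential peak forms the parameter ``a`` is the thermal
time at which the curve attains its maximum, which equals the amplitude
A exactly.  The amplitude is a free parameter rather than being pinned
to 1: fitted trajectories peak near, not exactly at, 1 on a discrete
sampling grid.

Fitting uses seeded multi-start bounded least squares (a deterministic
stand-in for stochastic global optimizers often used on these curves):
each start is drawn from a documented parameter box and refined with
``scipy.optimize.least_squares``; the best solution by residual cost
wins.  The cubic polynomial is linear in its coefficients and is solved
by exact linear least squares instead.

A fitted model reconstructs absolute LAI through the universal-model
identity LAI(g) = LAI_m * RLAI(g), which transfers a single relative
curve across treatments that differ only in their maximum LAI.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from ._exceptions import FitError, ValidationError
from .metrics import FitMetrics, fit_metrics

__all__ = [
    "MODEL_FORMS",
    "RLAIGrowthModel",
    "evaluate",
    "fit_form",
    "compare",
    "universal_lai",
]

_EXP_CLIP = 500.0  # exponent clamp against overflow in the logistic form


def _eval_modified_logistic(p, g):
    amp, a, b, c = p
    z = np.clip(a + b * g + c * g**2, -_EXP_CLIP, _EXP_CLIP)
    return amp / (1.0 + np.exp(z))


def _eval_gaussian(p, g):
    amp, a, b = p
    return amp * np.exp(-0.5 * ((g - a) / b) ** 2)


def _eval_modified_gaussian(p, g):
    amp, a, b, c = p
    return amp * np.exp(-0.5 * (np.abs(g - a) / b) ** c)


def _eval_log_normal(p, g):
    amp, a, b = p
    if np.any(np.asarray(g) <= 0):
        raise ValidationError("log_normal form requires gdd > 0")
    return amp * np.exp(-0.5 * (np.log(g / a) / b) ** 2)


def _eval_cubic(p, g):
    a0, a1, a2, a3 = p
    return a0 + a1 * g + a2 * g**2 + a3 * g**3


#: registry of the five forms: evaluator, parameter names, peak-form flag
MODEL_FORMS = {
    "modified_logistic": {
        "func": _eval_modified_logistic,
        "names": ("amplitude", "a", "b", "c"),
        "peak_at_a": False,
    },
    "gaussian": {
        "func": _eval_gaussian,
        "names": ("amplitude", "a", "b"),
        "peak_at_a": True,
    },
    "modified_gaussian": {
        "func": _eval_modified_gaussian,
        "names": ("amplitude", "a", "b", "c"),
        "peak_at_a": True,
    },
    "log_normal": {
        "func": _eval_log_normal,
        "names": ("amplitude", "a", "b"),
        "peak_at_a": True,
    },
    "cubic_polynomial": {
        "func": _eval_cubic,
        "names": ("a0", "a1", "a2", "a3"),
        "peak_at_a": False,
    },
}


def _param_vector(form: str, params: Mapping[str, float]) -> np.ndarray:
    names = MODEL_FORMS[form]["names"]
    missing = set(names) - set(params)
    if missing:
        raise ValidationError(f"{form} missing parameters {sorted(missing)}")
    return np.array([float(params[n]) for n in names])


def evaluate(form: str, params: Mapping[str, float], gdd):
    """Evaluate a growth-curve form at thermal time(s) ``gdd``."""
    if form not in MODEL_FORMS:
        raise ValidationError(f"unknown model form {form!r}")
    g = np.asarray(gdd, dtype=float)
    p = _param_vector(form, params)
    out = MODEL_FORMS[form]["func"](p, g)
    return float(out) if np.ndim(gdd) == 0 else out


def _bounds(form: str, gmin: float, gmax: float):
    """Parameter boxes used both as optimizer bounds and start-draw ranges."""
    if form in ("gaussian", "modified_gaussian", "log_normal"):
        lo = [0.5, gmin, 10.0 if form != "log_normal" else 0.05]
        hi = [1.5, gmax, 5000.0 if form != "log_normal" else 5.0]
        if form == "modified_gaussian":
            lo.append(0.5)
            hi.append(10.0)
        return np.array(lo), np.array(hi)
    if form == "modified_logistic":
        return (np.array([0.5, -30.0, -0.1, -1e-4]), np.array([1.5, 30.0, 0.1, 1e-4]))
    raise ValidationError(f"no optimizer box for {form}")


def _smart_start(form, g, y, lo, hi):
    """A data-driven initial point: peak location/height plus shape defaults."""
    amp0 = max(float(np.max(y)), 1e-6)
    a0 = float(g[np.argmax(y)])
    span = float(g.max() - g.min()) or 1.0
    if form == "gaussian":
        p0 = [amp0, a0, span / 3.0]
    elif form == "modified_gaussian":
        p0 = [amp0, a0, span / 3.0, 2.0]
    elif form == "log_normal":
        p0 = [amp0, a0, 0.6]
    else:  # modified_logistic: linearize log(amp/y - 1) as a quadratic in g
        amp0 = amp0 * 1.05
        mask = (y > 0) & (y < amp0)
        if mask.sum() >= 3:
            z = np.log(amp0 / y[mask] - 1.0)
            c2, c1, c0 = np.polyfit(g[mask], z, 2)
            p0 = [amp0, c0, c1, c2]
        else:
            p0 = [amp0, 5.0, -0.01, 3e-6]
    return np.clip(p0, lo, hi)


def fit_form(
    form: str,
    gdd: Sequence[float],
    rlai: Sequence[float],
    n_starts: int = 32,
    random_state: int | None = 0,
) -> "RLAIGrowthModel":
    """Fit one form to (gdd, rlai) points; thin wrapper over the estimator."""
    return RLAIGrowthModel(form=form, n_starts=n_starts, random_state=random_state).fit(
        gdd, rlai
    )


class RLAIGrowthModel(RegressorMixin, BaseEstimator):
    """Least-squares fit of one single-peak RLAI(GDD) form.

    Parameters
    ----------
    form : one of ``MODEL_FORMS``; default the modified Gaussian, the most
        accurate form on the trial data this package ships.
    n_starts : number of seeded multi-start draws for the nonlinear forms.
    random_state : seed for the start draws; fitting is deterministic per seed.

    Attributes (after ``fit``)
    --------------------------
    params_ : dict of named parameters.
    amplitude_ : peak multiplier (None for the cubic polynomial).
    n_params_ : number of free parameters of the form.
    metrics_ : :class:`~cottonlai.metrics.FitMetrics` on the training points.
    """

    def __init__(self, form: str = "modified_gaussian", n_starts: int = 32, random_state=0):
        self.form = form
        self.n_starts = n_starts
        self.random_state = random_state

    # -- construction from known parameters (published fits, serialized fits)
    @classmethod
    def from_parameters(cls, form: str, params: Mapping[str, float]) -> "RLAIGrowthModel":
        """Build an already-parameterized model (no fitting)."""
        model = cls(form=form)
        model._set_fitted(_param_vector(form, params))
        return model

    def _set_fitted(self, vector: np.ndarray):
        names = MODEL_FORMS[self.form]["names"]
        self.params_ = dict(zip(names, (float(v) for v in vector)))
        self.amplitude_ = self.params_.get("amplitude")
        self.n_params_ = len(names)
        return self

    def _check_xy(self, X, y=None):
        g = np.asarray(X, dtype=float)
        if g.ndim == 2 and g.shape[1] == 1:
            g = g.ravel()
        if g.ndim != 1:
            raise ValidationError("gdd must be a 1-d array or a single column")
        if y is None:
            return g
        r = np.asarray(y, dtype=float).ravel()
        if r.shape != g.shape:
            raise ValidationError("gdd and rlai lengths differ")
        return g, r

    def fit(self, X, y):
        if self.form not in MODEL_FORMS:
            raise ValidationError(f"unknown model form {self.form!r}")
        g, r = self._check_xy(X, y)
        names = MODEL_FORMS[self.form]["names"]
        if g.size <= len(names):
            raise ValidationError(
                f"{self.form} needs more points ({g.size}) than parameters ({len(names)})"
            )
        if self.form == "cubic_polynomial":
            # linear in a0..a3 -> exact linear least squares
            coef = np.polynomial.polynomial.polyfit(g, r, 3)
            self._set_fitted(coef)
        else:
            self._fit_nonlinear(g, r)
        self.metrics_ = fit_metrics(r, self.predict(g))
        return self

    def _fit_nonlinear(self, g, r):
        func = MODEL_FORMS[self.form]["func"]
        lo, hi = _bounds(self.form, float(g.min()), float(g.max()))
        rng = np.random.default_rng(self.random_state)
        starts = [_smart_start(self.form, g, r, lo, hi)]
        starts += list(rng.uniform(lo, hi, size=(max(self.n_starts - 1, 0), lo.size)))

        def resid(p):
            return func(p, g) - r

        best = None
        for p0 in starts:
            try:
                sol = least_squares(resid, p0, bounds=(lo, hi), method="trf")
            except Exception:  # a pathological start; other starts still count
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise FitError(
                f"no start converged for {self.form}",
                diagnostics={"n_starts": self.n_starts, "bounds": (lo.tolist(), hi.tolist())},
            )
        self._set_fitted(best.x)

    def predict(self, X):
        if not hasattr(self, "params_"):
            raise ValidationError("model is not fitted")
        if np.ndim(X) == 0:
            return evaluate(self.form, self.params_, X)
        g = self._check_xy(X)
        return evaluate(self.form, self.params_, g)

    def peak(self) -> tuple[float, float]:
        """(gdd, value) at the curve's maximum for the peak-at-a forms."""
        if not MODEL_FORMS[self.form]["peak_at_a"]:
            raise ValidationError(f"{self.form} has no closed-form peak")
        return self.params_["a"], self.amplitude_

    def to_dict(self) -> dict:
        return {"form": self.form, **self.params_}


def compare(fits: Sequence[RLAIGrowthModel], observed_gdd=None, observed_rlai=None) -> pd.DataFrame:
    """Rank fitted models by RMSE (stable tie-break: parameter count, input order).

    If observation vectors are given, metrics are recomputed on them;
    otherwise each fit's training metrics are used.
    """
    if len(fits) == 0:
        raise ValidationError("nothing to compare")
    rows = []
    for i, fit in enumerate(fits):
        if observed_gdd is not None:
            m = fit_metrics(observed_rlai, fit.predict(observed_gdd))
        else:
            m = fit.metrics_
        rows.append(
            {
                "form": fit.form,
                "params": ", ".join(f"{k}={v:.6g}" for k, v in fit.params_.items()),
                "re_percent": m.re_percent,
                "r_squared": m.r_squared,
                "rmse": m.rmse,
                "n_params": fit.n_params_,
                "_order": i,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["rmse", "n_params", "_order"], kind="stable", ignore_index=True
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return table.drop(columns="_order")


def universal_lai(fit: RLAIGrowthModel, lai_m: float, gdd):
    """Absolute LAI via the universal model: LAI(g) = LAI_m * RLAI(g).

    ``fit`` must have been trained on relative LAI; ``lai_m`` is the
    treatment's maximum LAI acting as the scale factor.
    """
    if lai_m <= 0:
        raise ValidationError("lai_m must be positive")
    return lai_m * fit.predict(gdd)
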