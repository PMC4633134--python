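"""Goodness-of-fit statistics used by every fitting stage.

Three statistics are exposed: the root-mean-square error (RMSE), the
coefficient of determination (R^2), and the relative error Re, a
scale-invariant percentage defined as

    Re = 100 * sqrt( sum_i (o_i - s_i)^2 / sum_i o_i^2 )

where ``o`` are observed and ``s`` simulated values.  Note the square
root: Re is the ratio of the deviation norm to the observation norm,
which keeps it on the same percentage scale as a relative error (the
unrooted ratio would be a squared quantity two orders of magnitude
smaller on typical canopy data).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from ._exceptions import ValidationError

__all__ = ["FitMetrics", "rmse", "r_squared", "re_percent", "fit_metrics"]


class FitMetrics(NamedTuple):
    """Bundle of the three fit statistics for one model on one dataset.

    Attributes
    ----------
    rmse : float
        Root-mean-square error, in units of the fitted quantity.
    r_squared : float
        Coefficient of determination, 1 - SS_res / SS_tot; at most 1.
    re_percent : float
        Relative error in percent (see module docstring).
    """

    rmse: float
    r_squared: float
    re_percent: float


def _as_pair(observed, simulated, min_len=1):
    o = np.asarray(observed, dtype=float).ravel()
    s = np.asarray(simulated, dtype=float).ravel()
    if o.shape != s.shape:
        raise ValidationError(
            f"observed and simulated lengths differ: {o.size} vs {s.size}"
        )
    if o.size < min_len:
        raise ValidationError(f"need at least {min_len} points, got {o.size}")
    if not (np.all(np.isfinite(o)) and np.all(np.isfinite(s))):
        raise ValidationError("non-finite values in input")
    return o, s


def rmse(observed, simulated) -> float:
    """Root-mean-square deviation between observed and simulated values."""
    o, s = _as_pair(observed, simulated, min_len=1)
    return float(np.sqrt(np.mean((o - s) ** 2)))


def r_squared(observed, simulated) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot.

    SS_tot is taken about the mean of the observations.  Undefined (raises)
    when the observations are constant.
    """
    o, s = _as_pair(observed, simulated, min_len=2)
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValidationError("r_squared undefined for constant observations")
    ss_res = float(np.sum((o - s) ** 2))
    return 1.0 - ss_res / ss_tot


def re_percent(observed, simulated) -> float:
    """Relative error in percent: 100 * sqrt(sum (o-s)^2 / sum o^2)."""
    o, s = _as_pair(observed, simulated, min_len=1)
    denom = float(np.sum(o**2))
    if denom == 0.0:
        raise ValidationError("re_percent undefined for all-zero observations")
    return float(100.0 * np.sqrt(np.sum((o - s) ** 2) / denom))


def fit_metrics(observed, simulated) -> FitMetrics:
    """Compute all three statistics at once."""
    return FitMetrics(
        rmse=rmse(observed, simulated),
        r_squared=r_squared(observed, simulated),
        re_percent=re_percent(observed, simulated),
    )
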