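"""Growing degree days (GDD) from daily min/max air temperature.

Daily thermal time follows the FAO capping convention: the daily maximum
and minimum temperatures are each clamped into ``[t_base, t_upper]``
before averaging, and the base temperature is subtracted from the capped
average.  The daily value is therefore never negative, and cumulative
GDD is non-decreasing.  GDD = 0 corresponds to 1 January (day_of_year 1
starts the accumulation).

The base and upper temperatures are crop- and region-specific and must
be supplied; the shipped defaults (10 degC base, 35 degC upper) are common
values for cotton.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import ValidationError

__all__ = [
    "ThermalConfig",
    "daily_gdd",
    "accumulate",
    "read_temperature_csv",
    "write_gdd_csv",
]


@dataclass(frozen=True)
class ThermalConfig:
    """Base and upper temperature thresholds for GDD accumulation (degC)."""

    t_base: float = 10.0
    t_upper: float = 35.0

    def __post_init__(self):
        if not self.t_upper > self.t_base:
            raise ValidationError(
                f"t_upper ({self.t_upper}) must exceed t_base ({self.t_base})"
            )


def _clamp(t, cfg: ThermalConfig):
    return np.clip(t, cfg.t_base, cfg.t_upper)


def daily_gdd(t_max, t_min, cfg: ThermalConfig = ThermalConfig()) -> float:
    """Daily thermal time: capped average temperature minus the base.

    Vectorized over ``t_max``/``t_min``; scalar inputs give a scalar.
    """
    t_max = np.asarray(t_max, dtype=float)
    t_min = np.asarray(t_min, dtype=float)
    if np.any(t_max < t_min):
        raise ValidationError("t_max < t_min in temperature record")
    gdd = (_clamp(t_max, cfg) + _clamp(t_min, cfg)) / 2.0 - cfg.t_base
    return float(gdd) if gdd.ndim == 0 else gdd


def accumulate(temps: pd.DataFrame, cfg: ThermalConfig = ThermalConfig()) -> pd.DataFrame:
    """Cumulative GDD series from a daily temperature table.

    Parameters
    ----------
    temps : DataFrame with columns ``day_of_year``, ``t_max``, ``t_min``;
        days must be strictly increasing (missing days are an error at the
        point of use, not interpolated — there is no gap rule).

    Returns
    -------
    DataFrame with columns ``day_of_year``, ``daily_gdd``, ``cumulative_gdd``.
    """
    required = {"day_of_year", "t_max", "t_min"}
    missing = required - set(temps.columns)
    if missing:
        raise ValidationError(f"temperature table missing columns: {sorted(missing)}")
    days = np.asarray(temps["day_of_year"], dtype=int)
    if days.size and np.any(np.diff(days) <= 0):
        raise ValidationError("day_of_year must be strictly increasing")
    if days.size and days.min() < 1:
        raise ValidationError("day_of_year must be >= 1")
    daily = daily_gdd(temps["t_max"].to_numpy(), temps["t_min"].to_numpy(), cfg)
    daily = np.atleast_1d(daily)
    return pd.DataFrame(
        {
            "day_of_year": days,
            "daily_gdd": daily,
            "cumulative_gdd": np.cumsum(daily),
        }
    )


def read_temperature_csv(path) -> pd.DataFrame:
    """Read a daily temperature CSV with day_of_year (or ISO ``date``), t_max, t_min."""
    df = pd.read_csv(path)
    if "day_of_year" not in df.columns:
        if "date" in df.columns:
            df["day_of_year"] = pd.to_datetime(df["date"]).dt.dayofyear
        else:
            raise ValidationError("need a day_of_year or date column")
    return df[["day_of_year", "t_max", "t_min"]]


def write_gdd_csv(gdd: pd.DataFrame, path) -> None:
    gdd.to_csv(path, index=False)
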