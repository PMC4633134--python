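"""Leaf area index from plant-census rows and its normalization to RLAI.

LAI is one-sided leaf area per unit ground area.  From a census of one
plant it is (branches x leaves-per-branch x mean leaf area in cm^2 /
10000) / ground area in m^2.  Individual leaf areas come from the
standard cotton allometry: 0.7 x main-vein length x maximum width.

The relative LAI (RLAI) divides each treatment's trajectory by that
treatment's own empirical maximum over the observed thermal-time grid,
so exactly one grid point per treatment maps to 1.  Across treatments
the RLAI trajectories collapse onto a common single-peak curve, which
is what makes a universal growth model possible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._exceptions import ValidationError

__all__ = [
    "leaf_area",
    "lai_from_census",
    "normalize_rlai",
    "aggregate_mean_sd",
    "read_lai_csv",
]

#: empirical shape factor for cotton leaves (area = 0.7 * length * width)
LEAF_SHAPE_FACTOR = 0.7


def leaf_area(vein_length: float, max_width: float) -> float:
    """Leaf area (cm^2) from main-vein length and maximum width (cm)."""
    if vein_length <= 0 or max_width <= 0:
        raise ValidationError("leaf dimensions must be positive")
    return LEAF_SHAPE_FACTOR * vein_length * max_width


def lai_from_census(branches, leaves_per_branch, mean_leaf_area, ground_area):
    """LAI from a plant census.

    Parameters
    ----------
    branches : number of branches on the plant (B).
    leaves_per_branch : number of leaves per branch (I).
    mean_leaf_area : mean single-leaf area in cm^2 (W).
    ground_area : ground area covered by the plant in m^2 (S).
    """
    b, i, w, s = (float(x) for x in (branches, leaves_per_branch, mean_leaf_area, ground_area))
    if min(b, i, w) <= 0:
        raise ValidationError("census counts and leaf area must be positive")
    if s <= 0:
        raise ValidationError("ground_area must be positive")
    return (b * i * w / 10000.0) / s


def normalize_rlai(observations: pd.DataFrame) -> pd.DataFrame:
    """Normalize per-treatment LAI trajectories to relative LAI.

    Parameters
    ----------
    observations : DataFrame with columns ``treatment_id``, ``gdd``, ``lai``.

    Returns
    -------
    DataFrame with the input columns plus ``rlai`` and ``lai_m`` (the
    per-treatment empirical maximum used as the normalizer).
    """
    required = {"treatment_id", "gdd", "lai"}
    missing = required - set(observations.columns)
    if missing:
        raise ValidationError(f"LAI table missing columns: {sorted(missing)}")
    if len(observations) == 0:
        raise ValidationError("empty LAI table")
    lai = observations["lai"].to_numpy(dtype=float)
    if np.any(lai < 0):
        raise ValidationError("negative LAI")
    out = observations.copy()
    lai_m = out.groupby("treatment_id")["lai"].transform("max")
    if np.any(lai_m.to_numpy() <= 0):
        bad = out.loc[lai_m <= 0, "treatment_id"].unique().tolist()
        raise ValidationError(f"all-zero LAI trajectory for treatments {bad}")
    out["lai_m"] = lai_m
    out["rlai"] = out["lai"] / lai_m
    return out


def aggregate_mean_sd(rlai: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample (n-1) standard deviation of RLAI per grid point.

    Aggregates only at thermal-time grid points shared across treatments;
    every grid point must carry at least two treatments (the sample SD is
    undefined otherwise).  No interpolation across grids is attempted.
    """
    if "rlai" not in rlai.columns:
        raise ValidationError("expected a table with an rlai column (run normalize_rlai)")
    counts = rlai.groupby("gdd")["rlai"].count()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValidationError(f"fewer than 2 treatments at grid points {bad}")
    agg = rlai.groupby("gdd")["rlai"].agg(mean_rlai="mean", sample_sd=lambda v: v.std(ddof=1))
    return agg.reset_index()


def read_lai_csv(path) -> pd.DataFrame:
    """Read LAI observations: treatment_id, gdd, lai — or census columns.

    A census-style file carries branches, leaves_per_branch, mean_leaf_area
    and ground_area instead of lai; LAI is then computed row by row.
    """
    df = pd.read_csv(path)
    if "lai" not in df.columns:
        census_cols = ["branches", "leaves_per_branch", "mean_leaf_area", "ground_area"]
        if not set(census_cols) <= set(df.columns):
            raise ValidationError("need either a lai column or full census columns")
        df["lai"] = [
            lai_from_census(r.branches, r.leaves_per_branch, r.mean_leaf_area, r.ground_area)
            for r in df.itertuples()
        ]
    return df[["treatment_id", "gdd", "lai"]]
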