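"""Virtual conditioner-trial generator.

Generates field-trial tables with the statistical structure the analysis
chain assumes, so every stage can be exercised and checked without any
field data: a ten-treatment design (three conditioners at three rates
each plus an untreated control), single-peak relative-LAI trajectories
over a thermal-time grid, concave quadratic dose-responses of maximum
LAI to application rate, a saturating LAI-dry-matter link, and a
near-constant harvest index with small treatment scatter.

Noise model: LAI noise is multiplicative (CV-style), matching the
roughly scale-proportional spread of replicated canopy measurements;
harvest-index jitter is additive and small, reflecting how tightly HI
clusters across treatments.  All generators are pure functions of
(design, seed).

What this emulates — and what it does not: real trials have plot-level
spatial heterogeneity, measurement error correlated within a sampling
date, and weather-driven departures from a smooth thermal-time response;
none of those are modelled.  Passing recovery tests on these tables
shows the estimators are consistent under the model's own assumptions,
not that the assumptions hold in any particular field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._exceptions import ValidationError
from .biomass import MichaelisMentenRelation
from .growth import evaluate

__all__ = ["TrialDesign", "SyntheticTrial", "gen_temperature", "gen_trial", "recovery_report"]


def _default_rates():
    return {
        "PAM": (0.75, 1.5, 3.0),
        "FA": (75.0, 150.0, 300.0),
        "gypsum": (199.5, 400.5, 501.0),
    }


def _default_grid():
    return (368.5, 558.2, 725.4, 996.4, 1221.7, 1639.0, 1894.1, 2513.6)


#: shared intercept: the control's LAI_m, which anchors every conditioner's
#: curve at rate 0 — one control observation must lie on all three quadratics,
#: so a self-consistent truth uses a common c0 (the reference trial's fitted
#: intercepts straddle this value because each was estimated separately).
_CONTROL_LAI_M = 2.27


def _default_quadratics():
    return {
        "PAM": (-0.1463, 0.5196, _CONTROL_LAI_M),
        "FA": (-1.5522e-5, 4.6446e-3, _CONTROL_LAI_M),
        "gypsum": (-7.3212e-6, 3.2596e-3, _CONTROL_LAI_M),
    }


@dataclass(frozen=True)
class TrialDesign:
    """Ground truth and noise levels for one virtual trial.

    Defaults mirror the bundled reference trial: its treatment design and
    thermal-time grid, its fitted modified-Gaussian growth-curve shape
    (amplitude 1: the true relative curve peaks at 1 by definition), its
    quadratic maximum-LAI dose-responses (with a shared intercept equal to
    the control's LAI_m, so the single control is consistent with every
    conditioner's curve), its saturating biomass link and its mean harvest
    index.  ``hi_sd`` defaults to the observed
    between-treatment HI scatter (0.0115); LAI and biomass noise default
    to a 2% coefficient of variation, in line with the mid/late-season
    relative spread of the reference RLAI table.
    """

    seed: int
    conditioner_rates: Mapping[str, tuple] = field(default_factory=_default_rates)
    gdd_grid: tuple = field(default_factory=_default_grid)
    rlai_form: str = "modified_gaussian"
    rlai_params: Mapping[str, float] = field(
        default_factory=lambda: {"amplitude": 1.0, "a": 1772.9780, "b": 928.9753, "c": 4.4947}
    )
    lai_m_quadratics: Mapping[str, tuple] = field(default_factory=_default_quadratics)
    control_lai_m: float = _CONTROL_LAI_M
    mm_p: float = 10.1317
    mm_q: float = 1.6312
    harvest_index: float = 0.5148
    rlai_sd: float = 0.02
    biomass_cv: float = 0.02
    hi_sd: float = 0.0115

    def __post_init__(self):
        if min(self.rlai_sd, self.biomass_cv, self.hi_sd) < 0:
            raise ValidationError("noise levels must be nonnegative")
        if not 0 < self.harvest_index < 1:
            raise ValidationError("harvest index must lie in (0, 1)")

    def treatments(self) -> pd.DataFrame:
        """The design table: treatment_id, conditioner, rate, true lai_m."""
        rows, i = [], 1
        for cond, rates in self.conditioner_rates.items():
            c2, c1, c0 = self.lai_m_quadratics[cond]
            for rate in rates:
                rows.append((f"X{i}", cond, rate, c2 * rate**2 + c1 * rate + c0))
                i += 1
        rows.append((f"X{i}", "none", 0.0, self.control_lai_m))
        return pd.DataFrame(rows, columns=["treatment_id", "conditioner", "rate", "lai_m_true"])


@dataclass(frozen=True)
class SyntheticTrial:
    """Generated tables, shaped like the readers of the analysis chain expect."""

    design: TrialDesign
    lai_observations: pd.DataFrame  # treatment_id, gdd, lai
    results: pd.DataFrame  # treatment_id, conditioner, rate, yield_, dry_biomass, ...
    temperature: pd.DataFrame  # day_of_year, t_max, t_min


def gen_temperature(
    seed: int,
    n_days: int = 365,
    mean_annual: float = 12.0,
    amplitude: float = 16.0,
    noise_sd: float = 1.5,
    diurnal_half_range: float = 5.0,
) -> pd.DataFrame:
    """Sinusoidal seasonal temperature cycle with seeded day-to-day noise.

    The daily mean follows mean_annual - amplitude*cos(2*pi*(d-15)/365)
    (coldest mid-January), and max/min sit a fixed half-range above and
    below the jittered mean, so t_max >= t_min holds by construction.
    """
    if n_days < 1:
        raise ValidationError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    d = np.arange(1, n_days + 1)
    t_mean = mean_annual - amplitude * np.cos(2 * np.pi * (d - 15) / 365.0)
    t_mean = t_mean + rng.normal(0.0, noise_sd, size=n_days)
    return pd.DataFrame(
        {
            "day_of_year": d,
            "t_max": t_mean + diurnal_half_range,
            "t_min": t_mean - diurnal_half_range,
        }
    )


def gen_trial(design: TrialDesign) -> SyntheticTrial:
    """Generate one trial: LAI trajectories, per-treatment results, weather.

    Per treatment: the true maximum LAI comes from that conditioner's
    quadratic; LAI(g) = LAI_m * RLAI_true(g) * (1 + eps) with
    eps ~ N(0, rlai_sd); peak dry matter inverts the true saturating
    link (with CV-style jitter); yield applies the jittered harvest
    index; total biomass is their sum.
    """
    rng = np.random.default_rng(design.seed)
    mm = MichaelisMentenRelation.from_parameters(design.mm_p, design.mm_q)
    treatments = design.treatments()
    if (treatments["lai_m_true"] >= mm.asymptote_).any():
        bad = treatments.loc[
            treatments["lai_m_true"] >= mm.asymptote_, "treatment_id"
        ].tolist()
        raise ValidationError(f"true lai_m beyond the MM asymptote for {bad}")

    grid = np.asarray(design.gdd_grid, dtype=float)
    rlai_true = evaluate(design.rlai_form, design.rlai_params, grid)

    lai_rows, result_rows = [], []
    for row in treatments.itertuples():
        eps = rng.normal(0.0, design.rlai_sd, size=grid.size)
        lai = row.lai_m_true * rlai_true * (1.0 + eps)
        lai = np.maximum(lai, 0.0)
        for g, v in zip(grid, lai):
            lai_rows.append((row.treatment_id, g, v))

        m_m = mm.dry_matter(row.lai_m_true) * (1.0 + rng.normal(0.0, design.biomass_cv))
        hi = float(np.clip(design.harvest_index + rng.normal(0.0, design.hi_sd), 1e-3, 1 - 1e-3))
        y = hi / (1.0 - hi) * m_m
        result_rows.append(
            (row.treatment_id, row.conditioner, row.rate, y, m_m, m_m + y, y / (m_m + y))
        )

    return SyntheticTrial(
        design=design,
        lai_observations=pd.DataFrame(lai_rows, columns=["treatment_id", "gdd", "lai"]),
        results=pd.DataFrame(
            result_rows,
            columns=[
                "treatment_id",
                "conditioner",
                "rate",
                "yield_",
                "dry_biomass",
                "total_biomass",
                "harvest_index",
            ],
        ),
        temperature=gen_temperature(design.seed),
    )


def _truth_map(design: TrialDesign) -> dict:
    truths = {
        "p": design.mm_p,
        "q": design.mm_q,
        "harvest_index": design.harvest_index,
    }
    for name, value in design.rlai_params.items():
        truths[f"rlai_{name}"] = value
    for cond, (c2, c1, c0) in design.lai_m_quadratics.items():
        truths[f"{cond}_c2"] = c2
        truths[f"{cond}_c1"] = c1
        truths[f"{cond}_c0"] = c0
        if c2 < 0:
            truths[f"{cond}_rate_star"] = -c1 / (2.0 * c2)
    return truths


def recovery_report(design: TrialDesign, estimates: Mapping[str, float]) -> pd.DataFrame:
    """Relative error of pipeline estimates against the design's truths.

    ``estimates`` maps parameter names (``p``, ``q``, ``harvest_index``,
    ``rlai_<param>``, ``<conditioner>_c2/c1/c0``, ``<conditioner>_rate_star``)
    to fitted values; only names present in both the estimates and the
    design are reported.
    """
    if not estimates:
        raise ValidationError("empty pipeline output")
    truths = _truth_map(design)
    rows = []
    for name, est in estimates.items():
        if name not in truths:
            continue
        true = truths[name]
        rel = abs(est - true) / abs(true) if true != 0 else np.inf
        rows.append((name, true, est, rel))
    if not rows:
        raise ValidationError("no estimate matches a design parameter")
    return pd.DataFrame(rows, columns=["parameter", "true", "estimated", "relative_error"])
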