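"""Bundled calibration dataset: a drip-irrigated cotton field trial with
three soil conditioners on saline-alkali sandy soil (Korla, Xinjiang,
2011 season).

Ten treatments: polyacrylamide (PAM) at 0.75/1.5/3.0 g m-2, fulvic acid
(FA) at 75/150/300 g m-2, gypsum at 199.5/400.5/501.0 g m-2, and an
untreated control.  The tables shipped here are the trial's published
summary numbers — the relative-LAI grid for the six calibration
treatments, per-treatment yield and biomass, the fitted growth-curve
parameterizations, the quadratic dose-response coefficients for maximum
LAI and water-use efficiency, and the saturating LAI-dry-matter
parameters — and serve as reference inputs for the model chain and its
tests.  Mass-area quantities are converted to the package's canonical
kg m-2 at this boundary (the source tables print t/ha).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "treatment_design",
    "rlai_table",
    "biomass_table",
    "validation_table",
    "growth_curve_parameters",
    "lai_m_dose_response",
    "wue_dose_response",
    "mm_parameters",
    "reference_harvest_index",
    "wue_laim_line",
    "CALIBRATION_IDS",
    "VALIDATION_IDS",
]

#: treatments used to build the models vs. those held out to test them
CALIBRATION_IDS = ("X1", "X2", "X4", "X5", "X7", "X8")
VALIDATION_IDS = ("X3", "X6", "X9", "X10")


def treatment_design() -> pd.DataFrame:
    """Conditioner type and application rate (g m-2) for the ten treatments."""
    rows = [
        ("X1", "PAM", 0.75),
        ("X2", "PAM", 1.5),
        ("X3", "PAM", 3.0),
        ("X4", "FA", 75.0),
        ("X5", "FA", 150.0),
        ("X6", "FA", 300.0),
        ("X7", "gypsum", 199.5),
        ("X8", "gypsum", 400.5),
        ("X9", "gypsum", 501.0),
        ("X10", "none", 0.0),
    ]
    return pd.DataFrame(rows, columns=["treatment_id", "conditioner", "rate"])


def rlai_table() -> pd.DataFrame:
    """Relative LAI on the eight-point GDD grid for the six calibration
    treatments, with the published mean and sample SD columns."""
    cols = ["gdd", "X1", "X2", "X4", "X5", "X7", "X8", "mean_rlai", "sample_sd"]
    rows = [
        (368.5, 0.03, 0.04, 0.04, 0.03, 0.03, 0.03, 0.03, 0.0052),
        (558.2, 0.16, 0.18, 0.19, 0.20, 0.19, 0.19, 0.19, 0.0138),
        (725.4, 0.44, 0.40, 0.46, 0.46, 0.41, 0.44, 0.43, 0.0251),
        (996.4, 0.74, 0.80, 0.81, 0.82, 0.78, 0.82, 0.79, 0.0308),
        (1221.7, 0.93, 0.94, 0.93, 0.93, 0.94, 0.92, 0.93, 0.0075),
        (1639.0, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 0.0),
        (1894.1, 0.97, 0.97, 0.99, 0.99, 0.98, 0.99, 0.99, 0.0098),
        (2513.6, 0.82, 0.84, 0.83, 0.84, 0.83, 0.83, 0.83, 0.0071),
    ]
    return pd.DataFrame(rows, columns=cols)


def biomass_table() -> pd.DataFrame:
    """Yield, dry biomass, total biomass (kg m-2) and harvest index per
    treatment at the end of the wadding stage (source units t/ha, x0.1)."""
    rows = [
        ("X1", 4.4400, 4.0400, 8.4800, 0.5236),
        ("X2", 4.6500, 4.6012, 9.2512, 0.5026),
        ("X3", 4.1700, 4.1503, 8.3203, 0.5012),
        ("X4", 4.5225, 4.4306, 8.9531, 0.5051),
        ("X5", 4.7550, 4.3552, 9.1102, 0.5219),
        ("X6", 3.9675, 3.8347, 7.8022, 0.5085),
        ("X7", 4.9350, 4.4054, 9.3404, 0.5284),
        ("X8", 3.9225, 3.4272, 7.3497, 0.5337),
        ("X9", 3.8550, 3.6157, 7.4707, 0.5160),
        ("X10", 3.2100, 3.1220, 6.3320, 0.5070),
    ]
    df = pd.DataFrame(
        rows, columns=["treatment_id", "yield_", "dry_biomass", "total_biomass", "harvest_index"]
    )
    for col in ("yield_", "dry_biomass", "total_biomass"):
        df[col] = df[col] * 0.1  # t/ha -> kg/m^2
    return df


def validation_table() -> pd.DataFrame:
    """Held-out treatments: maximum LAI with observed dry matter and yield
    (kg m-2), against which model simulations are compared."""
    rows = [
        ("X3", 2.47, 0.415, 0.417),
        ("X6", 2.28, 0.353, 0.397),
        ("X9", 2.29, 0.362, 0.3855),
    ]
    return pd.DataFrame(
        rows, columns=["treatment_id", "lai_m", "observed_dry_matter", "observed_yield"]
    )


def growth_curve_parameters() -> dict:
    """Published parameterizations of the five RLAI(GDD) growth-curve forms.

    Keys are form names; values are parameter dicts in this package's
    conventions (``amplitude`` is the peak multiplier of the exponential
    forms).
    """
    return {
        "modified_gaussian": {"amplitude": 0.9968, "a": 1772.9780, "b": 928.9753, "c": 4.4947},
        "log_normal": {"amplitude": 1.0298, "a": 1638.4502, "b": 0.6294},
        "modified_logistic": {"amplitude": 1.03, "a": 7.2955, "b": -0.01191, "c": 3.3565e-6},
        "cubic_polynomial": {"a0": -0.6533, "a1": 2.1006e-3, "a2": -7.7320e-7, "a3": 6.8419e-11},
        "gaussian": {"amplitude": 1.1186, "a": 1856.3693, "b": 810.3980},
    }


def lai_m_dose_response() -> dict:
    """Quadratic coefficients (c2, c1, c0) of maximum LAI vs application
    rate per conditioner: LAI_m = c2*I^2 + c1*I + c0, I in g m-2."""
    return {
        "PAM": (-0.1463, 0.5196, 2.2341),
        "FA": (-1.5522e-5, 4.6446e-3, 2.2781),
        "gypsum": (-7.3212e-6, 3.2596e-3, 2.3018),
    }


def wue_dose_response() -> dict:
    """Quadratic coefficients (c2, c1, c0) of water-use efficiency
    (kg ha-1 mm-1) vs application rate per conditioner."""
    return {
        "PAM": (-0.9799, 3.4987, 5.8941),
        "FA": (-1.0229e-4, 3.5089e-2, 5.9337),
        "gypsum": (-3.7585e-5, 2.0064e-2, 5.9689),
    }


def mm_parameters() -> tuple[float, float]:
    """(P, Q) of the saturating LAI = P*M/(1 + Q*M) link, M in kg m-2."""
    return (10.1317, 1.6312)


def reference_harvest_index() -> float:
    """Mean harvest index over the trial's ten treatments."""
    return 0.5148


def wue_laim_line() -> tuple[float, float]:
    """(slope, intercept) of the linear LAI_m = slope*WUE + intercept relation."""
    return (0.2383, 0.2774)
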