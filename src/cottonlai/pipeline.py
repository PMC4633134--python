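"""End-to-end orchestration: calibrate the model chain, validate it on
held-out treatments, and emit report tables.

Calibration fits, on the calibration treatments only: the mean relative
LAI curve and the five growth-curve forms, the saturating LAI-dry-matter
link, and the mean harvest index.  The quadratic dose-response stage is
the one exception to the split: a conditioner contributes only two
non-zero rates to the calibration set, so its quadratic is fitted on
every treatment with a maximum LAI (including the control that anchors
rate 0) — exactly how the reference trial's dose curves were built.

Validation reconstructs each held-out treatment's absolute LAI
trajectory through the universal model LAI = LAI_m * RLAI(g), scores it
(R^2, Re, RMSE), and compares predicted peak dry matter and yield with
the observations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import ValidationError
from .biomass import MichaelisMentenRelation, YieldModel, mean_hi
from .canopy import aggregate_mean_sd, normalize_rlai
from .dose import QuadraticDoseResponse
from .growth import MODEL_FORMS, RLAIGrowthModel, compare, universal_lai
from .metrics import fit_metrics
from .thermal import ThermalConfig

logger = logging.getLogger("cottonlai.pipeline")

__all__ = ["PipelineConfig", "CalibrationBundle", "run_calibration", "run_validation"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration shared by the calibration and validation stages."""

    thermal: ThermalConfig = field(default_factory=ThermalConfig)
    universal_form: str = "modified_logistic"
    calibration_ids: tuple = ("X1", "X2", "X4", "X5", "X7", "X8")
    validation_ids: tuple = ("X3", "X6", "X9", "X10")
    hi_override: float | None = None
    seed: int = 0
    mm_method: str = "linearized"

    def __post_init__(self):
        overlap = set(self.calibration_ids) & set(self.validation_ids)
        if overlap:
            raise ValidationError(f"calibration and validation sets overlap: {sorted(overlap)}")
        if self.universal_form not in MODEL_FORMS:
            raise ValidationError(f"unknown universal model form {self.universal_form!r}")


@dataclass
class CalibrationBundle:
    """Everything fitted during calibration."""

    rlai_fits: Mapping[str, RLAIGrowthModel]
    comparison: pd.DataFrame
    mean_curve: pd.DataFrame  # gdd, mean_rlai, sample_sd
    lai_m: pd.Series  # per treatment, all treatments
    mm: MichaelisMentenRelation
    hi_mean: float
    hi_sd: float
    hi_used: float
    dose_fits: Mapping[str, QuadraticDoseResponse]
    yield_model: YieldModel


def _require_treatments(table: pd.DataFrame, ids: Sequence[str], what: str):
    present = set(table["treatment_id"].unique())
    missing = [t for t in ids if t not in present]
    if missing:
        raise ValidationError(f"{what} treatments missing from table: {missing}")


def run_calibration(
    config: PipelineConfig,
    lai_observations: pd.DataFrame,
    results: pd.DataFrame,
    design: pd.DataFrame | None = None,
) -> CalibrationBundle:
    """Fit the full model chain on the calibration treatments.

    Parameters
    ----------
    lai_observations : treatment_id, gdd, lai — all treatments.
    results : treatment_id, yield_, dry_biomass (kg m-2) and optionally
        total_biomass; conditioner/rate columns are taken from here when
        ``design`` is not given.
    design : optional treatment_id, conditioner, rate table.
    """
    if len(lai_observations) == 0:
        raise ValidationError("empty LAI table")
    _require_treatments(lai_observations, config.calibration_ids, "calibration")
    _require_treatments(results, config.calibration_ids, "calibration")

    normalized = normalize_rlai(lai_observations)
    calib_norm = normalized[normalized["treatment_id"].isin(config.calibration_ids)]
    mean_curve = aggregate_mean_sd(calib_norm)
    logger.info(
        "stage=rlai n_treatments=%d n_grid=%d",
        calib_norm["treatment_id"].nunique(),
        len(mean_curve),
    )

    fits = {}
    for form in MODEL_FORMS:
        fits[form] = RLAIGrowthModel(form=form, random_state=config.seed).fit(
            mean_curve["gdd"], mean_curve["mean_rlai"]
        )
        logger.info("stage=fit form=%s rmse=%.5f", form, fits[form].metrics_.rmse)
    comparison = compare(list(fits.values()))

    lai_m = normalized.groupby("treatment_id")["lai"].max()

    calib_results = results[results["treatment_id"].isin(config.calibration_ids)]
    calib_lai_m = lai_m.loc[calib_results["treatment_id"]].to_numpy()
    mm = MichaelisMentenRelation(method=config.mm_method).fit(
        calib_results["dry_biomass"].to_numpy(), calib_lai_m
    )
    logger.info("stage=mm method=%s p=%.4f q=%.4f", config.mm_method, mm.p_, mm.q_)

    if "harvest_index" in calib_results.columns:
        hi_values = calib_results["harvest_index"].to_numpy()
    else:
        hi_values = (
            calib_results["yield_"] / (calib_results["yield_"] + calib_results["dry_biomass"])
        ).to_numpy()
    hi_mean, hi_sd = mean_hi(hi_values)
    hi_used = config.hi_override if config.hi_override is not None else hi_mean
    logger.info("stage=hi mean=%.4f sd=%.4f used=%.4f", hi_mean, hi_sd, hi_used)

    meta = design if design is not None else results
    if not {"conditioner", "rate"} <= set(meta.columns):
        raise ValidationError("need conditioner and rate columns (results or design table)")
    meta = meta[["treatment_id", "conditioner", "rate"]].drop_duplicates("treatment_id")
    dose_table = meta.merge(lai_m.rename("lai_m"), on="treatment_id")
    control = dose_table[dose_table["conditioner"] == "none"]
    dose_fits = {}
    for cond, grp in dose_table[dose_table["conditioner"] != "none"].groupby("conditioner"):
        pts = pd.concat([grp, control])
        dose_fits[cond] = QuadraticDoseResponse(response_name="LAI_m").fit(
            pts["rate"].to_numpy(), pts["lai_m"].to_numpy()
        )
        logger.info("stage=dose conditioner=%s coef=%s", cond, dose_fits[cond].coef_)

    bundle = CalibrationBundle(
        rlai_fits=fits,
        comparison=comparison,
        mean_curve=mean_curve,
        lai_m=lai_m,
        mm=mm,
        hi_mean=hi_mean,
        hi_sd=hi_sd,
        hi_used=hi_used,
        dose_fits=dose_fits,
        yield_model=YieldModel(hi_used, mm),
    )
    return bundle


def run_validation(
    config: PipelineConfig,
    bundle: CalibrationBundle,
    lai_observations: pd.DataFrame,
    results: pd.DataFrame,
) -> pd.DataFrame:
    """Score the calibrated chain on the held-out treatments.

    Returns one row per validation treatment: universal-LAI fit metrics
    and the observed vs simulated peak dry matter and yield with percent
    deviations.  A treatment absent from the results table is skipped
    with a logged warning.
    """
    form = config.universal_form
    if form not in bundle.rlai_fits:
        raise ValidationError(f"bundle has no fit for configured form {form!r}")
    fit = bundle.rlai_fits[form]

    rows = []
    for tid in config.validation_ids:
        obs = lai_observations[lai_observations["treatment_id"] == tid]
        if len(obs) == 0:
            logger.warning("stage=validate treatment=%s skipped: no LAI observations", tid)
            continue
        lai_m = float(obs["lai"].max())
        if lai_m <= 0:
            logger.warning("stage=validate treatment=%s skipped: no positive LAI", tid)
            continue
        sim = universal_lai(fit, lai_m, obs["gdd"].to_numpy())
        m = fit_metrics(obs["lai"].to_numpy(), sim)

        row = {
            "treatment_id": tid,
            "lai_m": lai_m,
            "form": form,
            "r_squared": m.r_squared,
            "re_percent": m.re_percent,
            "rmse": m.rmse,
        }
        res = results[results["treatment_id"] == tid]
        if len(res) == 1:
            obs_m = float(res["dry_biomass"].iloc[0])
            obs_y = float(res["yield_"].iloc[0])
            sim_m = bundle.yield_model.predict_dry_matter(lai_m)
            sim_y = bundle.yield_model.predict(lai_m)
            row.update(
                observed_dry_matter=obs_m,
                simulated_dry_matter=sim_m,
                dry_matter_deviation_pct=100.0 * (sim_m - obs_m) / obs_m,
                observed_yield=obs_y,
                simulated_yield=sim_y,
                yield_deviation_pct=100.0 * (sim_y - obs_y) / obs_y,
            )
        else:
            logger.warning("stage=validate treatment=%s no results row; LAI metrics only", tid)
        rows.append(row)
    if not rows:
        raise ValidationError("no validation treatment could be scored")
    report = pd.DataFrame(rows)
    logger.info("stage=validate n=%d mean_rmse=%.4f", len(report), report["rmse"].mean())
    return report
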