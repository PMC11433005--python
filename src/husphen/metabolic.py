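"""Body-composition and blood-chemistry derived indices.

Per-mouse longitudinal operations (body-weight gain, food efficiency ratio)
work on cohort-table slices; scalar conversions (caloric intake, HOMA-IR,
hyperglycemia flag, liver/body-weight ratio) work on single records. The
homeostatic model assessment of insulin resistance uses the murine-adjusted
unit chain: insulin ng/mL -> pmol/L (x 172.18) -> uIU/mL (/ 6); glucose
mg/dL -> mmol/L (x 0.0555); HOMA-IR = insulin(uIU/mL) x glucose(mmol/L) / 22.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    AmbiguityError,
    ConfigurationError,
    DomainError,
    MissingDataError,
    UndefinedValueError,
    ValidationError,
    WrongContextError,
)

INSULIN_NG_TO_PMOL = 172.18
INSULIN_PMOL_TO_UIU = 6.0
GLUCOSE_MG_TO_MMOL = 0.0555
HOMA_DENOMINATOR = 22.5

#: Non-fasting blood glucose threshold (mg/dL) flagging hyperglycemia.
HYPERGLYCEMIA_MG_DL = 250.0

DAYS_PER_WEEK = 7.0


@dataclass(frozen=True)
class InsulinIndices:
    insulin_uIU_mL: float
    glucose_mmol_L: float
    homa_ir: float


def _one_mouse(records: pd.DataFrame) -> pd.DataFrame:
    if records.empty:
        raise ValidationError("need at least one record")
    if "mouse_id" in records.columns and records["mouse_id"].nunique() > 1:
        raise ValidationError("records span multiple mice")
    if records["age_weeks"].duplicated().any():
        dup = records.loc[records["age_weeks"].duplicated(), "age_weeks"]
        raise AmbiguityError(f"duplicate (mouse, age) rows at weeks {list(dup)}")
    return records.sort_values("age_weeks")


def bw_gain(records: pd.DataFrame) -> pd.Series:
    """Body-weight change (g) from the earliest-age measurement.

    Returns a series indexed by ``age_weeks``; the baseline gain is 0 by
    construction.
    """
    recs = _one_mouse(records)
    gain = recs["bw"] - recs["bw"].iloc[0]
    gain.index = pd.Index(recs["age_weeks"], name="age_weeks")
    gain.name = "bw_gain"
    return gain


def fer(records: pd.DataFrame, mode: str = "grams",
        cumulative: bool = True) -> pd.Series:
    """Food efficiency ratio (%) by week.

    ``grams`` mode: 100 x cumulative BW gain (g) / cumulative food intake
    (g); ``kcal`` mode divides by cumulative energy intake instead. Weekly
    intake is 7 x the recorded average daily intake. ``cumulative=False``
    exposes the per-week variant (week-on-week gain over that week's
    intake).
    """
    if mode not in ("grams", "kcal"):
        raise ValidationError("mode must be 'grams' or 'kcal'")
    recs = _one_mouse(records)
    weekly_g = recs["food_intake_daily"].to_numpy() * DAYS_PER_WEEK
    if mode == "kcal":
        if recs["kcal_per_g"].isna().any():
            raise ConfigurationError("kcal_per_g missing for kcal-mode FER")
        weekly = weekly_g * recs["kcal_per_g"].to_numpy()
    else:
        weekly = weekly_g
    gain = (recs["bw"] - recs["bw"].iloc[0]).to_numpy()
    if cumulative:
        intake = np.cumsum(weekly)
    else:
        intake = weekly
        gain = np.concatenate([[0.0], np.diff(recs["bw"].to_numpy())])
    if np.any(intake <= 0):
        week = recs["age_weeks"].to_numpy()[np.argmax(intake <= 0)]
        raise UndefinedValueError(f"zero cumulative intake at week {week}")
    out = pd.Series(100.0 * gain / intake,
                    index=pd.Index(recs["age_weeks"], name="age_weeks"),
                    name=f"fer_{mode}")
    return out


def caloric_intake(food_intake_daily_g: float, kcal_per_g: float) -> float:
    """Daily energy intake (kcal/day) from mass intake and diet density."""
    if kcal_per_g is None or (isinstance(kcal_per_g, float)
                              and np.isnan(kcal_per_g)):
        raise ConfigurationError("kcal_per_g is missing")
    if food_intake_daily_g < 0:
        raise DomainError("food intake must be >= 0")
    return food_intake_daily_g * kcal_per_g


def homa_ir(insulin_ng_mL: float, glucose_mg_dL: float) -> InsulinIndices:
    """HOMA-IR with the murine unit conversions applied.

    Caller asserts fasting samples; negative inputs raise
    :class:`~husphen.errors.DomainError`.
    """
    if insulin_ng_mL < 0 or glucose_mg_dL < 0:
        raise DomainError("insulin and glucose must be >= 0")
    insulin_uiu = insulin_ng_mL * INSULIN_NG_TO_PMOL / INSULIN_PMOL_TO_UIU
    glucose_mmol = glucose_mg_dL * GLUCOSE_MG_TO_MMOL
    return InsulinIndices(
        insulin_uIU_mL=insulin_uiu,
        glucose_mmol_L=glucose_mmol,
        homa_ir=insulin_uiu * glucose_mmol / HOMA_DENOMINATOR,
    )


def flag_hyperglycemia(glucose_mg_dL: float, fasting: bool) -> bool:
    """True iff a non-fasting glucose value is >= 250 mg/dL."""
    if fasting:
        raise WrongContextError(
            "hyperglycemia threshold applies to non-fasting samples only")
    return bool(glucose_mg_dL >= HYPERGLYCEMIA_MG_DL)


def liver_bw_ratio(liver_weight_g: float, bw_g: float) -> float:
    """Hepatomegaly index: liver weight as a percentage of body weight."""
    if liver_weight_g is None or (isinstance(liver_weight_g, float)
                                  and np.isnan(liver_weight_g)):
        raise MissingDataError("liver_weight is missing")
    if bw_g <= 0:
        raise DomainError("body weight must be > 0")
    return 100.0 * liver_weight_g / bw_g


def derive_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Derived-variable table: one row per mouse x week.

    Adds body-weight gain, cumulative FER in both denominations, daily
    caloric intake, the non-fasting hyperglycemia flag, and (where the
    inputs are present) HOMA-IR and the liver/BW percentage.
    """
    out = []
    for mouse_id, recs in cohort.groupby("mouse_id", sort=False):
        recs = recs.sort_values("age_weeks").copy()
        recs["bw_gain"] = bw_gain(recs).to_numpy()
        recs["fer_grams"] = fer(recs, "grams").to_numpy()
        recs["fer_kcal"] = fer(recs, "kcal").to_numpy()
        recs["caloric_intake"] = (recs["food_intake_daily"]
                                  * recs["kcal_per_g"])
        recs["hyperglycemia"] = [
            flag_hyperglycemia(g, f) if not f and not np.isnan(g) else pd.NA
            for g, f in zip(recs["glucose"], recs["fasting"])
        ]
        homa = []
        for _, row in recs.iterrows():
            if row["fasting"] and not np.isnan(row.get("insulin", np.nan)) \
                    and not np.isnan(row.get("glucose", np.nan)):
                homa.append(homa_ir(row["insulin"], row["glucose"]).homa_ir)
            else:
                homa.append(np.nan)
        recs["homa_ir"] = homa
        recs["liver_bw_pct"] = [
            liver_bw_ratio(lw, bw) if not np.isnan(lw) else np.nan
            for lw, bw in zip(recs["liver_weight"], recs["bw"])
        ]
        out.append(recs)
    return pd.concat(out, ignore_index=True)
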