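"""Derivation of analysis variables from raw cohort tables.

Covers BMI, LMS z-scores, maternal and child BMI categories, gestational
weight gain (GWG) with its Institute of Medicine (IOM) adequacy
classification, and selection of the age-4 outcome measurement (last
height-weight pair recorded between 48 and 59 months).

Units: weight kg, height cm, age months internally; GWG is reported in
pounds because the IOM adequacy ranges are stated in pounds
(1 lb = 0.45359237 kg exactly).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .errors import DomainError, UnderweightExclusion
from .lms import LMSTable

logger = logging.getLogger(__name__)

KG_PER_LB = 0.45359237

#: z-score cutoffs for the child BMI categories, defined through the
#: standard normal quantiles of the 5th/85th/95th percentiles.
Z_P05 = float(ndtri(0.05))
Z_P85 = float(ndtri(0.85))
Z_P95 = float(ndtri(0.95))

#: IOM adequacy ranges (lbs) by pre-pregnancy BMI category.  Closed
#: intervals: gains on either endpoint count as adequate.  The
#: underweight range is carried for completeness but unused because
#: underweight mothers are excluded from the analysis.
IOM_RANGES_LBS = {
    "underweight": (28.0, 40.0),
    "normal": (25.0, 35.0),
    "overweight": (15.0, 25.0),
    "obese": (11.0, 20.0),
}

#: Age window (months) in which the outcome measurement must fall.
AGE4_WINDOW = (48.0, 59.0)

MAX_DELIVERY_GAP_DAYS = 7


def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """BMI = weight (kg) / height (m)^2."""
    weight = np.asarray(weight_kg, dtype=float)
    height = np.asarray(height_cm, dtype=float)
    if np.any(weight <= 0) or np.any(height <= 0):
        raise DomainError("weight and height must be positive for BMI")
    bmi = weight / (height / 100.0) ** 2
    return bmi.item() if bmi.ndim == 0 else bmi


def classify_child_bmi(z) -> str:
    """Category from a BMI-for-age z-score.

    underweight: z < 5th pct; normal: [5th, 85th); overweight:
    [85th, 95th); obese: >= 95th percentile of the reference normal.
    """
    z_arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z_arr)):
        raise DomainError("z-score must be finite for classification")
    cats = np.select(
        [z_arr < Z_P05, z_arr < Z_P85, z_arr < Z_P95],
        ["underweight", "normal", "overweight"],
        default="obese",
    )
    return cats.item() if cats.ndim == 0 else cats


def classify_maternal_bmi(bmi: float) -> str:
    """Maternal pre-pregnancy BMI category; < 18.5 signals exclusion."""
    if not np.isfinite(bmi):
        raise DomainError("maternal BMI must be finite")
    if bmi < 18.5:
        raise UnderweightExclusion(
            f"maternal BMI {bmi:.1f} < 18.5; underweight mothers are excluded")
    if bmi < 25.0:
        return "normal"
    if bmi < 30.0:
        return "overweight"
    return "obese"


def compute_gwg(weight_lmp_kg: float, weight_delivery_kg: float,
                delivery_gap_days: float) -> float:
    """Gestational weight gain in lbs, or NaN if the last weight is stale.

    GWG is the difference between the weight at last menstrual period and
    the last weight measured no more than 7 days before delivery; a
    larger gap invalidates the measurement and GWG is set missing.
    Negative gains (weight loss) are allowed.
    """
    if weight_lmp_kg <= 0 or weight_delivery_kg <= 0:
        raise DomainError("weights must be positive for GWG")
    if delivery_gap_days > MAX_DELIVERY_GAP_DAYS:
        logger.info("GWG rejected: last weight %.0f days before delivery",
                    delivery_gap_days)
        return float("nan")
    return (weight_delivery_kg - weight_lmp_kg) / KG_PER_LB


def classify_gwg(gwg_lbs: float, maternal_category: str) -> tuple[str, int]:
    """IOM adequacy category and the binary excessive-GWG mediator.

    Returns ``(category, mediator)`` with mediator 1 iff excessive.
    Adequate is the closed IOM interval for the mother's pre-pregnancy
    BMI category; below is inadequate, above is excessive.
    """
    if maternal_category not in IOM_RANGES_LBS:
        raise DomainError(f"unknown maternal BMI category {maternal_category!r}")
    if not np.isfinite(gwg_lbs):
        raise DomainError("GWG is missing; cannot classify")
    lo, hi = IOM_RANGES_LBS[maternal_category]
    if gwg_lbs < lo:
        return "inadequate", 0
    if gwg_lbs > hi:
        return "excessive", 1
    return "adequate", 0


def select_age4_measurement(records: pd.DataFrame) -> pd.Series | None:
    """Last record in the 48-59 month window with both height and weight.

    ``records`` is one child's growth table with columns ``age_months``,
    ``height_cm``, ``weight_kg``, sorted by age.  Returns the selected
    row or None when the child never visited in the window (excluded).
    """
    lo, hi = AGE4_WINDOW
    ok = records[(records["age_months"] >= lo) & (records["age_months"] <= hi)
                 & records["height_cm"].notna() & records["weight_kg"].notna()]
    if ok.empty:
        return None
    return ok.loc[ok["age_months"].idxmax()]


def derive_analysis_rows(mothers: pd.DataFrame, growth: pd.DataFrame,
                         lms: LMSTable) -> tuple[pd.DataFrame, dict]:
    """Build one analysis row per mother-child pair.

    Applies the exclusion rules (underweight mother; no usable
    measurement in the age-4 window; missing GWG after the 7-day rule
    leaves the mediator missing but keeps the row for imputation only if
    configured -- by default such rows are excluded).  Returns the
    analysis table and a per-rule exclusion count dict.
    """
    exclusions = {"underweight_mother": 0, "no_age4_visit": 0,
                  "missing_exposure": 0, "missing_mediator": 0}
    growth_by_child = dict(tuple(growth.groupby("child_id")))
    rows = []
    for rec in mothers.itertuples(index=False):
        rec = rec._asdict()
        mid = rec["mother_id"]
        try:
            bmi = compute_bmi(rec["weight_prepreg_kg"], rec["height_cm"])
        except DomainError:
            bmi = float("nan")
        if not np.isfinite(bmi):
            exclusions["missing_exposure"] += 1
            continue
        try:
            mcat = classify_maternal_bmi(bmi)
        except UnderweightExclusion as exc:
            logger.info("mother %s excluded: %s", mid, exc)
            exclusions["underweight_mother"] += 1
            continue
        child = growth_by_child.get(mid)
        sel = None if child is None else select_age4_measurement(
            child.sort_values("age_months"))
        if sel is None:
            exclusions["no_age4_visit"] += 1
            continue
        gwg = compute_gwg(rec["weight_lmp_kg"], rec["weight_delivery_kg"],
                          rec["delivery_gap_days"])
        if not np.isfinite(gwg):
            exclusions["missing_mediator"] += 1
            continue
        gcat, mediator = classify_gwg(gwg, mcat)
        child_bmi = compute_bmi(sel["weight_kg"], sel["height_cm"])
        z = lms.zscore(child_bmi, rec["child_sex"], sel["age_months"])
        rows.append({
            "mother_id": mid,
            "bmi": bmi,
            "maternal_category": mcat,
            "gwg_lbs": gwg,
            "gwg_category": gcat,
            "excessive_gwg": mediator,
            "child_z": z,
            "child_category": classify_child_bmi(z),
            "child_age_months": sel["age_months"],
            "race": rec["race"],
            "education": rec["education"],
            "smoking": rec["smoking"],
            "gdm": rec["gdm"],
            "cohort_period": rec["cohort_period"],
            "age_delivery": rec["age_delivery"],
            "cesarean": rec["cesarean"],
            "gestational_age_days": rec["gestational_age_days"],
            "child_sex": rec["child_sex"],
            "birth_weight_g": rec["birth_weight_g"],
            "parity": rec["parity"],
        })
    return pd.DataFrame(rows), exclusions
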