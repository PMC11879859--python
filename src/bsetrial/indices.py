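"""Closed-form derived clinical indices.

All functions are pure and vectorized over numpy arrays / pandas Series.

Conventions
-----------
* HOMA uses the closed-form (HOMA1) expressions
  ``HOMA-IR = G·I / 22.5`` and ``HOMA-B = 20·I / (G − 3.5)`` with glucose G
  in mmol/l and insulin I in mIE/l.  Externally computed HOMA2 values can be
  supplied as input columns instead; nothing downstream assumes HOMA1.
* The fatty liver index is the 0–100 logistic score of Bedogni and
  colleagues; its source formula expects triglycerides in mg/dl and GGT in
  U/l, so fixed conversions (1 mmol/l TG = 88.57 mg/dl; 1 μkat/l GGT =
  60 U/l) are applied internally — inputs stay in the units the trial
  recorded.
* IPAQ MET-minutes use the protocol constants 8.0 (vigorous), 4.0
  (moderate) and 3.3 (walking), with each activity capped at 180 min/day
  before scoring.
"""

from __future__ import annotations

from typing import Mapping, Tuple

import numpy as np
import pandas as pd

from .datamodel import DomainError

TG_MMOL_TO_MGDL = 88.57
GGT_UKAT_TO_UL = 60.0

IPAQ_MET = {"vigorous": 8.0, "moderate": 4.0, "walking": 3.3}
IPAQ_DAILY_CAP_MIN = 180.0


def homa_ir(glucose, insulin):
    """Insulin-resistance index: glucose [mmol/l] × insulin [mIE/l] / 22.5."""
    glucose = np.asarray(glucose, dtype=float)
    insulin = np.asarray(insulin, dtype=float)
    if np.any(insulin[~np.isnan(insulin)] <= 0):
        raise DomainError("insulin must be positive")
    return glucose * insulin / 22.5


def homa_b(glucose, insulin):
    """Beta-cell-function index: 20 × insulin / (glucose − 3.5).

    Undefined at glucose ≤ 3.5 mmol/l (the formula's pole).
    """
    glucose = np.asarray(glucose, dtype=float)
    insulin = np.asarray(insulin, dtype=float)
    if np.any(insulin[~np.isnan(insulin)] <= 0):
        raise DomainError("insulin must be positive")
    if np.any(glucose[~np.isnan(glucose)] <= 3.5):
        raise DomainError("HOMA-B undefined for glucose <= 3.5 mmol/l")
    return 20.0 * insulin / (glucose - 3.5)


def homa_indices(glucose, insulin) -> Tuple[np.ndarray, np.ndarray]:
    """Return ``(HOMA-IR, HOMA-B)`` for fasting glucose and insulin."""
    return homa_ir(glucose, insulin), homa_b(glucose, insulin)


def fatty_liver_index(bmi, waist, triglycerides, ggt):
    """Fatty liver index (0–100) from BMI [kg/m²], waist [cm],
    triglycerides [mmol/l] and GGT [μkat/l]."""
    bmi = np.asarray(bmi, dtype=float)
    waist = np.asarray(waist, dtype=float)
    tg = np.asarray(triglycerides, dtype=float)
    ggt = np.asarray(ggt, dtype=float)
    for name, arr in (("bmi", bmi), ("waist", waist),
                      ("triglycerides", tg), ("ggt", ggt)):
        if np.any(arr[~np.isnan(arr)] <= 0):
            raise DomainError(f"{name} must be positive")
    L = (
        0.953 * np.log(tg * TG_MMOL_TO_MGDL)
        + 0.139 * bmi
        + 0.718 * np.log(ggt * GGT_UKAT_TO_UL)
        + 0.053 * waist
        - 15.745
    )
    return 100.0 / (1.0 + np.exp(-L))


def bsa_du_bois(weight, height):
    """Du Bois body surface area [m²] from weight [kg] and height [cm]:
    0.007184 · weight^0.425 · height^0.725."""
    weight = np.asarray(weight, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(weight[~np.isnan(weight)] <= 0) or np.any(height[~np.isnan(height)] <= 0):
        raise DomainError("weight and height must be positive")
    return 0.007184 * weight**0.425 * height**0.725


def insulin_clearance(c_peptide, insulin):
    """Fasting C-peptide-to-insulin ratio [(nmol/l)/(mIE/l)], the trial's
    insulin-clearance estimate."""
    c_peptide = np.asarray(c_peptide, dtype=float)
    insulin = np.asarray(insulin, dtype=float)
    if np.any(insulin[~np.isnan(insulin)] == 0):
        raise DomainError("insulin must be nonzero")
    return c_peptide / insulin


def ipaq_met_minutes(vigorous=(0, 0.0), moderate=(0, 0.0), walking=(0, 0.0),
                     cap_min_per_day: float = IPAQ_DAILY_CAP_MIN):
    """Weekly MET-minutes from (days/week, min/day) pairs for vigorous,
    moderate and walking activity, per the IPAQ scoring protocol."""
    total = 0.0
    for name, (days, minutes) in (
        ("vigorous", vigorous), ("moderate", moderate), ("walking", walking)
    ):
        if not 0 <= days <= 7:
            raise DomainError(f"{name} days must be in [0, 7]")
        if minutes < 0:
            raise DomainError(f"{name} minutes must be >= 0")
        total += IPAQ_MET[name] * days * min(minutes, cap_min_per_day)
    return total


#: default food-frequency scoring map — one point per item when the response
#: matches the recommended category.  The questionnaire's exact indicator
#: mapping is institution-specific; this default is a synthetic stand-in
#: preserving the 0–9 contract and is fully replaceable via config.
DEFAULT_FOOD_SCORING: Mapping[str, Mapping[str, int]] = {
    item: {"recommended": 1, "other": 0}
    for item in (
        "vegetables", "fruit", "fish", "whole_grain", "red_meat",
        "sweets", "soft_drinks", "dietary_fat", "salt",
    )
}


def food_frequency_score(responses: Mapping[str, str],
                         scoring_map: Mapping[str, Mapping[str, int]] | None = None) -> int:
    """Sum per-item points into a 0–9 diet-adherence score (9 = most
    adherent to official food recommendations)."""
    scoring_map = scoring_map if scoring_map is not None else DEFAULT_FOOD_SCORING
    score = 0
    for item, response in responses.items():
        if item not in scoring_map:
            raise DomainError(f"unknown questionnaire item {item!r}")
        if response not in scoring_map[item]:
            raise DomainError(f"unknown category {response!r} for item {item!r}")
        score += scoring_map[item][response]
    if not 0 <= score <= 9:
        raise DomainError(f"food score {score} outside 0-9")
    return score


def append_derived_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Append derived-index columns (per visit where inputs exist) to a
    participant table; used by the ``indices`` CLI stage."""
    out = table.copy()
    for visit in ("baseline", "week12"):
        g, i = out.get(f"{visit}_glucose"), out.get(f"{visit}_insulin")
        if g is not None and i is not None:
            out[f"{visit}_homa_ir"] = homa_ir(g, i)
            out[f"{visit}_homa_b"] = homa_b(g, i)
        cols = [f"{visit}_{c}" for c in ("bmi", "waist", "triglycerides", "ggt")]
        if all(c in out.columns for c in cols):
            out[f"{visit}_fli"] = fatty_liver_index(*(out[c] for c in cols))
        if g is not None and f"{visit}_c_peptide" in out.columns:
            out[f"{visit}_cpep_insulin_ratio"] = insulin_clearance(
                out[f"{visit}_c_peptide"], i
            )
    if "weight" in out.columns and "height" in out.columns:
        out["bsa"] = bsa_du_bois(out["weight"], out["height"])
    return out
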