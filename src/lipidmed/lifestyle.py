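"""Healthy-lifestyle-factor (HLF) scoring.

Five binary factors define the combined healthy-lifestyle exposure:

1. never smoking;
2. moderate alcohol consumption — weekly but not daily drinking, or daily
   drinking of less than 30 g pure alcohol;
3. healthy diet — at least 4 of 6 dietary habits (fresh vegetables daily,
   fresh fruit daily, red meat <7 days/week, soybean products >=4 days/week,
   fish >=1 day/week, coarse grains >=4 days/week);
4. physically active — at or above the sex-specific median MET-h/day;
5. healthy adiposity — BMI in [18.5, 27.9] kg/m2 (normal/overweight by the
   Chinese classification) and waist circumference <90 cm (men) / <85 cm
   (women).

Boundary conventions are taken literally from those definitions: the BMI
interval is closed, WC cut-offs are strict, "less than 30 g" is strict for
moderate drinking and ">=30 g" inclusive for heavy, and "median or higher"
activity is inclusive.  Missing raw fields are hard errors, never imputed.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

#: raw columns required by :func:`classify_hlf`
RAW_FIELDS = [
    "sex",
    "smoking_status",
    "alcohol_freq",
    "alcohol_g_per_day",
    "diet_veg_daily",
    "diet_fruit_daily",
    "diet_red_meat_lt7",
    "diet_soybean_ge4",
    "diet_fish_ge1",
    "diet_grains_ge4",
    "activity_met_h",
    "bmi",
    "wc",
]

DIET_COMPONENTS = [
    "diet_veg_daily",
    "diet_fruit_daily",
    "diet_red_meat_lt7",
    "diet_soybean_ge4",
    "diet_fish_ge1",
    "diet_grains_ge4",
]

HLF_FLAGS = [
    "never_smoking",
    "moderate_alcohol",
    "healthy_diet",
    "physically_active",
    "healthy_adiposity",
]

#: adiposity cut-offs: (bmi_low, bmi_high, wc_male, wc_female)
ADIPOSITY_RULES = {
    "standard": (18.5, 27.9, 90.0, 85.0),
    "strict": (18.5, 24.9, 90.0, 80.0),
}


def _check_complete(raw: pd.DataFrame, fields: list[str]) -> None:
    missing_cols = [f for f in fields if f not in raw.columns]
    if missing_cols:
        raise ValueError(f"missing required lifestyle field(s): {missing_cols}")
    for f in fields:
        na = raw[f].isna()
        if na.any():
            who = raw.index[na][:5].tolist()
            raise ValueError(
                f"field '{f}' is missing for {int(na.sum())} participant(s), "
                f"e.g. {who}; lifestyle fields are never imputed"
            )


def activity_threshold(cohort: pd.DataFrame) -> dict[str, float]:
    """Sex-specific median MET-h/day; 'active' means >= this (inclusive)."""
    _check_complete(cohort, ["sex", "activity_met_h"])
    out: dict[str, float] = {}
    for sex in ("male", "female"):
        vals = cohort.loc[cohort["sex"] == sex, "activity_met_h"]
        if len(vals) == 0:
            raise ValueError(f"no participants of sex '{sex}': cannot form activity median")
        out[sex] = float(np.median(vals))
    return out


def alcohol_three_group(raw: pd.DataFrame) -> pd.Series:
    """Three-level drinking category: non_regular / moderate / heavy.

    Heavy: daily drinking of >=30 g pure alcohol (inclusive); moderate:
    weekly-but-not-daily, or daily <30 g; non-regular: everything else.
    """
    _check_complete(raw, ["alcohol_freq", "alcohol_g_per_day"])
    freq = raw["alcohol_freq"]
    grams = raw["alcohol_g_per_day"].astype(float)
    heavy = (freq == "daily") & (grams >= 30.0)
    moderate = (freq == "weekly") | ((freq == "daily") & (grams < 30.0))
    out = pd.Series("non_regular", index=raw.index, name="alcohol_class")
    out[moderate] = "moderate"
    out[heavy] = "heavy"
    return out


def hlf_count_to_group(count: pd.Series | np.ndarray) -> pd.Series:
    """Three-level grouping of the HLF count: 0-1 (reference), 2-3, 4-5."""
    count = pd.Series(np.asarray(count))
    if ((count < 0) | (count > 5)).any():
        raise ValueError("hlf_count out of range 0..5")
    bins = pd.cut(count, bins=[-0.5, 1.5, 3.5, 5.5], labels=["0-1", "2-3", "4-5"])
    return bins.astype(str)


def hlf_count_to_group2(count: pd.Series | np.ndarray) -> pd.Series:
    """Two-level grouping used in the joint genetic-score analysis: 0-2 vs 3-5."""
    count = pd.Series(np.asarray(count))
    return pd.Series(np.where(count >= 3, "3-5", "0-2"), index=count.index)


def classify_hlf(
    raw: pd.DataFrame,
    activity_thresholds: Mapping[str, float] | None = None,
    adiposity_rule: str = "standard",
) -> pd.DataFrame:
    """Score the five HLFs from raw lifestyle fields.

    Parameters
    ----------
    raw
        One row per participant with the columns in :data:`RAW_FIELDS`.
    activity_thresholds
        ``{"male": met_h, "female": met_h}``; computed from ``raw`` itself
        when omitted (the default mirrors deriving the median from the
        analysis sample).
    adiposity_rule
        ``"standard"`` (BMI 18.5-27.9, WC <90/<85) or ``"strict"``
        (BMI 18.5-24.9, WC <90/<80), the sensitivity-analysis variant.

    Returns
    -------
    DataFrame with the five boolean flags, ``diet_score``, ``alcohol_class``,
    ``hlf_count`` and the categorical ``hlf_group`` / ``hlf_group2``.
    """
    if adiposity_rule not in ADIPOSITY_RULES:
        raise ValueError(f"unknown adiposity_rule {adiposity_rule!r}")
    _check_complete(raw, RAW_FIELDS)
    if activity_thresholds is None:
        activity_thresholds = activity_threshold(raw)

    out = pd.DataFrame(index=raw.index)
    out["never_smoking"] = raw["smoking_status"] == "never"

    alcohol_class = alcohol_three_group(raw)
    out["moderate_alcohol"] = alcohol_class == "moderate"

    diet_score = raw[DIET_COMPONENTS].astype(bool).sum(axis=1)
    out["healthy_diet"] = diet_score >= 4

    thr = raw["sex"].map(activity_thresholds).astype(float)
    if thr.isna().any():
        bad = sorted(raw.loc[thr.isna(), "sex"].unique())
        raise ValueError(f"no activity threshold for sex value(s) {bad}")
    out["physically_active"] = raw["activity_met_h"].astype(float) >= thr

    bmi_lo, bmi_hi, wc_m, wc_f = ADIPOSITY_RULES[adiposity_rule]
    wc_cut = np.where(raw["sex"] == "male", wc_m, wc_f)
    bmi = raw["bmi"].astype(float)
    out["healthy_adiposity"] = (bmi >= bmi_lo) & (bmi <= bmi_hi) & (raw["wc"].astype(float) < wc_cut)

    out["diet_score"] = diet_score.astype(int)
    out["alcohol_class"] = alcohol_class
    out["hlf_count"] = out[HLF_FLAGS].sum(axis=1).astype(int)
    out["hlf_group"] = hlf_count_to_group(out["hlf_count"]).values
    out["hlf_group2"] = hlf_count_to_group2(out["hlf_count"]).values
    return out


def hlf_sensitivity_variants(
    raw: pd.DataFrame,
    mode: str,
    activity_thresholds: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Recompute the profile under a sensitivity definition.

    ``drop_alcohol``
        Score over the remaining four factors (count 0-4; groups re-derived
        with the same 0-1 / 2-3 / 4-5 boundaries).
    ``strict_adiposity``
        Standard five factors but with the strict BMI/WC cut-offs.
    """
    if mode == "strict_adiposity":
        return classify_hlf(raw, activity_thresholds, adiposity_rule="strict")
    if mode == "drop_alcohol":
        prof = classify_hlf(raw, activity_thresholds)
        flags = [f for f in HLF_FLAGS if f != "moderate_alcohol"]
        prof = prof.drop(columns=["moderate_alcohol"])
        prof["hlf_count"] = prof[flags].sum(axis=1).astype(int)
        prof["hlf_group"] = hlf_count_to_group(prof["hlf_count"]).values
        prof["hlf_group2"] = hlf_count_to_group2(prof["hlf_count"]).values
        return prof
    raise ValueError(f"unknown sensitivity mode {mode!r}")
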