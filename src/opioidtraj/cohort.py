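"""Incident ("new user") cohort derivation and baseline covariates.

A new user is an adult whose first opioid prescription inside the study
window (the index date) is preceded by a 24-month exposure-free wash-out,
with no non-excepted cancer flag in the 10 years before index and no
methadone record.  Exclusions are logged with reason codes in a fixed
precedence order (age → cancer → methadone → not-incident → no-follow-up)
so the attrition flow is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposure import (
    ALL_CLASSED_OPIOIDS,
    MODERATE_OPIOIDS,
    STRONG_OPIOIDS,
    WEAK_OPIOIDS,
)

__all__ = [
    "CohortSettings",
    "derive_new_users",
    "classify_index_strength",
    "derive_covariates",
    "StrengthClassificationError",
    "AGE_BANDS",
    "DEFAULT_CHARLSON_WEIGHTS",
]

REASON_UNDER_AGE = "under_age"
REASON_CANCER = "cancer_history"
REASON_METHADONE = "methadone"
REASON_NOT_INCIDENT = "not_incident"
REASON_NO_FOLLOW_UP = "no_follow_up"
REASON_UNLINKED = "unlinked"
REASON_NO_STUDY_SCRIPT = "no_opioid_in_study_period"

#: Age bands used for baseline reporting and reference coding (18–24 ... ≥85).
AGE_BANDS = ["18-24", "25-34", "35-44", "45-54", "55-64", "65-74", "75-84", "85+"]

#: Charlson-constituent weights; supplied as config so code lists stay out of scope.
DEFAULT_CHARLSON_WEIGHTS = {
    "diabetes": 1,
    "rheumatological": 1,
    "cancer": 2,
}

DIAGNOSIS_FLAGS = (
    "alcohol_dependency",
    "substance_use",
    "depression",
    "suicide_self_harm",
    "fibromyalgia",
    "back_pain",
    "migraine",
    "rheumatological",
    "diabetes",
    "major_surgery",
)
DRUG_FLAGS = ("benzodiazepine", "gabapentinoid", "psychotropic")


class StrengthClassificationError(ValueError):
    def __init__(self, ingredient: str):
        super().__init__(f"ingredient {ingredient!r} is outside the weak/moderate/strong lists")
        self.ingredient = ingredient


@dataclass
class CohortSettings:
    washout_days: int = 730  # 24-month exposure-free lookback
    cancer_lookback_days: int = 3650  # 10 years
    min_age: int = 18
    cancer_conditions: tuple = ("cancer",)  # non-melanoma skin cancer exempt
    excluded_ingredients: tuple = ("methadone",)
    covariate_lookback_days: int = 365
    charlson_weights: dict = field(default_factory=lambda: dict(DEFAULT_CHARLSON_WEIGHTS))


def age_band(age: float) -> str:
    edges = [(25, "18-24"), (35, "25-34"), (45, "35-44"), (55, "45-54"), (65, "55-64"), (75, "65-74"), (85, "75-84")]
    for hi, label in edges:
        if age < hi:
            return label
    return "85+"


def classify_index_strength(ingredients) -> str:
    """Strength class of the index-day prescription set.

    One distinct classed ingredient maps to its class; more than one
    distinct ingredient on the index date is the combination group.
    """
    distinct = sorted(set(ingredients))
    if not distinct:
        raise ValueError("no index-day prescriptions to classify")
    for ing in distinct:
        if ing not in ALL_CLASSED_OPIOIDS:
            raise StrengthClassificationError(ing)
    if len(distinct) > 1:
        return "combination"
    ing = distinct[0]
    if ing in WEAK_OPIOIDS:
        return "weak"
    if ing in MODERATE_OPIOIDS:
        return "moderate"
    if ing in STRONG_OPIOIDS:
        return "strong"
    raise StrengthClassificationError(ing)  # pragma: no cover


def derive_new_users(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    condition_flags: pd.DataFrame,
    study_start,
    study_end,
    settings: CohortSettings | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive the incident cohort; return (cohort table, exclusion log).

    The candidate index date is each patient's first opioid prescription on
    or after ``study_start``; a failed rule excludes the patient rather than
    moving the index to a later script.  Only the first failed rule (in
    precedence order) is logged per patient.
    """
    settings = settings or CohortSettings()
    study_start = pd.Timestamp(study_start)
    study_end = pd.Timestamp(study_end)

    rx = prescriptions.copy()
    rx["issue_date"] = pd.to_datetime(rx["issue_date"])
    pat = patients.set_index("patient_id")

    exclusions: list[dict] = []
    linked = rx["patient_id"].isin(pat.index)
    for pid in sorted(rx.loc[~linked, "patient_id"].unique()):
        exclusions.append({"patient_id": pid, "reason": REASON_UNLINKED})
    rx = rx[linked]

    in_study = rx[(rx["issue_date"] >= study_start) & (rx["issue_date"] <= study_end)]
    index_date = in_study.groupby("patient_id")["issue_date"].min()
    for pid in sorted(set(rx["patient_id"]) - set(index_date.index)):
        exclusions.append({"patient_id": pid, "reason": REASON_NO_STUDY_SCRIPT})

    df = pd.DataFrame({"index_date": index_date}).join(pat, how="left")
    if "age_at_index" in df.columns:
        age = df["age_at_index"].astype(float)
    else:
        age = df["index_date"].dt.year - df["birth_year"].astype(int)
    df["_age"] = age

    flags = condition_flags.copy()
    cancer_hit = pd.Series(False, index=df.index)
    if len(flags):
        crows = flags[flags["condition"].isin(settings.cancer_conditions)].copy()
        if len(crows):
            crows["flag_date"] = pd.to_datetime(crows["flag_date"])
            crows = crows[crows["patient_id"].isin(df.index)]
            cidx = crows["patient_id"].map(df["index_date"])
            delta = (cidx - crows["flag_date"]).dt.days
            # flags strictly before index exclude, and so do index-day flags
            hit = crows.loc[(delta >= 0) & (delta <= settings.cancer_lookback_days), "patient_id"]
            cancer_hit.loc[cancer_hit.index.isin(set(hit))] = True

    meth_pids = set(rx.loc[rx["ingredient"].isin(settings.excluded_ingredients), "patient_id"])
    methadone_hit = pd.Series(df.index.isin(meth_pids), index=df.index)

    rx_idx = rx["patient_id"].map(df["index_date"])
    gap = (rx_idx - rx["issue_date"]).dt.days
    prior_pids = set(rx.loc[(gap > 0) & (gap < settings.washout_days), "patient_id"])
    not_incident = pd.Series(df.index.isin(prior_pids), index=df.index)

    follow_up_end = pd.to_datetime(df["registration_end"]).clip(upper=study_end)
    no_follow_up = follow_up_end <= df["index_date"]

    reason = np.select(
        [
            (df["_age"] < settings.min_age).to_numpy(),
            cancer_hit.to_numpy(),
            methadone_hit.to_numpy(),
            not_incident.to_numpy(),
            no_follow_up.to_numpy(),
        ],
        [REASON_UNDER_AGE, REASON_CANCER, REASON_METHADONE, REASON_NOT_INCIDENT, REASON_NO_FOLLOW_UP],
        default="",
    )
    for pid, r in zip(df.index, reason):
        if r:
            exclusions.append({"patient_id": pid, "reason": r})
    keep = reason == ""
    df = df[keep]
    follow_up_end = follow_up_end[keep]

    # index-day strength classification for the retained cohort
    on_index = rx[rx["patient_id"].isin(df.index)]
    on_index = on_index[on_index["issue_date"] == on_index["patient_id"].map(df["index_date"])]
    unknown = set(on_index["ingredient"]) - ALL_CLASSED_OPIOIDS
    if unknown:
        raise StrengthClassificationError(sorted(unknown)[0])
    class_map = (
        {i: "weak" for i in WEAK_OPIOIDS}
        | {i: "moderate" for i in MODERATE_OPIOIDS}
        | {i: "strong" for i in STRONG_OPIOIDS}
    )
    n_distinct = on_index.groupby("patient_id")["ingredient"].nunique()
    first_ing = on_index.groupby("patient_id")["ingredient"].min()
    strength = first_ing.map(class_map).where(n_distinct == 1, "combination")

    fup_days = (follow_up_end - df["index_date"]).dt.days.astype(int)
    cohort = pd.DataFrame(
        {
            "patient_id": df.index,
            "index_date": df["index_date"].to_numpy(),
            "follow_up_end": follow_up_end.to_numpy(),
            "follow_up_days": fup_days.to_numpy(),
            "index_strength_class": df.index.map(strength).to_numpy(),
            "age_at_index": df["_age"].to_numpy(),
            "short_follow_up": (fup_days < 365).astype(int).to_numpy(),
        }
    ).reset_index(drop=True)
    log = pd.DataFrame(exclusions, columns=["patient_id", "reason"])
    log = log.sort_values("patient_id", kind="stable").reset_index(drop=True)
    return cohort, log


def derive_covariates(
    cohort: pd.DataFrame,
    condition_flags: pd.DataFrame,
    patients: pd.DataFrame,
    settings: CohortSettings | None = None,
    index_mme: pd.Series | None = None,
) -> pd.DataFrame:
    """Attach the baseline covariate vector to each cohort entry.

    Diagnosis flags are true iff a flagged record falls in the year before
    index (``[index − 365 d, index)``); baseline drug flags additionally
    include the index date itself.  The Charlson category is low/medium/high
    for weighted sums of 0 / 1–3 / ≥4.  Missing deprivation and ethnicity are
    carried as explicit ``missing`` categories, never dropped.
    """
    settings = settings or CohortSettings()
    out = cohort.copy()
    out["index_date"] = pd.to_datetime(out["index_date"])
    idx_by_pat = out.set_index("patient_id")["index_date"]

    flags = condition_flags.copy()
    if len(flags):
        flags["flag_date"] = pd.to_datetime(flags["flag_date"])
        flags = flags[flags["patient_id"].isin(idx_by_pat.index)]
        flags = flags.assign(_index=flags["patient_id"].map(idx_by_pat))
        delta = (flags["_index"] - flags["flag_date"]).dt.days
        diag_ok = (delta > 0) & (delta <= settings.covariate_lookback_days)
        drug_ok = (delta >= 0) & (delta <= settings.covariate_lookback_days)

    def _flag_col(cond: str, window_mask) -> pd.Series:
        if not len(flags):
            return pd.Series(0, index=out.index)
        hit = flags[(flags["condition"] == cond) & window_mask]
        have = set(hit["patient_id"])
        return out["patient_id"].isin(have).astype(int)

    for cond in DIAGNOSIS_FLAGS:
        out[cond] = _flag_col(cond, diag_ok if len(flags) else None)
    for cond in DRUG_FLAGS:
        out[cond] = _flag_col(cond, drug_ok if len(flags) else None)

    # Charlson weighted sum over diagnosis-window flags
    score = pd.Series(0, index=out.index)
    for cond, w in settings.charlson_weights.items():
        score = score + int(w) * _flag_col(cond, diag_ok if len(flags) else None)
    out["charlson_score"] = score
    out["charlson_category"] = pd.cut(
        score, bins=[-1, 0, 3, np.inf], labels=["low", "medium", "high"]
    ).astype(str)

    pat = patients.set_index("patient_id")
    out["sex"] = out["patient_id"].map(pat["sex"]).fillna("missing")
    out["ethnicity"] = out["patient_id"].map(pat["ethnicity"]).fillna("missing")
    out["townsend_quintile"] = out["patient_id"].map(pat["townsend_quintile"]).fillna("missing").astype(str)
    out["age_group"] = out["age_at_index"].map(age_band)

    if index_mme is not None:
        out["index_mme"] = out["patient_id"].map(index_mme).fillna(0.0)
    return out
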