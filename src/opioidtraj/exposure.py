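"""Prescription cleaning, MME/day conversion, and daily exposure timelines.

Every opioid prescription is standardised to morphine milligram equivalents
per day (MME/day): for oral preparations, ``unit_strength × daily_count ×
equianalgesic factor``; for transdermal patches, ``µg/hour strength ×
transdermal factor`` (the transdermal factor already folds in the 24-hour
delivery rate, so patch records need no daily count).  Per-patient daily
exposure timelines are built on day offsets from the index date, with
half-open supply intervals ``[start, start + duration)``; concurrent
different-ingredient prescriptions sum, while same-ingredient prescriptions
issued into an active supply are stockpiled sequentially.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Marker returned by window averaging when no covered day falls in the window.
OFF = "off"

#: Ingredient strength classes used for index-strength grouping.
WEAK_OPIOIDS = frozenset({"codeine", "dihydrocodeine", "meptazinol"})
MODERATE_OPIOIDS = frozenset({"tramadol", "tapentadol"})
STRONG_OPIOIDS = frozenset(
    {
        "morphine",
        "oxycodone",
        "fentanyl",
        "buprenorphine",
        "diamorphine",
        "hydromorphone",
        "pethidine",
    }
)
ALL_CLASSED_OPIOIDS = WEAK_OPIOIDS | MODERATE_OPIOIDS | STRONG_OPIOIDS


class ConversionLookupError(KeyError):
    """No equianalgesic factor is available for an (ingredient, route) pair."""

    def __init__(self, ingredient: str, route: str):
        super().__init__(f"no MME conversion factor for {ingredient!r} via route {route!r}")
        self.ingredient = ingredient
        self.route = route


@dataclass(frozen=True)
class ConversionEntry:
    factor: float
    strength_unit: str
    patch_wear_days: float | None = None


class ConversionTable:
    """Map (ingredient, route) to an equianalgesic (MME) factor.

    Oral factors are multipliers per mg of daily dose; transdermal factors
    are per µg/hour of patch strength with 24-hour delivery folded in.
    """

    def __init__(self, entries: Mapping[tuple[str, str], ConversionEntry]):
        bad = [k for k, e in entries.items() if not e.factor > 0]
        if bad:
            raise ValueError(f"conversion factors must be strictly positive; offending keys: {bad}")
        self._entries = dict(entries)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConversionTable":
        entries: dict[tuple[str, str], ConversionEntry] = {}
        for row in df.itertuples(index=False):
            wear = getattr(row, "patch_wear_days", None)
            wear = None if wear is None or (isinstance(wear, float) and math.isnan(wear)) else float(wear)
            entries[(str(row.ingredient), str(row.route))] = ConversionEntry(
                factor=float(row.factor), strength_unit=str(row.strength_unit), patch_wear_days=wear
            )
        return cls(entries)

    @classmethod
    def from_csv(cls, path) -> "ConversionTable":
        return cls.from_frame(pd.read_csv(path, comment="#"))

    @classmethod
    def default(cls) -> "ConversionTable":
        """The shipped CDC-derived factor table."""
        ref = resources.files("opioidtraj.data").joinpath("conversion_factors.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return tuple(key) in self._entries

    def entry(self, ingredient: str, route: str) -> ConversionEntry:
        try:
            return self._entries[(ingredient, route)]
        except KeyError:
            raise ConversionLookupError(ingredient, route) from None

    def factor(self, ingredient: str, route: str) -> float:
        return self.entry(ingredient, route).factor

    def ingredients(self) -> set[str]:
        return {ing for ing, _ in self._entries}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "ingredient": ing,
                "route": route,
                "factor": e.factor,
                "strength_unit": e.strength_unit,
                "patch_wear_days": e.patch_wear_days,
            }
            for (ing, route), e in sorted(self._entries.items())
        ]
        return pd.DataFrame(rows)


def compute_mme_per_day(record: Mapping, table: ConversionTable) -> float:
    """MME/day of one cleaned prescription record.

    Oral: ``unit_strength [mg] × daily_count × factor``.
    Transdermal: ``unit_strength [µg/hour] × factor`` (24-h delivery folded
    into the factor, so no daily count is involved).
    """
    ingredient = record["ingredient"]
    route = record["route"]
    entry = table.entry(ingredient, route)
    strength = float(record["unit_strength"])
    if route == "transdermal":
        mme = strength * entry.factor
    else:
        daily_count = float(record["daily_count"])
        mme = strength * daily_count * entry.factor
    if not mme > 0:
        raise ValueError(f"non-positive MME/day ({mme}) computed for record {dict(record)!r}")
    return mme


@dataclass
class CleaningRules:
    """Repair/exclusion rules applied to raw prescription records.

    duration_days = ceil(quantity / daily_count), floored at
    ``min_duration_days`` and capped at ``max_duration_days``.  A missing
    daily count is imputed from the patient's modal daily count for the same
    ingredient, else the population median for the ingredient.
    """

    max_duration_days: int = 183
    min_duration_days: int = 1
    impute_daily_count: bool = True


REASON_BAD_DATE = "bad_date"
REASON_ZERO_QUANTITY = "zero_quantity"
REASON_UNKNOWN_INGREDIENT = "unknown_ingredient"
REASON_NO_DAILY_COUNT = "no_daily_count"

RAW_THERAPY_COLUMNS = [
    "patient_id",
    "prescriber_id",
    "ingredient",
    "route",
    "unit_strength",
    "quantity",
    "daily_count",
    "issue_date",
]


def clean_prescriptions(
    raw: pd.DataFrame,
    rules: CleaningRules | None = None,
    conversion: ConversionTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clean a raw therapy table; return (cleaned records, exclusion log).

    The exclusion log has one row per dropped record with a reason code;
    records are never silently dropped.  Cleaned records gain a
    ``duration_days`` column (and keep a parsed ``issue_date``).
    """
    rules = rules or CleaningRules()
    df = raw.copy()
    df["_row"] = np.arange(len(df))
    exclusions: list[dict] = []

    def _drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        for r in df.loc[mask, "_row"]:
            exclusions.append({"row": int(r), "reason": reason})
        df = df.loc[~mask]

    parsed = pd.to_datetime(df["issue_date"], format="%Y-%m-%d", errors="coerce")
    df = df.assign(issue_date=parsed)
    _drop(df["issue_date"].isna(), REASON_BAD_DATE)

    if conversion is not None and len(df):
        known_keys = {(i, r) for i, r in zip(df["ingredient"], df["route"]) if (i, r) in conversion}
        known = pd.Series(
            [(i, r) in known_keys for i, r in zip(df["ingredient"], df["route"])], index=df.index
        )
        _drop(~known, REASON_UNKNOWN_INGREDIENT)

    qty = pd.to_numeric(df["quantity"], errors="coerce")
    df = df.assign(quantity=qty)
    _drop(df["quantity"].isna() | (df["quantity"] <= 0), REASON_ZERO_QUANTITY)

    df = df.assign(daily_count=pd.to_numeric(df["daily_count"], errors="coerce"))
    oral = df["route"] != "transdermal"
    missing = oral & df["daily_count"].isna()
    if rules.impute_daily_count and missing.any():
        # patient-level modal daily count for the same ingredient, else the
        # population median for the ingredient
        def _mode(s: pd.Series):
            m = s.dropna().mode()
            return m.iloc[0] if len(m) else np.nan

        pat_mode = (
            df.loc[oral]
            .groupby(["patient_id", "ingredient"])["daily_count"]
            .agg(_mode)
            .rename("_pat_mode")
        )
        pop_med = df.loc[oral].groupby("ingredient")["daily_count"].median().rename("_pop_med")
        df = df.join(pat_mode, on=["patient_id", "ingredient"])
        df = df.join(pop_med, on="ingredient")
        fill = df["_pat_mode"].fillna(df["_pop_med"])
        df = df.assign(daily_count=df["daily_count"].fillna(fill)).drop(columns=["_pat_mode", "_pop_med"])
    _drop((df["route"] != "transdermal") & (df["daily_count"].isna() | (df["daily_count"] <= 0)), REASON_NO_DAILY_COUNT)

    # duration: oral from quantity/daily_count; transdermal from patches × wear days
    duration = pd.Series(np.nan, index=df.index)
    oral = df["route"] != "transdermal"
    duration[oral] = np.ceil(df.loc[oral, "quantity"] / df.loc[oral, "daily_count"])
    if (~oral).any():
        if conversion is None:
            wear = 3.0
            duration[~oral] = np.ceil(df.loc[~oral, "quantity"] * wear)
        else:
            wears = df.loc[~oral].apply(
                lambda r: conversion.entry(r["ingredient"], r["route"]).patch_wear_days or 1.0, axis=1
            )
            duration[~oral] = np.ceil(df.loc[~oral, "quantity"] * wears)
    duration = duration.clip(lower=rules.min_duration_days, upper=rules.max_duration_days)
    df = df.assign(duration_days=duration.astype(int)).drop(columns=["_row"])

    log = pd.DataFrame(exclusions, columns=["row", "reason"])
    return df.reset_index(drop=True), log


def add_mme(records: pd.DataFrame, table: ConversionTable) -> pd.DataFrame:
    """Annotate cleaned records with an ``mme_per_day`` column."""
    out = records.copy()
    factors = np.empty(len(out))
    for (ing, route), grp in out.groupby(["ingredient", "route"], sort=False):
        factors[out.index.get_indexer(grp.index)] = table.factor(ing, route)
    strength = out["unit_strength"].astype(float).to_numpy()
    daily = pd.to_numeric(out["daily_count"], errors="coerce").fillna(1.0).to_numpy()
    transdermal = (out["route"] == "transdermal").to_numpy()
    mme = np.where(transdermal, strength * factors, strength * daily * factors)
    if np.any(mme <= 0):
        bad = out.iloc[int(np.argmin(mme))]
        raise ValueError(f"non-positive MME/day computed for record {bad.to_dict()!r}")
    out["mme_per_day"] = mme
    return out


@dataclass
class ExposureTimeline:
    """Per-patient daily MME/day series on day offsets from the index date.

    ``values[d]`` is total MME/day on day ``d`` (0 on uncovered days);
    ``episodes`` lists maximal runs of constant positive exposure as
    ``(start, end, mme)`` with half-open ``[start, end)`` bounds.
    """

    patient_id: object
    values: np.ndarray
    episodes: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self):
        if np.any(self.values < 0):
            raise ValueError("exposure values must be non-negative")


def _episodes_from_values(values: np.ndarray) -> list[tuple[int, int, float]]:
    episodes = []
    n = len(values)
    d = 0
    while d < n:
        if values[d] > 0:
            start = d
            v = values[d]
            while d < n and values[d] == v:
                d += 1
            episodes.append((start, d, float(v)))
        else:
            d += 1
    return episodes


def build_timeline(
    records: pd.DataFrame,
    n_days: int,
    patient_id=None,
    day_column: str = "day",
) -> ExposureTimeline:
    """Build a patient's exposure timeline from MME-annotated records.

    ``records`` must carry ``day_column`` (integer day offset of issue from
    the index date), ``duration_days``, ``ingredient`` and ``mme_per_day``.
    A same-ingredient prescription issued while a previous supply of that
    ingredient is still running starts when the running supply ends
    (stockpiling); different ingredients contribute additively.  Records
    outside ``[0, n_days)`` are clipped, never errors.
    """
    values = np.zeros(n_days)
    if patient_id is None and len(records):
        patient_id = records.iloc[0].get("patient_id")
    for _, grp in records.groupby("ingredient", sort=True):
        grp = grp.sort_values([day_column, "duration_days"], kind="stable")
        cursor = -(10**9)
        for row in grp.itertuples(index=False):
            day = int(getattr(row, day_column))
            start = max(day, cursor)
            end = start + int(row.duration_days)
            cursor = end
            s, e = max(start, 0), min(end, n_days)
            if s < e:
                values[s:e] += float(row.mme_per_day)
    return ExposureTimeline(patient_id=patient_id, values=values, episodes=_episodes_from_values(values))


def window_average_mme(
    timeline: ExposureTimeline,
    start: int,
    stop: int,
    convention: str = "covered",
):
    """Mean MME/day over a half-open day window ``[start, stop)``.

    With the default ``covered`` convention the mean is taken over covered
    (exposure > 0) days only; a window with no covered day returns the
    :data:`OFF` marker.  ``convention="calendar"`` divides the summed
    exposure by the full window length instead.
    """
    if stop <= start:
        raise ValueError(f"empty window [{start}, {stop})")
    s = max(start, 0)
    e = min(stop, len(timeline.values))
    window = timeline.values[s:e]
    covered = window > 0
    if not covered.any():
        return OFF
    if convention == "covered":
        return float(window[covered].mean())
    if convention == "calendar":
        return float(window.sum() / (stop - start))
    raise ValueError(f"unknown averaging convention {convention!r}")


def build_timelines(
    records: pd.DataFrame,
    follow_up_days: Mapping | pd.Series,
    day_column: str = "day",
) -> dict:
    """Build timelines for every patient in ``follow_up_days`` (id → length)."""
    out = {}
    grouped = dict(tuple(records.groupby("patient_id")))
    for pid, n_days in dict(follow_up_days).items():
        grp = grouped.get(pid)
        if grp is None:
            grp = records.iloc[0:0]
        out[pid] = build_timeline(grp, int(n_days), patient_id=pid, day_column=day_column)
    return out
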