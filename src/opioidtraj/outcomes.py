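"""Long-term-use phenotyping, MME dose categories, and 2-year transitions.

Long-term opioid use: at least 3 prescriptions issued within a sliding
90-day window, or one prescription lasting ≥90 days, during days 31–365 of
follow-up; prescriptions issued in the first 30 days are ignored entirely
(acute-pain blanking).  Average MME/day per 6-month band maps to the dose
categories low (<50), medium (50–119), high (120–199), very high (≥200),
plus an off-treatment state for bands with no covered day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exposure import OFF, ExposureTimeline, window_average_mme

__all__ = [
    "LongTermStatus",
    "classify_long_term",
    "assign_mme_category",
    "TransitionResult",
    "build_transition_table",
    "MME_CATEGORIES",
    "STATES",
]

MME_CATEGORIES = ["low", "medium", "high", "very_high"]
STATES = MME_CATEGORIES + [OFF]

#: 6-month analysis bands as half-open day ranges from the index date.
WINDOW_BOUNDS = [(0, 182), (182, 364), (364, 546), (546, 728)]
WINDOW_LABELS = ["0-6m", "6-12m", "12-18m", "18-24m"]

BLANKING_DAYS = 30
OUTCOME_YEAR_END = 365
WINDOW_SPAN = 90
MIN_SCRIPTS = 3
MIN_SINGLE_DURATION = 90


@dataclass(frozen=True)
class LongTermStatus:
    patient_id: object
    is_long_term: bool
    rule: str | None = None  # "window3" | "single90"
    qualifying_start: int | None = None
    qualifying_end: int | None = None

    def __post_init__(self):
        has_detail = self.rule is not None
        if has_detail != self.is_long_term:
            raise ValueError("qualifying fields must be present iff long-term")


def classify_long_term(issue_days, duration_days=None, patient_id=None) -> LongTermStatus:
    """Apply the long-term-use phenotype to one patient's prescriptions.

    ``issue_days`` are integer day offsets from the index date; only
    prescriptions issued in days 31–365 count (full blanking of days 0–30
    for both rules).  The 90-day window is a sliding half-open interval
    ``[t, t+90)``, so three issues spanning exactly 90 days (x … x+89)
    qualify while x+90 does not.
    """
    days = np.asarray(issue_days, dtype=int)
    if duration_days is None:
        durations = np.zeros(len(days), dtype=int)
    else:
        durations = np.asarray(duration_days, dtype=int)
        if len(durations) != len(days):
            raise ValueError("issue_days and duration_days must have equal length")
    eligible = (days > BLANKING_DAYS) & (days <= OUTCOME_YEAR_END)
    e_days = np.sort(days[eligible])
    e_dur = durations[eligible]

    for i in range(len(e_days) - (MIN_SCRIPTS - 1)):
        if e_days[i + MIN_SCRIPTS - 1] - e_days[i] <= WINDOW_SPAN - 1:
            return LongTermStatus(
                patient_id,
                True,
                rule="window3",
                qualifying_start=int(e_days[i]),
                qualifying_end=int(e_days[i]) + WINDOW_SPAN,
            )
    long_mask = e_dur >= MIN_SINGLE_DURATION
    if long_mask.any():
        # first long-lasting script by issue order (pre-sorting by day)
        order = np.argsort(days[eligible], kind="stable")
        for j in order:
            if durations[eligible][j] >= MIN_SINGLE_DURATION:
                d = int(days[eligible][j])
                return LongTermStatus(
                    patient_id,
                    True,
                    rule="single90",
                    qualifying_start=d,
                    qualifying_end=d + int(durations[eligible][j]),
                )
    return LongTermStatus(patient_id, False)


def classify_long_term_table(records: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Vectorised wrapper: one LongTermStatus row per cohort member.

    ``records`` must carry ``patient_id``, ``issue_date`` and
    ``duration_days``; days are computed relative to each member's index
    date and truncated at the member's follow-up end.
    """
    rx = records.copy()
    rx["issue_date"] = pd.to_datetime(rx["issue_date"])
    idx = cohort.set_index("patient_id")["index_date"]
    fup = cohort.set_index("patient_id")["follow_up_days"]
    rx = rx[rx["patient_id"].isin(idx.index)]
    rx = rx.assign(day=(rx["issue_date"] - rx["patient_id"].map(pd.to_datetime(idx))).dt.days)
    # vectorised screen: only patients with ≥3 eligible scripts or one
    # eligible script lasting ≥90 days can possibly qualify
    horizon = rx["patient_id"].map(fup).clip(upper=OUTCOME_YEAR_END)
    elig = rx[(rx["day"] > BLANKING_DAYS) & (rx["day"] <= horizon)]
    n_elig = elig.groupby("patient_id").size()
    max_dur = elig.groupby("patient_id")["duration_days"].max()
    candidates = set(n_elig[n_elig >= MIN_SCRIPTS].index) | set(max_dur[max_dur >= MIN_SINGLE_DURATION].index)
    rows = []
    grouped = {pid: grp for pid, grp in elig.groupby("patient_id") if pid in candidates}
    for pid in cohort["patient_id"]:
        grp = grouped.get(pid)
        if grp is None:
            rows.append(LongTermStatus(pid, False))
            continue
        rows.append(classify_long_term(grp["day"], grp["duration_days"], patient_id=pid))
    return pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in rows],
            "is_long_term": [int(s.is_long_term) for s in rows],
            "rule": [s.rule for s in rows],
            "qualifying_start": [s.qualifying_start for s in rows],
            "qualifying_end": [s.qualifying_end for s in rows],
        }
    )


def assign_mme_category(avg_mme) -> str:
    """Dose category of a window-average MME/day (or the off marker)."""
    if isinstance(avg_mme, str):
        if avg_mme == OFF:
            return OFF
        raise ValueError(f"unrecognised MME value {avg_mme!r}")
    if avg_mme is None:
        return OFF
    x = float(avg_mme)
    if x < 0:
        raise ValueError(f"MME/day must be non-negative, got {x}")
    if x < 50:
        return "low"
    if x < 120:
        return "medium"
    if x < 200:
        return "high"
    return "very_high"


@dataclass
class TransitionResult:
    """Per-index-category transition counts over the four 6-month bands."""

    sequences: pd.DataFrame  # patient_id, index_category, state per window
    long: pd.DataFrame  # index_category, window, state, n, proportion
    flows: pd.DataFrame  # index_category, from_window, from_state, to_state, n

    def counts(self, index_category: str) -> pd.DataFrame:
        sub = self.long[self.long["index_category"] == index_category]
        return sub.pivot(index="window", columns="state", values="n").fillna(0).astype(int)


def state_sequence(timeline: ExposureTimeline, convention: str = "covered") -> list[str]:
    """Dose-category sequence over the four 6-month bands of one timeline."""
    seq = []
    for start, stop in WINDOW_BOUNDS:
        avg = window_average_mme(timeline, start, stop, convention=convention)
        seq.append(assign_mme_category(avg))
    return seq


def build_transition_table(
    cohort: pd.DataFrame,
    timelines: dict,
    convention: str = "covered",
) -> TransitionResult:
    """Aggregate 2-year dose-category transitions, stratified by index category.

    Each member occupies exactly one state per window (off when no covered
    day falls in the window, which also covers time after censoring), so per
    window the state counts sum to the index-category cohort size and the
    proportions to 1.
    """
    rows = []
    for pid in cohort["patient_id"]:
        tl = timelines[pid]
        seq = state_sequence(tl, convention=convention)
        rows.append({"patient_id": pid, "index_category": seq[0], **dict(zip(WINDOW_LABELS, seq))})
    sequences = pd.DataFrame(rows)

    long_rows = []
    flow_rows = []
    for cat, grp in sequences.groupby("index_category", sort=True):
        denom = len(grp)
        for w in WINDOW_LABELS:
            counts = grp[w].value_counts()
            for state in STATES:
                n = int(counts.get(state, 0))
                long_rows.append(
                    {
                        "index_category": cat,
                        "window": w,
                        "state": state,
                        "n": n,
                        "proportion": n / denom,
                    }
                )
        for w_from, w_to in zip(WINDOW_LABELS[:-1], WINDOW_LABELS[1:]):
            pair_counts = grp.groupby([w_from, w_to]).size()
            for (s_from, s_to), n in pair_counts.items():
                flow_rows.append(
                    {
                        "index_category": cat,
                        "from_window": w_from,
                        "from_state": s_from,
                        "to_window": w_to,
                        "to_state": s_to,
                        "n": int(n),
                    }
                )
    long = pd.DataFrame(long_rows)
    flows = pd.DataFrame(flow_rows, columns=["index_category", "from_window", "from_state", "to_window", "to_state", "n"])
    return TransitionResult(sequences=sequences, long=long, flows=flows)
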