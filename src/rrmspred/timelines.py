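"""Therapy-timeline construction, filtering, censoring and temporal splitting.

Raw therapy episodes are turned into a gapless sequence of therapy cycles per
patient: periods without treatment become ``NoDMT`` cycles and periods during
which episodes of *different* DMTs overlap become ``OtherDMT`` cycles.
Consecutive cycles then form treatment switches (current cycle -> index cycle)
which are filtered for eligibility, censored at the last EDSS assessment,
reduced to one switch per patient and split temporally on the index-therapy
start date.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .vocab import DMT6, NODMT, OTHERDMT, SECOND_LINE, SIX_MONTHS_DAYS, DAYS_PER_YEAR

#: labels accepted in the raw therapy table
KNOWN_DMT_LABELS = frozenset(DMT6) | SECOND_LINE | {NODMT, OTHERDMT}

RRMS = "RRMS"

PAIR_COLUMNS = [
    "patient_id",
    "centre_id",
    "current_dmt",
    "current_start",
    "current_end",
    "index_dmt",
    "index_start",
    "index_end",
    "index_censored",
]


@dataclass(frozen=True)
class TherapyCycle:
    """One contiguous exposure interval (a DMT, a NoDMT gap, or an overlap)."""

    patient_id: object
    dmt: str
    start_date: pd.Timestamp
    end_date: pd.Timestamp
    censored: bool = False

    def __post_init__(self):
        if not self.start_date < self.end_date:
            raise ValueError(
                f"cycle start {self.start_date} must precede end {self.end_date}"
            )

    @property
    def duration_years(self) -> float:
        return (self.end_date - self.start_date) / pd.Timedelta(days=1) / DAYS_PER_YEAR


@dataclass
class FlowLog:
    """Exact participant-flow accounting: one row per named filter."""

    steps: list = field(default_factory=list)

    def record(self, filter_name: str, n_before: int, n_after: int) -> None:
        if n_after > n_before:
            raise ValueError("filter cannot add rows")
        self.steps.append(
            {
                "filter_name": filter_name,
                "n_before": int(n_before),
                "n_after": int(n_after),
                "n_removed": int(n_before - n_after),
            }
        )

    def extend(self, other: "FlowLog") -> None:
        self.steps.extend(other.steps)

    def total_removed(self) -> int:
        return sum(s["n_removed"] for s in self.steps)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["filter_name", "n_before", "n_after", "n_removed"])

    def to_records(self) -> list:
        return list(self.steps)


def build_timeline(episodes: pd.DataFrame) -> list[TherapyCycle]:
    """Partition one patient's observed span into therapy cycles.

    Parameters
    ----------
    episodes
        Therapy table rows of a single patient with columns ``patient_id``,
        ``dmt_name``, ``start_date``, ``end_date``; dates must be valid and
        closed (quality-filter and censor open episodes first).

    Returns
    -------
    list of TherapyCycle ordered by start date.  Gaps between episodes are
    emitted as ``NoDMT`` cycles; intervals where episodes of different DMTs
    overlap are emitted as ``OtherDMT``; episodes of the same DMT separated by
    at most one day are merged.
    """
    if len(episodes) == 0:
        return []
    pid = episodes["patient_id"].iloc[0]
    starts = pd.to_datetime(episodes["start_date"])
    ends = pd.to_datetime(episodes["end_date"])
    if starts.isna().any() or ends.isna().any() or (ends <= starts).any():
        raise ValueError("build_timeline requires quality-filtered closed episodes")

    bounds = sorted(set(starts) | set(ends))
    segments: list[list] = []  # [start, end, label]
    for a, b in zip(bounds[:-1], bounds[1:]):
        active = set(
            episodes["dmt_name"][(starts <= a) & (ends >= b)]
        )
        if not active:
            label = NODMT
        elif len(active) == 1:
            label = next(iter(active))
        else:
            label = OTHERDMT
        segments.append([a, b, label])

    # registry date granularity: a same-DMT pair separated by <= 1 day merges
    one_day = pd.Timedelta(days=1)
    for i in range(1, len(segments) - 1):
        s = segments[i]
        if (
            s[2] == NODMT
            and (s[1] - s[0]) <= one_day
            and segments[i - 1][2] == segments[i + 1][2]
        ):
            s[2] = segments[i - 1][2]

    merged: list[list] = []
    for seg in segments:
        if merged and merged[-1][2] == seg[2] and merged[-1][1] == seg[0]:
            merged[-1][1] = seg[1]
        else:
            merged.append(list(seg))

    return [TherapyCycle(pid, label, a, b) for a, b, label in merged if a < b]


def cycles_to_frame(cycles: Iterable[TherapyCycle], centre_by_patient=None) -> pd.DataFrame:
    rows = [
        {
            "patient_id": c.patient_id,
            "dmt": c.dmt,
            "start_date": c.start_date,
            "end_date": c.end_date,
            "censored": c.censored,
        }
        for c in cycles
    ]
    df = pd.DataFrame(rows, columns=["patient_id", "dmt", "start_date", "end_date", "censored"])
    if centre_by_patient is not None and len(df):
        df.insert(1, "centre_id", df["patient_id"].map(centre_by_patient))
    return df


def quality_filter(
    episodes: pd.DataFrame, patients: pd.DataFrame
) -> tuple[pd.DataFrame, FlowLog]:
    """Remove raw therapy-episode rows failing named validity rules.

    Rules applied in order: ``missing_start`` (no start date),
    ``invalid_interval`` (closed end on or before start), ``unknown_dmt``
    (label outside the known vocabulary), ``before_onset`` (start precedes
    the patient's recorded disease onset).  Open ends (NaT) are legitimate
    ongoing episodes and pass through.
    """
    log = FlowLog()
    df = episodes.copy()
    df["start_date"] = pd.to_datetime(df["start_date"], errors="coerce")
    df["end_date"] = pd.to_datetime(df["end_date"], errors="coerce")

    n = len(df)
    df = df[df["start_date"].notna()]
    log.record("missing_start", n, len(df))

    n = len(df)
    bad = df["end_date"].notna() & (df["end_date"] <= df["start_date"])
    df = df[~bad]
    log.record("invalid_interval", n, len(df))

    n = len(df)
    df = df[df["dmt_name"].isin(KNOWN_DMT_LABELS)]
    log.record("unknown_dmt", n, len(df))

    n = len(df)
    onset = patients.set_index("patient_id")["onset_date"]
    onset = pd.to_datetime(onset)
    ep_onset = df["patient_id"].map(onset)
    df = df[~(ep_onset.notna() & (df["start_date"] < ep_onset))]
    log.record("before_onset", n, len(df))

    return df.reset_index(drop=True), log


def censor_at_last_edss(
    cycles: pd.DataFrame,
    visits: pd.DataFrame,
    cutoff_date,
    start_col: str = "start_date",
    end_col: str = "end_date",
    censored_col: str = "censored",
) -> tuple[pd.DataFrame, FlowLog]:
    """Censor open/over-running intervals at the last EDSS before ``cutoff_date``.

    Any row whose ``end_date`` is missing or on/after the cutoff has its end
    replaced by the date of that patient's last EDSS measurement strictly
    before the cutoff and is flagged ``censored``.  Rows left with no
    qualifying measurement, or with zero follow-up after censoring, are
    dropped and logged.  Works on any frame with ``patient_id``, ``start_date``
    and ``end_date`` columns (raw episodes or switch-pair index cycles).
    """
    cutoff = pd.Timestamp(cutoff_date)
    log = FlowLog()
    df = cycles.copy()
    if censored_col not in df.columns:
        df[censored_col] = False
    if len(df) == 0:
        log.record("no_edss_before_cutoff", 0, 0)
        log.record("zero_followup", 0, 0)
        return df, log

    v = visits.copy()
    v["date"] = pd.to_datetime(v["date"])
    last_edss = (
        v[v["date"] < cutoff].groupby("patient_id")["date"].max()
    )

    end = pd.to_datetime(df[end_col])
    needs = end.isna() | (end >= cutoff)
    new_end = df["patient_id"].map(last_edss)

    n = len(df)
    dropped_no_edss = needs & new_end.isna()
    df = df[~dropped_no_edss]
    needs = needs[~dropped_no_edss]
    new_end = new_end[~dropped_no_edss]
    log.record("no_edss_before_cutoff", n, len(df))

    df.loc[needs, end_col] = new_end[needs]
    df.loc[needs, censored_col] = True

    n = len(df)
    df = df[pd.to_datetime(df[end_col]) > pd.to_datetime(df[start_col])]
    log.record("zero_followup", n, len(df))
    return df.reset_index(drop=True), log


def make_switch_pairs(cycles: pd.DataFrame) -> pd.DataFrame:
    """Form (current, index) pairs from consecutive cycles of each patient."""
    rows = []
    for pid, grp in cycles.groupby("patient_id", sort=True):
        grp = grp.sort_values("start_date")
        recs = grp.to_dict("records")
        for cur, idx in zip(recs[:-1], recs[1:]):
            rows.append(
                {
                    "patient_id": pid,
                    "centre_id": cur.get("centre_id"),
                    "current_dmt": cur["dmt"],
                    "current_start": cur["start_date"],
                    "current_end": cur["end_date"],
                    "index_dmt": idx["dmt"],
                    "index_start": idx["start_date"],
                    "index_end": idx["end_date"],
                    "index_censored": bool(idx.get("censored", False)),
                }
            )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def eligibility_filter(
    pairs: pd.DataFrame, patients: pd.DataFrame, registry_start
) -> tuple[pd.DataFrame, FlowLog]:
    """Apply the target-population rules to switch pairs, logging each removal.

    Keeps pairs whose index DMT is one of the six modelled treatments, whose
    patient is an adult with relapsing-remitting course, and whose index
    therapy starts no earlier than both the registry foundation date and six
    months after diagnosis.  Missing birth/diagnosis dates or course labels
    fall under ``complete_case``.
    """
    registry_start = pd.Timestamp(registry_start)
    log = FlowLog()
    df = pairs.copy()
    pat = patients.set_index("patient_id")
    birth = pd.to_datetime(pat["birth_date"])
    diag = pd.to_datetime(pat["diagnosis_date"])
    course = pat["course_label"]

    n = len(df)
    df = df[df["index_dmt"].isin(DMT6)]
    log.record("index_dmt_not_eligible", n, len(df))

    n = len(df)
    b = df["patient_id"].map(birth)
    d = df["patient_id"].map(diag)
    c = df["patient_id"].map(course)
    ok = b.notna() & d.notna() & c.notna()
    df, b, d, c = df[ok], b[ok], d[ok], c[ok]
    log.record("complete_case", n, len(df))

    n = len(df)
    start = pd.to_datetime(df["index_start"])
    age_years = (start - b).dt.days / DAYS_PER_YEAR
    keep = age_years >= 18
    df, d, c, start = df[keep], d[keep], c[keep], start[keep]
    log.record("adult", n, len(df))

    n = len(df)
    keep = start >= d + pd.Timedelta(days=SIX_MONTHS_DAYS)
    df, c, start = df[keep], c[keep], start[keep]
    log.record("min_6_months_post_diagnosis", n, len(df))

    n = len(df)
    keep = start >= registry_start
    df, c = df[keep], c[keep]
    log.record("before_registry_start", n, len(df))

    n = len(df)
    df = df[c == RRMS]
    log.record("non_rrms_course", n, len(df))

    return df.reset_index(drop=True), log


def select_one_cycle_per_patient(pairs: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Pick exactly one switch pair per patient uniformly at random (seeded)."""
    rng = np.random.default_rng(seed)
    chosen = []
    for _, grp in pairs.sort_values(["patient_id", "index_start"]).groupby(
        "patient_id", sort=True
    ):
        chosen.append(grp.index[rng.integers(len(grp))])
    return pairs.loc[chosen].reset_index(drop=True)


def temporal_split(
    pairs: pd.DataFrame, split_date, train_includes_boundary: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split on index-therapy start: strictly before ``split_date`` -> train.

    The boundary convention is declared (and flippable): an index therapy
    starting exactly on the split date goes to the test set by default.
    """
    split = pd.Timestamp(split_date)
    start = pd.to_datetime(pairs["index_start"])
    in_train = start <= split if train_includes_boundary else start < split
    train = pairs[in_train].reset_index(drop=True)
    test = pairs[~in_train].reset_index(drop=True)
    return train, test
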