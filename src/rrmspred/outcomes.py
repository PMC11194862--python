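"""Effectiveness outcomes of an index therapy cycle.

Two outcomes are derived per cycle: the number of on-therapy relapses and the
occurrence of confirmed disability progression (CDP).  CDP is a sustained,
confirmed step increase of the EDSS score: at least 1.0 point above baseline
(0.5 if baseline EDSS exceeds 5.5), not undercut during the following three
months, and confirmed by a later measurement that itself meets the threshold,
falls between three months after the increase and twelve months after the end
of therapy, and is at least three months after any relapse.  Cycles without a
baseline or on-therapy EDSS measurement count as CDP-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .vocab import THREE_MONTHS_DAYS, TWELVE_MONTHS_DAYS, DAYS_PER_YEAR

#: sustainment compares post-candidate values against the progression threshold
SUSTAIN_THRESHOLD = "threshold"
#: alternative: compare against the candidate measurement's own value
SUSTAIN_CANDIDATE_VALUE = "candidate_value"


@dataclass(frozen=True)
class CdpDetail:
    baseline_edss: float
    threshold: float
    candidate_date: pd.Timestamp
    confirmation_date: pd.Timestamp


@dataclass(frozen=True)
class OutcomeRecord:
    relapse_count: int
    cdp: bool
    duration_years: float
    cdp_detail: Optional[CdpDetail] = None

    def __post_init__(self):
        if self.duration_years <= 0:
            raise ValueError("duration must be positive")
        if self.relapse_count < 0:
            raise ValueError("relapse_count must be non-negative")


def _days(delta) -> float:
    return delta / pd.Timedelta(days=1)


def count_on_therapy_relapses(cycle, relapse_dates) -> int:
    """Count relapses in the half-open interval [start_date, end_date)."""
    dates = pd.to_datetime(pd.Series(list(relapse_dates), dtype="object"))
    if dates.empty:
        return 0
    return int(((dates >= cycle.start_date) & (dates < cycle.end_date)).sum())


def baseline_edss(cycle, visits: pd.DataFrame) -> Optional[float]:
    """Most recent EDSS measured on or before the cycle start; None if absent."""
    if len(visits) == 0:
        return None
    v = visits.sort_values("date")
    pre = v[pd.to_datetime(v["date"]) <= cycle.start_date]
    if pre.empty:
        return None
    return float(pre["edss"].iloc[-1])


def detect_cdp(
    cycle,
    visits: pd.DataFrame,
    relapse_dates,
    sustain_mode: str = SUSTAIN_THRESHOLD,
    relapse_guard_days: float = THREE_MONTHS_DAYS,
    confirm_gap_days: float = THREE_MONTHS_DAYS,
    tail_days: float = TWELVE_MONTHS_DAYS,
) -> tuple[bool, Optional[CdpDetail]]:
    """Detect confirmed disability progression during an index cycle.

    Parameters
    ----------
    cycle
        Object with ``start_date`` and ``end_date`` timestamps.
    visits
        The patient's EDSS table (``date``, ``edss``); sorted internally.
    relapse_dates
        Iterable of the patient's relapse dates.
    sustain_mode
        ``"threshold"`` (default): the increase is sustained if no measurement
        within three months after the candidate falls below the progression
        threshold.  ``"candidate_value"``: below the candidate's own value.

    Returns
    -------
    (bool, CdpDetail | None) — verdict and the first qualifying
    candidate/confirmation pair.
    """
    if sustain_mode not in (SUSTAIN_THRESHOLD, SUSTAIN_CANDIDATE_VALUE):
        raise ValueError(f"unknown sustain_mode {sustain_mode!r}")

    v = visits.copy()
    v["date"] = pd.to_datetime(v["date"])
    v = v.sort_values("date", kind="mergesort").reset_index(drop=True)
    rel = pd.to_datetime(pd.Series(list(relapse_dates), dtype="object"))

    b = baseline_edss(cycle, v)
    if b is None:
        return False, None

    on = v[(v["date"] > cycle.start_date) & (v["date"] <= cycle.end_date)]
    if on.empty:
        return False, None

    t = b + (0.5 if b > 5.5 else 1.0)
    horizon = cycle.end_date + pd.Timedelta(days=tail_days)

    for _, cand in on[on["edss"] >= t].iterrows():
        limit = t if sustain_mode == SUSTAIN_THRESHOLD else cand["edss"]
        win = v[
            (v["date"] > cand["date"])
            & (_days(v["date"] - cand["date"]) <= THREE_MONTHS_DAYS)
        ]
        if (win["edss"] < limit).any():
            continue

        conf = v[
            (_days(v["date"] - cand["date"]) > confirm_gap_days)
            & (v["date"] <= horizon)
            & (v["edss"] >= t)
        ]
        for _, c in conf.iterrows():
            gaps = _days(c["date"] - rel) if len(rel) else pd.Series(dtype=float)
            if len(gaps) and ((gaps >= 0) & (gaps < relapse_guard_days)).any():
                continue
            return True, CdpDetail(b, t, cand["date"], c["date"])
    return False, None


def derive_outcomes(
    pairs: pd.DataFrame,
    visits: pd.DataFrame,
    relapses: pd.DataFrame,
    **cdp_kwargs,
) -> pd.DataFrame:
    """Compute both outcomes for every switch pair (vectorized over patients)."""
    v = visits.copy()
    v["date"] = pd.to_datetime(v["date"])
    r = relapses.copy()
    r["date"] = pd.to_datetime(r["date"])
    visits_by = dict(tuple(v.groupby("patient_id")))
    relapses_by = dict(tuple(r.groupby("patient_id")))
    empty_v = v.iloc[:0]

    rows = []
    for rec in pairs.itertuples(index=False):
        cycle = _Interval(rec.index_start, rec.index_end)
        pv = visits_by.get(rec.patient_id, empty_v)
        pr = relapses_by.get(rec.patient_id)
        pr_dates = pr["date"].tolist() if pr is not None else []
        n_rel = count_on_therapy_relapses(cycle, pr_dates)
        cdp, detail = detect_cdp(cycle, pv, pr_dates, **cdp_kwargs)
        dur = _days(cycle.end_date - cycle.start_date) / DAYS_PER_YEAR
        rows.append(
            {
                "patient_id": rec.patient_id,
                "relapse_count": n_rel,
                "cdp": int(cdp),
                "duration_years": dur,
                "cdp_candidate_date": detail.candidate_date if detail else pd.NaT,
                "cdp_confirmation_date": detail.confirmation_date if detail else pd.NaT,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "relapse_count",
            "cdp",
            "duration_years",
            "cdp_candidate_date",
            "cdp_confirmation_date",
        ],
    )


class _Interval:
    __slots__ = ("start_date", "end_date")

    def __init__(self, start, end):
        self.start_date = pd.Timestamp(start)
        self.end_date = pd.Timestamp(end)
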