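"""Baseline predictor derivation, coding, standardization and design matrices.

Eleven predictors are assessed at baseline (the index-therapy start):
age group, sex, baseline EDSS group, time since last relapse, relapse count in
the previous year, time since disease onset, number of prior DMT cycles,
current therapy and its duration, index therapy, and prior second-line
exposure; the log index-therapy duration is carried along as the count-model
offset.  Categorical coding is nominal dummy (treatment-vs-reference) coding;
continuous predictors are standardized with training-set statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import vocab
from .outcomes import baseline_edss
from .vocab import (
    CONTINUOUS_PREDICTORS,
    DAYS_PER_YEAR,
    DMT6,
    FACTOR_LEVELS,
    NODMT,
    SECOND_LINE,
)

FEATURE_COLUMNS = [
    "age_cat",
    "sex",
    "edss_cat",
    "relapse_distance_cat",
    "relapse_count_prev_year",
    "onset_distance",
    "dmt_count_cat",
    "current_therapy",
    "current_duration",
    "index_therapy",
    "second_line_prior",
]

#: default reference levels — the most frequent categories of the source
#: population's training column; overridable per analysis.
DEFAULT_REFERENCES = {
    "age_cat": "31 to 40",
    "sex": "F",
    "edss_cat": "1.5 or less",
    "relapse_distance_cat": "0.25 to 0.99",
    "dmt_count_cat": "1",
    "current_therapy": NODMT,
    "index_therapy": "fingolimod",
}

#: default interaction terms (treatment-by-prognostic-factor structure)
DEFAULT_INTERACTIONS = [
    ("current_therapy", "current_duration"),
    ("index_therapy", "relapse_count_prev_year"),
    ("index_therapy", "relapse_distance_cat"),
]


@dataclass(frozen=True)
class InteractionSpec:
    """Pairs of factors to interact plus the reference level per categorical."""

    interactions: tuple = tuple(DEFAULT_INTERACTIONS)
    references: dict = field(default_factory=lambda: dict(DEFAULT_REFERENCES))

    def __post_init__(self):
        for fac, ref in self.references.items():
            if fac not in FACTOR_LEVELS:
                raise ValueError(f"unknown factor {fac!r}")
            if ref not in FACTOR_LEVELS[fac]:
                raise ValueError(f"{ref!r} is not a level of {fac!r}")
        for a, b in self.interactions:
            for term in (a, b):
                if term not in FACTOR_LEVELS and term not in CONTINUOUS_PREDICTORS:
                    raise ValueError(f"interaction references unknown predictor {term!r}")


@dataclass(frozen=True)
class StandardizationParams:
    """Per-predictor (mean, sd) learned on the training set."""

    stats: dict  # name -> (mean, sd)

    def __post_init__(self):
        for name, (_, sd) in self.stats.items():
            if sd <= 0:
                raise ValueError(f"zero standard deviation for predictor {name!r}")


def age_category(age_years: float) -> str:
    if age_years <= 30:
        return "30 or younger"
    if age_years <= 40:
        return "31 to 40"
    if age_years <= 50:
        return "41 to 50"
    return "51 or older"


def edss_category(edss: float) -> str:
    if edss <= 1.5:
        return "1.5 or less"
    if edss <= 2.5:
        return "2 to 2.5"
    if edss <= 3.5:
        return "3 to 3.5"
    return "4 to 10"


def relapse_distance_category(years: float) -> str:
    if years < 0.25:
        return "less than 0.25"
    if years < 1:
        return "0.25 to 0.99"
    if years < 3:
        return "1 to 2.99"
    return "3 or more"


def dmt_count_category(n: int) -> str:
    return str(n) if n < 3 else "3 or more"


def derive_features(
    pair,
    patient,
    visits: pd.DataFrame,
    relapses: pd.DataFrame,
    prior_cycles: pd.DataFrame,
    never_relapsed_distance_cat: str = "3 or more",
) -> dict:
    """Derive the 11-predictor feature vector for one switch pair.

    ``pair`` needs current/index cycle fields (as produced by
    :func:`rrmspred.timelines.make_switch_pairs`); ``prior_cycles`` are all of
    the patient's cycles starting before the index cycle.  Returns a dict with
    an ``incomplete`` flag set when any component cannot be derived; incomplete
    rows are meant to flow into complete-case removal, never to raise.
    """
    baseline = pd.Timestamp(pair.index_start)
    out: dict = {"patient_id": pair.patient_id, "incomplete": False}

    def miss():
        out["incomplete"] = True

    birth = pd.Timestamp(patient["birth_date"]) if pd.notna(patient["birth_date"]) else None
    if birth is None:
        miss()
        out["age_cat"] = None
    else:
        out["age_cat"] = age_category((baseline - birth).days / DAYS_PER_YEAR)

    out["sex"] = patient.get("sex") if patient.get("sex") in vocab.SEX_LEVELS else None
    if out["sex"] is None:
        miss()

    cycle = _Cycle(pair.index_start, pair.index_end)
    b_edss = baseline_edss(cycle, visits)
    if b_edss is None:
        miss()
        out["edss_cat"] = None
    else:
        out["edss_cat"] = edss_category(b_edss)

    rel = pd.to_datetime(relapses["date"]) if len(relapses) else pd.Series(dtype="datetime64[ns]")
    prior_rel = rel[rel <= baseline]
    if prior_rel.empty:
        out["relapse_distance_cat"] = never_relapsed_distance_cat
    else:
        dist = (baseline - prior_rel.max()).days / DAYS_PER_YEAR
        out["relapse_distance_cat"] = relapse_distance_category(dist)
    year_ago = baseline - pd.Timedelta(days=DAYS_PER_YEAR)
    out["relapse_count_prev_year"] = int(((rel > year_ago) & (rel <= baseline)).sum())

    onset = pd.Timestamp(patient["onset_date"]) if pd.notna(patient["onset_date"]) else None
    if onset is None or onset > baseline:
        miss()
        out["onset_distance"] = np.nan
    else:
        out["onset_distance"] = (baseline - onset).days / DAYS_PER_YEAR

    dmt_cycles = prior_cycles[~prior_cycles["dmt"].isin([NODMT, vocab.OTHERDMT])]
    out["dmt_count_cat"] = dmt_count_category(len(dmt_cycles))
    out["second_line_prior"] = bool(dmt_cycles["dmt"].isin(SECOND_LINE).any())

    if pair.current_dmt in FACTOR_LEVELS["current_therapy"]:
        out["current_therapy"] = pair.current_dmt
    else:
        out["current_therapy"] = None
        miss()
    cur_dur = (pd.Timestamp(pair.current_end) - pd.Timestamp(pair.current_start)).days / DAYS_PER_YEAR
    if cur_dur <= 0:
        miss()
        out["current_duration"] = np.nan
    else:
        out["current_duration"] = cur_dur

    if pair.index_dmt in DMT6:
        out["index_therapy"] = pair.index_dmt
    else:
        out["index_therapy"] = None
        miss()

    dur = (pd.Timestamp(pair.index_end) - baseline).days / DAYS_PER_YEAR
    if dur <= 0:
        miss()
        out["log_offset"] = np.nan
    else:
        out["log_offset"] = float(np.log(dur))
    return out


class _Cycle:
    __slots__ = ("start_date", "end_date")

    def __init__(self, start, end):
        self.start_date = pd.Timestamp(start)
        self.end_date = pd.Timestamp(end)


def derive_feature_table(
    pairs: pd.DataFrame,
    patients: pd.DataFrame,
    visits: pd.DataFrame,
    relapses: pd.DataFrame,
    cycles: pd.DataFrame,
    **kwargs,
) -> pd.DataFrame:
    """Apply :func:`derive_features` to every pair; one row per pair."""
    pat = patients.set_index("patient_id")
    visits_by = dict(tuple(visits.groupby("patient_id")))
    relapses_by = dict(tuple(relapses.groupby("patient_id")))
    cycles_by = dict(tuple(cycles.groupby("patient_id"))) if len(cycles) else {}
    empty_v = visits.iloc[:0]
    empty_r = relapses.iloc[:0]
    empty_c = cycles.iloc[:0]

    rows = []
    for pair in pairs.itertuples(index=False):
        pc = cycles_by.get(pair.patient_id, empty_c)
        prior = pc[pd.to_datetime(pc["start_date"]) < pd.Timestamp(pair.index_start)]
        rows.append(
            derive_features(
                pair,
                pat.loc[pair.patient_id],
                visits_by.get(pair.patient_id, empty_v),
                relapses_by.get(pair.patient_id, empty_r),
                prior,
                **kwargs,
            )
        )
    return pd.DataFrame(rows)


def fit_standardization(
    train_rows: pd.DataFrame, predictors=CONTINUOUS_PREDICTORS
) -> StandardizationParams:
    """Learn (mean, sd) of each continuous predictor from the training rows."""
    if len(train_rows) == 0:
        raise ValueError("empty training set")
    stats = {}
    for name in predictors:
        col = train_rows[name].astype(float)
        sd = float(col.std(ddof=0))
        if sd <= 0 or not np.isfinite(sd):
            raise ValueError(f"zero standard deviation for predictor {name!r}")
        stats[name] = (float(col.mean()), sd)
    return StandardizationParams(stats)


def apply_standardization(params: StandardizationParams, rows: pd.DataFrame) -> pd.DataFrame:
    out = rows.copy()
    for name, (mean, sd) in params.stats.items():
        out[name] = (out[name].astype(float) - mean) / sd
    return out


def _dummy_cols(factor: str, ref: str) -> list[tuple[str, str]]:
    return [(factor, lvl) for lvl in FACTOR_LEVELS[factor] if lvl != ref]


def build_design_matrix(
    rows: pd.DataFrame, spec: InteractionSpec | None = None
) -> tuple[np.ndarray, list[str]]:
    """Build the nominal-coded design matrix (no intercept column).

    Main effects in canonical predictor order followed by interaction product
    columns; dummy columns are named ``factor[level]`` and interactions
    ``a[level]:b`` / ``a[la]:b[lb]``.  Raises on categories outside the
    declared vocabularies.
    """
    spec = spec or InteractionSpec()
    refs = {**DEFAULT_REFERENCES, **spec.references}
    n = len(rows)
    cols: list[np.ndarray] = []
    names: list[str] = []

    base: dict[str, np.ndarray] = {}

    def factor_dummy(factor: str, level: str) -> np.ndarray:
        key = f"{factor}[{level}]"
        if key not in base:
            vals = rows[factor]
            bad = ~vals.isin(FACTOR_LEVELS[factor])
            if bad.any():
                raise ValueError(
                    f"unknown category {vals[bad].iloc[0]!r} in factor {factor!r}"
                )
            base[key] = (vals == level).to_numpy(dtype=float)
        return base[key]

    def continuous(name: str) -> np.ndarray:
        return rows[name].to_numpy(dtype=float)

    for pred in FEATURE_COLUMNS:
        if pred in FACTOR_LEVELS:
            for factor, lvl in _dummy_cols(pred, refs[pred]):
                cols.append(factor_dummy(factor, lvl))
                names.append(f"{factor}[{lvl}]")
        elif pred == "second_line_prior":
            cols.append(rows[pred].astype(bool).to_numpy(dtype=float))
            names.append(pred)
        else:
            cols.append(continuous(pred))
            names.append(pred)

    for a, b in spec.interactions:
        a_cat, b_cat = a in FACTOR_LEVELS, b in FACTOR_LEVELS
        if a_cat and b_cat:
            for fa, la in _dummy_cols(a, refs[a]):
                for fb, lb in _dummy_cols(b, refs[b]):
                    cols.append(factor_dummy(fa, la) * factor_dummy(fb, lb))
                    names.append(f"{fa}[{la}]:{fb}[{lb}]")
        elif a_cat and not b_cat:
            for fa, la in _dummy_cols(a, refs[a]):
                cols.append(factor_dummy(fa, la) * continuous(b))
                names.append(f"{fa}[{la}]:{b}")
        elif b_cat and not a_cat:
            for fb, lb in _dummy_cols(b, refs[b]):
                cols.append(continuous(a) * factor_dummy(fb, lb))
                names.append(f"{a}:{fb}[{lb}]")
        else:
            cols.append(continuous(a) * continuous(b))
            names.append(f"{a}:{b}")

    X = np.column_stack(cols) if cols else np.empty((n, 0))
    return X, names


def complete_cases(rows: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows flagged incomplete; returns (kept rows, number removed)."""
    keep = ~rows["incomplete"].astype(bool)
    return rows[keep].reset_index(drop=True), int((~keep).sum())
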