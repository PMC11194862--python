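"""Synthetic registry generation with known ground truth.

Two tiers are provided.  :func:`generate_cycle_table` samples analysis-ready
cycle rows directly from the outcome model families (negative-binomial counts
with a log-duration offset and centre random intercepts; Bernoulli CDP), so
model fits can be checked against the exact generating coefficients.
:func:`generate_raw_registry` emits raw longitudinal tables — patients, EDSS
visits, relapse events and therapy episodes — to exercise the full pipeline,
including planted EDSS trajectories that satisfy the CDP definition by
construction and near-miss trajectories violating exactly one CDP condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from . import vocab
from .features import InteractionSpec, build_design_matrix
from .vocab import DAYS_PER_YEAR, DMT6, NODMT

PLANT_POSITIVE = "positive"
PLANT_NEAR_SUSTAIN = "near_miss_sustain"
PLANT_NEAR_WINDOW = "near_miss_window"
PLANT_NEAR_RELAPSE = "near_miss_relapse"
PLANT_KINDS = (PLANT_POSITIVE, PLANT_NEAR_SUSTAIN, PLANT_NEAR_WINDOW, PLANT_NEAR_RELAPSE)


def default_case_mix() -> dict:
    """Category frequencies approximating the training-population case mix."""
    return {
        "age_cat": {"30 or younger": 0.17, "31 to 40": 0.33, "41 to 50": 0.31, "51 or older": 0.19},
        "sex": {"F": 0.75, "M": 0.25},
        "edss_cat": {"1.5 or less": 0.44, "2 to 2.5": 0.24, "3 to 3.5": 0.14, "4 to 10": 0.18},
        "relapse_distance_cat": {
            "less than 0.25": 0.07,
            "0.25 to 0.99": 0.36,
            "1 to 2.99": 0.28,
            "3 or more": 0.29,
        },
        "dmt_count_cat": {"0": 0.26, "1": 0.37, "2": 0.21, "3 or more": 0.16},
        "current_therapy": {
            "dimethyl fumarate": 0.03,
            "fingolimod": 0.02,
            "glatiramer acetate": 0.11,
            "interferon beta1": 0.22,
            "natalizumab": 0.09,
            "teriflunomide": 0.01,
            NODMT: 0.52,
        },
        "index_therapy": {
            "dimethyl fumarate": 0.20,
            "fingolimod": 0.25,
            "glatiramer acetate": 0.12,
            "interferon beta1": 0.16,
            "natalizumab": 0.10,
            "teriflunomide": 0.17,
        },
        "second_line_prior": {True: 0.19, False: 0.81},
    }


def default_duration_dist() -> dict:
    # log-normal parameters chosen to approximate registry medians/IQRs
    return {
        "index_median": 1.37,
        "index_sigma": 0.7,
        "current_median": 2.0,
        "current_sigma": 1.0,
        "onset_median": 7.5,
        "onset_sigma": 0.8,
        "gap_median": 0.5,
        "gap_sigma": 1.0,
        "prev_year_relapse_rate": 0.6,
    }


@dataclass
class SimConfig:
    """Ground-truth parameters of the synthetic registry."""

    n_centres: int = 20
    n_patients: int = 1000
    sigma_centre: float = 0.3
    beta_relapse: dict = field(default_factory=lambda: {"intercept": np.log(0.3)})
    phi: float = 1.0
    beta_cdp: dict = field(default_factory=lambda: {"intercept": -2.3})
    case_mix: dict = field(default_factory=default_case_mix)
    duration_dist: dict = field(default_factory=default_duration_dist)
    visit_interval_days: tuple = (90.0, 30.0)
    study_window: tuple = ("2011-01-01", "2021-12-15")
    cdp_plant_rate: float = 0.0
    gap_rate: float = 0.4
    overlap_rate: float = 0.1
    seed: int = 0
    interaction_spec: InteractionSpec = field(default_factory=InteractionSpec)

    def validate(self) -> None:
        if self.n_centres < 1 or self.n_patients < 0:
            raise ValueError("need n_centres >= 1 and n_patients >= 0")
        if self.n_patients and self.n_patients < self.n_centres:
            raise ValueError("need n_patients >= n_centres")
        if self.sigma_centre < 0:
            raise ValueError("sigma_centre must be non-negative")
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if not (0 <= self.cdp_plant_rate <= 1):
            raise ValueError("cdp_plant_rate must be in [0, 1]")
        if self.visit_interval_days[0] <= 0:
            raise ValueError("visit_interval_days mean must be positive")
        start, end = (pd.Timestamp(d) for d in self.study_window)
        if not start < end:
            raise ValueError("empty study window")
        for pred, freqs in self.case_mix.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-8:
                raise ValueError(f"case_mix frequencies for {pred!r} sum to {total}, not 1")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["interaction_spec"] = {
            "interactions": [list(p) for p in self.interaction_spec.interactions],
            "references": dict(self.interaction_spec.references),
        }
        d["beta_relapse"] = {k: float(v) for k, v in self.beta_relapse.items()}
        d["beta_cdp"] = {k: float(v) for k, v in self.beta_cdp.items()}
        d["case_mix"] = {
            p: {str(k): float(v) for k, v in f.items()} for p, f in self.case_mix.items()
        }
        return d


@dataclass
class RegistryBundle:
    """The four linked longitudinal tables plus optional planted-CDP truth."""

    patients: pd.DataFrame
    visits: pd.DataFrame
    relapses: pd.DataFrame
    therapies: pd.DataFrame
    cdp_truth: Optional[pd.DataFrame] = None

    def save(self, outdir, config: SimConfig | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(outdir / "patients.csv", index=False, date_format="%Y-%m-%d")
        self.visits.to_csv(outdir / "visits.csv", index=False, date_format="%Y-%m-%d")
        self.relapses.to_csv(outdir / "relapses.csv", index=False, date_format="%Y-%m-%d")
        self.therapies.to_csv(outdir / "therapies.csv", index=False, date_format="%Y-%m-%d")
        if self.cdp_truth is not None:
            self.cdp_truth.to_csv(outdir / "cdp_truth.csv", index=False, date_format="%Y-%m-%d")
        if config is not None:
            with open(outdir / "truth.json", "w") as fh:
                json.dump(config.to_jsonable(), fh, indent=2, default=str)

    @classmethod
    def load(cls, indir) -> "RegistryBundle":
        indir = Path(indir)
        date_cols = {
            "patients": ["birth_date", "onset_date", "diagnosis_date"],
            "visits": ["date"],
            "relapses": ["date"],
            "therapies": ["start_date", "end_date"],
        }
        frames = {}
        for name, cols in date_cols.items():
            df = pd.read_csv(indir / f"{name}.csv")
            for c in cols:
                df[c] = pd.to_datetime(df[c], errors="coerce")
            frames[name] = df
        truth_path = indir / "cdp_truth.csv"
        truth = None
        if truth_path.exists():
            truth = pd.read_csv(truth_path, parse_dates=["start_date", "end_date"])
        return cls(**frames, cdp_truth=truth)


@dataclass
class CycleDataset:
    """Analysis-ready cycle rows with the generating truth attached."""

    features: pd.DataFrame
    centre_id: np.ndarray
    index_duration: np.ndarray
    relapse_count: np.ndarray
    cdp: np.ndarray
    design: np.ndarray
    design_names: list
    truth: SimConfig
    centre_effects_relapse: np.ndarray
    centre_effects_cdp: np.ndarray


def _sample_categorical(rng, freqs: dict, n: int):
    levels = list(freqs.keys())
    probs = np.array([freqs[l] for l in levels], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(len(levels), size=n, p=probs), levels


def _lognormal(rng, median: float, sigma: float, n: int, floor: float = 0.01):
    return np.maximum(floor, rng.lognormal(np.log(median), sigma, size=n))


def sample_feature_table(config: SimConfig, n_rows: int, rng) -> pd.DataFrame:
    """Draw n_rows feature vectors from the configured case mix."""
    cm = config.case_mix
    dd = config.duration_dist
    out = {}
    for factor in ("age_cat", "sex", "edss_cat", "relapse_distance_cat", "dmt_count_cat",
                   "current_therapy", "index_therapy"):
        idx, levels = _sample_categorical(rng, cm[factor], n_rows)
        out[factor] = pd.Categorical.from_codes(idx, levels).astype(object)
    idx, levels = _sample_categorical(rng, cm["second_line_prior"], n_rows)
    out["second_line_prior"] = np.array([levels[i] for i in idx], dtype=bool)
    out["relapse_count_prev_year"] = rng.poisson(dd["prev_year_relapse_rate"], size=n_rows)
    out["onset_distance"] = 0.5 + _lognormal(rng, dd["onset_median"], dd["onset_sigma"], n_rows)
    out["current_duration"] = _lognormal(rng, dd["current_median"], dd["current_sigma"], n_rows)
    return pd.DataFrame(out)


def beta_vector(beta: dict, names: list[str]) -> tuple[float, np.ndarray]:
    """Split a coefficient mapping into (intercept, slope vector over names)."""
    unknown = set(beta) - set(names) - {"intercept"}
    if unknown:
        raise ValueError(f"coefficients not in design: {sorted(unknown)}")
    b0 = float(beta.get("intercept", 0.0))
    return b0, np.array([float(beta.get(n, 0.0)) for n in names])


def random_truth(names: list[str], X: np.ndarray, rng, scale: float = 0.3) -> dict:
    """Random generating coefficients, shrunk on wide-amplitude columns.

    Scaling by a robust column amplitude (not the SD) keeps the linear
    predictor bounded even for long-tailed continuous covariates, so the
    implied outcome means stay in a realistic range.
    """
    med = np.median(X, axis=0)
    amp = np.quantile(np.abs(X - med), 0.995, axis=0)
    beta = {
        name: float(rng.normal(0.0, scale / max(1.0, a)))
        for name, a in zip(names, amp)
    }
    return beta


def generate_cycle_table(config: SimConfig, n_rows: int) -> CycleDataset:
    """Sample cycle-level rows directly from the generative outcome models.

    Covariates come from the case mix, centre intercepts from
    Normal(0, sigma_centre^2) (independently for the two outcomes), relapse
    counts from NegBin(mean = exp(x'b + u_c + log d), dispersion phi) and CDP
    from Bernoulli(invlogit(x'b' + u'_c)).  Fully reproducible from the
    config seed.
    """
    config.validate()
    if n_rows <= 0:
        raise ValueError("n_rows must be positive")
    rng = np.random.default_rng(config.seed)

    feats = sample_feature_table(config, n_rows, rng)
    X, names = build_design_matrix(feats, config.interaction_spec)

    dd = config.duration_dist
    d = _lognormal(rng, dd["index_median"], dd["index_sigma"], n_rows, floor=0.05)

    centre = rng.integers(config.n_centres, size=n_rows)
    u_rel = rng.normal(0.0, config.sigma_centre, size=config.n_centres)
    u_cdp = rng.normal(0.0, config.sigma_centre, size=config.n_centres)

    b0_rel, b_rel = beta_vector(config.beta_relapse, names)
    b0_cdp, b_cdp = beta_vector(config.beta_cdp, names)

    mu = np.exp(b0_rel + X @ b_rel + u_rel[centre] + np.log(d))
    y_rel = rng.negative_binomial(config.phi, config.phi / (config.phi + mu))

    p = expit(b0_cdp + X @ b_cdp + u_cdp[centre])
    y_cdp = rng.binomial(1, p)

    feats = feats.copy()
    feats["log_offset"] = np.log(d)
    return CycleDataset(
        features=feats,
        centre_id=centre,
        index_duration=d,
        relapse_count=y_rel,
        cdp=y_cdp,
        design=X,
        design_names=names,
        truth=config,
        centre_effects_relapse=u_rel,
        centre_effects_cdp=u_cdp,
    )


def _round_edss(x: float) -> float:
    return float(np.clip(np.round(x * 2) / 2, 0.0, 10.0))


def _plant_trajectory(kind: str, start: pd.Timestamp, end: pd.Timestamp, b: float):
    """Visits/relapses realizing (or near-missing) the CDP rule on [start, end]."""
    t = b + 1.0
    day = pd.Timedelta(days=1)
    visits = [(start - 20 * day, b), (start + 90 * day, t)]
    relapses: list[pd.Timestamp] = []
    cand = start + 90 * day
    if kind == PLANT_POSITIVE:
        visits.append((cand + 150 * day, t))
    elif kind == PLANT_NEAR_SUSTAIN:
        # dip below threshold inside the 3-month sustainment window
        visits.append((cand + 45 * day, b))
        visits.append((cand + 150 * day, t))
    elif kind == PLANT_NEAR_WINDOW:
        # only confirmation candidate lies beyond end + 12 months
        visits.append((end + 400 * day, t))
    elif kind == PLANT_NEAR_RELAPSE:
        conf = cand + 150 * day
        visits.append((conf, t))
        relapses.append(conf - 30 * day)
    else:
        raise ValueError(f"unknown plant kind {kind!r}")
    return visits, relapses


def generate_raw_registry(config: SimConfig) -> RegistryBundle:
    """Generate the four raw longitudinal tables plus planted-CDP truth labels."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    win_start, win_end = (pd.Timestamp(d) for d in config.study_window)
    span_days = (win_end - win_start).days
    dd = config.duration_dist
    mean_iv, jitter_iv = config.visit_interval_days
    day = pd.Timedelta(days=1)

    n_plant = int(round(config.cdp_plant_rate * config.n_patients))
    plant_ids = set(rng.choice(config.n_patients, size=n_plant, replace=False)) if n_plant else set()

    idx_freqs = config.case_mix["index_therapy"]
    dmt_levels = list(idx_freqs.keys())
    dmt_probs = np.array([idx_freqs[l] for l in dmt_levels])
    dmt_probs = dmt_probs / dmt_probs.sum()
    age_freqs = config.case_mix["age_cat"]
    age_bounds = {"30 or younger": (18, 30), "31 to 40": (31, 40), "41 to 50": (41, 50), "51 or older": (51, 70)}

    patients, visits, relapses, therapies, truth_rows = [], [], [], [], []

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        centre = f"C{rng.integers(config.n_centres):03d}"
        sex = "F" if rng.random() < config.case_mix["sex"]["F"] else "M"
        course = "RRMS" if rng.random() < 0.95 else "SPMS"
        planted = i in plant_ids
        plant_kind = PLANT_KINDS[len(truth_rows) % len(PLANT_KINDS)] if planted else None

        first_start = win_start + day * int(rng.uniform(0.05, 0.55) * span_days)
        age_idx, age_levels = _sample_categorical(rng, age_freqs, 1)
        lo, hi = age_bounds[age_levels[age_idx[0]]]
        age_years = rng.uniform(lo, hi)
        birth = first_start - day * int(age_years * DAYS_PER_YEAR)
        onset_years = max(0.6, rng.lognormal(np.log(dd["onset_median"]), dd["onset_sigma"]))
        onset = first_start - day * int(onset_years * DAYS_PER_YEAR)
        diag = min(onset + day * int(rng.uniform(30, 700)), first_start - 200 * day)
        diag = max(diag, onset)
        patients.append(
            {
                "patient_id": pid,
                "centre_id": centre,
                "sex": sex,
                "birth_date": birth,
                "onset_date": onset,
                "diagnosis_date": diag,
                "course_label": course,
            }
        )

        # therapy episodes
        episodes = []
        if planted:
            dur = rng.uniform(1.5, 2.5) * DAYS_PER_YEAR
            end = min(first_start + day * int(dur), win_end - 450 * day)
            dmt = dmt_levels[int(rng.choice(len(dmt_levels), p=dmt_probs))]
            episodes.append((dmt, first_start, end))
        else:
            n_ep = 1 + int(rng.poisson(1.2))
            cur = first_start
            for _ in range(min(n_ep, 5)):
                if cur >= win_end - 30 * day:
                    break
                if rng.random() < 0.03:
                    dmt = "rituximab"
                else:
                    dmt = dmt_levels[int(rng.choice(len(dmt_levels), p=dmt_probs))]
                dur_days = int(
                    max(60, rng.lognormal(np.log(dd["index_median"]), dd["index_sigma"]) * DAYS_PER_YEAR)
                )
                end = cur + day * dur_days
                open_end = end >= win_end
                episodes.append((dmt, cur, pd.NaT if open_end else end))
                if open_end:
                    break
                u = rng.random()
                if u < config.overlap_rate:
                    cur = end - day * max(1, int(rng.uniform(0.1, 0.5) * dur_days))
                elif u < config.overlap_rate + config.gap_rate:
                    gap = max(2, int(rng.lognormal(np.log(dd["gap_median"]), dd["gap_sigma"]) * DAYS_PER_YEAR))
                    cur = end + day * gap
                else:
                    cur = end
        for dmt, s, e in episodes:
            therapies.append({"patient_id": pid, "dmt_name": dmt, "start_date": s, "end_date": e})

        last_end = max(
            [e for _, _, e in episodes if pd.notna(e)] + [first_start + day * 365]
        )
        obs_start = max(win_start, first_start - day * int(1.5 * DAYS_PER_YEAR))
        obs_end = min(win_end, last_end + day * 365)

        if planted:
            s, e = episodes[0][1], episodes[0][2]
            b = float(rng.choice([1.0, 1.5, 2.0, 2.5, 3.0]))
            pv, prel = _plant_trajectory(plant_kind, s, e, b)
            for d_, val in pv:
                visits.append({"patient_id": pid, "date": d_, "edss": _round_edss(val)})
            for d_ in prel:
                relapses.append({"patient_id": pid, "date": d_})
            truth_rows.append(
                {
                    "patient_id": pid,
                    "start_date": s,
                    "end_date": e,
                    "kind": plant_kind,
                    "expected_cdp": plant_kind == PLANT_POSITIVE,
                }
            )
        else:
            edss = _round_edss(abs(rng.normal(2.0, 1.5)))
            d_ = obs_start
            while d_ <= obs_end:
                visits.append({"patient_id": pid, "date": d_, "edss": edss})
                step = rng.random()
                if step < 0.15:
                    edss = _round_edss(edss + 0.5)
                elif step < 0.30:
                    edss = _round_edss(edss - 0.5)
                d_ = d_ + day * max(7, int(rng.normal(mean_iv, jitter_iv)))
            # gamma frailty makes counts overdispersed across patients
            frailty = rng.gamma(1.5, 1 / 1.5)
            n_rel = rng.poisson(0.35 * frailty * (obs_end - obs_start).days / DAYS_PER_YEAR)
            for _ in range(n_rel):
                relapses.append(
                    {"patient_id": pid, "date": obs_start + day * int(rng.uniform(0, (obs_end - obs_start).days))}
                )

    bundle = RegistryBundle(
        patients=pd.DataFrame(
            patients,
            columns=["patient_id", "centre_id", "sex", "birth_date", "onset_date", "diagnosis_date", "course_label"],
        ),
        visits=pd.DataFrame(visits, columns=["patient_id", "date", "edss"]),
        relapses=pd.DataFrame(relapses, columns=["patient_id", "date"]),
        therapies=pd.DataFrame(therapies, columns=["patient_id", "dmt_name", "start_date", "end_date"]),
        cdp_truth=pd.DataFrame(
            truth_rows, columns=["patient_id", "start_date", "end_date", "kind", "expected_cdp"]
        ),
    )
    return bundle
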