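"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive every rule from scratch (plain loops and
pair enumeration) so the package implementations are checked against an
independent path, never against themselves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

DAY = pd.Timedelta(days=1)
THREE_MONTHS = 3 * 30.4375
TWELVE_MONTHS = 365.25


class Interval:
    def __init__(self, start, end):
        self.start_date = pd.Timestamp(start)
        self.end_date = pd.Timestamp(end)


def visits_frame(items):
    """items: iterable of (date-like, edss)."""
    return pd.DataFrame(
        {"date": [pd.Timestamp(d) for d, _ in items], "edss": [e for _, e in items]}
    )


def oracle_detect_cdp(cycle, visits, relapse_dates, sustain_mode="threshold"):
    """Brute force: enumerate every (candidate, confirmation) measurement pair
    and re-check all conditions independently."""
    # stable sort by date only: same-date measurements keep input order (the
    # declared tie-break convention, matched by the implementation)
    vs = [(pd.Timestamp(d), float(e)) for d, e in zip(visits["date"], visits["edss"])]
    vs.sort(key=lambda t: t[0])
    rels = [pd.Timestamp(d) for d in relapse_dates]
    start, end = cycle.start_date, cycle.end_date

    pre = [(d, e) for d, e in vs if d <= start]
    if not pre:
        return False
    b = pre[-1][1]
    on = [(d, e) for d, e in vs if start < d <= end]
    if not on:
        return False
    t = b + (0.5 if b > 5.5 else 1.0)

    for cd, ce in on:
        if ce < t:
            continue
        limit = t if sustain_mode == "threshold" else ce
        sustained = all(
            e >= limit
            for d, e in vs
            if cd < d and (d - cd) / DAY <= THREE_MONTHS
        )
        if not sustained:
            continue
        for dd, de in vs:
            if (dd - cd) / DAY <= THREE_MONTHS:
                continue
            if dd > end + TWELVE_MONTHS * DAY:
                continue
            if de < t:
                continue
            if any(0 <= (dd - r) / DAY < THREE_MONTHS for r in rels):
                continue
            return True
    return False


def oracle_count_relapses(cycle, relapse_dates):
    return sum(
        1
        for d in relapse_dates
        if cycle.start_date <= pd.Timestamp(d) < cycle.end_date
    )


def oracle_cindex(pred, obs):
    """O(n^2) pair enumeration; tied predictions score one half."""
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    conc = pairs = 0.0
    n = len(pred)
    for i in range(n):
        for j in range(i + 1, n):
            if obs[i] == obs[j]:
                continue
            pairs += 1
            hi = i if obs[i] > obs[j] else j
            lo = j if hi == i else i
            if pred[hi] > pred[lo]:
                conc += 1
            elif pred[hi] == pred[lo]:
                conc += 0.5
    return conc / pairs


def oracle_mse(pred, obs):
    total = 0.0
    for p, o in zip(pred, obs):
        total += (p - o) ** 2
    return total / len(pred)


def oracle_spearman(a, b):
    """Rank (mid-ranks for ties) then Pearson."""

    def ranks(x):
        x = np.asarray(x, float)
        order = np.argsort(x, kind="mergesort")
        r = np.empty(len(x))
        i = 0
        while i < len(x):
            j = i
            while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r

    ra, rb = ranks(a), ranks(b)
    ra -= ra.mean()
    rb -= rb.mean()
    return float((ra @ rb) / np.sqrt((ra @ ra) * (rb @ rb)))


def random_trajectory(rng):
    """One random cycle + visit/relapse series for CDP oracle comparison."""
    start = pd.Timestamp("2015-01-01") + int(rng.integers(0, 400)) * DAY
    end = start + int(rng.integers(120, 900)) * DAY
    n_v = int(rng.integers(0, 12))
    dates = start + (rng.integers(-300, (end - start) / DAY + 500, size=n_v)) * DAY
    edss = np.round(rng.uniform(0, 7, size=n_v) * 2) / 2
    visits = pd.DataFrame({"date": dates, "edss": edss})
    n_r = int(rng.integers(0, 4))
    rel = [start + int(d) * DAY for d in rng.integers(-200, (end - start) / DAY + 400, size=n_r)]
    return Interval(start, end), visits, rel


@pytest.fixture(scope="session")
def default_cycle_dataset():
    """Mid-sized cycle-level dataset with nonzero truth, reused across tests."""
    from rrmspred.synthetic_registry import SimConfig, generate_cycle_table, random_truth

    probe = generate_cycle_table(SimConfig(seed=0), 500)
    rng = np.random.default_rng(7)
    beta_rel = random_truth(probe.design_names, probe.design, rng, 0.3)
    beta_rel["intercept"] = float(np.log(0.3))
    beta_cdp = random_truth(probe.design_names, probe.design, rng, 0.3)
    beta_cdp["intercept"] = -2.2
    cfg = SimConfig(
        n_centres=20,
        sigma_centre=0.3,
        beta_relapse=beta_rel,
        beta_cdp=beta_cdp,
        phi=1.0,
        seed=11,
    )
    return generate_cycle_table(cfg, 3000)
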