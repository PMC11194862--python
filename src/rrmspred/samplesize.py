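"""Sample size for testing a C-index against a null value.

Solves for the smallest total N such that a two-sided level-alpha z-test of
the null concordance attains the target power at the alternative, with the
event fraction fixed at the given prevalence.  The default AUC variance is
Hanley-McNeil (1982); Noether's null variance is selectable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

METHODS = ("hanley", "noether")

_N_MAX = 10_000_000


@dataclass(frozen=True)
class SampleSizeSpec:
    c_null: float
    c_alt: float
    alpha: float = 0.05
    power: float = 0.9
    prevalence: float = 0.25

    def __post_init__(self):
        for name in ("c_null", "c_alt"):
            v = getattr(self, name)
            if not 0.5 < v < 1:
                raise ValueError(f"{name} must lie in (0.5, 1)")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.c_alt == self.c_null:
            raise ValueError("c_alt must differ from c_null (no finite N exists)")


def auc_variance_hanley(auc: float, n_events: float, n_nonevents: float) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    return (
        auc * (1 - auc)
        + (n_events - 1) * (q1 - auc**2)
        + (n_nonevents - 1) * (q2 - auc**2)
    ) / (n_events * n_nonevents)


def auc_variance_noether(auc: float, n_events: float, n_nonevents: float) -> float:
    # null-hypothesis variance of the Mann-Whitney statistic, continuous data
    return (n_events + n_nonevents + 1) / (12 * n_events * n_nonevents)


_VARIANCES = {"hanley": auc_variance_hanley, "noether": auc_variance_noether}


def power_at_n(n_total: float, spec: SampleSizeSpec, method: str = "hanley") -> float:
    """Power of the two-sided level-alpha test of c_null at c_alt for total N."""
    var = _VARIANCES[method]
    m = spec.prevalence * n_total
    k = (1 - spec.prevalence) * n_total
    if m < 2 or k < 2:
        return 0.0
    se0 = np.sqrt(var(spec.c_null, m, k))
    se1 = np.sqrt(var(spec.c_alt, m, k))
    z_crit = norm.ppf(1 - spec.alpha / 2)
    delta = abs(spec.c_alt - spec.c_null)
    return float(norm.cdf((delta - z_crit * se0) / se1))


def cindex_sample_size(spec: SampleSizeSpec, method: str = "hanley") -> int:
    """Smallest integer N whose power reaches the target (rounded up)."""
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    lo, hi = 4, 8
    while power_at_n(hi, spec, method) < spec.power:
        hi *= 2
        if hi > _N_MAX:
            raise ValueError("no attainable N below the search limit")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_at_n(mid, spec, method) >= spec.power:
            hi = mid
        else:
            lo = mid
    return hi
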