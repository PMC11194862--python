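"""Performance battery: cross-validation, discrimination, calibration, errors.

Implements 10-fold out-of-sample prediction, the concordance index with a
bootstrap confidence interval, mean squared error and the relative percentage
of root MSE, 20-bin equal-frequency calibration tables, calibration
intercept/slope (logistic recalibration for binary outcomes, weighted
least squares on bin means for counts), events per variable, and Spearman
rank correlation of coefficient MADs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines.utils import concordance_index
from scipy.special import logit
from scipy.stats import spearmanr

PROB_CLIP = 1e-6


def c_index(pred, obs, ci: bool = True, n_boot: int = 2000, seed: int = 0):
    """Concordance over outcome-discordant pairs; tied predictions score 0.5.

    Returns ``(estimate, (lo, hi))`` with a seeded percentile-bootstrap 95%
    interval, or ``(estimate, None)`` when ``ci`` is false.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if len(pred) != len(obs):
        raise ValueError("pred and obs must have equal length")
    if len(obs) < 2 or np.all(obs == obs[0]):
        raise ValueError("C-index undefined: all observations are equal")
    est = float(concordance_index(obs, pred))
    if not ci:
        return est, None
    rng = np.random.default_rng(seed)
    n = len(obs)
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(n, size=n)
        o = obs[idx]
        if np.all(o == o[0]):
            continue
        stats.append(concordance_index(o, pred[idx]))
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return est, (float(lo), float(hi))


def mse(pred, obs) -> float:
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if len(pred) != len(obs) or len(obs) < 2:
        raise ValueError("need equal-length inputs with n >= 2")
    return float(np.mean((pred - obs) ** 2))


def rmse_pct(pred, obs) -> float:
    """100 * RMSE / population SD of the observations."""
    sd = float(np.std(np.asarray(obs, dtype=float)))
    if sd == 0:
        raise ValueError("rmse_pct undefined: observations have zero variance")
    return 100.0 * np.sqrt(mse(pred, obs)) / sd


def binary_rmse_pct(mse_value: float, prevalence: float) -> float:
    """RMSE% of a binary outcome from its MSE and observed event proportion."""
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    return 100.0 * np.sqrt(mse_value) / np.sqrt(prevalence * (1 - prevalence))


def _bin_sizes(n: int, n_bins: int) -> list[int]:
    base, rem = divmod(n, n_bins)
    # remainder rows go to the lowest-prediction bins
    return [base + 1 if i < rem else base for i in range(n_bins)]


def calibration_bins(
    pred, obs, n_bins: int = 20, groups=None
) -> pd.DataFrame:
    """Equal-frequency calibration table: per bin n, mean predicted, mean observed.

    Rows are sorted by prediction (stable, so ties keep input order) and split
    into ``n_bins`` contiguous groups whose sizes differ by at most one.  With
    ``groups`` (e.g. index DMT labels) a table is computed per group and
    stacked, with an added ``group`` column.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if groups is not None:
        groups = np.asarray(groups)
        parts = []
        for g in pd.unique(groups):
            m = groups == g
            t = calibration_bins(pred[m], obs[m], n_bins=min(n_bins, int(m.sum())))
            t.insert(0, "group", g)
            parts.append(t)
        return pd.concat(parts, ignore_index=True)

    n = len(pred)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} rows, got {n}")
    order = np.argsort(pred, kind="mergesort")
    sizes = _bin_sizes(n, n_bins)
    rows, pos = [], 0
    for i, size in enumerate(sizes):
        idx = order[pos : pos + size]
        pos += size
        rows.append(
            {
                "bin": i + 1,
                "n": size,
                "mean_predicted": float(pred[idx].mean()),
                "mean_observed": float(obs[idx].mean()),
            }
        )
    return pd.DataFrame(rows)


def calibration_line(
    pred, obs, family: str, n_bins: int = 20, count_method: str = "bins"
) -> dict:
    """Calibration intercept and slope with 95% CIs.

    ``family="binary"``: logistic recalibration — the slope is the coefficient
    of logit(pred) in a logistic regression of the outcome, the intercept is
    the intercept of a logistic regression with logit(pred) as fixed offset.
    ``family="count"``: weighted least squares of bin-mean observed on
    bin-mean predicted over equal-frequency bins (``count_method="rows"``
    switches to row-level ordinary least squares).
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if family == "binary":
        p = np.clip(pred, PROB_CLIP, 1 - PROB_CLIP)
        lp = logit(p)
        slope_fit = sm.GLM(obs, sm.add_constant(lp), family=sm.families.Binomial()).fit()
        slope = float(slope_fit.params[1])
        slope_ci = tuple(np.asarray(slope_fit.conf_int())[1])
        int_fit = sm.GLM(
            obs, np.ones((len(obs), 1)), family=sm.families.Binomial(), offset=lp
        ).fit()
        intercept = float(int_fit.params[0])
        int_ci = tuple(np.asarray(int_fit.conf_int())[0])
    elif family == "count":
        if count_method == "bins":
            tab = calibration_bins(pred, obs, n_bins=n_bins)
            x = sm.add_constant(tab["mean_predicted"].to_numpy())
            fit = sm.WLS(tab["mean_observed"].to_numpy(), x, weights=tab["n"].to_numpy()).fit()
        elif count_method == "rows":
            fit = sm.OLS(obs, sm.add_constant(pred)).fit()
        else:
            raise ValueError(f"unknown count_method {count_method!r}")
        intercept, slope = (float(v) for v in fit.params)
        ci = np.asarray(fit.conf_int())
        int_ci, slope_ci = tuple(ci[0]), tuple(ci[1])
    else:
        raise ValueError(f"unknown family {family!r}")
    return {
        "intercept": intercept,
        "intercept_ci": (float(int_ci[0]), float(int_ci[1])),
        "slope": slope,
        "slope_ci": (float(slope_ci[0]), float(slope_ci[1])),
    }


def events_per_variable(n_events: int, df: int) -> float:
    if df < 1:
        raise ValueError("df must be at least 1")
    if n_events < 0:
        raise ValueError("n_events must be non-negative")
    return n_events / df


def mad_spearman(mads_a: dict, mads_b: dict) -> float:
    """Spearman rank correlation of coefficient MADs over shared names."""
    shared = sorted(set(mads_a) & set(mads_b))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared coefficient names")
    a = [mads_a[k] for k in shared]
    b = [mads_b[k] for k in shared]
    return float(spearmanr(a, b).statistic)


def fold_assignments(n: int, k: int, seed: int) -> np.ndarray:
    """Deterministic shuffled fold labels with sizes differing by at most one."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError("more folds than rows")
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.full(size, i) for i, size in enumerate(_bin_sizes(n, k))])
    return labels[rng.permutation(n)]


def kfold_oos_predictions(
    features: pd.DataFrame,
    y: np.ndarray,
    centre,
    model_spec,
    interaction_spec,
    k: int = 10,
    seed: int = 0,
    bayes: bool = False,
    **fit_kwargs,
) -> pd.DataFrame:
    """Out-of-sample predictions: each row predicted by the fit excluding its fold.

    Standardization is re-learned inside every training fold.  Returns one
    ``mean``/``outcome_free`` row per input row, in input order.
    """
    from .models import fit_outcome_model, predict_observed

    n = len(features)
    folds = fold_assignments(n, k, seed)
    y = np.asarray(y)
    centre = np.asarray(centre)
    mean = np.empty(n)
    free = np.empty(n)
    for f in range(k):
        hold = folds == f
        fit = fit_outcome_model(
            features[~hold].reset_index(drop=True),
            y[~hold],
            centre[~hold],
            model_spec,
            interaction_spec,
            bayes=bayes,
            **fit_kwargs,
        )
        pred = predict_observed(fit, features[hold].reset_index(drop=True))
        mean[hold] = pred["mean"].to_numpy()
        free[hold] = pred["outcome_free"].to_numpy()
    return pd.DataFrame({"mean": mean, "outcome_free": free, "fold": folds})


@dataclass
class MetricsReport:
    """Table-3-style summary of one validation scheme."""

    scheme: str
    outcome: str
    n: int
    c_index: float
    c_index_ci: tuple
    mse: float
    rmse_pct: float
    calibration_intercept: float
    calibration_intercept_ci: tuple
    calibration_slope: float
    calibration_slope_ci: tuple
    mean_predicted: float
    predicted_range: tuple
    mean_observed: float
    observed_range: tuple
    events_per_variable: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_predictions(
    pred_mean,
    obs,
    outcome: str,
    scheme: str,
    n_params: Optional[int] = None,
    n_boot: int = 2000,
    seed: int = 0,
    n_bins: int = 20,
) -> MetricsReport:
    """Assemble the full metric set for one prediction/observation vector."""
    pred_mean = np.asarray(pred_mean, dtype=float)
    obs = np.asarray(obs, dtype=float)
    family = "binary" if outcome == "cdp" else "count"
    cal = calibration_line(pred_mean, obs, family, n_bins=min(n_bins, len(obs)))
    est, ci = c_index(pred_mean, obs, n_boot=n_boot, seed=seed)
    epv = None
    if n_params is not None:
        n_events = int((obs > 0).sum())
        epv = events_per_variable(n_events, n_params)
    return MetricsReport(
        scheme=scheme,
        outcome=outcome,
        n=len(obs),
        c_index=est,
        c_index_ci=ci,
        mse=mse(pred_mean, obs),
        rmse_pct=rmse_pct(pred_mean, obs),
        calibration_intercept=cal["intercept"],
        calibration_intercept_ci=cal["intercept_ci"],
        calibration_slope=cal["slope"],
        calibration_slope_ci=cal["slope_ci"],
        mean_predicted=float(pred_mean.mean()),
        predicted_range=(float(pred_mean.min()), float(pred_mean.max())),
        mean_observed=float(obs.mean()),
        observed_range=(float(obs.min()), float(obs.max())),
        events_per_variable=epv,
    )
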