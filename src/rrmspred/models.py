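"""Outcome models: hierarchical GLMs with centre intercepts and fixed-effects GLMs.

The hierarchical negative-binomial (log link, log-duration offset) and
binomial (logit link) models carry a centre random intercept with weakly
informative priors.  Posterior inference uses a Laplace approximation: the
joint posterior mode over (intercept, slopes, centre effects, log sigma and —
for the count model — log dispersion) is located with analytic gradients, and
posterior draws are taken from the Gaussian approximation at the mode.
Fixed-effects counterparts are maximum-likelihood fits via statsmodels.
Predictions assume an average centre effect (null random intercept) and
report, per row, the posterior-mean outcome and the outcome-free probability
(negative-binomial mass at zero, or one minus the event probability).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, gammaln, digamma
from scipy.stats import median_abs_deviation

import statsmodels.api as sm

from .features import (
    InteractionSpec,
    StandardizationParams,
    apply_standardization,
    build_design_matrix,
)
from .vocab import DMT6

FAMILY_NEGBIN = "negbinomial"
FAMILY_BINOMIAL = "binomial"


class ConvergenceError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    """Sampler/prior/convergence settings for a model fit."""

    family: str
    prior_scale: float = 1.0
    intercept_prior_sd: float = 10.0
    sigma_prior_scale: float = 1.0
    n_chains: int = 4
    n_draws: int = 1000
    seed: int = 0
    rhat_max: float = 1.01
    ess_min: float = 400.0
    max_divergences: int = 0

    def __post_init__(self):
        if self.family not in (FAMILY_NEGBIN, FAMILY_BINOMIAL):
            raise ValueError(f"unknown family {self.family!r}")
        if min(self.rhat_max, self.ess_min, self.n_chains, self.n_draws) <= 0:
            raise ValueError("thresholds and draw counts must be positive")


# reduced preset for tests / quick pipelines
def reduced_preset(family: str, seed: int = 0) -> ModelSpec:
    # fewer draws -> noisier ESS/R-hat estimates, so thresholds loosen too
    return ModelSpec(
        family=family, n_chains=2, n_draws=250, seed=seed, ess_min=100.0, rhat_max=1.05
    )


@dataclass
class PosteriorFit:
    """Laplace-approximate posterior with metadata to rebuild designs."""

    family: str
    names: list
    centre_labels: list
    draws: dict  # name -> array with leading (chains, draws) axes
    theta_map: np.ndarray
    diagnostics: pd.DataFrame
    interaction_spec: Optional[InteractionSpec] = None
    standardization: Optional[StandardizationParams] = None

    def coef_draws(self) -> np.ndarray:
        """(n_draws_total, 1 + p): intercept then slopes."""
        a = self.draws["intercept"].reshape(-1, 1)
        b = self.draws["beta"].reshape(-1, len(self.names))
        return np.hstack([a, b])

    def phi_draws(self) -> Optional[np.ndarray]:
        if "phi" not in self.draws:
            return None
        return self.draws["phi"].reshape(-1)

    def sigma_draws(self) -> np.ndarray:
        return self.draws["sigma_centre"].reshape(-1)

    def save(self, path) -> None:
        path = Path(path)
        arrays = {k: np.asarray(v) for k, v in self.draws.items()}
        arrays["theta_map"] = self.theta_map
        meta = {
            "family": self.family,
            "names": list(self.names),
            "centre_labels": [str(c) for c in self.centre_labels],
            "diagnostics": self.diagnostics.to_dict(orient="list"),
            "standardization": self.standardization.stats if self.standardization else None,
            "interaction_spec": (
                {
                    "interactions": [list(p) for p in self.interaction_spec.interactions],
                    "references": dict(self.interaction_spec.references),
                }
                if self.interaction_spec
                else None
            ),
        }
        np.savez(path, **arrays)
        Path(str(path) + ".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path) -> "PosteriorFit":
        path = Path(path)
        with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as z:
            arrays = {k: z[k] for k in z.files}
        meta = json.loads(Path(str(path) + ".json").read_text())
        theta = arrays.pop("theta_map")
        spec = None
        if meta["interaction_spec"]:
            spec = InteractionSpec(
                interactions=tuple(tuple(p) for p in meta["interaction_spec"]["interactions"]),
                references=meta["interaction_spec"]["references"],
            )
        std = None
        if meta["standardization"]:
            std = StandardizationParams(
                {k: tuple(v) for k, v in meta["standardization"].items()}
            )
        return cls(
            family=meta["family"],
            names=meta["names"],
            centre_labels=meta["centre_labels"],
            draws=arrays,
            theta_map=theta,
            diagnostics=pd.DataFrame(meta["diagnostics"]),
            interaction_spec=spec,
            standardization=std,
        )


@dataclass
class GLMFit:
    """Fixed-effects maximum-likelihood fit (no centre effects)."""

    family: str
    names: list
    params: np.ndarray  # intercept then slopes
    cov: np.ndarray
    phi: Optional[float]
    llf: float
    converged: bool
    interaction_spec: Optional[InteractionSpec] = None
    standardization: Optional[StandardizationParams] = None

    def __post_init__(self):
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")

    def coef_draws(self) -> np.ndarray:
        return self.params[None, : 1 + len(self.names)]

    def phi_draws(self) -> Optional[np.ndarray]:
        return None if self.phi is None else np.array([self.phi])

    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _independent_columns(X: np.ndarray, tol: float = 1e-9) -> list[int]:
    """Indices of a maximal linearly independent column subset (after intercept)."""
    from scipy.linalg import qr

    Xc = np.hstack([np.ones((X.shape[0], 1)), X])
    _, r, piv = qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > tol * diag.max()))
    kept = {int(j) for j in piv[:rank]}
    return sorted(j - 1 for j in kept if j > 0)


def _check_design(X: np.ndarray) -> None:
    Xc = np.hstack([np.ones((X.shape[0], 1)), X])
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ConvergenceError("design matrix is rank deficient")


def _neg_log_posterior_and_grad(theta, Z, y, centre, offset, family,
                                prior_sd_beta, intercept_sd, sigma_scale):
    """Joint negative log posterior over (a, b, w, log sigma[, log phi]).

    Uses the non-centered parametrization u = sigma * w so the posterior
    density stays bounded (the centered funnel has no joint mode); Z is the
    internally whitened design.
    """
    n, p = Z.shape
    C = int(centre.max()) + 1 if len(centre) else 0
    a = theta[0]
    b = theta[1 : 1 + p]
    w = theta[1 + p : 1 + p + C]
    ls = theta[1 + p + C]
    sigma = np.exp(ls)
    eta = a + Z @ b + sigma * w[centre]
    if offset is not None:
        eta = eta + offset

    if family == FAMILY_NEGBIN:
        lphi = theta[1 + p + C + 1]
        phi = np.exp(lphi)
        # stable: log(phi + mu) = logaddexp(lphi, eta); mu/(phi+mu) = expit(eta-lphi)
        log_pm = np.logaddexp(lphi, eta)
        s = expit(eta - lphi)
        ll = np.sum(
            gammaln(y + phi) - gammaln(phi) - gammaln(y + 1)
            + phi * (lphi - log_pm) + y * (eta - log_pm)
        )
        deta = y - (y + phi) * s
        dphi = np.sum(
            digamma(y + phi) - digamma(phi) + lphi + 1 - log_pm - (y + phi) * np.exp(-log_pm)
        )
        g_lphi = dphi * phi + (-1.0 + 1.0 / phi)  # prior on 1/phi ~ Exp(1)
        lp_phi = -lphi - 1.0 / phi
    else:
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
        deta = y - expit(eta)
        g_lphi = None
        lp_phi = 0.0

    lp = (
        -0.5 * (a / intercept_sd) ** 2
        - 0.5 * np.sum((b / prior_sd_beta) ** 2)
        - 0.5 * np.sum(w**2)
        - 0.5 * (sigma / sigma_scale) ** 2
        + ls  # Jacobian of sigma -> log sigma
        + lp_phi
    )

    group = np.bincount(centre, weights=deta, minlength=C)
    g = np.empty_like(theta)
    g[0] = np.sum(deta) - a / intercept_sd**2
    g[1 : 1 + p] = Z.T @ deta - b / prior_sd_beta**2
    g[1 + p : 1 + p + C] = sigma * group - w
    g[1 + p + C] = sigma * np.dot(group, w) - (sigma / sigma_scale) ** 2 + 1.0
    if family == FAMILY_NEGBIN:
        g[1 + p + C + 1] = g_lphi
    return -(ll + lp), -g


def _loglik_derivs(eta, y, family, phi):
    if family == FAMILY_NEGBIN:
        lphi = np.log(phi)
        log_pm = np.logaddexp(lphi, eta)
        s = expit(eta - lphi)
        ll = (
            gammaln(y + phi) - gammaln(phi) - gammaln(y + 1)
            + phi * (lphi - log_pm) + y * (eta - log_pm)
        )
        d1 = y - (y + phi) * s
        d2 = -(y + phi) * s * (1.0 - s)
    else:
        pr = expit(eta)
        ll = y * eta - np.logaddexp(0.0, eta)
        d1 = y - pr
        d2 = -pr * (1 - pr)
    return ll, d1, d2


def _conditional_centre_modes(u, sigma, eta_fixed, y, centre, family, phi, n_iter=40):
    """Newton solve of the per-centre conditional modes at fixed sigma."""
    C = len(u)
    for _ in range(n_iter):
        _, d1, d2 = _loglik_derivs(eta_fixed + u[centre], y, family, phi)
        g = np.bincount(centre, weights=d1, minlength=C) - u / sigma**2
        h = -np.bincount(centre, weights=d2, minlength=C) + 1.0 / sigma**2
        step = np.clip(g / h, -2.0, 2.0)
        u = u + step
        if np.max(np.abs(step)) < 1e-10:
            break
    _, _, d2 = _loglik_derivs(eta_fixed + u[centre], y, family, phi)
    h = -np.bincount(centre, weights=d2, minlength=C) + 1.0 / sigma**2
    return u, h


def _sigma_marginal(ls_grid, eta_fixed, y, centre, family, phi, sigma_scale):
    """Laplace-integrated (over centre effects) log posterior of log sigma."""
    C = int(centre.max()) + 1
    out = np.empty(len(ls_grid))
    u = np.zeros(C)
    for k, ls in enumerate(ls_grid):
        sigma = np.exp(ls)
        u, h = _conditional_centre_modes(u, sigma, eta_fixed, y, centre, family, phi)
        ll, _, _ = _loglik_derivs(eta_fixed + u[centre], y, family, phi)
        f_c = np.bincount(centre, weights=ll, minlength=C) - 0.5 * u**2 / sigma**2 - ls
        out[k] = np.sum(f_c - 0.5 * np.log(h)) - 0.5 * (sigma / sigma_scale) ** 2 + ls
    return out


def _fd_hessian(grad_fn, theta, eps=1e-5):
    k = len(theta)
    H = np.empty((k, k))
    for i in range(k):
        h = eps * max(1.0, abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        H[:, i] = (grad_fn(tp) - grad_fn(tm)) / (2 * h)
    return 0.5 * (H + H.T)


def fit_hierarchical(
    X: np.ndarray,
    y: np.ndarray,
    centre,
    spec: ModelSpec,
    offset: Optional[np.ndarray] = None,
    names: Optional[list] = None,
    interaction_spec: Optional[InteractionSpec] = None,
    standardization: Optional[StandardizationParams] = None,
) -> PosteriorFit:
    """Fit the hierarchical GLM and return Laplace-approximate posterior draws.

    `centre` may hold arbitrary labels; slopes get Normal(0, 2.5 * prior_scale
    / sd(column)) priors, the intercept Normal(0, 10), the centre SD a
    half-Normal and the reciprocal dispersion an Exponential prior.  For the
    count family `offset` must be the log index-therapy duration.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if spec.family == FAMILY_NEGBIN and offset is None:
        raise ValueError("negative-binomial fit requires a log-duration offset")
    _check_design(X)
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]

    centre_codes, centre_labels = pd.factorize(np.asarray(centre), sort=True)
    C = len(centre_labels)
    n, p = X.shape

    sd_cols = X.std(axis=0)
    if np.any(sd_cols <= 0):
        raise ConvergenceError(
            f"constant design columns: {[names[i] for i in np.flatnonzero(sd_cols <= 0)]}"
        )
    # whiten internally for conditioning; slope priors are Normal(0, 2.5 *
    # prior_scale) on the whitened scale, i.e. auto-scaled by column SD
    mean_cols = X.mean(axis=0)
    Z = (X - mean_cols) / sd_cols
    prior_sd_beta = np.full(p, 2.5 * spec.prior_scale)

    k = 1 + p + C + 1 + (1 if spec.family == FAMILY_NEGBIN else 0)
    theta0 = np.zeros(k)
    if spec.family == FAMILY_NEGBIN:
        mean_rate = max(y.mean() / max(np.exp(offset).mean(), 1e-12), 1e-3)
        theta0[0] = np.log(mean_rate)
        theta0[1 + p + C] = np.log(0.3)
        theta0[-1] = 0.0
    else:
        prev = np.clip(y.mean(), 1e-3, 1 - 1e-3)
        theta0[0] = np.log(prev / (1 - prev))
        theta0[1 + p + C] = np.log(0.3)

    args = (
        Z,
        y,
        centre_codes,
        offset,
        spec.family,
        prior_sd_beta,
        spec.intercept_prior_sd,
        spec.sigma_prior_scale,
    )
    # generous box bounds keep the line search away from exp overflow;
    # interior optima are unaffected
    bounds = (
        [(-30.0, 30.0)] * (1 + p)
        + [(-10.0, 10.0)] * C
        + [(-13.0, 3.0)]
        + ([(-8.0, 8.0)] if spec.family == FAMILY_NEGBIN else [])
    )
    res = optimize.minimize(
        _neg_log_posterior_and_grad,
        theta0,
        args=args,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 4000, "maxfun": 8000, "ftol": 1e-14, "gtol": 1e-8},
    )
    grad_only = lambda t: _neg_log_posterior_and_grad(t, *args)[1]
    theta = res.x
    # Newton polish: a few damped steps wipe out residual L-BFGS error
    H = _fd_hessian(grad_only, theta)
    for _ in range(8):
        gvec = grad_only(theta)
        if np.linalg.norm(gvec, ord=np.inf) < 1e-6:
            break
        H = _fd_hessian(grad_only, theta)
        evals, evecs = np.linalg.eigh(H)
        evals = np.maximum(evals, 1e-6)
        step = (evecs / evals) @ evecs.T @ gvec
        f0 = _neg_log_posterior_and_grad(theta, *args)[0]
        lam = 1.0
        while lam > 1e-6:
            cand = theta - lam * step
            if _neg_log_posterior_and_grad(cand, *args)[0] < f0:
                theta = cand
                break
            lam /= 2
        else:
            break
    if np.linalg.norm(grad_only(theta), ord=np.inf) > 1e-2:
        raise ConvergenceError(f"MAP optimization failed: {res.message}")

    H = _fd_hessian(grad_only, theta)
    evals, evecs = np.linalg.eigh(H)
    evals = np.maximum(evals, 1e-8)
    cov = (evecs / evals) @ evecs.T

    rng = np.random.default_rng(spec.seed)
    total = spec.n_chains * spec.n_draws
    L = np.linalg.cholesky(0.5 * (cov + cov.T) + 1e-12 * np.eye(k))
    z = rng.standard_normal((total, k))
    samples = theta + z @ L.T

    def shape(a):
        return a.reshape(spec.n_chains, spec.n_draws, *a.shape[1:])

    # map back: beta = beta_s / sd, intercept = a_s - beta_s . (mean/sd)
    beta_s = samples[:, 1 : 1 + p]
    draws = {
        "intercept": shape(samples[:, 0] - beta_s @ (mean_cols / sd_cols)),
        "beta": shape(beta_s / sd_cols),
    }
    if spec.family == FAMILY_NEGBIN:
        draws["phi"] = shape(np.exp(samples[:, -1]))

    theta = theta.copy()
    b_map = theta[1 : 1 + p]
    theta[0] = theta[0] - b_map @ (mean_cols / sd_cols)
    theta[1 : 1 + p] = b_map / sd_cols

    # sigma and centre effects from the Laplace-integrated marginal: the
    # joint Gaussian sits on a (sigma * w) ridge and misstates sigma itself
    eta_fixed = theta[0] + X @ theta[1 : 1 + p]
    if offset is not None:
        eta_fixed = eta_fixed + offset
    phi_map = np.exp(theta[-1]) if spec.family == FAMILY_NEGBIN else None
    ls_grid = np.linspace(np.log(5e-3), np.log(5.0 * spec.sigma_prior_scale), 80)
    logpost = _sigma_marginal(
        ls_grid, eta_fixed, y, centre_codes, spec.family, phi_map, spec.sigma_prior_scale
    )
    prob = np.exp(logpost - logpost.max())
    prob /= prob.sum()
    step_ls = ls_grid[1] - ls_grid[0]
    ls_draws = ls_grid[rng.choice(len(ls_grid), size=total, p=prob)]
    ls_draws = ls_draws + rng.uniform(-0.5 * step_ls, 0.5 * step_ls, size=total)
    sigma_draws = np.exp(ls_draws)
    draws["sigma_centre"] = shape(sigma_draws)

    sigma_hat = float(np.exp(np.sum(prob * ls_grid)))
    u_hat, h_u = _conditional_centre_modes(
        np.zeros(C), sigma_hat, eta_fixed, y, centre_codes, spec.family, phi_map
    )
    u_draws = u_hat + rng.standard_normal((total, C)) / np.sqrt(h_u)
    draws["u"] = shape(u_draws)

    diagnostics = _diagnostics(draws, names)
    fit = PosteriorFit(
        family=spec.family,
        names=names,
        centre_labels=list(centre_labels),
        draws=draws,
        theta_map=theta,
        diagnostics=diagnostics,
        interaction_spec=interaction_spec,
        standardization=standardization,
    )
    _check_convergence(fit, spec)
    return fit


def _diagnostics(draws: dict, names: list) -> pd.DataFrame:
    import arviz as az

    rows = []

    def add(label, arr):
        data = {"x": arr}
        rows.append(
            {
                "parameter": label,
                "rhat": float(az.rhat(az.convert_to_dataset(data))["x"].max()),
                "ess": float(az.ess(az.convert_to_dataset(data))["x"].min()),
                "divergences": 0,
            }
        )

    add("intercept", draws["intercept"])
    beta = draws["beta"]
    for j, name in enumerate(names):
        add(name, beta[:, :, j])
    add("sigma_centre", draws["sigma_centre"])
    if "phi" in draws:
        add("phi", draws["phi"])
    return pd.DataFrame(rows)


def _check_convergence(fit: PosteriorFit, spec: ModelSpec) -> None:
    d = fit.diagnostics
    bad = d[(d["rhat"] > spec.rhat_max) | (d["ess"] < spec.ess_min) | (d["divergences"] > spec.max_divergences)]
    if len(bad):
        raise ConvergenceError(
            "convergence thresholds breached for: " + ", ".join(bad["parameter"].tolist())
        )


def fit_glm_fixed(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    offset: Optional[np.ndarray] = None,
    names: Optional[list] = None,
    interaction_spec: Optional[InteractionSpec] = None,
    standardization: Optional[StandardizationParams] = None,
) -> GLMFit:
    """Maximum-likelihood fixed-effects GLM (centres excluded from the design)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_design(X)
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    Xc = sm.add_constant(X, has_constant="add")

    if spec.family == FAMILY_NEGBIN:
        if offset is None:
            raise ValueError("negative-binomial fit requires a log-duration offset")
        model = sm.NegativeBinomial(y, Xc, offset=offset)
        # a Poisson IRLS fit gives stable start values; alpha starts at 1
        pois = sm.GLM(y, Xc, family=sm.families.Poisson(), offset=offset).fit()
        start = np.append(np.asarray(pois.params), 1.0)
        def ok(r):
            # accept on a small total-score norm: statsmodels' own flag is
            # stricter than needed and trips on flat likelihoods
            if not np.isfinite(r.llf):
                return False
            return np.linalg.norm(model.score(r.params), ord=np.inf) < max(
                0.1, 1e-4 * len(y)
            )

        res = model.fit(start_params=start, method="bfgs", maxiter=2000, disp=0)
        if not ok(res) and np.isfinite(res.llf) and res.params[-1] > 1e-3:
            try:
                res = model.fit(start_params=res.params, method="newton", maxiter=200, disp=0)
            except np.linalg.LinAlgError:
                pass
        if ok(res) and res.params[-1] > 1e-3:
            alpha = float(res.params[-1])
            params = np.asarray(res.params[:-1], dtype=float)
            cov = np.asarray(res.cov_params())[:-1, :-1]
            return GLMFit(spec.family, names, params, cov, 1.0 / alpha,
                          float(res.llf), True, interaction_spec, standardization)
        # alpha on the zero boundary (equidispersed data): the NB2 MLE is the
        # Poisson MLE with infinite dispersion
        if not np.isfinite(getattr(res, "llf", np.nan)) or res.params[-1] <= 1e-3:
            return GLMFit(
                spec.family, names, np.asarray(pois.params, dtype=float),
                np.asarray(pois.cov_params()), np.inf, float(pois.llf), True,
                interaction_spec, standardization,
            )
        raise ConvergenceError(f"fixed-effects fit did not converge: {res.mle_retvals}")

    model = sm.GLM(y, Xc, family=sm.families.Binomial(), offset=offset)
    res = model.fit(maxiter=200)
    if not res.converged:
        raise ConvergenceError("fixed-effects logistic fit did not converge")
    return GLMFit(
        spec.family,
        names,
        np.asarray(res.params, dtype=float),
        np.asarray(res.cov_params()),
        None,
        float(res.llf),
        True,
        interaction_spec,
        standardization,
    )


def negbin_zero_prob(mu, phi):
    """P(count = 0) of the NB(mean mu, dispersion phi); Poisson limit at phi=inf."""
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    with np.errstate(invalid="ignore"):
        out = np.exp(-phi * np.log1p(mu / phi))
    return np.where(np.isfinite(phi), out, np.exp(-mu))


def predict_from_design(fit, X: np.ndarray, offset: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Per-row prediction summary under a null (average) centre effect."""
    coefs = fit.coef_draws()  # (ndraw, 1+p)
    eta = coefs[:, 0:1] + coefs[:, 1:] @ np.asarray(X, dtype=float).T
    if offset is not None:
        eta = eta + np.asarray(offset, dtype=float)[None, :]

    if fit.family == FAMILY_NEGBIN:
        mu = np.exp(eta)
        phi = fit.phi_draws()
        free = negbin_zero_prob(mu, phi[:, None])
        mean = mu
    else:
        p = expit(eta)
        free = 1.0 - p
        mean = p

    out = pd.DataFrame(
        {
            "mean": mean.mean(axis=0),
            "outcome_free": free.mean(axis=0),
        }
    )
    if mean.shape[0] > 1:
        lo, hi = np.percentile(mean, [2.5, 97.5], axis=0)
        out["lo95"], out["hi95"] = lo, hi
    else:
        out["lo95"] = out["hi95"] = out["mean"]
    return out


def fit_outcome_model(
    features: pd.DataFrame,
    y,
    centre,
    spec: ModelSpec,
    interaction_spec: Optional[InteractionSpec] = None,
    bayes: bool = True,
    standardize: bool = True,
    cdp_log_duration: bool = True,
    continuous_predictors=None,
):
    """Fit one outcome model from a (raw, unstandardized) feature table.

    Standardization parameters are learned here and stored on the returned
    fit, so held-out rows are transformed with training statistics only.  For
    the count family the ``log_offset`` column is used as offset; for the
    binomial family it enters as a plain covariate unless ``cdp_log_duration``
    is false.
    """
    from .features import fit_standardization
    from .vocab import CONTINUOUS_PREDICTORS

    interaction_spec = interaction_spec or InteractionSpec()
    if continuous_predictors is None:
        continuous_predictors = CONTINUOUS_PREDICTORS
    std = fit_standardization(features, continuous_predictors) if standardize else None
    rows = apply_standardization(std, features) if std else features
    X, names = build_design_matrix(rows, interaction_spec)
    offset = None
    if spec.family == FAMILY_NEGBIN:
        offset = features["log_offset"].to_numpy(dtype=float)
    elif cdp_log_duration:
        X = np.column_stack([X, features["log_offset"].to_numpy(dtype=float)])
        names = names + ["log_offset"]
    # drop empty category levels and exactly collinear columns (small cohorts)
    keep = _independent_columns(X)
    if len(keep) < X.shape[1]:
        X = X[:, keep]
        names = [names[j] for j in keep]
    if bayes:
        return fit_hierarchical(
            X, y, centre, spec, offset=offset, names=names,
            interaction_spec=interaction_spec, standardization=std,
        )
    return fit_glm_fixed(
        X, y, spec, offset=offset, names=names,
        interaction_spec=interaction_spec, standardization=std,
    )


def _design_for(fit, rows: pd.DataFrame, index_dmt: Optional[str], duration_years: Optional[float]):
    if fit.interaction_spec is None:
        raise ValueError("fit carries no interaction spec; use predict_from_design")
    rows = rows.copy()
    if index_dmt is not None:
        if index_dmt not in DMT6:
            raise ValueError(f"unknown index DMT {index_dmt!r}")
        rows["index_therapy"] = index_dmt
    if duration_years is not None:
        if duration_years <= 0:
            raise ValueError("duration_years must be positive")
        rows["log_offset"] = np.log(duration_years)
    if fit.standardization is not None:
        rows = apply_standardization(fit.standardization, rows)
    X_full, names_full = build_design_matrix(rows, fit.interaction_spec)
    cols = {n: X_full[:, j] for j, n in enumerate(names_full)}
    if "log_offset" in fit.names:
        cols["log_offset"] = rows["log_offset"].to_numpy(dtype=float)
    missing = [n for n in fit.names if n not in cols]
    if missing:
        raise ValueError(f"design columns do not match the fitted model: {missing}")
    X = np.column_stack([cols[n] for n in fit.names])
    offset = None
    if fit.family == FAMILY_NEGBIN:
        if "log_offset" not in rows:
            raise ValueError("count-family prediction needs a log_offset column or duration")
        offset = rows["log_offset"].to_numpy(dtype=float)
    return X, offset


def predict_observed(fit, rows: pd.DataFrame) -> pd.DataFrame:
    """Predict each row's own outcome (actual index DMT and follow-up)."""
    X, offset = _design_for(fit, rows, index_dmt=None, duration_years=None)
    return predict_from_design(fit, X, offset)


def predict_outcomes(fit, rows: pd.DataFrame, index_dmt: str, duration_years: float) -> pd.DataFrame:
    """Counterfactual prediction with ``index_therapy`` set to ``index_dmt``."""
    if duration_years is None or duration_years <= 0:
        raise ValueError("duration_years must be positive")
    X, offset = _design_for(fit, rows, index_dmt, duration_years)
    return predict_from_design(fit, X, offset)


def predict_all_dmts(fit, rows: pd.DataFrame, duration_years: float) -> pd.DataFrame:
    """Predictions under each of the six index DMTs with identical covariates.

    Returns a frame with ``<dmt>|mean`` and ``<dmt>|outcome_free`` columns and
    a ``dmt_ranking`` column listing the DMTs by decreasing outcome-free
    probability per row.
    """
    out = pd.DataFrame(index=range(len(rows)))
    free_cols = {}
    for dmt in DMT6:
        pred = predict_outcomes(fit, rows, dmt, duration_years)
        out[f"{dmt}|mean"] = pred["mean"].to_numpy()
        out[f"{dmt}|outcome_free"] = pred["outcome_free"].to_numpy()
        free_cols[dmt] = pred["outcome_free"].to_numpy()
    free = np.column_stack([free_cols[d] for d in DMT6])
    order = np.argsort(-free, axis=1, kind="stable")
    out["dmt_ranking"] = [";".join(DMT6[j] for j in row) for row in order]
    return out


def coefficient_mads(fit: PosteriorFit, scaled: bool = True) -> dict:
    """Median absolute deviation of each coefficient's posterior draws."""
    scale = "normal" if scaled else 1.0
    out = {"intercept": float(median_abs_deviation(fit.draws["intercept"].reshape(-1), scale=scale))}
    beta = fit.draws["beta"].reshape(-1, len(fit.names))
    for j, name in enumerate(fit.names):
        out[name] = float(median_abs_deviation(beta[:, j], scale=scale))
    return out
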