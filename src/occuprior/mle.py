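"""Maximum-likelihood fitting of the occupancy model.

The marginal likelihood (latent state summed out) is maximized on the
unconstrained scale theta = (alpha, beta..., logit p) by quasi-Newton
search with multiple dispersed restarts; standard errors come from the
central-difference Hessian at the optimum and 95% intervals are Wald on
the logit scale with back-transformed endpoints. These estimates are the
prior-free reference the Bayesian fits are compared against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

from .core import (
    CovariateMatrix,
    DataError,
    DetectionHistory,
    OccupancyParams,
    dataset_log_likelihood,
)

__all__ = ["FitResultMLE", "fit_mle"]

_Z975 = float(norm.ppf(0.975))


@dataclass
class FitResultMLE:
    """Point estimates, curvature SEs and Wald CIs for (alpha, beta, p)."""

    estimates: OccupancyParams
    theta: np.ndarray  # (alpha, beta..., logit p)
    names: tuple[str, ...]  # logit-scale parameter names
    se: np.ndarray | None
    ci_logit: np.ndarray | None  # shape (d, 2)
    log_likelihood: float
    converged: bool
    n_restarts_used: int
    boundary: bool = False

    @property
    def psi_hat(self) -> float:
        """Occupancy at the reference covariate point (all covariates 0)."""
        return float(expit(self.estimates.alpha))

    @property
    def p_hat(self) -> float:
        return self.estimates.p

    def ci_prob(self) -> dict[str, tuple[float, float]]:
        """Back-transformed 95% intervals for psi (reference) and p."""
        if self.ci_logit is None:
            return {}
        lo, hi = self.ci_logit[0], self.ci_logit[-1]
        return {
            "psi": (float(expit(lo[0])), float(expit(lo[1]))),
            "p": (float(expit(hi[0])), float(expit(hi[1]))),
        }

    def summary_frame(self) -> pd.DataFrame:
        """Flat summary: parameter, estimate, se, ci_lo, ci_hi, scale."""
        rows = []
        for j, name in enumerate(self.names):
            se = float(self.se[j]) if self.se is not None else np.nan
            lo, hi = (
                (float(self.ci_logit[j, 0]), float(self.ci_logit[j, 1]))
                if self.ci_logit is not None
                else (np.nan, np.nan)
            )
            rows.append((name, float(self.theta[j]), se, lo, hi, "logit"))
        prob = self.ci_prob()
        psi_lo, psi_hi = prob.get("psi", (np.nan, np.nan))
        p_lo, p_hi = prob.get("p", (np.nan, np.nan))
        rows.append(("psi", self.psi_hat, np.nan, psi_lo, psi_hi, "probability"))
        rows.append(("p", self.p_hat, np.nan, p_lo, p_hi, "probability"))
        return pd.DataFrame(
            rows,
            columns=["parameter", "estimate", "se", "ci_lo", "ci_hi", "scale"],
        )


def _neg_loglik(theta: np.ndarray, data: DetectionHistory, x) -> float:
    k = 0 if x is None else x.k
    alpha, beta, logit_p = theta[0], theta[1 : 1 + k], theta[1 + k]
    if not np.all(np.isfinite(theta)):
        return 1e12
    params = OccupancyParams(alpha, float(expit(logit_p)), beta)
    out = -dataset_log_likelihood(data, params, x)
    # keep the objective finite so numeric gradients stay well defined
    return float(out) if np.isfinite(out) else 1e12


def _central_hessian(f, theta: np.ndarray, h: float = 1e-5) -> np.ndarray:
    d = theta.size
    H = np.empty((d, d))
    f0 = f(theta)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h
        H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(theta + ei + ej)
                - f(theta + ei - ej)
                - f(theta - ei + ej)
                + f(theta - ei - ej)
            ) / (4 * h**2)
    return H


def _boundary_result(data, x, psi_hat, p_hat, names) -> FitResultMLE:
    d = len(names)
    alpha = 40.0 if psi_hat >= 1.0 else -40.0  # numerically pins expit at 1/0
    logit_p = (
        40.0 if p_hat >= 1.0 else (-40.0 if p_hat <= 0.0 else float(np.log(p_hat / (1 - p_hat))))
    )
    k = d - 2
    params = OccupancyParams(alpha, p_hat, np.zeros(k))
    ll = dataset_log_likelihood(data, params, x)
    theta = np.concatenate([[alpha], np.zeros(k), [logit_p]])
    return FitResultMLE(
        estimates=params,
        theta=theta,
        names=names,
        se=None,
        ci_logit=None,
        log_likelihood=ll,
        converged=True,
        n_restarts_used=0,
        boundary=True,
    )


def fit_mle(
    data: DetectionHistory,
    x: CovariateMatrix | None = None,
    n_restarts: int = 5,
    seed: int = 0,
) -> FitResultMLE:
    """Fit the occupancy model by maximizing the marginal likelihood.

    Requires at least one detected site (with none, psi*p is
    unidentifiable). Degenerate all-detected data yield boundary-pinned
    estimates with a warning and no standard errors.
    """
    if data.n_sites < 1:
        raise DataError("cannot fit an empty dataset")
    if x is not None and x.n_sites != data.n_sites:
        raise DataError("covariate row count does not match site count")
    k = 0 if x is None else x.k
    names = (
        ("alpha",)
        + tuple(f"beta_{nm}" for nm in (x.names if x is not None else ()))
        + ("logit_p",)
    )

    if not np.any(data.y > 0):
        warnings.warn(
            "no detections at any site: psi*p is unidentifiable", stacklevel=2
        )
        raise DataError("refusing to fit: no site has a detection")
    if np.all(data.y > 0):
        # every site detected -> psi_hat on the boundary at 1
        p_hat = float(data.y.sum() / data.n.sum())
        warnings.warn(
            "every site detected: psi estimate pinned at the boundary 1",
            stacklevel=2,
        )
        return _boundary_result(data, x, 1.0, p_hat, names)

    # heuristic start: naive detection rate among detected sites, occupancy
    # from the detected fraction corrected for detectability
    det = data.detected
    p0 = float(np.clip((data.y[det] / data.n[det]).mean(), 0.05, 0.95))
    frac_det = det.mean()
    p_star = 1.0 - float(np.mean((1 - p0) ** data.n))
    psi0 = float(np.clip(frac_det / max(p_star, 1e-3), 0.05, 0.95))
    start0 = np.concatenate(
        [[np.log(psi0 / (1 - psi0))], np.zeros(k), [np.log(p0 / (1 - p0))]]
    )

    rng = np.random.default_rng(seed)
    starts = [start0]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(
            np.concatenate(
                [
                    rng.uniform(-3, 3, 1),
                    rng.uniform(-2, 2, k),
                    rng.uniform(-3, 1, 1),
                ]
            )
        )

    best = None
    used = 0
    for s in starts:
        used += 1
        res = minimize(
            _neg_loglik,
            s,
            args=(data, x),
            method="BFGS",
            options={"gtol": 1e-8, "maxiter": 1000},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    assert best is not None
    theta = best.x
    converged = bool(best.success) or float(np.max(np.abs(best.jac))) < 1e-4

    se = None
    ci = None
    try:
        H = _central_hessian(lambda t: _neg_loglik(t, data, x), theta)
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        if np.all(np.isfinite(diag)) and np.all(diag > 0):
            se = np.sqrt(diag)
            ci = np.column_stack([theta - _Z975 * se, theta + _Z975 * se])
    except np.linalg.LinAlgError:
        pass

    params = OccupancyParams(
        theta[0], float(expit(theta[1 + k])), theta[1 : 1 + k]
    )
    return FitResultMLE(
        estimates=params,
        theta=theta,
        names=names,
        se=se,
        ci_logit=ci,
        log_likelihood=-float(best.fun),
        converged=converged,
        n_restarts_used=used,
    )
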