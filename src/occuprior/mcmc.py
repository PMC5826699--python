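"""From-scratch Bayesian sampler for the occupancy model.

One sweep cycles three block updates:

1. latent occupancy ``z`` from its exact full conditional (a detected site
   is occupied with probability 1; an undetected site is occupied with
   probability psi (1-p)^n / (psi (1-p)^n + 1 - psi));
2. detection ``p`` from its Beta conjugate update under the Uniform(0, 1)
   prior, Beta(1 + sum y_i, 1 + sum (n_i - y_i)) over occupied sites;
3. the logit-scale coefficients (alpha, beta) by per-coordinate random-walk
   Metropolis against the Bernoulli(z | inv_logit(alpha + x beta)) target
   times the coefficient prior, with proposal scales adapted toward 44%
   acceptance during burn-in and frozen afterwards (so the retained chain
   keeps the correct invariant distribution).

Each sweep opens with a partially collapsed independence refresh of the
coefficients: a proposal from the prior accepted on the MARGINAL likelihood
ratio (z integrated out, p held fixed), immediately followed by the exact z
redraw. Under very diffuse priors the posterior splits into far-apart modes
(one near the MLE, one at the probability boundary) that neither a random
walk nor a z-conditioned move can hop between — conditioning on z makes the
boundary mode quasi-absorbing. Refreshing against the z-marginal conditional
and then redrawing z from its full conditional is a valid blocked update
for the joint target and restores mixing across the modes.

Multiple chains start from dispersed random initial values; diagnostics
(potential-scale-reduction R-hat, KDE posterior modes) and pooled summaries
live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import gaussian_kde

from .core import (
    CovariateMatrix,
    DataError,
    DetectionHistory,
    LatentState,
)
from .priors import PriorSpec, prior_log_density, sample_prior

__all__ = [
    "McmcConfig",
    "PosteriorDraws",
    "PosteriorSummary",
    "update_latent_z",
    "update_detection",
    "update_regression",
    "fit_bayes",
    "gelman_rubin",
    "posterior_mode",
    "summarize",
]

_ADAPT_BATCH = 50
_ADAPT_TARGET = 0.44  # canonical univariate random-walk target


@dataclass(frozen=True)
class McmcConfig:
    n_iter: int = 10_000
    burn_in: int = 5_000
    n_chains: int = 3
    seed: int = 0
    proposal_adaptation: bool = True
    trace_z: bool = False

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")


@dataclass
class PosteriorDraws:
    """Retained multi-chain draws of (alpha, beta..., p) plus derived psi.

    ``psi`` is occupancy at the reference covariate point (all standardized
    covariates at 0), i.e. inv_logit(alpha).
    """

    draws: np.ndarray  # (n_chains, n_retained, n_params)
    parameter_names: tuple[str, ...]
    config: McmcConfig
    acceptance_rates: np.ndarray  # (n_chains, 1 + k) for alpha, beta
    priors: tuple[PriorSpec, ...]
    z_trace: np.ndarray | None = None  # (n_chains, n_retained, n_sites)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_retained(self) -> int:
        return self.draws.shape[1]

    def pooled(self, parameter: str) -> np.ndarray:
        """All chains concatenated, one parameter."""
        j = self.parameter_names.index(parameter)
        return self.draws[:, :, j].reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """Long format: chain, iteration, parameter, value."""
        n_c, n_r, n_p = self.draws.shape
        chain = np.repeat(np.arange(1, n_c + 1), n_r * n_p)
        iteration = np.tile(np.repeat(np.arange(1, n_r + 1), n_p), n_c)
        parameter = np.tile(np.array(self.parameter_names), n_c * n_r)
        return pd.DataFrame(
            {
                "chain": chain,
                "iteration": iteration,
                "parameter": parameter,
                "value": self.draws.reshape(-1),
            }
        )


@dataclass
class PosteriorSummary:
    """Per-parameter pooled median, KDE mode, 95% equal-tailed CI, R-hat."""

    frame: pd.DataFrame

    def __getitem__(self, parameter: str) -> pd.Series:
        row = self.frame[self.frame["parameter"] == parameter]
        if row.empty:
            raise KeyError(parameter)
        return row.iloc[0]


def update_latent_z(
    data: DetectionHistory,
    psi,
    p: float,
    rng: np.random.Generator,
) -> LatentState:
    """Draw z from its full conditional given (psi, p) and the data."""
    psi = np.broadcast_to(np.asarray(psi, dtype=float), (data.n_sites,))
    with np.errstate(divide="ignore"):
        q = np.exp(data.n * np.log1p(-p))  # (1-p)^n, 0 when p=1
    num = psi * q
    den = num + (1.0 - psi)
    with np.errstate(invalid="ignore"):
        pr1 = np.where(den > 0, num / np.where(den > 0, den, 1.0), psi)
    z = np.where(data.y > 0, 1, (rng.random(data.n_sites) < pr1).astype(np.int64))
    return LatentState(z)


def update_detection(
    data: DetectionHistory,
    z: LatentState | np.ndarray,
    rng: np.random.Generator,
) -> float:
    """Conjugate Beta draw for p under its Uniform(0, 1) prior.

    With no occupied sites this reduces to Beta(1, 1), i.e. a draw from
    the prior itself.
    """
    zz = z.z if isinstance(z, LatentState) else np.asarray(z)
    a = 1.0 + float(np.sum(zz * data.y))
    b = 1.0 + float(np.sum(zz * (data.n - data.y)))
    return float(rng.beta(a, b))


def _log_sigmoid(x):
    return -np.logaddexp(0.0, -x)


def _z_loglik(alpha: float, beta: np.ndarray, xv, z_sum1, z_sum0, z, eta_x):
    """Bernoulli(z | inv_logit(alpha + x beta)) log-likelihood.

    Constant-psi fast path when there are no covariates (only the counts of
    occupied/unoccupied sites matter).
    """
    if xv is None:
        return z_sum1 * _log_sigmoid(alpha) + z_sum0 * _log_sigmoid(-alpha)
    eta = alpha + eta_x
    return float(np.sum(np.where(z == 1, _log_sigmoid(eta), _log_sigmoid(-eta))))


def update_regression(
    alpha: float,
    beta: np.ndarray,
    z: LatentState | np.ndarray,
    x: CovariateMatrix | None,
    priors: Sequence[PriorSpec],
    rng: np.random.Generator,
    proposal_scales: Sequence[float],
) -> tuple[float, np.ndarray, np.ndarray]:
    """One per-coordinate random-walk Metropolis sweep over (alpha, beta).

    Returns the new (alpha, beta) and a boolean acceptance flag per
    coordinate. Proposal scales are taken as given; adaptation is the
    caller's concern.
    """
    zz = z.z if isinstance(z, LatentState) else np.asarray(z)
    beta = np.atleast_1d(np.asarray(beta, dtype=float)).copy()
    k = beta.size
    if len(priors) != 1 + k:
        raise ValueError(f"need {1 + k} priors, got {len(priors)}")
    xv = None if x is None else x.values
    z_sum1 = float(np.sum(zz))
    z_sum0 = float(zz.size - z_sum1)
    scales = np.asarray(proposal_scales, dtype=float)
    accepted = np.zeros(1 + k, dtype=bool)

    eta_x = 0.0 if xv is None else xv @ beta
    cur_ll = _z_loglik(alpha, beta, xv, z_sum1, z_sum0, zz, eta_x)
    cur_lp = [prior_log_density(priors[0], alpha)] + [
        prior_log_density(priors[1 + j], beta[j]) for j in range(k)
    ]

    # intercept
    prop = alpha + scales[0] * rng.standard_normal()
    new_ll = _z_loglik(prop, beta, xv, z_sum1, z_sum0, zz, eta_x)
    new_lp = prior_log_density(priors[0], prop)
    if np.log(rng.random()) < new_ll + new_lp - cur_ll - cur_lp[0]:
        alpha, cur_ll, cur_lp[0] = prop, new_ll, new_lp
        accepted[0] = True

    for j in range(k):
        prop_b = beta.copy()
        prop_b[j] += scales[1 + j] * rng.standard_normal()
        eta_prop = xv @ prop_b
        new_ll = _z_loglik(alpha, prop_b, xv, z_sum1, z_sum0, zz, eta_prop)
        new_lp = prior_log_density(priors[1 + j], prop_b[j])
        if np.log(rng.random()) < new_ll + new_lp - cur_ll - cur_lp[1 + j]:
            beta, cur_ll, cur_lp[1 + j] = prop_b, new_ll, new_lp
            eta_x = eta_prop
            accepted[1 + j] = True

    return float(alpha), beta, accepted


def _marginal_loglik(alpha: float, beta: np.ndarray, p: float, data, xv):
    """Dataset log-likelihood with z summed out, as a function of the
    coefficients at fixed p (binomial factors at detected sites that do not
    involve alpha or beta are included but cancel in MH ratios)."""
    eta = alpha if xv is None else alpha + xv @ beta
    psi = expit(eta)
    with np.errstate(divide="ignore"):
        log_psi = np.log(np.broadcast_to(np.asarray(psi, float), data.y.shape))
        occupied = log_psi + data.n * np.log1p(-p)
        empty = np.log1p(-np.asarray(psi, dtype=float))
        ll_y0 = np.logaddexp(occupied, empty)
        out = np.where(data.y > 0, log_psi, ll_y0)
    return float(np.sum(out))


def _independence_refresh(
    alpha: float,
    beta: np.ndarray,
    p: float,
    data,
    xv,
    priors: Sequence[PriorSpec],
    rng: np.random.Generator,
) -> tuple[float, np.ndarray]:
    """One independence-Metropolis attempt per coefficient against the
    z-marginalized conditional, proposing from the coefficient's own prior
    (prior terms cancel, so acceptance is the marginal-likelihood ratio).

    Must be followed by a fresh z draw before z is used again.
    """
    k = beta.size
    cur_ll = _marginal_loglik(alpha, beta, p, data, xv)

    prop = float(sample_prior(priors[0], 1, rng)[0])
    if np.isfinite(prop):
        new_ll = _marginal_loglik(prop, beta, p, data, xv)
        if np.log(rng.random()) < new_ll - cur_ll:
            alpha, cur_ll = prop, new_ll

    for j in range(k):
        prop_b = beta.copy()
        prop_b[j] = float(sample_prior(priors[1 + j], 1, rng)[0])
        if not np.isfinite(prop_b[j]):
            continue
        new_ll = _marginal_loglik(alpha, prop_b, p, data, xv)
        if np.log(rng.random()) < new_ll - cur_ll:
            beta, cur_ll = prop_b, new_ll

    return float(alpha), beta


def _normalize_priors(
    priors: PriorSpec | Sequence[PriorSpec], k: int, has_covariates: bool
) -> tuple[PriorSpec, ...]:
    if isinstance(priors, PriorSpec):
        out = (priors,) * (1 + k)
    else:
        out = tuple(priors)
        if len(out) != 1 + k:
            raise ValueError(
                f"need 1 intercept prior plus {k} coefficient priors, "
                f"got {len(out)}"
            )
    if has_covariates and any(s.family == "jeffreys" for s in out):
        # the Jeffreys prior is parameter-dependent once covariates enter;
        # it is only defined here for the intercept-only model
        raise ValueError("jeffreys prior is restricted to intercept-only models")
    return out


def _prior_initial(spec: PriorSpec, rng: np.random.Generator) -> float:
    """Draw a dispersed but non-degenerate start from the prior, truncated
    to (-10, 10)."""
    for _ in range(1000):
        a = float(sample_prior(spec, 1, rng)[0])
        if -10.0 < a < 10.0:
            return a
    return 0.0


def fit_bayes(
    data: DetectionHistory,
    x: CovariateMatrix | None = None,
    priors: PriorSpec | Sequence[PriorSpec] = PriorSpec("logistic", 0.0, 1.0),
    config: McmcConfig = McmcConfig(),
) -> PosteriorDraws:
    """Run the Gibbs-within-Metropolis sampler; seeded-deterministic.

    ``priors`` is one spec applied to the intercept and every coefficient,
    or a sequence of 1 + k specs. Detection always carries the Uniform(0, 1)
    prior.
    """
    if x is not None and x.n_sites != data.n_sites:
        raise DataError("covariate row count does not match site count")
    k = 0 if x is None else x.k
    prior_tuple = _normalize_priors(priors, k, x is not None and k > 0)
    names = (
        ("alpha",)
        + tuple(f"beta_{nm}" for nm in (x.names if x is not None else ()))
        + ("p", "psi")
    )
    n_keep = config.n_iter - config.burn_in
    draws = np.empty((config.n_chains, n_keep, 3 + k))
    acc_rates = np.empty((config.n_chains, 1 + k))
    z_trace = (
        np.empty((config.n_chains, n_keep, data.n_sites), dtype=np.int8)
        if config.trace_z
        else None
    )

    y0 = data.y == 0  # only undetected sites have a random z
    xv = None if x is None else x.values

    for c in range(config.n_chains):
        rng = np.random.default_rng([config.seed, c])
        alpha = _prior_initial(prior_tuple[0], rng)
        beta = np.array(
            [_prior_initial(prior_tuple[1 + j], rng) for j in range(k)]
        )
        p = float(rng.uniform(0.05, 0.95))
        z = np.where(y0, rng.integers(0, 2, data.n_sites), 1).astype(np.int64)

        scales = np.full(1 + k, 0.5)
        batch_acc = np.zeros(1 + k)
        batch_no = 0
        acc_total = np.zeros(1 + k)

        for it in range(config.n_iter):
            # collapsed refresh first: it invalidates z, and the exact
            # z redraw that follows restores the joint target
            alpha, beta = _independence_refresh(
                alpha, beta, p, data, xv, prior_tuple, rng
            )
            eta = alpha if xv is None else alpha + xv @ beta
            psi = expit(eta)
            z = update_latent_z(data, psi, p, rng).z
            p = update_detection(data, z, rng)
            alpha, beta, accepted = update_regression(
                alpha, beta, z, x, prior_tuple, rng, scales
            )

            if config.proposal_adaptation and it < config.burn_in:
                batch_acc += accepted
                if (it + 1) % _ADAPT_BATCH == 0:
                    batch_no += 1
                    delta = min(0.1, 1.0 / np.sqrt(batch_no))
                    rate = batch_acc / _ADAPT_BATCH
                    scales *= np.exp(
                        np.where(rate > _ADAPT_TARGET, delta, -delta)
                    )
                    scales = np.clip(scales, 1e-4, 50.0)
                    batch_acc[:] = 0.0

            if it >= config.burn_in:
                j = it - config.burn_in
                draws[c, j, 0] = alpha
                draws[c, j, 1 : 1 + k] = beta
                draws[c, j, 1 + k] = p
                draws[c, j, 2 + k] = expit(alpha)
                acc_total += accepted
                if z_trace is not None:
                    z_trace[c, j] = z

        acc_rates[c] = acc_total / n_keep

    return PosteriorDraws(
        draws=draws,
        parameter_names=names,
        config=config,
        acceptance_rates=acc_rates,
        priors=prior_tuple,
        z_trace=z_trace,
    )


def _rhat_matrix(x: np.ndarray) -> float:
    """Potential scale reduction from an (m chains, n draws) matrix.

    Classic between/within form, floored at 1 (values below 1 are finite-
    sample noise; the floor also makes identical chains report exactly 1).
    """
    m, n = x.shape
    w = float(x.var(axis=1, ddof=1).mean())
    b_over_n = float(x.mean(axis=1).var(ddof=1))
    if w == 0.0:
        return 1.0 if b_over_n == 0.0 else float("inf")
    var_hat = (n - 1) / n * w + b_over_n
    return max(1.0, float(np.sqrt(var_hat / w)))


def gelman_rubin(draws: PosteriorDraws | np.ndarray) -> dict[str, float] | float:
    """Gelman-Rubin R-hat per parameter (needs >= 2 chains, >= 10 draws).

    Accepts a PosteriorDraws (returns a name -> R-hat dict) or a raw
    (chains, iterations) array for a single parameter (returns a float).
    """
    if isinstance(draws, PosteriorDraws):
        arr = draws.draws
        if arr.shape[0] < 2:
            raise ValueError("Gelman-Rubin requires at least 2 chains")
        if arr.shape[1] < 10:
            raise ValueError("Gelman-Rubin requires at least 10 retained draws")
        return {
            name: _rhat_matrix(arr[:, :, j])
            for j, name in enumerate(draws.parameter_names)
        }
    arr = np.asarray(draws, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a (chains >= 2, iterations) array")
    if arr.shape[1] < 10:
        raise ValueError("Gelman-Rubin requires at least 10 retained draws")
    return _rhat_matrix(arr)


def posterior_mode(
    samples: np.ndarray,
    lo: float | None = None,
    hi: float | None = None,
    grid_size: int = 512,
) -> float:
    """Argmax of a Gaussian KDE (Silverman bandwidth) on a grid over the
    sample range, optionally clipped to [lo, hi] (use 0, 1 for psi or p)."""
    s = np.asarray(samples, dtype=float).ravel()
    if np.ptp(s) < 1e-14:
        return float(s[0])
    if s.size < 100:
        raise ValueError(
            f"posterior_mode needs >= 100 samples (got {s.size}); run longer"
        )
    gmin, gmax = float(s.min()), float(s.max())
    if lo is not None:
        gmin = max(gmin, lo)
    if hi is not None:
        gmax = min(gmax, hi)
    kde = gaussian_kde(s, bw_method="silverman")
    grid = np.linspace(gmin, gmax, grid_size)
    return float(grid[int(np.argmax(kde(grid)))])


def summarize(draws: PosteriorDraws) -> PosteriorSummary:
    """Pooled-chain median, KDE mode, equal-tailed 95% CI and R-hat."""
    rhats = (
        gelman_rubin(draws)
        if draws.n_chains >= 2 and draws.n_retained >= 10
        else {name: np.nan for name in draws.parameter_names}
    )
    rows = []
    for name in draws.parameter_names:
        s = draws.pooled(name)
        bounded = name in ("p", "psi")
        mode = posterior_mode(s, 0.0 if bounded else None, 1.0 if bounded else None)
        lo, med, hi = np.quantile(s, [0.025, 0.5, 0.975])
        rows.append((name, float(med), mode, float(lo), float(hi), rhats[name]))
    return PosteriorSummary(
        pd.DataFrame(
            rows,
            columns=["parameter", "median", "mode", "ci_lo", "ci_hi", "rhat"],
        )
    )
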