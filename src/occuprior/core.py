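"""Core types and the marginal likelihood for site-occupancy data.

The model: site ``i`` is occupied with probability ``psi_i``; conditional on
occupancy, the number of detections across ``n_i`` survey occasions is
Binomial(``n_i``, ``p``); an unoccupied site yields no detections.
Marginalizing the latent occupancy indicator ``z_i`` gives the per-site
likelihood

    P(y_i) = psi_i * Binom(y_i | n_i, p) + (1 - psi_i) * 1{y_i = 0}

which is what :func:`site_log_likelihood` evaluates (in log space).
Occupancy may depend on site covariates through a logit link,
``logit(psi_i) = alpha + x_i @ beta``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit, gammaln, xlog1py, xlogy
from scipy.special import logit as _sp_logit

__all__ = [
    "DataError",
    "DetectionHistory",
    "CovariateMatrix",
    "OccupancyParams",
    "LatentState",
    "inv_logit",
    "logit",
    "linear_predictor",
    "site_log_likelihood",
    "dataset_log_likelihood",
]


class DataError(ValueError):
    """Raised when data or parameters violate a model invariant."""


@dataclass(frozen=True)
class DetectionHistory:
    """Per-site detection counts ``y`` out of ``n`` survey occasions."""

    y: np.ndarray
    n: np.ndarray
    site_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        y = np.atleast_1d(np.asarray(self.y, dtype=np.int64))
        n = np.atleast_1d(np.asarray(self.n, dtype=np.int64))
        if y.ndim != 1 or n.shape != y.shape:
            raise DataError("y and n must be 1-D sequences of equal length")
        ids = tuple(str(s) for s in self.site_ids)
        if not ids:
            ids = tuple(f"site_{i + 1}" for i in range(y.size))
        if len(ids) != y.size:
            raise DataError(
                f"{len(ids)} site labels for {y.size} sites"
            )
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise DataError(f"duplicate site labels: {dupes}")
        if y.size and n.min(initial=1) < 1:
            bad = ids[int(np.argmin(n))]
            raise DataError(f"n_i must be >= 1 (site {bad})")
        if y.size and (np.any(y < 0) or np.any(y > n)):
            bad = ids[int(np.argmax((y < 0) | (y > n)))]
            raise DataError(f"need 0 <= y_i <= n_i (violated at site {bad})")
        y.setflags(write=False)
        n.setflags(write=False)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "site_ids", ids)

    @property
    def n_sites(self) -> int:
        return int(self.y.size)

    @property
    def detected(self) -> np.ndarray:
        """Boolean mask of sites with at least one detection."""
        return self.y > 0


@dataclass(frozen=True)
class CovariateMatrix:
    """Sites-by-k covariate matrix, optionally standardized.

    When ``standardized`` is set, ``centers`` and ``scales`` record the
    column means and sample standard deviations removed, so predictions
    can be mapped back to the raw covariate scale.
    """

    values: np.ndarray
    names: tuple[str, ...] = ()
    standardized: bool = False
    centers: np.ndarray | None = None
    scales: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if v.ndim != 2:
            raise DataError("covariate values must be a 2-D matrix")
        names = tuple(str(s) for s in self.names)
        if not names:
            names = tuple(f"x{j + 1}" for j in range(v.shape[1]))
        if len(names) != v.shape[1]:
            raise DataError(
                f"{len(names)} covariate names for {v.shape[1]} columns"
            )
        if not np.all(np.isfinite(v)):
            raise DataError("covariates must be finite")
        if self.standardized and v.shape[0] > 1:
            mu = v.mean(axis=0)
            sd = v.std(axis=0, ddof=1)
            if np.any(np.abs(mu) > 1e-8) or np.any(np.abs(sd - 1) > 1e-8):
                raise DataError(
                    "standardized flag set but columns are not mean-0 / SD-1"
                )
        v.setflags(write=False)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "names", names)
        if self.centers is not None:
            object.__setattr__(
                self, "centers", np.asarray(self.centers, dtype=float)
            )
        if self.scales is not None:
            object.__setattr__(
                self, "scales", np.asarray(self.scales, dtype=float)
            )

    @property
    def n_sites(self) -> int:
        return int(self.values.shape[0])

    @property
    def k(self) -> int:
        return int(self.values.shape[1])


@dataclass(frozen=True)
class OccupancyParams:
    """Logit-scale occupancy parameters plus the detection probability."""

    alpha: float
    p: float
    beta: Sequence[float] | np.ndarray = ()

    def __post_init__(self) -> None:
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if not np.isfinite(self.alpha) or not np.all(np.isfinite(beta)):
            raise DataError("alpha and beta must be finite")
        if not 0.0 <= self.p <= 1.0:
            raise DataError(f"p must lie in [0, 1], got {self.p}")
        beta.setflags(write=False)
        object.__setattr__(self, "alpha", float(self.alpha))
        object.__setattr__(self, "p", float(self.p))
        object.__setattr__(self, "beta", beta)


@dataclass(frozen=True)
class LatentState:
    """Per-site 0/1 occupancy indicators."""

    z: np.ndarray

    def __post_init__(self) -> None:
        z = np.atleast_1d(np.asarray(self.z, dtype=np.int64))
        if z.size and not np.all((z == 0) | (z == 1)):
            raise DataError("z must be 0/1")
        z.setflags(write=False)
        object.__setattr__(self, "z", z)

    def validate_against(self, data: DetectionHistory) -> None:
        """A detected site must be occupied: z_i = 1 wherever y_i > 0."""
        if self.z.shape != data.y.shape:
            raise DataError("latent state length does not match data")
        if np.any((data.y > 0) & (self.z == 0)):
            raise DataError("z_i = 0 at a site with detections")


def inv_logit(x):
    """Numerically stable inverse logit, e^x / (1 + e^x).

    Total on the extended reals: +/-inf map to exactly 1/0; no overflow
    for any finite input.
    """
    return expit(x)


def logit(psi):
    """Log-odds, log(psi / (1 - psi)). Defined only on the open (0, 1)."""
    arr = np.asarray(psi, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        bad = arr[(arr <= 0.0) | (arr >= 1.0)].ravel()[0]
        raise DataError(f"logit undefined at {bad}: need 0 < psi < 1")
    out = _sp_logit(psi)
    return float(out) if np.ndim(psi) == 0 else out


def linear_predictor(
    params: OccupancyParams,
    x: CovariateMatrix | None = None,
    n_sites: int | None = None,
) -> np.ndarray:
    """Per-site logit-scale occupancy, alpha + x_i @ beta.

    With no covariates, returns ``alpha`` replicated ``n_sites`` times
    (``params.beta`` must then be empty).
    """
    if x is None:
        if params.beta.size:
            raise DataError("beta supplied but no covariate matrix")
        m = 1 if n_sites is None else int(n_sites)
        return np.full(m, params.alpha)
    if params.beta.size != x.k:
        raise DataError(
            f"beta has {params.beta.size} entries but x has {x.k} columns"
        )
    return params.alpha + x.values @ params.beta


def binomial_logpmf(y, n, p):
    """log C(n, y) + y log p + (n - y) log(1-p), safe at p in {0, 1}."""
    y = np.asarray(y)
    n = np.asarray(n)
    return (
        gammaln(n + 1)
        - gammaln(y + 1)
        - gammaln(n - y + 1)
        + xlogy(y, p)
        + xlog1py(n - y, -p)
    )


def site_log_likelihood(y, n, psi, p):
    """Marginal log-likelihood of one site (z summed out).

    log[ psi * Binom(y | n, p) + (1 - psi) * 1{y = 0} ], evaluated with a
    stable log-sum-exp so it does not underflow even when the occupied-site
    term is ~1e-300 (large n, small p, or psi pinned near a boundary).
    Broadcasts over array inputs.
    """
    y_arr = np.asarray(y)
    n_arr = np.asarray(n)
    if np.any(y_arr < 0) or np.any(y_arr > n_arr) or np.any(n_arr < 1):
        raise DataError("need 0 <= y <= n and n >= 1")
    psi_arr = np.asarray(psi, dtype=float)
    p_arr = np.asarray(p, dtype=float)
    if np.any((psi_arr < 0) | (psi_arr > 1)) or np.any((p_arr < 0) | (p_arr > 1)):
        raise DataError("psi and p must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        occupied = np.log(psi_arr) + binomial_logpmf(y_arr, n_arr, p_arr)
        empty = np.where(y_arr == 0, np.log1p(-psi_arr), -np.inf)
    out = np.logaddexp(occupied, empty)
    return float(out) if out.ndim == 0 else out


def dataset_log_likelihood(
    data: DetectionHistory,
    params: OccupancyParams,
    x: CovariateMatrix | None = None,
) -> float:
    """Sum of site log-likelihoods with psi_i from the logit-linear model."""
    if x is not None and x.n_sites != data.n_sites:
        raise DataError(
            f"covariate matrix has {x.n_sites} rows for {data.n_sites} sites"
        )
    if data.n_sites == 0:
        return 0.0
    eta = linear_predictor(params, x, data.n_sites)
    psi = expit(eta)
    return float(np.sum(site_log_likelihood(data.y, data.n, psi, params.p)))
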