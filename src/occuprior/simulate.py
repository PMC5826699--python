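"""Synthetic detection-history generation.

Draws the latent occupancy state z_i ~ Bernoulli(psi_i) — with psi_i either
constant or inv_logit(alpha + x_i @ beta) — then detections
y_i ~ Binomial(n_i, p * z_i). The latent truth is returned alongside the
data so recovery tests never have to re-derive occupancy from detections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .core import (
    CovariateMatrix,
    DataError,
    DetectionHistory,
    LatentState,
    OccupancyParams,
    linear_predictor,
)

__all__ = ["SimulationConfig", "simulate_dataset", "standardize_covariates"]


@dataclass(frozen=True)
class SimulationConfig:
    """Inputs for one simulated dataset.

    ``truth.alpha`` is the logit-scale intercept; for a constant-psi design
    pass ``OccupancyParams(alpha=logit(psi), p=p)`` or use
    :meth:`from_psi`. ``n_covariates`` columns are drawn i.i.d. standard
    normal (already standardized in distribution); a user matrix can be
    passed to :func:`simulate_dataset` instead.
    """

    n_sites: int
    n_occasions: int
    truth: OccupancyParams
    n_covariates: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise DataError("n_sites must be >= 1")
        if self.n_occasions < 1:
            raise DataError("n_occasions must be >= 1")
        if self.n_covariates < 0:
            raise DataError("n_covariates must be >= 0")
        if self.truth.beta.size not in (0, self.n_covariates):
            raise DataError(
                f"truth has {self.truth.beta.size} coefficients for "
                f"{self.n_covariates} covariates"
            )

    @classmethod
    def from_psi(
        cls,
        n_sites: int,
        n_occasions: int,
        psi: float,
        p: float,
        seed: int = 0,
    ) -> "SimulationConfig":
        """Constant-occupancy design specified directly by psi in [0, 1]."""
        if not 0.0 <= psi <= 1.0:
            raise DataError(f"psi must lie in [0, 1], got {psi}")
        if psi == 0.0:
            alpha = -np.inf
        elif psi == 1.0:
            alpha = np.inf
        else:
            alpha = float(np.log(psi / (1.0 - psi)))
        # OccupancyParams requires finite alpha; carry boundary psi directly
        cfg = cls.__new__(cls)
        object.__setattr__(cfg, "n_sites", n_sites)
        object.__setattr__(cfg, "n_occasions", n_occasions)
        object.__setattr__(cfg, "n_covariates", 0)
        object.__setattr__(cfg, "seed", seed)
        if np.isfinite(alpha):
            object.__setattr__(cfg, "truth", OccupancyParams(alpha, p))
        else:
            object.__setattr__(cfg, "truth", _BoundaryTruth(alpha, p))
        cls.__post_init__(cfg)
        return cfg


class _BoundaryTruth:
    """Stand-in truth for psi exactly 0 or 1 (alpha = -/+inf)."""

    def __init__(self, alpha: float, p: float):
        if not 0.0 <= p <= 1.0:
            raise DataError(f"p must lie in [0, 1], got {p}")
        self.alpha = alpha
        self.p = float(p)
        self.beta = np.empty(0)


def simulate_dataset(
    config: SimulationConfig,
    covariates: CovariateMatrix | None = None,
) -> tuple[DetectionHistory, CovariateMatrix | None, LatentState]:
    """Generate one dataset; identical seed means bit-identical output.

    A user-supplied covariate matrix overrides the config's generated
    columns (its row count must equal ``n_sites``).
    """
    rng = np.random.default_rng(config.seed)
    x = covariates
    if x is None and config.n_covariates > 0:
        vals = rng.standard_normal((config.n_sites, config.n_covariates))
        x = CovariateMatrix(vals)
    if x is not None and x.n_sites != config.n_sites:
        raise DataError(
            f"covariate matrix has {x.n_sites} rows for {config.n_sites} sites"
        )

    truth = config.truth
    if isinstance(truth, _BoundaryTruth):
        psi = np.full(config.n_sites, 1.0 if truth.alpha > 0 else 0.0)
    else:
        psi = expit(linear_predictor(truth, x, config.n_sites))
    z = (rng.random(config.n_sites) < psi).astype(np.int64)
    n = np.full(config.n_sites, config.n_occasions, dtype=np.int64)
    y = rng.binomial(n, truth.p * z)
    data = DetectionHistory(y, n)
    return data, x, LatentState(z)


def standardize_covariates(x: CovariateMatrix) -> CovariateMatrix:
    """Center and scale each column to mean 0 and sample SD 1 (divisor n-1).

    Idempotent; centers and scales are recorded (composed with any prior
    standardization) so fitted coefficients can be mapped back to the raw
    scale. A constant column is a degenerate covariate and is an error.
    """
    v = x.values
    if v.shape[0] < 2:
        raise DataError("standardization needs at least 2 sites")
    centers = v.mean(axis=0)
    scales = v.std(axis=0, ddof=1)
    if np.any(scales == 0):
        bad = x.names[int(np.argmax(scales == 0))]
        raise DataError(f"degenerate covariate (constant column): {bad}")
    prev_c = x.centers if x.centers is not None else np.zeros(x.k)
    prev_s = x.scales if x.scales is not None else np.ones(x.k)
    return CovariateMatrix(
        (v - centers) / scales,
        names=x.names,
        standardized=True,
        centers=prev_c + centers * prev_s,
        scales=prev_s * scales,
    )
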