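"""Prior families for logit-scale coefficients and their probability-scale
pushforwards.

A prior placed on a logit-scale parameter ``alpha`` induces a distribution
on ``psi = inv_logit(alpha)`` through the change of variables

    f_psi(psi) = f_alpha(logit(psi)) / (psi * (1 - psi)).

:func:`induced_density` evaluates this on a grid; :func:`sample_induced` is
its Monte-Carlo counterpart. The ``uniform_probability`` family is the
Logistic(0, 1) prior on the logit scale, which induces exactly Uniform(0, 1)
on the probability scale; ``jeffreys`` is the logit-scale pushforward of
Beta(1/2, 1/2).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln
from scipy.special import logit as _sp_logit

__all__ = [
    "PriorSpec",
    "InducedDensity",
    "prior_log_density",
    "precision_from_sigma",
    "sigma_from_precision",
    "variance_from_sigma",
    "sigma_from_variance",
    "induced_density",
    "sample_induced",
    "sample_prior",
    "parse_prior",
]

FAMILIES = (
    "normal",
    "logistic",
    "student_t",
    "cauchy",
    "jeffreys",
    "uniform_probability",
)

#: families whose density has no free location/scale/df parameters
_PARAMETER_FREE = ("jeffreys", "uniform_probability")

# grid endpoints are excluded: several induced densities (Jeffreys,
# large-sigma Normal) diverge at psi in {0, 1}
GRID_EPS = 1e-6


@dataclass(frozen=True)
class PriorSpec:
    """A named prior family for a logit-scale coefficient.

    ``normal`` is parameterized by its standard deviation ``scale`` (sigma)
    everywhere in the public API; use the converters below for the variance
    (sigma^2) and precision (tau = 1/sigma^2) conventions.
    """

    family: str
    location: float = 0.0
    scale: float = 1.0
    df: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown prior family {self.family!r}; choose from {FAMILIES}"
            )
        if self.family in _PARAMETER_FREE:
            if self.location != 0.0 or self.scale != 1.0 or self.df is not None:
                raise ValueError(f"{self.family} takes no parameters")
        else:
            if not (self.scale > 0 and np.isfinite(self.scale)):
                raise ValueError(f"scale must be positive, got {self.scale}")
            if not np.isfinite(self.location):
                raise ValueError("location must be finite")
        if self.family == "student_t":
            if self.df is None or not (self.df > 0):
                raise ValueError("student_t requires df > 0")
        elif self.family != "student_t" and self.df is not None:
            raise ValueError(f"df is only meaningful for student_t")

    @property
    def label(self) -> str:
        """Flat text form, e.g. ``normal(0,2)`` or ``t(0,1.566,7.763)``."""
        if self.family in _PARAMETER_FREE:
            return self.family
        if self.family == "student_t":
            return f"t({self.location:g},{self.scale:g},{self.df:g})"
        return f"{self.family}({self.location:g},{self.scale:g})"


@dataclass(frozen=True)
class InducedDensity:
    """A prior density evaluated on a probability-scale grid."""

    psi_grid: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.psi_grid, dtype=float)
        d = np.asarray(self.density, dtype=float)
        if g.shape != d.shape or g.ndim != 1:
            raise ValueError("grid and density must be 1-D and equal length")
        if np.any(np.diff(g) <= 0) or g[0] <= 0 or g[-1] >= 1:
            raise ValueError("grid must be increasing inside (0, 1)")
        if np.any(d < 0) or not np.all(np.isfinite(d)):
            raise ValueError("density must be finite and nonnegative")
        object.__setattr__(self, "psi_grid", g)
        object.__setattr__(self, "density", d)

    def integral(self) -> float:
        """Trapezoid integral over the grid."""
        return float(np.trapezoid(self.density, self.psi_grid))


def _log_sigmoid(x):
    """log(inv_logit(x)), stable for large |x|."""
    return -np.logaddexp(0.0, -np.asarray(x, dtype=float))


def prior_log_density(spec: PriorSpec, alpha):
    """Log density of the logit-scale parameter under ``spec``.

    For ``uniform_probability`` this is the Logistic(0, 1) log density; for
    ``jeffreys`` it is the logit-scale pushforward of Beta(1/2, 1/2),
    sqrt(psi (1-psi)) / pi with psi = inv_logit(alpha).
    """
    a = np.asarray(alpha, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("alpha must be finite")
    fam = spec.family
    if fam == "normal":
        z = (a - spec.location) / spec.scale
        out = -0.5 * z * z - math.log(spec.scale) - 0.5 * math.log(2 * math.pi)
    elif fam in ("logistic", "uniform_probability"):
        loc, s = (spec.location, spec.scale) if fam == "logistic" else (0.0, 1.0)
        z = (a - loc) / s
        out = _log_sigmoid(z) + _log_sigmoid(-z) - math.log(s)
    elif fam in ("student_t", "cauchy"):
        nu = spec.df if fam == "student_t" else 1.0  # Cauchy = t with 1 df
        z = (a - spec.location) / spec.scale
        out = (
            gammaln((nu + 1) / 2)
            - gammaln(nu / 2)
            - 0.5 * math.log(nu * math.pi)
            - math.log(spec.scale)
            - (nu + 1) / 2 * np.log1p(z * z / nu)
        )
    elif fam == "jeffreys":
        out = 0.5 * (_log_sigmoid(a) + _log_sigmoid(-a)) - math.log(math.pi)
    else:  # pragma: no cover - constructor forbids
        raise ValueError(fam)
    return float(out) if np.ndim(alpha) == 0 else out


def precision_from_sigma(sigma: float) -> float:
    """tau = 1 / sigma^2 (the precision convention of BUGS-family engines)."""
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return 1.0 / (sigma * sigma)


def sigma_from_precision(tau: float) -> float:
    if not tau > 0:
        raise ValueError(f"precision must be positive, got {tau}")
    return 1.0 / math.sqrt(tau)


def variance_from_sigma(sigma: float) -> float:
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return sigma * sigma


def sigma_from_variance(var: float) -> float:
    if not var > 0:
        raise ValueError(f"variance must be positive, got {var}")
    return math.sqrt(var)


def induced_density(spec: PriorSpec, grid_size: int = 2001) -> InducedDensity:
    """Probability-scale density induced by ``spec`` through the logit link.

    Evaluated on a uniform open-interval grid [GRID_EPS, 1 - GRID_EPS]; the
    endpoints are excluded because the pushforward can diverge there. Note
    that for priors placing non-negligible logit-scale mass beyond
    |alpha| > logit(1 - GRID_EPS) (e.g. normal with sigma >> 10, cauchy),
    the visible grid deliberately carries less than the full unit mass.
    """
    if grid_size < 3:
        raise ValueError("grid_size must be >= 3")
    psi = np.linspace(GRID_EPS, 1.0 - GRID_EPS, grid_size)
    x = _sp_logit(psi)
    # log Jacobian log(psi (1 - psi)) from the same x so that the
    # logistic(0,1) case cancels exactly, giving density == 1.0 bitwise
    log_jac = _log_sigmoid(x) + _log_sigmoid(-x)
    dens = np.exp(prior_log_density(spec, x) - log_jac)
    return InducedDensity(psi, dens)


def sample_prior(spec: PriorSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """n draws of the logit-scale parameter alpha from the prior."""
    fam = spec.family
    if fam == "normal":
        return rng.normal(spec.location, spec.scale, n)
    if fam == "logistic":
        return rng.logistic(spec.location, spec.scale, n)
    if fam == "uniform_probability":
        return rng.logistic(0.0, 1.0, n)
    if fam == "student_t":
        return spec.location + spec.scale * rng.standard_t(spec.df, n)
    if fam == "cauchy":
        return spec.location + spec.scale * rng.standard_t(1.0, n)
    # jeffreys: logit of Beta(1/2, 1/2)
    b = np.clip(rng.beta(0.5, 0.5, n), 1e-300, 1 - 1e-16)
    return _sp_logit(b)


def sample_induced(spec: PriorSpec, n: int, seed: int) -> np.ndarray:
    """n seeded draws of inv_logit(alpha), alpha drawn from the prior."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return expit(sample_prior(spec, n, rng))


_SPEC_RE = re.compile(r"^\s*([a-zA-Z_]+)\s*(?:\(([^)]*)\))?\s*$")

_ALIASES = {
    "t": "student_t",
    "student_t": "student_t",
    "normal": "normal",
    "gaussian": "normal",
    "logistic": "logistic",
    "cauchy": "cauchy",
    "jeffreys": "jeffreys",
    "uniform": "uniform_probability",
    "uniform_probability": "uniform_probability",
}


def parse_prior(text: str) -> PriorSpec:
    """Parse the flat prior mini-language: ``family(location, scale[, df])``.

    Examples: ``normal(0,2)``, ``logistic(0,1)``, ``t(0,1.566,7.763)``,
    ``cauchy(0,2.5)``, ``jeffreys``, ``uniform``.
    """
    m = _SPEC_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse prior spec {text!r}")
    name, argstr = m.group(1).lower(), m.group(2)
    family = _ALIASES.get(name)
    if family is None:
        raise ValueError(f"unknown prior family {name!r} in {text!r}")
    args = []
    if argstr and argstr.strip():
        try:
            args = [float(tok) for tok in argstr.split(",")]
        except ValueError:
            raise ValueError(f"non-numeric argument in prior spec {text!r}")
    if family in _PARAMETER_FREE:
        if args:
            raise ValueError(f"{family} takes no parameters: {text!r}")
        return PriorSpec(family)
    if family == "student_t":
        if len(args) != 3:
            raise ValueError(f"t prior needs (location, scale, df): {text!r}")
        return PriorSpec(family, args[0], args[1], args[2])
    if len(args) != 2:
        raise ValueError(f"{family} prior needs (location, scale): {text!r}")
    return PriorSpec(family, args[0], args[1])
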