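"""Independent reference implementations used to check the package.

Everything here is deliberately written from first principles with plain
math/scipy only — no imports from the package under test — so the tests
compare two independent code paths.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import expit


def enum_site_likelihood(y: int, n: int, psi: float, p: float) -> float:
    """P(y) by brute-force enumeration over the latent state z in {0, 1}."""
    total = 0.0
    for z in (0, 1):
        p_y_given_z = (
            math.comb(n, y) * (p * z) ** y * (1 - p * z) ** (n - y)
            if y > 0
            else (1 - p * z) ** n
        )
        # 0**0 convention: (p*z)**y with y=0 handled by the branch above
        p_z = psi if z == 1 else 1 - psi
        total += p_y_given_z * p_z
    return total


def direct_dataset_likelihood(y, n, psi: float, p: float) -> float:
    """Product of per-site probabilities, direct arithmetic (no logs)."""
    out = 1.0
    for yi, ni in zip(y, n):
        out *= psi * math.comb(ni, yi) * p**yi * (1 - p) ** (ni - yi) + (
            1 - psi
        ) * (1 if yi == 0 else 0)
    return out


def grid_search_mle(y, n, grid_points: int = 1000):
    """Exhaustive (psi, p) grid search of the marginal likelihood at
    resolution 1/grid_points (cell centers)."""
    y = np.asarray(y)
    n = np.asarray(n)
    g = (np.arange(grid_points) + 0.5) / grid_points
    psi = g[:, None]
    p = g[None, :]
    ll = np.zeros((grid_points, grid_points))
    for yi, ni in zip(y, n):
        like = psi * math.comb(int(ni), int(yi)) * p**yi * (1 - p) ** (
            ni - yi
        ) + (1 - psi) * (1 if yi == 0 else 0)
        ll += np.log(like)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return float(g[i]), float(g[j]), float(ll[i, j])


def quadrature_posterior(
    y,
    n,
    prior_logpdf,
    n_alpha: int = 1601,
    n_p: int = 1601,
    alpha_range: tuple[float, float] = (-25.0, 25.0),
):
    """Dense 2-D integration of likelihood x prior over (alpha, p) with a
    Uniform(0, 1) prior on p.

    Returns (psi_mean, psi_median, p_mean, p_median) for psi = expit(alpha).
    """
    a = np.linspace(*alpha_range, n_alpha)
    p = np.linspace(1e-6, 1 - 1e-6, n_p)
    psi = expit(a)
    ll = np.zeros((n_alpha, n_p))
    for yi, ni in zip(y, n):
        like = psi[:, None] * math.comb(int(ni), int(yi)) * p[None, :] ** yi * (
            1 - p[None, :]
        ) ** (ni - yi) + (1 - psi[:, None]) * (1 if yi == 0 else 0)
        ll += np.log(like)
    lp = ll + prior_logpdf(a)[:, None]
    w = np.exp(lp - lp.max())
    w /= w.sum()

    def moments(values, weights):
        mean = float(weights @ values)
        c = np.cumsum(weights)
        median = float(values[np.searchsorted(c, 0.5 * c[-1])])
        return mean, median

    psi_mean, psi_median = moments(psi, w.sum(axis=1))
    p_mean, p_median = moments(p, w.sum(axis=0))
    return psi_mean, psi_median, p_mean, p_median
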