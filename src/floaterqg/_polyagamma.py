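"""Exact Polya-Gamma PG(1, z) sampling (Devroye-style alternating series).

Used for data augmentation in the Bayesian logistic animal model: with
``omega_i ~ PG(1, eta_i)`` the Bernoulli-logit likelihood becomes
conditionally Gaussian in all location effects, giving closed-form Gibbs
updates.  The sampler follows the standard accept-reject scheme on the
Jacobi J*(1, z/2) density (PG(1,z) = J*(1, z/2) / 4) with a truncated
inverse-Gaussian proposal left of the truncation point and an
exponential tail to the right.

All routines consume a ``numpy.random.Generator`` so draws share the
caller's stream and are reproducible under a fixed seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["pg_draw", "pg_vector"]

_TRUNC = 0.64  # truncation point t of the two-piece proposal


@njit(cache=True)
def _norm_cdf(x: float) -> float:
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


@njit(cache=True)
def _a_coef(n: int, x: float) -> float:
    """n-th coefficient of the alternating series for the Jacobi density."""
    h = n + 0.5
    if x > _TRUNC:
        return math.pi * h * math.exp(-(h * h) * (math.pi * math.pi) * x / 2.0)
    return math.pi * h * (2.0 / (math.pi * x)) ** 1.5 * math.exp(-2.0 * h * h / x)


@njit(cache=True)
def _pigauss_cdf(x: float, z: float) -> float:
    """CDF at x of the inverse-Gaussian IG(mu=1/z, lambda=1); z >= 0.

    The z = 0 limit is the Levy (one-sided stable) CDF.
    """
    rx = 1.0 / math.sqrt(x)
    return _norm_cdf(rx * (x * z - 1.0)) + math.exp(2.0 * z) * _norm_cdf(-rx * (x * z + 1.0))


@njit(cache=True)
def _rtigauss(z: float, rng) -> float:
    """IG(1/z, 1) truncated to (0, t]; z >= 0."""
    t = _TRUNC
    if z < 1.0 / t:  # mean above the truncation point: chi-like proposal
        while True:
            e1 = rng.standard_exponential()
            e2 = rng.standard_exponential()
            while e1 * e1 > 2.0 * e2 / t:
                e1 = rng.standard_exponential()
                e2 = rng.standard_exponential()
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            if rng.random() <= math.exp(-0.5 * z * z * x):
                return x
    else:
        mu = 1.0 / z
        while True:
            y = rng.standard_normal()
            y = y * y
            x = mu + 0.5 * mu * mu * y - 0.5 * mu * math.sqrt(4.0 * mu * y + (mu * y) * (mu * y))
            if rng.random() > mu / (mu + x):
                x = mu * mu / x
            if x <= t:
                return x


@njit(cache=True)
def pg_draw(zin: float, rng) -> float:
    """One exact draw from PG(1, z)."""
    z = 0.5 * abs(zin)
    t = _TRUNC
    k = math.pi * math.pi / 8.0 + z * z / 2.0
    p = (math.pi / (2.0 * k)) * math.exp(-k * t)
    q = 2.0 * math.exp(-z) * _pigauss_cdf(t, z)
    while True:
        if rng.random() * (p + q) <= p:
            x = t + rng.standard_exponential() / k
        else:
            x = _rtigauss(z, rng)
        s = _a_coef(0, x)
        y = rng.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    return x / 4.0
            else:
                s += _a_coef(n, x)
                if y > s:
                    break


@njit(cache=True)
def pg_vector(zs: np.ndarray, rng) -> np.ndarray:
    """Independent PG(1, z_i) draws for a vector of tilts."""
    out = np.empty(zs.size)
    for i in range(zs.size):
        out[i] = pg_draw(zs[i], rng)
    return out
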