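"""Response distributions for the two mixed models.

Zero-inflated Beta: a point mass ``pi`` at zero mixed with a Beta law on
(0, 1) parameterised by mean ``mu`` and precision ``phi`` (shapes
``mu*phi`` and ``(1-mu)*phi``), the standard model for proportion data with
true zeros.

Tweedie with power 1 < p < 2: the compound Poisson-gamma law with mean
``mu``, dispersion ``phi`` and variance ``phi * mu**p``.  It places positive
mass ``exp(-lam)`` at zero, with ``lam = mu**(2-p) / (phi*(2-p))``, and a
continuous density on (0, inf) evaluated by the series expansion over the
Poisson count, summed in log space with adaptive term selection.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

__all__ = [
    "zib_logpdf", "zib_density", "squeeze_unit_interval",
    "tweedie_logpdf", "tweedie_density", "tweedie_zero_mass", "tweedie_rvs",
    "tweedie_compound_params",
]


def squeeze_unit_interval(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Smithson-Verkuilen squeeze ``y' = (y*(n-1) + 0.5) / n``.

    Maps values on [0, 1] into the open interval so that a Beta likelihood
    is finite at full coverage; ``n`` defaults to the number of values.
    """
    y = np.asarray(y, dtype=float)
    if n is None:
        n = y.size
    if n < 1:
        raise ValueError("n must be >= 1")
    return (y * (n - 1) + 0.5) / n


def _check_unit(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("responses must lie in [0, 1]")
    return y


def zib_logpdf(y, mu, phi, pi_zero) -> np.ndarray:
    """Log density/mass of the zero-inflated Beta law (vectorised).

    ``log(pi)`` at y = 0; ``log(1-pi) + logBeta(y; mu*phi, (1-mu)*phi)`` on
    (0, 1).  Responses equal to 1 must be squeezed beforehand (see
    :func:`squeeze_unit_interval`); an exact 1 yields ``-inf`` here.
    """
    y = _check_unit(y)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    pi_zero = np.asarray(pi_zero, dtype=float)
    if np.any((mu <= 0) | (mu >= 1)):
        raise ValueError("mu must lie in (0, 1)")
    if np.any(phi <= 0):
        raise ValueError("phi must be positive")
    if np.any((pi_zero < 0) | (pi_zero >= 1)):
        raise ValueError("pi_zero must lie in [0, 1)")
    y_b, mu_b, phi_b, pi_b = np.broadcast_arrays(y, mu, phi, pi_zero)
    out = np.full(y_b.shape, -np.inf, dtype=float)
    zero = y_b == 0
    with np.errstate(divide="ignore"):
        out[zero] = np.log(pi_b[zero])
    pos = (y_b > 0) & (y_b < 1)
    a = mu_b[pos] * phi_b[pos]
    b = (1.0 - mu_b[pos]) * phi_b[pos]
    out[pos] = np.log1p(-pi_b[pos]) + stats.beta.logpdf(y_b[pos], a, b)
    return out if out.shape else float(out)


def zib_density(y, mu, phi, pi_zero):
    """Density/mass of the zero-inflated Beta law (see :func:`zib_logpdf`)."""
    return np.exp(zib_logpdf(y, mu, phi, pi_zero))


def tweedie_compound_params(mu, phi, p):
    """Compound Poisson-gamma parameters (lam, alpha, theta) of a Tweedie law.

    ``lam`` is the Poisson rate, ``alpha`` the gamma shape and ``theta`` the
    gamma scale: Y = sum of N ~ Poisson(lam) iid Gamma(alpha, theta) terms.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or np.any(np.asarray(phi) <= 0):
        raise ValueError("mu and phi must be positive")
    p = float(p)
    if not 1.0 < p < 2.0:
        raise ValueError("power p must lie in (1, 2)")
    lam = mu ** (2.0 - p) / (phi * (2.0 - p))
    alpha = (2.0 - p) / (p - 1.0)
    theta = phi * (p - 1.0) * mu ** (p - 1.0)
    return lam, alpha, theta


def tweedie_zero_mass(mu, phi, p):
    """Probability of an exact zero: ``exp(-lam)``."""
    lam, _, _ = tweedie_compound_params(mu, phi, p)
    return np.exp(-lam)


def _series_logpdf_positive(y, mu, phi, p):
    """Series log density for strictly positive y (arrays broadcastable).

    Sums Poisson(j; lam) * Gamma(y; j*alpha, theta) over j in log space.
    The dominant index is approximately ``y**(2-p) / (phi*(2-p))``; terms
    are evaluated on a window wide enough that the truncation error is
    negligible at double precision.
    """
    lam, alpha, theta = tweedie_compound_params(mu, phi, p)
    y = np.asarray(y, dtype=float)
    y_b, lam_b, theta_b = np.broadcast_arrays(y, lam, theta)
    j_peak = y_b ** (2.0 - p) / (np.asarray(phi) * (2.0 - p))
    j_hi = int(np.ceil(np.max(j_peak + 12.0 * np.sqrt(j_peak + 1.0) + 25.0)))
    j = np.arange(1, j_hi + 1, dtype=float)
    # (n, J) matrix of log terms
    yy = y_b.reshape(-1, 1)
    ll = lam_b.reshape(-1, 1)
    tt = theta_b.reshape(-1, 1)
    log_terms = (
        -ll + j * np.log(ll) - special.gammaln(j + 1.0)
        + (j * alpha - 1.0) * np.log(yy) - yy / tt
        - special.gammaln(j * alpha) - j * alpha * np.log(tt)
    )
    out = special.logsumexp(log_terms, axis=1).reshape(y_b.shape)
    return out


def tweedie_logpdf(y, mu, phi, p) -> np.ndarray:
    """Log density/mass of a Tweedie law with power 1 < p < 2 (vectorised)."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("responses must be nonnegative")
    lam, _, _ = tweedie_compound_params(mu, phi, p)
    y_b, lam_b = np.broadcast_arrays(y, lam)
    mu_b = np.broadcast_to(np.asarray(mu, dtype=float), y_b.shape)
    out = np.empty(y_b.shape, dtype=float)
    zero = y_b == 0
    out[zero] = -lam_b[zero]
    pos = ~zero
    if np.any(pos):
        out[pos] = _series_logpdf_positive(y_b[pos], mu_b[pos], phi, p)
    return out if out.shape else float(out)


def tweedie_density(y, mu, phi, p):
    """Density/mass of a Tweedie law (see :func:`tweedie_logpdf`)."""
    return np.exp(tweedie_logpdf(y, mu, phi, p))


def tweedie_rvs(mu, phi, p, size=None, rng: np.random.Generator | None = None):
    """Draw from the compound Poisson-gamma representation.

    N ~ Poisson(lam); given N = n > 0, Y ~ Gamma(n * alpha, theta); Y = 0
    when N = 0.
    """
    rng = np.random.default_rng() if rng is None else rng
    lam, alpha, theta = tweedie_compound_params(mu, phi, p)
    if size is None:
        lam_b = np.broadcast_arrays(np.asarray(lam), np.asarray(theta))[0]
        size = lam_b.shape
    n = rng.poisson(np.broadcast_to(lam, size))
    out = np.zeros(size, dtype=float)
    pos = n > 0
    theta_b = np.broadcast_to(theta, size)
    out[pos] = rng.gamma(shape=n[pos] * alpha, scale=theta_b[pos])
    return out
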