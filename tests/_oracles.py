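"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: brute-force
pixel loops for morphology, and nested adaptive Gauss-Hermite quadrature
(mode-centred, curvature-scaled, high order) for the random-effect
integrals, built only on the density functions.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats
from scipy.special import expit

from caaquant.families import squeeze_unit_interval, tweedie_logpdf, zib_logpdf

_GH_NODES, _GH_WEIGHTS = hermgauss(64)


def brute_force_max_projection(stack_3d: np.ndarray) -> np.ndarray:
    """Element-wise maximum over z by explicit loops."""
    nz, ny, nx = stack_3d.shape
    out = np.empty((ny, nx))
    for i in range(ny):
        for j in range(nx):
            m = stack_3d[0, i, j]
            for k in range(1, nz):
                m = max(m, stack_3d[k, i, j])
            out[i, j] = m
    return out


def brute_force_white_top_hat(img: np.ndarray, radius: int) -> np.ndarray:
    """Erosion-then-dilation subtraction with an explicit disk window."""
    ny, nx = img.shape
    offsets = [(dy, dx) for dy in range(-radius, radius + 1)
               for dx in range(-radius, radius + 1)
               if dy * dy + dx * dx <= radius * radius]

    def window_extreme(src, i, j, fun):
        vals = []
        for dy, dx in offsets:
            y, x = i + dy, j + dx
            if 0 <= y < ny and 0 <= x < nx:
                vals.append(src[y, x])
        return fun(vals)

    eroded = np.empty_like(img, dtype=float)
    for i in range(ny):
        for j in range(nx):
            eroded[i, j] = window_extreme(img, i, j, min)
    opened = np.empty_like(img, dtype=float)
    for i in range(ny):
        for j in range(nx):
            opened[i, j] = window_extreme(eroded, i, j, max)
    return img - opened


def _per_obs_loglik(y, eta, family, params):
    if family == "zibeta":
        return zib_logpdf(y, expit(eta), params.phi, expit(params.gamma0))
    return tweedie_logpdf(y, np.exp(eta), params.phi, params.p)


def _adaptive_gh(log_f, sigma):
    """log of integral exp(log_f(t)) * N(t; 0, sigma^2) dt, mode-adapted."""
    def neg(t):
        return -(log_f(t) - 0.5 * t * t / sigma**2)
    res = optimize.minimize_scalar(neg, bounds=(-8 * sigma, 8 * sigma),
                                   method="bounded")
    mode = res.x
    h = 1e-4 * max(sigma, 1e-3)
    curv = (neg(mode + h) - 2 * neg(mode) + neg(mode - h)) / h**2
    scale = 1.0 / np.sqrt(max(curv, 1.0 / (64.0 * sigma**2)))
    t = mode + np.sqrt(2.0) * scale * _GH_NODES
    logvals = np.array([
        log_f(ti) + stats.norm.logpdf(ti, 0.0, sigma) for ti in t
    ])
    logw = np.log(_GH_WEIGHTS) + _GH_NODES**2 + 0.5 * np.log(2.0) + np.log(scale)
    m = np.max(logvals + logw)
    return m + np.log(np.sum(np.exp(logvals + logw - m)))


def aghq_marginal_loglik(data, params, family: str) -> float:
    """Nested adaptive Gauss-Hermite marginal log-likelihood oracle.

    Integrates the image intercept per image (inner) and the mouse
    intercept (outer), each with 64 mode-centred nodes.  Matches the model
    convention of squeezing nonzero coverage responses before evaluation.
    """
    y = data.y.copy()
    if family == "zibeta":
        pos = y > 0
        y[pos] = squeeze_unit_interval(y[pos], n=int(pos.sum()))
    total = 0.0
    for m in np.unique(data.mouse):
        imgs = np.unique(data.image[data.mouse == m])

        def log_outer(u):
            s = 0.0
            for img in imgs:
                sel = data.image == img
                eta0 = params.beta0 + params.beta1 * data.group[sel] + u

                def log_inner(v, eta0=eta0, sel=sel):
                    return float(np.sum(
                        _per_obs_loglik(y[sel], eta0 + v, family, params)))

                s += _adaptive_gh(log_inner, params.sigma_image)
            return s

        total += _adaptive_gh(log_outer, params.sigma_mouse)
    return total
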