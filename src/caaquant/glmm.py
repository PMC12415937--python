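"""Hierarchical mixed models for the two study outcomes.

Both models share the same structure: a group fixed effect on the linear
predictor of the conditional mean, plus Gaussian random intercepts for mouse
and for image nested in mouse, written ``(1 | mouse / image)``.  Vessel
coverage (a proportion with a large point mass at zero) uses a zero-inflated
Beta response with logit link; aggregate size (nonnegative, skewed,
overdispersed) uses a Tweedie response with log link and power 1 < p < 2.

The random intercepts are integrated out by a Laplace approximation around
the joint posterior mode, computed per mouse (the marginal likelihood
factorises over mice).  The inner mode is found by damped Newton iterations
batched across mice; the outer maximisation is quasi-Newton (L-BFGS-B) with
optional random restarts.  Standard errors come from the inverse of the
observed information (central finite differences of the marginal
log-likelihood); tests are Wald z with two-sided normal p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .families import squeeze_unit_interval

__all__ = [
    "ModelData", "ZIBetaParams", "TweedieParams", "GLMMFit", "GLMMOptions",
    "laplace_marginal_loglik", "fit_zib_glmm", "fit_tweedie_glmm",
    "wald_test", "estimated_marginal_means",
]

_INNER_TOL = 1e-8
_INNER_MAXIT = 100
_SIGMA_EXACT_EPS = 1e-8


# --------------------------------------------------------------------------
# parameter containers

@dataclass
class ZIBetaParams:
    """Zero-inflated Beta GLMM parameters.

    ``beta0/beta1``: logit-scale intercept and group effect of the
    conditional Beta mean; ``phi``: Beta precision; ``gamma0`` (and optional
    ``gamma1``): logit-scale zero-inflation coefficients; ``sigma_mouse`` /
    ``sigma_image``: random-intercept standard deviations.
    """

    beta0: float
    beta1: float
    phi: float
    gamma0: float
    gamma1: float | None = None
    sigma_mouse: float = 0.0
    sigma_image: float = 0.0

    def __post_init__(self) -> None:
        if not self.phi > 0:
            raise ValueError("phi must be positive")
        if self.sigma_mouse < 0 or self.sigma_image < 0:
            raise ValueError("random-intercept SDs must be nonnegative")


@dataclass
class TweedieParams:
    """Tweedie GLMM parameters (log link; variance = phi * mu**p)."""

    beta0: float
    beta1: float
    phi: float
    p: float
    sigma_mouse: float = 0.0
    sigma_image: float = 0.0

    def __post_init__(self) -> None:
        if not self.phi > 0:
            raise ValueError("phi must be positive")
        if not 1.0 < self.p < 2.0:
            raise ValueError("power p must lie in (1, 2)")
        if self.sigma_mouse < 0 or self.sigma_image < 0:
            raise ValueError("random-intercept SDs must be nonnegative")


@dataclass
class GLMMOptions:
    """Fitting options: restarts, seeds and structural switches."""

    n_restarts: int = 3
    seed: int = 0
    fix_sigmas: bool = False
    zero_inflation_group: bool = False
    maxiter: int = 300
    fd_step: float = 1e-4


# --------------------------------------------------------------------------
# data container

@dataclass
class ModelData:
    """Response vector with group indicator and mouse/image nesting codes.

    ``group`` is 0 (control) / 1 (treatment); ``mouse`` and ``image`` are
    integer codes, with every image belonging to exactly one mouse and every
    mouse to exactly one group.
    """

    y: np.ndarray
    group: np.ndarray
    mouse: np.ndarray
    image: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.group = np.asarray(self.group, dtype=int).ravel()
        self.mouse = np.asarray(self.mouse).ravel()
        self.image = np.asarray(self.image).ravel()
        n = self.y.size
        if not (self.group.size == self.mouse.size == self.image.size == n):
            raise ValueError("y, group, mouse and image must share one length")
        if n == 0:
            raise ValueError("empty dataset")
        if not set(np.unique(self.group)) <= {0, 1}:
            raise ValueError("group must be coded 0/1")
        # recode mouse and image to dense integer codes
        self.mouse = pd.factorize(self.mouse)[0]
        self.image = pd.factorize(self.image)[0]
        for parent, child, what in (
            (self.mouse, self.image, "image nested in mouse"),
            (self.group, self.mouse, "mouse nested in group"),
        ):
            frame = pd.DataFrame({"p": parent, "c": child})
            if (frame.groupby("c")["p"].nunique() > 1).any():
                raise ValueError(f"inconsistent nesting: {what}")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        response: str,
        group: str = "group",
        mouse: str = "mouse_id",
        image: str = "image_id",
        control_level: str | None = None,
    ) -> "ModelData":
        levels = sorted(frame[group].unique())
        if len(levels) != 2:
            raise ValueError(f"expected exactly 2 group levels, got {levels}")
        if control_level is None:
            control_level = "control" if "control" in levels else levels[0]
        g = (frame[group] != control_level).astype(int).to_numpy()
        return cls(
            y=frame[response].to_numpy(),
            group=g,
            mouse=frame[mouse].to_numpy(),
            image=frame[image].to_numpy(),
        )

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_mice(self) -> int:
        return int(self.mouse.max()) + 1


class _Design:
    """Precomputed index arrays for the batched per-mouse Newton solver.

    Images are assigned slots 0..Jmax-1 within their mouse; mice with fewer
    images are padded with empty slots, whose Gaussian factors integrate to
    one exactly, so padding does not change the marginal likelihood.
    """

    def __init__(self, data: ModelData):
        self.data = data
        self.n = data.n_obs
        self.M = data.n_mice
        img_mouse = pd.DataFrame({"img": data.image, "m": data.mouse})
        first = img_mouse.drop_duplicates("img").set_index("img")["m"]
        n_images = int(data.image.max()) + 1
        slot_of_image = np.zeros(n_images, dtype=int)
        counts = np.zeros(self.M, dtype=int)
        for img in range(n_images):
            m = int(first.loc[img])
            slot_of_image[img] = counts[m]
            counts[m] += 1
        self.Jmax = int(counts.max())
        self.D = 1 + self.Jmax
        self.midx = data.mouse
        self.slot = slot_of_image[data.image]
        self.flat = self.midx * self.Jmax + self.slot
        self.x = data.group.astype(float)
        # group of each mouse (for summaries)
        self.mouse_group = np.zeros(self.M, dtype=int)
        self.mouse_group[data.mouse] = data.group


# --------------------------------------------------------------------------
# family objects: per-observation log densities and eta-derivatives

class _ZIBFamily:
    name = "zibeta"

    def __init__(self, data: ModelData, zero_inflation_group: bool = False):
        y = data.y
        if np.any((y < 0) | (y > 1)):
            raise ValueError("coverage responses must lie in [0, 1]")
        self.zi_group = zero_inflation_group
        self.nonzero = y > 0
        if not np.any(self.nonzero):
            raise ValueError(
                "all responses are exactly zero: the Beta component is "
                "unidentified"
            )
        y_pos = y[self.nonzero]
        # squeeze the nonzero part so full coverage has finite likelihood
        self.y_pos = squeeze_unit_interval(y_pos, n=y_pos.size)
        self.log_y = np.log(self.y_pos)
        self.log_1my = np.log1p(-self.y_pos)
        self.x_pos = data.group[self.nonzero].astype(float)
        self.x_zero = data.group[~self.nonzero].astype(float)

    # theta layout: beta0, beta1, log_phi, gamma0, (gamma1)
    @property
    def n_mean_params(self) -> int:
        return 4 + (1 if self.zi_group else 0)

    def theta_names(self):
        names = ["beta0", "beta1", "log_phi", "gamma0"]
        if self.zi_group:
            names.append("gamma1")
        return names

    def prepare(self, theta):
        """Per-theta precomputation; returns the state consumed by derivs."""
        beta0, beta1, log_phi, gamma0 = theta[:4]
        gamma1 = theta[4] if self.zi_group else 0.0
        phi = np.exp(log_phi)
        eta_zi_zero = gamma0 + gamma1 * self.x_zero
        eta_zi_pos = gamma0 + gamma1 * self.x_pos
        # zero observations: log(pi); nonzero get log(1 - pi) added below
        const = float(np.sum(-np.logaddexp(0.0, -eta_zi_zero)))  # log expit
        log_1mpi_pos = -np.logaddexp(0.0, eta_zi_pos)
        return {
            "phi": phi,
            "offset": beta0 + beta1 * self.x_pos,
            "const": const,
            "per_obs_const": log_1mpi_pos + special.gammaln(phi),
        }

    def loglik_derivs(self, eta, state, order=2):
        """(l, dl/deta, d2l/deta2) for the Newton observations (nonzero y)."""
        phi = state["phi"]
        mu = special.expit(np.clip(eta, -30.0, 30.0))
        a = mu * phi
        b = (1.0 - mu) * phi
        l = (
            state["per_obs_const"]
            - special.gammaln(a) - special.gammaln(b)
            + (a - 1.0) * self.log_y + (b - 1.0) * self.log_1my
        )
        if order == 0:
            return l, None, None
        dmu = mu * (1.0 - mu)
        dl_dmu = phi * (self.log_y - self.log_1my - special.digamma(a)
                        + special.digamma(b))
        dl = dl_dmu * dmu
        d2l_dmu2 = -(phi**2) * (special.polygamma(1, a) + special.polygamma(1, b))
        d2l = d2l_dmu2 * dmu**2 + dl_dmu * dmu * (1.0 - 2.0 * mu)
        return l, dl, d2l

    def params_from_theta(self, theta, sigma_mouse, sigma_image) -> ZIBetaParams:
        return ZIBetaParams(
            beta0=float(theta[0]), beta1=float(theta[1]),
            phi=float(np.exp(theta[2])), gamma0=float(theta[3]),
            gamma1=float(theta[4]) if self.zi_group else None,
            sigma_mouse=sigma_mouse, sigma_image=sigma_image,
        )

    def theta_from_params(self, params: ZIBetaParams):
        theta = [params.beta0, params.beta1, np.log(params.phi), params.gamma0]
        if self.zi_group:
            theta.append(params.gamma1 if params.gamma1 is not None else 0.0)
        elif params.gamma1 not in (None, 0.0):
            raise ValueError("gamma1 given but zero_inflation_group is False")
        return np.asarray(theta, dtype=float)

    def initial_theta(self, data: ModelData):
        y = data.y
        frac0 = float(np.clip(np.mean(y == 0), 0.02, 0.98))
        gamma0 = special.logit(frac0)
        means = []
        for g in (0, 1):
            sel = (data.group == g) & self.nonzero
            if sel.any():
                means.append(float(np.clip(np.mean(y[sel]), 0.02, 0.98)))
            else:
                means.append(0.5)
        beta0 = special.logit(means[0])
        beta1 = float(np.clip(special.logit(means[1]) - beta0, -5, 5))
        y_pos = y[self.nonzero]
        v = float(np.var(y_pos)) if y_pos.size > 1 else 0.02
        m = float(np.mean(y_pos))
        phi = np.clip(m * (1 - m) / max(v, 1e-4) - 1.0, 0.5, 100.0)
        theta = [beta0, beta1, np.log(phi), gamma0]
        if self.zi_group:
            theta.append(0.0)
        return np.asarray(theta, dtype=float)

    def bounds(self):
        b = [(-30, 30), (-30, 30), (np.log(1e-3), np.log(1e4)), (-30, 30)]
        if self.zi_group:
            b.append((-30.0, 30.0))
        return b


class _TweedieFamily:
    name = "tweedie"

    def __init__(self, data: ModelData, **_ignored):
        y = data.y
        if np.any(y < 0):
            raise ValueError("size responses must be nonnegative")
        if not np.any(y > 0):
            raise ValueError("all responses are zero: Tweedie mean unidentified")
        self.y = y
        self.pos = y > 0
        self.y_pos = y[self.pos]
        self.x_all = data.group.astype(float)

    # theta layout: beta0, beta1, log_phi, eta_p (logit of p - 1)
    @property
    def n_mean_params(self) -> int:
        return 4

    def theta_names(self):
        return ["beta0", "beta1", "log_phi", "eta_p"]

    def _log_a(self, phi, p):
        """mu-free series part of the Tweedie log density for positive y.

        In exponential-dispersion form the density is
        ``a(y, phi, p) * exp((y*thetat - kappa) / phi)`` where the series
        factor ``a`` does not involve the mean, so it is computed once per
        outer parameter value rather than per Newton step.
        """
        alpha = (2.0 - p) / (p - 1.0)
        log_c = -np.log(phi * (2.0 - p)) - alpha * np.log(phi * (p - 1.0))
        y = self.y_pos
        j_peak = y ** (2.0 - p) / (phi * (2.0 - p))
        j_hi = int(np.ceil(np.max(j_peak + 12.0 * np.sqrt(j_peak + 1.0) + 25.0)))
        j_hi = min(j_hi, 5000)  # truncation guard far outside the fit region
        j = np.arange(1, j_hi + 1, dtype=float)
        log_terms = (
            j * log_c
            + (j * alpha - 1.0)[np.newaxis, :] * np.log(y)[:, np.newaxis]
            - special.gammaln(j + 1.0)
            - special.gammaln(j * alpha)
        )
        return special.logsumexp(log_terms, axis=1)

    def prepare(self, theta):
        beta0, beta1, log_phi, eta_p = theta[:4]
        phi = float(np.exp(log_phi))
        p = 1.0 + float(special.expit(eta_p))
        log_a = np.zeros(self.y.size)
        log_a[self.pos] = self._log_a(phi, p)
        return {
            "phi": phi, "p": p,
            "offset": beta0 + beta1 * self.x_all,
            "const": 0.0,
            "log_a": log_a,
        }

    def loglik_derivs(self, eta, state, order=2):
        phi, p = state["phi"], state["p"]
        eta = np.clip(eta, -60.0, 60.0)
        mu_1mp = np.exp((1.0 - p) * eta)   # mu**(1-p)
        mu_2mp = np.exp((2.0 - p) * eta)   # mu**(2-p)
        y = self.y
        l = (y * mu_1mp / (1.0 - p) - mu_2mp / (2.0 - p)) / phi + state["log_a"]
        if order == 0:
            return l, None, None
        mu = np.exp(eta)
        dl = (y - mu) * mu_1mp / phi
        d2l = ((1.0 - p) * y * mu_1mp - (2.0 - p) * mu_2mp) / phi
        return l, dl, d2l

    def params_from_theta(self, theta, sigma_mouse, sigma_image) -> TweedieParams:
        return TweedieParams(
            beta0=float(theta[0]), beta1=float(theta[1]),
            phi=float(np.exp(theta[2])),
            p=1.0 + float(special.expit(theta[3])),
            sigma_mouse=sigma_mouse, sigma_image=sigma_image,
        )

    def theta_from_params(self, params: TweedieParams):
        return np.asarray([
            params.beta0, params.beta1, np.log(params.phi),
            special.logit(params.p - 1.0),
        ], dtype=float)

    def initial_theta(self, data: ModelData):
        y = data.y
        means = []
        for g in (0, 1):
            sel = data.group == g
            means.append(float(max(np.mean(y[sel]) if sel.any() else 1.0, 1e-3)))
        beta0 = np.log(means[0])
        beta1 = float(np.clip(np.log(means[1] / means[0]), -4, 4))
        p0 = 1.5
        phi = np.clip(np.var(y) / max(np.mean(y) ** p0, 1e-6), 0.05, 1e3)
        return np.asarray([beta0, beta1, np.log(phi), special.logit(p0 - 1.0)])

    def bounds(self):
        # the power is kept inside (1.05, 1.95): toward p = 1 the compound
        # law degenerates to a lattice and the series likelihood turns rugged
        eta_p_lim = float(special.logit(0.05))
        return [(-30, 30), (-30, 30), (np.log(1e-2), np.log(1e4)),
                (eta_p_lim, -eta_p_lim)]


_FAMILIES = {"zibeta": _ZIBFamily, "tweedie": _TweedieFamily}


# --------------------------------------------------------------------------
# Laplace marginal log-likelihood

def _newton_modes(design: _Design, fam, state, midx, slot, n_sub,
                  sigma_m, sigma_i, b0=None):
    """Penalised-likelihood modes of (u, v) per mouse, batched damped Newton.

    Returns (b, Q, negH) where b is (M, D), Q the penalised log-likelihood
    per mouse at the mode, and negH the (M, D, D) negative Hessians there.
    """
    M, Jmax, D = design.M, design.Jmax, design.D
    inv_sm2 = 1.0 / sigma_m**2
    inv_si2 = 1.0 / sigma_i**2
    flat = midx * Jmax + slot
    b = np.zeros((M, D)) if b0 is None else b0.copy()

    def q_of(b_arr):
        eta = state["offset"] + b_arr[midx, 0] + b_arr[midx, 1 + slot]
        l, _, _ = fam.loglik_derivs(eta, state, order=0)
        ql = np.bincount(midx, weights=l, minlength=M)
        pen = 0.5 * inv_sm2 * b_arr[:, 0] ** 2 + 0.5 * inv_si2 * np.sum(
            b_arr[:, 1:] ** 2, axis=1)
        return ql - pen

    q = q_of(b)
    for _ in range(_INNER_MAXIT):
        eta = state["offset"] + b[midx, 0] + b[midx, 1 + slot]
        l, dl, d2l = fam.loglik_derivs(eta, state)
        g_u = np.bincount(midx, weights=dl, minlength=M) - inv_sm2 * b[:, 0]
        g_v = (np.bincount(flat, weights=dl, minlength=M * Jmax)
               .reshape(M, Jmax) - inv_si2 * b[:, 1:])
        c_u = np.bincount(midx, weights=d2l, minlength=M)
        c_v = np.bincount(flat, weights=d2l, minlength=M * Jmax).reshape(M, Jmax)
        grad = np.concatenate([g_u[:, None], g_v], axis=1)
        gmax = np.max(np.abs(grad))
        if gmax < _INNER_TOL:
            break
        negH = np.zeros((M, D, D))
        negH[:, 0, 0] = inv_sm2 - c_u
        idx = np.arange(1, D)
        negH[:, idx, idx] = inv_si2 - c_v
        negH[:, 0, 1:] = -c_v
        negH[:, 1:, 0] = -c_v
        # ridge for any non-PD block (rare; likelihood curvature positive)
        for _try in range(6):
            try:
                step = np.linalg.solve(negH, grad[..., np.newaxis])[..., 0]
                break
            except np.linalg.LinAlgError:
                negH[:, np.arange(D), np.arange(D)] += 10.0 ** _try * 1e-6
        else:
            raise FloatingPointError("inner Hessian solve failed")
        decrement = np.sum(grad * step, axis=1)
        if np.max(np.abs(step)) < 1e-10 or np.max(decrement) < 1e-12:
            break  # mode located to solver precision; gradient noise-bound
        # per-mouse backtracking to keep Q monotone (up to float noise)
        alpha = np.ones(M)
        for _ls in range(25):
            b_new = b + alpha[:, None] * step
            q_new = q_of(b_new)
            bad = (q_new < q - 1e-8 * (1.0 + np.abs(q))) | ~np.isfinite(q_new)
            if not bad.any():
                break
            alpha[bad] *= 0.5
        b, q = b_new, q_new
    # final curvature at the mode
    eta = state["offset"] + b[midx, 0] + b[midx, 1 + slot]
    _, _, d2l = fam.loglik_derivs(eta, state)
    c_u = np.bincount(midx, weights=d2l, minlength=M)
    c_v = np.bincount(flat, weights=d2l, minlength=M * Jmax).reshape(M, Jmax)
    negH = np.zeros((M, D, D))
    negH[:, 0, 0] = inv_sm2 - c_u
    idx = np.arange(1, D)
    negH[:, idx, idx] = inv_si2 - c_v
    negH[:, 0, 1:] = -c_v
    negH[:, 1:, 0] = -c_v
    return b, q, negH


def _marginal_loglik(design: _Design, fam, theta_mean, sigma_m, sigma_i):
    """Laplace marginal log-likelihood at one parameter point."""
    state = fam.prepare(theta_mean)
    # observation subset entering the Newton solve
    if fam.name == "zibeta":
        sub = fam.nonzero
    else:
        sub = np.ones(design.n, dtype=bool)
    midx = design.midx[sub]
    slot = design.slot[sub]

    if sigma_m < _SIGMA_EXACT_EPS and sigma_i < _SIGMA_EXACT_EPS:
        eta = state["offset"]
        l, _, _ = fam.loglik_derivs(eta, state, order=0)
        return float(np.sum(l) + state["const"])

    sm = max(sigma_m, _SIGMA_EXACT_EPS)
    si = max(sigma_i, _SIGMA_EXACT_EPS)
    warm = getattr(design, "_warm_b", None)
    if warm is not None and warm.shape != (design.M, design.D):
        warm = None
    b, q, negH = _newton_modes(design, fam, state, midx, slot, design.n, sm, si,
                               b0=warm)
    design._warm_b = b
    sign, logdet = np.linalg.slogdet(negH)
    if np.any(sign <= 0) or not np.all(np.isfinite(logdet)):
        raise FloatingPointError(
            "non-positive-definite curvature at the random-effect mode"
        )
    M, D, Jmax = design.M, design.D, design.Jmax
    prior_norm = -0.5 * np.log(2 * np.pi * sm**2) - 0.5 * Jmax * np.log(
        2 * np.pi * si**2)
    per_mouse = q + prior_norm + 0.5 * D * np.log(2 * np.pi) - 0.5 * logdet
    return float(np.sum(per_mouse) + state["const"])


def laplace_marginal_loglik(data: ModelData, params, family: str) -> float:
    """Marginal log-likelihood with random intercepts integrated out.

    Exact (no integral) when both random-intercept SDs are zero; otherwise a
    Laplace approximation around the per-mouse joint mode.
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    zi_group = isinstance(params, ZIBetaParams) and params.gamma1 is not None
    fam = _FAMILIES[family](data, zero_inflation_group=zi_group)
    design = _Design(data)
    theta = fam.theta_from_params(params)
    out = _marginal_loglik(design, fam, theta, params.sigma_mouse,
                           params.sigma_image)
    if not np.isfinite(out):
        raise FloatingPointError("non-finite marginal log-likelihood")
    return out


# --------------------------------------------------------------------------
# fitting

@dataclass
class GLMMFit:
    """Result of a GLMM fit: estimates, inference and diagnostics."""

    family: str
    params: object
    fixed_effects: pd.DataFrame
    varcomp: dict
    loglik: float
    converged: bool
    n_obs: int
    theta: np.ndarray = field(repr=False)
    theta_names: list = field(repr=False)
    cov: np.ndarray = field(repr=False)
    options: GLMMOptions = field(repr=False, default_factory=GLMMOptions)

    def summary(self) -> str:
        lines = [
            f"{self.family} GLMM  (n = {self.n_obs}, "
            f"loglik = {self.loglik:.3f}, converged = {self.converged})",
            self.fixed_effects.to_string(index=False),
            "variance components: "
            + ", ".join(f"{k} = {v:.4g}" for k, v in self.varcomp.items()),
        ]
        return "\n".join(lines)


def wald_test(estimate: float, se: float) -> tuple[float, float]:
    """Wald z statistic and two-sided normal p-value."""
    if not se > 0:
        raise ValueError("standard error must be positive")
    z = estimate / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def _fd_hessian(fun, x, step):
    """Central finite-difference Hessian of a scalar function."""
    k = x.size
    h = step * np.maximum(1.0, np.abs(x))
    hess = np.zeros((k, k))
    f0 = fun(x)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        fpp = fun(x + ei); fmm = fun(x - ei)
        hess[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k); ej[j] = h[j]
            fp_p = fun(x + ei + ej); fp_m = fun(x + ei - ej)
            fm_p = fun(x - ei + ej); fm_m = fun(x - ei - ej)
            hess[i, j] = hess[j, i] = (
                fp_p - fp_m - fm_p + fm_m) / (4.0 * h[i] * h[j])
    return hess


def _fit_glmm(data: ModelData, family: str, options: GLMMOptions) -> GLMMFit:
    fam = _FAMILIES[family](data, zero_inflation_group=options.zero_inflation_group)
    design = _Design(data)
    k_mean = fam.n_mean_params
    names = fam.theta_names()
    bounds = fam.bounds()
    if not options.fix_sigmas:
        names = names + ["log_sigma_mouse", "log_sigma_image"]
        bounds = bounds + [(np.log(1e-4), np.log(10.0))] * 2

    def unpack(theta):
        if options.fix_sigmas:
            return theta, 0.0, 0.0
        return (theta[:k_mean], float(np.exp(theta[k_mean])),
                float(np.exp(theta[k_mean + 1])))

    def negloglik(theta):
        mean_theta, sm, si = unpack(theta)
        try:
            return -_marginal_loglik(design, fam, mean_theta, sm, si)
        except (FloatingPointError, np.linalg.LinAlgError):
            return 1e12

    theta0 = fam.initial_theta(data)
    if family == "tweedie":
        # coarse profile over the power before joint refinement
        best_p, best_val = None, np.inf
        for p_grid in (1.2, 1.4, 1.6, 1.8):
            cand = theta0.copy()
            cand[3] = special.logit(p_grid - 1.0)
            full = cand if options.fix_sigmas else np.concatenate(
                [cand, [np.log(0.2), np.log(0.2)]])
            val = negloglik(full)
            if val < best_val:
                best_p, best_val = p_grid, val
        theta0[3] = special.logit(best_p - 1.0)
    if not options.fix_sigmas:
        theta0 = np.concatenate([theta0, [np.log(0.2), np.log(0.2)]])

    rng = np.random.default_rng(options.seed)
    best = None
    for r in range(max(1, options.n_restarts)):
        design._warm_b = None  # modes from the previous restart do not carry
        x0 = theta0 if r == 0 else theta0 + rng.normal(0.0, 0.3, theta0.size)
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(
            negloglik, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": options.maxiter, "ftol": 1e-11, "gtol": 1e-6,
                     "eps": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta_hat = best.x
    loglik = -float(best.fun)

    def negloglik_cold(theta):
        # path-independent evaluation: the warm-started inner solve is
        # reproducible only from a fixed start, which finite differences need
        design._warm_b = None
        return negloglik(theta)

    hess = _fd_hessian(negloglik_cold, theta_hat, options.fd_step)
    se_ok = True

    def _invert(h):
        c = np.linalg.inv(h)
        if np.any(np.diag(c)[: k_mean] <= 0):
            raise np.linalg.LinAlgError("nonpositive variance")
        return c

    try:
        cov = _invert(hess)
    except np.linalg.LinAlgError:
        # collapsed variance components (sigma -> 0) leave flat log-SD
        # directions, and bound-pinned nuisance parameters are not free
        # coordinates; profile both out of the observed information
        keep = np.ones(theta_hat.size, dtype=bool)
        if not options.fix_sigmas:
            for i in (k_mean, k_mean + 1):
                if np.exp(theta_hat[i]) < 1e-2 or abs(hess[i, i]) < 1e-3:
                    keep[i] = False
        fe_idx = {"zibeta": {0, 1, 3}, "tweedie": {0, 1}}[family]
        for i, (lo_i, hi_i) in enumerate(bounds):
            at_bound = (theta_hat[i] <= lo_i + 1e-8
                        or theta_hat[i] >= hi_i - 1e-8)
            if at_bound and i not in fe_idx:
                keep[i] = False
        try:
            if keep.all():
                raise np.linalg.LinAlgError("no flat direction identified")
            sub = np.linalg.inv(hess[np.ix_(keep, keep)])
            if np.any(np.diag(sub)[: k_mean] <= 0):
                raise np.linalg.LinAlgError("nonpositive variance")
            cov = np.zeros_like(hess)
            cov[np.ix_(keep, keep)] = sub
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(hess)
            se_ok = False
            warnings.warn(
                "observed information not positive definite; standard errors "
                "use a pseudo-inverse", RuntimeWarning, stacklevel=2)
    if best.jac is not None:
        proj = np.array(best.jac, dtype=float)
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        # at an active bound only the inward gradient component matters,
        # and collapsed variance components (sigma -> 0) are flat directions
        proj[(theta_hat <= lo + 1e-8) & (proj > 0)] = 0.0
        proj[(theta_hat >= hi - 1e-8) & (proj < 0)] = 0.0
        if not options.fix_sigmas:
            for i in (k_mean, k_mean + 1):
                if np.exp(theta_hat[i]) < 1e-2:
                    proj[i] = 0.0
        gradnorm = float(np.max(np.abs(proj)))
    else:
        gradnorm = np.nan
    grad_tol = max(5e-2, 1e-4 * abs(loglik))  # gradient scale grows with n
    converged = bool(best.success) and se_ok and gradnorm < grad_tol
    if not converged:
        warnings.warn(
            f"GLMM fit did not cleanly converge (status={best.message!r}, "
            f"max|grad|={gradnorm:.2e})", RuntimeWarning, stacklevel=2)

    mean_theta, sm, si = unpack(theta_hat)
    params = fam.params_from_theta(mean_theta, sm, si)
    fe_terms = {
        "zibeta": ["mu_(Intercept)", "mu_group", "zi_(Intercept)"]
        + (["zi_group"] if options.zero_inflation_group else []),
        "tweedie": ["(Intercept)", "group"],
    }[family]
    fe_index = {
        "zibeta": [0, 1, 3] + ([4] if options.zero_inflation_group else []),
        "tweedie": [0, 1],
    }[family]
    rows = []
    for term, i in zip(fe_terms, fe_index):
        est = float(theta_hat[i])
        se = float(np.sqrt(max(cov[i, i], 0.0))) if cov[i, i] > 0 else np.nan
        if np.isfinite(se) and se > 0:
            z, p = wald_test(est, se)
        else:
            z, p = np.nan, np.nan
        rows.append({"term": term, "estimate": est, "se": se, "z": z, "p": p})
    fixed = pd.DataFrame(rows, columns=["term", "estimate", "se", "z", "p"])
    varcomp = {"sigma_mouse": sm, "sigma_image": si, "phi": params.phi}
    if family == "tweedie":
        varcomp["p"] = params.p
    return GLMMFit(
        family=family, params=params, fixed_effects=fixed, varcomp=varcomp,
        loglik=loglik, converged=converged, n_obs=data.n_obs,
        theta=theta_hat, theta_names=names, cov=cov, options=options,
    )


def fit_zib_glmm(data: ModelData, options: GLMMOptions | None = None) -> GLMMFit:
    """Fit the zero-inflated Beta GLMM for vessel coverage.

    Responses are proportions in [0, 1]; the group effect acts on the logit
    of the conditional Beta mean, the zero-inflation part is intercept-only
    unless ``options.zero_inflation_group`` is set.
    """
    return _fit_glmm(data, "zibeta", options or GLMMOptions())


def fit_tweedie_glmm(data: ModelData, options: GLMMOptions | None = None) -> GLMMFit:
    """Fit the Tweedie GLMM for aggregate size (log link, 1 < p < 2)."""
    return _fit_glmm(data, "tweedie", options or GLMMOptions())


# --------------------------------------------------------------------------
# estimated marginal means

def estimated_marginal_means(
    fit: GLMMFit,
    groups: tuple[str, str] = ("control", "clu"),
    kind: str = "overall",
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-group model means with delta-method confidence intervals.

    Random effects are set to zero.  For the Tweedie model the mean is
    ``exp(beta0 + beta1*g)`` with a CI formed on the log scale.  For the
    zero-inflated Beta model the default ``overall`` mean is
    ``(1 - pi) * mu`` with a CI on its log; ``conditional`` reports the Beta
    mean ``mu`` with a logit-scale CI.
    """
    if not fit.converged:
        raise ValueError("estimated marginal means require a converged fit")
    zcrit = float(stats.norm.ppf(0.5 + level / 2.0))
    theta, cov = fit.theta, fit.cov
    rows = []
    for g, label in enumerate(groups):
        grad = np.zeros(theta.size)
        if fit.family == "tweedie":
            eta = theta[0] + theta[1] * g
            grad[0], grad[1] = 1.0, float(g)
            se = float(np.sqrt(grad @ cov @ grad))
            mean = float(np.exp(eta))
            lo, hi = np.exp(eta - zcrit * se), np.exp(eta + zcrit * se)
        else:
            eta = theta[0] + theta[1] * g
            mu = float(special.expit(eta))
            zi_has_group = fit.options.zero_inflation_group
            eta_zi = theta[3] + (theta[4] * g if zi_has_group else 0.0)
            pi = float(special.expit(eta_zi))
            if kind == "conditional":
                grad[0], grad[1] = 1.0, float(g)
                se = float(np.sqrt(grad @ cov @ grad))
                mean = mu
                lo = float(special.expit(eta - zcrit * se))
                hi = float(special.expit(eta + zcrit * se))
            else:
                # log mean = log mu + log(1 - pi)
                grad[0] = 1.0 - mu
                grad[1] = (1.0 - mu) * g
                grad[3] = -pi
                if zi_has_group:
                    grad[4] = -pi * g
                se = float(np.sqrt(grad @ cov @ grad))
                log_mean = np.log(mu) + np.log1p(-pi)
                mean = float(np.exp(log_mean))
                lo = float(np.exp(log_mean - zcrit * se))
                hi = float(np.exp(log_mean + zcrit * se))
        rows.append({"group": label, "mean": mean,
                     "ci_low": float(lo), "ci_high": float(hi)})
    return pd.DataFrame(rows, columns=["group", "mean", "ci_low", "ci_high"])
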