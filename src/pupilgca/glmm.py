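"""Logistic generalized linear mixed models via the Laplace approximation.

Maximum-likelihood estimation for a Bernoulli GLMM with logit link and
independent (diagonal) Gaussian random-effect components:

    y_i ~ Bernoulli(sigmoid(x_i' beta + sum_c z_ci' u_c)),
    u_c ~ N(0, sigma_c^2 I).

Estimation follows the standard two-level scheme: for fixed variance
parameters, the joint penalized log-likelihood is maximized over
(beta, u) by Newton iterations (penalized IRLS); the marginal likelihood
is approximated by Laplace's method at that mode; the variance
parameters are then optimized on the log-SD scale by Nelder-Mead.
Profiling the fixed effects inside the penalized inner step makes this
the scheme lme4's ``glmer`` uses with ``nAGQ = 0`` (it reproduces that
fit to numerical precision), restricted to diagonal random-effect
covariance; it differs slightly from the default ``nAGQ = 1`` fit, with
the difference vanishing as the number of observations grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .lmm import LmmFit, bic_from_fit

__all__ = ["GlmmComponent", "fit_logistic_glmm", "SeparationError"]

_LOG_SD_BOUNDS = (-8.0, 4.0)


class SeparationError(RuntimeError):
    """Raised when the response is degenerate (complete separation)."""


@dataclass
class GlmmComponent:
    """One diagonal random-effect component.

    ``groups`` assigns each observation to a level; ``weights`` (default
    1) multiplies the indicator, so a random slope for a coded covariate
    is expressed as weights = that covariate.
    """

    name: str
    groups: np.ndarray
    weights: np.ndarray | None = None

    def design(self) -> np.ndarray:
        codes, _ = pd.factorize(self.groups)
        q = codes.max() + 1
        z = np.zeros((len(codes), q))
        w = np.ones(len(codes)) if self.weights is None else np.asarray(self.weights, float)
        z[np.arange(len(codes)), codes] = w
        return z


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _bernoulli_ll(y, eta):
    # numerically stable: -log(1 + exp(-(2y-1) * eta))
    s = (2.0 * y - 1.0) * eta
    return -np.logaddexp(0.0, -s).sum()


def _inner_mode(y, w_full, pen_diag, theta0, max_iter=100, tol=1e-9):
    """Penalized Newton (IRLS) for the joint mode over (beta, u)."""
    theta = theta0.copy()
    eta = w_full @ theta
    obj = _bernoulli_ll(y, eta) - 0.5 * np.sum(pen_diag * theta**2)
    for _ in range(max_iter):
        mu = _sigmoid(eta)
        wt = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = w_full.T @ (y - mu) - pen_diag * theta
        h = (w_full * wt[:, None]).T @ w_full
        h[np.diag_indices_from(h)] += pen_diag
        try:
            delta = np.linalg.solve(h, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(h, grad, rcond=None)[0]
        step = 1.0
        for _ in range(30):
            cand = theta + step * delta
            eta_c = w_full @ cand
            obj_c = _bernoulli_ll(y, eta_c) - 0.5 * np.sum(pen_diag * cand**2)
            if obj_c >= obj - 1e-12:
                break
            step *= 0.5
        theta, eta, new_obj = cand, eta_c, obj_c
        if abs(new_obj - obj) < tol * (1.0 + abs(obj)):
            obj = new_obj
            break
        obj = new_obj
    return theta, eta, h, obj


def fit_logistic_glmm(
    y,
    x: np.ndarray,
    components: list[GlmmComponent],
    fixed_names: list[str] | None = None,
    start_log_sd: float = np.log(0.5),
) -> LmmFit:
    """Fit the Laplace-approximated logistic GLMM.

    Returns an :class:`~pupilgca.lmm.LmmFit` whose ``params`` table holds
    the fixed effects with Wald z statistics, ``varcomps`` the estimated
    random-effect SDs, and ``loglik``/``bic`` the Laplace marginal
    log-likelihood and its BIC (parameter count = fixed effects +
    variance parameters).

    Raises
    ------
    SeparationError
        If the response takes a single value (complete separation).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.min() == y.max():
        raise SeparationError("response is constant; the logistic model is unidentified")
    if fixed_names is None:
        fixed_names = [f"x{j}" for j in range(x.shape[1])]
    z_blocks = [c.design() for c in components]
    sizes = [z.shape[1] for z in z_blocks]
    w_full = np.hstack([x] + z_blocks)
    p = x.shape[1]
    q = sum(sizes)
    n = len(y)

    comp_slices = []
    off = p
    for s in sizes:
        comp_slices.append(slice(off, off + s))
        off += s

    theta0 = np.zeros(p + q)
    state = {"theta": theta0}

    def neg_lap(log_sd):
        log_sd = np.clip(log_sd, *_LOG_SD_BOUNDS)
        pen = np.zeros(p + q)
        for sl, ls in zip(comp_slices, log_sd):
            pen[sl] = np.exp(-2.0 * ls)
        theta, eta, h, _ = _inner_mode(y, w_full, pen, state["theta"])
        state["theta"] = theta
        u = theta[p:]
        pen_u = pen[p:]
        ll = _bernoulli_ll(y, eta) - 0.5 * np.sum(pen_u * u**2)
        h_uu = h[p:, p:]
        sign, logdet_huu = np.linalg.slogdet(h_uu)
        if sign <= 0:
            return 1e10
        logdet_d = 2.0 * np.sum(np.asarray(log_sd) * np.asarray(sizes))
        return -(ll - 0.5 * logdet_d - 0.5 * logdet_huu)

    x0 = np.full(len(components), start_log_sd)
    res = None
    stalled = False
    for _ in range(3):  # restart to escape degenerate simplices near boundaries
        cand = optimize.minimize(
            neg_lap,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-7, "maxiter": 400},
        )
        stalled = res is not None and cand.fun >= res.fun - 1e-7
        if res is None or cand.fun < res.fun:
            res = cand
        x0 = res.x
        if stalled:
            break
    converged = bool(res.success or stalled)
    log_sd = np.clip(res.x, *_LOG_SD_BOUNDS)
    pen = np.zeros(p + q)
    for sl, ls in zip(comp_slices, log_sd):
        pen[sl] = np.exp(-2.0 * ls)
    theta, eta, h, _ = _inner_mode(y, w_full, pen, state["theta"])
    loglik = -neg_lap(log_sd)

    h_inv = np.linalg.inv(h)
    beta = theta[:p]
    se = np.sqrt(np.diag(h_inv)[:p])
    stat = beta / se
    p_two = 2.0 * stats.norm.sf(np.abs(stat))
    params = pd.DataFrame(
        {"estimate": beta, "se": se, "stat": stat, "p_two": p_two, "p": p_two},
        index=fixed_names,
    )
    notes = []
    if np.abs(eta).max() > 25:
        notes.append("very large linear predictor; possible quasi-separation")
    n_params = p + len(components)
    return LmmFit(
        params=params,
        varcomps={
            "random_sd": {c.name: float(np.exp(ls)) for c, ls in zip(components, log_sd)},
        },
        loglik=float(loglik),
        bic=bic_from_fit(float(loglik), n_params, n),
        n_obs=n,
        n_params=n_params,
        converged=converged,
        method="laplace-ml",
        structure="diagonal",
        notes=notes,
    )
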