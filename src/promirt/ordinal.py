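"""Cumulative-logit (proportional-odds) maximum likelihood.

A small, fast fitter purpose-built for the DIF engine, which runs many
thousands of low-dimensional ordinal regressions inside Monte-Carlo
loops.  Cutpoints are optimised on an order-preserving
reparameterisation (first cutpoint plus log-increments) with an exact
analytic gradient, so the likelihood surface is smooth and separation
manifests as drifting coefficients rather than crashes; fits with
runaway coefficients are returned with a ``separation_flag`` instead of
raising.

Model: P(Y <= k | x) = logistic(c_k - x'beta), c_1 < ... < c_{K-1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

__all__ = ["OrdinalFit", "fit_proportional_odds", "intercept_only_loglik"]

_COEF_LIMIT = 30.0  # |beta| beyond this is treated as (quasi-)separation


@dataclass
class OrdinalFit:
    """A fitted proportional-odds model."""

    loglik: float
    cutpoints: np.ndarray
    beta: np.ndarray
    converged: bool
    separation_flag: bool
    n_obs: int
    n_categories: int

    @property
    def coefficients(self) -> np.ndarray:
        return np.concatenate([self.cutpoints, self.beta])


def intercept_only_loglik(y: np.ndarray, n_categories: int | None = None) -> float:
    """Closed-form maximum log-likelihood of the intercept-only model.

    The MLE fits the observed category proportions exactly:
    ll0 = sum_k n_k log(n_k / n).
    """
    y = np.asarray(y, dtype=np.int64)
    k = n_categories or int(y.max())
    counts = np.bincount(y, minlength=k + 1)[1:]
    nz = counts[counts > 0]
    return float(np.sum(nz * np.log(nz / len(y))))


def _pack(cutpoints: np.ndarray, beta: np.ndarray) -> np.ndarray:
    d = np.diff(cutpoints)
    return np.concatenate([[cutpoints[0]], np.log(np.maximum(d, 1e-8)), beta])


def _unpack(x: np.ndarray, n_cut: int) -> tuple[np.ndarray, np.ndarray]:
    cut = x[0] + np.concatenate([[0.0], np.cumsum(np.exp(x[1:n_cut]))])
    return cut, x[n_cut:]


def _negloglik_grad(x, y0, X, n_cut):
    """Negative log-likelihood and gradient on the reparameterised scale."""
    cut, beta = _unpack(x, n_cut)
    eta = X @ beta if X.shape[1] else np.zeros(X.shape[0])
    u = cut[None, :] - eta[:, None]  # (n, K-1)
    s = expit(u)
    # P(y=k) = s_k - s_{k-1}; category k indexed 0..K-1 with s_{-1}=0, s_{K-1}=1
    s_hi = np.where(y0 < n_cut, np.take_along_axis(s, np.minimum(y0, n_cut - 1)[:, None], 1)[:, 0], 1.0)
    s_lo = np.where(y0 > 0, np.take_along_axis(s, np.maximum(y0 - 1, 0)[:, None], 1)[:, 0], 0.0)
    p = np.clip(s_hi - s_lo, 1e-300, None)
    f = -np.sum(np.log(p))

    # gradient wrt cutpoints and beta
    d_hi = np.where(y0 < n_cut, s_hi * (1 - s_hi), 0.0) / p   # dP/dc_{y}
    d_lo = np.where(y0 > 0, s_lo * (1 - s_lo), 0.0) / p       # -dP/dc_{y-1}
    g_cut = (
        -np.bincount(np.minimum(y0, n_cut - 1), weights=d_hi, minlength=n_cut)
        + np.bincount(np.maximum(y0 - 1, 0), weights=d_lo, minlength=n_cut)
    )
    resid = d_hi - d_lo  # d loglik / d eta with sign: dll/deta = -(d_hi - d_lo)
    g_beta = X.T @ resid if X.shape[1] else np.zeros(0)

    g = np.empty_like(x)
    g[0] = g_cut.sum()
    if n_cut > 1:
        d = np.exp(x[1:n_cut])
        g[1:n_cut] = d * np.cumsum(g_cut[::-1])[::-1][1:]
    g[n_cut:] = g_beta
    return f, g


def _loglik_grad_hess(cut, beta, y0, X, n_cut):
    """Log-likelihood, gradient and Hessian on the direct (c, beta) scale.

    The cut-cut block of the Hessian is tridiagonal because each
    observation touches only the two cutpoints bracketing its category.
    """
    n, p_dim = X.shape
    eta = X @ beta if p_dim else np.zeros(n)
    hi_idx = np.minimum(y0, n_cut - 1)
    lo_idx = np.maximum(y0 - 1, 0)
    has_hi = y0 < n_cut
    has_lo = y0 > 0
    s_hi = np.where(has_hi, expit(cut[hi_idx] - eta), 1.0)
    s_lo = np.where(has_lo, expit(cut[lo_idx] - eta), 0.0)
    p = np.clip(s_hi - s_lo, 1e-300, None)
    ll = float(np.sum(np.log(p)))

    phi_hi = np.where(has_hi, s_hi * (1 - s_hi), 0.0)
    phi_lo = np.where(has_lo, s_lo * (1 - s_lo), 0.0)
    phip_hi = phi_hi * (1 - 2 * s_hi)
    phip_lo = phi_lo * (1 - 2 * s_lo)

    g_cut = (
        np.bincount(hi_idx, weights=phi_hi / p, minlength=n_cut)
        - np.bincount(lo_idx, weights=phi_lo / p, minlength=n_cut)
    )
    g_eta = (-phi_hi + phi_lo) / p
    g = np.concatenate([g_cut, X.T @ g_eta if p_dim else np.zeros(0)])

    dim = n_cut + p_dim
    H = np.zeros((dim, dim))
    w_hh = phip_hi / p - (phi_hi / p) ** 2
    w_ll = -phip_lo / p - (phi_lo / p) ** 2
    w_hl = phi_hi * phi_lo / p**2
    diag = np.bincount(hi_idx, weights=w_hh, minlength=n_cut) + np.bincount(
        lo_idx, weights=w_ll, minlength=n_cut
    )
    off = np.bincount(lo_idx, weights=w_hl * (has_hi & has_lo), minlength=n_cut)
    H[:n_cut, :n_cut][np.diag_indices(n_cut)] = diag
    for j in range(n_cut - 1):
        H[j, j + 1] = H[j + 1, j] = off[j]
    if p_dim:
        v_hi = -phip_hi / p - phi_hi * (-phi_hi + phi_lo) / p**2
        v_lo = phip_lo / p + phi_lo * (-phi_hi + phi_lo) / p**2
        for c in range(p_dim):
            xc = X[:, c]
            cross = np.bincount(hi_idx, weights=v_hi * xc, minlength=n_cut) + np.bincount(
                lo_idx, weights=v_lo * xc, minlength=n_cut
            )
            H[:n_cut, n_cut + c] = H[n_cut + c, :n_cut] = cross
        w_b = (phip_hi - phip_lo) / p - g_eta**2
        H[n_cut:, n_cut:] = (X * w_b[:, None]).T @ X
    return ll, g, H


def _newton_fit(y0, X, n_cut, cut0, beta0, max_iter=30, tol=1e-10):
    """Maximise the proportional-odds likelihood by damped Newton steps."""
    cut, beta = cut0.copy(), beta0.copy()
    ll, g, H = _loglik_grad_hess(cut, beta, y0, X, n_cut)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(step)):
            return None
        scale = 1.0
        for _ in range(30):
            cut_new = cut + scale * step[:n_cut]
            beta_new = beta + scale * step[n_cut:]
            if np.all(np.diff(cut_new) > 0):
                ll_new, g_new, H_new = _loglik_grad_hess(cut_new, beta_new, y0, X, n_cut)
                if ll_new >= ll - 1e-12:
                    break
            scale *= 0.5
        else:
            return None
        improved = ll_new - ll
        cut, beta, ll, g, H = cut_new, beta_new, ll_new, g_new, H_new
        if improved < tol and np.max(np.abs(g)) < 1e-6:
            return ll, cut, beta
    if np.max(np.abs(g)) < 1e-4:  # near-flat likelihood (separation drift)
        return ll, cut, beta
    return None


def fit_proportional_odds(
    y: np.ndarray,
    X: np.ndarray | None = None,
    n_categories: int | None = None,
    start: OrdinalFit | None = None,
) -> OrdinalFit:
    """Maximum-likelihood proportional-odds fit.

    ``y`` holds ordinal codes 1..K (at least two observed levels); ``X``
    is the predictor matrix, or ``None``/empty for the intercept-only
    model (solved in closed form).  ``start`` warm-starts from a nested
    fit (its coefficients are prefix-padded with zeros).
    """
    y = np.asarray(y, dtype=np.int64)
    if X is None:
        X = np.empty((len(y), 0))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(y) != X.shape[0]:
        raise ValueError("y and X must have the same number of rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("predictors must be finite")

    levels = np.unique(y)
    if len(levels) < 2:
        raise ValueError("y must have at least two observed levels")
    k = int(n_categories or y.max())
    # compress to observed contiguous codes for the fit
    recode = {int(v): i for i, v in enumerate(levels)}
    y0 = np.array([recode[int(v)] for v in y], dtype=np.int64)
    n_cut = len(levels) - 1

    # start at the intercept-only solution
    props = np.array([(y0 <= j).mean() for j in range(n_cut)])
    props = np.clip(props, 1e-6, 1 - 1e-6)
    cut0 = np.log(props / (1 - props))
    cut0 = np.maximum.accumulate(cut0 + np.linspace(0, 1e-9, n_cut))
    if n_cut > 1:
        d = np.maximum(np.diff(cut0), 1e-4)
        cut0 = cut0[0] + np.concatenate([[0.0], np.cumsum(d)])
    beta0 = np.zeros(X.shape[1])
    if start is not None and len(start.cutpoints) == n_cut:
        cut0 = start.cutpoints
        beta0[: len(start.beta)] = start.beta

    if X.shape[1] == 0:
        ll0 = intercept_only_loglik(y, k)
        return OrdinalFit(ll0, cut0, np.zeros(0), True, False, len(y), k)

    newton = _newton_fit(y0, X, n_cut, cut0, beta0)
    if newton is not None:
        ll, cut, beta = newton
        separation = bool(np.any(np.abs(beta) > _COEF_LIMIT) or np.any(np.abs(cut) > 1e3))
        return OrdinalFit(ll, cut, beta, True, separation, len(y), k)

    x0 = _pack(cut0, beta0)
    res = minimize(
        _negloglik_grad,
        x0,
        args=(y0, X, n_cut),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9},
    )
    cut, beta = _unpack(res.x, n_cut)
    separation = bool(np.any(np.abs(beta) > _COEF_LIMIT) or np.any(np.abs(cut) > 1e3))
    return OrdinalFit(
        loglik=-float(res.fun),
        cutpoints=cut,
        beta=beta,
        converged=bool(res.success),
        separation_flag=separation,
        n_obs=len(y),
        n_categories=k,
    )
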