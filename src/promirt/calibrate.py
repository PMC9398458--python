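"""Marginal-maximum-likelihood calibration of the graded response model.

The fitter is a Bock–Aitkin EM: the E-step integrates each person's
posterior over a fixed quadrature grid under a standard-normal latent
prior; the M-step maximises the expected complete-data log-likelihood
item by item with a quasi-Newton solver on an order-preserving
reparameterisation (log slope; first threshold plus log-increments), so
threshold ordering can never be violated during optimisation.

Categories that are never observed for an item are collapsed into the
adjacent lower category before fitting; the recoding map is returned so
callers can interpret the reduced parameterisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

from .data import MISSING, ResponseMatrix
from .grm import posterior_over_grid
from .parameters import ItemParameters, ParameterSet
from .quadrature import QuadratureGrid

__all__ = ["GRMFit", "fit_grm", "CalibrationError"]


class CalibrationError(ValueError):
    """Raised when an item cannot be calibrated (e.g. one observed category)."""


@dataclass
class GRMFit:
    """Result of an EM calibration run."""

    parameters: ParameterSet
    loglik_history: list[float]
    converged: bool
    n_cycles: int
    recode_maps: dict[str, dict[int, int]] = field(default_factory=dict)

    @property
    def loglik(self) -> float:
        return self.loglik_history[-1]


def _pack(slope: float, thresholds: np.ndarray) -> np.ndarray:
    d = np.diff(thresholds)
    return np.concatenate([[np.log(slope), thresholds[0]], np.log(d)])


def _unpack(x: np.ndarray) -> tuple[float, np.ndarray]:
    slope = float(np.exp(x[0]))
    thresholds = x[1] + np.concatenate([[0.0], np.cumsum(np.exp(x[2:]))])
    return slope, thresholds


def _item_negloglik_grad(x: np.ndarray, nodes: np.ndarray, r: np.ndarray):
    """Expected negative log-likelihood for one item and its gradient.

    ``r`` holds expected response counts per (node, category) from the
    E-step.  Gradient is exact, derived through the boundary curves.
    """
    slope, b = _unpack(x)
    k = r.shape[1]
    z = slope * (nodes[:, None] - b[None, :])
    s = expit(z)  # (Q, K-1): P(X >= category k+1)
    p = np.empty_like(r)
    p[:, 0] = 1.0 - s[:, 0]
    if k > 2:
        p[:, 1:-1] = s[:, :-1] - s[:, 1:]
    p[:, -1] = s[:, -1]
    p = np.clip(p, 1e-12, None)
    f = -np.sum(r * np.log(p))

    a_over_p = r / p  # (Q, K)
    # dF/dS_j (boundary j separates categories j and j+1, 0-based)
    dF_dS = a_over_p[:, :-1] - a_over_p[:, 1:]
    sprime = s * (1.0 - s)
    dF_da = np.sum(dF_dS * (nodes[:, None] - b[None, :]) * sprime)
    dF_db = np.sum(dF_dS * (-slope) * sprime, axis=0)
    g = np.empty_like(x)
    g[0] = dF_da * slope  # chain through log slope
    g[1] = dF_db.sum()
    if len(x) > 2:
        d = np.exp(x[2:])
        # b_j includes increment m for j >= m (1-based threshold index)
        g[2:] = d * np.cumsum(dF_db[::-1])[::-1][1:]
    return f, g


def _collapse_item(y: np.ndarray, n_categories: int) -> tuple[np.ndarray, dict[int, int]]:
    """Collapse unobserved categories into the adjacent lower category."""
    obs = y[y != MISSING]
    observed = sorted(set(int(v) for v in obs))
    recode: dict[int, int] = {}
    new = 0
    for c in range(1, n_categories + 1):
        if c in observed:
            new += 1
        recode[c] = max(new, 1)
    y_new = y.copy()
    mask = y != MISSING
    y_new[mask] = np.vectorize(recode.get)(y[mask])
    return y_new, recode


def _initial_item(y: np.ndarray, nk: int) -> tuple[float, np.ndarray]:
    """Start values: unit-ish slope, thresholds from marginal cumulative props."""
    obs = y[y != MISSING]
    props = np.array([(obs >= c).mean() for c in range(2, nk + 1)])
    props = np.clip(props, 1e-3, 1 - 1e-3)
    b = norm.ppf(1.0 - props)
    b = np.maximum.accumulate(b + np.linspace(0, 1e-6, len(b)))
    d = np.diff(b)
    d[d < 1e-3] = 1e-3
    b = b[0] + np.concatenate([[0.0], np.cumsum(d)])
    return 1.5, b


def fit_grm(
    responses: ResponseMatrix | np.ndarray,
    grid: QuadratureGrid | None = None,
    tol: float = 1e-4,
    max_cycles: int = 500,
    min_n_warn: int = 100,
    item_ids: list[str] | None = None,
    metric_tag: str = "fitted",
) -> GRMFit:
    """Fit a graded response model by EM under a standard-normal prior.

    The marginal log-likelihood is non-decreasing across cycles; the run
    stops when the largest absolute parameter change falls below ``tol``
    or ``max_cycles`` is reached (``converged`` flags which).
    """
    grid = grid or QuadratureGrid.normal()
    if isinstance(responses, ResponseMatrix):
        arr = responses.responses()
        ids = list(responses.item_columns)
        n_categories = responses.n_categories
    else:
        arr = np.asarray(responses, dtype=np.int64)
        ids = item_ids or [f"item_{j + 1}" for j in range(arr.shape[1])]
        n_categories = int(arr[arr != MISSING].max()) if (arr != MISSING).any() else 2

    n, n_items = arr.shape
    if n < min_n_warn:
        import warnings

        warnings.warn(f"calibrating on only {n} persons; estimates may be unstable")

    # collapse sparse categories and validate
    recode_maps: dict[str, dict[int, int]] = {}
    item_k: list[int] = []
    work = arr.copy()
    for j, item_id in enumerate(ids):
        y = arr[:, j]
        obs = y[y != MISSING]
        n_obs_cats = len(set(obs.tolist()))
        if n_obs_cats < 2:
            raise CalibrationError(
                f"item {item_id!r} has {n_obs_cats} observed category(ies); cannot calibrate"
            )
        y_new, recode = _collapse_item(y, n_categories)
        if any(recode[c] != c for c in range(1, n_categories + 1)):
            recode_maps[item_id] = recode
        work[:, j] = y_new
        item_k.append(int(work[:, j][work[:, j] != MISSING].max()))

    # initial parameters
    slopes = np.empty(n_items)
    thresholds: list[np.ndarray] = []
    for j in range(n_items):
        a0, b0 = _initial_item(work[:, j], item_k[j])
        slopes[j] = a0
        thresholds.append(b0)

    def current_params() -> ParameterSet:
        return ParameterSet(
            tuple(
                ItemParameters(ids[j], slopes[j], tuple(thresholds[j])) for j in range(n_items)
            ),
            metric_tag=metric_tag,
        )

    loglik_history: list[float] = []
    converged = False
    obs_mask = work != MISSING
    onehots = []
    for j in range(n_items):
        oh = np.zeros((n, item_k[j]))
        rows = np.nonzero(obs_mask[:, j])[0]
        oh[rows, work[rows, j] - 1] = 1.0
        onehots.append(oh)

    cycle = 0
    for cycle in range(1, max_cycles + 1):
        params = current_params()
        post, marginal = posterior_over_grid(work, params, grid)
        loglik_history.append(float(marginal.sum()))

        max_change = 0.0
        for j in range(n_items):
            r = post.T @ onehots[j]  # (Q, K_j) expected counts
            x0 = _pack(slopes[j], thresholds[j])
            res = minimize(
                _item_negloglik_grad,
                x0,
                args=(grid.nodes, r),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-9},
            )
            a_new, b_new = _unpack(res.x)
            a_new = float(np.clip(a_new, 1e-3, 50.0))
            max_change = max(
                max_change,
                abs(a_new - slopes[j]),
                float(np.max(np.abs(b_new - thresholds[j]))),
            )
            slopes[j] = a_new
            thresholds[j] = b_new

        if max_change < tol:
            converged = True
            break

    params = current_params()
    _, marginal = posterior_over_grid(work, params, grid)
    loglik_history.append(float(marginal.sum()))
    return GRMFit(
        parameters=params,
        loglik_history=loglik_history,
        converged=converged,
        n_cycles=cycle,
        recode_maps=recode_maps,
    )
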