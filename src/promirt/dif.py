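"""Hybrid ordinal-regression/IRT differential item functioning detection.

For each item, three nested cumulative-logit models are compared:

  model 1: response ~ trait
  model 2: response ~ trait + group
  model 3: response ~ trait + group + trait x group

where the trait is the EAP estimate from the graded response model (the
"hybrid" of logistic regression and IRT).  The 1-2 comparison detects
uniform DIF, 2-3 non-uniform DIF, each a 1-df likelihood-ratio test.
Flagging is by magnitude: McFadden's pseudo-R-squared change on the 1-3
comparison at a critical threshold (default 0.02), with the 1-2 / 2-3
decomposition labelling the DIF type; the chi-squared tests are reported
but do not gate flagging.

The iterative scan purifies: after each pass the trait is re-estimated
with group-specific parameters for flagged items (rescaled onto the
reference metric through Stocking-Lord linking on the unflagged
anchors), and the scan repeats until the flag set stabilises.
Monte-Carlo simulation under the no-DIF null provides empirical
thresholds for both the p-values and the R-squared changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibrate import fit_grm
from .data import MISSING, ResponseMatrix
from .grm import eap_scores
from .linking import build_hybrid, stocking_lord, transform_parameters
from .parameters import ParameterSet
from .quadrature import QuadratureGrid
from .simulate import simulate_responses
from .ordinal import fit_proportional_odds, intercept_only_loglik

__all__ = [
    "DIFModelFit",
    "DIFScanConfig",
    "DIFScanResult",
    "MonteCarloThresholds",
    "dif_test_item",
    "iterative_dif_scan",
    "monte_carlo_thresholds",
]


@dataclass
class DIFModelFit:
    """Nested-model comparison for one item."""

    item_id: str
    loglik_0: float  # intercept-only baseline for McFadden's R2
    loglik_1: float
    loglik_2: float
    loglik_3: float
    chi2_12: float
    chi2_13: float
    chi2_23: float
    df_12: int
    df_13: int
    df_23: int
    p_12: float
    p_13: float
    p_23: float
    r2_1: float
    r2_2: float
    r2_3: float
    dr2_12: float
    dr2_13: float
    dr2_23: float
    flagged: bool
    dif_type: str  # none | uniform | nonuniform
    separation: bool = False

    def as_row(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def dif_test_item(
    item_responses: np.ndarray,
    theta: np.ndarray,
    group: np.ndarray,
    n_categories: int | None = None,
    r2_threshold: float = 0.02,
    item_id: str = "item",
) -> DIFModelFit:
    """Run the three-model DIF comparison for a single item.

    Rows with missing responses are dropped.  Flag if the 1-3 McFadden
    R-squared change reaches ``r2_threshold``; the dominant of the 1-2
    (uniform) and 2-3 (non-uniform) changes labels the type.
    """
    y = np.asarray(item_responses, dtype=np.int64)
    theta = np.asarray(theta, dtype=float)
    group = np.asarray(group, dtype=float)
    if not (len(y) == len(theta) == len(group)):
        raise ValueError("item responses, theta and group must have equal length")
    if not set(np.unique(group)) <= {0.0, 1.0}:
        raise ValueError("group must be binary 0/1")
    keep = y != MISSING
    y, theta, group = y[keep], theta[keep], group[keep]
    if len(np.unique(y)) < 2:
        raise ValueError(f"item {item_id!r} is degenerate (single observed category)")

    X1 = theta[:, None]
    X2 = np.column_stack([theta, group])
    X3 = np.column_stack([theta, group, theta * group])
    f1 = fit_proportional_odds(y, X1, n_categories)
    f2 = fit_proportional_odds(y, X2, n_categories, start=f1)
    f3 = fit_proportional_odds(y, X3, n_categories, start=f2)
    ll0 = intercept_only_loglik(y, n_categories)

    # guard tiny negative LR noise from finite optimizer tolerance
    ll1, ll2, ll3 = f1.loglik, max(f2.loglik, f1.loglik), 0.0
    ll3 = max(f3.loglik, ll2)
    chi2_12 = 2.0 * (ll2 - ll1)
    chi2_23 = 2.0 * (ll3 - ll2)
    chi2_13 = 2.0 * (ll3 - ll1)
    r2 = lambda ll: 1.0 - ll / ll0
    r2_1, r2_2, r2_3 = r2(ll1), r2(ll2), r2(ll3)
    dr2_12, dr2_23, dr2_13 = r2_2 - r2_1, r2_3 - r2_2, r2_3 - r2_1

    flagged = dr2_13 >= r2_threshold
    if not flagged:
        dif_type = "none"
    elif dr2_12 >= dr2_23:
        dif_type = "uniform"
    else:
        dif_type = "nonuniform"

    return DIFModelFit(
        item_id=item_id,
        loglik_0=ll0,
        loglik_1=ll1,
        loglik_2=ll2,
        loglik_3=ll3,
        chi2_12=chi2_12,
        chi2_13=chi2_13,
        chi2_23=chi2_23,
        df_12=1,
        df_13=2,
        df_23=1,
        p_12=float(stats.chi2.sf(chi2_12, 1)),
        p_13=float(stats.chi2.sf(chi2_13, 2)),
        p_23=float(stats.chi2.sf(chi2_23, 1)),
        r2_1=r2_1,
        r2_2=r2_2,
        r2_3=r2_3,
        dr2_12=dr2_12,
        dr2_13=dr2_13,
        dr2_23=dr2_23,
        flagged=bool(flagged),
        dif_type=dif_type,
        separation=f1.separation_flag or f2.separation_flag or f3.separation_flag,
    )


@dataclass
class DIFScanConfig:
    """Options for the iterative scan."""

    r2_threshold: float = 0.02
    alpha: float = 0.01
    max_iterations: int = 10
    grid: QuadratureGrid | None = None
    em_tol: float = 1e-3
    em_max_cycles: int = 200


@dataclass
class DIFScanResult:
    """Outcome of the iterative purification scan."""

    fits: list[DIFModelFit]
    iterations: int
    flag_history: list[set[str]]
    theta: np.ndarray
    converged: bool

    @property
    def flagged_items(self) -> set[str]:
        return self.flag_history[-1] if self.flag_history else set()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([f.as_row() for f in self.fits])


def iterative_dif_scan(
    responses: ResponseMatrix,
    config: DIFScanConfig | None = None,
    params_reference: ParameterSet | None = None,
) -> DIFScanResult:
    """Iterative DIF scan with purification.

    Iteration 0 scores everyone from a single pooled calibration (or the
    supplied reference-metric parameters).  Each subsequent iteration
    re-scores with group-specific parameters for flagged items, anchored
    on the unflagged items via Stocking-Lord linking, then re-tests.
    Stops when a flag set repeats (normally: two identical consecutive
    sets) or after ``max_iterations``.
    """
    config = config or DIFScanConfig()
    grid = config.grid or QuadratureGrid.normal()
    group = responses.groups
    if len(np.unique(group)) != 2:
        raise ValueError("iterative DIF scan needs both groups present")

    arr = responses.responses()
    if params_reference is not None:
        base_params = params_reference.subset(responses.item_columns)
    else:
        base_params = fit_grm(
            responses, grid=grid, tol=config.em_tol, max_cycles=config.em_max_cycles
        ).parameters

    focal = responses.subset_persons(group == 1)
    reference = responses.subset_persons(group == 0)

    theta = eap_scores(arr, base_params, grid).eap
    flag_history: list[set[str]] = []
    fits: list[DIFModelFit] = []
    converged = False
    params_focal_fit: ParameterSet | None = None

    for iteration in range(1, config.max_iterations + 1):
        fits = []
        for j, item_id in enumerate(responses.item_columns):
            fits.append(
                dif_test_item(
                    arr[:, j],
                    theta,
                    group,
                    n_categories=responses.n_categories,
                    r2_threshold=config.r2_threshold,
                    item_id=item_id,
                )
            )
        flagged = {f.item_id for f in fits if f.flagged}
        if flagged and len(flagged) == len(responses.item_columns):
            raise RuntimeError("all items flagged for DIF: no anchor items remain")
        if flag_history and flagged == flag_history[-1]:
            flag_history.append(flagged)
            converged = True
            break
        if flagged in flag_history:  # a cycle: stop and report
            flag_history.append(flagged)
            break
        flag_history.append(flagged)
        if not flagged:
            # theta would be unchanged, so a re-test must repeat the empty set
            converged = True
            break
        if iteration == config.max_iterations:
            break

        # purification: group-specific parameters for flagged items,
        # focal estimates rescaled onto the base metric via the anchors
        if params_focal_fit is None:
            params_focal_fit = fit_grm(
                focal, grid=grid, tol=config.em_tol, max_cycles=config.em_max_cycles
            ).parameters
        # items whose focal calibration collapsed a category live on a
        # different response scale and can be neither anchors nor replacements
        matching_k = {
            i for i in responses.item_columns
            if params_focal_fit[i].n_categories == base_params[i].n_categories
        }
        anchors = [i for i in responses.item_columns if i not in flagged and i in matching_k]
        if not anchors:
            raise RuntimeError("no usable anchor items for purification linking")
        replaceable = sorted(flagged & matching_k)
        constants = stocking_lord(params_focal_fit, base_params, anchors, grid)
        focal_rescaled = transform_parameters(
            params_focal_fit, constants, items=replaceable
        )
        params_for_focal = build_hybrid(base_params, focal_rescaled, replaceable)
        theta_ref = eap_scores(reference.responses(), base_params, grid).eap
        theta_foc = eap_scores(focal.responses(), params_for_focal, grid).eap
        theta = np.empty(len(group))
        theta[group == 0] = theta_ref
        theta[group == 1] = theta_foc

    return DIFScanResult(
        fits=fits,
        iterations=len(flag_history),
        flag_history=flag_history,
        theta=theta,
        converged=converged,
    )


@dataclass
class MonteCarloThresholds:
    """Empirical null thresholds from no-DIF simulations."""

    n_replications: int
    alpha: float
    p_thresholds: dict[str, float]  # alpha-quantile of null p-values per statistic
    r2_quantiles: dict[str, float]  # (1 - alpha)-quantile of null R2 changes
    per_item: pd.DataFrame | None
    seed: int


def monte_carlo_thresholds(
    params: ParameterSet,
    group_sizes: tuple[int, int],
    theta_dists: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 1.0), (0.0, 1.0)),
    n_replications: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    grid: QuadratureGrid | None = None,
    keep_null_draws: bool = False,
) -> MonteCarloThresholds:
    """Simulate the no-DIF null and collect empirical detection thresholds.

    Each replication draws group traits from the stated normal
    distributions, generates responses from the *same* parameter set for
    both groups, EAP-scores with that set and runs the three-model test
    per item.  Reported are the alpha-quantiles of the pooled null
    p-value distributions (one per chi-squared statistic) and the
    (1 - alpha)-quantiles of the null R-squared changes.
    """
    grid = grid or QuadratureGrid.normal()
    n_ref, n_foc = group_sizes
    master = np.random.SeedSequence(seed)
    reps = master.spawn(n_replications)
    group = np.concatenate([np.zeros(n_ref), np.ones(n_foc)])

    cols = {"p_12": [], "p_13": [], "p_23": [], "dr2_12": [], "dr2_13": [], "dr2_23": []}
    item_ids: list[str] = []
    for ss in reps:
        s_ref, s_foc = ss.spawn(2)
        resp_ref, _ = simulate_responses(params, n=n_ref, theta=theta_dists[0], seed=s_ref)
        resp_foc, _ = simulate_responses(params, n=n_foc, theta=theta_dists[1], seed=s_foc)
        arr = np.vstack([resp_ref, resp_foc])
        theta = eap_scores(arr, params, grid).eap
        for j, item in enumerate(params):
            try:
                fit = dif_test_item(
                    arr[:, j], theta, group,
                    n_categories=item.n_categories, item_id=item.item_id,
                )
            except ValueError:
                continue  # degenerate item in a small replication
            for key in ("p_12", "p_13", "p_23"):
                cols[key].append(getattr(fit, key))
            for key in ("dr2_12", "dr2_13", "dr2_23"):
                cols[key].append(getattr(fit, key))
            item_ids.append(item.item_id)

    p_thresholds = {k: float(np.quantile(cols[k], alpha)) for k in ("p_12", "p_13", "p_23")}
    r2_quantiles = {
        k: float(np.quantile(cols[k], 1.0 - alpha)) for k in ("dr2_12", "dr2_13", "dr2_23")
    }
    per_item = None
    if keep_null_draws:
        per_item = pd.DataFrame({"item_id": item_ids, **cols})
    return MonteCarloThresholds(
        n_replications=n_replications,
        alpha=alpha,
        p_thresholds=p_thresholds,
        r2_quantiles=r2_quantiles,
        per_item=per_item,
        seed=seed,
    )
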