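"""Stocking-Lord test-characteristic-curve equating.

Two calibrations of the same items generally sit on different latent
metrics.  The Stocking-Lord method finds the linear transformation
``theta_ref = A * theta_focal + B`` whose induced parameter rescaling
(``slope / A``, ``A * threshold + B``) makes the anchor items' test
characteristic curve on the focal metric match the reference one in
weighted least squares over a quadrature grid.  The rescaled parameters
of DIF items can then replace their reference counterparts, giving a
"hybrid" parameter set on the reference metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .grm import test_characteristic_curve
from .parameters import ItemParameters, ParameterSet
from .quadrature import QuadratureGrid

__all__ = ["LinkingConstants", "stocking_lord", "transform_parameters", "build_hybrid"]

#: Default criterion grid: 49 nodes on [-4, 4] with standard-normal weights.
DEFAULT_LINKING_GRID = (49, (-4.0, 4.0))


@dataclass(frozen=True)
class LinkingConstants:
    """Linear transformation constants from the focal to the reference metric."""

    A: float
    B: float
    anchor_items: tuple[str, ...]
    objective_value: float

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError(f"scale constant A must be positive, got {self.A}")
        if len(self.anchor_items) == 0:
            raise ValueError("anchor item list must be non-empty")
        if self.objective_value < 0:
            raise ValueError("objective value cannot be negative")

    def to_dict(self) -> dict:
        return {
            "A": self.A,
            "B": self.B,
            "anchor_items": list(self.anchor_items),
            "objective_value": self.objective_value,
        }


def _transform_item(item: ItemParameters, A: float, B: float) -> ItemParameters:
    return ItemParameters(
        item.item_id,
        item.slope / A,
        tuple(A * b + B for b in item.thresholds),
    )


def stocking_lord(
    params_focal: ParameterSet,
    params_reference: ParameterSet,
    anchors: Sequence[str],
    grid: QuadratureGrid | None = None,
    n_starts: int = 3,
) -> LinkingConstants:
    """Estimate (A, B) minimising the weighted squared TCC discrepancy.

    The objective is evaluated over the anchor items only:

        Q(A, B) = sum_q w_q [TCC_ref(theta_q) - TCC_focal->ref(theta_q; A, B)]^2

    with the focal TCC computed from transformed parameters.  Optimised
    over (log A, B) with multi-start quasi-Newton to enforce A > 0 and
    dodge local minima.
    """
    anchors = list(anchors)
    if not anchors:
        raise ValueError("anchor item list must be non-empty")
    missing_f = [a for a in anchors if a not in params_focal]
    missing_r = [a for a in anchors if a not in params_reference]
    if missing_f or missing_r:
        raise KeyError(f"anchors absent from parameter sets: {missing_f + missing_r}")
    for a in anchors:
        if params_focal[a].n_categories != params_reference[a].n_categories:
            raise ValueError(f"anchor {a!r} has mismatched category counts")

    if grid is None:
        n_nodes, bounds = DEFAULT_LINKING_GRID
        grid = QuadratureGrid.normal(n_nodes, bounds)
    nodes, weights = grid.nodes, grid.weights
    tcc_ref = test_characteristic_curve(params_reference, nodes, items=anchors)
    focal_anchor = params_focal.subset(anchors)

    def objective(x: np.ndarray) -> float:
        A, B = float(np.exp(x[0])), float(x[1])
        transformed = ParameterSet(
            tuple(_transform_item(it, A, B) for it in focal_anchor),
            metric_tag="transformed",
        )
        tcc_foc = test_characteristic_curve(transformed, nodes)
        return float(np.sum(weights * (tcc_ref - tcc_foc) ** 2))

    starts = [(0.0, 0.0), (np.log(1.5), 0.5), (np.log(0.7), -0.5)][:n_starts]
    best = None
    for x0 in starts:
        res = minimize(objective, np.asarray(x0), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
        res = minimize(objective, res.x, method="BFGS",
                       options={"gtol": 1e-10, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("Stocking-Lord optimisation failed to converge")

    A, B = float(np.exp(best.x[0])), float(best.x[1])
    return LinkingConstants(
        A=A, B=B, anchor_items=tuple(anchors), objective_value=float(max(best.fun, 0.0))
    )


def transform_parameters(
    params: ParameterSet,
    constants: LinkingConstants,
    items: Sequence[str] | None = None,
    metric_tag: str = "rescaled",
) -> ParameterSet:
    """Rescale (a subset of) item parameters onto the reference metric.

    ``slope_new = slope / A`` and ``threshold_new = A * threshold + B``;
    items not listed are carried through unchanged.  The transformation
    leaves category probabilities invariant under ``theta -> A theta + B``.
    """
    targets = list(items) if items is not None else params.item_ids
    unknown = [i for i in targets if i not in params]
    if unknown:
        raise KeyError(f"unknown item ids: {unknown}")
    new_items = [_transform_item(params[i], constants.A, constants.B) for i in targets]
    return params.replace_items(new_items, metric_tag=metric_tag)


def build_hybrid(
    params_reference: ParameterSet,
    params_focal_rescaled: ParameterSet,
    dif_items: Sequence[str],
) -> ParameterSet:
    """Reference parameters everywhere except DIF items, which carry the
    rescaled focal estimates.  Tagged ``"hybrid"``."""
    missing_r = [i for i in dif_items if i not in params_reference]
    missing_f = [i for i in dif_items if i not in params_focal_rescaled]
    if missing_r or missing_f:
        raise KeyError(f"DIF items absent from parameter sets: {missing_r + missing_f}")
    replacements = [params_focal_rescaled[i] for i in dif_items]
    return params_reference.replace_items(replacements, metric_tag="hybrid")
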