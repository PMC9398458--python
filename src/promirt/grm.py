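"""Samejima graded-response-model probabilities, EAP scoring and curves.

The boundary ("operating characteristic") curves are two-parameter
logistics sharing one slope per item:

    P*(X >= k | theta) = 1 / (1 + exp(-a (theta - b_{k-1}))),  k = 2..K,

and category probabilities are adjacent differences of the boundary
curves.  The slope ``a`` is in the pure-logistic metric: no 1.7 scaling
constant is applied, matching the convention in which PROMIS item
parameters are published.  Scores are reported both on the latent theta
scale (standard normal in the scaling population) and as T-scores,
``T = 50 + 10 * theta``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import MISSING, ResponseMatrix
from .parameters import ItemParameters, ParameterSet
from .quadrature import QuadratureGrid

__all__ = [
    "boundary_probability",
    "category_probabilities",
    "LatentScores",
    "eap_scores",
    "test_characteristic_curve",
    "category_response_curves",
    "t_score",
]

T_MEAN = 50.0
T_SD = 10.0


def t_score(theta: np.ndarray | float) -> np.ndarray | float:
    """Transform latent-trait values to the T metric (mean 50, SD 10)."""
    return T_MEAN + T_SD * np.asarray(theta, dtype=float)


def boundary_probability(slope: float, threshold: float, theta):
    """P(X >= category above `threshold` | theta), a 2-PL logistic in theta."""
    if slope <= 0:
        raise ValueError(f"slope must be positive, got {slope}")
    return expit(slope * (np.asarray(theta, dtype=float) - threshold))


def category_probabilities(item: ItemParameters, theta) -> np.ndarray:
    """Probability of each response category 1..K at the given theta values.

    Returns an array of shape ``(len(theta), K)`` (or ``(K,)`` for scalar
    theta); rows are nonnegative and sum to one.
    """
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    b = np.asarray(item.thresholds)
    pstar = expit(item.slope * (th[:, None] - b[None, :]))  # P(X >= k+1), k = 1..K-1
    k = item.n_categories
    probs = np.empty((th.shape[0], k))
    probs[:, 0] = 1.0 - pstar[:, 0]
    if k > 2:
        probs[:, 1:-1] = pstar[:, :-1] - pstar[:, 1:]
    probs[:, -1] = pstar[:, -1]
    np.clip(probs, 0.0, 1.0, out=probs)
    if np.isscalar(theta) or np.asarray(theta).ndim == 0:
        return probs[0]
    return probs


def _log_category_probabilities(params: ParameterSet, nodes: np.ndarray) -> list[np.ndarray]:
    """Per item: log P(X = k | node), shape (n_nodes, K).  Floor avoids -inf."""
    out = []
    for item in params:
        p = category_probabilities(item, nodes)
        out.append(np.log(np.clip(p, 1e-300, None)))
    return out


@dataclass
class LatentScores:
    """Per-person EAP estimates with posterior SDs and T-scores."""

    df: pd.DataFrame  # columns: person_id, eap, posterior_sd, t_score, n_answered, all_missing

    @property
    def eap(self) -> np.ndarray:
        return self.df["eap"].to_numpy()

    @property
    def posterior_sd(self) -> np.ndarray:
        return self.df["posterior_sd"].to_numpy()

    @property
    def t(self) -> np.ndarray:
        return self.df["t_score"].to_numpy()

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def posterior_over_grid(
    responses: np.ndarray, params: ParameterSet, grid: QuadratureGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised posterior weights over grid nodes for each response row.

    Returns ``(posterior, marginal_loglik)`` where posterior has shape
    ``(n_persons, n_nodes)`` and marginal_loglik is the per-person log of
    the integrated likelihood (used by the EM calibration).
    """
    n_persons = responses.shape[0]
    log_lik = np.zeros((n_persons, len(grid)))
    logp = _log_category_probabilities(params, grid.nodes)
    for j in range(responses.shape[1]):
        y = responses[:, j]
        obs = y != MISSING
        if not obs.any():
            continue
        log_lik[obs] += logp[j][:, y[obs] - 1].T
    log_post = log_lik + np.log(grid.weights)[None, :]
    m = log_post.max(axis=1, keepdims=True)
    w = np.exp(log_post - m)
    tot = w.sum(axis=1, keepdims=True)
    marginal = (m[:, 0] + np.log(tot[:, 0]))
    return w / tot, marginal


def eap_scores(
    responses: ResponseMatrix | np.ndarray,
    params: ParameterSet,
    grid: QuadratureGrid | None = None,
) -> LatentScores:
    """Expected-a-posteriori trait estimates under a standard-normal prior.

    Only non-missing responses contribute; a person with no responses gets
    the prior mean (theta 0, T 50) and is flagged ``all_missing``.
    """
    grid = grid or QuadratureGrid.normal()
    if isinstance(responses, ResponseMatrix):
        unknown = [c for c in responses.item_columns if c not in params]
        if unknown:
            raise KeyError(f"response items missing from parameter set: {unknown}")
        arr = responses.responses()
        use_params = params.subset(responses.item_columns)
        person_id = responses.df["person_id"].to_numpy() if "person_id" in responses.df else np.arange(len(arr))
    else:
        arr = np.asarray(responses, dtype=np.int64)
        use_params = params
        person_id = np.arange(arr.shape[0])
        if arr.shape[1] != len(params):
            raise ValueError(
                f"response array has {arr.shape[1]} columns but parameter set has {len(params)} items"
            )

    post, _ = posterior_over_grid(arr, use_params, grid)
    eap = post @ grid.nodes
    second = post @ grid.nodes**2
    var = np.clip(second - eap**2, 0.0, None)
    sd = np.sqrt(var)
    n_answered = (arr != MISSING).sum(axis=1)
    all_missing = n_answered == 0
    df = pd.DataFrame(
        {
            "person_id": person_id,
            "eap": eap,
            "posterior_sd": sd,
            "t_score": t_score(eap),
            "n_answered": n_answered,
            "all_missing": all_missing,
        }
    )
    return LatentScores(df)


def test_characteristic_curve(
    params: ParameterSet,
    theta_grid: np.ndarray,
    items: list[str] | None = None,
) -> np.ndarray:
    """Expected total score sum_items sum_k k P(X=k|theta) over a theta grid."""
    ids = items if items is not None else params.item_ids
    if len(ids) == 0:
        raise ValueError("item subset must be non-empty")
    sub = params.subset(ids)
    th = np.asarray(theta_grid, dtype=float)
    tcc = np.zeros_like(th)
    for item in sub:
        p = category_probabilities(item, th)
        tcc += p @ np.arange(1, item.n_categories + 1)
    return tcc


def category_response_curves(
    item_ref: ItemParameters,
    item_focal: ItemParameters,
    theta_grid: np.ndarray,
) -> pd.DataFrame:
    """Paired per-category probability curves for two groups' versions of an item.

    Long-format table with ``|grid| * K * 2`` rows: theta, group, category,
    probability — ready for plotting or export.
    """
    if item_ref.n_categories != item_focal.n_categories:
        raise ValueError("items must share the number of categories")
    th = np.asarray(theta_grid, dtype=float)
    frames = []
    for label, item in (("reference", item_ref), ("focal", item_focal)):
        p = category_probabilities(item, th)
        for k in range(item.n_categories):
            frames.append(
                pd.DataFrame(
                    {
                        "theta": th,
                        "group": label,
                        "category": k + 1,
                        "probability": p[:, k],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
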