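"""Two-group graded-response-model data generator with known truth.

Emulates a cross-cultural item-bank study: a large reference sample
(the calibration population on whose metric the bank is scaled) and a
smaller focal sample whose latent trait is near-standard-normal on that
metric, answering 5-point Likert items.  DIF can be planted in chosen
items, either uniform (all thresholds shifted by a constant) or
non-uniform (slope multiplied by a factor, optionally also shifted), and
the complete generating truth — parameters per group, per-person thetas,
the DIF list — is retained so recovery can be tested downstream.

Default design constants mirror the emulated study: a 29-item bank with
5 categories, n_focal = 1002, n_reference = 14,836, both trait
distributions standard normal, gender split 47.9/52.1 and age-bin
proportions 25/15/17/22/19/2 percent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .data import AGE_BINS, ResponseMatrix, age_to_bin
from .grm import category_probabilities
from .parameters import ItemParameters, ParameterSet

__all__ = [
    "DIFSpec",
    "SimulationDesign",
    "TruthRecord",
    "simulate_item_bank",
    "inject_dif",
    "simulate_responses",
    "simulate_two_group_study",
]

DifType = Literal["uniform", "nonuniform"]

#: Study-shaped covariate defaults (proportions over AGE_BINS; gender male/female).
DEFAULT_AGE_PROPORTIONS = (0.25, 0.15, 0.17, 0.22, 0.19, 0.02)
DEFAULT_GENDER_PROPORTIONS = {"male": 0.479, "female": 0.521}

_AGE_RANGES = {
    "18-34": (18, 34),
    "35-44": (35, 44),
    "45-54": (45, 54),
    "55-64": (55, 64),
    "65-74": (65, 74),
    "75+": (75, 90),
}


class InvalidDesignError(ValueError):
    """A simulation design violates its invariants."""


@dataclass(frozen=True)
class DIFSpec:
    """One planted DIF item: which item, what kind, how large."""

    item_index: int
    dif_type: DifType
    threshold_shift: float = 0.0
    slope_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.dif_type not in ("uniform", "nonuniform"):
            raise InvalidDesignError(f"unknown dif_type {self.dif_type!r}")
        if not np.isfinite(self.threshold_shift) or not np.isfinite(self.slope_factor):
            raise InvalidDesignError("DIF shift/factor must be finite")
        if self.slope_factor <= 0:
            raise InvalidDesignError("slope_factor must be positive")
        if self.dif_type == "uniform" and self.slope_factor != 1.0:
            raise InvalidDesignError("uniform DIF must keep slope_factor = 1")
        if self.dif_type == "nonuniform" and self.slope_factor == 1.0:
            raise InvalidDesignError("nonuniform DIF requires slope_factor != 1")


@dataclass(frozen=True)
class SimulationDesign:
    """Full description of a two-group simulated item-bank study."""

    n_items: int = 29
    n_categories: int = 5
    n_reference: int = 14836
    n_focal: int = 1002
    theta_reference: tuple[float, float] = (0.0, 1.0)
    theta_focal: tuple[float, float] = (0.0, 1.0)
    dif_spec: tuple[DIFSpec, ...] = ()
    age_proportions: tuple[float, ...] = DEFAULT_AGE_PROPORTIONS
    gender_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENDER_PROPORTIONS)
    )
    age_theta_shift: dict[str, float] | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_items < 1 or self.n_categories < 2:
            raise InvalidDesignError("need n_items >= 1 and n_categories >= 2")
        if self.n_reference < 1 or self.n_focal < 1:
            raise InvalidDesignError("group sizes must be >= 1")
        if self.theta_reference[1] <= 0 or self.theta_focal[1] <= 0:
            raise InvalidDesignError("trait SDs must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidDesignError("missing_rate must be in [0, 1)")
        idx = [d.item_index for d in self.dif_spec]
        if len(set(idx)) != len(idx):
            raise InvalidDesignError("DIF item indices must be unique")
        if any(i < 0 or i >= self.n_items for i in idx):
            raise InvalidDesignError("DIF item index outside the bank")
        if len(self.age_proportions) != len(AGE_BINS):
            raise InvalidDesignError(f"age_proportions must have {len(AGE_BINS)} entries")
        if abs(sum(self.age_proportions) - 1.0) > 1e-8:
            raise InvalidDesignError("age_proportions must sum to 1")
        if abs(sum(self.gender_proportions.values()) - 1.0) > 1e-8:
            raise InvalidDesignError("gender_proportions must sum to 1")


@dataclass
class TruthRecord:
    """Ground truth behind a simulated study, for recovery tests."""

    params_reference: ParameterSet
    params_focal: ParameterSet
    theta: np.ndarray  # stacked: reference block then focal block
    group: np.ndarray  # 0 reference, 1 focal
    dif_items: list[str]
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "params_reference": self.params_reference.to_dict(),
                    "params_focal": self.params_focal.to_dict(),
                    "theta": self.theta.tolist(),
                    "group": self.group.tolist(),
                    "dif_items": self.dif_items,
                    "seed": self.seed,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        d = json.loads(Path(path).read_text())
        return cls(
            params_reference=ParameterSet.from_dict(d["params_reference"]),
            params_focal=ParameterSet.from_dict(d["params_focal"]),
            theta=np.asarray(d["theta"]),
            group=np.asarray(d["group"], dtype=np.int64),
            dif_items=list(d["dif_items"]),
            seed=int(d["seed"]),
        )


def simulate_item_bank(
    n_items: int,
    n_categories: int = 5,
    seed: int = 0,
    slope_range: tuple[float, float] = (1.0, 4.5),
    first_threshold_range: tuple[float, float] = (-1.2, 0.6),
    increment_range: tuple[float, float] = (0.4, 1.1),
    metric_tag: str = "reference",
) -> ParameterSet:
    """Draw a random but realistic graded-response item bank.

    Slopes are uniform on a range bracketing published item-bank values
    (roughly 1–4.5); thresholds start between about -1.2 and 0.6 and rise
    in increments of 0.4–1.1, spanning roughly -1.5 to 3 on the latent
    scale.  Deterministic given the seed.
    """
    if n_items < 1 or n_categories < 2:
        raise InvalidDesignError("need n_items >= 1 and n_categories >= 2")
    rng = np.random.default_rng(seed)
    items = []
    for j in range(n_items):
        slope = rng.uniform(*slope_range)
        b1 = rng.uniform(*first_threshold_range)
        inc = rng.uniform(*increment_range, size=n_categories - 2)
        thresholds = b1 + np.concatenate([[0.0], np.cumsum(inc)])
        items.append(ItemParameters(f"item_{j + 1:02d}", slope, tuple(thresholds)))
    return ParameterSet(tuple(items), metric_tag=metric_tag)


def inject_dif(
    params: ParameterSet,
    item: int | str,
    dif_type: DifType,
    threshold_shift: float = 0.0,
    slope_factor: float = 1.0,
) -> ParameterSet:
    """Return a focal-group parameter set with DIF planted in one item.

    Uniform DIF shifts all the item's thresholds by a constant (ordering
    is preserved by construction); non-uniform DIF multiplies the slope
    (and may also shift).  Every other item is untouched.
    """
    DIFSpec(0, dif_type, threshold_shift, slope_factor)  # validate the combination
    if isinstance(item, int):
        if not 0 <= item < len(params):
            raise InvalidDesignError(f"item index {item} outside bank of {len(params)}")
        target = params.items[item]
    else:
        target = params[item]
    new = ItemParameters(
        target.item_id,
        target.slope * slope_factor,
        tuple(b + threshold_shift for b in target.thresholds),
    )
    return params.replace_items([new], metric_tag="focal")


def simulate_responses(
    params: ParameterSet,
    n: int | None = None,
    theta: tuple[float, float] | np.ndarray = (0.0, 1.0),
    seed: int = 0,
    missing_rate: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample GRM responses; returns ``(responses, thetas)``.

    ``theta`` is either a ``(mean, sd)`` pair, in which case ``n`` thetas
    are drawn normally, or an explicit vector.  Responses are integers
    1..K (missing coded -1 when ``missing_rate`` > 0); ``n = 0`` yields
    an empty matrix, not an error.
    """
    rng = np.random.default_rng(seed)
    if isinstance(theta, tuple):
        if n is None:
            raise ValueError("n is required when theta is a (mean, sd) pair")
        thetas = rng.normal(theta[0], theta[1], size=n)
    else:
        thetas = np.asarray(theta, dtype=float)
    n = len(thetas)
    out = np.empty((n, len(params)), dtype=np.int64)
    if n == 0:
        return out, thetas
    for j, item in enumerate(params):
        p = category_probabilities(item, thetas)  # (n, K)
        cum = np.cumsum(p, axis=1)
        cum[:, -1] = 1.0
        u = rng.random(n)
        out[:, j] = 1 + (u[:, None] > cum).sum(axis=1)
    if missing_rate > 0:
        mask = rng.random(out.shape) < missing_rate
        out[mask] = -1
    return out, thetas


def _draw_covariates(
    rng: np.random.Generator,
    n: int,
    age_proportions: Sequence[float],
    gender_proportions: dict[str, float],
) -> pd.DataFrame:
    bins = rng.choice(len(AGE_BINS), size=n, p=np.asarray(age_proportions))
    ages = np.empty(n, dtype=np.int64)
    for i, b in enumerate(bins):
        lo, hi = _AGE_RANGES[AGE_BINS[b]]
        ages[i] = rng.integers(lo, hi + 1)
    genders = rng.choice(
        list(gender_proportions), size=n, p=list(gender_proportions.values())
    )
    return pd.DataFrame(
        {
            "age_years": ages,
            "age_bin": [age_to_bin(a) for a in ages],
            "gender": genders,
        }
    )


def simulate_two_group_study(design: SimulationDesign) -> tuple[ResponseMatrix, TruthRecord]:
    """Generate a stacked two-group study matrix with its truth record.

    One master seed spawns deterministic sub-streams for the bank, the
    covariates and each group's responses, so stages are individually
    reproducible.
    """
    master = np.random.SeedSequence(design.seed)
    s_bank, s_cov_ref, s_cov_foc, s_resp_ref, s_resp_foc = master.spawn(5)

    params_ref = simulate_item_bank(
        design.n_items,
        design.n_categories,
        seed=s_bank,
        metric_tag="reference",
    )
    params_foc = params_ref.with_metric_tag("focal")
    for d in design.dif_spec:
        params_foc = inject_dif(
            params_foc, d.item_index, d.dif_type, d.threshold_shift, d.slope_factor
        )

    cov_ref = _draw_covariates(
        np.random.default_rng(s_cov_ref), design.n_reference,
        design.age_proportions, design.gender_proportions,
    )
    cov_foc = _draw_covariates(
        np.random.default_rng(s_cov_foc), design.n_focal,
        design.age_proportions, design.gender_proportions,
    )

    def theta_vector(cov: pd.DataFrame, dist: tuple[float, float], ss) -> np.ndarray:
        rng = np.random.default_rng(ss)
        th = rng.normal(dist[0], dist[1], size=len(cov))
        if design.age_theta_shift:
            for bin_label, shift in design.age_theta_shift.items():
                th[cov["age_bin"].to_numpy() == bin_label] += shift
        return th

    theta_ref = theta_vector(cov_ref, design.theta_reference, s_resp_ref.spawn(1)[0])
    theta_foc = theta_vector(cov_foc, design.theta_focal, s_resp_foc.spawn(1)[0])
    resp_ref, _ = simulate_responses(
        params_ref, theta=theta_ref, seed=s_resp_ref, missing_rate=design.missing_rate
    )
    resp_foc, _ = simulate_responses(
        params_foc, theta=theta_foc, seed=s_resp_foc, missing_rate=design.missing_rate
    )

    responses = np.vstack([resp_ref, resp_foc]).astype(float)
    responses[responses < 0] = np.nan
    group = np.concatenate(
        [np.zeros(design.n_reference, dtype=np.int64), np.ones(design.n_focal, dtype=np.int64)]
    )
    cov = pd.concat([cov_ref, cov_foc], ignore_index=True)
    df = pd.DataFrame(
        {
            "person_id": np.arange(len(group)),
            "group": group,
            "age_years": cov["age_years"].to_numpy(),
            "age_bin": cov["age_bin"].to_numpy(),
            "gender": cov["gender"].to_numpy(),
        }
    )
    for j, item_id in enumerate(params_ref.item_ids):
        df[item_id] = responses[:, j]

    matrix = ResponseMatrix(df, params_ref.item_ids, design.n_categories)
    truth = TruthRecord(
        params_reference=params_ref,
        params_focal=params_foc,
        theta=np.concatenate([theta_ref, theta_foc]),
        group=group,
        dif_items=[params_ref.item_ids[d.item_index] for d in design.dif_spec],
        seed=design.seed,
    )
    return matrix, truth
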