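"""Impact of DIF on T-scores: original vs hybrid parameters, full bank
and short-form subsets, at population and individual level.

Scoring of a subset re-uses the full response-pattern EAP machinery
restricted to the subset's items (matching how item banks are scored in
practice), not sum-score lookup tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ResponseMatrix
from .grm import LatentScores, eap_scores
from .parameters import ParameterSet
from .quadrature import QuadratureGrid

__all__ = [
    "InstrumentVersion",
    "ImpactSummary",
    "score_version",
    "compare_approaches",
    "default_short_forms",
]


@dataclass(frozen=True)
class InstrumentVersion:
    """A named fixed-length view of the bank (the full bank or a short form)."""

    name: str
    item_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.item_ids) == 0:
            raise ValueError(f"version {self.name!r} has no items")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValueError(f"version {self.name!r} repeats items")


#: Fixed short forms published for the anxiety and depression banks,
#: by version name -> item count.  Their item memberships are external
#: instrument metadata, not derivable here: pair these names with real
#: item-id lists via configuration when scoring actual instruments.
STANDARD_SHORT_FORM_LENGTHS: dict[str, dict[str, int]] = {
    "anxiety": {"4a": 4, "6a": 6, "7a": 7, "8a": 8},
    "depression": {"4a": 4, "6a": 6, "8a": 8, "8b": 8},
}


def default_short_forms(bank_item_ids: Sequence[str], lengths: Sequence[int] = (4, 6, 8)) -> list[InstrumentVersion]:
    """Placeholder short-form definitions built from bank position.

    Real short-form memberships are external metadata; these synthetic
    versions simply take the first ``n`` items so subset behaviour can be
    exercised.  Supply real item lists in configuration when available.
    """
    out = [InstrumentVersion("full_bank", tuple(bank_item_ids))]
    for n in lengths:
        if n <= len(bank_item_ids):
            out.append(InstrumentVersion(f"short_form_{n}", tuple(bank_item_ids[:n])))
    return out


def named_short_forms(bank_item_ids: Sequence[str], family: str) -> list[InstrumentVersion]:
    """Standard short-form names for a bank family with placeholder
    (positional) memberships — replace with real item lists to score
    actual instruments."""
    if family not in STANDARD_SHORT_FORM_LENGTHS:
        raise KeyError(f"unknown bank family {family!r}; known: {sorted(STANDARD_SHORT_FORM_LENGTHS)}")
    out = [InstrumentVersion("full_bank", tuple(bank_item_ids))]
    for name, n in STANDARD_SHORT_FORM_LENGTHS[family].items():
        if n <= len(bank_item_ids):
            out.append(InstrumentVersion(f"{family}_{name}", tuple(bank_item_ids[:n])))
    return out


@dataclass
class ImpactSummary:
    """Population- and individual-level T-score impact for one version."""

    version: str
    n_items: int
    mean_t_original: float
    sd_t_original: float
    mean_t_hybrid: float
    sd_t_hybrid: float
    mean_abs_diff: float
    sd_abs_diff: float
    min_abs_diff: float
    max_abs_diff: float

    def as_row(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def score_version(
    responses: ResponseMatrix,
    params: ParameterSet,
    version: InstrumentVersion,
    grid: QuadratureGrid | None = None,
) -> LatentScores:
    """EAP/T scores using only the version's items."""
    missing_data = [i for i in version.item_ids if i not in responses.item_columns]
    missing_par = [i for i in version.item_ids if i not in params]
    if missing_data or missing_par:
        raise KeyError(
            f"version {version.name!r}: items absent from data {missing_data} "
            f"or parameters {missing_par}"
        )
    sub = responses.subset_items(list(version.item_ids))
    return eap_scores(sub, params.subset(list(version.item_ids)), grid)


def compare_approaches(
    responses: ResponseMatrix,
    params_original: ParameterSet,
    params_hybrid: ParameterSet,
    versions: Sequence[InstrumentVersion],
    grid: QuadratureGrid | None = None,
) -> tuple[list[ImpactSummary], pd.DataFrame]:
    """Score every version under both parameter sets and summarise |ΔT|.

    Returns the per-version summaries plus a per-person long table
    (person_id, version, t_original, t_hybrid, abs_diff) for scatter
    plots of ΔT against T.
    """
    summaries: list[ImpactSummary] = []
    person_rows: list[pd.DataFrame] = []
    for version in versions:
        s_orig = score_version(responses, params_original, version, grid)
        s_hyb = score_version(responses, params_hybrid, version, grid)
        diff = np.abs(s_orig.t - s_hyb.t)
        summaries.append(
            ImpactSummary(
                version=version.name,
                n_items=len(version.item_ids),
                mean_t_original=float(s_orig.t.mean()),
                sd_t_original=float(s_orig.t.std(ddof=1)),
                mean_t_hybrid=float(s_hyb.t.mean()),
                sd_t_hybrid=float(s_hyb.t.std(ddof=1)),
                mean_abs_diff=float(diff.mean()),
                sd_abs_diff=float(diff.std(ddof=1)),
                min_abs_diff=float(diff.min()),
                max_abs_diff=float(diff.max()),
            )
        )
        person_rows.append(
            pd.DataFrame(
                {
                    "person_id": s_orig.df["person_id"],
                    "version": version.name,
                    "t_original": s_orig.t,
                    "t_hybrid": s_hyb.t,
                    "abs_diff": diff,
                }
            )
        )
    return summaries, pd.concat(person_rows, ignore_index=True)
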