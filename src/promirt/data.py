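"""Response-matrix container: ordinal item responses plus group and covariates.

The on-disk form is a plain CSV with one row per person and columns
``person_id, group, age_years, age_bin, gender, <item columns>``; responses
are ordinal codes ``1..K`` with missing cells left empty.  In memory the
matrix wraps a :class:`pandas.DataFrame` and exposes validated integer
response arrays (missing coded ``-1``) for the numerical routines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ResponseMatrix", "MISSING", "AGE_BINS", "age_to_bin"]

MISSING = -1

#: Age strata used for reference-value reporting (lower bound inclusive).
AGE_BINS: tuple[str, ...] = ("18-34", "35-44", "45-54", "55-64", "65-74", "75+")
_AGE_EDGES = (18, 35, 45, 55, 65, 75)

META_COLUMNS = ("person_id", "group", "age_years", "age_bin", "gender")


def age_to_bin(age_years: float) -> str:
    """Map a whole-year age to its reporting stratum."""
    if age_years < _AGE_EDGES[0]:
        raise ValueError(f"age {age_years} below the adult range")
    for lo, hi, label in zip(_AGE_EDGES, _AGE_EDGES[1:], AGE_BINS):
        if lo <= age_years < hi:
            return label
    return AGE_BINS[-1]


@dataclass
class ResponseMatrix:
    """Person x item ordinal responses with group labels and covariates."""

    df: pd.DataFrame
    item_columns: list[str] = field(default_factory=list)
    n_categories: int = 5

    def __post_init__(self) -> None:
        if not self.item_columns:
            self.item_columns = [c for c in self.df.columns if c not in META_COLUMNS]
        missing_cols = [c for c in self.item_columns if c not in self.df.columns]
        if missing_cols:
            raise ValueError(f"item columns absent from frame: {missing_cols}")
        self.validate()

    def validate(self) -> None:
        """Check every response code is in 1..K or missing; report offenders."""
        bad: list[str] = []
        for col in self.item_columns:
            vals = self.df[col]
            obs = vals.dropna()
            if len(obs) == 0:
                continue
            as_float = obs.astype(float)
            nonint = as_float[as_float != np.round(as_float)]
            out = as_float[(as_float < 1) | (as_float > self.n_categories)]
            for idx in list(nonint.index) + list(out.index):
                bad.append(f"row {idx}, column {col!r}: value {vals.loc[idx]!r}")
        if bad:
            raise ValueError(
                "invalid response codes (expected integers in 1..%d):\n  %s"
                % (self.n_categories, "\n  ".join(bad[:20]))
            )

    # ---------------------------------------------------------------- access
    @property
    def n_persons(self) -> int:
        return len(self.df)

    @property
    def n_items(self) -> int:
        return len(self.item_columns)

    def responses(self, item_ids: Sequence[str] | None = None) -> np.ndarray:
        """Integer response array (persons x items), missing coded ``-1``."""
        cols = list(item_ids) if item_ids is not None else self.item_columns
        unknown = [c for c in cols if c not in self.item_columns]
        if unknown:
            raise KeyError(f"unknown item columns: {unknown}")
        arr = self.df[cols].to_numpy(dtype=float)
        out = np.where(np.isnan(arr), MISSING, arr).astype(np.int64)
        return out

    @property
    def groups(self) -> np.ndarray:
        """Binary group indicator: 0 = reference, 1 = focal."""
        if "group" not in self.df.columns:
            raise ValueError("response matrix has no 'group' column")
        g = self.df["group"]
        labels = sorted(g.unique())
        if set(labels) <= {0, 1}:
            return g.to_numpy(dtype=np.int64)
        if set(labels) <= {"reference", "focal"}:
            return (g == "focal").to_numpy(dtype=np.int64)
        raise ValueError(f"group labels must be binary (0/1 or reference/focal), got {labels}")

    def subset_items(self, item_ids: Sequence[str]) -> "ResponseMatrix":
        unknown = [c for c in item_ids if c not in self.item_columns]
        if unknown:
            raise KeyError(f"unknown item columns: {unknown}")
        keep = [c for c in self.df.columns if c not in self.item_columns] + list(item_ids)
        return ResponseMatrix(self.df[keep].copy(), list(item_ids), self.n_categories)

    def subset_persons(self, mask: np.ndarray) -> "ResponseMatrix":
        return ResponseMatrix(
            self.df.loc[np.asarray(mask, dtype=bool)].copy(), list(self.item_columns), self.n_categories
        )

    # ------------------------------------------------------------------- I/O
    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        n_categories: int = 5,
        item_columns: Sequence[str] | None = None,
    ) -> "ResponseMatrix":
        path = Path(path)
        if path.stat().st_size == 0:
            raise ValueError(f"empty input file: {path}")
        df = pd.read_csv(path)
        if len(df.columns) == 0 or len(df) == 0:
            raise ValueError(f"no data rows in {path}")
        cols = list(item_columns) if item_columns is not None else None
        return cls(df, cols or [], n_categories)
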