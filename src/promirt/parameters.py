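"""Item parameter containers for the graded response model.

An item is described by one discrimination (slope, ``a``) and ``K - 1``
strictly increasing category thresholds (``b_1 < ... < b_{K-1}``) on the
latent-trait scale.  Parameters are in the pure-logistic metric (no 1.7
scaling constant), the convention of the PROMIS calibrations these tools
emulate.  A :class:`ParameterSet` carries a ``metric_tag`` naming the scale
the parameters live on (e.g. ``"reference"``, ``"focal"``, ``"hybrid"``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = ["ItemParameters", "ParameterSet"]


@dataclass(frozen=True)
class ItemParameters:
    """Slope and ordered thresholds of one graded-response item."""

    item_id: str
    slope: float
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "thresholds", tuple(float(t) for t in self.thresholds))
        object.__setattr__(self, "slope", float(self.slope))
        if not np.isfinite(self.slope) or self.slope <= 0:
            raise ValueError(f"item {self.item_id!r}: slope must be positive, got {self.slope}")
        if len(self.thresholds) < 1:
            raise ValueError(f"item {self.item_id!r}: needs at least one threshold")
        if not all(np.isfinite(self.thresholds)):
            raise ValueError(f"item {self.item_id!r}: thresholds must be finite")
        if any(b2 <= b1 for b1, b2 in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError(
                f"item {self.item_id!r}: thresholds must be strictly increasing, got {self.thresholds}"
            )

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1


@dataclass(frozen=True)
class ParameterSet:
    """An ordered collection of item parameters on one metric."""

    items: tuple[ItemParameters, ...]
    metric_tag: str = "unspecified"

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item ids: {dupes}")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[ItemParameters]:
        return iter(self.items)

    def __getitem__(self, item_id: str) -> ItemParameters:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def __contains__(self, item_id: str) -> bool:
        return any(it.item_id == item_id for it in self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def subset(self, item_ids: Sequence[str]) -> "ParameterSet":
        missing = [i for i in item_ids if i not in self]
        if missing:
            raise KeyError(f"unknown item ids: {missing}")
        return ParameterSet(tuple(self[i] for i in item_ids), metric_tag=self.metric_tag)

    def with_metric_tag(self, tag: str) -> "ParameterSet":
        return replace(self, metric_tag=tag)

    def replace_items(
        self, new_items: Iterable[ItemParameters], metric_tag: str | None = None
    ) -> "ParameterSet":
        """Return a copy with matching ``item_id`` entries swapped out."""
        by_id = {it.item_id: it for it in new_items}
        unknown = [i for i in by_id if i not in self]
        if unknown:
            raise KeyError(f"unknown item ids: {unknown}")
        items = tuple(by_id.get(it.item_id, it) for it in self.items)
        return ParameterSet(items, metric_tag=metric_tag or self.metric_tag)

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        max_k = max(it.n_categories for it in self.items)
        rows = []
        for it in self.items:
            row: dict[str, object] = {
                "item_id": it.item_id,
                "slope": it.slope,
                "n_categories": it.n_categories,
                "metric_tag": self.metric_tag,
            }
            for j in range(1, max_k):
                row[f"b{j}"] = it.thresholds[j - 1] if j - 1 < len(it.thresholds) else np.nan
            rows.append(row)
        cols = ["item_id", "slope"] + [f"b{j}" for j in range(1, max_k)] + ["n_categories", "metric_tag"]
        return pd.DataFrame(rows)[cols]

    def to_csv(self, path: str | Path) -> None:
        # %.17g keeps the write -> read round trip bit-exact
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ParameterSet":
        b_cols = sorted(
            (c for c in df.columns if c.startswith("b") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        items = []
        for _, row in df.iterrows():
            thresholds = [row[c] for c in b_cols if pd.notna(row[c])]
            items.append(ItemParameters(str(row["item_id"]), float(row["slope"]), tuple(thresholds)))
        tag = str(df["metric_tag"].iloc[0]) if "metric_tag" in df.columns and len(df) else "unspecified"
        return cls(tuple(items), metric_tag=tag)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ParameterSet":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))

    def to_dict(self) -> dict:
        return {
            "metric_tag": self.metric_tag,
            "items": [
                {"item_id": it.item_id, "slope": it.slope, "thresholds": list(it.thresholds)}
                for it in self.items
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        items = tuple(
            ItemParameters(e["item_id"], e["slope"], tuple(e["thresholds"])) for e in d["items"]
        )
        return cls(items, metric_tag=d.get("metric_tag", "unspecified"))

    @classmethod
    def from_json(cls, path: str | Path) -> "ParameterSet":
        return cls.from_dict(json.loads(Path(path).read_text()))
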