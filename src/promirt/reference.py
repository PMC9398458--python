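"""Population reference values: stratified T-score norms, severity
thresholds and symptom-category percentages.

Strata follow the reporting convention for adult norms: the total
sample, gender, and six age bins (18-34, 35-44, 45-54, 55-64, 65-74,
75+).  Severity thresholds are the reference mean plus 0.5, 1 and 2
standard deviations — with the T metric's (50, 10) this gives the
familiar 55 / 60 / 70 cutoffs — and scores are classified as within
normal limits (<= mild cutoff), mild, moderate or severe (> severe
cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AGE_BINS
from .grm import LatentScores

__all__ = [
    "ReferenceTable",
    "SeverityThresholds",
    "reference_table",
    "severity_thresholds",
    "classify_scores",
    "CATEGORY_LABELS",
]

CATEGORY_LABELS = ("normal", "mild", "moderate", "severe")


@dataclass(frozen=True)
class SeverityThresholds:
    """T-score cutoffs for mild, moderate and severe symptom levels."""

    mild: float
    moderate: float
    severe: float

    def __post_init__(self) -> None:
        if not self.mild < self.moderate < self.severe:
            raise ValueError(
                f"thresholds must increase: {self.mild}, {self.moderate}, {self.severe}"
            )


def severity_thresholds(
    reference_mean: float = 50.0,
    reference_sd: float = 10.0,
    round_to_int: bool = True,
) -> SeverityThresholds:
    """Cutoffs at mean + 0.5 / 1 / 2 SD (rounded to integers by default)."""
    if reference_sd <= 0:
        raise ValueError("reference SD must be positive")
    vals = [reference_mean + k * reference_sd for k in (0.5, 1.0, 2.0)]
    if round_to_int:
        vals = [float(round(v)) for v in vals]
    return SeverityThresholds(*vals)


@dataclass
class ReferenceTable:
    """Stratified reference values: n, percentage, mean and SD of T-scores."""

    df: pd.DataFrame  # columns: partition, stratum, n, percent, mean_t, sd_t

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def row(self, partition: str, stratum: str) -> pd.Series:
        m = (self.df["partition"] == partition) & (self.df["stratum"] == stratum)
        return self.df.loc[m].iloc[0]


def reference_table(scores: LatentScores, covariates: pd.DataFrame) -> ReferenceTable:
    """Unweighted stratified means/SDs of T-scores.

    ``covariates`` must align row-wise with the scores and provide
    ``age_bin`` and ``gender`` columns; missing covariate values land in
    an ``unknown`` stratum that is reported but excluded from the
    partition percentages.  Empty strata get n = 0 rows with absent
    statistics rather than an error.
    """
    if len(scores) != len(covariates):
        raise ValueError("scores and covariates must align row-wise")
    t = scores.t
    rows = []

    def add_row(partition: str, stratum: str, mask: np.ndarray, denom: int) -> None:
        n = int(mask.sum())
        rows.append(
            {
                "partition": partition,
                "stratum": stratum,
                "n": n,
                "percent": 100.0 * n / denom if denom else np.nan,
                "mean_t": float(t[mask].mean()) if n else np.nan,
                "sd_t": float(t[mask].std(ddof=1)) if n > 1 else np.nan,
            }
        )

    n_total = len(t)
    add_row("total", "total", np.ones(n_total, dtype=bool), n_total)

    for partition, column, strata in (
        ("gender", "gender", ("male", "female")),
        ("age", "age_bin", AGE_BINS),
    ):
        col = covariates[column].astype("object")
        known = col.notna().to_numpy()
        denom = int(known.sum())
        for stratum in strata:
            add_row(partition, stratum, (col == stratum).to_numpy() & known, denom)
        if (~known).any():
            add_row(partition, "unknown", ~known, n_total)

    return ReferenceTable(pd.DataFrame(rows))


def classify_scores(
    scores: LatentScores | np.ndarray,
    thresholds: SeverityThresholds,
    round_scores: bool = True,
) -> tuple[dict[str, float], pd.Series]:
    """Percentage of persons per severity category plus per-person labels.

    The normal band includes the mild cutoff (<= mild); mild is
    (mild, moderate]; moderate is (moderate, severe]; severe is above
    the severe cutoff.  With ``round_scores`` (default) T-scores are
    rounded to integers first, emulating reporting against integer
    cutoff ranges.
    """
    t = scores.t if isinstance(scores, LatentScores) else np.asarray(scores, dtype=float)
    vals = np.round(t) if round_scores else t
    labels = np.select(
        [vals <= thresholds.mild, vals <= thresholds.moderate, vals <= thresholds.severe],
        CATEGORY_LABELS[:3],
        default=CATEGORY_LABELS[3],
    )
    series = pd.Series(labels, name="severity")
    pct = {
        lab: float(100.0 * np.mean(labels == lab)) for lab in CATEGORY_LABELS
    }
    return pct, series
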