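"""Transcriptome-instability (TIN) estimates from FIRMA scores.

Exons are called aberrantly spliced when their FIRMA score falls outside
dataset-wide percentile thresholds (by default the lower and upper 1st
percentiles of the pooled exon x sample score distribution). Per-sample
counts of aberrant skipping (below the lower threshold) and inclusion
(above the upper threshold) are then expressed on a log2 scale relative
to the dataset-average count. The TIN-estimate of a sample is

    T_s = log2(total aberrant exons in s / mean total over samples),

so T_s = +1 means twice as much aberrant splicing as the average sample
and T_s = -1 half as much; samples with |T_s| >= 1.0 are TIN-samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .firma import FirmaScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AberranceThresholds",
    "TinProfile",
    "compute_thresholds",
    "count_aberrant_exons",
    "compute_tin_estimates",
]

#: replacement for a zero count before forming log2 ratios
ZERO_COUNT_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class AberranceThresholds:
    """Aberrant skipping / inclusion cutoffs, log2 FIRMA units."""

    lower: float
    upper: float
    lower_percentile: float = 1.0
    upper_percentile: float = 99.0

    def __post_init__(self) -> None:
        if not (0 < self.lower_percentile < self.upper_percentile < 100):
            raise ValueError("percentiles must satisfy 0 < lower < upper < 100")
        if self.lower > self.upper:
            raise ValueError("lower threshold exceeds upper threshold")


@dataclass
class TinProfile:
    """Per-sample aberrance counts, relative log2 amounts and TIN flags.

    ``table`` columns: skip_count, incl_count, total_count, rel_skip,
    rel_incl, tin_estimate, is_tin_sample (indexed by sample id).
    """

    table: pd.DataFrame
    tin_cutoff: float
    tin_range: float

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def tin_estimates(self) -> pd.Series:
        return self.table["tin_estimate"]

    @property
    def tin_samples(self) -> list[str]:
        return list(self.table.index[self.table["is_tin_sample"]])


def compute_thresholds(
    scores: FirmaScoreMatrix,
    lower_percentile: float = 1.0,
    upper_percentile: float = 99.0,
) -> AberranceThresholds:
    """Empirical percentiles of the pooled exon x sample score set.

    Linear-interpolation quantile convention. Percentiles are computed
    across the whole dataset pool, not per sample.
    """
    pool = scores.pooled()
    if pool.size == 0:
        raise ValueError("empty score matrix")
    if pool.size < 100.0 / lower_percentile:
        warnings.warn(
            "fewer than 100/lower_percentile scores: thresholds rest on extreme order statistics"
        )
    lower, upper = np.percentile(pool, [lower_percentile, upper_percentile], method="linear")
    if lower == upper:
        warnings.warn("degenerate score distribution: lower and upper thresholds coincide")
    return AberranceThresholds(
        lower=float(lower),
        upper=float(upper),
        lower_percentile=lower_percentile,
        upper_percentile=upper_percentile,
    )


def count_aberrant_exons(
    scores: FirmaScoreMatrix, thr: AberranceThresholds
) -> pd.DataFrame:
    """Per-sample counts of exons strictly exceeding the thresholds.

    skip_count(i) = #{exons k : score(k, i) < lower};
    incl_count(i) = #{exons k : score(k, i) > upper}.
    Scores exactly at a threshold are not counted.
    """
    arr = scores.scores.to_numpy(dtype=float)
    skip = (arr < thr.lower).sum(axis=0)
    incl = (arr > thr.upper).sum(axis=0)
    return pd.DataFrame(
        {"skip_count": skip, "incl_count": incl},
        index=scores.scores.columns,
    )


def _relative_log2(counts: np.ndarray) -> np.ndarray:
    """log2 of counts over their arithmetic mean, zeros -> pseudocount."""
    c = counts.astype(float).copy()
    if (c == 0).any():
        logger.info(
            "%d zero counts replaced by pseudocount %.1f", (c == 0).sum(), ZERO_COUNT_PSEUDOCOUNT
        )
        c[c == 0] = ZERO_COUNT_PSEUDOCOUNT
    return np.log2(c / c.mean())


def compute_tin_estimates(
    counts: pd.DataFrame,
    tin_cutoff: float = 1.0,
    mode: str = "total",
) -> TinProfile:
    """TIN-estimates from per-sample skip/inclusion counts.

    ``mode='total'`` (default): T_s = log2(total_s / mean total) — the
    total amount of aberrant skipping plus inclusion relative to the
    dataset average. ``mode='sum_components'``: T_s = rel_skip + rel_incl
    (an alternative reading, kept as a switch).
    """
    if mode not in ("total", "sum_components"):
        raise ValueError(f"unknown TIN mode: {mode!r}")
    if len(counts) < 2:
        raise ValueError("TIN-estimates need at least 2 samples")
    skip = counts["skip_count"].to_numpy()
    incl = counts["incl_count"].to_numpy()
    total = skip + incl
    if (total == 0).all():
        raise ValueError("all samples have zero aberrant-exon counts; no aberrance signal")

    rel_skip = _relative_log2(skip)
    rel_incl = _relative_log2(incl)
    if mode == "total":
        tin = _relative_log2(total)
    else:
        tin = rel_skip + rel_incl

    table = pd.DataFrame(
        {
            "skip_count": skip,
            "incl_count": incl,
            "total_count": total,
            "rel_skip": rel_skip,
            "rel_incl": rel_incl,
            "tin_estimate": tin,
            "is_tin_sample": np.abs(tin) >= tin_cutoff,
        },
        index=counts.index,
    )
    tin_range = float(tin.max() - tin.min())
    return TinProfile(table=table, tin_cutoff=tin_cutoff, tin_range=tin_range)
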