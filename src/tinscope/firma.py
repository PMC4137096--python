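"""FIRMA exon-level splicing scores.

A FIRMA score summarizes, for one exon (probeset) in one sample, how far
that exon's probes deviate from the additive gene model fitted across all
samples: the median of the model residuals over the probes of the
probeset, in log2 units. Strongly positive scores indicate differential
exon inclusion, strongly negative scores differential skipping, relative
to the other samples in the dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ExonAnnotation, GeneModelFit

logger = logging.getLogger(__name__)

__all__ = ["FirmaScoreMatrix", "firma_scores"]


@dataclass
class FirmaScoreMatrix:
    """Exon (probeset) x sample splicing scores, log2 residual units."""

    scores: pd.DataFrame
    source_dataset: str = ""

    def __post_init__(self) -> None:
        arr = self.scores.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("FIRMA scores must be finite")

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)

    def pooled(self) -> np.ndarray:
        """All exon x sample scores as a flat vector (dataset pool)."""
        return self.scores.to_numpy(dtype=float).ravel()


def firma_scores(
    fits: dict[str, GeneModelFit],
    annotation: ExonAnnotation,
    source_dataset: str = "",
) -> FirmaScoreMatrix:
    """Median probe residual per probeset and sample.

    Probesets with no probes present in the fitted data are dropped with
    a warning. Row order follows the annotation's probeset order.
    """
    probeset_of = annotation.probeset_of_probe()
    frames = []
    for cluster, fit in fits.items():
        resid = fit.residuals  # samples x probes
        groups = probeset_of.reindex(resid.columns)
        med = resid.T.groupby(groups, sort=False).median()  # probesets x samples
        frames.append(med)
    if not frames:
        raise ValueError("no fitted clusters to score")
    scores = pd.concat(frames)

    wanted = annotation.table["probeset_id"].drop_duplicates()
    missing = wanted[~wanted.isin(scores.index)]
    if len(missing):
        logger.warning(
            "%d probesets have no probes in the data and were dropped (e.g. %s)",
            len(missing),
            missing.iloc[0],
        )
    scores = scores.reindex(wanted[wanted.isin(scores.index)])
    scores.index.name = "probeset_id"
    return FirmaScoreMatrix(scores=scores, source_dataset=source_dataset)
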