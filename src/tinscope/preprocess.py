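"""Probe-level preprocessing: quantile normalization and additive gene models.

The exon-array pipeline models every transcript cluster (gene) as an
additive two-way table in log2 space,

    log2(PM_ij) = m + c_i + p_j + eps_ij,

with a chip (sample) effect ``c_i``, a probe effect ``p_j`` and a residual
``eps_ij``, fitted robustly by Tukey median polish as in RMA summarization.
The residuals are the raw material for exon-level splicing scores; the
fitted ``m + c_i`` is the gene-level expression summary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeIntensityMatrix",
    "ExonAnnotation",
    "GeneModelFit",
    "quantile_normalize",
    "median_polish",
    "fit_gene_models",
    "gene_level_expression",
]


@dataclass
class ProbeIntensityMatrix:
    """Raw linear-scale intensities, probes x samples.

    ``values`` is a DataFrame indexed by probe id with one column per
    sample. All entries must be strictly positive and both index and
    columns unique.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = v.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("intensity matrix contains missing values")
        if (arr <= 0).any():
            raise ValueError("intensity matrix must be strictly positive")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ExonAnnotation:
    """Probe -> probeset (exon) -> transcript cluster (gene) hierarchy.

    ``table`` has columns probe_id, probeset_id, transcript_cluster_id.
    Each probe appears exactly once and each probeset belongs to exactly
    one transcript cluster.
    """

    table: pd.DataFrame

    REQUIRED = ("probe_id", "probeset_id", "transcript_cluster_id")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        t = self.table
        if t["probe_id"].duplicated().any():
            dups = t.loc[t["probe_id"].duplicated(), "probe_id"].tolist()
            raise ValueError(f"probe annotated more than once: {dups[:5]}")
        n_clusters = t.groupby("probeset_id")["transcript_cluster_id"].nunique()
        bad = n_clusters[n_clusters > 1]
        if len(bad):
            raise ValueError(
                f"probesets mapped to multiple transcript clusters: {list(bad.index)[:5]}"
            )

    def probes_by_cluster(self) -> dict[str, list[str]]:
        return {
            str(k): list(g) for k, g in self.table.groupby("transcript_cluster_id")["probe_id"]
        }

    def probeset_of_probe(self) -> pd.Series:
        return self.table.set_index("probe_id")["probeset_id"]


@dataclass
class GeneModelFit:
    """Median-polish fit of one transcript cluster.

    overall ``m`` plus chip effects (per sample), probe effects (per probe)
    and the residual table (samples x probes), all in log2 units. The
    reconstruction m + c_i + p_j + eps_ij recovers the input exactly.
    """

    overall: float
    chip_effects: pd.Series
    probe_effects: pd.Series
    residuals: pd.DataFrame  # samples x probes
    iterations_used: int
    converged: bool
    _log2_input: pd.DataFrame | None = field(default=None, repr=False)

    def reconstruct(self) -> pd.DataFrame:
        return (
            self.residuals
            + self.overall
            + np.add.outer(self.chip_effects.to_numpy(), self.probe_effects.to_numpy())
        )


def quantile_normalize(matrix: ProbeIntensityMatrix) -> ProbeIntensityMatrix:
    """Force all samples onto the mean order-statistic distribution.

    Every column of the result has the identical sorted multiset (the
    across-sample mean of order statistics); within-column ranks are
    preserved. Ties within a column get the mean of the reference values
    spanned by the tied ranks, so the map is well defined and idempotent.
    """
    df = matrix.values
    if df.shape[1] < 2:
        warnings.warn("quantile normalization with a single sample is the identity")
        return ProbeIntensityMatrix(df.copy())

    arr = df.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # ties: average reference values across the tied block
        s = pd.Series(assigned)
        out[:, j] = s.groupby(col, sort=False).transform("mean").to_numpy()
    return ProbeIntensityMatrix(pd.DataFrame(out, index=df.index, columns=df.columns))


def median_polish(
    table: np.ndarray | pd.DataFrame,
    max_iter: int = 10,
    tol: float = 1e-4,
) -> GeneModelFit:
    """Tukey median polish of a samples x probes log2 table (rows first).

    Alternates row- and column-median sweeps until the largest absolute
    median removed in a sweep is <= ``tol`` or ``max_iter`` sweeps are
    reached. Median of an even count is the mean of the two central values.
    """
    if isinstance(table, pd.DataFrame):
        values = table.to_numpy(dtype=float)
        row_index, col_index = table.index, table.columns
    else:
        values = np.asarray(table, dtype=float)
        if values.ndim == 1:
            values = values[None, :]
        row_index = pd.RangeIndex(values.shape[0])
        col_index = pd.RangeIndex(values.shape[1])
    if values.size == 0:
        raise ValueError("median polish of an empty matrix")
    if np.isnan(values).any():
        raise ValueError("median polish requires complete data")

    z = values.copy()
    n, p = z.shape
    overall = 0.0
    row_eff = np.zeros(n)
    col_eff = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rdelta = np.median(z, axis=1)
        z -= rdelta[:, None]
        row_eff += rdelta
        delta = np.median(col_eff)
        col_eff -= delta
        overall += delta

        cdelta = np.median(z, axis=0)
        z -= cdelta[None, :]
        col_eff += cdelta
        delta = np.median(row_eff)
        row_eff -= delta
        overall += delta

        change = max(np.abs(rdelta).max(), np.abs(cdelta).max())
        if change <= tol:
            converged = True
            break

    return GeneModelFit(
        overall=float(overall),
        chip_effects=pd.Series(row_eff, index=row_index),
        probe_effects=pd.Series(col_eff, index=col_index),
        residuals=pd.DataFrame(z, index=row_index, columns=col_index),
        iterations_used=it,
        converged=converged,
    )


def fit_gene_models(
    normalized: ProbeIntensityMatrix,
    annotation: ExonAnnotation,
    max_iter: int = 10,
    tol: float = 1e-4,
    background_offset: float = 0.0,
) -> dict[str, GeneModelFit]:
    """Fit one additive gene model per transcript cluster.

    Intensities are log2-transformed (after subtracting an optional
    constant background offset) and each cluster's samples x probes block
    is median-polished independently. Every probe in the matrix must be
    annotated.
    """
    df = normalized.values
    if background_offset:
        df = df - background_offset
        if (df.to_numpy() <= 0).any():
            raise ValueError("background offset drives intensities non-positive")
    annotated = set(annotation.table["probe_id"])
    unknown = [p for p in df.index if p not in annotated]
    if unknown:
        raise ValueError(f"probes without annotation: {unknown[:5]}")

    log2 = np.log2(df)
    fits: dict[str, GeneModelFit] = {}
    for cluster, probes in annotation.probes_by_cluster().items():
        probes_present = [p for p in probes if p in log2.index]
        if not probes_present:
            continue
        block = log2.loc[probes_present].T  # samples x probes
        fits[cluster] = median_polish(block, max_iter=max_iter, tol=tol)
    return fits


def gene_level_expression(
    fits: dict[str, GeneModelFit], sample_ids: list[str] | None = None
) -> pd.DataFrame:
    """RMA-style gene summaries: expression(g, i) = m_g + c_gi (log2)."""
    if not fits:
        raise ValueError("no fitted gene models")
    rows = {}
    for cluster, fit in fits.items():
        rows[cluster] = fit.overall + fit.chip_effects
    expr = pd.DataFrame(rows).T
    if sample_ids is not None:
        expr = expr.loc[:, list(sample_ids)]
    expr.index.name = "gene_id"
    return expr
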