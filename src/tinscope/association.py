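"""Association between TIN-estimates and gene expression.

Per-gene Pearson correlation with two-sided Student p-values
(t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom), set-level
summaries (percent significant, sign balance, mean strengths), a
pooled-variance two-group t-test for subgroup comparisons, and paired
cancer-normal TIN correlation. No multiple-testing correction is applied
anywhere: inference on the set level rests on the resampling nulls in
:mod:`tinscope.nulls`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tin import TinProfile

__all__ = [
    "CorrelationRecord",
    "CorrelationResult",
    "AssociationSummary",
    "correlate_genes_with_tin",
    "summarize_association",
    "independent_ttest",
    "paired_tin_correlation",
    "pearson_with_p",
]


@dataclass(frozen=True)
class CorrelationRecord:
    gene_id: str
    r: float
    p: float
    n: int
    significant: bool
    degenerate: bool = False


@dataclass
class CorrelationResult:
    """Per-gene correlation records plus genes skipped (absent from expr)."""

    records: list[CorrelationRecord]
    skipped: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(rec) for rec in self.records]).set_index("gene_id")


@dataclass
class AssociationSummary:
    set_name: str
    n_genes_tested: int
    pct_significant: float
    mean_r_significant: float
    n_neg_significant: int
    n_pos_significant: int
    neg_pos_ratio: float  # inf when no positive significant genes
    mean_abs_r: float
    alpha: float = 0.05


def pearson_with_p(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Pearson r of ``X`` (genes x n) against ``y`` (n,) with p.

    Returns (r, p, degenerate). Degenerate rows (zero variance in the gene
    or in y) get r = 0, p = 1 and the degenerate flag.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    xnorm = np.sqrt((Xc**2).sum(axis=1))
    ynorm = math.sqrt((yc**2).sum())
    degenerate = (xnorm == 0) | (ynorm == 0)
    denom = np.where(degenerate, 1.0, xnorm * (ynorm if ynorm > 0 else 1.0))
    r = (Xc @ yc) / denom
    r = np.clip(np.where(degenerate, 0.0, r), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(degenerate, 1.0, np.minimum(p, 1.0))
    return r, p, degenerate


def correlate_genes_with_tin(
    expr: pd.DataFrame,
    tin: TinProfile,
    gene_set: list[str],
    alpha: float = 0.05,
) -> CorrelationResult:
    """Pearson correlation of each gene-set member's expression with T_s.

    ``expr`` is genes x samples (log2); its columns must cover the TIN
    profile's samples. Genes absent from ``expr`` are reported in the
    skipped list. Zero-variance genes yield degenerate records excluded
    from downstream summaries.
    """
    samples = tin.sample_ids
    missing_samples = [s for s in samples if s not in expr.columns]
    if missing_samples:
        raise ValueError(f"expression matrix lacks samples: {missing_samples[:5]}")
    n = len(samples)
    if n < 3:
        raise ValueError("Pearson p-values need at least 3 samples")

    present = [g for g in gene_set if g in expr.index]
    skipped = [g for g in gene_set if g not in expr.index]
    if not present:
        raise ValueError("no gene-set members present in the expression matrix")

    X = expr.loc[present, samples].to_numpy(dtype=float)
    y = tin.tin_estimates.to_numpy(dtype=float)
    r, p, degen = pearson_with_p(X, y)
    records = [
        CorrelationRecord(
            gene_id=g,
            r=float(ri),
            p=float(pi),
            n=n,
            significant=bool((pi < alpha) and not di),
            degenerate=bool(di),
        )
        for g, ri, pi, di in zip(present, r, p, degen)
    ]
    return CorrelationResult(records=records, skipped=skipped)


def summarize_association(
    records: list[CorrelationRecord] | CorrelationResult,
    alpha: float = 0.05,
    set_name: str = "",
) -> AssociationSummary:
    """Set-level summary: percent significant at p < alpha, sign balance,
    mean r over significant genes, mean |r| over all non-degenerate genes."""
    if isinstance(records, CorrelationResult):
        records = records.records
    usable = [rec for rec in records if not rec.degenerate]
    if not usable:
        raise ValueError("all correlation records are degenerate")
    sig = [rec for rec in usable if rec.p < alpha]
    n_neg = sum(1 for rec in sig if rec.r < 0)
    n_pos = sum(1 for rec in sig if rec.r > 0)
    ratio = float("inf") if n_pos == 0 else n_neg / n_pos
    return AssociationSummary(
        set_name=set_name,
        n_genes_tested=len(usable),
        pct_significant=100.0 * len(sig) / len(usable),
        mean_r_significant=float(np.mean([rec.r for rec in sig])) if sig else float("nan"),
        n_neg_significant=n_neg,
        n_pos_significant=n_pos,
        neg_pos_ratio=ratio,
        mean_abs_r=float(np.mean([abs(rec.r) for rec in usable])),
        alpha=alpha,
    )


def independent_ttest(tin: TinProfile, labels: pd.Series) -> tuple[float, float]:
    """Two-sided pooled-variance Student t-test on TIN-estimates by group."""
    labels = labels.reindex(tin.sample_ids).dropna()
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(groups)}")
    a = tin.tin_estimates.loc[labels.index[labels == groups[0]]].to_numpy()
    b = tin.tin_estimates.loc[labels.index[labels == groups[1]]].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("degenerate separation: zero pooled variance with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def paired_tin_correlation(
    tin_a: TinProfile,
    tin_b: TinProfile,
    pairing: dict[str, str],
) -> tuple[CorrelationRecord, list[str]]:
    """Pearson correlation of TIN-estimates over matched sample pairs.

    ``pairing`` maps sample ids of cohort A to sample ids of cohort B;
    the two cohorts are scored as separate datasets beforehand. Pairs
    referencing a missing sample are skipped and reported.
    """
    a_vals, b_vals, skipped = [], [], []
    ta, tb = tin_a.tin_estimates, tin_b.tin_estimates
    for sa, sb in pairing.items():
        if sa in ta.index and sb in tb.index:
            a_vals.append(ta[sa])
            b_vals.append(tb[sb])
        else:
            skipped.append(sa)
    if len(a_vals) < 3:
        raise ValueError(f"need at least 3 complete pairs, got {len(a_vals)}")
    r, p, degen = pearson_with_p(np.asarray(a_vals)[None, :], np.asarray(b_vals))
    rec = CorrelationRecord(
        gene_id="paired_tin",
        r=float(r[0]),
        p=float(p[0]),
        n=len(a_vals),
        significant=bool(p[0] < 0.05 and not degen[0]),
        degenerate=bool(degen[0]),
    )
    return rec, skipped
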