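"""Unsupervised structure checks on splicing-factor expression.

PCA by singular value decomposition of the (unscaled) covariance matrix,
with samples as observations and genes as variables; agglomerative
hierarchical clustering with Euclidean distance and complete linkage;
and a quantitative separation score for the visual claim that high- and
low-TIN samples split in the PC1/PC2 plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .tin import TinProfile

__all__ = ["PcaResult", "Dendrogram", "pca_covariance", "hierarchical_clustering", "tin_separation"]


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components
    variance_fraction: np.ndarray


@dataclass
class Dendrogram:
    """Merge table (scipy linkage convention) and ordered leaves."""

    linkage: np.ndarray  # (n-1) x 4: cluster_a, cluster_b, height, size
    leaf_order: list[str]
    sample_ids: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def pca_covariance(expr: pd.DataFrame) -> PcaResult:
    """PCA of samples in gene space via SVD of the centered data.

    ``expr`` is genes x samples. Variables (genes) are centered across
    samples but not scaled, so components diagonalize the covariance
    matrix. Component signs are fixed by making the largest-|loading|
    entry of each component positive.
    """
    X = expr.to_numpy(dtype=float).T  # samples x genes
    n, g = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    if not Xc.any():
        raise ValueError("zero total variance")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-magnitude loading positive per component
    for k in range(len(s)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = U * s
    var = s**2
    frac = var / var.sum()
    comps = [f"PC{k + 1}" for k in range(len(s))]
    return PcaResult(
        scores=pd.DataFrame(scores, index=expr.columns, columns=comps),
        loadings=pd.DataFrame(Vt.T, index=expr.index, columns=comps),
        variance_fraction=frac,
    )


def hierarchical_clustering(expr: pd.DataFrame) -> Dendrogram:
    """Complete-linkage agglomeration of samples on Euclidean distance.

    ``expr`` is genes x samples; samples are the leaves.
    """
    X = expr.to_numpy(dtype=float).T  # samples x genes
    if X.shape[0] < 2:
        raise ValueError("clustering needs at least 2 samples")
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method="complete")
    order = hierarchy.leaves_list(Z)
    sample_ids = list(expr.columns)
    return Dendrogram(
        linkage=Z,
        leaf_order=[sample_ids[i] for i in order],
        sample_ids=sample_ids,
    )


def tin_separation(pca: PcaResult, tin: TinProfile, cutoff: float | None = None) -> float:
    """Ranking score for high- vs low-TIN separation in the PC1/PC2 plane.

    Only samples with |T_s| >= cutoff (the profile's TIN cutoff by
    default) enter. For every (high, low) pair the Fisher discriminant
    direction of the first two PC scores is computed from the *other*
    samples (leave-pair-out), and the pair counts as separated when the
    high sample projects above the low one. The score is the fraction of
    separated pairs: 1.0 = perfect separation, 0.5 = none. Leaving the
    scored pair out keeps the score unbiased at 0.5 under label
    exchange.
    """
    if cutoff is None:
        cutoff = tin.tin_cutoff
    est = tin.tin_estimates.reindex(pca.scores.index)
    high = est.index[est >= cutoff]
    low = est.index[est <= -cutoff]
    if len(high) == 0 or len(low) == 0:
        raise ValueError("few samples with TIN-estimates >= ±%.1f" % cutoff)
    ncomp = min(2, pca.scores.shape[1])
    A = pca.scores.loc[high].iloc[:, :ncomp].to_numpy()
    B = pca.scores.loc[low].iloc[:, :ncomp].to_numpy()
    # pooled within-group covariance; ridge keeps the direction defined
    # for singleton groups and degenerate planes
    resid = np.vstack([A - A.mean(axis=0), B - B.mean(axis=0)])
    S = resid.T @ resid / max(len(resid) - 2, 1) + 1e-9 * np.eye(ncomp)
    Sinv = np.linalg.inv(S)

    sumA, sumB = A.sum(axis=0), B.sum(axis=0)
    nA, nB = len(A), len(B)
    hits = 0.0
    for i in range(nA):
        muA = (sumA - A[i]) / (nA - 1) if nA > 1 else A[i]
        for j in range(nB):
            muB = (sumB - B[j]) / (nB - 1) if nB > 1 else B[j]
            w = Sinv @ (muA - muB)
            d = (A[i] - B[j]) @ w
            hits += 1.0 if d > 0 else (0.5 if d == 0 else 0.0)
    return float(hits / (nA * nB))
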