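"""Empirical null distributions for the TIN / splicing-factor association.

Two resampling nulls, mirroring each other:

* **permutation null** — permute the TIN-estimate vector across samples
  B times and recompute the set statistic for the fixed gene set;
* **random-gene-set null** — draw B gene sets of matched size uniformly
  without replacement from the full expression universe (the focal set's
  genes are not excluded) and recompute the statistic against the fixed
  TIN vector.

Empirical p-values use the add-one estimator (b+1)/(B+1), whose minimum
with B = 1,000 resamples is 1/1001 ~ 0.001; ties count as extreme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import pearson_with_p
from .tin import TinProfile

__all__ = [
    "NullDistribution",
    "STATISTICS",
    "permutation_null",
    "random_geneset_null",
    "empirical_p",
    "geneset_battery",
]

STATISTICS = ("pct_significant", "neg_pos_ratio", "mean_abs_r")


@dataclass
class NullDistribution:
    statistic_name: str
    observed: float
    null_values: np.ndarray
    direction: str  # "greater" | "less"
    empirical_p: float
    seed: int
    B: int = field(init=False)

    def __post_init__(self) -> None:
        self.B = len(self.null_values)


def empirical_p(observed: float, null_values: np.ndarray, direction: str = "greater") -> float:
    """Add-one empirical p: (b+1)/(B+1), ties as-or-more-extreme."""
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValueError("empty null distribution")
    if direction == "greater":
        b = int((null_values >= observed).sum())
    elif direction == "less":
        b = int((null_values <= observed).sum())
    else:
        raise ValueError(f"unknown direction: {direction!r}")
    return (b + 1) / (null_values.size + 1)


def _statistic_from_rp(
    r: np.ndarray, p: np.ndarray, degenerate: np.ndarray, statistic_name: str, alpha: float
) -> float:
    """Set statistic from per-gene (r, p) vectors; degenerate genes excluded."""
    ok = ~degenerate
    if not ok.any():
        return float("nan")
    r, p = r[ok], p[ok]
    sig = p < alpha
    if statistic_name == "pct_significant":
        return 100.0 * sig.mean()
    if statistic_name == "neg_pos_ratio":
        n_neg = int((sig & (r < 0)).sum())
        n_pos = int((sig & (r > 0)).sum())
        return float("inf") if n_pos == 0 else n_neg / n_pos
    if statistic_name == "mean_abs_r":
        return float(np.abs(r).mean())
    raise ValueError(f"unknown statistic: {statistic_name!r} (use one of {STATISTICS})")


def _aligned_matrix(expr: pd.DataFrame, tin: TinProfile, gene_ids: list[str]) -> np.ndarray:
    present = [g for g in gene_ids if g in expr.index]
    if not present:
        raise ValueError("no genes of the set present in the expression matrix")
    return expr.loc[present, tin.sample_ids].to_numpy(dtype=float)


def permutation_null(
    expr: pd.DataFrame,
    tin: TinProfile,
    gene_set: list[str],
    statistic_name: str = "pct_significant",
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    direction: str = "greater",
) -> NullDistribution:
    """Null from B permutations of the TIN vector, fixed gene set."""
    if B < 1:
        raise ValueError("B must be >= 1")
    X = _aligned_matrix(expr, tin, gene_set)
    y = tin.tin_estimates.to_numpy(dtype=float)

    r_obs, p_obs, degen = pearson_with_p(X, y)
    observed = _statistic_from_rp(r_obs, p_obs, degen, statistic_name, alpha)

    rng = np.random.default_rng(seed)
    n = y.size
    nulls = np.empty(B)
    # one matrix product per batch of permutations
    perms = np.stack([rng.permutation(y) for _ in range(B)])  # B x n
    Xc = X - X.mean(axis=1, keepdims=True)
    xnorm = np.sqrt((Xc**2).sum(axis=1))
    gene_degen = xnorm == 0
    Pc = perms - perms.mean(axis=1, keepdims=True)
    pnorm = np.sqrt((Pc**2).sum(axis=1))
    pnorm[pnorm == 0] = 1.0
    R = (Xc @ Pc.T) / np.outer(np.where(gene_degen, 1.0, xnorm), pnorm)  # genes x B
    R = np.clip(R, -1.0, 1.0)
    from scipy import stats as _st

    with np.errstate(divide="ignore"):
        T = R * np.sqrt((n - 2) / np.maximum(1.0 - R**2, np.finfo(float).tiny))
    P = 2.0 * _st.t.sf(np.abs(T), df=n - 2)
    for b in range(B):
        nulls[b] = _statistic_from_rp(R[:, b], P[:, b], gene_degen, statistic_name, alpha)

    return NullDistribution(
        statistic_name=statistic_name,
        observed=float(observed),
        null_values=nulls,
        direction=direction,
        empirical_p=empirical_p(observed, nulls, direction),
        seed=seed,
    )


def random_geneset_null(
    expr: pd.DataFrame,
    tin: TinProfile,
    set_size: int,
    statistic_name: str = "pct_significant",
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    direction: str = "greater",
    observed: float | None = None,
    gene_set: list[str] | None = None,
) -> NullDistribution:
    """Null from B random gene sets of ``set_size`` drawn from the full
    universe of ``expr`` genes (focal genes included), fixed TIN vector.

    ``observed`` is taken from ``gene_set`` when given, else must be
    supplied directly.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    universe = list(expr.index)
    if set_size > len(universe):
        raise ValueError(f"set_size {set_size} exceeds universe of {len(universe)} genes")
    if set_size == len(universe):
        import warnings

        warnings.warn("set_size equals the universe: zero-variance null")

    y = tin.tin_estimates.to_numpy(dtype=float)
    X_all = expr.loc[:, tin.sample_ids].to_numpy(dtype=float)
    r_all, p_all, degen_all = pearson_with_p(X_all, y)

    if observed is None:
        if gene_set is None:
            raise ValueError("provide either observed or gene_set")
        idx = pd.Index(universe).get_indexer([g for g in gene_set if g in expr.index])
        observed = _statistic_from_rp(
            r_all[idx], p_all[idx], degen_all[idx], statistic_name, alpha
        )

    rng = np.random.default_rng(seed)
    nulls = np.empty(B)
    n_genes = len(universe)
    for b in range(B):
        pick = rng.choice(n_genes, size=set_size, replace=False)
        nulls[b] = _statistic_from_rp(
            r_all[pick], p_all[pick], degen_all[pick], statistic_name, alpha
        )

    return NullDistribution(
        statistic_name=statistic_name,
        observed=float(observed),
        null_values=nulls,
        direction=direction,
        empirical_p=empirical_p(observed, nulls, direction),
        seed=seed,
    )


def geneset_battery(
    expr: pd.DataFrame,
    tin: TinProfile,
    genesets: dict[str, list[str]],
    statistic_name: str = "pct_significant",
    alpha: float = 0.05,
    focal_set: str | None = None,
) -> tuple[pd.DataFrame, list[str], int | None]:
    """Summaries for a collection of gene sets plus a whole-genome row.

    Returns (table, skipped set names, rank of the focal set by the
    chosen statistic, 1 = highest). Sets with no genes present in the
    expression matrix are skipped and reported.
    """
    if not genesets:
        raise ValueError("empty gene-set collection")
    y = tin.tin_estimates.to_numpy(dtype=float)
    X_all = expr.loc[:, tin.sample_ids].to_numpy(dtype=float)
    r_all, p_all, degen_all = pearson_with_p(X_all, y)
    index = pd.Index(expr.index)

    rows, skipped = [], []
    for name, members in genesets.items():
        idx = index.get_indexer([g for g in members if g in expr.index])
        if len(idx) == 0 or (degen_all[idx]).all():
            skipped.append(name)
            continue
        rows.append(
            {
                "set_name": name,
                "n_genes_tested": int((~degen_all[idx]).sum()),
                statistic_name: _statistic_from_rp(
                    r_all[idx], p_all[idx], degen_all[idx], statistic_name, alpha
                ),
            }
        )
    rows.append(
        {
            "set_name": "__genome__",
            "n_genes_tested": int((~degen_all).sum()),
            statistic_name: _statistic_from_rp(r_all, p_all, degen_all, statistic_name, alpha),
        }
    )
    table = pd.DataFrame(rows).set_index("set_name")

    rank = None
    if focal_set is not None and focal_set in table.index:
        ranked = table[statistic_name].rank(ascending=False, method="min")
        rank = int(ranked.loc[focal_set])
    return table, skipped, rank
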