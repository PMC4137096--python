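"""End-to-end orchestration: single-dataset and pooled (pan-cancer) runs.

One normalized fit drives everything downstream: quantile normalization,
per-gene median-polish models, FIRMA scores, pooled percentile
thresholds, per-sample TIN-estimates, gene-level expression,
splicing-factor association and both resampling nulls, then PCA and
hierarchical clustering on the focal gene set. Every random draw flows
from a single root seed recorded in the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd

from . import association as assoc
from . import multivariate, nulls
from .firma import FirmaScoreMatrix, firma_scores
from .preprocess import (
    ExonAnnotation,
    ProbeIntensityMatrix,
    fit_gene_models,
    gene_level_expression,
    quantile_normalize,
)
from .tin import TinProfile, compute_thresholds, compute_tin_estimates, count_aberrant_exons

logger = logging.getLogger(__name__)

__all__ = ["DatasetBundle", "AnalysisReport", "DEFAULT_CONFIG", "run_dataset_analysis", "run_pan_cancer"]

DEFAULT_CONFIG: dict[str, Any] = {
    "polish": {"max_iter": 10, "tol": 1e-4},
    "background": {"offset": 0.0},
    "thresholds": {"lower_percentile": 1.0, "upper_percentile": 99.0},
    "tin": {"cutoff": 1.0, "mode": "total"},
    "association": {"alpha": 0.05},
    "nulls": {"B": 1000, "statistic": "pct_significant", "direction": "greater"},
}


def merge_config(overrides: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for section, vals in (overrides or {}).items():
        cfg.setdefault(section, {}).update(vals)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class DatasetBundle:
    """One dataset's inputs: intensities, annotation, optional metadata."""

    name: str
    intensities: ProbeIntensityMatrix
    annotation: ExonAnnotation
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.metadata is not None:
            extra = [s for s in self.metadata.index if s not in self.intensities.sample_ids]
            if extra:
                raise ValueError(f"metadata samples absent from intensities: {extra[:5]}")
        annotated = set(self.annotation.table["probe_id"])
        unknown = [p for p in self.intensities.probe_ids if p not in annotated]
        if unknown:
            raise ValueError(f"probes not covered by annotation: {unknown[:5]}")


@dataclass
class AnalysisReport:
    dataset_name: str
    thresholds: Any
    tin: TinProfile
    firma: FirmaScoreMatrix
    expression: pd.DataFrame
    correlations: dict[str, assoc.CorrelationResult]
    summaries: dict[str, assoc.AssociationSummary]
    null_distributions: dict[str, nulls.NullDistribution]
    pca: multivariate.PcaResult | None
    dendrogram: multivariate.Dendrogram | None
    tin_separation: float | None
    seed: int
    config: dict
    config_hash: str = ""
    version: str = "0.1.0"

    def __post_init__(self) -> None:
        if not self.config_hash:
            self.config_hash = config_hash(self.config)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: vars(v) for k, v in self.summaries.items()}).T


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    return wrap


def run_dataset_analysis(
    bundle: DatasetBundle,
    gene_sets: dict[str, list[str]],
    config: dict | None = None,
    seed: int = 0,
    focal_set: str | None = None,
) -> AnalysisReport:
    """Run the full single-dataset analysis.

    ``gene_sets`` maps set names to gene (transcript-cluster) ids; the
    focal set (default: the first) is used for the nulls, PCA and
    clustering.
    """
    cfg = merge_config(config)
    if not gene_sets:
        raise ValueError("at least one gene set is required")
    focal = focal_set or next(iter(gene_sets))
    if focal not in gene_sets:
        raise ValueError(f"focal set {focal!r} not in gene_sets")
    rng = np.random.SeedSequence(seed)
    seed_perm, seed_rand = (int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(2))

    logger.info("[%s] normalizing %d probes x %d samples", bundle.name,
                len(bundle.intensities.probe_ids), len(bundle.intensities.sample_ids))
    normalized = _stage("quantile_normalize")(quantile_normalize, bundle.intensities)
    fits = _stage("fit_gene_models")(
        fit_gene_models,
        normalized,
        bundle.annotation,
        max_iter=cfg["polish"]["max_iter"],
        tol=cfg["polish"]["tol"],
        background_offset=cfg["background"]["offset"],
    )
    scores = _stage("firma_scores")(firma_scores, fits, bundle.annotation, bundle.name)
    thr = _stage("compute_thresholds")(
        compute_thresholds,
        scores,
        cfg["thresholds"]["lower_percentile"],
        cfg["thresholds"]["upper_percentile"],
    )
    logger.info("[%s] thresholds: lower %.3f upper %.3f", bundle.name, thr.lower, thr.upper)
    counts = _stage("count_aberrant_exons")(count_aberrant_exons, scores, thr)
    tin = _stage("compute_tin_estimates")(
        compute_tin_estimates, counts, cfg["tin"]["cutoff"], cfg["tin"]["mode"]
    )
    expr = _stage("gene_level_expression")(
        gene_level_expression, fits, bundle.intensities.sample_ids
    )

    alpha = cfg["association"]["alpha"]
    correlations, summaries = {}, {}
    for name, members in gene_sets.items():
        res = _stage(f"correlate[{name}]")(assoc.correlate_genes_with_tin, expr, tin, members, alpha)
        correlations[name] = res
        summaries[name] = assoc.summarize_association(res, alpha, set_name=name)

    B = cfg["nulls"]["B"]
    stat = cfg["nulls"]["statistic"]
    direction = cfg["nulls"]["direction"]
    null_dists = {
        "permutation": _stage("permutation_null")(
            nulls.permutation_null, expr, tin, gene_sets[focal], stat, B, seed_perm, alpha, direction
        ),
        "random_genesets": _stage("random_geneset_null")(
            nulls.random_geneset_null,
            expr,
            tin,
            len([g for g in gene_sets[focal] if g in expr.index]),
            stat,
            B,
            seed_rand,
            alpha,
            direction,
            None,
            gene_sets[focal],
        ),
    }

    focal_expr = expr.loc[[g for g in gene_sets[focal] if g in expr.index]]
    pca = dendro = None
    separation = None
    try:
        pca = multivariate.pca_covariance(focal_expr)
        dendro = multivariate.hierarchical_clustering(focal_expr)
        separation = multivariate.tin_separation(pca, tin)
    except ValueError as exc:
        logger.warning("[%s] multivariate stage skipped: %s", bundle.name, exc)

    return AnalysisReport(
        dataset_name=bundle.name,
        thresholds=thr,
        tin=tin,
        firma=scores,
        expression=expr,
        correlations=correlations,
        summaries=summaries,
        null_distributions=null_dists,
        pca=pca,
        dendrogram=dendro,
        tin_separation=separation,
        seed=seed,
        config=cfg,
    )


def subsample_bundle(bundle: DatasetBundle, n: int, seed: int) -> DatasetBundle:
    """Uniform without-replacement sample of n columns, deterministic by seed."""
    samples = bundle.intensities.sample_ids
    if len(samples) < n:
        raise ValueError(f"bundle {bundle.name!r} has {len(samples)} samples, fewer than {n}")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(samples), size=n, replace=False))
    keep = [samples[i] for i in chosen]
    return DatasetBundle(
        name=bundle.name,
        intensities=ProbeIntensityMatrix(bundle.intensities.values[keep]),
        annotation=bundle.annotation,
        metadata=bundle.metadata.loc[bundle.metadata.index.intersection(keep)]
        if bundle.metadata is not None
        else None,
    )


def run_pan_cancer(
    bundles: list[DatasetBundle],
    gene_sets: dict[str, list[str]],
    n_per_dataset: int = 20,
    seed: int = 0,
    config: dict | None = None,
    focal_set: str | None = None,
) -> AnalysisReport:
    """Pooled analysis across datasets.

    ``n_per_dataset`` samples are drawn uniformly without replacement
    from each bundle (per-bundle seeds derived from the root seed), the
    intensity columns are pooled, and normalization, FIRMA scoring,
    thresholds and TIN-estimates are recomputed across the pooled
    samples — pooling re-scores, it does not concatenate per-dataset
    results. All bundles must share the same probe/annotation scheme.
    """
    if not bundles:
        raise ValueError("no bundles to pool")
    root = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(len(bundles) + 1)]
    picked = [
        subsample_bundle(b, n_per_dataset, child_seeds[i]) for i, b in enumerate(bundles)
    ]

    frames, meta_frames = [], []
    for b in picked:
        vals = b.intensities.values.copy()
        vals.columns = [f"{b.name}:{s}" for s in vals.columns]
        frames.append(vals)
        meta_frames.append(
            pd.DataFrame({"dataset": b.name}, index=vals.columns)
        )
    pooled_values = pd.concat(frames, axis=1)
    if pooled_values.isna().any().any():
        raise ValueError("bundles do not share a common probe universe")
    pooled = DatasetBundle(
        name="+".join(b.name for b in picked),
        intensities=ProbeIntensityMatrix(pooled_values),
        annotation=picked[0].annotation,
        metadata=pd.concat(meta_frames),
    )
    return run_dataset_analysis(
        pooled, gene_sets, config=config, seed=child_seeds[-1], focal_set=focal_set
    )
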