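"""Synthetic exon-array datasets with planted aberrant splicing.

The generator emulates the structure of a post-normalization exon array:
multi-probe probesets (exons) nested in transcript clusters (genes),
log-normal intensity noise around an additive gene model, and per-sample
aberrant exon events whose counts are coupled to a latent per-sample
splicing capacity ``z``:

* ``z_i ~ Normal(0, 1)``;
* splicing-factor (SF) genes load on z with gene-specific variation on
  top: ``a_gi = mu_g + lambda * z_i + N(0, sf_noise_sd)``; other genes
  get independent sample effects ``a_gi = mu_g + N(0, 0.5)``;
* probe affinities ``b_p`` are fixed per probe; ``log2 intensity =
  a_gi + b_p + N(0, noise_sd)``;
* each sample receives ``N_i = max(0, round(n0 * 2**(-beta * z_i)))``
  planted events (or a Poisson draw with that mean) on distinct
  (gene, exon) pairs: all probes of the chosen exon are shifted by
  ``+delta`` (inclusion) or ``-delta`` (skipping).

High z means high splicing capacity: more SF expression and fewer
aberrant events, so the planted SF / TIN association is negative —
the single minimal mechanism consistent with an inverse correlation
between splicing-factor expression and aberrant-splicing amounts.
With ``coupling_beta = 0`` the generator is a null model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ExonAnnotation, ProbeIntensityMatrix

__all__ = ["SimConfig", "SimTruth", "SimulatedDataset", "generate_dataset", "make_random_gene_universe"]


@dataclass
class SimConfig:
    """Study conditions for one simulated exon-array dataset.

    Defaults are the strong-coupling conditions used throughout the
    analyses: 60 samples, 300 genes of 8 exons x 4 probes, 40 SF genes,
    coupling beta = 1, ~40 baseline events per sample of magnitude
    3 log2 units, probe noise 0.25 log2 units.
    """

    n_samples: int = 60
    n_genes: int = 300
    exons_per_gene: int = 8
    probes_per_exon: int = 4  # exon arrays average four probes per probeset
    n_sf_genes: int = 40
    coupling_beta: float = 1.0  # log2 events per unit latent z; 0 = null model
    baseline_events_n0: int = 40
    event_magnitude_delta: float = 3.0  # log2 shift of an aberrant exon's probes
    event_inclusion_fraction: float = 0.5
    sf_loading_lambda: float = 1.0
    sf_noise_sd: float = 1.0  # idiosyncratic expression noise of SF genes
    noise_sd: float = 0.25
    gene_mu_range: tuple[float, float] = (6.0, 12.0)
    count_model: str = "deterministic"  # or "poisson"
    group_labels: list[str] | None = None  # per-sample categorical labels
    group_effect: float = 0.0  # log2 modifier of event counts for affected_group
    affected_group: str | None = None  # defaults to the first distinct label
    paired: bool = False
    seed: int = 0
    # array structure (gene means, probe affinities) can be pinned to its
    # own seed so that several datasets emulate the same array platform;
    # None draws it from the main stream
    array_seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "exons_per_gene", "probes_per_exon", "n_sf_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_sf_genes > self.n_genes:
            raise ValueError("n_sf_genes exceeds n_genes")
        if not 0.0 <= self.event_inclusion_fraction <= 1.0:
            raise ValueError("event_inclusion_fraction must be in [0, 1]")
        if self.coupling_beta < 0 or self.sf_loading_lambda < 0:
            raise ValueError("coupling_beta and sf_loading_lambda must be >= 0")
        if self.count_model not in ("deterministic", "poisson"):
            raise ValueError(f"unknown count_model: {self.count_model!r}")
        n_exons = self.n_genes * self.exons_per_gene
        if self.baseline_events_n0 * 2 ** (self.coupling_beta * 3) > n_exons:
            raise ValueError(
                "baseline_events_n0 * 2**(3*coupling_beta) exceeds the exon count; "
                "cannot draw events without replacement"
            )
        if self.group_labels is not None and len(self.group_labels) != self.n_samples:
            raise ValueError("group_labels length must equal n_samples")

    @property
    def n_probes(self) -> int:
        return self.n_genes * self.exons_per_gene * self.probes_per_exon


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset."""

    z: np.ndarray  # latent splicing capacity per sample
    planted_events: list[tuple[str, str, str, int, float]]  # (sample, gene, probeset, sign, magnitude)
    planted_counts: np.ndarray  # per-sample total planted events
    sf_gene_ids: list[str]
    config_echo: SimConfig

    def counts_by_sample(self) -> pd.Series:
        ids = [f"S{i + 1:03d}" for i in range(len(self.planted_counts))]
        return pd.Series(self.planted_counts, index=ids)


@dataclass
class SimulatedDataset:
    intensities: ProbeIntensityMatrix
    annotation: ExonAnnotation
    gene_sets: dict[str, list[str]]
    metadata: pd.DataFrame
    truth: SimTruth


def make_random_gene_universe(n_genes: int, seed: int = 0) -> list[str]:
    """Stable, unique, zero-padded gene identifiers (seed-independent order)."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    width = max(5, len(str(n_genes)))
    return [f"G{i + 1:0{width}d}" for i in range(n_genes)]


def generate_dataset(config: SimConfig) -> SimulatedDataset:
    """Draw one dataset from the generative model; deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    n, g, epg, ppe = config.n_samples, config.n_genes, config.exons_per_gene, config.probes_per_exon
    n_exons = g * epg

    gene_ids = make_random_gene_universe(g)
    sf_gene_ids = gene_ids[: config.n_sf_genes]
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    probeset_ids = [f"{gene_ids[k // epg]}_E{k % epg + 1:02d}" for k in range(n_exons)]
    probe_ids = [f"{probeset_ids[k]}_P{j + 1}" for k in range(n_exons) for j in range(ppe)]

    arr_rng = rng if config.array_seed is None else np.random.default_rng(config.array_seed)

    # gene model in log2 space
    z = rng.standard_normal(n)
    mu = arr_rng.uniform(*config.gene_mu_range, size=g)
    a = np.empty((g, n))
    a[: config.n_sf_genes] = (
        mu[: config.n_sf_genes, None]
        + config.sf_loading_lambda * z[None, :]
        + rng.normal(0.0, config.sf_noise_sd, size=(config.n_sf_genes, n))
    )
    a[config.n_sf_genes:] = mu[config.n_sf_genes:, None] + rng.normal(
        0.0, 0.5, size=(g - config.n_sf_genes, n)
    )
    b = arr_rng.normal(0.0, 0.5, size=config.n_probes)

    gene_of_probe = np.repeat(np.arange(g), epg * ppe)
    log2 = a[gene_of_probe] + b[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_probes, n))

    # planted aberrant events, counts coupled to z
    mean_counts = config.baseline_events_n0 * 2.0 ** (-config.coupling_beta * z)
    if config.group_labels is not None and config.group_effect:
        affected = config.affected_group or config.group_labels[0]
        mask = np.array([lab == affected for lab in config.group_labels])
        mean_counts = mean_counts * np.where(mask, 2.0**config.group_effect, 1.0)
    if config.count_model == "poisson":
        counts = rng.poisson(mean_counts)
    else:
        counts = np.maximum(0, np.round(mean_counts)).astype(int)
    counts = np.minimum(counts, n_exons)

    planted_events: list[tuple[str, str, str, int, float]] = []
    delta = config.event_magnitude_delta
    for i in range(n):
        if counts[i] == 0:
            continue
        exons = rng.choice(n_exons, size=counts[i], replace=False)
        signs = np.where(rng.random(counts[i]) < config.event_inclusion_fraction, 1, -1)
        for k, s in zip(exons, signs):
            rows = slice(k * ppe, (k + 1) * ppe)
            log2[rows, i] += s * delta
            planted_events.append(
                (sample_ids[i], gene_ids[k // epg], probeset_ids[k], int(s), float(delta))
            )

    intensities = ProbeIntensityMatrix(
        pd.DataFrame(2.0**log2, index=probe_ids, columns=sample_ids)
    )
    annotation = ExonAnnotation(
        pd.DataFrame(
            {
                "probe_id": probe_ids,
                "probeset_id": np.repeat(probeset_ids, ppe),
                "transcript_cluster_id": [gene_ids[k] for k in gene_of_probe],
            }
        )
    )

    pair_id = [f"P{i // 2 + 1:03d}" if config.paired else "" for i in range(n)]
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": config.group_labels if config.group_labels is not None else [""] * n,
            "pair_id": pair_id,
        }
    ).set_index("sample_id")

    truth = SimTruth(
        z=z,
        planted_events=planted_events,
        planted_counts=counts,
        sf_gene_ids=sf_gene_ids,
        config_echo=config,
    )
    return SimulatedDataset(
        intensities=intensities,
        annotation=annotation,
        gene_sets={"SF_SET": sf_gene_ids},
        metadata=metadata,
        truth=truth,
    )
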