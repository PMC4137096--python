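import numpy as np
import pandas as pd
import pytest

import tinscope as ts


@pytest.fixture(scope="session")
def strong_dataset() -> ts.SimulatedDataset:
    """Strong negative coupling at the default study conditions."""
    return ts.generate_dataset(ts.SimConfig(seed=1))


@pytest.fixture(scope="session")
def strong_report(strong_dataset) -> ts.AnalysisReport:
    """Full pipeline run on the strong-coupling dataset, B = 1,000."""
    bundle = ts.DatasetBundle(
        "strong",
        strong_dataset.intensities,
        strong_dataset.annotation,
        strong_dataset.metadata,
    )
    return ts.run_dataset_analysis(bundle, strong_dataset.gene_sets, seed=1)


def small_config(**overrides) -> ts.SimConfig:
    """Compact dataset for replicate-heavy simulations."""
    fields = dict(
        n_samples=20,
        n_genes=60,
        exons_per_gene=6,
        probes_per_exon=3,
        n_sf_genes=15,
        baseline_events_n0=5,
        coupling_beta=1.0,
        event_magnitude_delta=3.0,
        noise_sd=0.25,
    )
    fields.update(overrides)
    return ts.SimConfig(**fields)


def run_small_pipeline(config: ts.SimConfig):
    """Normalize -> gene models -> FIRMA -> TIN -> expression (no nulls)."""
    ds = ts.generate_dataset(config)
    normalized = ts.quantile_normalize(ds.intensities)
    fits = ts.fit_gene_models(normalized, ds.annotation)
    scores = ts.firma_scores(fits, ds.annotation)
    thr = ts.compute_thresholds(scores)
    tin = ts.compute_tin_estimates(ts.count_aberrant_exons(scores, thr))
    expr = ts.gene_level_expression(fits, ds.intensities.sample_ids)
    return ds, scores, tin, expr


@pytest.fixture
def tin_profile_from_counts():
    def build(skip, incl, cutoff=1.0):
        counts = pd.DataFrame(
            {"skip_count": np.asarray(skip), "incl_count": np.asarray(incl)},
            index=[f"S{i}" for i in range(len(skip))],
        )
        return ts.compute_tin_estimates(counts, tin_cutoff=cutoff)

    return build
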