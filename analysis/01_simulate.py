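"""Generate the study's synthetic exon-array datasets.

Writes two datasets under scratch/data/: a strong-coupling dataset
(splicing-factor expression and planted aberrant-splicing loads driven
by one latent splicing-capacity variable) and an uncoupled control with
Poisson event counts. Both are plain-text (TSV/GMT/JSON) and fully
reproducible from the seed.
"""

from pathlib import Path

import tinscope as ts
from tinscope import io as tio

# raw simulated matrices are bulky; they go under scratch/, the
# downstream drivers regenerate from SimConfig directly
OUT = Path(__file__).resolve().parents[1] / "scratch" / "data"


def main(seed: int = 1) -> None:
    strong = ts.generate_dataset(ts.SimConfig(seed=seed))
    tio.write_dataset(strong, OUT / "strong_coupling")
    null = ts.generate_dataset(
        ts.SimConfig(coupling_beta=0.0, count_model="poisson", seed=seed)
    )
    tio.write_dataset(null, OUT / "uncoupled_control")
    print(f"strong-coupling: {strong.intensities.values.shape[0]} probes x "
          f"{strong.intensities.values.shape[1]} samples, "
          f"{len(strong.truth.planted_events)} planted events")
    print(f"uncoupled control: {len(null.truth.planted_events)} planted events")
    print(f"written under {OUT}")


if __name__ == "__main__":
    main()
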