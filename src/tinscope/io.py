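"""Tab-delimited and GMT file I/O with strict validation.

All formats are plain text: matrices as TSV with an id column plus one
column per sample, annotation/metadata as TSV, gene sets as GMT
(set name, description, then tab-separated member ids). Readers refuse
malformed input (duplicate ids, ragged rows, non-numeric cells) with
line numbers; write-then-read round-trips are exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .preprocess import ExonAnnotation
from .synthetic import SimulatedDataset

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_gmt",
    "write_gmt",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "write_dataset",
]


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Numeric matrix with row ids in the first column, samples across."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header)
        if len(set(header[1:])) != ncol - 1:
            raise ValueError(f"{path}: duplicate column ids in header")
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != ncol:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(parts)} fields, expected {ncol})"
                )
            ids.append(parts[0])
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    frame = pd.DataFrame(rows, index=ids, columns=header[1:])
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        lineno = 2 + list(frame.index).index(dup, list(frame.index).index(dup) + 1)
        raise ValueError(f"{path}:{lineno}: duplicate row id {dup!r}")
    frame.index.name = header[0]
    return frame


def write_matrix_tsv(frame: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    frame.to_csv(path, sep="\t", index_label=frame.index.name or index_label)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: one set per line, name TAB description TAB members."""
    sets: dict[str, list[str]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
            name, members = parts[0], [m for m in parts[2:] if m]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "") -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_annotation_tsv(path: str | Path) -> ExonAnnotation:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return ExonAnnotation(table)  # validation (duplicates etc.) in the type


def write_annotation_tsv(annotation: ExonAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "sample_id" not in meta.columns:
        raise ValueError(f"{path}: metadata needs a sample_id column")
    if meta["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in metadata")
    return meta.set_index("sample_id")


def write_metadata_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Persist a simulated dataset: intensities, annotation, GMT, metadata, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix_tsv(dataset.intensities.values, outdir / "intensities.tsv", "probe_id")
    write_annotation_tsv(dataset.annotation, outdir / "annotation.tsv")
    write_gmt(dataset.gene_sets, outdir / "genesets.gmt", "synthetic splicing-factor set")
    write_metadata_tsv(dataset.metadata, outdir / "metadata.tsv")
    truth = dataset.truth
    payload = {
        "z": truth.z.tolist(),
        "planted_events": truth.planted_events,
        "planted_counts": truth.planted_counts.tolist(),
        "sf_gene_ids": truth.sf_gene_ids,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(truth.config_echo).items()
        },
    }
    (outdir / "truth.json").write_text(json.dumps(payload, indent=1))
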