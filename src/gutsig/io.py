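"""Tab-separated readers and writers for the pipeline's tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .composition import SampleTaxaMatrix
from .em import AbundanceEstimate

METADATA_COLUMNS = ("subject_id", "group")


def write_sample_taxa(matrix: SampleTaxaMatrix, abundance_path, metadata_path) -> None:
    matrix.abundance.to_csv(abundance_path, sep="\t", index_label="sample_id")
    matrix.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_sample_taxa(abundance_path, metadata_path) -> SampleTaxaMatrix:
    abundance = pd.read_csv(abundance_path, sep="\t", index_col="sample_id")
    metadata = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata file lacks columns: {missing}")
    return SampleTaxaMatrix(abundance, metadata)


def write_abundance_estimate(estimate: AbundanceEstimate, path) -> None:
    frame = estimate.proportions.rename("proportion").rename_axis("genome").reset_index()
    frame.to_csv(path, sep="\t", index=False)


def read_strain_map(path) -> dict[str, str]:
    """Two-column TSV: strain id, species id."""
    df = pd.read_csv(path, sep="\t", header=None, names=["strain", "species"], dtype=str)
    return dict(zip(df["strain"], df["species"]))


def write_dataframe(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    df.to_csv(Path(path), sep="\t", index=index_label is not None, index_label=index_label)
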