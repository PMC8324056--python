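"""File readers/writers and pipeline configuration.

All interchange is plain text: TSV tables with fixed column names, FASTA
for barcode sequences, ages as integer calibrated years BP.  The counts
TSV is long format — one row per (sample, barcode sequence) with one
integer column per PCR replicate (``rep_1`` ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from sedadiv.filtering import KEY_COLUMNS, rep_cols
from sedadiv.reference import ReferenceDatabase


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a per-replicate counts table, validating structure.

    Counts must parse as non-negative integers; a malformed row raises
    with its line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if len(df) == 0:
        cols = list(KEY_COLUMNS) + ["rep_1"]
        return pd.DataFrame(columns=[c for c in df.columns] or cols)
    missing = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    reps = rep_cols(df)
    if not reps:
        raise ValueError(f"{path}: no replicate count columns (rep_1 ...)")
    for c in reps:
        as_num = pd.to_numeric(df[c], errors="coerce")
        bad = as_num.isna() | (as_num < 0) | (as_num % 1 != 0)
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(f"{path}: malformed count in column {c}, line {line}")
        df[c] = as_num.astype(int)
    return df


def write_counts_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_reference(
    fasta_path, taxonomy_path,
    blacklist_synthetic_path=None, blacklist_false_positive_path=None,
) -> ReferenceDatabase:
    """Load the barcode reference database (see :class:`ReferenceDatabase`)."""
    return ReferenceDatabase.from_files(
        fasta_path, taxonomy_path,
        blacklist_synthetic_path, blacklist_false_positive_path,
    )


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path, float_format: str = "%.10g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def write_taxon_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the harmonized taxon table with replicate flags as a bitstring."""
    cols = rep_cols(table)
    out = table.copy()
    flags = (out[cols] > 0).astype(int).astype(str)
    out["replicate_flags"] = flags.agg("".join, axis=1)
    keep = ["lake_id", "sample_id", "sample_type", "taxon", "rank", "group",
            "reads", "n_replicates", "replicate_flags"] + cols
    write_table(out[keep], path)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full pipeline run."""

    counts_path: str = "counts.tsv"
    reference_fasta: str = "reference.fasta"
    taxonomy_path: str = "taxonomy.tsv"
    blacklist_synthetic: str | None = None
    blacklist_false_positives: str | None = None
    lakes_path: str = "lakes.tsv"
    proxy_path: str = "proxy.tsv"
    out_dir: str = "results"

    min_reads: int = 3
    min_total_reads: int = 10
    min_total_replicates: int = 3
    mtq_threshold: float = 0.75
    maq_threshold: float = 0.2
    wtrep_min_mean_prop: float = 0.33
    wtrep_min_barcodes: int = 10
    bin_width: int = 500
    subsample_size: int = 5
    n_resamples: int = 1000
    exclude_d18o_below: float = -39.0
    n_replicates: int = 8
    seed: int = 0

    def __post_init__(self):
        for name in ("min_reads", "min_total_reads", "min_total_replicates",
                     "bin_width", "subsample_size", "n_resamples", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
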