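"""TSV readers/writers with validation.

All tables are UTF-8 tab-separated with fixed headers.  Floats are
written in scientific notation with six significant digits so diffs are
stable across platforms.  Readers validate types and keys and raise
errors that name the offending row or sample.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

FLOAT_FORMAT = "%.5e"

SPECIES_LABELS = {"collared", "pied", "hybrid"}


def read_counts(path) -> pd.DataFrame:
    """Gene x sample integer count matrix; first column is the gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicated gene id {dup!r} in {path}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"non-numeric counts in {path}")
    neg = np.argwhere(values < 0)
    if neg.size:
        r = int(neg[0, 0])
        raise ValueError(f"negative count on row {r + 2} (gene {df.index[r]!r})")
    if not np.allclose(values, np.round(values)):
        raise ValueError(f"non-integer counts in {path}")
    return df.astype(np.int64)


def read_samples(path, counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Sample table with columns sample, species, tissue, individual."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "species", "tissue", "individual"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample table lacks columns {sorted(missing)}")
    bad = ~df["species"].isin(SPECIES_LABELS)
    if bad.any():
        r = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"unknown species {df['species'].iloc[r]!r} on row {r + 2}")
    if df.duplicated(["species", "tissue", "individual"]).any():
        raise ValueError("duplicate (species, tissue, individual) in sample table")
    if counts is not None:
        unknown = set(counts.columns) - set(df["sample"])
        if unknown:
            raise ValueError(
                f"samples in counts but not in sample table: {sorted(unknown)}")
    return df


def read_allele_counts(path) -> pd.DataFrame:
    """Phased allelic count table (gene, individual, tissue, snp, hap_a,
    hap_b, phase_set)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "individual", "tissue", "snp", "hap_a", "hap_b"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"allele count table lacks columns {sorted(missing)}")
    for col in ("hap_a", "hap_b"):
        neg = df[col] < 0
        if neg.any():
            r = int(np.flatnonzero(neg)[0])
            raise ValueError(f"negative {col} on row {r + 2}")
    if df.duplicated(["gene", "individual", "tissue", "snp"]).any():
        raise ValueError("duplicate (gene, individual, tissue, snp) rows")
    return df


def read_annotation(path) -> pd.DataFrame:
    """Per-gene annotation; optional covariates load as missing-marked."""
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise ValueError("annotation lacks a 'gene' column")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicated gene {dup!r} in annotation")
    if "cne_flag" in df.columns:
        df["cne_flag"] = df["cne_flag"].astype(bool)
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def write_counts(counts: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    counts.to_csv(path, sep="\t", index_label="gene")
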