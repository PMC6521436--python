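"""Readers and writers for the tabular interchange formats.

All tables travel as TSV (human-readable, fixture-friendly); gene sets
as GMT. Expression matrices are genes x samples with the row identifier
in the first column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from mofsync.genesets import GeneSetCollection, read_gmt, write_gmt  # noqa: F401

#: Decimal format used by all writers; fixed so reruns are byte-identical.
_FLOAT_FMT = "%.10g"


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV matrix.

    Duplicate row ids are an error (collapse probes upstream), as are
    missing or non-numeric cells — reported with their coordinates.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated row ids {dups[:5]}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        values[:, j] = converted
    return pd.DataFrame(values, index=df.index, columns=df.columns)


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="gene")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_annotation(path: str | Path) -> dict[str, str]:
    """Gene -> chromosome map from a two-column TSV (gene_id, chromosome)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["gene_id"], df["chromosome"]))


def read_probe_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["probe_id"], df["gene_id"]))


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
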