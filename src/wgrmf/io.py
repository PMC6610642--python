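"""CSV/TSV readers and writers for response, similarity and feature tables.

All on-disk matrices share one layout: a header row of column names and a
first column of row identifiers.  The delimiter is sniffed, so comma- and
tab-separated files with the same content parse identically.  In a response
matrix, empty cells (or ``NA``/``NaN`` tokens) mark unobserved entries and
become mask zeros; anywhere else a missing value is an error.  Writes are
atomic (temp file + rename).
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .similarity import FeatureTable, SimilarityMatrix, ValidationError
from .solver import ResponseMatrix

__all__ = [
    "read_frame",
    "read_response",
    "read_similarity",
    "read_features",
    "write_frame",
    "write_response",
    "atomic_write_text",
]

NA_TOKENS = ["", "NA", "NaN", "nan"]


def read_frame(path: str | Path) -> pd.DataFrame:
    """Parse a labeled CSV/TSV matrix into a DataFrame of floats (NaN = blank)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, na_values=NA_TOKENS,
                         keep_default_na=False, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed table {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValidationError(f"duplicate row ids in {path}: {dups}")
    if df.columns.duplicated().any():
        dups = sorted(set(df.columns[df.columns.duplicated()]))
        raise ValidationError(f"duplicate column ids in {path}: {dups}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        for line_no, (_, row) in enumerate(df.iterrows(), start=2):
            if pd.to_numeric(row, errors="coerce").isna().sum() != row.isna().sum():
                raise ValidationError(
                    f"non-numeric cell in {path} at line {line_no}"
                ) from exc
        raise ValidationError(f"non-numeric data in {path}") from exc
    return df


def read_response(path: str | Path) -> ResponseMatrix:
    """Read a drug × cell-line response matrix; blank cells become mask 0."""
    df = read_frame(path)
    W = (~df.isna()).to_numpy(dtype=float)
    R = df.to_numpy(dtype=float)
    return ResponseMatrix(list(df.index), list(df.columns), R, W)


def read_similarity(
    path: str | Path, kind: Literal["drug", "cell_line"]
) -> SimilarityMatrix:
    """Read a square similarity matrix with matching row/column ids."""
    df = read_frame(path)
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: row and column ids must match in order")
    if df.isna().any().any():
        raise ValidationError(f"{path}: similarity matrices may not have blanks")
    S = df.to_numpy(dtype=float)
    S = (S + S.T) / 2.0
    return SimilarityMatrix(list(df.index), S, kind=kind)


def read_features(
    path: str | Path,
    feature_kind: Literal["binary_fingerprint", "continuous_profile"],
) -> FeatureTable:
    df = read_frame(path)
    if df.isna().any().any():
        bad = list(df.index[df.isna().any(axis=1)])
        raise ValidationError(f"{path}: missing feature values for {bad}")
    return FeatureTable(list(df.index), df.to_numpy(dtype=float), feature_kind)


def atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _repr_float(v: float) -> str:
    # shortest representation that round-trips exactly
    return repr(float(v))


def write_frame(df: pd.DataFrame, path: str | Path) -> None:
    atomic_write_text(path, df.to_csv(float_format=_repr_float))


def write_response(rm: ResponseMatrix, path: str | Path) -> None:
    """Write a response matrix; masked entries become empty cells."""
    grid = np.where(rm.W == 1, rm.R, np.nan)
    df = pd.DataFrame(grid, index=rm.drug_ids, columns=rm.cell_ids)
    atomic_write_text(path, df.to_csv(float_format=_repr_float))


def write_manifest(path: str | Path, payload: dict) -> None:
    """Reproducibility record: inputs, seeds, parameters, package version."""
    from . import __version__

    payload = dict(payload)
    payload.setdefault("wgrmf_version", __version__)
    atomic_write_text(path, json.dumps(payload, indent=2, sort_keys=True, default=str))
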