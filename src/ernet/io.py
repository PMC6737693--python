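"""TSV dialects for expression matrices and time-course datasets.

Matrices are genes × samples: first column gene ID, header row of sample IDs,
tab-separated, full-precision floats (write∘read is the identity on values).
Time courses are tidy: scenario, species, time_h, replicate, value.
Malformed input is rejected with the offending line number; Windows line
endings are accepted.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_timecourses",
    "write_timecourses",
    "MatrixFormatError",
]

TIMECOURSE_COLUMNS = ["scenario", "species", "time_h", "replicate", "value"]


class MatrixFormatError(ValueError):
    """Malformed matrix TSV; message carries the line number."""


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label=matrix.index.name or "gene")


def read_matrix(path) -> pd.DataFrame:
    """Read a genes × samples TSV, validating structure.

    Errors: duplicated gene IDs (cites the ID and line), ragged rows and
    non-numeric cells (cite the line).  Line numbers are 1-based including
    the header.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0,
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise MatrixFormatError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        import numpy as np

        line = int(np.flatnonzero(df.index == dup)[-1]) + 2
        raise MatrixFormatError(f"{path}: duplicated gene ID {dup!r} at line {line}")
    bad_cols = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if bad_cols:
        col = bad_cols[0]
        numeric = pd.to_numeric(df[col], errors="coerce")
        line = int(numeric.isna().to_numpy().nonzero()[0][0]) + 2
        raise MatrixFormatError(f"{path}: non-numeric cell in column {col!r} at line {line}")
    if df.isna().any().any():
        line = int(df.isna().any(axis=1).to_numpy().nonzero()[0][0]) + 2
        raise MatrixFormatError(f"{path}: ragged or missing values at line {line}")
    df.index.name = "gene"
    return df


def write_timecourses(data: pd.DataFrame, path) -> None:
    data.to_csv(path, sep="\t", index=False, columns=TIMECOURSE_COLUMNS)


def read_timecourses(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in TIMECOURSE_COLUMNS if c not in df.columns]
    if missing:
        raise MatrixFormatError(f"{path}: missing columns {missing}")
    for col in ("time_h", "value"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            numeric = pd.to_numeric(df[col], errors="coerce")
            line = int(numeric.isna().to_numpy().nonzero()[0][0]) + 2
            raise MatrixFormatError(f"{path}: non-numeric {col} at line {line}")
    return df[TIMECOURSE_COLUMNS]
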