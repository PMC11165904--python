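"""Readers and writers for the matrix formats the tool touches.

Two families of formats are supported: delimited text (TSV/CSV) for dense
matrices, and Matrix Market coordinate format (MTX) for sparse ones —
the de-facto standard container for single-cell count matrices.  The
internal convention is rows = observations; MTX files in the wild are
usually genes x cells, so readers accept a transpose flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = ["read_matrix", "write_matrix", "detect_format"]


def detect_format(path: str) -> str:
    """Infer the file format from the extension: .mtx -> matrix-market,
    .csv -> delimited-csv, anything else -> delimited-tsv."""
    p = str(path).lower()
    if p.endswith(".mtx"):
        return "matrix-market"
    if p.endswith(".csv"):
        return "delimited-csv"
    return "delimited-tsv"


def _is_float(token: str) -> bool:
    try:
        float(token)
        return True
    except (TypeError, ValueError):
        return False


def read_matrix(path, fmt: str | None = None, transpose: bool = False):
    """Read a matrix file into an ndarray (delimited) or CSR matrix (MTX).

    Delimited files: a header row and/or a leading id column are
    auto-detected — if the first row (resp. first column, excluding the
    header cell) contains any token that does not parse as a float it is
    treated as labels and dropped.  Ragged rows and non-numeric data cells
    raise with the offending line number.

    Matrix Market: coordinate triplets are assembled sparsely; dimension or
    header problems raise with a diagnostic.

    ``transpose=True`` flips to rows-are-observations for genes x cells
    inputs.
    """
    fmt = fmt or detect_format(path)
    if fmt == "matrix-market":
        try:
            M = mmread(path)
        except ValueError as e:
            raise ValueError(f"{path}: invalid Matrix Market file: {e}") from e
        X = sp.csr_matrix(M)
    elif fmt in ("delimited-tsv", "delimited-csv"):
        X = _read_delimited(path, sep="," if fmt == "delimited-csv" else "\t")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if transpose:
        X = X.T
        if sp.issparse(X):
            X = X.tocsr()
    return X


def _read_delimited(path, sep: str) -> np.ndarray:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: file is empty")
    rows = [ln.split(sep) for ln in lines]
    width = len(rows[0])
    for ln_no, r in enumerate(rows, start=1):
        if len(r) != width:
            raise ValueError(
                f"{path}:{ln_no}: ragged row ({len(r)} fields, expected {width})"
            )
    has_header = not all(_is_float(tok) for tok in rows[0])
    body = rows[1:] if has_header else rows
    if not body:
        raise ValueError(f"{path}: no data rows below the header")
    has_ids = not all(_is_float(r[0]) for r in body)
    start_col = 1 if has_ids else 0
    if width - start_col < 1:
        raise ValueError(f"{path}: no numeric columns found")
    data = np.empty((len(body), width - start_col))
    offset = 2 if has_header else 1
    for i, r in enumerate(body):
        for j, tok in enumerate(r[start_col:]):
            try:
                data[i, j] = float(tok)
            except ValueError:
                raise ValueError(
                    f"{path}:{i + offset}: non-numeric cell {tok!r} "
                    f"in column {j + start_col + 1}"
                ) from None
    return data


def write_matrix(X, path, fmt: str | None = None) -> str:
    """Write a matrix deterministically.

    Delimited mode prints floats at 17 significant digits (lossless for
    float64); MTX uses the standard ``coordinate real general`` dialect.
    Returns the path written.
    """
    fmt = fmt or detect_format(path)
    if hasattr(X, "shape") and (X.shape[0] < 1 or X.shape[1] < 1):
        raise ValueError("refusing to write an empty matrix")
    if fmt == "matrix-market":
        mmwrite(path, sp.coo_matrix(X))
    elif fmt in ("delimited-tsv", "delimited-csv"):
        if sp.issparse(X):
            X = X.toarray()
        X = np.asarray(X, dtype=float)
        sep = "," if fmt == "delimited-csv" else "\t"
        pd.DataFrame(X).to_csv(path, sep=sep, header=False, index=False,
                               float_format="%.17g")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return str(path)
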