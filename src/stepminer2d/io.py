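"""Readers and writers for the tab-delimited matrix formats.

All matrices are features x samples: first column feature ids, header row
sample ids.  Missing methylation entries may appear as empty fields or NA
tokens.  Beta values are validated to [0, 1] and expression to
non-negative, with parse errors naming the offending feature and sample.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParseError

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "read_groups",
    "intersect_samples",
    "IntersectionReport",
]

_NA_TOKENS = ["", "NA", "N/A", "NaN", "nan", "null", "NULL"]
_PROBE_RE = re.compile(r"^cg\d+$")


def read_matrix(path, kind: str) -> pd.DataFrame:
    """Read a features x samples TSV matrix.

    ``kind`` is ``"methylation"`` (beta in [0,1], NaN allowed) or
    ``"expression"`` (non-negative).  A methylation matrix whose column
    header is made of probe ids is rejected as transposed rather than
    silently fixed.
    """
    if kind not in ("methylation", "expression"):
        raise ParseError(f"unknown matrix kind {kind!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=_NA_TOKENS, keep_default_na=False)
    except Exception as err:
        raise ParseError(f"cannot parse {path}: {err}") from err
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found")
    if df.columns.duplicated().any() or df.index.duplicated().any():
        raise ParseError(f"{path}: duplicate sample or feature identifiers")
    probe_like = sum(bool(_PROBE_RE.match(str(c))) for c in df.columns)
    if probe_like > df.shape[1] / 2:
        raise ParseError(
            f"{path}: column header looks like probe ids — matrix appears transposed "
            "(expected features on rows, samples on columns)"
        )
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            feature = bad[0] if len(bad) else "?"
            raise ParseError(f"{path}: non-numeric value at feature {feature!r}, sample {col!r}")
    values = df.to_numpy(dtype=float)
    if kind == "methylation":
        bad = (values < 0) | (values > 1)
    else:
        bad = values < 0
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: out-of-range value {values[i, j]!r} at feature "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a matrix in the same TSV dialect ``read_matrix`` accepts."""
    df.to_csv(path, sep="\t", na_rep="NA")


def read_annotation(path) -> pd.DataFrame:
    """Two-column (cpg_id, gene_id) TSV, with or without a header row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: annotation needs two tab-separated columns")
    first = df.columns[0]
    if _PROBE_RE.match(str(first)):  # headerless file: first row was data
        df = pd.read_csv(path, sep="\t", dtype=str, header=None)
    df = df.iloc[:, :2]
    df.columns = ["cpg_id", "gene_id"]
    return df


def read_groups(path) -> pd.Series:
    """Two-column (sample_id, group) TSV -> Series indexed by sample id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: group table needs two tab-separated columns")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")


@dataclass(frozen=True)
class IntersectionReport:
    n_common: int
    n_meth_only: int
    n_expr_only: int

    def summary(self) -> str:
        return (
            f"samples in common {self.n_common}; methylation-only dropped "
            f"{self.n_meth_only}; expression-only dropped {self.n_expr_only}"
        )


def intersect_samples(
    meth: pd.DataFrame, expr: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, IntersectionReport]:
    """Restrict both matrices to the exact-match sample intersection.

    Columns are kept in the methylation matrix's order; an empty
    intersection is fatal.
    """
    common = [c for c in meth.columns if c in set(expr.columns)]
    report = IntersectionReport(
        n_common=len(common),
        n_meth_only=meth.shape[1] - len(common),
        n_expr_only=expr.shape[1] - len(common),
    )
    if not common:
        raise ParseError("no samples shared between the methylation and expression matrices")
    return meth[common], expr[common], report
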