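"""Log2 expression matrices: container, TSV I/O, duplicate-probe collapsing.

The matrix is genes x samples, log2 scale, with missing entries allowed
(NaN). Gene and sample identifiers must be unique; duplicate gene rows
in an input file (multiple probes mapping to one gene) are collapsed at
read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

CollapseRule = Literal["max_variance", "mean"]


class ExpressionParseError(ValueError):
    """Raised when an expression file violates the expected layout."""


@dataclass
class ExpressionMatrix:
    """Validated log2 expression values, genes in rows, samples in columns.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric frame indexed by gene id with sample ids as columns.
        NaN marks a missing measurement; all finite otherwise.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if np.isinf(arr).any():
            raise ValueError("expression values must be finite or missing (NaN)")
        self.values.index = idx.astype(str)
        self.values.columns = cols.astype(str)
        self.values.index.name = None
        self.values.columns.name = None

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[genes].copy())

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = [s for s in samples if s in self.values.columns]
        return ExpressionMatrix(self.values[samples].copy())


def _collapse_duplicates(df: pd.DataFrame, rule: CollapseRule) -> pd.DataFrame:
    if not df.index.has_duplicates:
        return df
    if rule == "mean":
        return df.groupby(level=0, sort=False).mean()
    if rule == "max_variance":
        # keep, per gene, the row (probe) with the largest variance across samples
        variances = df.var(axis=1, ddof=1).fillna(-np.inf).to_numpy()
        order = pd.Series(np.arange(len(df)), index=df.index)
        keep_pos = []
        for _, positions in order.groupby(level=0, sort=False):
            pos = positions.to_numpy()
            keep_pos.append(pos[np.argmax(variances[pos])])
        keep_pos.sort()
        return df.iloc[keep_pos]
    raise ValueError(f"unknown collapse rule: {rule!r}")


def read_expression(
    path: str | Path,
    *,
    collapse: CollapseRule = "max_variance",
    sep: str = "\t",
) -> ExpressionMatrix:
    """Read a genes-x-samples TSV into an :class:`ExpressionMatrix`.

    Layout: first column gene ids, header row sample ids. Duplicate gene
    rows are collapsed (default: keep the highest-variance row, which
    preserves the probe with the largest dynamic range; ``collapse="mean"``
    averages instead). Empty cells and ``NA`` become missing values.

    Raises
    ------
    ExpressionParseError
        On a malformed header, repeated sample ids, or a non-numeric cell
        (the error names the offending row and column).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    sample_names = header[1:]
    if len(set(sample_names)) != len(sample_names):
        dups = sorted({s for s in sample_names if sample_names.count(s) > 1})
        raise ExpressionParseError(f"{path}: repeated sample ids {dups}")
    raw = pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=str, na_values=["NA", ""])
    if raw.columns.size == 0:
        raise ExpressionParseError(f"{path}: header row contains no sample ids")
    if raw.columns.has_duplicates:
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise ExpressionParseError(f"{path}: repeated sample ids {dups}")
    if any(str(c).startswith("Unnamed:") for c in raw.columns):
        raise ExpressionParseError(f"{path}: malformed header (unnamed sample columns)")
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad.to_numpy()][0]
            raise ExpressionParseError(
                f"{path}: non-numeric value {raw.loc[gene, col]!r} at gene {gene!r}, sample {col!r}"
            )
        numeric[col] = converted
    numeric = _collapse_duplicates(numeric, collapse)
    return ExpressionMatrix(numeric)


def write_expression(matrix: ExpressionMatrix, path: str | Path, *, sep: str = "\t") -> None:
    """Write the matrix in the same TSV layout :func:`read_expression` reads."""
    matrix.values.to_csv(path, sep=sep, index_label="gene_id", na_rep="NA")
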