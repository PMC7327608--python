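"""Reading and writing incomplete numeric feature tables.

The on-disk dialect is the one used by the UCI arrhythmia distribution:
comma-separated values, no header, ``?`` marking a missing cell, and
(optionally) a final integer class-label column.  In memory an incomplete
table is a :class:`MaskedMatrix` -- a dense value array paired with a binary
observation mask.  By convention missing cells carry the placeholder 0, but
no operation in this package may depend on the placeholder: everything is
computed through the mask.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

MISSING_TOKEN = "?"


class FormatError(ValueError):
    """Raised when an input file does not conform to the CSV dialect."""


@dataclass
class MaskedMatrix:
    """A numeric matrix with a binary observation mask.

    Parameters
    ----------
    values : (N, d) float array
        Cell values; cells with ``mask == 0`` are unknown and carry an
        arbitrary placeholder (0 by convention).
    mask : (N, d) array of {0, 1}
        1 where the cell is observed, 0 where it is missing.
    """

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != self.mask.shape:
            raise ValueError(
                f"values shape {self.values.shape} != mask shape {self.mask.shape}"
            )
        uniq = np.unique(self.mask)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask entries must be 0 or 1")
        self.mask = self.mask.astype(np.uint8)

    @classmethod
    def from_dense(cls, values: np.ndarray) -> "MaskedMatrix":
        """Build from a dense array, treating NaN as missing."""
        values = np.asarray(values, dtype=float)
        mask = (~np.isnan(values)).astype(np.uint8)
        return cls(np.where(mask, values, 0.0), mask)

    @classmethod
    def fully_observed(cls, values: np.ndarray) -> "MaskedMatrix":
        values = np.asarray(values, dtype=float)
        return cls(values, np.ones(values.shape, dtype=np.uint8))

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def n_missing(self) -> int:
        return int(self.mask.size - self.mask.sum())

    @property
    def missing_fraction(self) -> float:
        """Exact fraction of mask-0 cells: ``n_missing / (N * d)``."""
        return self.n_missing / self.mask.size

    @property
    def is_fully_observed(self) -> bool:
        return bool(np.all(self.mask == 1))

    def observed_values(self) -> np.ndarray:
        """Values with the placeholder forced to 0 at missing cells."""
        return self.values * self.mask

    def copy(self) -> "MaskedMatrix":
        return MaskedMatrix(self.values.copy(), self.mask.copy())


@dataclass
class LabeledDataset:
    """A masked feature matrix with per-row integer class labels.

    ``labels`` may be ``None`` for unlabeled tables (e.g. low-rank
    completion fixtures); labeled operations reject such datasets.
    """

    features: MaskedMatrix
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.ndim != 1 or len(self.labels) != self.features.n_rows:
                raise ValueError("labels must be a vector with one entry per row")

    @classmethod
    def from_arrays(cls, values: np.ndarray, labels=None) -> "LabeledDataset":
        """Wrap a fully observed value array (and optional labels)."""
        return cls(MaskedMatrix.fully_observed(values), labels)

    @property
    def n(self) -> int:
        return self.features.n_rows

    @property
    def class_counts(self) -> dict:
        """Map class label -> number of rows in that class (phi)."""
        if self.labels is None:
            return {}
        uniq, counts = np.unique(self.labels, return_counts=True)
        return {int(c): int(m) for c, m in zip(uniq, counts)}

    def copy(self) -> "LabeledDataset":
        labels = None if self.labels is None else self.labels.copy()
        return LabeledDataset(self.features.copy(), labels)


def _parse_cell(cell: str, row: int, col: int) -> tuple:
    cell = cell.strip()
    if cell == MISSING_TOKEN:
        return 0.0, 0
    try:
        return float(cell), 1
    except ValueError:
        raise FormatError(
            f"unparseable cell at row {row + 1}, column {col + 1}: {cell!r} "
            f"(expected a decimal numeral or '{MISSING_TOKEN}')"
        ) from None


def read_uci_table(path, label_column: bool = True, header: bool = False) -> LabeledDataset:
    """Read a comma-separated incomplete table in the UCI arrhythmia dialect.

    Parameters
    ----------
    path : str or path-like
        File to read.  Cells are decimal numerals or ``?`` (missing).
    label_column : bool
        If True (default), the last column is an integer class label and is
        kept out of the feature matrix.
    header : bool
        If True, the first line is a header and is skipped.

    Returns
    -------
    LabeledDataset
        Mask is 0 exactly where ``?`` occurred; row order preserved;
        ``labels`` is None when ``label_column`` is False.
    """
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh)]
    if header and rows:
        rows = rows[1:]
    rows = [r for r in rows if r]  # drop blank trailing lines
    if not rows:
        raise FormatError(f"{path}: empty table")
    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise FormatError(
                f"inconsistent column count at row {i + 1}: "
                f"expected {width}, found {len(r)}"
            )
    min_width = 2 if label_column else 1
    if width < min_width:
        raise FormatError(f"table has too few columns ({width})")

    n, d = len(rows), width - (1 if label_column else 0)
    values = np.zeros((n, d))
    mask = np.ones((n, d), dtype=np.uint8)
    labels = np.zeros(n, dtype=int) if label_column else None
    for i, r in enumerate(rows):
        for j in range(d):
            values[i, j], mask[i, j] = _parse_cell(r[j], i, j)
        if label_column:
            cell = r[-1].strip()
            try:
                labels[i] = int(float(cell))
            except ValueError:
                raise FormatError(
                    f"unparseable label at row {i + 1}: {cell!r}"
                ) from None
    return LabeledDataset(MaskedMatrix(values, mask), labels)


def _format_number(v: float) -> str:
    # repr of a Python float is the shortest round-tripping decimal
    if v == int(v) and abs(v) < 1e16:
        return str(int(v))
    return repr(float(v))


def write_table(dataset: LabeledDataset, path, header: bool = False) -> None:
    """Write a dataset in the same dialect (``?`` for missing cells).

    Deterministic: repeated writes of the same dataset are byte-identical,
    and ``read_uci_table`` reads the file back to an identical dataset.
    """
    mm = dataset.features
    with_labels = dataset.labels is not None
    lines = []
    if header:
        cols = [f"f{j + 1}" for j in range(mm.n_cols)]
        if with_labels:
            cols.append("label")
        lines.append(",".join(cols))
    for i in range(mm.n_rows):
        cells = [
            _format_number(mm.values[i, j]) if mm.mask[i, j] else MISSING_TOKEN
            for j in range(mm.n_cols)
        ]
        if with_labels:
            cells.append(str(int(dataset.labels[i])))
        lines.append(",".join(cells))
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(lines) + "\n")
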