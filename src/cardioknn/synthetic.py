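"""Seeded synthetic fixtures: low-rank matrices, imbalanced blobs, a UCI-like table.

Everything the package's tests and demos need is generated here, so no
download is ever required.  Three generators:

* :func:`gen_lowrank` -- partially observed low-rank matrices with known
  ground truth, for matrix-completion experiments;
* :func:`gen_imbalanced_blobs` -- labeled Gaussian blobs with arbitrary
  class sizes, for the class-imbalance mechanism;
* :func:`gen_uci_like` -- a 452 x 279 table whose class-size profile copies
  the UCI arrhythmia inventory (one dominant class, several classes with
  five or fewer members, three empty classes) with ~0.33% missing cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_io import LabeledDataset, MaskedMatrix

__all__ = [
    "LowRankSpec",
    "BlobSpec",
    "UCI_CLASS_LABELS",
    "UCI_CLASS_COUNTS",
    "gen_lowrank",
    "gen_imbalanced_blobs",
    "gen_uci_like",
]

# class inventory of the 452-row arrhythmia table: labels of the 13
# non-empty classes (1..10, 14..16; 11-13 are empty) and their counts
UCI_CLASS_LABELS = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 14, 15, 16)
UCI_CLASS_COUNTS = (245, 44, 15, 15, 13, 25, 3, 2, 9, 50, 4, 5, 22)


@dataclass
class LowRankSpec:
    n_rows: int = 100
    n_cols: int = 100
    rank: int = 5
    observed_fraction: float = 0.4
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.rank <= min(self.n_rows, self.n_cols):
            raise ValueError("rank must be in 1..min(n_rows, n_cols)")
        if not 0 < self.observed_fraction <= 1:
            raise ValueError("observed fraction must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


@dataclass
class BlobSpec:
    class_sizes: Sequence[int] = (50, 50)
    dim: int = 2
    separation: float = 5.0
    within_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = list(self.class_sizes)
        if any(s < 0 for s in sizes) or not any(s > 0 for s in sizes):
            raise ValueError("class sizes must be non-negative with at least one positive")
        self.class_sizes = sizes


def gen_lowrank(spec: LowRankSpec):
    """Generate (masked matrix, full ground truth) for a completion problem.

    Ground truth is A B' with A (n_rows x r) and B (n_cols x r) i.i.d.
    standard normal, plus optional i.i.d. Gaussian noise; the observed set
    is an exact-count uniform sample of cells.
    """
    rng = np.random.default_rng(spec.seed)
    a = rng.standard_normal((spec.n_rows, spec.rank))
    b = rng.standard_normal((spec.n_cols, spec.rank))
    truth = a @ b.T
    if spec.noise_sd > 0:
        truth = truth + spec.noise_sd * rng.standard_normal(truth.shape)
    n_cells = spec.n_rows * spec.n_cols
    n_obs = int(round(spec.observed_fraction * n_cells))
    mask = np.zeros(n_cells, dtype=np.uint8)
    mask[rng.choice(n_cells, size=n_obs, replace=False)] = 1
    mask = mask.reshape(spec.n_rows, spec.n_cols)
    return MaskedMatrix(truth * mask, mask), truth


def _class_centers(n_classes: int, dim: int, separation: float, rng) -> np.ndarray:
    """Deterministic centers at pairwise distance ~ separation.

    The first min(c, dim) classes sit on scaled coordinate axes; any
    further classes take seeded random directions at the same radius.
    """
    centers = np.zeros((n_classes, dim))
    radius = separation / np.sqrt(2.0) if n_classes > 1 else 0.0
    for c in range(n_classes):
        if c < dim:
            centers[c, c] = radius
        else:
            direction = rng.standard_normal(dim)
            centers[c] = radius * direction / np.linalg.norm(direction)
    return centers


def gen_imbalanced_blobs(spec: BlobSpec) -> LabeledDataset:
    """Labeled isotropic Gaussian blobs with exact per-class row counts.

    Class c (labels are 1-based) has exactly ``class_sizes[c-1]`` rows drawn
    from N(center_c, within_sd^2 I); rows are emitted class by class, fully
    observed.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = spec.class_sizes
    centers = _class_centers(len(sizes), spec.dim, spec.separation, rng)
    blocks, labels = [], []
    for c, size in enumerate(sizes):
        if size == 0:
            continue
        blocks.append(centers[c] + spec.within_sd * rng.standard_normal((size, spec.dim)))
        labels.extend([c + 1] * size)
    return LabeledDataset.from_arrays(np.vstack(blocks), np.array(labels))


def gen_uci_like(seed: int = 0) -> LabeledDataset:
    """A synthetic stand-in for the 452 x 279 arrhythmia feature table.

    Reproduces the aspects of the real table that the algorithms here react
    to -- the exact imbalanced class inventory, heterogeneous column scales,
    a block of 0/1 columns, class-dependent mean shifts that make
    classification clearly better than chance but far from perfect, and
    ~0.33% of feature cells missing uniformly at random.  It does not
    emulate real ECG feature dependence structure.
    """
    rng = np.random.default_rng(seed)
    n, d = 452, 279
    n_binary = 75  # the real table mixes binary flags into the numeric columns
    n_classes = len(UCI_CLASS_LABELS)

    # heterogeneous column scales spanning a few orders of magnitude; the
    # class-shift magnitude (0.3 within-class sd per column) puts 10-fold
    # accuracy in the 50-75% band the real table occupies
    scales = np.exp(rng.normal(1.0, 1.2, size=d))
    class_shift = 0.3 * rng.standard_normal((n_classes, d)) * scales
    binary_cols = rng.choice(d, size=n_binary, replace=False)
    binary_p = np.clip(
        0.5 + 0.15 * rng.standard_normal((n_classes, n_binary)), 0.05, 0.95
    )

    values = np.empty((n, d))
    labels = np.empty(n, dtype=int)
    row = 0
    for ci, (label, count) in enumerate(zip(UCI_CLASS_LABELS, UCI_CLASS_COUNTS)):
        block = class_shift[ci] + scales * rng.standard_normal((count, d))
        block[:, binary_cols] = rng.random((count, n_binary)) < binary_p[ci]
        values[row : row + count] = block
        labels[row : row + count] = label
        row += count
    assert row == n

    n_missing = int(round(0.0033 * n * d))
    mask = np.ones(n * d, dtype=np.uint8)
    mask[rng.choice(n * d, size=n_missing, replace=False)] = 0
    mask = mask.reshape(n, d)
    return LabeledDataset(MaskedMatrix(values * mask, mask), labels)
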