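"""Nearest-neighbour classifiers: KNN, DS-WKNN, DF-WKNN, KDF-WKNN, MKDF-WKNN.

All five classifiers share the same exact Euclidean neighbour search and a
deterministic rule-based tie-break, and differ only in how the k neighbours'
votes are weighted:

* KNN        -- unweighted majority vote.
* DS-WKNN    -- distance weights w_i = (d_k - d_i) / (d_k - d_1) (Dudani).
* DF-WKNN    -- difference weights: w minimises ||x - w' X_NN||^2 subject to
  sum(w) = 1, solved through the regularized difference Gram matrix
  G = D D' with D's rows the differences x - x_i^NN.
* KDF-WKNN   -- the same with the Gram matrix expressed through kernel
  evaluations, so differences live in a feature space.
* MKDF-WKNN  -- KDF-WKNN with a per-class correction factor gamma that
  penalises over-represented classes, for imbalanced training sets.

Negative difference weights are allowed (the constraint is sum-to-one, not
non-negativity); votes use signed sums.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data_io import LabeledDataset

__all__ = [
    "NeighborSet",
    "WeightVector",
    "GramContext",
    "CorrectionFactors",
    "find_neighbors",
    "knn_predict",
    "dswknn_weights",
    "dfwknn_weights",
    "kernel_gram",
    "solve_gram_weights",
    "correction_factors",
    "weighted_vote",
    "classify",
    "CLASSIFIER_NAMES",
]

CLASSIFIER_NAMES = ("knn", "dswknn", "dfwknn", "kdfwknn", "mkdfwknn")


@dataclass
class NeighborSet:
    """The k nearest training rows of one query, sorted by distance."""

    indices: np.ndarray
    distances: np.ndarray  # ascending
    labels: np.ndarray
    query: np.ndarray

    @property
    def k(self) -> int:
        return len(self.indices)


@dataclass
class WeightVector:
    """Per-neighbour voting weights."""

    w: np.ndarray


@dataclass
class GramContext:
    """A (possibly kernelized) difference Gram matrix with its provenance."""

    g: np.ndarray
    kernel: str = "linear"
    bandwidth: Optional[float] = None


@dataclass
class CorrectionFactors:
    """Class-imbalance correction factors.

    gamma maps each class present in training to
    log(lambda + n/phi(i) + zeta) / log(lambda + 1), which is strictly
    decreasing in the class count phi(i): rare classes get a boost, the
    dominant class is damped toward 1.
    """

    gamma: dict
    lambda_: int
    zeta: float
    n: int
    phi: dict


def _check_finite(x: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{what} contains non-finite values; impute missing data first")


def _full_features(train: LabeledDataset) -> np.ndarray:
    if not train.features.is_fully_observed:
        raise ValueError("training features contain missing cells; impute first")
    x = train.features.values
    _check_finite(x, "training matrix")
    return x


def _pairwise_sqdist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    sq = (
        np.einsum("ij,ij->i", a, a)[:, None]
        + np.einsum("ij,ij->i", b, b)[None, :]
        - 2.0 * a @ b.T
    )
    return np.clip(sq, 0.0, None)


def find_neighbors(query: np.ndarray, train: LabeledDataset, k: int) -> NeighborSet:
    """Exact k-nearest-neighbour search under the Euclidean metric.

    Ties in distance are broken by training-row order (stable sort), which
    keeps every downstream classifier deterministic.
    """
    x = _full_features(train)
    query = np.asarray(query, dtype=float).ravel()
    _check_finite(query, "query")
    if not 1 <= k <= len(x):
        raise ValueError(f"k={k} must be in 1..{len(x)}")
    sqd = _pairwise_sqdist(query[None, :], x)[0]
    order = np.argsort(sqd, kind="stable")[:k]
    return NeighborSet(
        indices=order,
        distances=np.sqrt(sqd[order]),
        labels=train.labels[order],
        query=query,
    )


def _nearest_member_tiebreak(neighbors: NeighborSet, tied: np.ndarray) -> int:
    # among tied classes, the one owning the closest neighbour wins
    for lab in neighbors.labels:
        if lab in tied:
            return int(lab)
    raise RuntimeError("tie-break found no member among neighbours")  # pragma: no cover


def _vote(neighbors: NeighborSet, weights: np.ndarray, gamma: Optional[dict] = None) -> int:
    classes = np.unique(neighbors.labels)
    scores = np.empty(len(classes))
    for i, c in enumerate(classes):
        s = weights[neighbors.labels == c].sum()
        if gamma is not None:
            if int(c) not in gamma:
                raise ValueError(f"no correction factor for class {int(c)}")
            s *= gamma[int(c)]
        scores[i] = s
    best = scores.max()
    tied = classes[scores == best]
    if len(tied) == 1:
        return int(tied[0])
    return _nearest_member_tiebreak(neighbors, tied)


def knn_predict(neighbors: NeighborSet) -> int:
    """Majority vote; ties go to the tied class containing the nearest member."""
    return _vote(neighbors, np.ones(neighbors.k))


def dswknn_weights(neighbors: NeighborSet) -> WeightVector:
    """Distance weights w_i = (d_k - d_i) / (d_k - d_1).

    The nearest neighbour gets weight 1 and the k-th gets 0; when all k
    distances coincide the convention is w = 1 for every neighbour (plain
    majority vote).
    """
    d = neighbors.distances
    span = d[-1] - d[0]
    if span <= 0:
        return WeightVector(np.ones(neighbors.k))
    return WeightVector((d[-1] - d) / span)


def solve_gram_weights(g: np.ndarray, eta: float) -> np.ndarray:
    """Solve the sum-to-one constrained least-squares weights from a Gram matrix.

    Regularizes G to G + (eta * tr(G) / k) I, solves G_reg w = 1 and
    normalizes w to sum to one -- the closed form of the equality-constrained
    quadratic programme min w'Gw s.t. sum(w) = 1.  A zero-trace Gram (every
    neighbour coincides with the query) degenerates to uniform weights.
    """
    if eta < 0:
        raise ValueError("eta must be non-negative")
    k = g.shape[0]
    trace = float(np.trace(g))
    if trace <= 0:
        return np.full(k, 1.0 / k)
    g_reg = g + (eta * trace / k) * np.eye(k)
    w = np.linalg.solve(g_reg, np.ones(k))
    total = w.sum()
    if total == 0:  # pragma: no cover - cannot happen for PD g_reg
        return np.full(k, 1.0 / k)
    return w / total


def dfwknn_weights(neighbors: NeighborSet, train_rows: np.ndarray, eta: float = 1e-2) -> WeightVector:
    """Difference weights from the Gram of neighbour differences D = x - X_NN."""
    diffs = neighbors.query[None, :] - np.asarray(train_rows, dtype=float)
    g = diffs @ diffs.T
    return WeightVector(solve_gram_weights(g, eta))


def _rbf_bandwidth(neighbor_sqdists: np.ndarray, bandwidth) -> float:
    if bandwidth == "median":
        k = neighbor_sqdists.shape[0]
        iu = np.triu_indices(k, 1)
        med = float(np.median(np.sqrt(neighbor_sqdists[iu]))) if len(iu[0]) else 0.0
        return med if med > 0 else 1.0
    b = float(bandwidth)
    if b <= 0:
        raise ValueError("rbf bandwidth must be positive")
    return b


def kernel_gram(
    neighbors: NeighborSet,
    train_rows: np.ndarray,
    kernel: str = "rbf",
    bandwidth="median",
) -> GramContext:
    """Kernelized difference Gram matrix.

    Entry (i, j) expands the feature-space inner product
    <phi(x) - phi(x_i), phi(x) - phi(x_j)> into
    k(x_i, x_j) - k(x_i, x) - k(x, x_j) + k(x, x); with the linear kernel
    this is exactly D D'.  The rbf kernel is
    exp(-||a - b||^2 / (2 h^2)) with h either explicit or the median of the
    pairwise neighbour distances (fallback 1 if that median is 0).
    """
    rows = np.asarray(train_rows, dtype=float)
    x = neighbors.query
    if kernel == "linear":
        diffs = x[None, :] - rows
        return GramContext(diffs @ diffs.T, "linear", None)
    if kernel == "rbf":
        sq_nn = _pairwise_sqdist(rows, rows)
        sq_qn = _pairwise_sqdist(x[None, :], rows)[0]
        h = _rbf_bandwidth(sq_nn, bandwidth)
        k_nn = np.exp(-sq_nn / (2.0 * h * h))
        k_qn = np.exp(-sq_qn / (2.0 * h * h))
        g = k_nn - k_qn[:, None] - k_qn[None, :] + 1.0
        return GramContext((g + g.T) / 2.0, "rbf", h)
    raise ValueError(f"unknown kernel {kernel!r}; valid: linear, rbf")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def correction_factors(train: LabeledDataset, zeta: float = 1e-4) -> CorrectionFactors:
    """Class-imbalance correction factors gamma for MKDF-WKNN.

    lambda = round(max(phi) / avg(phi)) with the average over classes that
    actually appear in training (empty classes are not considered), floored
    at 1; then for each present class i

        gamma_i = log(lambda + n / phi(i) + zeta) / log(lambda + 1).

    gamma is strictly decreasing in phi(i): a class holding nearly all the
    training data has gamma close to 1, a two-member class in a data set of
    hundreds gets a factor of 2-3.
    """
    if train.labels is None or train.n == 0:
        raise ValueError("correction factors need a labeled, non-empty training set")
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    phi = train.class_counts
    counts = np.array(list(phi.values()), dtype=float)
    n = train.n
    lam = max(_round_half_up(counts.max() / counts.mean()), 1)
    denom = math.log(lam + 1.0)
    gamma = {c: math.log(lam + n / m + zeta) / denom for c, m in phi.items()}
    return CorrectionFactors(gamma=gamma, lambda_=lam, zeta=zeta, n=n, phi=phi)


def weighted_vote(
    neighbors: NeighborSet,
    weights: WeightVector,
    gamma: Optional[CorrectionFactors] = None,
) -> int:
    """Per-class signed weight sums, optionally scaled by gamma; argmax wins.

    Ties are broken by the nearest-member rule shared with ``knn_predict``.
    """
    if len(weights.w) != neighbors.k:
        raise ValueError("weights are not aligned with the neighbour set")
    return _vote(neighbors, weights.w, gamma.gamma if gamma is not None else None)


def _standardizer(x: np.ndarray):
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return lambda a: (a - mu) / sd


def classify(
    train: LabeledDataset,
    test_rows: np.ndarray,
    method: str,
    k: int = 151,
    eta: float = 1e-2,
    kernel: str = "rbf",
    bandwidth="median",
    zeta: float = 1e-4,
    standardize: bool = False,
) -> np.ndarray:
    """Classify each test row with one of the five nearest-neighbour methods.

    Training features must be fully observed (impute first).  ``k`` is the
    neighbourhood size (the benchmark default is 151), ``eta`` the Gram
    regularization of the difference-weighted methods, ``kernel``/
    ``bandwidth`` the KDF/MKDF kernel, and ``zeta`` the additive constant of
    the MKDF correction factor.  With ``standardize`` the features are
    z-scored using training statistics before any distance computation.
    """
    if method not in CLASSIFIER_NAMES:
        raise ValueError(f"unknown classifier {method!r}; valid: {CLASSIFIER_NAMES}")
    if train.labels is None:
        raise ValueError("classify needs a labeled training set")
    x_train = _full_features(train)
    test_rows = np.atleast_2d(np.asarray(test_rows, dtype=float))
    _check_finite(test_rows, "test matrix")
    if test_rows.shape[1] != x_train.shape[1]:
        raise ValueError("train and test dimensionality differ")
    if not 1 <= k <= len(x_train):
        raise ValueError(f"k={k} must be in 1..{len(x_train)}")

    if standardize:
        scale = _standardizer(x_train)
        x_train = scale(x_train)
        test_rows = scale(test_rows)
        train = LabeledDataset.from_arrays(x_train, train.labels)

    gamma = correction_factors(train, zeta) if method == "mkdfwknn" else None

    sqd = _pairwise_sqdist(test_rows, x_train)
    predictions = np.empty(len(test_rows), dtype=int)
    for i in range(len(test_rows)):
        order = np.argsort(sqd[i], kind="stable")[:k]
        neighbors = NeighborSet(
            indices=order,
            distances=np.sqrt(sqd[i][order]),
            labels=train.labels[order],
            query=test_rows[i],
        )
        if method == "knn":
            predictions[i] = knn_predict(neighbors)
            continue
        if method == "dswknn":
            weights = dswknn_weights(neighbors)
        elif method == "dfwknn":
            weights = dfwknn_weights(neighbors, x_train[order], eta)
        else:  # kdfwknn, mkdfwknn
            ctx = kernel_gram(neighbors, x_train[order], kernel, bandwidth)
            weights = WeightVector(solve_gram_weights(ctx.g, eta))
        predictions[i] = weighted_vote(neighbors, weights, gamma)
    return predictions
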