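"""Benchmark harness: missingness injection, k-fold CV, imputer x classifier grid.

The experimental procedure mirrors the study design for incomplete
arrhythmia-style feature tables:

1. delete an additional random set of feature cells so the table reaches a
   target overall missing proportion;
2. impute the whole table with one of the four imputers;
3. run 10-fold cross-validation of a nearest-neighbour classifier (k = 151
   by default) on the completed table;
4. report per-fold and mean accuracy per (imputer, classifier, proportion)
   cell.

Imputing the full table before splitting folds follows that original
pipeline and leaks test-row information into the imputation; a
``per_fold_imputation`` flag provides the leakage-free variant in which the
imputer is fitted on the training folds only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_io import LabeledDataset, MaskedMatrix
from .imputation import (
    IMPUTER_NAMES,
    PCAImputeConfig,
    SVTConfig,
    _observed_column_means,
    impute,
    pca_basis,
    pca_reconstruct_rows,
    svt_complete,
)
from .classifiers import CLASSIFIER_NAMES, classify

__all__ = [
    "MissingnessSpec",
    "CVReport",
    "BenchmarkResult",
    "inject_missing",
    "kfold_indices",
    "cross_validate",
    "benchmark_grid",
]


@dataclass
class MissingnessSpec:
    """Target overall missing proportion (feature cells only) and seed."""

    target_proportion: float
    seed: int

    def __post_init__(self) -> None:
        if not 0 <= self.target_proportion < 1:
            raise ValueError("target proportion must lie in [0, 1)")


@dataclass
class CVReport:
    """Cross-validation outcome for one (imputer, classifier, proportion) cell."""

    imputer: str
    classifier: str
    proportion: Optional[float]
    fold_accuracies: list
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    def to_dict(self) -> dict:
        out = asdict(self)
        out["mean_accuracy"] = self.mean_accuracy
        return out


def inject_missing(data: MaskedMatrix, spec: MissingnessSpec) -> MaskedMatrix:
    """Mask additional observed cells so the overall missing fraction hits the target.

    The number of missing cells in the result is exactly
    ``round(target * N * d)``; the extra cells are drawn uniformly at random
    (seeded) from the currently observed ones, existing missing cells stay
    missing, and newly masked cells have their placeholder zeroed so no
    imputer can see the deleted values.
    """
    n_cells = data.mask.size
    n_target = int(round(spec.target_proportion * n_cells))
    n_current = data.n_missing
    if n_target < n_current:
        raise ValueError(
            f"target proportion {spec.target_proportion} is below the current "
            f"missing fraction {data.missing_fraction:.4f}"
        )
    extra = n_target - n_current
    mask = data.mask.copy()
    if extra > 0:
        rng = np.random.default_rng(spec.seed)
        observed_flat = np.flatnonzero(mask.ravel())
        chosen = rng.choice(observed_flat, size=extra, replace=False)
        mask.ravel()[chosen] = 0
    values = np.where(mask, data.values, 0.0)
    return MaskedMatrix(values, mask)


def kfold_indices(n: int, folds: int, seed: int) -> list:
    """Seeded shuffled partition of range(n) into ``folds`` near-equal folds.

    Folds are disjoint, cover every row, and differ in size by at most 1.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError(f"cannot split {n} rows into {folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, folds)]


def _impute_full(features: MaskedMatrix, imputer: str, pca_config, svt_config) -> np.ndarray:
    config = {"pca": pca_config, "svt": svt_config}.get(imputer)
    return impute(features, imputer, config).completed


def _impute_per_fold(
    features: MaskedMatrix,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    imputer: str,
    pca_config,
    svt_config,
):
    """Leakage-free imputation: fit on the training block, apply to both blocks.

    zero/mean transfer trivially (zeros / training column means).  PCA
    transfers its basis: test rows are reconstructed with the train-fold
    projector and mean.  SVT is transductive with no out-of-sample rule, so
    the train block is completed by SVT and test-row missing cells take the
    completed-train column means.
    """
    train_block = MaskedMatrix(features.values[train_idx], features.mask[train_idx])
    test_block = MaskedMatrix(features.values[test_idx], features.mask[test_idx])
    t_obs = test_block.mask.astype(bool)

    if imputer == "zero":
        train_done = train_block.observed_values()
        test_done = test_block.observed_values()
    elif imputer == "mean":
        means = _observed_column_means(train_block)
        train_done = np.where(train_block.mask, train_block.values, means)
        test_done = np.where(t_obs, test_block.values, means)
    elif imputer == "pca":
        w, mu, _ = pca_basis(train_block, pca_config)
        fallback = _observed_column_means(train_block)
        train_fill, _ = pca_reconstruct_rows(train_block, w, mu, fallback)
        test_fill, _ = pca_reconstruct_rows(test_block, w, mu, fallback)
        train_done = np.where(train_block.mask, train_block.values, train_fill)
        test_done = np.where(t_obs, test_block.values, test_fill)
    elif imputer == "svt":
        train_done = svt_complete(train_block, svt_config).completed
        means = train_done.mean(axis=0)
        test_done = np.where(t_obs, test_block.values, means)
    else:
        raise ValueError(f"unknown imputation method {imputer!r}; valid: {IMPUTER_NAMES}")
    return train_done, test_done


def _resolve_k(k: int, n_train: int, clamp_k: bool) -> int:
    if k <= n_train:
        return k
    if clamp_k:
        warnings.warn(f"k={k} exceeds training-fold size {n_train}; clamping")
        return n_train
    raise ValueError(f"k={k} exceeds the smallest training-fold size {n_train}")


# Benchmark SVT runs are capped at 500 shrinkage iterations: tabular data
# are not exactly low rank, so the residual tolerance is never reached and
# the cap bounds the cost of one grid cell.
BENCHMARK_SVT_CONFIG = SVTConfig(max_iter=500)


def cross_validate(
    data: LabeledDataset,
    imputer: str,
    classifier: str,
    folds: int = 10,
    seed: int = 0,
    k: int = 151,
    eta: float = 1e-2,
    kernel: str = "rbf",
    bandwidth="median",
    zeta: float = 1e-4,
    per_fold_imputation: bool = False,
    pca_config: Optional[PCAImputeConfig] = None,
    svt_config: Optional[SVTConfig] = None,
    proportion: Optional[float] = None,
    clamp_k: bool = False,
) -> CVReport:
    """Impute, then k-fold cross-validate one classifier on the completed table.

    By default the imputer sees the whole masked table once before folds are
    split (the original pipeline order); ``per_fold_imputation`` refits the
    imputer inside each training fold instead.  The MKDF correction factors
    are always computed from the training folds only, because ``classify``
    derives them from the training set it receives.
    """
    if classifier not in CLASSIFIER_NAMES:
        raise ValueError(f"unknown classifier {classifier!r}; valid: {CLASSIFIER_NAMES}")
    if imputer not in IMPUTER_NAMES:
        raise ValueError(f"unknown imputation method {imputer!r}; valid: {IMPUTER_NAMES}")
    if data.labels is None:
        raise ValueError("cross-validation needs labels")

    fold_sets = kfold_indices(data.n, folds, seed)
    smallest_train = data.n - max(len(f) for f in fold_sets)
    k_eff = _resolve_k(k, smallest_train, clamp_k)

    completed = None
    if not per_fold_imputation:
        completed = _impute_full(data.features, imputer, pca_config, svt_config)

    accuracies = []
    all_idx = np.arange(data.n)
    for test_idx in fold_sets:
        train_idx = np.setdiff1d(all_idx, test_idx)
        if per_fold_imputation:
            x_train, x_test = _impute_per_fold(
                data.features, train_idx, test_idx, imputer, pca_config, svt_config
            )
        else:
            x_train, x_test = completed[train_idx], completed[test_idx]
        train = LabeledDataset.from_arrays(x_train, data.labels[train_idx])
        pred = classify(
            train, x_test, classifier,
            k=min(k_eff, len(train_idx)), eta=eta, kernel=kernel,
            bandwidth=bandwidth, zeta=zeta,
        )
        accuracies.append(float(np.mean(pred == data.labels[test_idx])))

    return CVReport(
        imputer=imputer,
        classifier=classifier,
        proportion=proportion,
        fold_accuracies=accuracies,
        seed=seed,
        params={
            "k": k_eff, "eta": eta, "kernel": kernel,
            "bandwidth": str(bandwidth), "zeta": zeta, "folds": folds,
            "per_fold_imputation": per_fold_imputation,
        },
    )


@dataclass
class BenchmarkResult:
    """All CVReports of a proportions x imputers x classifiers grid."""

    reports: list
    seed: int

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {"seed": self.seed, "reports": [r.to_dict() for r in self.reports]},
            indent=indent,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "classifier": r.classifier,
                "imputer": r.imputer,
                "proportion": r.proportion,
                "mean_accuracy": r.mean_accuracy,
            }
            for r in self.reports
        ]
        return pd.DataFrame(rows)

    def to_text_table(self) -> str:
        """Accuracy matrix (percent): classifier x imputer rows, proportion columns."""
        frame = self.to_frame()
        frame["mean_accuracy"] *= 100.0
        pivot = frame.pivot_table(
            index=["classifier", "imputer"],
            columns="proportion",
            values="mean_accuracy",
            sort=False,
        )
        pivot.columns = [f"{100 * p:g}%" for p in pivot.columns]
        return pivot.to_string(float_format=lambda v: f"{v:.2f}")

    def lookup(self, imputer: str, classifier: str, proportion: float) -> CVReport:
        for r in self.reports:
            if (
                r.imputer == imputer
                and r.classifier == classifier
                and r.proportion == proportion
            ):
                return r
        raise KeyError((imputer, classifier, proportion))


def _injection_seed(master_seed: int, proportion: float) -> int:
    ss = np.random.SeedSequence([master_seed, int(round(proportion * 10000))])
    return int(ss.generate_state(1)[0] % (2**31))


def benchmark_grid(
    data: LabeledDataset,
    proportions: Sequence[float],
    imputers: Sequence[str] = IMPUTER_NAMES,
    classifiers: Sequence[str] = CLASSIFIER_NAMES,
    folds: int = 10,
    seed: int = 0,
    k: int = 151,
    eta: float = 1e-2,
    kernel: str = "rbf",
    bandwidth="median",
    zeta: float = 1e-4,
    per_fold_imputation: bool = False,
    pca_config: Optional[PCAImputeConfig] = None,
    svt_config: Optional[SVTConfig] = None,
) -> BenchmarkResult:
    """Run the full imputer x classifier grid over missing proportions.

    One deletion pattern is drawn per proportion (seeded deterministically
    from the master seed) and shared by every imputer and classifier, so
    cells at the same proportion are compared on identical missingness.
    Each (proportion, imputer) pair is imputed once and scored by all
    classifiers on the same fold partition.
    """
    if svt_config is None:
        svt_config = BENCHMARK_SVT_CONFIG
    reports = []
    for proportion in proportions:
        masked = inject_missing(
            data.features,
            MissingnessSpec(proportion, _injection_seed(seed, proportion)),
        )
        injected = LabeledDataset(masked, data.labels)
        for imputer in imputers:
            completed = None
            if not per_fold_imputation:
                completed = _impute_full(masked, imputer, pca_config, svt_config)
            for classifier in classifiers:
                if per_fold_imputation:
                    report = cross_validate(
                        injected, imputer, classifier,
                        folds=folds, seed=seed, k=k, eta=eta, kernel=kernel,
                        bandwidth=bandwidth, zeta=zeta,
                        per_fold_imputation=True,
                        pca_config=pca_config, svt_config=svt_config,
                        proportion=proportion, clamp_k=True,
                    )
                else:
                    report = cross_validate(
                        LabeledDataset.from_arrays(completed, data.labels),
                        "zero",  # table already complete; zero is a no-op
                        classifier,
                        folds=folds, seed=seed, k=k, eta=eta, kernel=kernel,
                        bandwidth=bandwidth, zeta=zeta,
                        proportion=proportion, clamp_k=True,
                    )
                    report.imputer = imputer
                reports.append(report)
    return BenchmarkResult(reports, seed)
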