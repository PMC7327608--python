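"""Four imputers for incomplete feature matrices.

* ``impute_zero``  -- fill missing cells with 0.
* ``impute_mean``  -- fill with the observed column mean.
* ``pca_impute``   -- masked-PCA reconstruction: eigenvectors of the masked
  scatter matrix give a low-dimensional basis; each row's coordinates are
  recovered by least squares on its observed entries only.
* ``svt_complete`` -- low-rank matrix completion by singular value
  thresholding (SVT): iterate a singular-value shrinkage step and an
  observed-entry correction step on the nuclear-norm relaxation of the
  rank-minimisation problem.

All imputers share the contract that observed cells pass through
bit-identical and the output has no missing cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .data_io import MaskedMatrix

__all__ = [
    "PCAImputeConfig",
    "SVTConfig",
    "ImputationResult",
    "impute_zero",
    "impute_mean",
    "masked_mean",
    "masked_scatter",
    "pca_impute",
    "soft_threshold_svd",
    "svt_complete",
    "impute",
    "IMPUTER_NAMES",
]

IMPUTER_NAMES = ("zero", "mean", "pca", "svt")


@dataclass
class PCAImputeConfig:
    """Configuration for masked-PCA imputation.

    n_components : int or "auto"
        Number of retained eigenvectors q.  "auto" keeps the smallest q
        whose (non-negative-clamped) eigenvalues cover 95% of the positive
        eigenvalue mass.
    mean_divisor_mode : {"paper_literal", "observed_count"}
        "paper_literal" divides masked column sums by the total row count N;
        "observed_count" divides by the number of observed cells per column.
    center : bool
        Subtract the masked mean before projection and add it back on
        reconstruction.
    """

    n_components: Union[int, str] = "auto"
    mean_divisor_mode: str = "paper_literal"
    center: bool = True

    def __post_init__(self) -> None:
        if self.mean_divisor_mode not in ("paper_literal", "observed_count"):
            raise ValueError(f"unknown divisor mode {self.mean_divisor_mode!r}")
        if self.n_components != "auto":
            q = int(self.n_components)
            if q < 1:
                raise ValueError("n_components must be >= 1 or 'auto'")
            self.n_components = q


@dataclass
class SVTConfig:
    """Configuration for SVT matrix completion.

    ``tau`` (shrinkage level) and ``step_size`` (delta) are resolved against
    the input matrix at call time when left as None: tau = 25 * max(N, d)
    and delta = min(1.2 * N * d / |Omega|, 1.9).  The SVT fixed point only
    approaches the exact nuclear-norm minimiser for large tau; the common
    5 * max(N, d) heuristic leaves a visible shrinkage bias on small
    matrices, so the default is 25 * max(N, d).  The step-size sequence is
    constant.
    """

    tau: Optional[float] = None
    step_size: Optional[float] = None
    tolerance: float = 1e-4
    max_iter: int = 5000

    def __post_init__(self) -> None:
        if self.tau is not None and self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.step_size is not None and self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")

    def resolved(self, n_rows: int, n_cols: int, n_observed: int) -> "SVTConfig":
        tau = self.tau if self.tau is not None else 25.0 * max(n_rows, n_cols)
        if self.step_size is not None:
            delta = self.step_size
        elif n_observed > 0:
            delta = min(1.2 * n_rows * n_cols / n_observed, 1.9)
        else:
            delta = 1.0
        return SVTConfig(tau, delta, self.tolerance, self.max_iter)


@dataclass
class ImputationResult:
    """A completed matrix plus method diagnostics."""

    completed: np.ndarray
    method: str
    diagnostics: dict = field(default_factory=dict)


def _finish(data: MaskedMatrix, fill: np.ndarray, method: str, diagnostics=None) -> ImputationResult:
    """Combine: observed cells from the input, missing cells from ``fill``."""
    observed = data.mask.astype(bool)
    completed = np.where(observed, data.values, fill)
    return ImputationResult(completed, method, diagnostics or {})


def impute_zero(data: MaskedMatrix) -> ImputationResult:
    """Fill every missing cell with 0."""
    return _finish(data, np.zeros(data.shape), "zero")


def _observed_column_means(data: MaskedMatrix) -> np.ndarray:
    counts = data.mask.sum(axis=0)
    sums = data.observed_values().sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return means


def impute_mean(data: MaskedMatrix) -> ImputationResult:
    """Fill each missing cell with its column's observed-value mean.

    Columns with no observed value fall back to 0.
    """
    means = _observed_column_means(data)
    fill = np.broadcast_to(means, data.shape)
    return _finish(data, fill, "mean", {"column_means": means})


def masked_mean(data: MaskedMatrix, divisor_mode: str = "paper_literal") -> np.ndarray:
    """Column means of the observed entries.

    ``paper_literal`` divides the masked sum by the total row count N, i.e.
    x_bar_i = (1/N) sum_j x_j^(i) z_j^(i); ``observed_count`` divides by the
    number of observed entries in the column (0 when none are observed).
    """
    if divisor_mode == "paper_literal":
        return data.observed_values().sum(axis=0) / data.n_rows
    if divisor_mode == "observed_count":
        return _observed_column_means(data)
    raise ValueError(f"unknown divisor mode {divisor_mode!r}")


def masked_scatter(data: MaskedMatrix, divisor_mode: str = "paper_literal") -> np.ndarray:
    """Masked scatter matrix S(k,l) = (1/N) sum_j x_jk x_jl z_jk z_jl - xbar_k xbar_l.

    Only co-observed entry pairs contribute to the cross-product term; the
    mean is the masked mean under the same divisor mode.  Reduces to the
    classical scatter (1/N) X'X - xbar xbar' when the mask is all ones.
    The result is symmetric but can be indefinite under heavy masking.
    """
    xz = data.observed_values()
    xbar = masked_mean(data, divisor_mode)
    s = xz.T @ xz / data.n_rows - np.outer(xbar, xbar)
    return (s + s.T) / 2.0


def _auto_components(eigvals_desc: np.ndarray, mass: float = 0.95) -> int:
    pos = np.clip(eigvals_desc, 0.0, None)
    total = pos.sum()
    if total <= 0:
        return 1
    cum = np.cumsum(pos) / total
    return int(np.searchsorted(cum, mass) + 1)


def pca_basis(data: MaskedMatrix, config: Optional[PCAImputeConfig] = None):
    """Fit the masked-PCA basis: (W, mu, retained eigenvalues).

    W holds the top-q eigenvectors (descending eigenvalue) of the masked
    scatter matrix; mu is the masked mean when centering is on, else 0.
    """
    config = config or PCAImputeConfig()
    d = data.n_cols
    if config.n_components != "auto" and config.n_components > d:
        raise ValueError(f"n_components={config.n_components} exceeds {d} columns")
    scatter = masked_scatter(data, config.mean_divisor_mode)
    eigvals, eigvecs = np.linalg.eigh(scatter)  # ascending
    eigvals, eigvecs = eigvals[::-1], eigvecs[:, ::-1]
    q = config.n_components if config.n_components != "auto" else _auto_components(eigvals)
    w = eigvecs[:, :q]
    mu = masked_mean(data, config.mean_divisor_mode) if config.center else np.zeros(d)
    return w, mu, eigvals[:q].copy()


def pca_reconstruct_rows(
    rows: MaskedMatrix, w: np.ndarray, mu: np.ndarray, fallback: np.ndarray
):
    """Reconstruct each row from a fitted basis by restricted least squares.

    For a row with observed coordinates o the coordinates y solve
    min_y ||x_o - mu_o - W_o y||^2 (least-norm solution when the restricted
    system is singular) and the reconstruction is mu + W y.  Rows with no
    observed coordinate take ``fallback`` (column means).  Returns the
    reconstruction matrix and the list of empty-row indices.
    """
    observed = rows.mask.astype(bool)
    recon = np.empty(rows.shape)
    empty_rows = []
    for j in range(rows.n_rows):
        obs = observed[j]
        if not obs.any():
            recon[j] = fallback
            empty_rows.append(j)
            continue
        r = rows.values[j, obs] - mu[obs]
        y, *_ = np.linalg.lstsq(w[obs, :], r, rcond=None)
        recon[j] = mu + w @ y
    return recon, empty_rows


def pca_impute(data: MaskedMatrix, config: Optional[PCAImputeConfig] = None) -> ImputationResult:
    """Masked-PCA reconstruction of missing cells.

    The projector W holds the top-q eigenvectors of the masked scatter
    matrix.  For each row the low-dimensional coordinates y solve the least
    squares problem restricted to the row's observed coordinates,

        min_y  sum_i z_j^(i) (x_j^(i) - mu^(i) - (W y)^(i))^2,

    and the reconstruction mu + W y fills that row's missing cells.  Rows
    with no observed cell are filled with observed column means and listed
    in ``diagnostics["empty_rows"]``.
    """
    config = config or PCAImputeConfig()
    w, mu, eigvals = pca_basis(data, config)
    col_means = _observed_column_means(data)
    fill, empty_rows = pca_reconstruct_rows(data, w, mu, col_means)
    diagnostics = {
        "n_components": w.shape[1],
        "eigenvalues": eigvals,
        "empty_rows": empty_rows,
    }
    return _finish(data, fill, "pca", diagnostics)


def soft_threshold_svd(x: np.ndarray, tau: float) -> np.ndarray:
    """Singular-value soft-thresholding: U diag((sigma_i - tau)_+) V*.

    Shrinks every singular value by ``tau`` and floors at zero; singular
    values below ``tau`` vanish, so the result has reduced rank.  The
    operator is non-expansive in the Frobenius norm.
    """
    u, s, vt = np.linalg.svd(np.asarray(x, dtype=float), full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    keep = s > 0
    return (u[:, keep] * s[keep]) @ vt[keep]


def svt_complete(data: MaskedMatrix, config: Optional[SVTConfig] = None) -> ImputationResult:
    """Complete a partially observed matrix by singular value thresholding.

    Iterates, from Y_0 = 0,

        X_k = shrink_tau(Y_{k-1});   Y_k = Y_{k-1} + delta * P_Omega(M - X_k),

    where P_Omega zeroes entries outside the observed set, until the
    relative residual on observed entries ||P_Omega(X_k - M)||_F /
    ||P_Omega(M)||_F drops below the tolerance or ``max_iter`` is reached
    (then the best iterate is returned with ``converged=False`` -- no
    exception).  Observed cells of the output keep their input values.
    """
    base = config or SVTConfig()
    observed = data.mask.astype(bool)
    n_obs = int(observed.sum())
    if n_obs == 0:
        raise ValueError("svt_complete requires at least one observed cell")
    cfg = base.resolved(data.n_rows, data.n_cols, n_obs)

    m = data.observed_values()
    norm_m = np.linalg.norm(m)
    if norm_m == 0:
        warnings.warn("all observed entries are zero; returning zero completion")
        return _finish(
            data, np.zeros(data.shape), "svt",
            {"iterations": 0, "relative_residual": 0.0, "converged": True,
             "tau": cfg.tau, "step_size": cfg.step_size,
             "warning": "zero observed data"},
        )

    y = np.zeros(data.shape)
    best_x = np.zeros(data.shape)
    best_res = np.inf
    converged = False
    iterations = 0
    for iterations in range(1, cfg.max_iter + 1):
        x = soft_threshold_svd(y, cfg.tau)
        residual = np.where(observed, m - x, 0.0)
        rel = np.linalg.norm(residual) / norm_m
        if rel < best_res:
            best_res = rel
            best_x = x
        if rel <= cfg.tolerance:
            converged = True
            break
        y = y + cfg.step_size * residual

    diagnostics = {
        "iterations": iterations,
        "relative_residual": best_res,
        "converged": converged,
        "tau": cfg.tau,
        "step_size": cfg.step_size,
    }
    return _finish(data, best_x, "svt", diagnostics)


def impute(data: MaskedMatrix, method: str, config=None) -> ImputationResult:
    """Dispatch to one of the four imputers by name."""
    if method == "zero":
        return impute_zero(data)
    if method == "mean":
        return impute_mean(data)
    if method == "pca":
        return pca_impute(data, config)
    if method == "svt":
        return svt_complete(data, config)
    raise ValueError(f"unknown imputation method {method!r}; valid: {IMPUTER_NAMES}")
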