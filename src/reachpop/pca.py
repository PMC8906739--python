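"""PCA on stacked square-root-transformed spike counts.

The data matrix D has one row per (trial, time-bin) pair and one column
per unit; PCA yields X = DW with orthonormal weight columns W, giving
low-dimensional population trajectories once projections are
trial-averaged and strung together across time. Columns are mean-
centered before the decomposition, and each component's sign is fixed so
its largest-magnitude weight is positive, making results seed-stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["PCAResult", "fit_pca", "pc_trajectories"]


@dataclass
class PCAResult:
    W: np.ndarray  # (units, components), orthonormal columns
    X: np.ndarray  # (rows, components) projections of centered data
    explained_variance_ratio: np.ndarray  # descending
    column_means: np.ndarray

    @property
    def n_components(self) -> int:
        return self.W.shape[1]


def fit_pca(D: np.ndarray, n_components: Optional[int] = None) -> PCAResult:
    """PCA of a (rows, units) matrix via SVD of the centered data."""
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] < 2:
        raise ValueError("D must be 2D with at least 2 rows")
    n_rows, n_units = D.shape
    max_k = min(n_rows - 1, n_units)
    if n_components is None:
        n_components = max_k
    if not 1 <= n_components <= max_k:
        raise ValueError(f"n_components must be in [1, {max_k}]")
    mu = D.mean(axis=0)
    Dc = D - mu
    _, s, Vt = np.linalg.svd(Dc, full_matrices=False)
    W = Vt[:n_components].T
    # sign convention: largest-|weight| element of each component positive
    for j in range(n_components):
        i = int(np.argmax(np.abs(W[:, j])))
        if W[i, j] < 0:
            W[:, j] = -W[:, j]
    X = Dc @ W
    total_var = float(np.sum(Dc**2))
    evr = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    return PCAResult(W=W, X=X, explained_variance_ratio=evr, column_means=mu)


def pc_trajectories(
    result: PCAResult,
    n_bins: int,
    n_trials: int,
    top_k: int = 3,
    condition_labels: Optional[Sequence] = None,
) -> dict:
    """Trial-averaged population trajectories along the top PCs.

    Rows of ``result.X`` must be ordered bin-major within trial, trials
    concatenated (the ``sqrt_stack`` convention). Returns a dict mapping
    condition label to a (n_bins, top_k) trajectory; without labels, a
    single 'all' trajectory averaged over every trial.
    """
    if result.X.shape[0] != n_bins * n_trials:
        raise ValueError("row count does not match n_bins * n_trials; unknown row order")
    top_k = min(top_k, result.n_components)
    X = result.X[:, :top_k].reshape(n_trials, n_bins, top_k)
    if condition_labels is None:
        return {"all": X.mean(axis=0)}
    condition_labels = np.asarray(condition_labels)
    if condition_labels.size != n_trials:
        raise ValueError("one condition label per trial required")
    return {str(c): X[condition_labels == c].mean(axis=0) for c in np.unique(condition_labels)}
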