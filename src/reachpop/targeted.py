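"""Targeted dimensionality reduction into AMP and DIR encoding dimensions.

Per-trial normalized spike counts over the outward-movement window are
regressed (consensus over batches of permuted trials) against movement
amplitude and direction, giving per-unit coefficient vectors beta_amp
and beta_dir. Gram-Schmidt orthogonalization (AMP first by default)
turns these into orthonormal population dimensions omega_a and omega_d.
Tuning along a dimension is the slope of a five-point line: trials are
split into equal-count quintiles of the behavioral value, and per
quintile the mean value is paired with the mean projection of weighted
activity onto the dimension. Direction is treated as a plain scalar in
radians; sessions whose direction arc exceeds pi are flagged because a
linear treatment of a circular variable is then dubious.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .preprocessing import TrialTensor

logger = logging.getLogger(__name__)

__all__ = [
    "EncodingDims",
    "TuningResult",
    "movement_window_counts",
    "consensus_regression",
    "orthonormalize",
    "quintile_tuning",
    "per_unit_tuning_slopes",
    "rank_auc",
]

ORTHO_TOL = 1e-10


@dataclass
class EncodingDims:
    """Orthonormal AMP and DIR population weight vectors."""

    omega_a: np.ndarray
    omega_d: np.ndarray
    gram_schmidt_order: str = "amp_first"

    def __post_init__(self) -> None:
        for name in ("omega_a", "omega_d"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if abs(np.linalg.norm(v) - 1.0) > ORTHO_TOL:
                raise ValueError(f"{name} must be unit-norm")
        if abs(float(self.omega_a @ self.omega_d)) > ORTHO_TOL:
            raise ValueError("omega_a and omega_d must be orthogonal")


@dataclass
class TuningResult:
    """Quintile tuning along one encoding dimension."""

    which: str  # 'AMP' or 'DIR'
    quintile_values: np.ndarray  # 5 behavioral means, strictly increasing
    quintile_proj: np.ndarray  # 5 mean projections
    slope: float  # z per mm (AMP) or z per rad (DIR)

    def __post_init__(self) -> None:
        if len(self.quintile_values) != 5 or len(self.quintile_proj) != 5:
            raise ValueError("exactly 5 quintile points required")
        if not np.all(np.diff(self.quintile_values) > 0):
            raise ValueError("quintile behavioral means must be strictly increasing")


def movement_window_counts(
    tensor: TrialTensor,
    window: tuple[float, float] = (0.0, 0.35),
    normalize: bool = True,
    sd_floor: float = 1e-12,
) -> np.ndarray:
    """Per-trial spike count in the outward-movement window, per unit.

    ``tensor`` must be aligned to reach start with raw counts. The
    window (seconds relative to reach start) defaults to the outward
    stroke plus hold. With ``normalize`` the counts are z-scored per
    unit across trials (silent units floored to all-zero). Returns a
    (trials, units) matrix.
    """
    if tensor.transform != "raw":
        raise ValueError("movement_window_counts expects raw counts")
    lo, hi = window
    centers = tensor.bin_centers
    mask = (centers >= lo) & (centers < hi)
    if not mask.any():
        raise ValueError("movement window contains no bins")
    counts = tensor.counts[:, mask, :].sum(axis=1).T.astype(float)  # (trials, units)
    if counts.shape[0] == 0:
        raise ValueError("window covers zero trials")
    if normalize:
        mu = counts.mean(axis=0)
        sd = counts.std(axis=0)
        silent = sd < sd_floor
        sd = np.where(silent, 1.0, sd)
        counts = (counts - mu) / sd
        counts[:, silent] = 0.0
    return counts


def consensus_regression(
    counts: np.ndarray,
    values: np.ndarray,
    n_batches: int = 50,
    batch_size: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Consensus per-unit regression coefficients of counts on a kinematic value.

    For each batch of permuted trials the simple least-squares slope
    ``cov(count_u, value) / var(value)`` is computed per unit; the
    consensus coefficient is the mean over batches. ``batch_size=None``
    uses every trial in each batch, so ``n_batches=1`` reduces to a
    plain regression.
    """
    counts = np.asarray(counts, dtype=float)
    values = np.asarray(values, dtype=float)
    if counts.shape[0] != values.size:
        raise ValueError("counts and values must agree on the trial count")
    if np.unique(values).size < 2:
        raise ValueError("values must take at least 2 distinct values")
    if rng is None:
        rng = np.random.default_rng(0)
    n_trials = values.size

    def slope(idx: np.ndarray) -> np.ndarray:
        v = values[idx]
        c = counts[idx]
        vc = v - v.mean()
        denom = float(vc @ vc)
        if denom == 0:
            return np.zeros(counts.shape[1])
        return (c - c.mean(axis=0)).T @ vc / denom

    if batch_size is None or batch_size >= n_trials:
        if n_batches == 1:
            return slope(np.arange(n_trials))
        betas = [slope(rng.permutation(n_trials)) for _ in range(n_batches)]
    else:
        betas = [
            slope(rng.choice(n_trials, size=batch_size, replace=False))
            for _ in range(n_batches)
        ]
    return np.mean(betas, axis=0)


def orthonormalize(
    beta_amp: np.ndarray,
    beta_dir: np.ndarray,
    order: str = "amp_first",
    collinear_tol: float = 1e-8,
) -> EncodingDims:
    """Gram-Schmidt the consensus coefficient vectors into orthonormal dims.

    With ``amp_first`` (default), omega_a is beta_amp normalized and
    omega_d is beta_dir with its omega_a component removed, then
    normalized. Swapping the order changes omega_d (documented order
    sensitivity); the regression coefficients themselves are order-free.
    """
    a = np.asarray(beta_amp, dtype=float)
    d = np.asarray(beta_dir, dtype=float)
    if order == "dir_first":
        dims = orthonormalize(d, a, order="amp_first", collinear_tol=collinear_tol)
        return EncodingDims(
            omega_a=dims.omega_d, omega_d=dims.omega_a, gram_schmidt_order="dir_first"
        )
    na, nd = np.linalg.norm(a), np.linalg.norm(d)
    if na == 0 or nd == 0:
        raise ValueError("coefficient vectors must be nonzero")
    omega_a = a / na
    resid = d - (d @ omega_a) * omega_a
    if np.linalg.norm(resid) < collinear_tol * nd:
        raise ValueError("beta_amp and beta_dir are collinear; dimensions degenerate")
    omega_d = resid / np.linalg.norm(resid)
    return EncodingDims(omega_a=omega_a, omega_d=omega_d, gram_schmidt_order="amp_first")


def _quintile_splits(values: np.ndarray) -> list[np.ndarray]:
    order = np.argsort(values, kind="stable")
    return np.array_split(order, 5)


def quintile_tuning(
    counts: np.ndarray,
    values: np.ndarray,
    dims: EncodingDims,
    which: str,
) -> TuningResult:
    """Five-point quintile tuning along the AMP or DIR dimension.

    Trials are split into 5 equal-count bins of the behavioral value
    (stable sort breaks ties); per bin the mean value is paired with the
    mean projection ``counts @ omega``. The slope of the least-squares
    line through the 5 points is the tuning.
    """
    counts = np.asarray(counts, dtype=float)
    values = np.asarray(values, dtype=float)
    if which not in ("AMP", "DIR"):
        raise ValueError("which must be 'AMP' or 'DIR'")
    if np.unique(values).size < 5:
        raise ValueError("need at least 5 distinct behavioral values for quintiles")
    omega = dims.omega_a if which == "AMP" else dims.omega_d
    proj = counts @ omega
    vq, pq = [], []
    for idx in _quintile_splits(values):
        vq.append(values[idx].mean())
        pq.append(proj[idx].mean())
    vq = np.asarray(vq)
    pq = np.asarray(pq)
    slope = float(np.polyfit(vq, pq, 1)[0])
    return TuningResult(which=which, quintile_values=vq, quintile_proj=pq, slope=slope)


def per_unit_tuning_slopes(
    counts: np.ndarray,
    amplitudes: np.ndarray,
    directions: np.ndarray,
    dims: EncodingDims,
) -> pd.DataFrame:
    """Per-unit AMP and DIR tuning: slope of the unit's weighted activity.

    For unit ``u``, its weighted z-scored activity along a dimension is
    ``omega[u] * counts[:, u]``; the tuning is the slope of its quintile
    means against the quintile behavioral means. Returns a DataFrame
    with columns omega_a, omega_d, amp_slope, dir_slope and the
    preferential-tuning difference ``amp_slope - dir_slope``.
    """
    counts = np.asarray(counts, dtype=float)
    n_units = counts.shape[1]
    out = np.zeros((n_units, 2))
    for col, (vals, omega) in enumerate(
        [(np.asarray(amplitudes, float), dims.omega_a), (np.asarray(directions, float), dims.omega_d)]
    ):
        splits = _quintile_splits(vals)
        vq = np.array([vals[idx].mean() for idx in splits])
        # (5, units) mean weighted activity per quintile
        pq = np.stack([(counts[idx] * omega).mean(axis=0) for idx in splits])
        vc = vq - vq.mean()
        out[:, col] = (pq - pq.mean(axis=0)).T @ vc / float(vc @ vc)
    df = pd.DataFrame(
        {
            "omega_a": dims.omega_a,
            "omega_d": dims.omega_d,
            "amp_slope": out[:, 0],
            "dir_slope": out[:, 1],
        }
    )
    df.index.name = "unit_id"
    df["tuning_diff"] = df["amp_slope"] - df["dir_slope"]
    return df


def rank_auc(positives: np.ndarray, negatives: np.ndarray) -> float:
    """Rank-separation AUC: P(random positive > random negative), ties 1/2.

    Used to quantify how well a per-unit statistic (e.g. the AMP-minus-
    DIR tuning difference) separates two planted unit classes.
    """
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))
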