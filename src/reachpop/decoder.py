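"""Consensus (committee) linear decoding of joystick position.

A linear map ``W_decode`` (units x 2) predicts the 2D joystick position
from z-scored, Gaussian-smoothed population rates: ``K_hat = F.T @
W_decode`` with ``F`` (units x timepoints). Rather than one global
least-squares fit, many batches of movements are drawn in permuted
order, each batch decoder is solved with the pseudoinverse (the
mean-squared-error optimum), and the consensus decoder is the mean of
the batch decoders. Performance is the Pearson correlation between
predicted and actual position on held-out movements, compared against a
movement-shuffled control; the contribution of a unit subset is the
held-out correlation using only that subset's weights, normalized to the
full decoder's correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DecoderModel",
    "fit_batch",
    "fit_consensus",
    "decode",
    "evaluate",
    "partial_contribution",
    "pearson_pooled",
]

PINV_RCOND = 1e-10


@dataclass
class DecoderModel:
    W_decode: np.ndarray  # (units, 2)
    batch_decoders: list = field(default_factory=list)
    heldout_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    performance: dict = field(default_factory=dict)
    shuffle_r: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return self.W_decode.shape[0]


def fit_batch(F: np.ndarray, K: np.ndarray, rcond: float = PINV_RCOND) -> np.ndarray:
    """Least-squares decoder for one batch: ``W = pinv(F.T) @ K``.

    ``F`` is units x timepoints, ``K`` timepoints x 2. The SVD
    pseudoinverse (relative singular-value cutoff ``rcond``) returns the
    minimum-norm solution of the MSE-optimal weights; an all-zero ``F``
    therefore yields ``W = 0``.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    K = np.asarray(K, dtype=float)
    if K.ndim == 1:
        K = K[:, None]
    if F.size == 0 or K.size == 0:
        raise ValueError("empty input")
    if F.shape[1] != K.shape[0]:
        raise ValueError("F and K must share the timepoint count")
    return np.linalg.pinv(F.T, rcond=rcond) @ K


def _concat_movements(F: np.ndarray, K: np.ndarray, windows: Sequence[np.ndarray],
                      which: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    cols = np.concatenate([np.asarray(windows[i]) for i in which])
    return F[:, cols], K[cols]


def fit_consensus(
    F: np.ndarray,
    K: np.ndarray,
    reach_windows: Sequence[np.ndarray],
    n_batches: int = 50,
    batch_size: int = 50,
    heldout_frac: float = 0.10,
    rng: Optional[np.random.Generator] = None,
    n_shuffles: int = 100,
) -> DecoderModel:
    """Fit the consensus decoder and evaluate it on held-out movements.

    ``reach_windows[i]`` is the array of timepoint columns of movement
    ``i``. A random ~``heldout_frac`` of movements is held out; the
    remainder is permuted, and each of ``n_batches`` batches draws
    ``batch_size`` movements without replacement within the batch
    (independently across batches; with replacement, logged, if the pool
    is smaller than a batch). ``W_decode`` is the element-wise mean of
    the batch decoders.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n_mov = len(reach_windows)
    n_hold = max(1, int(round(heldout_frac * n_mov)))
    if n_mov - n_hold < 1:
        raise ValueError("fewer movements than the holdout requires")
    perm = rng.permutation(n_mov)
    heldout = np.sort(perm[:n_hold])
    pool = perm[n_hold:]
    replace = batch_size > pool.size
    if replace:
        logger.info("fit_consensus: pool of %d movements smaller than batch size %d; "
                    "sampling with replacement", pool.size, batch_size)
    batch_Ws = []
    for _ in range(n_batches):
        chosen = rng.choice(pool, size=batch_size, replace=replace)
        Fb, Kb = _concat_movements(F, K, reach_windows, chosen)
        batch_Ws.append(fit_batch(Fb, Kb))
    W = np.mean(batch_Ws, axis=0)
    model = DecoderModel(W_decode=W, batch_decoders=batch_Ws, heldout_ids=heldout)
    F_h, K_h, wins_h = heldout_arrays(F, K, reach_windows, heldout)
    r_obs, shuffle = evaluate(model, F_h, K_h, windows=wins_h, n_shuffles=n_shuffles, rng=rng)
    model.performance = r_obs
    model.shuffle_r = shuffle
    return model


def heldout_arrays(F, K, reach_windows, heldout_ids):
    """Concatenate the held-out movements, re-indexing their windows."""
    cols = [np.asarray(reach_windows[i]) for i in heldout_ids]
    lengths = [c.size for c in cols]
    offs = np.cumsum([0] + lengths)
    wins = [np.arange(offs[j], offs[j + 1]) for j in range(len(cols))]
    allcols = np.concatenate(cols) if cols else np.empty(0, dtype=int)
    return F[:, allcols], K[allcols], wins


def decode(model: DecoderModel, F: np.ndarray) -> np.ndarray:
    """Predicted joystick position ``K_hat = F.T @ W_decode``."""
    F = np.atleast_2d(np.asarray(F, dtype=float))
    if F.shape[0] != model.n_units:
        raise ValueError(
            f"unit count mismatch: model has {model.n_units}, F has {F.shape[0]}"
        )
    return F.T @ model.W_decode


def pearson_pooled(K_hat: np.ndarray, K: np.ndarray) -> dict:
    """Pearson r per output dimension, their mean, and pooled over x,y.

    The pooled value (default performance figure) correlates the x and y
    traces concatenated into one vector. A constant prediction has
    undefined correlation; it is reported as 0 with a flag.
    """
    out = {"flagged": False}
    rs = []
    for d, name in enumerate(("x", "y")):
        a, b = K_hat[:, d], K[:, d]
        if np.std(a) == 0 or np.std(b) == 0:
            out[f"r_{name}"] = 0.0
            out["flagged"] = True
        else:
            out[f"r_{name}"] = float(np.corrcoef(a, b)[0, 1])
        rs.append(out[f"r_{name}"])
    out["r_mean"] = float(np.mean(rs))
    a = K_hat.T.ravel()
    b = K.T.ravel()
    if np.std(a) == 0 or np.std(b) == 0:
        out["r_pooled"] = 0.0
        out["flagged"] = True
    else:
        out["r_pooled"] = float(np.corrcoef(a, b)[0, 1])
    return out


def evaluate(
    model: DecoderModel,
    F_heldout: np.ndarray,
    K_heldout: np.ndarray,
    windows: Optional[Sequence[np.ndarray]] = None,
    n_shuffles: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict, dict]:
    """Held-out performance and a movement-shuffled null distribution.

    The shuffle control circularly shifts the movement-to-prediction
    correspondence by a random whole-movement offset: the prediction for
    movement ``(j + s) mod M`` is scored against the actual trace of
    movement ``j`` (pairs truncated to their common length), destroying
    the temporal correspondence while preserving both marginals.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    K_hat = decode(model, F_heldout)
    r_obs = pearson_pooled(K_hat, K_heldout)
    shuffle: dict = {"r_pooled": []}
    if windows is not None and len(windows) >= 2 and n_shuffles > 0:
        M = len(windows)
        for _ in range(n_shuffles):
            s = int(rng.integers(1, M))
            pred_parts, act_parts = [], []
            for j in range(M):
                wj = np.asarray(windows[j])
                wk = np.asarray(windows[(j + s) % M])
                L = min(wj.size, wk.size)
                pred_parts.append(K_hat[wk[:L]])
                act_parts.append(K_heldout[wj[:L]])
            r = pearson_pooled(np.concatenate(pred_parts), np.concatenate(act_parts))
            shuffle["r_pooled"].append(r["r_pooled"])
        q = np.quantile(shuffle["r_pooled"], [0.025, 0.5, 0.975])
        shuffle.update(mean=float(np.mean(shuffle["r_pooled"])),
                       q025=float(q[0]), median=float(q[1]), q975=float(q[2]))
    return r_obs, shuffle


def partial_contribution(
    model: DecoderModel,
    unit_subset: Sequence[int],
    F_heldout: np.ndarray,
    K_heldout: np.ndarray,
) -> dict:
    """Fraction of decoder performance carried by a unit subset.

    The held-out prediction is recomputed with all weights outside the
    subset zeroed; the subset's pooled correlation is normalized to the
    full decoder's. By linearity, subset and complement predictions sum
    exactly to the full prediction.
    """
    subset = np.asarray(unit_subset, dtype=int)
    if subset.size == 0:
        raise ValueError("unit subset must be non-empty")
    if subset.min() < 0 or subset.max() >= model.n_units:
        raise ValueError("unit subset outside model range")
    W_sub = np.zeros_like(model.W_decode)
    W_sub[subset] = model.W_decode[subset]
    sub_model = DecoderModel(W_decode=W_sub)
    r_sub = pearson_pooled(decode(sub_model, F_heldout), K_heldout)
    r_full = pearson_pooled(decode(model, F_heldout), K_heldout)
    out = {
        "r_subset": r_sub["r_pooled"],
        "r_full": r_full["r_pooled"],
        "flagged": False,
    }
    if r_full["r_pooled"] <= 0:
        out["fraction"] = float("nan")
        out["flagged"] = True
    else:
        out["fraction"] = r_sub["r_pooled"] / r_full["r_pooled"]
    return out
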