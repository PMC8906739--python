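"""Spike-table to tensor conversions: binning, alignment, normalization.

Spikes are counted in 1-ms bins to form a unit-by-bin count matrix; for
peri-event displays the trial-aligned counts are reduced to 50-ms rate
bins and z-scored against a 2500-ms pre-reach baseline. The decoding path
instead smooths 1-ms rates with a Gaussian kernel (sigma = 24 ms) and
z-scores them. PCA consumes square-root-transformed counts stacked into a
(bins x trials, units) matrix.

All bins are half-open ``[t, t + width)``; a spike exactly on an edge
belongs to the later bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BinnedSpikes",
    "TrialTensor",
    "bin_spikes",
    "rebin",
    "align_trials",
    "zscore_baseline",
    "smooth_rates",
    "sqrt_stack",
]


@dataclass
class BinnedSpikes:
    """Session-long spike counts: one row per unit, half-open bins."""

    counts: np.ndarray  # (units, bins), integer
    unit_ids: np.ndarray
    t_start: float
    bin_s: float

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def t_stop(self) -> float:
        return self.t_start + self.n_bins * self.bin_s


@dataclass
class TrialTensor:
    """Event-aligned population tensor.

    ``counts`` is (units, bins, trials); raw counts are non-negative
    integers, transformed tensors carry a ``transform`` tag
    (raw | zscored | smoothed | sqrt | rate). Bin ``b`` covers
    ``[-pre + b*bin, -pre + (b+1)*bin)`` relative to the alignment event.
    """

    counts: np.ndarray
    bin_width_s: float
    alignment_event: str
    window: tuple[float, float]  # (pre_s, post_s), both positive
    unit_ids: np.ndarray
    trial_ids: np.ndarray
    transform: str = "raw"
    n_dropped: int = 0
    flagged_units: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        pre, post = self.window
        n_expected = int(round((pre + post) / self.bin_width_s))
        if self.counts.shape[1] != n_expected:
            raise ValueError(
                f"bin count {self.counts.shape[1]} inconsistent with window/bin width "
                f"(expected {n_expected})"
            )

    @property
    def bin_centers(self) -> np.ndarray:
        pre, _ = self.window
        return -pre + (np.arange(self.counts.shape[1]) + 0.5) * self.bin_width_s

    @property
    def n_trials(self) -> int:
        return self.counts.shape[2]


def bin_spikes(
    spikes: pd.DataFrame,
    bin_ms: float = 1.0,
    t_start: float = 0.0,
    t_stop: Optional[float] = None,
    unit_ids: Optional[Sequence[int]] = None,
) -> BinnedSpikes:
    """Count spikes in half-open ``bin_ms`` bins per unit.

    Requires the table sorted by time within each unit; total counts
    equal the number of spikes inside ``[t_start, t_stop)``.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    times = spikes["time_s"].to_numpy()
    units = spikes["unit_id"].to_numpy()
    # sortedness within unit
    if len(times) > 1:
        same_unit = units[1:] == units[:-1]
        if np.any(same_unit & (np.diff(times) < 0)):
            raise ValueError("spike table must be time-sorted within each unit")
    if unit_ids is None:
        unit_ids = np.unique(units)
    unit_ids = np.asarray(unit_ids)
    if t_stop is None:
        t_stop = float(times.max()) + bin_ms * 1e-3 if times.size else t_start + bin_ms * 1e-3
    bin_s = bin_ms * 1e-3
    n_bins = int(np.ceil((t_stop - t_start) / bin_s - 1e-9))
    counts = np.zeros((unit_ids.size, n_bins), dtype=np.int32)
    keep = (times >= t_start) & (times < t_start + n_bins * bin_s)
    b = np.floor((times[keep] - t_start) / bin_s).astype(np.int64)
    kept_units = units[keep]
    order = np.argsort(unit_ids, kind="stable")
    sorted_ids = unit_ids[order]
    uidx = np.searchsorted(sorted_ids, kept_units)
    uidx = np.clip(uidx, 0, sorted_ids.size - 1)
    valid = sorted_ids[uidx] == kept_units
    np.add.at(counts, (order[uidx[valid]], b[valid]), 1)
    return BinnedSpikes(counts=counts, unit_ids=unit_ids, t_start=t_start, bin_s=bin_s)


def rebin(binned: BinnedSpikes, factor: int) -> BinnedSpikes:
    """Sum adjacent bins (e.g. 1-ms -> 50-ms); trailing partial bin dropped.

    Because bins are half-open, summing ``factor`` adjacent 1-ms bins is
    identical to counting directly in the coarser bins.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    n = (binned.n_bins // factor) * factor
    coarse = binned.counts[:, :n].reshape(binned.counts.shape[0], -1, factor).sum(axis=2)
    return BinnedSpikes(
        counts=coarse, unit_ids=binned.unit_ids, t_start=binned.t_start, bin_s=binned.bin_s * factor
    )


def align_trials(
    binned: BinnedSpikes,
    event_times: Sequence[float],
    window: tuple[float, float],
    alignment_event: str = "reach_start",
) -> TrialTensor:
    """Cut per-event windows ``[-pre, post)`` out of the session counts.

    Events whose window falls outside the recording span are dropped and
    logged; with none usable an error is raised. The trial axis follows
    the order of ``event_times``.
    """
    pre, post = window
    if pre < 0 or post <= 0:
        raise ValueError("window must be (pre >= 0, post > 0)")
    n_bins = int(round((pre + post) / binned.bin_s))
    slabs = []
    kept_ids = []
    n_dropped = 0
    for i, te in enumerate(event_times):
        i0 = int(round((te - pre - binned.t_start) / binned.bin_s))
        i1 = i0 + n_bins
        if i0 < 0 or i1 > binned.n_bins:
            n_dropped += 1
            continue
        slabs.append(binned.counts[:, i0:i1])
        kept_ids.append(i)
    if n_dropped:
        logger.info("align_trials: dropped %d/%d events outside recording span",
                    n_dropped, len(event_times))
    if not slabs:
        raise ValueError("no events usable after edge dropping")
    counts = np.stack(slabs, axis=2)
    return TrialTensor(
        counts=counts,
        bin_width_s=binned.bin_s,
        alignment_event=alignment_event,
        window=(pre, post),
        unit_ids=binned.unit_ids,
        trial_ids=np.asarray(kept_ids),
        n_dropped=n_dropped,
    )


def zscore_baseline(
    tensor: TrialTensor,
    baseline_window: tuple[float, float] = (-2.5, 0.0),
    mode: str = "trial_average",
    sd_floor: float = 1e-6,
) -> TrialTensor:
    """Z-score rates against the pre-event baseline.

    ``trial_average`` (default): the tensor is averaged over trials into
    a PETH first; each unit's baseline-bin mean and SD then normalize its
    trace, so baseline mean is exactly 0 and SD exactly 1. ``per_trial``
    z-scores every trial with baseline statistics pooled over trials and
    baseline bins. Units with baseline SD below ``sd_floor`` are flagged
    and floored rather than producing infinities. Counts are converted to
    rates (Hz) before normalization; the operation is idempotent.
    """
    if mode not in ("trial_average", "per_trial"):
        raise ValueError("mode must be 'trial_average' or 'per_trial'")
    lo, hi = baseline_window
    centers = tensor.bin_centers
    base_mask = (centers >= lo) & (centers < hi)
    if not base_mask.any():
        raise ValueError("baseline window contains no bins")
    rates = tensor.counts.astype(float)
    if tensor.transform == "raw":
        rates = rates / tensor.bin_width_s
    if mode == "trial_average":
        data = rates.mean(axis=2, keepdims=True)  # (units, bins, 1)
        base = data[:, base_mask, 0]
        trial_ids = np.asarray(["trial_average"])
    else:
        data = rates
        base = rates[:, base_mask, :].reshape(rates.shape[0], -1)
        trial_ids = tensor.trial_ids
    mu = base.mean(axis=1)[:, None, None]
    sd = base.std(axis=1)[:, None, None]
    flagged = (sd[:, 0, 0] < sd_floor)
    sd = np.maximum(sd, sd_floor)
    z = (data - mu) / sd
    return TrialTensor(
        counts=z,
        bin_width_s=tensor.bin_width_s,
        alignment_event=tensor.alignment_event,
        window=tensor.window,
        unit_ids=tensor.unit_ids,
        trial_ids=trial_ids,
        transform="zscored",
        n_dropped=tensor.n_dropped,
        flagged_units=tensor.unit_ids[flagged] if flagged.any() else None,
    )


def gaussian_kernel(sigma_ms: float, bin_ms: float) -> np.ndarray:
    """Symmetric Gaussian kernel truncated at ±4 sigma, renormalized to sum 1."""
    if sigma_ms <= 0:
        raise ValueError("sigma_ms must be positive")
    half = int(np.ceil(4.0 * sigma_ms / bin_ms))
    tt = np.arange(-half, half + 1) * bin_ms
    k = np.exp(-0.5 * (tt / sigma_ms) ** 2)
    return k / k.sum()


def smooth_rates(rates: np.ndarray, sigma_ms: float, bin_ms: float = 1.0) -> np.ndarray:
    """Gaussian-smooth along the last (time) axis.

    Circular FFT convolution with a unit-sum kernel, so the total signal
    mass is conserved exactly and the operation is linear; sessions begin
    and end silent, making the wrap-around negligible in practice.
    """
    k = gaussian_kernel(sigma_ms, bin_ms)
    rates = np.asarray(rates, dtype=float)
    n = rates.shape[-1]
    if k.size >= n:
        # short signals: direct circular convolution via padding the kernel
        reps = int(np.ceil(k.size / n)) + 1
        kc = np.zeros(n)
        half = k.size // 2
        for j, kv in enumerate(k):
            kc[(j - half) % n] += kv
    else:
        kc = np.zeros(n)
        half = k.size // 2
        idx = (np.arange(k.size) - half) % n
        np.add.at(kc, idx, k)
    return np.fft.irfft(np.fft.rfft(rates, axis=-1) * np.fft.rfft(kc), n=n, axis=-1)


def sqrt_stack(tensor: TrialTensor) -> np.ndarray:
    """Square-root-transform counts and stack into a (bins*trials, units) matrix.

    Rows are ordered bin-major within each trial, trials concatenated:
    row ``j*b + i`` holds trial ``j``, bin ``i``. This is the data matrix
    D that PCA consumes.
    """
    if tensor.transform != "raw":
        raise ValueError("sqrt_stack expects raw counts")
    if np.any(tensor.counts < 0):
        raise ValueError("counts must be non-negative")
    # (units, bins, trials) -> (trials, bins, units) -> (trials*bins, units)
    d = np.sqrt(tensor.counts.astype(float))
    return d.transpose(2, 1, 0).reshape(-1, tensor.counts.shape[0])
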