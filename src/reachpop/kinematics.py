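"""Reach detection and kinematics from 2D joystick traces.

A session's raw behavior is a uniformly sampled (nominally 1 kHz) stream of
joystick position in the horizontal plane, zeroed at the resting point.
Individual reaches are detected from the speed profile with a hysteresis
rule, and each reach is summarized by the kinematic quantities that the
population analyses regress against: peak amplitude (maximum radial
displacement from the origin), direction (angle of the vector from the
origin to the peak-displacement point), peak speed and duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "JoystickTrace",
    "ReachEvent",
    "detect_reaches",
    "reach_amplitude",
    "reach_direction",
    "label_trials",
]


class UndefinedDirectionError(ValueError):
    """Raised when a direction is requested for a zero-amplitude reach."""


@dataclass
class JoystickTrace:
    """Uniformly sampled 2D joystick position.

    Attributes
    ----------
    t : array of float
        Sample times in seconds, strictly increasing with a constant step.
    x, y : array of float
        Joystick position in mm; (0, 0) is the resting origin.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have identical shapes")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("t must be strictly increasing")
            if np.ptp(dt) > 1e-9:
                raise ValueError("sampling interval must be constant (±1e-9 s)")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size >= 2 else math.nan

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    @property
    def n_samples(self) -> int:
        return self.t.size

    def displacement(self) -> np.ndarray:
        """Radial distance from the origin, in mm."""
        return np.hypot(self.x, self.y)

    def speed(self, smooth_ms: float = 10.0) -> np.ndarray:
        """Tangential speed (mm/s) from central differences of position.

        The raw speed is boxcar-smoothed over ``smooth_ms`` before any
        thresholding; smoothing widths are rounded to an odd number of
        samples so the filter is symmetric and introduces no lag.
        """
        vx = np.gradient(self.x, self.dt)
        vy = np.gradient(self.y, self.dt)
        sp = np.hypot(vx, vy)
        if smooth_ms and smooth_ms > 0:
            w = max(1, int(round(smooth_ms * 1e-3 * self.fs)))
            if w % 2 == 0:
                w += 1
            kernel = np.full(w, 1.0 / w)
            sp = np.convolve(sp, kernel, mode="same")
        return sp


@dataclass
class ReachEvent:
    """One detected joystick movement."""

    start_s: float
    stop_s: float
    amplitude: float  # mm, peak displacement from origin
    direction: float  # rad in (-pi, pi], +x axis = 0; NaN if amplitude == 0
    peak_speed: float  # mm/s
    duration_s: float
    rewarded: Optional[bool] = None
    block_id: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.start_s < self.stop_s:
            raise ValueError("reach start must precede stop")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


def _wrap_half_open(theta: float) -> float:
    """Map an angle to (-pi, pi]; -pi is represented as +pi."""
    theta = math.atan2(math.sin(theta), math.cos(theta))
    if theta == -math.pi:
        theta = math.pi
    return theta


def detect_reaches(
    trace: JoystickTrace,
    speed_on: float = 15.0,
    speed_off: float = 5.0,
    min_duration_s: float = 0.05,
    merge_gap_s: float = 0.2,
    smooth_ms: float = 10.0,
) -> list[ReachEvent]:
    """Detect reaches with a speed-hysteresis rule.

    A candidate movement is a maximal run of samples with speed >=
    ``speed_off`` that contains at least one sample with speed >=
    ``speed_on``. The event start is the last sub-``speed_off`` sample
    before the run (hysteresis), and the stop is one sample past the run,
    so event windows are half-open ``[start, stop)``. Candidate windows
    separated by less than ``merge_gap_s`` are merged into a single reach
    (an outward stroke, a brief hold at peak and the return stroke form
    one movement). Events shorter than ``min_duration_s`` are discarded.
    """
    if not speed_on >= speed_off > 0:
        raise ValueError("require speed_on >= speed_off > 0")
    n = trace.n_samples
    if n < 2 or (trace.t[-1] - trace.t[0]) < min_duration_s:
        return []
    sp = trace.speed(smooth_ms)
    above_off = sp >= speed_off
    above_on = sp >= speed_on
    if not above_on.any():
        return []

    edges = np.diff(above_off.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1  # exclusive
    if above_off[0]:
        starts = np.r_[0, starts]
    if above_off[-1]:
        ends = np.r_[ends, n]

    windows: list[list[int]] = []
    for s, e in zip(starts, ends):
        if not above_on[s:e].any():
            continue
        i0 = max(s - 1, 0)
        i1 = min(e + 1, n)
        if windows and (i0 - windows[-1][1]) * trace.dt < merge_gap_s:
            windows[-1][1] = i1
        else:
            windows.append([i0, i1])

    disp = trace.displacement()
    events: list[ReachEvent] = []
    for i0, i1 in windows:
        start_s = float(trace.t[i0])
        stop_s = float(trace.t[i1 - 1] + trace.dt)
        if stop_s - start_s < min_duration_s:
            continue
        seg = disp[i0:i1]
        ipk = i0 + int(np.argmax(seg))
        amp = float(seg[ipk - i0])
        if amp > 0:
            direction = _wrap_half_open(math.atan2(trace.y[ipk], trace.x[ipk]))
        else:
            direction = math.nan
        events.append(
            ReachEvent(
                start_s=start_s,
                stop_s=stop_s,
                amplitude=amp,
                direction=direction,
                peak_speed=float(sp[i0:i1].max()),
                duration_s=stop_s - start_s,
            )
        )
    return events


def _window_slice(trace: JoystickTrace, event: ReachEvent) -> slice:
    i0 = int(np.searchsorted(trace.t, event.start_s - 1e-12, side="left"))
    i1 = int(np.searchsorted(trace.t, event.stop_s - 1e-12, side="left"))
    if i0 >= i1:
        raise ValueError("event window lies outside the trace extent")
    return slice(i0, i1)


def reach_amplitude(trace: JoystickTrace, event: ReachEvent) -> float:
    """Peak radial displacement (mm) within the event window."""
    sl = _window_slice(trace, event)
    return float(np.max(np.hypot(trace.x[sl], trace.y[sl])))


def reach_direction(trace: JoystickTrace, event: ReachEvent) -> float:
    """Angle (rad, (-pi, pi]) of the vector to the peak-displacement point."""
    sl = _window_slice(trace, event)
    disp = np.hypot(trace.x[sl], trace.y[sl])
    ipk = sl.start + int(np.argmax(disp))
    if disp[ipk - sl.start] == 0:
        raise UndefinedDirectionError("direction undefined for zero-amplitude reach")
    return _wrap_half_open(math.atan2(trace.y[ipk], trace.x[ipk]))


def label_trials(
    events: Sequence[ReachEvent],
    block_thresholds: Sequence[float],
    trials_per_block: int = 50,
    reward_delay_s: float = 1.0,
    iti_s: float = 3.0,
    trace: Optional[JoystickTrace] = None,
) -> tuple[list[ReachEvent], list[float]]:
    """Assign reward outcomes and block ids to detected reaches.

    Task contract: a reach is rewarded iff its amplitude reaches the
    current block's threshold (inclusive) and it starts outside the
    lockout following the previous reward (reward delivery plus the
    inter-trial interval). Rewards are delivered ``reward_delay_s`` after
    the threshold crossing; the block index advances every
    ``trials_per_block`` rewards. At most one reward is given per trial.

    Returns the events (mutated in place, also returned) and the list of
    reward-delivery times. If ``trace`` is given, the exact threshold-
    crossing time inside the reach is used; otherwise the reach start
    stands in for it.
    """
    thresholds = list(block_thresholds)
    if not thresholds or any(th <= 0 for th in thresholds):
        raise ValueError("block thresholds must be positive and non-empty")
    max_rewards = trials_per_block * len(thresholds)
    reward_times: list[float] = []
    lockout_until = -math.inf
    n_rewards = 0
    for ev in sorted(events, key=lambda e: e.start_s):
        block = min(n_rewards // trials_per_block, len(thresholds) - 1)
        ev.block_id = block
        th = thresholds[block]
        ev.rewarded = False
        if ev.start_s >= lockout_until and ev.amplitude >= th and n_rewards < max_rewards:
            if trace is not None:
                sl = _window_slice(trace, ev)
                disp = np.hypot(trace.x[sl], trace.y[sl])
                cross = np.flatnonzero(disp >= th)
                t_cross = float(trace.t[sl.start + cross[0]]) if cross.size else ev.start_s
            else:
                t_cross = ev.start_s
            ev.rewarded = True
            t_reward = t_cross + reward_delay_s
            reward_times.append(t_reward)
            lockout_until = t_reward + iti_s
            n_rewards += 1
    return list(events), reward_times
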