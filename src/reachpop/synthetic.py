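"""Synthetic joystick sessions with known ground truth.

Emulates the variable-amplitude operant task: head-fixed mice maneuver a
spring-loaded joystick past a block-wise amplitude threshold (near / far /
near, e.g. 4.2 / 5.7 / 4.2 mm) to earn a water reward delivered 1 s after
the threshold crossing, followed by a 3-s inter-trial interval. Reaches
have broadly (right-skew) distributed amplitudes and variable direction
within an arc around one body axis.

Spiking units are inhomogeneous-Poisson with planted tuning classes:

* ``amp_tuned``    -- perimovement rate scales with reach amplitude,
* ``dir_tuned``    -- perimovement rate follows cos(direction - preferred),
* ``reward_timed`` -- rate bump after reward delivery,
* ``untuned``      -- baseline only.

A subset of units is "tagged": during a separate optotagging block their
rate is multiplied by (1 - inhibition fraction) inside each laser pulse,
after a planted latency. Every generated quantity is recorded so each
downstream analysis has a parameter-recovery oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .kinematics import JoystickTrace, ReachEvent, detect_reaches, label_trials

__all__ = [
    "SessionConfig",
    "GroundTruth",
    "TrajectorySet",
    "Session",
    "generate_trajectories",
    "make_ground_truth",
    "generate_spikes",
    "generate_tagging_block",
    "generate_session",
]

UNIT_CLASSES = ("amp_tuned", "dir_tuned", "reward_timed", "untuned")

# Reach stroke geometry: minimum-jerk outward stroke, brief hold at peak
# displacement, minimum-jerk return. The hold guarantees the stored peak
# is present verbatim in the sampled trace.
OUTWARD_S = 0.30
HOLD_S = 0.05
RETURN_S = 0.30
REACH_S = OUTWARD_S + HOLD_S + RETURN_S

# Perimovement rate kernel: smooth bump covering the outward stroke and
# hold, peak-normalized to 1 so tuning gains are in Hz at the peak.
_MOVE_KERNEL_PEAK_S = 0.25
_MOVE_KERNEL_SIGMA_S = 0.12
_MOVE_KERNEL_SPAN_S = 0.65
# Reward kernel: bump peaking 200 ms after reward delivery.
_REWARD_KERNEL_PEAK_S = 0.20
_REWARD_KERNEL_SIGMA_S = 0.15
_REWARD_KERNEL_SPAN_S = 0.80


@dataclass
class SessionConfig:
    """Parameters of one synthetic session.

    Amplitudes are lognormal with block-dependent median
    ``amp_median_scale * block_threshold`` and log-SD ``amp_sigma``
    (``amp_sigma = 0`` collapses to a fixed amplitude), truncated by
    redraw to ``[amp_floor_mm, amp_ceil_mm]``. Directions are uniform on
    ``direction_arc``, a contiguous interval strictly inside (-pi, pi].
    """

    n_trials: int = 150
    block_thresholds: tuple[float, ...] = (4.2, 5.7, 4.2)
    trials_per_block: int = 50
    sample_rate: float = 1000.0
    iti_s: float = 3.0
    reward_delay_s: float = 1.0
    n_units: int = 48
    unit_class_fractions: dict = field(
        default_factory=lambda: {
            "amp_tuned": 0.25,
            "dir_tuned": 0.25,
            "reward_timed": 0.20,
            "untuned": 0.30,
        }
    )
    baseline_rate_range: tuple[float, float] = (2.0, 10.0)
    amp_gain_range: tuple[float, float] = (1.5, 3.0)  # Hz per mm
    dir_gain_range: tuple[float, float] = (6.0, 12.0)  # Hz per rad
    reward_mod_range: tuple[float, float] = (5.0, 15.0)  # Hz
    direction_arc: tuple[float, float] = (-math.pi / 2, math.pi / 2)
    amp_sigma: float = 0.45
    amp_median_scale: float = 1.5
    amp_floor_mm: float = 3.0
    amp_ceil_mm: float = 24.0
    pre_delay_range_s: tuple[float, float] = (0.5, 1.5)
    tagged_fraction: float = 0.25
    inhib_frac_range: tuple[float, float] = (0.7, 0.95)
    inhib_latency_range_ms: tuple[float, float] = (5.0, 20.0)
    speed_on: float = 15.0
    speed_off: float = 5.0
    noise_model: str = "poisson"
    seed: int = 0

    def validate(self) -> None:
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if not self.block_thresholds or any(th <= 0 for th in self.block_thresholds):
            raise ValueError("block thresholds must be positive")
        if self.n_units <= 0:
            raise ValueError("n_units must be positive")
        fr = self.unit_class_fractions
        if set(fr) - set(UNIT_CLASSES):
            raise ValueError(f"unknown unit classes: {set(fr) - set(UNIT_CLASSES)}")
        if abs(sum(fr.values()) - 1.0) > 1e-12:
            raise ValueError("unit class fractions must sum to 1")
        if any(v < 0 for v in fr.values()):
            raise ValueError("unit class fractions must be non-negative")
        lo, hi = self.direction_arc
        if not (lo < hi):
            raise ValueError("direction_arc must be a non-empty interval")
        if lo <= -math.pi or hi > math.pi:
            raise ValueError("direction_arc must lie strictly inside (-pi, pi]")
        for name in ("baseline_rate_range", "amp_gain_range", "dir_gain_range", "reward_mod_range"):
            a, b = getattr(self, name)
            if a < 0 or b < a:
                raise ValueError(f"{name} must be 0 <= lo <= hi")
        if self.amp_sigma < 0:
            raise ValueError("amp_sigma must be non-negative")
        if not 0 < self.amp_floor_mm <= self.amp_ceil_mm:
            raise ValueError("require 0 < amp_floor_mm <= amp_ceil_mm")
        if self.noise_model != "poisson":
            raise ValueError("only the poisson noise model is implemented")

    @property
    def slot_s(self) -> float:
        """Fixed duration of one trial slot (ITI + pre-delay + reach + pad)."""
        return self.iti_s + self.pre_delay_range_s[1] + REACH_S + 0.85

    @property
    def duration_s(self) -> float:
        return self.n_trials * self.slot_s + 1.0


@dataclass
class GroundTruth:
    """Planted parameters: one row per unit in ``units``.

    Columns: unit_id, cell_class, baseline_hz, amp_gain, dir_gain,
    pref_dir, reward_mod, tagged, inhib_frac, inhib_latency_ms.
    """

    units: pd.DataFrame

    def class_units(self, cell_class: str) -> np.ndarray:
        return self.units.index[self.units["cell_class"] == cell_class].to_numpy()

    @property
    def tagged_units(self) -> np.ndarray:
        return self.units.index[self.units["tagged"]].to_numpy()


@dataclass
class TrajectorySet:
    """Generated behavior: the trace, detected+labeled events, planted
    per-trial kinematics and the reward-delivery times."""

    trace: JoystickTrace
    events: list[ReachEvent]
    planted: pd.DataFrame  # trial, amplitude_mm, direction_rad, t_start_s, block
    reward_times: list[float]


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile s(tau) on [0, 1], s(0)=0, s(1)=1."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _draw_amplitude(rng: np.random.Generator, median: float, cfg: SessionConfig) -> float:
    if cfg.amp_sigma == 0:
        return median
    for _ in range(1000):
        a = median * math.exp(cfg.amp_sigma * rng.standard_normal())
        if cfg.amp_floor_mm <= a <= cfg.amp_ceil_mm:
            return a
    raise RuntimeError("amplitude truncation bounds reject essentially all draws")


def generate_trajectories(config: SessionConfig, rng: np.random.Generator) -> TrajectorySet:
    """Generate the joystick trace and one reach per trial.

    The trace is zero during ITIs; each trial slot contains a single
    outward-hold-return stroke along a straight line at the planted
    direction. The returned events are what ``kinematics.detect_reaches``
    recovers from the trace (then reward/block-labeled), so stored
    kinematics equal recovered kinematics by construction; the planted
    values live in ``planted`` for recovery tests.
    """
    config.validate()
    fs = config.sample_rate
    n_samp = int(round(config.duration_s * fs))
    x = np.zeros(n_samp)
    y = np.zeros(n_samp)
    t = np.arange(n_samp) / fs

    n_out = int(round(OUTWARD_S * fs))
    n_hold = int(round(HOLD_S * fs))
    n_ret = int(round(RETURN_S * fs))
    s_out = _min_jerk(np.arange(1, n_out + 1) / n_out)
    s_ret = _min_jerk(1.0 - np.arange(1, n_ret + 1) / n_ret)
    profile = np.concatenate([s_out, np.ones(n_hold), s_ret])

    lo, hi = config.direction_arc
    records = []
    n_rewards = 0
    for i in range(config.n_trials):
        # the current threshold is set by reward progression (blocks advance
        # every trials_per_block rewards), and the simulated subject's
        # amplitude tracks the current threshold
        block = min(n_rewards // config.trials_per_block, len(config.block_thresholds) - 1)
        median = config.amp_median_scale * config.block_thresholds[block]
        amp = _draw_amplitude(rng, median, config)
        if amp >= config.block_thresholds[block]:
            n_rewards += 1
        theta = float(rng.uniform(lo, hi))
        pre = float(rng.uniform(*config.pre_delay_range_s))
        t_start = i * config.slot_s + config.iti_s + pre
        i0 = int(round(t_start * fs))
        seg = slice(i0 + 1, i0 + 1 + profile.size)
        x[seg] = amp * math.cos(theta) * profile
        y[seg] = amp * math.sin(theta) * profile
        records.append(
            dict(trial=i, amplitude_mm=amp, direction_rad=theta, t_start_s=t_start, block=block)
        )

    trace = JoystickTrace(t=t, x=x, y=y)
    events = detect_reaches(trace, speed_on=config.speed_on, speed_off=config.speed_off)
    if len(events) != config.n_trials:
        raise RuntimeError(
            f"expected {config.n_trials} detected reaches, got {len(events)}; "
            "check amplitude floor against detection thresholds"
        )
    events, reward_times = label_trials(
        events,
        config.block_thresholds,
        trials_per_block=config.trials_per_block,
        reward_delay_s=config.reward_delay_s,
        iti_s=config.iti_s,
        trace=trace,
    )
    planted = pd.DataFrame.from_records(records).set_index("trial")
    return TrajectorySet(trace=trace, events=events, planted=planted, reward_times=reward_times)


def _largest_remainder_counts(fractions: dict, n: int) -> dict:
    raw = {k: fractions.get(k, 0.0) * n for k in UNIT_CLASSES}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    by_frac = sorted(UNIT_CLASSES, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_frac[:short]:
        counts[k] += 1
    return counts


def make_ground_truth(config: SessionConfig, rng: np.random.Generator) -> GroundTruth:
    """Assign unit classes, tuning gains and tagging status."""
    config.validate()
    counts = _largest_remainder_counts(config.unit_class_fractions, config.n_units)
    classes: list[str] = []
    for k in UNIT_CLASSES:
        classes.extend([k] * counts[k])
    lo, hi = config.direction_arc
    rows = []
    for u, cls in enumerate(classes):
        baseline = float(rng.uniform(*config.baseline_rate_range))
        amp_gain = float(rng.uniform(*config.amp_gain_range)) if cls == "amp_tuned" else 0.0
        dir_gain = float(rng.uniform(*config.dir_gain_range)) if cls == "dir_tuned" else 0.0
        # Preferred directions sit at the arc edges so the cosine tuning is
        # monotone across the arc and a linear regression on direction is
        # well-posed.
        pref = float(rng.choice([lo, hi])) if cls == "dir_tuned" else 0.0
        reward_mod = float(rng.uniform(*config.reward_mod_range)) if cls == "reward_timed" else 0.0
        rows.append(
            dict(
                unit_id=u,
                cell_class=cls,
                baseline_hz=baseline,
                amp_gain=amp_gain,
                dir_gain=dir_gain,
                pref_dir=pref,
                reward_mod=reward_mod,
            )
        )
    units = pd.DataFrame(rows).set_index("unit_id")
    n_tag = int(round(config.tagged_fraction * config.n_units))
    tagged_ids = rng.choice(config.n_units, size=n_tag, replace=False)
    units["tagged"] = False
    units.loc[tagged_ids, "tagged"] = True
    units["inhib_frac"] = 0.0
    units["inhib_latency_ms"] = 0.0
    units.loc[tagged_ids, "inhib_frac"] = rng.uniform(*config.inhib_frac_range, size=n_tag)
    units.loc[tagged_ids, "inhib_latency_ms"] = rng.uniform(
        *config.inhib_latency_range_ms, size=n_tag
    )
    return GroundTruth(units=units)


def _bump_kernel(fs: float, peak_s: float, sigma_s: float, span_s: float) -> np.ndarray:
    """Truncated Gaussian bump on [0, span], peak-normalized to 1."""
    tt = np.arange(int(round(span_s * fs))) / fs
    return np.exp(-0.5 * ((tt - peak_s) / sigma_s) ** 2)


def unit_rate(
    unit: pd.Series,
    events: Sequence[ReachEvent],
    config: SessionConfig,
    duration_s: Optional[float] = None,
    reward_times: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Planted instantaneous rate lambda(t) of one unit, at 1/fs resolution.

    lambda(t) = baseline
              + [amp_gain * A + dir_gain * cos(theta - pref)] * g(t - t_start)
              + reward_mod * h(t - t_reward),        clipped at 0,

    with g and h fixed peak-one bump kernels over the movement and
    post-reward epochs.
    """
    fs = config.sample_rate
    dur = config.duration_s if duration_s is None else duration_s
    n = int(round(dur * fs))
    lam = np.full(n, float(unit["baseline_hz"]))
    g = _bump_kernel(fs, _MOVE_KERNEL_PEAK_S, _MOVE_KERNEL_SIGMA_S, _MOVE_KERNEL_SPAN_S)
    h = _bump_kernel(fs, _REWARD_KERNEL_PEAK_S, _REWARD_KERNEL_SIGMA_S, _REWARD_KERNEL_SPAN_S)
    for ev in events:
        gain = unit["amp_gain"] * ev.amplitude
        if unit["dir_gain"] != 0 and np.isfinite(ev.direction):
            gain += unit["dir_gain"] * math.cos(ev.direction - unit["pref_dir"])
        if gain != 0.0:
            i0 = int(round(ev.start_s * fs))
            i1 = min(i0 + g.size, n)
            if i1 > i0:
                lam[i0:i1] += gain * g[: i1 - i0]
    if unit["reward_mod"] != 0.0 and reward_times:
        for tr in reward_times:
            i0 = int(round(tr * fs))
            i1 = min(i0 + h.size, n)
            if i1 > i0:
                lam[i0:i1] += unit["reward_mod"] * h[: i1 - i0]
    np.clip(lam, 0.0, None, out=lam)
    return lam


def _spikes_from_rate(lam: np.ndarray, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson spike times from a piecewise-constant rate.

    Counts are Poisson per 1/fs bin; each spike is placed uniformly
    within its bin (equivalently, thinning at the sampling resolution
    with sub-bin jitter breaking ties).
    """
    counts = rng.poisson(lam / fs)
    idx = np.repeat(np.flatnonzero(counts), counts[counts > 0])
    times = (idx + rng.uniform(0.0, 1.0, size=idx.size)) / fs
    return np.sort(times)


def generate_spikes(
    events: Sequence[ReachEvent],
    truth: GroundTruth,
    config: SessionConfig,
    rng: np.random.Generator,
    reward_times: Optional[Sequence[float]] = None,
    duration_s: Optional[float] = None,
) -> pd.DataFrame:
    """Poisson spike table for the task epoch, sorted by (unit_id, time_s)."""
    if not events:
        raise ValueError("events must be non-empty")
    frames = []
    for u, unit in truth.units.iterrows():
        lam = unit_rate(unit, events, config, duration_s=duration_s, reward_times=reward_times)
        times = _spikes_from_rate(lam, config.sample_rate, rng)
        frames.append(pd.DataFrame({"unit_id": u, "time_s": times}))
    spikes = pd.concat(frames, ignore_index=True)
    return spikes


def generate_tagging_block(
    truth: GroundTruth,
    n_pulses: int = 60,
    pulse_s: float = 1.0,
    interval_s: float = 8.0,
    rng: Optional[np.random.Generator] = None,
    pad_s: float = 2.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Optotagging epoch: laser pulses delivered at rest.

    Tagged units fire at ``baseline * (1 - inhib_frac)`` from pulse onset
    plus their planted latency to pulse end; untagged units are
    unaffected. Returns (spike table, laser onset times). Rates are
    homogeneous between pulses, so spikes are drawn per constant-rate
    segment (exact for a piecewise-constant Poisson process).
    """
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    if pulse_s <= 0:
        raise ValueError("pulse_s must be positive")
    if rng is None:
        rng = np.random.default_rng(0)
    onsets = pad_s + np.arange(n_pulses) * interval_s
    duration = pad_s + n_pulses * interval_s
    frames = []
    for u, unit in truth.units.iterrows():
        base = float(unit["baseline_hz"])
        if unit["tagged"] and unit["inhib_frac"] > 0:
            lat = unit["inhib_latency_ms"] * 1e-3
            inhibited = base * (1.0 - float(unit["inhib_frac"]))
            # segments alternate baseline / inhibited
            seg_bounds = [0.0]
            seg_rates = []
            for on in onsets:
                seg_bounds.append(on + lat)
                seg_rates.append(base)
                seg_bounds.append(on + pulse_s)
                seg_rates.append(inhibited)
            seg_bounds.append(duration)
            seg_rates.append(base)
        else:
            seg_bounds = [0.0, duration]
            seg_rates = [base]
        times_parts = []
        for (t0, t1), r in zip(zip(seg_bounds[:-1], seg_bounds[1:]), seg_rates):
            if t1 <= t0 or r <= 0:
                continue
            k = rng.poisson(r * (t1 - t0))
            if k:
                times_parts.append(rng.uniform(t0, t1, size=k))
        times = np.sort(np.concatenate(times_parts)) if times_parts else np.empty(0)
        frames.append(pd.DataFrame({"unit_id": u, "time_s": times}))
    spikes = pd.concat(frames, ignore_index=True)
    return spikes, onsets


@dataclass
class Session:
    """A complete synthetic session: behavior, spikes and ground truth."""

    config: SessionConfig
    trace: JoystickTrace
    events: list[ReachEvent]
    planted: pd.DataFrame
    reward_times: list[float]
    truth: GroundTruth
    spikes: pd.DataFrame
    tag_spikes: pd.DataFrame
    laser_onsets: np.ndarray

    @property
    def duration_s(self) -> float:
        return self.config.duration_s


def generate_session(
    config: SessionConfig,
    n_pulses: int = 60,
    pulse_s: float = 1.0,
    pulse_interval_s: float = 8.0,
) -> Session:
    """Generate a full session from a single seed.

    The config seed fans out into independent substreams for behavior,
    ground-truth assignment, task spiking and the tagging block, so
    regenerating one stage never perturbs another.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_traj, rng_truth, rng_spk, rng_tag = (np.random.default_rng(c) for c in ss.spawn(4))
    traj = generate_trajectories(config, rng_traj)
    truth = make_ground_truth(config, rng_truth)
    spikes = generate_spikes(
        traj.events, truth, config, rng_spk, reward_times=traj.reward_times
    )
    tag_spikes, onsets = generate_tagging_block(
        truth, n_pulses=n_pulses, pulse_s=pulse_s, interval_s=pulse_interval_s, rng=rng_tag
    )
    return Session(
        config=config,
        trace=traj.trace,
        events=traj.events,
        planted=traj.planted,
        reward_times=traj.reward_times,
        truth=truth,
        spikes=spikes,
        tag_spikes=tag_spikes,
        laser_onsets=onsets,
    )
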