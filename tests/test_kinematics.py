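"""Reach detection and kinematic quantities."""

import math

import numpy as np
import pytest

from reachpop.kinematics import (
    JoystickTrace,
    ReachEvent,
    UndefinedDirectionError,
    detect_reaches,
    label_trials,
    reach_amplitude,
    reach_direction,
)

FS = 1000.0


def _min_jerk(tau):
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def make_stroke_trace(amps_dirs_starts, duration_s=10.0, out_s=0.3, hold_s=0.05, ret_s=0.3):
    """Trace with one straight min-jerk out-hold-return stroke per entry."""
    n = int(duration_s * FS)
    t = np.arange(n) / FS
    x = np.zeros(n)
    y = np.zeros(n)
    n_out, n_hold, n_ret = int(out_s * FS), int(hold_s * FS), int(ret_s * FS)
    prof = np.concatenate(
        [
            _min_jerk(np.arange(1, n_out + 1) / n_out),
            np.ones(n_hold),
            _min_jerk(1 - np.arange(1, n_ret + 1) / n_ret),
        ]
    )
    for amp, theta, t0 in amps_dirs_starts:
        i0 = int(t0 * FS) + 1
        x[i0 : i0 + prof.size] = amp * math.cos(theta) * prof
        y[i0 : i0 + prof.size] = amp * math.sin(theta) * prof
    return JoystickTrace(t=t, x=x, y=y)


class TestDetectReaches:
    def test_flat_trace_yields_no_events(self):
        n = 2000
        trace = JoystickTrace(np.arange(n) / FS, np.zeros(n), np.zeros(n))
        assert detect_reaches(trace) == []

    def test_single_stroke_gives_one_event_bracketing_it(self):
        trace = make_stroke_trace([(8.0, 0.3, 2.0)])
        events = detect_reaches(trace)
        assert len(events) == 1
        ev = events[0]
        assert 1.9 < ev.start_s < 2.2
        assert 2.4 < ev.stop_s < 2.9
        assert ev.amplitude == pytest.approx(8.0, abs=1e-9)

    def test_two_separated_strokes_give_two_ordered_events(self):
        trace = make_stroke_trace([(6.0, 0.0, 2.0), (9.0, 0.5, 6.0)])
        events = detect_reaches(trace)
        assert len(events) == 2
        assert events[0].start_s < events[1].start_s
        assert events[0].amplitude == pytest.approx(6.0, abs=1e-9)
        assert events[1].amplitude == pytest.approx(9.0, abs=1e-9)

    def test_short_trace_returns_empty(self):
        trace = JoystickTrace(np.arange(10) / FS, np.zeros(10), np.zeros(10))
        assert detect_reaches(trace, min_duration_s=0.5) == []

    def test_invalid_hysteresis_thresholds_rejected(self):
        trace = make_stroke_trace([(6.0, 0.0, 2.0)])
        with pytest.raises(ValueError):
            detect_reaches(trace, speed_on=5.0, speed_off=15.0)


class TestAmplitudeDirection:
    def _trace_peaking_at(self, px, py):
        theta = math.atan2(py, px)
        amp = math.hypot(px, py)
        return make_stroke_trace([(amp, theta, 2.0)])

    @pytest.mark.parametrize(
        "px,py,amp,direction",
        [
            (3.0, 4.0, 5.0, math.atan2(4, 3)),  # 0.9273 rad by hand
            (7.0, 0.0, 7.0, 0.0),
            (0.0, 5.0, 5.0, math.pi / 2),
            (-5.0, 0.0, 5.0, math.pi),  # +pi, never -pi
        ],
    )
    def test_peak_position_oracle(self, px, py, amp, direction):
        trace = self._trace_peaking_at(px, py)
        (ev,) = detect_reaches(trace)
        assert reach_amplitude(trace, ev) == pytest.approx(amp, abs=1e-9)
        assert reach_direction(trace, ev) == pytest.approx(direction, abs=1e-9)
        assert reach_direction(trace, ev) > -math.pi  # interval convention

    def test_zero_trace_amplitude_and_undefined_direction(self):
        n = 3000
        trace = JoystickTrace(np.arange(n) / FS, np.zeros(n), np.zeros(n))
        ev = ReachEvent(start_s=1.0, stop_s=1.5, amplitude=0.0, direction=float("nan"),
                        peak_speed=0.0, duration_s=0.5)
        assert reach_amplitude(trace, ev) == 0.0
        with pytest.raises(UndefinedDirectionError):
            reach_direction(trace, ev)


class TestEquivariance:
    def test_quarter_turn_rotation_exact(self):
        trace = make_stroke_trace([(6.0, 0.4, 2.0), (10.0, -0.8, 6.0)])
        rot = JoystickTrace(trace.t, -trace.y.copy(), trace.x.copy())  # +90 degrees
        ev0 = detect_reaches(trace)
        ev1 = detect_reaches(rot)
        assert len(ev0) == len(ev1)
        for a, b in zip(ev0, ev1):
            assert b.amplitude == a.amplitude  # hypot symmetric in |args|
            # the pi/2 addition itself rounds, so allow one ulp
            assert b.direction == pytest.approx(a.direction + math.pi / 2, abs=5e-16)

    def test_arbitrary_rotation_shifts_directions(self):
        theta = 0.7
        trace = make_stroke_trace([(6.0, 0.4, 2.0), (10.0, -0.8, 6.0)])
        c, s = math.cos(theta), math.sin(theta)
        rot = JoystickTrace(trace.t, c * trace.x - s * trace.y, s * trace.x + c * trace.y)
        for a, b in zip(detect_reaches(trace), detect_reaches(rot)):
            assert b.amplitude == pytest.approx(a.amplitude, abs=1e-9)
            assert b.direction == pytest.approx(a.direction + theta, abs=1e-9)

    def test_scaling_scales_amplitudes_exactly(self):
        c = 4.0  # power of two: scaling commutes with hypot bit-for-bit
        trace = make_stroke_trace([(6.0, 0.4, 2.0)])
        scaled = JoystickTrace(trace.t, c * trace.x, c * trace.y)
        (a,) = detect_reaches(trace)
        (b,) = detect_reaches(scaled, speed_on=15 * c, speed_off=5 * c)
        assert b.amplitude == c * a.amplitude
        assert b.direction == pytest.approx(a.direction, abs=1e-12)


class TestLabelTrials:
    def _events(self, specs):
        return [
            ReachEvent(start_s=t0, stop_s=t0 + 0.5, amplitude=a, direction=0.0,
                       peak_speed=50.0, duration_s=0.5)
            for t0, a in specs
        ]

    def test_suprathreshold_outside_iti_rewarded(self):
        events, rewards = label_trials(self._events([(1.0, 5.0)]), [4.2])
        assert events[0].rewarded is True
        assert rewards == [2.0]  # start + 1-s delay

    def test_reach_within_iti_unrewarded(self):
        # second reach starts 2 s after the first reward -> inside the 3-s ITI
        events, rewards = label_trials(self._events([(1.0, 5.0), (4.0, 5.0)]), [4.2])
        assert events[0].rewarded is True
        assert events[1].rewarded is False
        assert len(rewards) == 1

    def test_threshold_boundary_inclusive(self):
        events, _ = label_trials(self._events([(1.0, 4.2)]), [4.2])
        assert events[0].rewarded is True

    def test_subthreshold_unrewarded_and_block_advance(self):
        specs = [(1.0 + 6 * i, 5.0) for i in range(4)]
        events, _ = label_trials(self._events(specs), [4.2, 5.7], trials_per_block=2)
        assert [ev.block_id for ev in events] == [0, 0, 1, 1]
        # threshold rose to 5.7 in block 1, amplitude 5.0 no longer suffices
        assert [ev.rewarded for ev in events] == [True, True, False, False]

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            label_trials([], [])
        with pytest.raises(ValueError):
            label_trials([], [-1.0])
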