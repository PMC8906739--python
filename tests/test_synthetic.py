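"""Synthetic-session generator: determinism, recovery, rate conservation."""

import math

import numpy as np
import pandas as pd
import pytest

from reachpop.kinematics import ReachEvent
from reachpop.synthetic import (
    GroundTruth,
    SessionConfig,
    generate_session,
    generate_spikes,
    generate_tagging_block,
    generate_trajectories,
    unit_rate,
)

from conftest import small_config


def _single_unit_truth(**kw) -> GroundTruth:
    row = dict(
        unit_id=0, cell_class="untuned", baseline_hz=5.0, amp_gain=0.0, dir_gain=0.0,
        pref_dir=0.0, reward_mod=0.0, tagged=False, inhib_frac=0.0, inhib_latency_ms=0.0,
    )
    row.update(kw)
    return GroundTruth(units=pd.DataFrame([row]).set_index("unit_id"))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "overrides",
        [
            dict(n_trials=0),
            dict(direction_arc=(1.0, 1.0)),
            dict(direction_arc=(-4.0, 0.0)),
            dict(unit_class_fractions={"amp_tuned": 0.6, "untuned": 0.3}),
            dict(baseline_rate_range=(-1.0, 5.0)),
            dict(amp_floor_mm=0.0),
            dict(noise_model="gaussian"),
        ],
    )
    def test_degenerate_configs_rejected(self, overrides):
        with pytest.raises(ValueError):
            SessionConfig(**overrides).validate()


class TestTrajectories:
    def test_block_means_track_thresholds_low_high_low(self, trajectories_small):
        pl = trajectories_small.planted
        amps = np.array([ev.amplitude for ev in trajectories_small.events])
        means = [amps[pl.block.values == b].mean() for b in range(3)]
        assert means[1] > means[0] and means[1] > means[2]

    def test_zero_spread_recovers_fixed_amplitude(self):
        cfg = small_config(
            n_trials=12, trials_per_block=4, block_thresholds=(5.0, 5.0, 5.0),
            amp_sigma=0.0, amp_median_scale=1.0,
        )
        traj = generate_trajectories(cfg, np.random.default_rng(0))
        amps = np.array([ev.amplitude for ev in traj.events])
        assert np.allclose(amps, 5.0, atol=1e-9)

    def test_same_seed_gives_identical_traces(self):
        cfg = small_config(n_trials=10, trials_per_block=4)
        t1 = generate_trajectories(cfg, np.random.default_rng(7))
        t2 = generate_trajectories(cfg, np.random.default_rng(7))
        assert np.array_equal(t1.trace.x, t2.trace.x)
        assert np.array_equal(t1.trace.y, t2.trace.y)
        assert t1.planted.equals(t2.planted)

    def test_round_trip_amplitude_and_direction(self, trajectories_small):
        """Detected kinematics match planted values for >=99% of reaches."""
        traj = trajectories_small
        rec_amp = np.array([ev.amplitude for ev in traj.events])
        rec_dir = np.array([ev.direction for ev in traj.events])
        amp_ok = np.abs(rec_amp - traj.planted.amplitude_mm.values) <= 1e-3
        dir_ok = np.abs(rec_dir - traj.planted.direction_rad.values) <= 1e-6
        assert amp_ok.mean() >= 0.99
        assert dir_ok.mean() >= 0.99

    def test_directions_stay_inside_arc(self, trajectories_small):
        lo, hi = small_config().direction_arc
        d = trajectories_small.planted.direction_rad.values
        assert np.all((d >= lo) & (d <= hi))


class TestSpikes:
    def _one_event(self, amp=5.0, t0=1.0):
        return [ReachEvent(start_s=t0, stop_s=t0 + 0.65, amplitude=amp, direction=0.0,
                           peak_speed=40.0, duration_s=0.65)]

    def test_homogeneous_poisson_count(self):
        cfg = small_config(n_trials=1, trials_per_block=1)
        truth = _single_unit_truth(baseline_hz=5.0)
        spikes = generate_spikes(self._one_event(), truth, cfg,
                                 np.random.default_rng(5), duration_s=100.0)
        n = len(spikes)
        assert abs(n - 500) < 3 * math.sqrt(500)

    def test_amp_tuned_unit_fires_more_for_larger_reaches(self):
        cfg = small_config()
        truth = _single_unit_truth(cell_class="amp_tuned", amp_gain=1.0, baseline_hz=4.0)
        events = []
        for i in range(200):
            amp = 2.0 if i % 2 == 0 else 10.0
            events.append(ReachEvent(start_s=1.0 + 2.0 * i, stop_s=1.65 + 2.0 * i,
                                     amplitude=amp, direction=0.0, peak_speed=40.0,
                                     duration_s=0.65))
        spikes = generate_spikes(events, truth, cfg, np.random.default_rng(9),
                                 duration_s=1.0 + 2.0 * 200)
        times = spikes["time_s"].to_numpy()
        counts = {2.0: [], 10.0: []}
        for ev in events:
            c = np.sum((times >= ev.start_s) & (times < ev.stop_s))
            counts[ev.amplitude].append(c)
        assert np.mean(counts[10.0]) > np.mean(counts[2.0])

    def test_seeded_spike_tables_identical(self, session_small):
        cfg = small_config()
        again = generate_session(cfg)
        assert session_small.spikes.equals(again.spikes)
        assert session_small.tag_spikes.equals(again.tag_spikes)

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError):
            generate_spikes([], _single_unit_truth(), small_config(), np.random.default_rng(0))

    def test_rate_conservation_against_integrated_lambda(self):
        """Empirical per-unit counts match the integral of the planted rate
        within Poisson sampling error (99% level) for >=95% of units."""
        s = generate_session(small_config(n_trials=18, trials_per_block=6, n_units=60, seed=21))
        times = s.spikes["time_s"].to_numpy()
        units = s.spikes["unit_id"].to_numpy()
        ok = []
        for u, unit in s.truth.units.iterrows():
            lam = unit_rate(unit, s.events, s.config, reward_times=s.reward_times)
            expected = lam.sum() / s.config.sample_rate
            n = int(np.sum(units == u))
            ok.append(abs(n - expected) <= 2.576 * math.sqrt(max(expected, 1.0)))
        assert np.mean(ok) >= 0.95


class TestTaggingBlock:
    def test_full_inhibition_zero_latency_silences_pulses(self):
        truth = _single_unit_truth(baseline_hz=20.0, tagged=True, inhib_frac=1.0)
        spikes, onsets = generate_tagging_block(truth, n_pulses=30, rng=np.random.default_rng(3))
        times = spikes["time_s"].to_numpy()
        for on in onsets:
            assert np.sum((times >= on) & (times < on + 1.0)) == 0

    def test_untagged_unit_unaffected_by_laser(self):
        truth = _single_unit_truth(baseline_hz=10.0)
        spikes, onsets = generate_tagging_block(truth, n_pulses=60, rng=np.random.default_rng(4))
        times = spikes["time_s"].to_numpy()
        n_in = sum(np.sum((times >= on) & (times < on + 1.0)) for on in onsets)
        expected = 10.0 * 60 * 1.0
        assert abs(n_in - expected) <= 2 * math.sqrt(expected)

    def test_partial_inhibition_rate_matches_prediction(self):
        truth = _single_unit_truth(baseline_hz=10.0, tagged=True, inhib_frac=0.7)
        spikes, onsets = generate_tagging_block(truth, n_pulses=60, rng=np.random.default_rng(8))
        times = spikes["time_s"].to_numpy()
        n_in = sum(np.sum((times >= on) & (times < on + 1.0)) for on in onsets)
        expected = 3.0 * 60  # 10 Hz * (1 - 0.7) over 60 one-second pulses
        assert abs(n_in - expected) <= 2 * math.sqrt(expected)

    def test_invalid_pulse_parameters_rejected(self):
        truth = _single_unit_truth()
        with pytest.raises(ValueError):
            generate_tagging_block(truth, n_pulses=0)
        with pytest.raises(ValueError):
            generate_tagging_block(truth, pulse_s=0.0)
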