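"""Synthetic-data generators: determinism, calibration, one-way structure."""

import numpy as np
import pytest

from larvahab import (
    BehaviorLabel,
    GeneratorConfig,
    HabituationParams,
    StimulusProtocol,
    TauResSchedule,
    TransitionKernel,
    classify_trajectory,
    generate_count_timeseries,
    generate_response_records,
    generate_trajectories,
    sensitivity_factor,
)
from larvahab.behavior import LABEL_ORDER


def _label_sequences(records):
    seqs = {}
    for r in records:
        seqs.setdefault(r.larva_id, {})[r.pulse_n] = r.label
    return seqs


class TestConfig:
    def test_seed_is_mandatory_in_files(self):
        with pytest.raises(ValueError, match="seed"):
            GeneratorConfig.from_dict({"n_larvae": 10})

    def test_json_round_trip(self, tmp_path):
        config = GeneratorConfig.from_preset("rut", n_larvae=42, seed=9)
        path = tmp_path / "gen.json"
        config.to_json(path)
        loaded = GeneratorConfig.from_json(path)
        assert loaded.habituation.tau_des == config.habituation.tau_des
        assert loaded.seed == 9 and loaded.n_larvae == 42
        np.testing.assert_array_equal(loaded.kernel.matrix, config.kernel.matrix)

    def test_presets_carry_published_constants(self):
        assert GeneratorConfig.from_preset("wildtype").habituation.tau_des == 18.9
        assert GeneratorConfig.from_preset("cam0").habituation.tau_res(0) == 6.5

    def test_kernel_entries_into_rev_rejected(self):
        m = TransitionKernel().matrix.copy()
        m[1, 3] = 0.1  # PAUSE -> REV
        m[1, 1] -= 0.1
        with pytest.raises(ValueError, match="REV"):
            TransitionKernel(m)

    def test_inconsistent_baselines_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(
                habituation=HabituationParams(baseline_rev=0.3), baseline_stop=0.2
            )

    def test_sensitivity_reference_and_floor(self):
        config = GeneratorConfig()
        assert sensitivity_factor(config, 500, 2.0) == pytest.approx(1.0, abs=1e-9)
        assert sensitivity_factor(config, 500, 0.0) < 0.005
        assert sensitivity_factor(config, 30, 2.0) < 0.05


class TestResponseRecords:
    def test_deterministic_under_fixed_seed(self, pulse_protocol):
        config = GeneratorConfig(n_larvae=30, seed=5)
        a = generate_response_records(config, pulse_protocol)
        b = generate_response_records(config, pulse_protocol)
        assert a == b

    def test_zero_larvae_gives_empty_list(self, pulse_protocol):
        assert generate_response_records(
            GeneratorConfig(n_larvae=0, seed=1), pulse_protocol
        ) == []

    def test_no_stimulus_baseline_fractions(self):
        # law-of-large-numbers calibration at N = 10,000, 3 binomial SDs
        protocol = StimulusProtocol(500, 0.0, t_on=2, t_off=0, n_pulses=1)
        config = GeneratorConfig(n_larvae=10_000, seed=77)
        records = generate_response_records(config, protocol, window_s=2.0)
        f_rev = np.mean([r.label is BehaviorLabel.REV for r in records])
        f_stop = np.mean([r.label is not BehaviorLabel.CONT for r in records])
        sd_rev = np.sqrt(0.03 * 0.97 / 10_000)
        sd_stop = np.sqrt(0.24 * 0.76 / 10_000)
        assert abs(f_rev - 0.03) < 3 * sd_rev
        assert abs(f_stop - 0.24) < 3 * sd_stop

    def test_strong_stimulus_first_pulse_fractions(self, pulse_protocol):
        config = GeneratorConfig(n_larvae=10_000, seed=78)
        records = generate_response_records(config, pulse_protocol)
        first = [r for r in records if r.pulse_n == 0]
        f_rev = np.mean([r.label is BehaviorLabel.REV for r in first])
        assert abs(f_rev - 0.55) < 3 * np.sqrt(0.55 * 0.45 / 10_000)

    def test_one_way_no_reentry_into_reversal(self, pulse_protocol):
        config = GeneratorConfig(n_larvae=500, seed=6)
        records = generate_response_records(config, pulse_protocol)
        for labels in _label_sequences(records).values():
            for n in range(pulse_protocol.n_pulses - 1):
                if labels[n] is not BehaviorLabel.REV:
                    assert labels[n + 1] is not BehaviorLabel.REV

    def test_full_recovery_keeps_repeat_at_kernel_value(self):
        # with OFF times far above tau_res the REV->REV repeat is the
        # kernel's unmodulated 85%
        protocol = StimulusProtocol(500, 2, t_on=30, t_off=500, n_pulses=4)
        config = GeneratorConfig(n_larvae=4000, seed=8)
        records = generate_response_records(config, protocol)
        seqs = _label_sequences(records)
        stay = tot = 0
        for labels in seqs.values():
            for n in range(3):
                if labels[n] is BehaviorLabel.REV:
                    tot += 1
                    stay += labels[n + 1] is BehaviorLabel.REV
        assert abs(stay / tot - 0.85) < 3 * np.sqrt(0.85 * 0.15 / tot)

    def test_short_gap_suppresses_repeat(self):
        # 1-s gap against tau_res = 5.3 s recovers only ~17% of sensitivity
        protocol = StimulusProtocol(500, 2, t_on=30, t_off=1.0, n_pulses=2)
        config = GeneratorConfig(n_larvae=4000, seed=9)
        records = generate_response_records(config, protocol)
        seqs = _label_sequences(records)
        stay = tot = 0
        for labels in seqs.values():
            if labels[0] is BehaviorLabel.REV:
                tot += 1
                stay += labels[1] is BehaviorLabel.REV
        expected = 0.85 * (1 - np.exp(-1.0 / 5.3))
        assert abs(stay / tot - expected) < 3 * np.sqrt(expected * (1 - expected) / tot)

    def test_per_gap_off_times(self):
        protocol = StimulusProtocol(500, 2, t_on=30, t_off=1.0, n_pulses=3)
        config = GeneratorConfig(n_larvae=10, seed=3)
        with pytest.raises(ValueError, match="gaps"):
            generate_response_records(config, protocol, gaps=[1.0])
        records = generate_response_records(config, protocol, gaps=[40.0, 1.0])
        assert len(records) == 30


class TestCountTimeSeries:
    def test_expectation_starts_at_naive_fraction(self, wildtype_config,
                                                  continuous_protocol):
        ts = generate_count_timeseries(wildtype_config, continuous_protocol, 120)
        # first bin center is dt/2 into the decay
        expected = 0.03 + 0.52 * np.exp(-0.5 / 18.9)
        assert ts.expected_rev[0] == pytest.approx(expected, abs=1e-9)

    def test_expectation_e_folds_at_tau_des(self, wildtype_config,
                                            continuous_protocol):
        ts = generate_count_timeseries(wildtype_config, continuous_protocol, 120)
        i = np.argmin(np.abs(ts.t - (18.9 + 0.5)))
        assert ts.expected_rev[i] == pytest.approx(0.03 + 0.52 / np.e, abs=0.01)

    def test_long_off_period_relaxes_to_baseline(self, wildtype_config):
        protocol = StimulusProtocol(500, 2, t_on=1, t_off=299, n_pulses=2)
        ts = generate_count_timeseries(wildtype_config, protocol, 600)
        late = ts.expected_rev[(ts.t > 250) & (ts.t < 299)]
        assert np.all(np.abs(late - 0.03) < 0.005)

    def test_counts_are_binomial_around_expectation(self, wildtype_config,
                                                    continuous_protocol):
        ts = generate_count_timeseries(wildtype_config, continuous_protocol, 120)
        z = (ts.f_rev - ts.expected_rev) / np.sqrt(
            ts.expected_rev * (1 - ts.expected_rev) / 100
        )
        assert np.abs(z).max() < 5
        assert np.all(ts.n_stop >= ts.n_rev)  # reversing larvae are stopped

    def test_recovery_scaled_peaks(self):
        config = GeneratorConfig(n_larvae=100, seed=2)
        protocol = StimulusProtocol(500, 2, t_on=10, t_off=20, n_pulses=3)
        ts = generate_count_timeseries(config, protocol, 90)
        r1 = 1 - np.exp(-20 / 5.3)
        assert ts.expected_rev[30] == pytest.approx(
            0.03 + 0.52 * r1 * np.exp(-0.5 / 18.9), abs=1e-9
        )

    def test_duration_must_cover_protocol(self, wildtype_config, pulse_protocol):
        with pytest.raises(ValueError, match="duration"):
            generate_count_timeseries(wildtype_config, pulse_protocol, 10.0)

    def test_deterministic_under_fixed_seed(self, wildtype_config,
                                            continuous_protocol):
        a = generate_count_timeseries(wildtype_config, continuous_protocol, 120)
        b = generate_count_timeseries(wildtype_config, continuous_protocol, 120)
        np.testing.assert_array_equal(a.n_rev, b.n_rev)


class TestTrajectories:
    def test_deterministic_under_fixed_seed(self, wildtype_config):
        protocol = StimulusProtocol(500, 2, 10, 20, 3)
        records = generate_response_records(wildtype_config, protocol)[:30]
        a = generate_trajectories(records, protocol, seed=11)
        b = generate_trajectories(records, protocol, seed=11)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.x, tb.x)
            np.testing.assert_array_equal(ta.head, tb.head)

    def test_empty_records_rejected(self, pulse_protocol):
        with pytest.raises(ValueError):
            generate_trajectories([], pulse_protocol, seed=1)

    def test_round_trip_label_agreement(self, wildtype_config):
        protocol = StimulusProtocol(500, 2, 10, 20, 4)
        records = generate_response_records(wildtype_config, protocol)
        trajs = generate_trajectories(records, protocol, seed=12)
        truth = {(r.larva_id, r.pulse_n): r.label for r in records}
        agree = total = 0
        for traj in trajs:
            for rec in classify_trajectory(traj, protocol):
                total += 1
                agree += rec.label is truth[(traj.larva_id, rec.pulse_n)]
        assert agree / total >= 0.99
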