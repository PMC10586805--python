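"""Habituation kinetics: curves, exponential fits, bootstrap, ratio analysis."""

import numpy as np
import pytest

from larvahab import (
    ExponentialDecayModel,
    GeneratorConfig,
    HabituationParams,
    RecoveryModel,
    StimulusProtocol,
    TauResSchedule,
    compare_fits,
    desensitization_curve,
    fit_exponential,
    fit_resensitization,
    generate_count_timeseries,
    generate_response_records,
    predict_pulse_train,
    recovery_factor,
    recovery_ratio_curve,
    resensitization_curve,
)

WT = HabituationParams()


class TestCurves:
    def test_desensitization_at_zero_is_naive_fraction(self):
        assert desensitization_curve(WT, 0.0) == pytest.approx(0.55)

    def test_desensitization_e_fold(self):
        params = HabituationParams(f0_rev=0.5, tau_des=10.0)
        assert desensitization_curve(params, 10.0) == pytest.approx(0.1839, abs=1e-4)

    def test_desensitization_limits(self):
        assert desensitization_curve(WT, 1e6) == pytest.approx(0.0, abs=1e-12)
        assert desensitization_curve(WT, 1e6, offset=True) == pytest.approx(0.03)

    def test_resensitization_limits(self):
        assert resensitization_curve(WT, 0.0, 1) == 0.0
        assert resensitization_curve(WT, 5.3, 1) == pytest.approx(1 - 1 / np.e)
        assert resensitization_curve(WT, 1e6, 1) == pytest.approx(1.0)

    def test_resensitization_monotone_in_off_time(self):
        t = np.linspace(0, 60, 200)
        rec = resensitization_curve(WT, t, 1)
        assert np.all(np.diff(rec) >= 0)

    def test_first_pulse_has_full_recovery_factor(self):
        assert recovery_factor(WT, 0.001, 0) == 1.0

    def test_schedule_indexing(self):
        sched = TauResSchedule(values=(5.3, 5.3), tail=0.8)
        assert sched(0) == 5.3 and sched(1) == 5.3 and sched(7) == 0.8
        with pytest.raises(ValueError):
            sched(-1)
        with pytest.raises(ValueError):
            TauResSchedule(values=(0.0,), tail=0.8)


class TestPulseTrainPrediction:
    def test_single_pulse_reduces_to_desensitization(self):
        protocol = StimulusProtocol(500, 2, t_on=30, t_off=0, n_pulses=1)
        t, f = predict_pulse_train(WT, protocol, dt=1.0)
        on = t < 30  # ON interval is half-open
        np.testing.assert_allclose(f[on], desensitization_curve(WT, t[on]), rtol=1e-12)
        assert np.all(f[~on] == 0.0)

    def test_full_recovery_restores_every_peak(self):
        params = HabituationParams(tau_res=TauResSchedule(values=(1.0,), tail=1.0))
        protocol = StimulusProtocol(500, 2, t_on=10, t_off=100, n_pulses=4)
        t, f = predict_pulse_train(params, protocol, dt=1.0)
        peaks = f[np.isin(t, protocol.pulse_onsets())]
        assert peaks == pytest.approx(np.full(4, 0.55), rel=1e-6)

    def test_first_recovery_peak_ratio(self):
        protocol = StimulusProtocol(500, 2, t_on=10, t_off=20, n_pulses=2)
        t, f = predict_pulse_train(WT, protocol, dt=1.0)
        p0 = f[t == 0.0][0]
        p1 = f[t == 30.0][0]
        assert p1 / p0 == pytest.approx(1 - np.exp(-20 / 5.3), rel=1e-9)

    def test_zero_while_stimulus_off(self):
        protocol = StimulusProtocol(500, 2, t_on=10, t_off=20, n_pulses=2)
        t, f = predict_pulse_train(WT, protocol, dt=1.0)
        off = ~protocol.is_on(t)
        assert np.all(f[off] == 0.0)

    def test_schedule_model_tracks_late_peaks_better_than_constant(self):
        """Adding the tau_res-vs-n dependence moves predicted late-pulse
        recovery profiles closer to the generator's expected peaks than
        keeping the first-recovery constant throughout.  Peaks are
        normalized to the first peak so amplitude conventions cancel."""
        protocol = StimulusProtocol(500, 2, t_on=10, t_off=20, n_pulses=8)
        config = GeneratorConfig(n_larvae=100, seed=1)
        ts = generate_count_timeseries(config, protocol, duration=protocol.span + 20)
        onset_bins = np.searchsorted(ts.t, protocol.pulse_onsets() + 0.5 - 1e-9)
        empirical = ts.expected_rev[onset_bins] - 0.03  # zero-noise peaks
        empirical = empirical / empirical[0]

        constant = HabituationParams(tau_res=TauResSchedule(values=(5.3,), tail=5.3))
        err = {}
        for name, params in (("schedule", WT), ("constant", constant)):
            t, f = predict_pulse_train(params, protocol, dt=1.0)
            peaks = f[np.isin(t, protocol.pulse_onsets())]
            err[name] = np.abs(peaks / peaks[0] - empirical).sum()
        assert err["schedule"] < err["constant"]


class TestExponentialFit:
    @pytest.mark.parametrize("tau", [1.0, 5.0, 18.9, 25.6])
    def test_noiseless_recovery_is_exact(self, tau):
        t = np.arange(0, 6 * tau, max(tau / 20, 0.05)) + 0.01
        y = 0.03 + 0.5 * np.exp(-t / tau)
        res = fit_exponential(t, y, y0=0.03, n_boot=10, seed=0)
        assert res.tau == pytest.approx(tau, rel=5e-4)
        assert res.amplitude == pytest.approx(0.5, rel=1e-3)

    def test_zero_sem_gives_zero_uncertainty(self):
        t = np.arange(20.0)
        y = 0.03 + 0.4 * np.exp(-t / 7.0)
        res = fit_exponential(t, y, sem=np.zeros_like(t), y0=0.03, n_boot=50, seed=1)
        assert res.sd_tau == 0.0
        assert np.all(res.bootstrap_taus == res.bootstrap_taus[0])

    def test_bootstrap_deterministic_under_seed(self):
        t = np.arange(40.0)
        rng = np.random.default_rng(3)
        y = np.clip(0.03 + 0.5 * np.exp(-t / 12) + rng.normal(0, 0.03, 40), 0, 1)
        sem = np.full(40, 0.03)
        a = fit_exponential(t, y, sem=sem, y0=0.03, n_boot=100, seed=9)
        b = fit_exponential(t, y, sem=sem, y0=0.03, n_boot=100, seed=9)
        assert a.tau == b.tau and a.sd_tau == b.sd_tau
        np.testing.assert_array_equal(a.bootstrap_taus, b.bootstrap_taus)

    def test_fixed_baseline_is_respected(self):
        t = np.arange(30.0)
        y = 0.1 + 0.4 * np.exp(-t / 5)
        res = fit_exponential(t, y, y0=0.1, n_boot=5, seed=0)
        assert res.y0 == 0.1
        assert res.tau == pytest.approx(5.0, rel=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ExponentialDecayModel([0, 1, 2], [1, 0.5, 0.2], y0=0.0)

    def test_summary_mentions_key_quantities(self):
        t = np.arange(20.0)
        res = fit_exponential(t, 0.03 + 0.4 * np.exp(-t / 7), y0=0.03, n_boot=5, seed=0)
        text = res.summary()
        assert "tau" in text and "y0" in text and "bootstrap" in text


class TestCompareFits:
    def _result_with(self, taus):
        t = np.arange(20.0)
        res = fit_exponential(t, 0.03 + 0.4 * np.exp(-t / 7), y0=0.03, n_boot=5, seed=0)
        res.bootstrap_taus = np.asarray(taus, dtype=float)
        return res

    def test_identical_sets_not_different(self):
        a = self._result_with(np.full(100, 7.0))
        b = self._result_with(np.full(100, 7.0))
        z, p = compare_fits(a, b)
        assert z == 0.0 and p == 1.0

    def test_widely_separated_sets(self):
        rng = np.random.default_rng(0)
        a = self._result_with(rng.normal(10, 0.5, 1000))
        b = self._result_with(rng.normal(20, 0.5, 1000))  # ~14 pooled SDs apart
        _, p = compare_fits(a, b)
        assert p < 1e-3

    def test_statistic_invariant_to_bootstrap_count(self):
        rng = np.random.default_rng(1)
        z_by_size = []
        for n in (500, 1000, 4000):
            a = self._result_with(10 + 1.0 * rng.standard_normal(n))
            b = self._result_with(12 + 1.0 * rng.standard_normal(n))
            z_by_size.append(compare_fits(a, b)[0])
        # SD-based statistic hovers around (10-12)/sqrt(2) regardless of n
        assert np.ptp(z_by_size) < 0.3
        assert z_by_size[-1] == pytest.approx(-2 / np.sqrt(2), abs=0.3)

    def test_missing_bootstrap_sets_rejected(self):
        a = self._result_with([1.0])
        a.bootstrap_taus = np.array([])
        with pytest.raises(ValueError):
            compare_fits(a, a)


class TestRecoveryAnalysis:
    def _family(self, config, t_offs, n_pulses=2, seed0=900, gaps=None):
        fam = {}
        for i, t_off in enumerate(t_offs):
            protocol = StimulusProtocol(500, 2, t_on=30, t_off=t_off, n_pulses=n_pulses)
            fam[t_off] = generate_response_records(
                config, protocol, seed=seed0 + i, gaps=gaps(t_off) if gaps else None
            )
        return fam

    def test_ratio_curve_plateaus_at_long_off_times(self):
        config = GeneratorConfig(n_larvae=2000, seed=31)
        fam = self._family(config, [40.0, 80.0])
        curve = recovery_ratio_curve(fam, pulse_n=1)
        # plateau is the kernel repeat probability at full recovery
        assert curve.ratio == pytest.approx([0.85, 0.85], abs=0.04)

    def test_low_count_conditions_dropped(self):
        config = GeneratorConfig(n_larvae=4, seed=32)
        fam = self._family(config, [0.5, 40.0])
        with pytest.raises(ValueError):
            recovery_ratio_curve(fam, pulse_n=1, min_count=5)

    def test_noiseless_ratio_fit_recovers_tau_exactly(self):
        t_off = np.array([0.5, 1, 2, 5, 10, 20, 40])
        ratio = 0.85 * (1 - np.exp(-t_off / 5.3))
        res = RecoveryModel(t_off, ratio).fit(n_boot=5, seed=0)
        assert res.tau == pytest.approx(5.3, rel=1e-4)
        assert res.amplitude == pytest.approx(0.85, rel=1e-4)

    def test_binomial_route_recovers_tau(self):
        config = GeneratorConfig(n_larvae=100, seed=33)
        fam = self._family(config, [0.5, 1, 2, 5, 10, 20, 40])
        res = fit_resensitization(fam, pulse_n=1, n_boot=100, seed=2)
        assert res.tau == pytest.approx(5.3, rel=0.45)  # single-family sanity
        assert res.sd_tau > 0

    def test_fixed_amplitude_normalization_available(self):
        t_off = np.array([1.0, 5.0, 20.0, 60.0])
        ratio = 1 - np.exp(-t_off / 5.3)
        res = RecoveryModel(t_off, ratio).fit(fix_amplitude=1.0, n_boot=5, seed=0)
        assert res.amplitude_fixed
        assert res.tau == pytest.approx(5.3, rel=1e-4)

    def test_isolated_final_gap_design_resolves_fast_recovery(self):
        """Late-pulse recovery (tau ~0.8 s) is measurable when earlier gaps
        are long enough for full recovery."""
        config = GeneratorConfig(n_larvae=200, seed=34)
        fam = self._family(
            config,
            [0.5, 1, 2, 5, 10, 20, 40],
            n_pulses=5,
            gaps=lambda t: [40.0, 40.0, 40.0, t],
        )
        res = fit_resensitization(fam, pulse_n=4, n_boot=50, seed=3)
        assert res.tau == pytest.approx(0.8, abs=0.4)
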