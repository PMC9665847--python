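"""Synaptic-event analysis: detection, statistics, decay mixtures, PPR,
drug-sensitivity classification, firing-rate normalization."""

import numpy as np
import pytest

from ceaphys.detect import Event, double_exponential_template, match_events
from ceaphys.ephys import (
    average_sweeps,
    classify_pgb_sensitivity,
    compute_ppr,
    detect_epsc_events,
    event_statistics,
    fit_event_decay,
    normalize_firing_rate,
    split_decay_populations,
)
from ceaphys.simulate import PairedPulseSweep, simulate_epsc_trace, simulate_paired_pulse_sweeps
from ceaphys.traces import InputError, Trace


class TestDetectEpsc:
    def test_three_ideal_templates(self):
        rate = 10000.0
        kernel = double_exponential_template(0.0005, 0.005, rate)
        x = np.zeros(30000)
        onsets = [2000, 12000, 22000]
        for i in onsets:
            x[i : i + kernel.size] -= 20.0 * kernel[: 30000 - i]
        events = detect_epsc_events(Trace(x, rate))
        assert len(events) == 3
        for e, i in zip(events, onsets):
            assert abs(e.onset_s - i / rate) <= 1e-3
            assert e.amplitude == pytest.approx(20.0, rel=0.05)

    def test_flat_trace_zero_events(self):
        assert detect_epsc_events(Trace(np.zeros(5000), 10000.0)) == []

    def test_recall_precision_on_generator_trace(self):
        trace, truth = simulate_epsc_trace(
            rate_hz=2.0, amp_mean_pa=10.0, amp_sd_pa=0.0, noise_sd_pa=2.0,
            duration_s=100.0, seed=4,
        )
        detected = np.array([e.onset_s for e in detect_epsc_events(trace)])
        matched, fp, missed = match_events(truth.times_s, detected, tolerance_s=0.005)
        assert matched / (matched + missed) >= 0.9
        assert matched / (matched + fp) >= 0.9


class TestEventStatistics:
    def test_frequency_from_count(self):
        events = [Event(onset_s=i * 0.5, amplitude=10.0, criterion=5.0) for i in range(10)]
        stats = event_statistics(events, duration_s=5.0)
        assert stats.frequency_hz == pytest.approx(2.0)
        assert stats.inter_event_intervals_s.size == 9

    def test_single_event(self):
        stats = event_statistics([Event(1.0, 5.0, 4.0)], duration_s=10.0)
        assert stats.frequency_hz == pytest.approx(0.1)
        assert stats.inter_event_intervals_s.size == 0

    def test_zero_events(self):
        stats = event_statistics([], duration_s=10.0)
        assert stats.frequency_hz == 0.0
        assert np.isnan(stats.mean_amplitude_pa)

    def test_frequency_estimate_within_poisson_se(self):
        trace, _ = simulate_epsc_trace(
            rate_hz=4.0, amp_mean_pa=15.0, amp_sd_pa=0.0, noise_sd_pa=2.0,
            duration_s=60.0, seed=6,
        )
        stats = event_statistics(detect_epsc_events(trace), trace.duration_s)
        se = np.sqrt(4.0 * 60.0) / 60.0
        assert abs(stats.frequency_hz - 4.0) < 3 * se


class TestFitEventDecay:
    def test_exact_exponential(self):
        rate = 10000.0
        t = np.arange(int(0.05 * rate)) / rate
        tau, ok = fit_event_decay(-10.0 * np.exp(-t / 0.005), rate)
        assert ok and tau == pytest.approx(5.0, abs=1e-6)

    def test_noisy_exponential_median_within_5pct(self, rng):
        rate = 10000.0
        t = np.arange(int(0.12 * rate)) / rate
        taus = []
        for _ in range(100):
            y = -10.0 * np.exp(-t / 0.012) + rng.normal(0, 0.5, t.size)
            tau, ok = fit_event_decay(y, rate)
            if ok:
                taus.append(tau)
        assert len(taus) >= 90
        assert abs(np.median(taus) - 12.0) / 12.0 < 0.05

    def test_non_decaying_segment_flagged(self):
        tau, ok = fit_event_decay(-np.ones(100), 10000.0)
        assert not ok and np.isnan(tau)


class TestDecayMixture:
    def test_identical_taus_select_one_component(self):
        res = split_decay_populations(np.full(50, 5.0))
        assert res.k_selected == 1

    def test_bimodal_recovery(self, rng):
        taus = np.concatenate(
            [np.exp(rng.normal(np.log(3.0), 0.15, 200)),
             np.exp(rng.normal(np.log(12.0), 0.15, 200))]
        )
        res = split_decay_populations(taus)
        assert res.at_least_two_populations
        assert res.means_ms[0] == pytest.approx(3.0, rel=0.1)
        assert res.means_ms[1] == pytest.approx(12.0, rel=0.1)
        # canonical ordering: ascending component mean
        assert res.means_log[0] < res.means_log[1]
        assert "selected k:  2" in res.summary()

    def test_bic_selection_rates(self):
        # unimodal sets pick k=1 and well-separated bimodal sets pick k=2
        # in >= 95% of seeded runs
        uni_hits = bi_hits = 0
        n_runs = 100
        for seed in range(n_runs):
            r = np.random.default_rng(seed)
            uni = np.exp(r.normal(np.log(5.0), 0.2, 200))
            uni_hits += split_decay_populations(uni).k_selected == 1
            bi = np.concatenate(
                [np.exp(r.normal(np.log(3.0), 0.15, 100)),
                 np.exp(r.normal(np.log(12.0), 0.15, 100))]
            )
            bi_hits += split_decay_populations(bi).k_selected == 2
        assert uni_hits >= 95
        assert bi_hits >= 95

    def test_too_few_values_rejected(self):
        with pytest.raises(InputError):
            split_decay_populations(np.full(10, 5.0))


class TestComputePpr:
    def test_identical_pulses_unity(self):
        sweeps = simulate_paired_pulse_sweeps(100.0, 1.0, n_sweeps=1, noise_sd_pa=0.0)
        assert compute_ppr(sweeps[0], noise_floor_k=0.0).ppr == pytest.approx(1.0)

    def test_paper_scale_arithmetic(self):
        sweeps = simulate_paired_pulse_sweeps(100.0, 0.58, n_sweeps=1, noise_sd_pa=0.0)
        res = compute_ppr(sweeps[0], noise_floor_k=0.0)
        # absolute amplitudes carry the (identical) smoothing attenuation of
        # the peak-measurement window; it cancels exactly in the ratio
        assert res.a1_pa == pytest.approx(100.0, rel=0.05)
        assert res.a2_pa == pytest.approx(58.0, rel=0.05)
        assert res.ppr == pytest.approx(0.58, abs=1e-6)

    def test_scale_invariance(self):
        sweeps = simulate_paired_pulse_sweeps(100.0, 0.7, n_sweeps=1, noise_sd_pa=1.0, seed=3)
        s = sweeps[0]
        scaled = PairedPulseSweep(
            Trace(4.2 * s.current.samples, s.current.rate_hz), s.pulse_onsets_s
        )
        assert compute_ppr(scaled).ppr == pytest.approx(compute_ppr(s).ppr, abs=1e-12)

    def test_noise_floor_guard(self):
        rng = np.random.default_rng(0)
        trace = Trace(rng.normal(0, 2.0, 5000), 10000.0)
        with pytest.raises(InputError):
            compute_ppr(trace, pulse_onsets_s=(0.1, 0.3))

    def test_wrong_interval_rejected(self):
        sweeps = simulate_paired_pulse_sweeps(100.0, 0.58, n_sweeps=1, noise_sd_pa=0.0)
        with pytest.raises(InputError):
            compute_ppr(sweeps[0], interval_ms=100.0)


class TestSensitivity:
    def test_clear_inhibition(self):
        res = classify_pgb_sensitivity([100, 105, 95, 100, 100], [90, 88, 92])
        assert res.label == "inhibited"
        assert res.inhibition_pct == pytest.approx(10.0, abs=1.0)

    def test_small_change_not_inhibited(self):
        res = classify_pgb_sensitivity([100, 105, 95, 100, 100], [98, 99, 97])
        assert res.label == "not_inhibited"

    def test_boundary_is_strict(self):
        bl = np.array([95.0, 100.0, 105.0])  # mean 100, sample SD 5
        res = classify_pgb_sensitivity(bl, [95.0])  # drop of exactly 1 SD_BL
        assert res.sd_bl_pa == pytest.approx(5.0)
        assert res.label == "not_inhibited"

    def test_rescaling_invariance_and_monotonicity(self):
        bl = [100.0, 104.0, 96.0, 101.0]
        assert (
            classify_pgb_sensitivity(bl, [90.0]).label
            == classify_pgb_sensitivity(np.array(bl) * 2.5, [225.0]).label
        )
        labels = [classify_pgb_sensitivity(bl, [m]).label for m in (80.0, 98.0, 100.0)]
        assert labels == ["inhibited", "not_inhibited", "not_inhibited"]

    def test_input_guards(self):
        with pytest.raises(InputError):
            classify_pgb_sensitivity([100, 101], [90])
        with pytest.raises(InputError):
            classify_pgb_sensitivity([100, 101, 99], [])


class TestNormalizeFiringRate:
    def test_constant_firing_all_unity(self):
        spikes = np.arange(0.05, 60.0, 0.5)  # steady 2 Hz
        _, rates = normalize_firing_rate(spikes, 5.0, (0.0, 30.0), total_duration_s=60.0)
        np.testing.assert_allclose(rates, 1.0)

    def test_halved_rate_reads_half(self):
        spikes = np.concatenate([np.arange(0.05, 30.0, 0.5), np.arange(30.05, 60.0, 1.0)])
        _, rates = normalize_firing_rate(spikes, 5.0, (0.0, 30.0), total_duration_s=60.0)
        np.testing.assert_allclose(rates[:6], 1.0)
        np.testing.assert_allclose(rates[6:], 0.5)

    def test_silent_bins_are_zero(self):
        spikes = np.arange(0.05, 30.0, 0.5)
        _, rates = normalize_firing_rate(spikes, 5.0, (0.0, 30.0), total_duration_s=60.0)
        np.testing.assert_allclose(rates[6:], 0.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(InputError):
            normalize_firing_rate(np.array([40.0, 41.0]), 5.0, (0.0, 30.0), 60.0)


def test_average_sweeps_requires_common_onsets():
    a = simulate_paired_pulse_sweeps(100.0, 0.58, n_sweeps=2, noise_sd_pa=1.0, seed=0)
    b = simulate_paired_pulse_sweeps(100.0, 0.58, interval_ms=100.0, n_sweeps=1, noise_sd_pa=1.0)
    avg = average_sweeps(a)
    assert avg.current.samples.shape == a[0].current.samples.shape
    with pytest.raises(InputError):
        average_sweeps([a[0], b[0]])
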