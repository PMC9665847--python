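"""Calcium pipeline: smoothing, normalization, AUC scoring, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ceaphys.calcium import (
    auc_per_second,
    classify_cohort,
    classify_deltas,
    concat_minmax_normalize,
    detect_ca_events,
    gaussian_smooth,
    resample_window,
)
from ceaphys.detect import double_exponential_template
from ceaphys.traces import DegenerateTraceError, InputError, Trace, TrialPair


def brute_force_smooth(x, b):
    """Direct evaluation of the self-normalizing kernel sum (oracle)."""
    n = x.size
    out = np.empty(n)
    idx = np.arange(n)
    for t in range(n):
        k = np.exp(-((t - idx) ** 2) / (2 * b * b))
        out[t] = (k * x).sum() / k.sum()
    return out


class TestGaussianSmooth:
    def test_constant_trace_unchanged(self):
        trace = Trace(np.full(50, 5.0), 15.0)
        out = gaussian_smooth(trace, 10.0)
        np.testing.assert_allclose(out.samples, 5.0, atol=1e-12)

    def test_unit_impulse_center_value(self):
        # center output = 1 / sum_j exp(-(c-j)^2/2) for b=1, length 21
        x = np.zeros(21)
        x[10] = 1.0
        out = gaussian_smooth(Trace(x, 15.0), 1.0)
        expected = 1.0 / np.exp(-np.arange(-10, 11) ** 2 / 2.0).sum()
        assert out.samples[10] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.3989, abs=2e-4)

    def test_linear_ramp_interior_preserved(self):
        # symmetric renormalized kernels preserve linear trends away from the
        # edges; the edge influence decays like the Gaussian tail times the
        # signal scale, so an 8b margin brings it below 1e-9 for this ramp
        x = np.arange(200, dtype=float)
        out = gaussian_smooth(Trace(x, 15.0), 3.0)
        interior = slice(8 * 3, 200 - 8 * 3)
        np.testing.assert_allclose(out.samples[interior], x[interior], atol=1e-9)

    def test_matches_brute_force_formula(self, rng):
        x = rng.normal(size=60)
        out = gaussian_smooth(Trace(x, 15.0), 3.0)
        np.testing.assert_allclose(out.samples, brute_force_smooth(x, 3.0), atol=1e-9)

    def test_truncated_kernel_close_to_full(self, rng):
        # truncation error tracks the Gaussian tail mass beyond the radius:
        # ~6e-5 at +/-4b, <1e-7 by +/-6b
        x = rng.normal(size=500)
        full = gaussian_smooth(Trace(x, 15.0), 10.0)
        trunc4 = gaussian_smooth(Trace(x, 15.0), 10.0, truncate=4.0)
        trunc6 = gaussian_smooth(Trace(x, 15.0), 10.0, truncate=6.0)
        assert np.abs(full.samples - trunc4.samples).max() < 2e-4
        assert np.abs(full.samples - trunc6.samples).max() < 1e-7

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=40),
        st.floats(0.5, 20.0),
    )
    def test_output_bounded_by_input_extrema(self, values, b):
        x = np.asarray(values)
        out = gaussian_smooth(Trace(x, 15.0), b)
        assert out.samples.min() >= x.min() - 1e-9
        assert out.samples.max() <= x.max() + 1e-9

    def test_empty_trace_rejected(self):
        with pytest.raises(InputError):
            gaussian_smooth(Trace(np.array([1.0]), 15.0).with_samples([]), 10.0)


class TestMinMaxNormalize:
    def test_basic_example(self):
        pair = TrialPair("n", Trace([2.0, 4.0], 10.0), Trace([6.0, 6.0], 10.0))
        out = concat_minmax_normalize(pair)
        np.testing.assert_allclose(out.baseline.samples, [0.0, 0.5])
        np.testing.assert_allclose(out.post.samples, [1.0, 1.0])

    def test_attains_both_bounds_on_concatenation(self, rng):
        pair = TrialPair("n", Trace(rng.normal(size=30), 10.0), Trace(rng.normal(size=30), 10.0))
        out = concat_minmax_normalize(pair)
        concat = np.concatenate([out.baseline.samples, out.post.samples])
        assert concat.min() == 0.0 and concat.max() == 1.0

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.floats(0.1, 50.0), st.floats(-100.0, 100.0))
    def test_affine_invariance(self, a, c):
        rng = np.random.default_rng(0)
        bl, post = rng.normal(size=20), rng.normal(size=20)
        base = concat_minmax_normalize(TrialPair("n", Trace(bl, 10.0), Trace(post, 10.0)))
        scaled = concat_minmax_normalize(
            TrialPair("n", Trace(a * bl + c, 10.0), Trace(a * post + c, 10.0))
        )
        np.testing.assert_allclose(base.baseline.samples, scaled.baseline.samples, atol=1e-9)
        np.testing.assert_allclose(base.post.samples, scaled.post.samples, atol=1e-9)

    def test_constant_pair_degenerate(self):
        pair = TrialPair("n", Trace([3.7, 3.7], 10.0), Trace([3.7], 10.0))
        with pytest.raises(DegenerateTraceError):
            concat_minmax_normalize(pair)


class TestResampleWindow:
    def test_sample_count(self):
        trace = Trace(np.zeros(int(9 * 60 * 15)), 15.0)  # 9 min at 15 Hz
        out = resample_window(trace)
        assert len(out) == 3600 and out.rate_hz == 10.0

    def test_linear_interpolation_values(self):
        out = resample_window(Trace([0.0, 1.0], 1.0), window_s=1.0, target_hz=10.0)
        np.testing.assert_allclose(out.samples, np.arange(10) / 10.0)

    def test_identity_at_native_rate(self):
        x = np.random.default_rng(0).normal(size=3600)
        out = resample_window(Trace(x, 10.0))
        np.testing.assert_allclose(out.samples, x)

    def test_short_trace_rejected(self):
        with pytest.raises(InputError):
            resample_window(Trace(np.zeros(100), 10.0))


class TestAucPerSecond:
    @pytest.mark.parametrize("level", [1.0, 0.5])
    def test_constant_level(self, level):
        assert auc_per_second(Trace(np.full(100, level), 10.0)) == pytest.approx(level)

    def test_symmetric_triangle(self):
        x = np.concatenate([np.linspace(0, 1, 51), np.linspace(1, 0, 51)[1:]])
        assert auc_per_second(Trace(x, 10.0)) == pytest.approx(0.5)

    def test_warns_outside_unit_range(self):
        with pytest.warns(UserWarning):
            auc_per_second(Trace([0.0, 2.0, 0.0], 10.0))


class TestClassifyDeltas:
    def test_sigma_and_labels_example(self):
        deltas = np.array([-0.05, -0.04, 0.001, 0.002, 0.04, 0.05])
        labels, sigma = classify_deltas(deltas)
        assert sigma == pytest.approx(np.std(deltas), abs=1e-15)
        assert sigma == pytest.approx(0.037, abs=5e-4)
        assert list(labels) == [
            "inhibited", "inhibited", "no_effect", "no_effect", "excited", "excited",
        ]

    def test_all_zero_deltas_no_effect(self):
        labels, sigma = classify_deltas(np.zeros(5))
        assert sigma == 0.0
        assert all(lab == "no_effect" for lab in labels)  # strict inequality

    def test_single_neuron_rejected(self):
        with pytest.raises(InputError):
            classify_deltas(np.array([0.1]))


class TestClassifyCohort:
    def test_flip_baseline_post_swaps_labels(self, small_cohort):
        pairs, _ = small_cohort
        res = classify_cohort(pairs)
        flipped = [TrialPair(p.neuron_id, p.post, p.baseline) for p in pairs]
        res_f = classify_cohort(flipped)
        swap = {"inhibited": "excited", "excited": "inhibited", "no_effect": "no_effect"}
        assert [swap[s.label] for s in res.scores] == [s.label for s in res_f.scores]

    def test_affine_transform_of_raw_traces_preserves_labels(self, small_cohort):
        pairs, _ = small_cohort
        res = classify_cohort(pairs)
        scaled = [
            TrialPair(
                p.neuron_id,
                p.baseline.with_samples(3.0 * p.baseline.samples + 7.0),
                p.post.with_samples(3.0 * p.post.samples + 7.0),
            )
            for p in pairs
        ]
        res_s = classify_cohort(scaled)
        assert [s.label for s in res.scores] == [s.label for s in res_s.scores]

    def test_counts_sum_and_frame(self, small_cohort):
        pairs, _ = small_cohort
        res = classify_cohort(pairs)
        assert sum(res.class_counts().values()) == len(pairs)
        df = res.to_frame()
        np.testing.assert_allclose(
            df["delta_auc"], df["auc_post"] - df["auc_bl"], atol=1e-15
        )
        assert "sigma_dev" in res.summary()

    def test_error_carries_neuron_id(self):
        pairs = [
            TrialPair("good", Trace(np.random.default_rng(0).normal(size=5400), 15.0),
                      Trace(np.random.default_rng(1).normal(size=5400), 15.0)),
            TrialPair("flatcell", Trace(np.zeros(5400), 15.0), Trace(np.zeros(5400), 15.0)),
        ]
        with pytest.raises(DegenerateTraceError, match="flatcell"):
            classify_cohort(pairs)


class TestDetectCaEvents:
    def test_noise_free_inserted_templates(self):
        rate = 15.0
        kernel = double_exponential_template(0.2, 1.0, rate)
        x = np.zeros(1200)
        onsets = [100, 500, 900]
        for i in onsets:
            x[i : i + kernel.size] += 0.5 * kernel[: 1200 - i]
        events = detect_ca_events(Trace(x, rate))
        assert len(events) == 3
        for e, i in zip(events, onsets):
            assert abs(e.onset_s - i / rate) <= 1.0 / rate + 1e-9  # within one frame
            assert e.amplitude == pytest.approx(0.5, rel=0.05)

    def test_flat_trace_zero_events(self):
        assert detect_ca_events(Trace(np.zeros(600), 15.0)) == []

    def test_null_false_positive_rate(self, rng):
        total_s, n_fp = 0.0, 0
        for _ in range(6):
            trace = Trace(rng.normal(0.0, 0.05, 8100), 15.0)
            n_fp += len(detect_ca_events(trace))
            total_s += trace.duration_s
        assert n_fp / total_s < 0.01
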