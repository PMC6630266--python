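"""Energy thresholding: the detection statistic, calibration and the
onset/offset rules, checked against hand traces and generator annotations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgfall.segmentation import (
    EnergySeries,
    calibrate_thresholds,
    combine_channels,
    detect_segments,
    segmentation_params,
    short_term_energy,
)
from emgfall.types import EmgRecording


def naive_short_term_energy(x, n, hop):
    """Independent loop evaluation of the mean-of-squares statistic."""
    out = []
    k = 0
    while k * hop + n <= len(x):
        acc = 0.0
        for i in range(n):
            acc += x[k * hop + i] ** 2
        out.append(acc / n)
        k += 1
    return out


class TestShortTermEnergy:
    def test_constant_signal(self):
        series = short_term_energy(np.full(500, 2.0), n=100)
        np.testing.assert_allclose(series.values, 4.0)

    def test_tiny_example(self):
        series = short_term_energy(np.array([1.0, 2.0, 3.0, 4.0]), n=2, hop=2)
        np.testing.assert_allclose(series.values, [2.5, 12.5])

    def test_matches_naive_loop(self, rng):
        x = rng.normal(size=1234)
        for n, hop in ((100, 100), (50, 25), (7, 3)):
            series = short_term_energy(x, n, hop)
            np.testing.assert_allclose(series.values, naive_short_term_energy(x, n, hop), rtol=1e-10)

    def test_trailing_partial_window_dropped(self):
        series = short_term_energy(np.ones(250), n=100)
        assert len(series) == 2

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            short_term_energy(np.ones(50), n=100)

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_amplitude_equivariance(self, c):
        """Scaling the signal by c scales every energy by c^2."""
        x = np.sin(np.linspace(0, 20, 400))
        base = short_term_energy(x, 100).values
        scaled = short_term_energy(c * x, 100).values
        np.testing.assert_allclose(scaled, c**2 * base, rtol=1e-9)


class TestCombineChannels:
    def test_single_channel_identity(self):
        rec = EmgRecording(samples=np.arange(10.0)[:, None], subject_id=1)
        np.testing.assert_allclose(combine_channels(rec), np.arange(10.0))

    def test_three_four_five(self):
        rec = EmgRecording(samples=np.array([[3.0, 4.0], [0.0, 0.0]]), subject_id=1)
        np.testing.assert_allclose(combine_channels(rec), [5.0, 0.0])

    def test_channel_permutation_invariant(self, rng):
        x = rng.normal(size=(200, 4))
        a = combine_channels(EmgRecording(samples=x, subject_id=1))
        b = combine_channels(EmgRecording(samples=x[:, ::-1], subject_id=1))
        np.testing.assert_allclose(a, b)


class TestCalibration:
    def _series(self, values):
        return EnergySeries(values=np.asarray(values, dtype=float), window_size=100, hop=100)

    def test_ratio_one_gives_holdout_max(self):
        cal = [(self._series([8.0, 8.0]), 0, 1)]
        c = calibrate_thresholds(cal, 10.0)
        assert c.sts == pytest.approx(10.0)

    def test_two_interval_example(self):
        cal = [
            (self._series([2.0, 8.0]), 0, 1),
            (self._series([1.0, 4.0]), 0, 1),
        ]
        c = calibrate_thresholds(cal, 10.0)
        assert c.sts == pytest.approx(2.5)  # mean(0.25, 0.25) * 10

    def test_scale_free_ratios(self):
        cal = [(self._series([2.0, 8.0, 4.0]), 0, 2)]
        c1 = calibrate_thresholds(cal, 10.0)
        scaled = [(self._series([6.0, 24.0, 12.0]), 0, 2)]
        c2 = calibrate_thresholds(scaled, 10.0)
        assert c1.sts == pytest.approx(c2.sts)
        assert c1.ste == pytest.approx(c2.ste)

    def test_empty_calibration_rejected(self):
        with pytest.raises(ValueError):
            calibrate_thresholds([], 10.0)


class TestParams:
    def test_canonical_operating_point(self):
        p = segmentation_params(1500, 100)
        assert (p.l, p.m) == (8, 11)  # l = round-half-even(7.5), m = round(11.25)

    def test_integer_case(self):
        p = segmentation_params(2000, 100)
        assert p.l == 10
        assert 10 < p.m < 20

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            segmentation_params(1500, 600)


class TestDetect:
    def _calib(self, sts, ste):
        from emgfall.segmentation import ThresholdCalibration

        return ThresholdCalibration(sts=sts, ste=ste, ratio_start=0, ratio_end=0, ek_max=0)

    def test_quiet_input_empty(self):
        series = EnergySeries(values=np.full(40, 0.1), window_size=100, hop=100)
        params = segmentation_params(1500, 100)
        assert detect_segments(series, self._calib(5.0, 5.0), params) == []

    def test_step_energy_hand_trace(self):
        """0.1-plateau-0.1 step: one segment opening at the rising edge."""
        e = np.array([0.1] * 10 + [10.0] * 12 + [0.1] * 8)
        series = EnergySeries(values=e, window_size=100, hop=100)
        params = segmentation_params(1500, 100)
        segs = detect_segments(series, self._calib(5.0, 5.0), params)
        assert len(segs) == 1
        assert segs[0].start_sample == 10 * 100

    def test_segments_sorted_non_overlapping(self, easy_cohort_100, easy_calibration):
        calib, series, params = easy_calibration
        for rec in easy_cohort_100[:20]:
            segs = detect_segments(series[rec.rec_id], calib, params)
            for a, b in zip(segs, segs[1:]):
                assert a.end_sample <= b.start_sample

    def test_recovers_annotated_burst(self, easy_cohort_100, easy_calibration):
        """Detected boundaries fall within 2 energy windows of ground truth."""
        calib, series, params = easy_calibration
        rec = easy_cohort_100[0]
        segs = detect_segments(series[rec.rec_id], calib, params)
        assert len(segs) == 1
        (bs, be) = rec.bursts[0]
        assert abs(segs[0].start_sample - bs) <= 200
        assert abs(segs[0].end_sample - be) <= 200

    def test_amplitude_equivariance_with_recalibration(self, easy_cohort_100):
        """Scaling the cohort and recalibrating yields identical boundaries."""
        from emgfall.segmentation import calibrate_dataset
        from dataclasses import replace

        subset = easy_cohort_100[:12]
        scaled = [replace(r, samples=r.samples * 3.7) for r in subset]
        params = segmentation_params(1500, 100)
        c1, s1 = calibrate_dataset(subset, 100)
        c2, s2 = calibrate_dataset(scaled, 100)
        for rec in subset:
            a = detect_segments(s1[rec.rec_id], c1, params)
            b = detect_segments(s2[rec.rec_id], c2, params)
            assert [(x.start_sample, x.end_sample) for x in a] == [
                (x.start_sample, x.end_sample) for x in b
            ]

    def test_per_window_lookahead_variant(self):
        e = np.array([0.1] * 10 + [10.0, 2.0] * 6 + [0.1] * 8)  # alternating plateau
        series = EnergySeries(values=e, window_size=100, hop=100)
        params = segmentation_params(1500, 100)
        mean_mode = detect_segments(series, self._calib(5.0, 0.05), params, lookahead_mode="mean")
        strict = detect_segments(series, self._calib(5.0, 0.05), params, lookahead_mode="per_window")
        assert len(mean_mode) >= len(strict)  # per-window condition is stricter
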