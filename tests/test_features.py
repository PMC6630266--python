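"""Spectrogram, PCA and time-domain feature contracts, with brute-force
loop oracles for the closed-form features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgfall.features import (
    WindowingConfig,
    apply_pca,
    build_feature_tensor,
    compute_spectrogram,
    fit_pca,
    frame_windows,
    hamming_window,
    sidelobe_attenuation_db,
    time_domain_features,
)
from emgfall.types import ActiveSegment, EmgRecording

# ---------------------------------------------------------------------------
# independent loop oracles for the six time-domain features
# ---------------------------------------------------------------------------


def naive_td(x, eps):
    n = len(x)
    mav = sum(abs(v) for v in x) / n
    xbar = sum(x) / n
    var = sum((v - xbar) ** 2 for v in x) / n
    wl = sum(abs(x[i + 1] - x[i]) for i in range(n - 1))
    rms = (sum(v * v for v in x) / n) ** 0.5
    zc = 0
    for i in range(n - 1):
        if x[i] * x[i + 1] < 0 and abs(x[i] - x[i + 1]) >= eps:
            zc += 1
    ssc = 0
    for i in range(1, n - 1):
        if (x[i] - x[i - 1]) * (x[i + 1] - x[i]) < 0:
            ssc += 1
    return mav, var, wl, rms, zc, ssc / (n - 2)


class TestHamming:
    def test_odd_window_center_is_one(self):
        w = hamming_window(301, 0.46)
        assert w[150] == pytest.approx(1.0)

    def test_endpoint_value(self):
        assert hamming_window(300, 0.46)[0] == pytest.approx(0.08)

    def test_symmetry(self):
        w = hamming_window(300, 0.46)
        np.testing.assert_allclose(w, w[::-1], rtol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            hamming_window(1)

    def test_sidelobe_attenuation_at_least_40db(self):
        assert sidelobe_attenuation_db(300, 0.46) >= 40.0


class TestFraming:
    @pytest.mark.parametrize("length,expected", [(600, 3), (300, 1), (450, 2)])
    def test_frame_counts(self, length, expected):
        cfg = WindowingConfig()
        assert frame_windows(np.ones(length), cfg).shape == (expected, 300)

    def test_short_signal_warns_empty(self):
        with pytest.warns(UserWarning):
            out = frame_windows(np.ones(299), WindowingConfig())
        assert out.shape == (0, 300)

    def test_frames_start_on_step_grid(self):
        x = np.arange(750.0)
        frames = frame_windows(x, WindowingConfig())
        np.testing.assert_allclose(frames[:, 0], [0.0, 150.0, 300.0, 450.0])


class TestSpectrogram:
    def test_sinusoid_peak_bin(self):
        t = np.arange(1500) / 1500
        x = np.sin(2 * np.pi * 100 * t)
        spec = compute_spectrogram(x, 1500.0)
        peak_freqs = spec.freq_bins_hz[np.argmax(spec.magnitudes, axis=1)]
        assert np.all(np.abs(peak_freqs - 100.0) < 3.0)

    def test_normalised_to_unit_max(self, rng):
        spec = compute_spectrogram(rng.normal(size=900), 1500.0)
        assert spec.magnitudes.max() == pytest.approx(1.0)
        assert spec.magnitudes.min() >= 0.0

    def test_band_limits(self, rng):
        spec = compute_spectrogram(rng.normal(size=600), 1500.0)
        assert spec.freq_bins_hz[0] >= 10.0
        assert spec.freq_bins_hz[-1] <= 500.0
        assert np.all(np.diff(spec.freq_bins_hz) > 0)

    def test_all_zero_degenerate(self):
        spec = compute_spectrogram(np.zeros(600), 1500.0)
        assert spec.degenerate
        np.testing.assert_array_equal(spec.magnitudes, 0.0)

    def test_parseval_consistency(self, rng):
        """Full-band spectrogram power equals windowed-frame power (DFT identity)."""
        x = rng.normal(size=300)
        spec = compute_spectrogram(x, 1500.0, band_hz=(0.0, 750.0))
        pre = spec.magnitudes * (spec.norm_max - spec.norm_min) + spec.norm_min
        nfft = 512
        weights = np.full(pre.shape[1], 2.0)
        weights[0] = 1.0  # DC bin counted once
        weights[-1] = 1.0  # Nyquist bin counted once
        lhs = np.sum(weights * pre[0] ** 2) / nfft
        rhs = np.sum((x * hamming_window(300)) ** 2)
        assert lhs == pytest.approx(rhs, rel=1e-10)


class TestPca:
    def test_orthonormal_loadings(self, rng):
        X = rng.normal(size=(60, 20))
        model = fit_pca(X, k=5)
        np.testing.assert_allclose(model.loadings.T @ model.loadings, np.eye(5), atol=1e-8)

    def test_rank_one_fixture_first_component_dominates(self, rng):
        base = rng.normal(size=30)
        gains = rng.uniform(0.5, 2.0, size=50)
        X = np.outer(gains, base) + 1e-4 * rng.normal(size=(50, 30))
        model = fit_pca(X, k=5)
        assert model.explained_variance_ratio[0] >= 0.99

    def test_variance_ratios_monotone_and_bounded(self, rng):
        model = fit_pca(rng.normal(size=(100, 40)), k=8)
        evr = model.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1.0 + 1e-9
        table = model.variance_table()
        cums = [row["cumulative_pct"] for row in table]
        assert all(b >= a for a, b in zip(cums, cums[1:]))
        assert cums[-1] <= 100.0 + 1e-6

    def test_mean_frame_projects_to_zero(self, rng):
        X = rng.normal(size=(40, 25))
        model = fit_pca(X, k=4)
        scores = (model.mean - model.mean) @ model.loadings
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_reconstruction_error_bounded_by_discarded_energy(self, rng):
        X = rng.normal(size=(20, 15))
        k = 4
        model = fit_pca(X, k=k)
        full = fit_pca(X, k=15)
        centred = X - model.mean
        recon = (centred @ model.loadings) @ model.loadings.T
        err = np.linalg.norm(centred - recon)
        discarded = np.linalg.norm(centred @ full.loadings[:, k:])
        assert err <= discarded + 1e-8

    def test_k_exceeding_bins_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.normal(size=(10, 5)), k=6)

    def test_apply_dimension_mismatch_rejected(self, rng):
        model = fit_pca(rng.normal(size=(30, 20)), k=3)
        spec = compute_spectrogram(rng.normal(size=600), 1500.0)
        with pytest.raises(ValueError):
            apply_pca(spec, model)


class TestTimeDomain:
    def test_alternating_example(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        f = time_domain_features(x, eps=0.1)
        assert (f.mav, f.var, f.wl, f.rms, f.zc, f.ssc) == (1.0, 1.0, 6.0, 1.0, 3, 1.0)

    def test_constant_window(self):
        f = time_domain_features(np.full(5, 3.0), eps=0.01)
        assert (f.mav, f.var, f.wl, f.rms, f.zc, f.ssc) == (3.0, 0.0, 0.0, 3.0, 0, 0.0)

    def test_matches_naive_loops(self, rng):
        """Vectorised features equal brute-force loops on random windows."""
        for _ in range(100):
            x = rng.normal(size=300)
            eps = 0.01 * np.sqrt(np.mean(x**2))
            f = time_domain_features(x, eps=eps)
            expect = naive_td(list(x), eps)
            np.testing.assert_allclose(f.as_array(), expect, rtol=1e-10)

    @given(st.floats(0.5, 8.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_homogeneity(self, c):
        rng = np.random.default_rng(7)
        x = rng.normal(size=64)
        eps = 0.05
        f1 = time_domain_features(x, eps=eps)
        f2 = time_domain_features(c * x, eps=c * eps)
        assert f2.mav == pytest.approx(c * f1.mav)
        assert f2.wl == pytest.approx(c * f1.wl)
        assert f2.rms == pytest.approx(c * f1.rms)
        assert f2.var == pytest.approx(c**2 * f1.var)
        assert f2.zc == f1.zc
        assert f2.ssc == f1.ssc

    def test_power_mean_inequality(self, rng):
        x = rng.normal(size=100)
        f = time_domain_features(x)
        assert f.rms**2 >= f.mav**2 - 1e-12

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            time_domain_features(np.array([1.0, 2.0]))


class TestFeatureTensor:
    def test_shapes_and_channel_depth(self, rng):
        rec = EmgRecording(samples=rng.normal(size=(4500, 4)), subject_id=1, gesture="walking")
        segs = [ActiveSegment(1000, 2500)]
        model = fit_pca(compute_spectrogram(rng.normal(size=4500), 1500.0).magnitudes, k=8)
        out = build_feature_tensor(rec, segs, model)
        assert len(out) == 1
        spm, td = out[0]["spm"], out[0]["td"]
        n_frames = (1500 - 300) // 150 + 1
        assert spm.shape == (n_frames, 8, 4)
        assert td.shape == (n_frames, 6, 4)

    def test_short_segment_skipped_with_warning(self, rng):
        rec = EmgRecording(samples=rng.normal(size=(4500, 4)), subject_id=1)
        model = fit_pca(compute_spectrogram(rng.normal(size=4500), 1500.0).magnitudes, k=8)
        with pytest.warns(UserWarning):
            out = build_feature_tensor(rec, [ActiveSegment(0, 200)], model)
        assert out == []

    def test_zero_segment_flagged_degenerate(self, rng):
        x = rng.normal(size=(4500, 4))
        x[1000:2500] = 0.0
        rec = EmgRecording(samples=x, subject_id=1)
        model = fit_pca(compute_spectrogram(rng.normal(size=4500), 1500.0).magnitudes, k=8)
        out = build_feature_tensor(rec, [ActiveSegment(1000, 2500)], model)
        assert out[0]["degenerate"]
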