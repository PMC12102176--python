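import numpy as np
import pytest

from deepscope.calcium import (
    Trace,
    detect_events,
    detect_peaks,
    dff_rolling_quantile,
    event_metrics,
    extract_roi_traces,
    gaussian_smooth,
    neuro_peak_metrics,
    propose_microdomain_rois,
    robust_zscore,
    summarize_events,
)
from deepscope.config import AstroConfig
from deepscope.synthetic import SyntheticCalciumConfig, gen_calcium_traces


class TestRobustZscore:
    def test_spike_positive_baseline_zero(self):
        x = np.full(100, 10.0)
        x[50] = 20.0
        x += np.linspace(0, 0.1, 100)  # avoid zero MAD
        z = robust_zscore(Trace(x, 1.0))
        assert z.values[50] > 10
        assert abs(np.median(z.values)) < 1e-9

    def test_affine_invariance(self, rng):
        x = rng.normal(0, 1, 500)
        z1 = robust_zscore(Trace(x, 1.0)).values
        z2 = robust_zscore(Trace(5 * x + 7, 1.0)).values
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_normal_consistency_calibration(self):
        """1.4826·MAD estimates the SD of normal noise: output SD ≈ 1."""
        rng = np.random.default_rng(77)
        z = robust_zscore(Trace(rng.normal(3.0, 2.5, 1000), 1.0))
        assert 0.9 <= z.values.std() <= 1.1

    def test_zero_mad_rejected(self):
        with pytest.raises(ValueError):
            robust_zscore(Trace(np.ones(10), 1.0))


class TestGaussianSmooth:
    def test_sigma_zero_identity(self, rng):
        x = rng.normal(size=100)
        np.testing.assert_array_equal(gaussian_smooth(Trace(x, 5.0), 0.0).values, x)

    def test_impulse_mass_preserved(self):
        x = np.zeros(201)
        x[100] = 1.0
        sm = gaussian_smooth(Trace(x, 2.0), 1.0)
        assert sm.values.sum() == pytest.approx(1.0, rel=1e-6)
        assert sm.values[100] == sm.values.max()

    def test_white_noise_variance_reduction(self):
        """Variance shrinks by the analytic factor 1/(2·√π·σ_samples)."""
        rng = np.random.default_rng(8)
        fs, sigma_s = 10.0, 1.0
        x = rng.normal(0, 1, 50000)
        sm = gaussian_smooth(Trace(x, fs), sigma_s)
        expected = 1.0 / (2 * np.sqrt(np.pi) * sigma_s * fs)
        assert sm.values.var() == pytest.approx(expected, rel=0.10)


class TestDetectPeaks:
    def test_flat_trace_empty(self):
        assert detect_peaks(Trace(np.zeros(100), 1.0)) == []

    def test_single_bump(self):
        t = np.arange(200) / 10.0
        x = 5 * np.exp(-((t - 10) ** 2) / 2)
        peaks = detect_peaks(Trace(x, 10.0), threshold_z=3.0)
        assert peaks == [100]

    def test_min_separation_merges_close_events(self):
        fs = 10.0
        t = np.arange(0, 30, 1 / fs)
        far = 5 * (np.exp(-((t - 10) ** 2) / 0.1) + np.exp(-((t - 20) ** 2) / 0.1))
        near = 5 * (np.exp(-((t - 10) ** 2) / 0.1) + np.exp(-((t - 10.5) ** 2) / 0.1))
        assert len(detect_peaks(Trace(far, fs), 3.0, min_sep_s=1.0)) == 2
        assert len(detect_peaks(Trace(near, fs), 3.0, min_sep_s=1.0)) == 1

    def test_plateau_takes_first_index(self):
        x = np.zeros(20)
        x[8:11] = 5.0
        assert detect_peaks(Trace(x, 1.0), 3.0) == [8]

    def test_zscore_then_detect_affine_invariant(self, rng):
        raw = rng.normal(50, 2, 600)
        raw[100] += 30
        raw[400] += 25

        def pipeline(x):
            return detect_peaks(gaussian_smooth(robust_zscore(Trace(x, 1.0)), 1.0), 3.0)

        assert pipeline(raw) == pipeline(0.3 * raw + 11.0)


class TestEventMetrics:
    def test_triangle_geometry(self):
        fs = 20.0
        t = np.arange(0, 60, 1 / fs)
        x = np.interp(t, [28, 30, 32], [0, 10, 0])
        ev = event_metrics(Trace(x, fs), int(30 * fs))
        assert ev.amplitude == pytest.approx(10.0, abs=1e-6)
        assert ev.fdhm == pytest.approx(2.0, abs=1 / fs)

    def test_gaussian_closed_form(self):
        fs = 20.0
        t = np.arange(0, 60, 1 / fs)
        x = 10 * np.exp(-((t - 30) ** 2) / 2)  # sigma = 1 s
        ev = event_metrics(Trace(x, fs), int(30 * fs))
        assert ev.fdhm == pytest.approx(2 * np.sqrt(2 * np.log(2)), abs=1 / fs)

    def test_exponential_decay_half_width(self):
        fs = 20.0
        tau = 2.0
        t = np.arange(0, 60, 1 / fs)
        x = np.where(t >= 30, 10 * np.exp(-(t - 30) / tau), 0.0)
        ev = neuro_peak_metrics(Trace(x, fs), int(30 * fs))
        assert ev.half_width_decay == pytest.approx(tau * np.log(2), abs=1 / fs)

    def test_truncated_decay_flagged(self):
        fs = 10.0
        t = np.arange(0, 30, 1 / fs)
        x = np.where(t >= 25, 10.0, 0.0)  # steps up, never comes down
        ev = event_metrics(Trace(x, fs), 255)
        assert ev.fdhm is None and "fdhm_undefined" in ev.flags

    def test_generator_kernel_matches_analytic_fdhm(self):
        """event_metrics on the noiseless kernel reproduces the analytic FDHM."""
        cfg = SyntheticCalciumConfig(
            seed=0, n_rois=1, duration_s=300, fs=10.0, event_rate_per_min=0.2,
            noise_sd=0.0, amplitude_mean=10.0,
        )
        traces, truth = gen_calcium_traces(cfg)
        tr = Trace(traces[0] - cfg.baseline, cfg.fs)
        peaks = detect_peaks(tr, threshold_z=5.0, min_sep_s=5.0)
        assert peaks, "no event in the noiseless trace"
        ev = event_metrics(tr, peaks[0])
        assert ev.fdhm == pytest.approx(truth.fdhm_s, abs=1 / cfg.fs)
        assert ev.half_width_decay == pytest.approx(
            truth.half_width_decay_s, abs=1 / cfg.fs
        )


class TestSummarize:
    def test_zero_events(self):
        s = summarize_events([], 300.0)
        assert s.n_events == 0 and s.frequency_per_min == 0.0

    def test_five_events_in_600s(self):
        evs = [event_metrics(Trace(np.interp(np.arange(100), [40, 50, 60], [0, 10, 0]), 1.0), 50)] * 5
        s = summarize_events(evs, 600.0)
        assert s.frequency_per_min == pytest.approx(0.5)

    def test_undefined_fdhm_excluded(self):
        fs = 10.0
        t = np.arange(0, 30, 1 / fs)
        good = event_metrics(Trace(10 * np.exp(-((t - 15) ** 2) / 2), fs), 150)
        bad = event_metrics(Trace(np.where(t >= 25, 10.0, 0.0), fs), 255)
        s = summarize_events([good, bad], 30.0)
        assert len(s.amplitudes) == 2 and len(s.fdhms) == 1


class TestRoisAndTraces:
    def test_three_flashing_patches_recovered(self, rng):
        T, H, W = 60, 64, 64
        movie = rng.normal(100, 1.0, size=(T, H, W))
        patches = [(10, 10), (30, 40), (50, 20)]
        truth_masks = []
        for cy, cx in patches:
            m = np.zeros((H, W), bool)
            m[cy - 3: cy + 3, cx - 3: cx + 3] = True
            truth_masks.append(m)
            movie[::7, m] += 50.0  # periodic flashes
        rois = propose_microdomain_rois(movie, AstroConfig())
        assert rois.n_rois == 3
        for tm in truth_masks:
            jacc = max(
                ((rois.labels == k) & tm).sum() / ((rois.labels == k) | tm).sum()
                for k in rois.roi_ids()
            )
            assert jacc >= 0.7

    def test_static_movie_empty(self):
        movie = np.full((20, 32, 32), 7.0)
        assert propose_microdomain_rois(movie, AstroConfig()).n_rois == 0

    def test_small_patch_excluded(self, rng):
        movie = rng.normal(100, 1.0, size=(40, 32, 32))
        movie[::5, 10, 10] += 80.0  # single flashing pixel < min_area
        rois = propose_microdomain_rois(movie, AstroConfig(roi_min_area=4, roi_smooth_sigma_px=0))
        assert rois.n_rois == 0

    def test_trace_extraction_matches_mean_oracle(self, rng):
        from deepscope.io import RoiLabelMask

        movie = rng.uniform(0, 100, size=(15, 16, 16))
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[2:5, 2:5] = 1
        labels[10, 10] = 2
        traces = extract_roi_traces(movie, RoiLabelMask(labels=labels), fs=3.0)
        np.testing.assert_allclose(traces[0].values, movie[:, 2:5, 2:5].mean(axis=(1, 2)))
        np.testing.assert_allclose(traces[1].values, movie[:, 10, 10])


class TestDffRollingQuantile:
    def test_constant_trace_zero(self):
        dff, f0 = dff_rolling_quantile(Trace(np.full(400, 100.0), 10.0), window=200)
        assert np.all(dff.values == 0.0)
        assert np.all(f0 == 100.0)

    def test_ten_percent_step(self):
        x = np.full(500, 100.0)
        x[250] = 110.0
        dff, _ = dff_rolling_quantile(Trace(x, 10.0), window=200, q=0.08)
        assert dff.values[250] == pytest.approx(0.10, abs=1e-9)

    def test_drift_recovery_within_two_percent(self):
        cfg = SyntheticCalciumConfig(
            seed=3, n_rois=1, duration_s=600, fs=10.0, event_rate_per_min=0.33,
            amplitude_mean=4.95, amplitude_sd=0.0, noise_sd=0.5, drift_frac=0.5,
        )
        traces, truth = gen_calcium_traces(cfg)
        _, f0 = dff_rolling_quantile(Trace(traces[0], 10.0), window=200, q=0.08)
        assert np.max(np.abs(f0 - truth.baseline[0]) / truth.baseline[0]) <= 0.02

    def test_global_min_mode_scalar(self):
        x = np.linspace(100, 150, 500)
        _, f0 = dff_rolling_quantile(Trace(x, 10.0), window=200, mode="global_min")
        assert np.all(f0 == f0[0])

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            dff_rolling_quantile(Trace(np.ones(10) * 5, 1.0), window=100)


class TestEventRecovery:
    def test_sensitivity_and_false_positives(self):
        """Astro-kinetics events ≥ 4 z at 0.5/min: sens ≥ 0.95, FP ≤ 0.05/min."""
        hits = n_true = fp = 0
        for seed in range(10):
            cfg = SyntheticCalciumConfig(
                seed=seed, n_rois=3, duration_s=600, fs=1.0, event_rate_per_min=0.5,
                amplitude_mean=6.0, amplitude_sd=1.0, amplitude_min=4.0,
                noise_sd=1.0, tau_rise_s=1.0, tau_decay_s=8.0,
            )
            traces, truth = gen_calcium_traces(cfg)
            for raw, tev in zip(traces, truth.events):
                z = gaussian_smooth(robust_zscore(Trace(raw, cfg.fs)), 1.0)
                events = detect_events(z, threshold_z=3.0, min_sep_s=8.0)
                det = np.array([e.peak_time for e in events])
                h = sum(
                    1 for tt in tev["times"] if det.size and np.min(np.abs(det - tt)) <= 8.0
                )
                hits += h
                n_true += len(tev["times"])
                fp += max(0, len(det) - h)
        assert hits / n_true >= 0.95
        assert fp / (10 * 3 * 10.0) <= 0.05
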