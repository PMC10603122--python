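import numpy as np
import pytest

from neurofatigue import hrv, spectral
from neurofatigue.synth import SimulationConfig, ecg_from_beats, generate_rr
from neurofatigue.types import Recording, RrSeries


@pytest.fixture(scope="module")
def clean_ecg():
    beats = np.arange(0.5, 119.5, 1.0)
    return beats, ecg_from_beats(beats, 120.0, 512.0)


class TestPanTompkins:
    def test_clean_detection_within_10ms(self, clean_ecg):
        beats, rec = clean_ecg
        detected = hrv.pan_tompkins(rec)
        assert detected.n_beats == len(beats)
        err = np.abs(detected.beat_times[:, None] - beats[None, :]).min(axis=1)
        assert err.max() <= 0.010
        # 100% sensitivity, zero false positives
        matched = np.abs(beats[:, None] - detected.beat_times[None, :]).min(axis=1)
        assert np.all(matched <= 0.010)

    def test_noisy_sensitivity(self, clean_ecg):
        beats, rec = clean_ecg
        sig_power = float((rec.data[0] ** 2).mean())
        noise_sd = np.sqrt(sig_power / 10.0)  # SNR 10 dB
        sens = []
        for seed in range(20):
            noisy = ecg_from_beats(
                beats, 120.0, 512.0, noise_sd_mv=noise_sd,
                rng=np.random.default_rng(seed),
            )
            det = hrv.pan_tompkins(noisy)
            d = np.abs(beats[:, None] - det.beat_times[None, :]).min(axis=1)
            sens.append(np.mean(d <= 0.050))
        assert np.mean(sens) >= 0.95

    def test_flat_line_rejected(self, fs):
        rec = Recording(np.zeros((1, int(60 * fs))), fs, ("ECG",), units="mV")
        with pytest.raises(ValueError):
            hrv.pan_tompkins(rec)

    def test_too_short_rejected(self, fs):
        rec = Recording(np.zeros((1, int(5 * fs))), fs, ("ECG",), units="mV")
        with pytest.raises(ValueError, match="10 s"):
            hrv.pan_tompkins(rec)

    def test_hr_matches_ground_truth_within_1pct(self):
        cfg = SimulationConfig(lecture_duration=600.0, hr_baseline=72.0, seed=2)
        from neurofatigue.synth import generate_rr_and_ecg

        rec, truth = generate_rr_and_ecg(cfg, 0)
        detected = hrv.clean_rr(hrv.pan_tompkins(rec))
        truth_series = RrSeries(truth.r_peak_times, provenance="ground_truth")
        hr_det = hrv.windowed_hrv(detected)["HR"].to_numpy()
        hr_true = hrv.windowed_hrv(truth_series)["HR"].to_numpy()
        assert np.all(np.abs(hr_det - hr_true) / hr_true < 0.01)


class TestCleanRr:
    def test_ectopic_interval_removed(self):
        times = [0.0, 1.0, 2.0, 2.1, 3.1, 4.1]  # 100 ms interval at index 2
        cleaned = hrv.clean_rr(RrSeries(np.array(times)))
        assert np.all(cleaned.rr_ms >= 200.0)

    def test_clean_series_untouched(self):
        times = np.arange(0.0, 30.0, 1.0)
        cleaned = hrv.clean_rr(RrSeries(times))
        assert np.array_equal(cleaned.beat_times, times)


class TestResampleRr:
    def test_constant_rr(self):
        rr = RrSeries(np.arange(0.0, 30.0, 1.0))
        grid, vals = hrv.resample_rr(rr)
        assert np.allclose(vals, 1000.0)
        assert np.allclose(np.diff(grid), 0.25)

    def test_linear_ramp_reproduced(self):
        # cubic interpolation reproduces polynomials up to degree 3
        times = [0.0]
        rr = 800.0
        for _ in range(60):
            times.append(times[-1] + rr / 1000.0)
            rr += 2.0
        series = RrSeries(np.array(times))
        grid, vals = hrv.resample_rr(series)
        from scipy.interpolate import CubicSpline

        expected = CubicSpline(series.rr_times, series.rr_ms)(grid)
        coeffs = np.polyfit(grid, vals, 1)
        assert abs(coeffs[0] - 2.0 / np.mean(np.diff(times))) / coeffs[0] < 0.05
        assert np.abs(vals - expected).max() < 1e-6

    def test_modulation_peak_recovered(self):
        times = [0.0]
        while times[-1] < 300.0:
            t = times[-1]
            rr_ms = 1000.0 + 100.0 * np.sin(2 * np.pi * 0.1 * t)
            times.append(t + rr_ms / 1000.0)
        grid, vals = hrv.resample_rr(RrSeries(np.array(times)))
        freqs, psd = spectral.welch_psd(vals - vals.mean(), 4.0)
        assert abs(freqs[np.argmax(psd)] - 0.1) < 0.02

    def test_too_few_beats_rejected(self):
        with pytest.raises(ValueError, match="3 beats"):
            hrv.resample_rr(RrSeries(np.array([0.0, 1.0])))


class TestTimeDomainIndices:
    def test_constant_rr(self):
        out = hrv.time_domain_indices(np.full(10, 1000.0))
        assert out["HR"] == 60.0
        assert out["RMSSD"] == 0.0
        assert out["pNN50"] == 0.0
        assert out["SDRR"] == 0.0

    def test_rmssd_hand_example(self):
        out = hrv.time_domain_indices(np.array([800.0, 850.0, 800.0]))
        assert np.isclose(out["RMSSD"], 50.0)

    def test_pnn50_brute_force_oracle(self):
        rr = np.array([800.0, 860.0, 870.0, 940.0])
        # successive differences: 60, 10, 70 -> NN50 = 2
        out = hrv.time_domain_indices(rr, count_all_intervals=True)
        assert np.isclose(out["pNN50"], 100.0 * 2 / 4)
        out_conv = hrv.time_domain_indices(rr, count_all_intervals=False)
        assert np.isclose(out_conv["pNN50"], 100.0 * 2 / 3)

    def test_brute_force_on_random_windows(self, rng):
        for _ in range(20):
            rr = rng.uniform(600, 1200, rng.integers(3, 40))
            out = hrv.time_domain_indices(rr)
            d = rr[1:] - rr[:-1]
            assert np.isclose(out["HR"], 60000.0 / rr.mean())
            assert np.isclose(out["RMSSD"], np.sqrt((d**2).mean()))
            assert np.isclose(out["pNN50"], 100.0 * np.sum(np.abs(d) > 50) / len(rr))
            assert np.isclose(out["SDRR"], rr.std(ddof=1))

    def test_single_interval(self):
        out = hrv.time_domain_indices(np.array([900.0]))
        assert np.isclose(out["HR"], 60000.0 / 900.0)
        assert np.isnan(out["RMSSD"]) and np.isnan(out["pNN50"])

    def test_shift_invariance(self, rng):
        rr = rng.uniform(700, 1100, 30)
        a = hrv.time_domain_indices(rr)
        b = hrv.time_domain_indices(rr + 100.0)
        assert np.isclose(a["RMSSD"], b["RMSSD"])
        assert np.isclose(a["SDRR"], b["SDRR"])
        assert not np.isclose(a["HR"], b["HR"])

    def test_pnn50_time_reversal_invariance(self, rng):
        rr = rng.uniform(700, 1100, 30)
        assert np.isclose(
            hrv.time_domain_indices(rr)["pNN50"],
            hrv.time_domain_indices(rr[::-1])["pNN50"],
        )


class TestFreqDomainIndices:
    def _band_series(self, lo, hi, n=720, rate=4.0, seed=0):
        rng = np.random.default_rng(seed)
        freqs = np.fft.rfftfreq(n, 1 / rate)
        spec = np.zeros(len(freqs), dtype=complex)
        mask = (freqs >= lo) & (freqs < hi)
        spec[mask] = np.exp(1j * rng.uniform(0, 2 * np.pi, mask.sum()))
        x = np.fft.irfft(spec, n=n)
        return 30.0 * x / x.std()

    def test_all_lf_power(self):
        # keep the content away from the band edges so Welch leakage does
        # not smear power outside 0.04-0.15
        out = hrv.freq_domain_indices(self._band_series(0.055, 0.135))
        assert out["LF_nu"] > 0.95 - 0.05
        assert out["HF_nu"] < 0.05

    def test_equal_bands_near_zero_log_ratio(self):
        vals = []
        for seed in range(50):
            x = self._band_series(0.04, 0.15, seed=seed) + self._band_series(
                0.15, 0.4, seed=seed + 1000
            )
            vals.append(hrv.freq_domain_indices(x)["ln_lf_hf"])
        assert abs(np.mean(vals)) < 0.2

    def test_nu_sum_bounded(self, rng):
        for seed in range(5):
            x = 50.0 * np.random.default_rng(seed).standard_normal(800)
            out = hrv.freq_domain_indices(x)
            assert out["LF_nu"] + out["HF_nu"] <= 1.0 + 1e-9
            assert 0 <= out["LF_nu"] <= 1 and 0 <= out["HF_nu"] <= 1

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="uniform series"):
            hrv.freq_domain_indices(np.zeros(100))


class TestWindowedHrv:
    def test_48min_record_gives_16_windows(self):
        rr = RrSeries(np.arange(0.0, 48 * 60 + 1, 0.9))
        table = hrv.windowed_hrv(rr)
        assert len(table) == 16

    def test_low_beat_window_flagged(self):
        with pytest.raises(ValueError):
            hrv.windowed_hrv(RrSeries(np.array([0.0, 1.0])))
        # ~20 beats per 3-min window -> unreliable
        table = hrv.windowed_hrv(RrSeries(np.arange(0.0, 400.0, 9.0)))
        assert not table["reliable"].any()

    def test_stationary_type_one_error(self):
        sig = 0
        reps = 100
        for seed in range(reps):
            cfg = SimulationConfig(lecture_duration=1440.0, rr_jitter_sd=20.0, seed=seed)
            series, _ = generate_rr(cfg, 0)
            table = hrv.windowed_hrv(series)
            feat = hrv.hrv_feature_series(table, "HR")
            sig += spectral.linear_trend(feat, "window_index").p_value < 0.05
        rate = sig / reps
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)

    def test_indices_within_type_invariants(self):
        cfg = SimulationConfig(
            lecture_duration=720.0, rr_modulation_sd=25.0, rr_jitter_sd=15.0, seed=0
        )
        series, _ = generate_rr(cfg, 0)
        table = hrv.windowed_hrv(series)
        assert (table["HR"] > 0).all()
        assert (table["RMSSD"] >= 0).all() and (table["SDRR"] >= 0).all()
        assert table["pNN50"].between(0, 100).all()
        assert table["LF_nu"].between(0, 1).all()
        assert table["HF_nu"].between(0, 1).all()
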