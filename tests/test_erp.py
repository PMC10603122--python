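import numpy as np
import pandas as pd
import pytest

from neurofatigue import erp
from neurofatigue._stats import bh_adjust
from neurofatigue.synth import generate_oddball_sequence
from neurofatigue.types import EpochSet, ErpWaveform, EventStream, Recording


@pytest.fixture
def flat_recording(fs):
    return Recording(np.zeros((5, int(600 * fs))), fs, ("Fz", "Cz", "Pz", "O1", "O2"))


def _epochs_from_array(data, fs=512.0):
    data = np.asarray(data, dtype=float)
    n_times = data.shape[2]
    times = np.arange(n_times) / fs - 0.2
    return EpochSet(
        data=data,
        times=times,
        channels=tuple(f"ch{i}" for i in range(data.shape[1])),
        labels=np.array(["target"] * data.shape[0], dtype=object),
    )


class TestEpoch:
    def test_fifty_targets_give_fifty_trials(self, flat_recording):
        events = generate_oddball_sequence(500, 0.10, seed=0)
        eps = erp.epoch(flat_recording, events)
        assert eps.n_trials == 50

    def test_boundary_event_dropped(self, fs):
        rec = Recording(np.zeros((1, int(5 * fs))), fs, ("Cz",))
        events = EventStream([0.0, 2.0], ["target", "target"], [0.5, 0.5])
        eps = erp.epoch(rec, events)
        assert eps.n_trials == 1  # t=0 cannot supply the 0.2 s pre-window

    def test_all_events_out_of_span_rejected(self, fs):
        rec = Recording(np.zeros((1, int(1 * fs))), fs, ("Cz",))
        events = EventStream([0.9], ["target"], [0.5])
        with pytest.raises(ValueError, match="no events"):
            erp.epoch(rec, events)

    def test_baseline_correction_removes_offset(self, fs):
        rec = Recording(np.full((1, int(5 * fs)), 7.0), fs, ("Cz",))
        events = EventStream([2.0], ["target"], [0.5])
        eps = erp.epoch(rec, events)
        assert np.abs(eps.data).max() < 1e-12


class TestRejectAmplitude:
    def test_excursion_trial_dropped(self):
        data = np.zeros((3, 2, 100))
        data[1, 0, 50] = 150.0
        eps = erp.reject_amplitude(_epochs_from_array(data), 100.0)
        assert eps.n_retained == 2
        assert not eps.retained[1]

    def test_all_zero_trials_retained(self):
        eps = erp.reject_amplitude(_epochs_from_array(np.zeros((4, 2, 50))))
        assert eps.n_retained == 4

    def test_threshold_sweep_monotone(self, rng):
        data = 40.0 * rng.standard_normal((30, 2, 64))
        eps = _epochs_from_array(data)
        counts = [
            erp.reject_amplitude(eps, thr).n_retained
            for thr in [200.0, 150.0, 100.0, 75.0, 50.0, 25.0]
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_idempotent_and_order_independent(self, rng):
        data = 60.0 * rng.standard_normal((20, 2, 64))
        eps = _epochs_from_array(data)
        once = erp.reject_amplitude(eps, 100.0)
        twice = erp.reject_amplitude(once, 100.0)
        assert np.array_equal(once.retained, twice.retained)
        a = erp.reject_amplitude(erp.reject_amplitude(eps, 120.0), 80.0)
        b = erp.reject_amplitude(erp.reject_amplitude(eps, 80.0), 120.0)
        assert np.array_equal(a.retained, b.retained)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            erp.reject_amplitude(_epochs_from_array(np.zeros((1, 1, 8))), 0.0)


class TestGrandAverage:
    def test_identical_trials(self, rng):
        wave = rng.standard_normal((1, 2, 64))
        data = np.repeat(wave, 5, axis=0)
        ga = erp.grand_average([_epochs_from_array(data)])
        assert np.allclose(ga["ch0"].amplitude, wave[0, 0])

    def test_independent_of_trial_count(self, rng):
        wave = rng.standard_normal((1, 1, 32))
        ga3 = erp.grand_average([_epochs_from_array(np.repeat(wave, 3, axis=0))])
        ga9 = erp.grand_average([_epochs_from_array(np.repeat(wave, 9, axis=0))])
        assert np.allclose(ga3["ch0"].amplitude, ga9["ch0"].amplitude)

    def test_opposite_subjects_cancel(self, rng):
        w = rng.standard_normal((1, 1, 32))
        ga = erp.grand_average([_epochs_from_array(w), _epochs_from_array(-w)])
        assert np.allclose(ga["ch0"].amplitude, 0.0)

    def test_subject_without_trials_excluded(self, rng):
        good = _epochs_from_array(rng.standard_normal((4, 1, 32)))
        bad = _epochs_from_array(rng.standard_normal((4, 1, 32)))
        bad.retained[:] = False
        ga = erp.grand_average([good, bad])
        assert ga["ch0"].n_trials_averaged == 1


class TestOnsetLatency:
    def _waveform(self, amp, fs=512.0):
        t = np.arange(-0.2, 0.8, 1 / fs)
        return ErpWaveform("Cz", t, amp(t), 1)

    def test_half_sine_onset(self):
        wv = self._waveform(
            lambda t: np.where((t >= 0.25) & (t <= 0.45), np.sin(np.pi * (t - 0.25) / 0.2), 0.0)
        )
        onset = erp.onset_latency(wv, (0.2, 0.5))
        assert abs(onset - 0.25) <= 1 / 512.0 + 1e-9

    def test_all_zero_missing(self):
        wv = self._waveform(lambda t: np.zeros_like(t))
        assert np.isnan(erp.onset_latency(wv, (0.2, 0.5)))

    def test_window_outside_waveform_rejected(self):
        wv = self._waveform(lambda t: np.zeros_like(t))
        with pytest.raises(ValueError, match="cover"):
            erp.onset_latency(wv, (0.5, 1.5))

    def test_noisy_onset_estimate(self):
        rng = np.random.default_rng(0)
        fs = 512.0
        estimates = []
        for _ in range(100):
            t = np.arange(-0.2, 0.8, 1 / fs)
            amp = np.where(
                (t >= 0.30) & (t <= 0.60), 6.0 * np.sin(np.pi * (t - 0.30) / 0.3), 0.0
            )
            amp = amp + 0.3 * rng.standard_normal(len(t))
            estimates.append(erp.onset_latency(ErpWaveform("Cz", t, amp, 1), (0.25, 0.5)))
        assert abs(np.nanmedian(estimates) - 0.30) <= 0.020


class TestPhaseLme:
    def test_null_no_effects(self, rng):
        before = rng.standard_normal((8, 6))
        eff = erp.fit_phase_lme(before, before.copy(), np.arange(6) * 0.01)
        assert np.allclose(eff.table["estimate"], 0.0, atol=1e-10)
        assert not eff.significant().any()

    def test_constructed_shift(self, rng):
        before = rng.standard_normal((8, 5))
        eff = erp.fit_phase_lme(before, before + 2.0, np.arange(5) * 0.01)
        assert np.allclose(eff.table["estimate"], 2.0, atol=1e-8)

    def test_ols_equivalence_zero_group_variance(self, rng):
        import statsmodels.api as sm

        # every subject mean is identical by construction (anti-symmetric
        # within-subject noise), so the REML random-intercept variance sits
        # at the zero boundary and the fit must equal the OLS oracle
        n_subj, n_t = 12, 4
        d = rng.standard_normal((n_subj, n_t))
        before = 1.0 - d
        after = 1.0 + d
        eff = erp.fit_phase_lme(before, after, np.arange(n_t) * 0.01)
        for k in range(n_t):
            y = np.concatenate([before[:, k], after[:, k]])
            phase = np.concatenate([np.zeros(n_subj), np.ones(n_subj)])
            ols = sm.OLS(y, sm.add_constant(phase)).fit()
            assert abs(eff.table["estimate"][k] - ols.params[1]) < 1e-6

    def test_paired_difference_oracle_balanced_noiseless(self, rng):
        # fixed effect equals the mean paired after-minus-before difference
        before = rng.standard_normal((10, 3))
        diffs = np.array([0.5, -1.0, 2.0])
        after = before + diffs[None, :]
        eff = erp.fit_phase_lme(before, after, np.arange(3) * 0.01)
        assert np.allclose(eff.table["estimate"], diffs, atol=1e-6)


class TestItemLme:
    def test_constructed_beta_recovered(self, rng):
        n = 24
        groups = np.repeat(np.arange(n // 2), 2)
        item = np.tile([-1.0, 1.0], n // 2)
        before = rng.standard_normal((n, 4))
        beta = 1.7
        after = before + beta * item[:, None]
        eff = erp.fit_item_lme(after, before, np.arange(4) * 0.01, groups, item)
        assert np.allclose(eff.table["estimate"], beta, atol=1e-6)

    def test_constant_item_rejected(self, rng):
        n = 10
        before = rng.standard_normal((n, 2))
        with pytest.raises(ValueError, match="constant"):
            erp.fit_item_lme(
                before, before, np.arange(2) * 0.01, np.arange(n), np.ones(n)
            )

    def test_doubling_noise_halves_standardized_effect(self, rng):
        n, beta = 60, 1.0
        groups = np.arange(n)
        item = rng.standard_normal(n)
        ratios = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            before = r.standard_normal((n, 1))
            noise = r.standard_normal((n, 1))
            t = np.array([0.0])
            a1 = before + beta * item[:, None] + 1.0 * noise
            a2 = before + beta * item[:, None] + 2.0 * noise
            e1 = erp.fit_item_lme(a1, before, t, groups, item)
            e2 = erp.fit_item_lme(a2, before, t, groups, item)
            ratios.append(e2.table["std_effect"][0] / e1.table["std_effect"][0])
        assert abs(np.mean(ratios) - 0.5) < 0.10

    def test_null_fdr_control(self, rng):
        # item scores independent of amplitudes: BH-significant sample rate
        # small (scaled-down replicate count for CI speed)
        n_subj, n_ch, n_t = 12, 5, 8
        groups = np.repeat(np.arange(n_subj), n_ch)
        any_sig = 0
        reps = 60
        for seed in range(reps):
            r = np.random.default_rng(seed)
            before = r.standard_normal((n_subj * n_ch, n_t))
            after = r.standard_normal((n_subj * n_ch, n_t))
            item = np.repeat(r.standard_normal(n_subj), n_ch)
            eff = erp.fit_item_lme(after, before, np.arange(n_t) * 0.01, groups, item)
            any_sig += eff.significant().any()
        assert any_sig / reps <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)


def test_bh_significance_monotone_in_alpha(rng):
    p = rng.uniform(0, 1, 40)
    adj = bh_adjust(p)
    counts = [(adj < a).sum() for a in (0.01, 0.05, 0.10, 0.20)]
    assert all(a <= b for a, b in zip(counts, counts[1:]))
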