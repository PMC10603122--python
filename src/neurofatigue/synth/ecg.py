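"""RR-interval and ECG waveform generation.

The interbeat series is mean-heart-rate trend + band-limited LF/HF
modulation + white beat-to-beat jitter. The jitter SD can follow a
window-wise profile chosen so that a stated ground-truth trajectory of
RMSSD, SDRR or pNN50 holds:

* white jitter with SD sigma gives successive differences ~ N(0, 2 sigma^2),
  hence RMSSD = sqrt(2)*sigma and SDRR = sigma;
* pNN50 = 200 * (1 - Phi(50 / (sqrt(2)*sigma))), inverted per window.

The ECG trace is built by stamping a QRS-like template (narrow R wave plus
a low T wave) at each cumulative beat time; the exact R times are emitted
as ground truth.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from ..types import GroundTruth, Recording, RrSeries
from .config import SimulationConfig, subject_rng

_SQRT2 = np.sqrt(2.0)


def jitter_sd_profile(config: SimulationConfig, n_windows: int) -> np.ndarray:
    """Per-window white-jitter SD (ms) implementing the configured ramp."""
    profiles = {
        "rmssd_profile": config.rmssd_profile,
        "sdrr_profile": config.sdrr_profile,
        "pnn50_profile": config.pnn50_profile,
    }
    active = {k: v for k, v in profiles.items() if v is not None}
    if len(active) > 1:
        raise ValueError(
            f"conflicting variability ramps {sorted(active)}; set at most one"
        )
    w = np.arange(n_windows, dtype=float)
    if config.rmssd_profile is not None:
        start, slope = config.rmssd_profile
        target = start + slope * w
        if np.any(target < 0):
            raise ValueError("RMSSD ramp goes negative")
        return target / _SQRT2
    if config.sdrr_profile is not None:
        start, slope = config.sdrr_profile
        target = start + slope * w
        if np.any(target < 0):
            raise ValueError("SDRR ramp goes negative")
        return target
    if config.pnn50_profile is not None:
        start, slope = config.pnn50_profile
        target = start + slope * w
        if np.any((target <= 0) | (target >= 100)):
            raise ValueError("pNN50 ramp must stay inside (0, 100)")
        return 50.0 / (_SQRT2 * norm.ppf(1.0 - target / 200.0))
    return np.full(n_windows, float(config.rr_jitter_sd))


def _modulation_series(config: SimulationConfig, rng, duration: float):
    """Continuous LF (0.04-0.15 Hz) + HF (0.15-0.4 Hz) Gaussian modulation
    sampled on a dense grid; returns (grid_times, values_ms)."""
    if config.rr_modulation_sd <= 0:
        return None
    rate = 8.0  # dense enough for cubic interpolation at beat times
    n = int(round(duration * rate)) + 1
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    ratio = np.exp(config.lf_hf_log_ratio)
    total_var = config.rr_modulation_sd**2
    var = {"lf": total_var * ratio / (1 + ratio), "hf": total_var / (1 + ratio)}
    bands = {"lf": (0.04, 0.15), "hf": (0.15, 0.4)}
    x = np.zeros(n)
    for key, (lo, hi) in bands.items():
        mask = (freqs >= lo) & (freqs < hi)
        if not mask.any():
            continue
        spec = np.zeros(len(freqs), dtype=complex)
        spec[mask] = np.exp(1j * rng.uniform(0, 2 * np.pi, mask.sum()))
        comp = np.fft.irfft(spec, n=n)
        sd = comp.std()
        if sd > 0:
            x += comp / sd * np.sqrt(var[key])
    return np.arange(n) / rate, x


def generate_rr(config: SimulationConfig, subject: int) -> tuple[RrSeries, GroundTruth]:
    """Simulate one subject's ground-truth beat-time series."""
    config.validate()
    rng = subject_rng(config, subject, stream=20)
    duration = config.lecture_duration
    wlen = config.window_length
    n_windows = int(np.ceil(duration / wlen))
    sigma = jitter_sd_profile(config, n_windows)

    mod = _modulation_series(config, rng, duration)
    if mod is not None:
        from scipy.interpolate import CubicSpline

        mod_fn = CubicSpline(*mod)
    else:
        mod_fn = None

    beats = [0.0]
    t = 0.0
    while True:
        w = min(int(t // wlen), n_windows - 1)
        hr = config.hr_baseline + config.hr_slope * (t / wlen)
        rr_ms = 60000.0 / hr
        if mod_fn is not None:
            rr_ms += float(mod_fn(t))
        rr_ms += sigma[w] * rng.standard_normal()
        rr_ms = max(rr_ms, 250.0)  # physiological floor
        t += rr_ms / 1000.0
        if t > duration:
            break
        beats.append(t)
    series = RrSeries(np.array(beats), provenance="ground_truth")
    truth = GroundTruth(
        hr_baseline=config.hr_baseline,
        hr_slope=config.hr_slope,
        r_peak_times=series.beat_times.copy(),
        rr_profile={
            "jitter_sd_by_window": sigma.tolist(),
            "rmssd_profile": config.rmssd_profile,
            "sdrr_profile": config.sdrr_profile,
            "pnn50_profile": config.pnn50_profile,
            "lf_hf_log_ratio": config.lf_hf_log_ratio,
            "rr_modulation_sd": config.rr_modulation_sd,
        },
    )
    return series, truth


def ecg_from_beats(
    beat_times: np.ndarray,
    duration: float,
    sfreq: float,
    r_amp_mv: float = 1.0,
    noise_sd_mv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Recording:
    """Render a 1-lead ECG by stamping a QRS-like template at each beat.

    Morphology is deliberately minimal (Gaussian R wave, sigma 8 ms, plus a
    0.15 mV T wave at +250 ms) - just enough for a QRS detector to lock on.
    """
    n = int(round(duration * sfreq))
    x = np.zeros(n)
    half = int(round(0.35 * sfreq))
    t_rel = np.arange(-half, half + 1) / sfreq
    template = r_amp_mv * np.exp(-0.5 * (t_rel / 0.008) ** 2)
    template += 0.15 * r_amp_mv * np.exp(-0.5 * ((t_rel - 0.25) / 0.05) ** 2)
    for t0 in beat_times:
        c = int(round(t0 * sfreq))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        if lo >= hi:
            continue
        x[lo:hi] += template[lo - (c - half) : hi - (c - half)]
    if noise_sd_mv > 0:
        if rng is None:
            rng = np.random.default_rng()
        x = x + noise_sd_mv * rng.standard_normal(n)
    return Recording(x[None, :], sfreq, ("ECG",), units="mV")


def generate_rr_and_ecg(
    config: SimulationConfig, subject: int, noise_sd_mv: float = 0.0
) -> tuple[Recording, GroundTruth]:
    """Full ECG path: RR ground truth plus the rendered waveform."""
    series, truth = generate_rr(config, subject)
    rng = subject_rng(config, subject, stream=21)
    rec = ecg_from_beats(
        series.beat_times,
        config.lecture_duration,
        config.sampling_rate,
        noise_sd_mv=noise_sd_mv,
        rng=rng,
    )
    return rec, truth
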