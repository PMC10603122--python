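"""Windowed Welch band powers, normalization, frontal theta/beta ratio,
and linear trend statistics on window series.

Conventions fixed here (and relied on by the recovery tests):

* "total signal power" for normalization is the PSD integral over the
  0.5-30 Hz analysis range;
* trailing partial windows (< window_length) are discarded;
* the primary trend axis is the window mid-point in clock seconds; a
  window-index axis is also available (HRV trends use it).
"""

from __future__ import annotations

import numpy as np
from scipy import signal, stats

from .synth.config import DEFAULT_BANDS
from .types import Recording, TrendResult, WindowedFeatureSeries

TOTAL_RANGE = (0.5, 30.0)

#: Welch segmentation: eight segments with 50% overlap.
N_SEGMENTS = 8


def welch_psd(x: np.ndarray, sfreq: float) -> tuple[np.ndarray, np.ndarray]:
    """Averaged Hamming-tapered periodograms over eight half-overlapping
    segments; density scaling (rectangular integral equals variance).

    Returns (freqs, psd).
    """
    x = np.asarray(x, dtype=float)
    nperseg = (2 * len(x)) // (N_SEGMENTS + 1)
    if nperseg < 16:
        raise ValueError(
            f"segment of {len(x)} samples too short for {N_SEGMENTS} "
            "half-overlapping sub-segments"
        )
    freqs, psd = signal.welch(
        x,
        fs=sfreq,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
    )
    return freqs, psd


def band_power(freqs: np.ndarray, psd: np.ndarray, low: float, high: float) -> float:
    """PSD integral over [low, high].

    Each frequency bin represents the cell [f - df/2, f + df/2]; edge
    cells contribute their fractional overlap with the band, so narrow
    bands (e.g. the 0.11 Hz-wide cardiac LF band) are not biased by bin
    quantization, and bands sharing an edge split the edge cell without
    double counting.
    """
    df = freqs[1] - freqs[0]
    cell_lo = freqs - df / 2
    cell_hi = freqs + df / 2
    overlap = np.clip(np.minimum(cell_hi, high) - np.maximum(cell_lo, low), 0.0, df)
    return float((psd * overlap).sum())


def normalized_band_powers(
    recording: Recording,
    bands: dict | None = None,
    window_length: float = 180.0,
    total_range: tuple = TOTAL_RANGE,
) -> dict:
    """Per-channel, per-band normalized power in non-overlapping windows.

    Returns ``{channel: {band: WindowedFeatureSeries}}``; values are the
    band integral divided by the total-range integral, hence in [0, 1].
    Windows containing non-finite samples yield NaN (excluded from trends).
    """
    bands = bands or DEFAULT_BANDS
    sfreq = recording.sfreq
    win = int(round(window_length * sfreq))
    n_windows = recording.n_samples // win
    if n_windows < 1:
        raise ValueError("recording shorter than one analysis window")
    starts = np.arange(n_windows) * window_length

    out: dict = {}
    for ch in recording.channels:
        x = recording.get_channel(ch)
        values = {band: np.full(n_windows, np.nan) for band in bands}
        for w in range(n_windows):
            seg = x[w * win : (w + 1) * win]
            if not np.all(np.isfinite(seg)):
                continue
            freqs, psd = welch_psd(seg, sfreq)
            total = band_power(freqs, psd, *total_range)
            if total <= 0:
                continue
            for band, (lo, hi) in bands.items():
                values[band][w] = band_power(freqs, psd, lo, hi) / total
        out[ch] = {
            band: WindowedFeatureSeries(
                feature=f"power_{band}",
                channel=ch,
                window_starts=starts,
                values=values[band],
                window_length=window_length,
            )
            for band in bands
        }
    return out


def theta_beta_ratio(
    theta: WindowedFeatureSeries, beta: WindowedFeatureSeries
) -> WindowedFeatureSeries:
    """Elementwise frontal Theta / Beta; zero-Beta windows become NaN."""
    if theta.channel != beta.channel or not np.array_equal(
        theta.window_starts, beta.window_starts
    ):
        raise ValueError("theta and beta series must be aligned on the same channel")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(beta.values != 0, theta.values / beta.values, np.nan)
    return WindowedFeatureSeries(
        feature="theta_beta_ratio",
        channel=theta.channel,
        window_starts=theta.window_starts,
        values=ratio,
        window_length=theta.window_length,
    )


def linear_trend(
    series: WindowedFeatureSeries, axis_convention: str = "seconds"
) -> TrendResult:
    """OLS of the window values on time with a two-sided slope test.

    ``axis_convention`` is either ``"seconds"`` (window mid-points; EEG
    convention) or ``"window_index"`` (HRV convention).
    """
    if axis_convention == "seconds":
        x = series.window_midpoints
    elif axis_convention == "window_index":
        x = np.arange(len(series), dtype=float)
    else:
        raise ValueError("axis_convention must be 'seconds' or 'window_index'")
    mask = series.valid_mask()
    x, y = x[mask], series.values[mask]
    if len(y) < 3:
        raise ValueError(f"need >= 3 valid windows, have {len(y)}")
    if np.ptp(y) == 0:
        return TrendResult(0.0, float(y[0]), 1.0, len(y), 0.0, axis_convention)
    res = stats.linregress(x, y)
    return TrendResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        n_points=len(y),
        stderr=float(res.stderr),
        axis=axis_convention,
    )


__all__ = [
    "TOTAL_RANGE",
    "welch_psd",
    "band_power",
    "normalized_band_powers",
    "theta_beta_ratio",
    "linear_trend",
]
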