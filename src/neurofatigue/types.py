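"""Core data containers shared across the pipeline.

All containers are thin wrappers around numpy arrays / pandas frames; they
carry the metadata (sampling rate, channel labels, units, masks) that the
operations need to stay honest about alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Standard montage used throughout: five EEG sites plus one ECG lead.
EEG_CHANNELS = ("Fz", "Cz", "Pz", "O1", "O2")


@dataclass
class Recording:
    """Uniformly sampled multichannel signal.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal samples. EEG in microvolts, ECG in millivolts.
    sfreq : float
        Sampling rate in Hz.
    channels : tuple of str
        Channel labels, one per row of ``data``.
    units : str
        Unit string for all channels ("uV" or "mV").
    """

    data: np.ndarray
    sfreq: float
    channels: tuple
    units: str = "uV"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[None, :]
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.channels)} channel labels"
            )
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        self.channels = tuple(self.channels)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sfreq

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sfreq

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"no channel {name!r}; have {self.channels}") from None

    def get_channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_index(name)]

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy())


@dataclass
class EventStream:
    """Ordered stimulus markers: onset (s), label, duration (s)."""

    onsets: np.ndarray
    labels: np.ndarray
    durations: np.ndarray

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.durations = np.asarray(self.durations, dtype=float)
        if not (len(self.onsets) == len(self.labels) == len(self.durations)):
            raise ValueError("onsets, labels, durations must have equal length")
        if np.any(np.diff(self.onsets) < 0):
            raise ValueError("event onsets must be non-decreasing")

    def __len__(self) -> int:
        return len(self.onsets)

    def select(self, label: str) -> "EventStream":
        keep = self.labels == label
        return EventStream(self.onsets[keep], self.labels[keep], self.durations[keep])


@dataclass
class EpochSet:
    """Per-trial, per-channel time-locked signal with a rejection mask.

    ``data`` has shape (n_trials, n_channels, n_times); ``times`` is in
    seconds relative to stimulus onset; ``retained`` marks trials that
    survived artifact rejection.
    """

    data: np.ndarray
    times: np.ndarray
    channels: tuple
    labels: np.ndarray
    subject: object = None
    phase: str | None = None
    condition: str | None = None
    retained: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.channels = tuple(self.channels)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.retained is None:
            self.retained = np.ones(self.data.shape[0], dtype=bool)
        self.retained = np.asarray(self.retained, dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def retained_data(self) -> np.ndarray:
        return self.data[self.retained]

    def channel_index(self, name: str) -> int:
        return self.channels.index(name)


@dataclass
class ErpWaveform:
    """Averaged stimulus-locked waveform for one channel."""

    channel: str
    times: np.ndarray
    amplitude: np.ndarray
    n_trials_averaged: int

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.n_trials_averaged < 1:
            raise ValueError("waveform must average at least one trial")


@dataclass
class WindowedFeatureSeries:
    """One feature tracked over non-overlapping fixed-length windows."""

    feature: str
    channel: str
    window_starts: np.ndarray
    values: np.ndarray
    window_length: float = 180.0

    def __post_init__(self):
        self.window_starts = np.asarray(self.window_starts, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.window_starts) != len(self.values):
            raise ValueError("window_starts and values must align")
        if len(self.window_starts) > 1:
            steps = np.diff(self.window_starts)
            if np.any(steps < self.window_length - 1e-9):
                raise ValueError("windows overlap")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def window_midpoints(self) -> np.ndarray:
        return self.window_starts + self.window_length / 2.0

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class TrendResult:
    """OLS line fit of a windowed feature series against time."""

    slope: float
    intercept: float
    p_value: float
    n_points: int
    stderr: float = float("nan")
    axis: str = "seconds"


@dataclass
class RrSeries:
    """Interbeat interval series.

    ``beat_times`` are the R-peak times in seconds (strictly increasing);
    ``rr_ms`` are the intervals ending at ``beat_times[1:]``.
    """

    beat_times: np.ndarray
    provenance: str = "detected"

    def __post_init__(self):
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if len(self.beat_times) >= 2 and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if self.provenance not in ("detected", "ground_truth"):
            raise ValueError("provenance must be 'detected' or 'ground_truth'")

    @property
    def n_beats(self) -> int:
        return len(self.beat_times)

    @property
    def rr_ms(self) -> np.ndarray:
        return np.diff(self.beat_times) * 1000.0

    @property
    def rr_times(self) -> np.ndarray:
        """Time stamps of the intervals (end beat of each interval)."""
        return self.beat_times[1:]


@dataclass
class GroundTruth:
    """Generator-side truth emitted with every simulated dataset.

    Analysis modules must never read this; it exists purely so tests can
    compare recovered quantities against what was injected.
    """

    band_baseline: dict | None = None
    band_slopes: dict | None = None
    hr_baseline: float | None = None
    hr_slope: float | None = None
    r_peak_times: np.ndarray | None = None
    rr_profile: dict | None = None
    erp_template: dict | None = None
    blink_times: np.ndarray | None = None
    latent_fatigue: dict | None = None
    extras: dict = field(default_factory=dict)
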