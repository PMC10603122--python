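"""Simulation configuration with ground-truth effect knobs.

Slope-unit conventions (documented, used consistently by the recovery
tests): EEG band-power drifts are injected and recovered in *normalized
power per second*; HR and HRV drifts are injected and recovered in *units
per 3-min window*.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ..types import EEG_CHANNELS

#: Band edges used both by the generator and the spectral module.
DEFAULT_BANDS = {
    "Delta": (0.5, 3.5),
    "Theta": (4.0, 7.5),
    "Alpha": (8.0, 12.5),
    "Beta": (13.0, 30.0),
}

#: Spectral gaps between the named bands; they count toward total power
#: and act as the reservoir that absorbs injected band drifts so that the
#: in-range total stays constant.
GAP_BANDS = ((3.5, 4.0), (7.5, 8.0), (12.5, 13.0))

#: Baseline normalized power fractions (roughly 1/f-ordered); gaps get the
#: remainder (0.10 here).
DEFAULT_BAND_BASELINE = {
    "Delta": 0.35,
    "Theta": 0.20,
    "Alpha": 0.20,
    "Beta": 0.15,
}

CONDITIONS = ("videoconference", "face_to_face")


@dataclass
class ErpComponent:
    """One stimulus-locked deflection: Gaussian bump of given amplitude
    (microvolts, sign carries polarity), peak latency and width (seconds,
    width is the Gaussian sigma)."""

    amplitude_uv: float
    latency_s: float
    width_s: float

    def __post_init__(self):
        if self.latency_s < 0 or self.width_s <= 0:
            raise ValueError("latency must be >= 0 and width > 0")


def default_erp_template() -> dict:
    return {
        "N2": ErpComponent(-3.0, 0.28, 0.030),
        "P3a": ErpComponent(4.0, 0.36, 0.045),
        "P300": ErpComponent(6.0, 0.45, 0.070),
    }


@dataclass
class SimulationConfig:
    """All generator knobs plus the seed that fully determines outputs."""

    n_subjects: int = 5
    sampling_rate: float = 512.0
    lecture_duration: float = 3000.0
    condition: str = "videoconference"
    window_length: float = 180.0

    # --- continuous EEG ---------------------------------------------------
    band_baseline: dict = field(default_factory=lambda: dict(DEFAULT_BAND_BASELINE))
    #: channel -> band -> normalized-power slope per second
    band_drift: dict = field(default_factory=dict)
    #: optional band -> [Hz, ...] override: use exactly these line
    #: frequencies (deterministic) instead of the jittered comb
    band_line_freqs: dict = field(default_factory=dict)
    total_power_uv2: float = 100.0
    blink_rate: float = 10.0  # events / min
    blink_amp: float = 120.0  # uV at Fz
    line_noise_amp: float = 5.0  # uV, 50 Hz

    # --- ERP --------------------------------------------------------------
    erp_template: dict = field(default_factory=default_erp_template)
    standard_scale: float = 0.3  # standards get this fraction of target amplitude
    erp_after_scale: float = 1.0  # post-lecture template amplitude ratio
    isi: float = 1.0  # onset-to-onset interval, s
    stimulus_duration: float = 0.5

    # --- ECG / RR ---------------------------------------------------------
    hr_baseline: float = 75.0  # bpm
    hr_slope: float = 0.0  # bpm per 3-min window
    rr_jitter_sd: float = 25.0  # ms, white beat-to-beat jitter
    lf_hf_log_ratio: float = 0.0  # target ln[LF/HF] of the modulation
    rr_modulation_sd: float = 0.0  # ms, total SD of the LF+HF modulation
    #: optional (start, slope-per-window) ramps; when set they override
    #: rr_jitter_sd with a window-wise jitter profile producing the stated
    #: ground-truth index trajectory.
    rmssd_profile: tuple | None = None
    sdrr_profile: tuple | None = None
    pnn50_profile: tuple | None = None

    # --- questionnaires ---------------------------------------------------
    latent_fatigue_effect: float = 0.0  # standardized latent shift (videoconference)

    seed: int = 0

    def __post_init__(self):
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.lecture_duration <= 0:
            raise ValueError("lecture_duration must be > 0")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        for name, amp in (
            ("blink_amp", self.blink_amp),
            ("line_noise_amp", self.line_noise_amp),
            ("rr_jitter_sd", self.rr_jitter_sd),
            ("rr_modulation_sd", self.rr_modulation_sd),
        ):
            if amp < 0:
                raise ValueError(f"{name} must be >= 0")
        self._validate_band_profile()
        self._validate_hr_profile()

    def _validate_band_profile(self) -> None:
        t_end = self.lecture_duration
        for channel in EEG_CHANNELS:
            for t in (0.0, t_end):
                total = 0.0
                for band, base in self.band_baseline.items():
                    frac = base + self.drift_for(channel, band) * t
                    if not 0.0 <= frac <= 1.0:
                        raise ValueError(
                            f"normalized {band} power on {channel} leaves [0, 1] "
                            f"at t={t:g}s (value {frac:g})"
                        )
                    total += frac
                if total > 1.0 + 1e-12:
                    raise ValueError(
                        f"band powers on {channel} sum to {total:g} > 1 at t={t:g}s"
                    )

    def _validate_hr_profile(self) -> None:
        n_windows = self.lecture_duration / self.window_length
        for w in (0.0, n_windows):
            hr = self.hr_baseline + self.hr_slope * w
            if not 30.0 <= hr <= 200.0:
                raise ValueError(
                    f"heart rate {hr:g} bpm at window {w:g} is unphysiological"
                )

    # ------------------------------------------------------------------
    def drift_for(self, channel: str, band: str) -> float:
        """Injected normalized-power slope (per second) for channel/band."""
        return float(self.band_drift.get(channel, {}).get(band, 0.0))

    @property
    def n_windows(self) -> int:
        return int(self.lecture_duration // self.window_length)

    # --- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["erp_template"] = {
            k: [v.amplitude_uv, v.latency_s, v.width_s]
            for k, v in self.erp_template.items()
        }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        tmpl = d.get("erp_template")
        if tmpl is not None:
            d["erp_template"] = {
                k: ErpComponent(*v) if not isinstance(v, ErpComponent) else v
                for k, v in tmpl.items()
            }
        for key in ("rmssd_profile", "sdrr_profile", "pnn50_profile"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def subject_rng(config: SimulationConfig, subject: int, stream: int) -> np.random.Generator:
    """Deterministic per-subject, per-stream random generator.

    ``stream`` namespaces independent generator parts (EEG, RR, blinks,
    questionnaires) so adding one does not perturb the others.
    """
    cond_code = CONDITIONS.index(config.condition)
    return np.random.default_rng([config.seed, int(subject), cond_code, stream])
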