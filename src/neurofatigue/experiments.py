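"""Self-contained recovery experiments: inject a known effect, run the
analysis path, and report the recovered quantity with its Monte-Carlo
spread. Used by the acceptance report and the recovery tests.

Reference injected values (videoconference-condition trend slopes, in the
module's documented unit conventions):

* frontal Theta normalized power: 2.7240e-06 per second
* mean HR: -0.1482 bpm per 3-min window
* pNN50: 0.3572 percentage points per 3-min window
* RMSSD: 0.4955 ms per 3-min window
* SDRR: 1.3040 ms per 3-min window
"""

from __future__ import annotations

import numpy as np

from . import hrv, spectral
from .synth import SimulationConfig, generate_continuous_eeg, generate_oddball_sequence, generate_rr

REFERENCE_SLOPES = {
    "fz_theta_per_s": 2.7240e-06,
    "hr_bpm_per_window": -0.1482,
    "pnn50_pct_per_window": 0.3572,
    "rmssd_ms_per_window": 0.4955,
    "sdrr_ms_per_window": 1.3040,
}


def _summary(values: list[float]) -> dict:
    v = np.asarray(values, dtype=float)
    return {
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)),
        "sd_of_mean": float(v.std(ddof=1) / np.sqrt(len(v))),
        "n_seeds": len(v),
        "values": v.tolist(),
    }


def oddball_target_count(n_events: int = 500, p_target: float = 0.10, seed: int = 0) -> int:
    """Count target-labelled events in one generated oddball sequence."""
    events = generate_oddball_sequence(n_events, p_target, seed)
    return int(np.sum(events.labels == "target"))


def recover_theta_slope(
    injected: float = REFERENCE_SLOPES["fz_theta_per_s"],
    n_seeds: int = 50,
    seed: int = 1,
    duration: float = 3000.0,
) -> dict:
    """Inject a frontal Theta normalized-power drift (per second), compute
    3-min-window normalized Theta power at Fz and its trend on the
    clock-seconds axis; clean generator path (no artifacts)."""
    slopes = []
    for k in range(n_seeds):
        config = SimulationConfig(
            lecture_duration=duration,
            band_drift={"Fz": {"Theta": injected}},
            blink_rate=0.0,
            line_noise_amp=0.0,
            seed=seed + k,
        )
        rec, _ = generate_continuous_eeg(config, subject=0, channels=("Fz",))
        powers = spectral.normalized_band_powers(rec)
        trend = spectral.linear_trend(powers["Fz"]["Theta"], axis_convention="seconds")
        slopes.append(trend.slope)
    out = _summary(slopes)
    out["injected"] = injected
    return out


def _hrv_trend_run(config: SimulationConfig, metric: str) -> float:
    series, _ = generate_rr(config, subject=0)
    table = hrv.windowed_hrv(series, window_length=config.window_length)
    feat = hrv.hrv_feature_series(table, metric, config.window_length)
    return spectral.linear_trend(feat, axis_convention="window_index").slope


def recover_hr_slope(
    injected: float = REFERENCE_SLOPES["hr_bpm_per_window"],
    n_seeds: int = 50,
    seed: int = 1,
    duration: float = 3000.0,
    hr_baseline: float = 75.0,
) -> dict:
    """Inject a linear mean-HR trend (bpm per window) into the ground-truth
    RR path and recover it from windowed HR."""
    slopes = []
    for k in range(n_seeds):
        config = SimulationConfig(
            lecture_duration=duration,
            hr_baseline=hr_baseline,
            hr_slope=injected,
            rr_jitter_sd=25.0,
            seed=seed + k,
        )
        slopes.append(_hrv_trend_run(config, "HR"))
    out = _summary(slopes)
    out["injected"] = injected
    return out


def recover_variability_slope(
    metric: str,
    injected: float,
    start: float,
    n_seeds: int = 50,
    seed: int = 1,
    duration: float = 3000.0,
) -> dict:
    """Inject a per-window ramp of RMSSD, SDRR or pNN50 via the calibrated
    jitter profile and recover the windowed-index trend (per window)."""
    profile_field = {"RMSSD": "rmssd_profile", "SDRR": "sdrr_profile", "pNN50": "pnn50_profile"}
    if metric not in profile_field:
        raise ValueError(f"metric must be one of {sorted(profile_field)}")
    slopes = []
    for k in range(n_seeds):
        kwargs = {profile_field[metric]: (start, injected)}
        config = SimulationConfig(
            lecture_duration=duration,
            hr_slope=0.0,
            seed=seed + k,
            **kwargs,
        )
        slopes.append(_hrv_trend_run(config, metric))
    out = _summary(slopes)
    out["injected"] = injected
    return out


def recover_rmssd_slope(n_seeds: int = 50, seed: int = 1, **kw) -> dict:
    return recover_variability_slope(
        "RMSSD", REFERENCE_SLOPES["rmssd_ms_per_window"], start=30.0,
        n_seeds=n_seeds, seed=seed, **kw,
    )


def recover_sdrr_slope(n_seeds: int = 50, seed: int = 1, **kw) -> dict:
    return recover_variability_slope(
        "SDRR", REFERENCE_SLOPES["sdrr_ms_per_window"], start=40.0,
        n_seeds=n_seeds, seed=seed, **kw,
    )


def recover_pnn50_slope(n_seeds: int = 50, seed: int = 1, **kw) -> dict:
    return recover_variability_slope(
        "pNN50", REFERENCE_SLOPES["pnn50_pct_per_window"], start=10.0,
        n_seeds=n_seeds, seed=seed, **kw,
    )


__all__ = [
    "REFERENCE_SLOPES",
    "oddball_target_count",
    "recover_theta_slope",
    "recover_hr_slope",
    "recover_variability_slope",
    "recover_rmssd_slope",
    "recover_sdrr_slope",
    "recover_pnn50_slope",
]
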