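"""Stage orchestration: simulate -> preprocess -> features -> erp -> hrv ->
scores -> link -> report, with a manifest for deterministic replay.

Each stage reads only artifacts written by earlier stages, fails with an
actionable message naming the missing stage, and appends a manifest entry
(config hash, seed, outputs, timestamp). Per-subject failures are
isolated: one corrupt recording does not abort the stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import erp as erp_mod
from . import hrv as hrv_mod
from . import io, linkstats, preprocess, questionnaires, spectral
from ._stats import zscore_items
from .synth import (
    SimulationConfig,
    embed_erp,
    generate_continuous_eeg,
    generate_oddball_sequence,
    generate_questionnaires,
    generate_rr_and_ecg,
)
from .synth.config import CONDITIONS
from .synth.questionnaire import BMIS_ITEMS, ZEF_ITEMS
from .types import EEG_CHANNELS

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "features", "erp", "hrv", "scores", "link", "report")


@dataclass
class PipelineConfig:
    """One simulation config per condition plus oddball/run settings."""

    videoconference: SimulationConfig
    face_to_face: SimulationConfig
    n_oddball_events: int = 100
    p_target: float = 0.1
    lme_decimate: int = 8  # time-resolved models run on every k-th sample

    def condition(self, name: str) -> SimulationConfig:
        return {"videoconference": self.videoconference, "face_to_face": self.face_to_face}[name]

    def to_dict(self) -> dict:
        return {
            "videoconference": self.videoconference.to_dict(),
            "face_to_face": self.face_to_face.to_dict(),
            "n_oddball_events": self.n_oddball_events,
            "p_target": self.p_target,
            "lme_decimate": self.lme_decimate,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            videoconference=SimulationConfig.from_dict(d["videoconference"]),
            face_to_face=SimulationConfig.from_dict(d["face_to_face"]),
            n_oddball_events=d.get("n_oddball_events", 100),
            p_target=d.get("p_target", 0.1),
            lme_decimate=d.get("lme_decimate", 8),
        )

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# fixtures

FIXTURE_PROFILES = ("null", "fatigue_injected", "erp_only", "hrv_only")


def make_fixture(profile: str, seed: int = 0) -> PipelineConfig:
    """Small deterministic dataset configuration for CI-scale runs."""
    if profile not in FIXTURE_PROFILES:
        raise ValueError(f"unknown profile {profile!r}; available: {FIXTURE_PROFILES}")
    base = dict(
        n_subjects=3,
        lecture_duration=600.0,
        blink_rate=4.0,
        line_noise_amp=5.0,
        rr_jitter_sd=25.0,
        seed=seed,
    )
    f2f = SimulationConfig(condition="face_to_face", **base)
    if profile == "null":
        vc = SimulationConfig(condition="videoconference", **base)
    elif profile == "fatigue_injected":
        vc = SimulationConfig(
            condition="videoconference",
            band_drift={"Fz": {"Theta": 5e-5}},
            hr_slope=-0.5,
            latent_fatigue_effect=1.0,
            erp_after_scale=0.7,
            **base,
        )
    elif profile == "erp_only":
        vc = SimulationConfig(condition="videoconference", erp_after_scale=0.6, **base)
    else:  # hrv_only
        vc = SimulationConfig(condition="videoconference", hr_slope=-0.5, **base)
    return PipelineConfig(videoconference=vc, face_to_face=f2f, n_oddball_events=60)


# ---------------------------------------------------------------------------
# manifest


def _append_manifest(outdir: Path, config: PipelineConfig, stage: str, outputs: list, extra=None):
    path = outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {
        "config_hash": config.config_hash(),
        "seed": config.videoconference.seed,
        "stages": [],
    }
    entry = {
        "stage": stage,
        "outputs": [str(o) for o in outputs],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra:
        entry.update(extra)
    manifest["stages"].append(entry)
    path.write_text(json.dumps(manifest, indent=2))


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the '{produced_by}' stage first"
        )
    return path


def _subject_dirs(outdir: Path, condition: str, n_subjects: int):
    for s in range(n_subjects):
        yield s, outdir / condition / f"sub-{s:02d}"


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig, outdir: Path) -> list:
    outputs = []
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_json(outdir / "config.json")
    for cond in CONDITIONS:
        sim = config.condition(cond)
        for s, sdir in _subject_dirs(outdir, cond, sim.n_subjects):
            sdir.mkdir(parents=True, exist_ok=True)
            eeg, eeg_truth = generate_continuous_eeg(sim, s)
            io.save_recording(eeg, sdir / "eeg.csv")
            ecg, ecg_truth = generate_rr_and_ecg(sim, s)
            io.save_recording(ecg, sdir / "ecg.csv")
            for phase in ("before", "after"):
                # deterministic event seed (never the builtin hash: salted)
                ev_seed = (
                    sim.seed * 100000 + s * 100
                    + (1 if phase == "after" else 0)
                    + (50 if cond == "videoconference" else 0)
                )
                events = generate_oddball_sequence(
                    config.n_oddball_events,
                    config.p_target,
                    seed=ev_seed,
                    isi=sim.isi,
                    stimulus_duration=sim.stimulus_duration,
                )
                odd_cfg = dataclasses.replace(
                    sim,
                    lecture_duration=float(events.onsets[-1] + 2.0),
                    band_drift={},
                )
                bg, _ = generate_continuous_eeg(odd_cfg, s + 1000 * (phase == "after"))
                scale = sim.erp_after_scale if phase == "after" else 1.0
                template = {
                    name: dataclasses.replace(c, amplitude_uv=c.amplitude_uv * scale)
                    for name, c in sim.erp_template.items()
                }
                rec = embed_erp(bg, events, template, sim.standard_scale)
                io.save_recording(rec, sdir / f"oddball_{phase}_eeg.csv")
                io.save_events(events, sdir / f"oddball_{phase}_events.tsv")
            io.save_json(
                {"eeg": dataclasses.asdict(eeg_truth), "ecg": dataclasses.asdict(ecg_truth)},
                sdir / "truth.json",
            )
            outputs.append(sdir)
    bmis_vc, zef_vc, truth = generate_questionnaires(config.videoconference)
    # conditions share subjects: the generator already emits both conditions
    bmis_vc.to_csv(outdir / "bmis.csv", index=False)
    zef_vc.to_csv(outdir / "zef.csv", index=False)
    io.save_json(dataclasses.asdict(truth), outdir / "questionnaire_truth.json")
    outputs += [outdir / "bmis.csv", outdir / "zef.csv"]
    _append_manifest(outdir, config, "simulate", outputs)
    return outputs


def stage_preprocess(config: PipelineConfig, outdir: Path) -> list:
    outputs, failed = [], []
    for cond in CONDITIONS:
        sim = config.condition(cond)
        for s, sdir in _subject_dirs(outdir, cond, sim.n_subjects):
            try:
                rec = io.read_recording(_require(sdir / "eeg.csv", "simulate"))
                clean, report = preprocess.preprocess_continuous(rec)
                io.save_recording(clean, sdir / "eeg_clean.csv")
                io.save_json(dataclasses.asdict(report), sdir / "wica_report.json")
                outputs.append(sdir / "eeg_clean.csv")
            except FileNotFoundError:
                raise
            except Exception as exc:  # noqa: BLE001 - per-subject isolation
                logger.error("preprocess failed for %s/%s: %s", cond, s, exc)
                failed.append(f"{cond}/sub-{s:02d}")
    if not outputs:
        raise RuntimeError("preprocess failed for every subject")
    _append_manifest(outdir, config, "preprocess", outputs, {"failed": failed})
    return outputs


def stage_features(config: PipelineConfig, outdir: Path) -> list:
    rows = []
    for cond in CONDITIONS:
        sim = config.condition(cond)
        for s, sdir in _subject_dirs(outdir, cond, sim.n_subjects):
            clean_path = sdir / "eeg_clean.csv"
            if not clean_path.exists():
                _require(clean_path, "preprocess")
            rec = io.read_recording(clean_path)
            powers = spectral.normalized_band_powers(rec, window_length=sim.window_length)
            for ch, by_band in powers.items():
                for band, series in by_band.items():
                    for t0, v in zip(series.window_starts, series.values):
                        rows.append(
                            dict(subject=s, condition=cond, channel=ch, band=band,
                                 window_start_s=t0, value=v)
                        )
            ratio = spectral.theta_beta_ratio(powers["Fz"]["Theta"], powers["Fz"]["Beta"])
            for t0, v in zip(ratio.window_starts, ratio.values):
                rows.append(
                    dict(subject=s, condition=cond, channel="Fz", band="theta_beta_ratio",
                         window_start_s=t0, value=v)
                )
    table = pd.DataFrame(rows)
    out = outdir / "features_eeg.csv"
    table.to_csv(out, index=False)
    _append_manifest(config=config, outdir=outdir, stage="features", outputs=[out])
    return [out]


def stage_hrv(config: PipelineConfig, outdir: Path) -> list:
    frames, failed = [], []
    for cond in CONDITIONS:
        sim = config.condition(cond)
        for s, sdir in _subject_dirs(outdir, cond, sim.n_subjects):
            try:
                ecg = io.read_recording(_require(sdir / "ecg.csv", "simulate"))
                rr = hrv_mod.clean_rr(hrv_mod.pan_tompkins(ecg))
                io.save_rr(rr, sdir / "rr.csv")
                table = hrv_mod.windowed_hrv(rr, window_length=sim.window_length)
                table.insert(0, "condition", cond)
                table.insert(0, "subject", s)
                frames.append(table)
            except FileNotFoundError:
                raise
            except Exception as exc:  # noqa: BLE001
                logger.error("hrv failed for %s/%s: %s", cond, s, exc)
                failed.append(f"{cond}/sub-{s:02d}")
    if not frames:
        raise RuntimeError("hrv stage failed for every subject")
    out = outdir / "hrv_windows.csv"
    pd.concat(frames, ignore_index=True).to_csv(out, index=False)
    _append_manifest(outdir, config, "hrv", [out], {"failed": failed})
    return [out]


def stage_erp(config: PipelineConfig, outdir: Path) -> list:
    outputs = []
    effects = []
    for cond in CONDITIONS:
        sim = config.condition(cond)
        averages = {"before": [], "after": []}
        times = None
        for s, sdir in _subject_dirs(outdir, cond, sim.n_subjects):
            for phase in ("before", "after"):
                rec_path = sdir / f"oddball_{phase}_eeg.csv"
                if not rec_path.exists():
                    _require(rec_path, "simulate")
                rec = preprocess.bandpass_erp(io.read_recording(rec_path))
                events = io.read_events(sdir / f"oddball_{phase}_events.tsv")
                epochs = erp_mod.epoch(rec, events, subject=s, phase=phase, condition=cond)
                epochs = erp_mod.reject_amplitude(epochs)
                averages[phase].append(erp_mod.subject_average(epochs))
                times = epochs.times
        ga_rows = []
        for ci, ch in enumerate(EEG_CHANNELS):
            for phase in ("before", "after"):
                wave = np.mean([a[ci] for a in averages[phase]], axis=0)
                for t, v in zip(times, wave):
                    ga_rows.append(dict(condition=cond, channel=ch, phase=phase,
                                        time_s=t, amplitude_uv=v))
        pd.DataFrame(ga_rows).to_csv(outdir / f"grand_average_{cond}.csv", index=False)
        outputs.append(outdir / f"grand_average_{cond}.csv")
        dec = slice(None, None, config.lme_decimate)
        for ci, ch in enumerate(EEG_CHANNELS):
            before = np.stack([a[ci][dec] for a in averages["before"]])
            after = np.stack([a[ci][dec] for a in averages["after"]])
            eff = erp_mod.fit_phase_lme(before, after, times[dec], channel=ch)
            t = eff.table.copy()
            t.insert(0, "channel", ch)
            t.insert(0, "condition", cond)
            effects.append(t)
    out = outdir / "erp_phase_effects.csv"
    pd.concat(effects, ignore_index=True).to_csv(out, index=False)
    outputs.append(out)
    _append_manifest(outdir, config, "erp", outputs)
    return outputs


def stage_scores(config: PipelineConfig, outdir: Path) -> list:
    bmis = pd.read_csv(_require(outdir / "bmis.csv", "simulate"))
    zef = pd.read_csv(_require(outdir / "zef.csv", "simulate"))
    bscores = questionnaires.bmis_scores(bmis)
    zscores = questionnaires.zef_scores(zef)
    bscores.to_csv(outdir / "bmis_scores.csv", index=False)
    zscores.to_csv(outdir / "zef_scores.csv", index=False)
    alpha = {
        "bmis": questionnaires.cronbach_alpha(bmis[list(BMIS_ITEMS)].to_numpy()),
        "zef": questionnaires.cronbach_alpha(zef[list(ZEF_ITEMS)].to_numpy()),
    }
    io.save_json(alpha, outdir / "reliability.json")
    zef_wide = zef.set_index(["subject", "condition"]).sort_index()
    vc = zef_wide.xs("videoconference", level="condition").reset_index()
    f2f = zef_wide.xs("face_to_face", level="condition").reset_index()
    tests = questionnaires.paired_condition_tests(vc, f2f, list(ZEF_ITEMS))
    tests.to_csv(outdir / "zef_condition_tests.csv", index=False)
    outputs = [outdir / p for p in
               ("bmis_scores.csv", "zef_scores.csv", "reliability.json", "zef_condition_tests.csv")]
    _append_manifest(outdir, config, "scores", outputs)
    return outputs


def _index_summaries(features: pd.DataFrame, hrv_windows: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (s, cond, ch, band), g in features.groupby(["subject", "condition", "channel", "band"]):
        v = g["value"].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if len(v):
            rows.append(dict(subject=s, condition=cond, index=f"{ch}_{band}", value=v.mean()))
    for (s, cond), g in hrv_windows.groupby(["subject", "condition"]):
        for index in ("HR", "RMSSD", "pNN50", "SDRR", "LF_nu", "HF_nu", "ln_lf_hf"):
            v = g[index].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if len(v):
                rows.append(dict(subject=s, condition=cond, index=index, value=v.mean()))
    return pd.DataFrame(rows)


def stage_link(config: PipelineConfig, outdir: Path) -> list:
    features = pd.read_csv(_require(outdir / "features_eeg.csv", "features"))
    hrv_windows = pd.read_csv(_require(outdir / "hrv_windows.csv", "hrv"))
    zef = pd.read_csv(_require(outdir / "zef.csv", "simulate"))
    summaries = _index_summaries(features, hrv_windows)
    summaries.to_csv(outdir / "index_summaries.csv", index=False)

    zef_std = zscore_items(zef, list(ZEF_ITEMS))
    items = zef_std.melt(
        id_vars=["subject", "condition"], value_vars=list(ZEF_ITEMS),
        var_name="item", value_name="score_after",
    )
    link = linkstats.fit_index_item_lme(summaries, items, model="zef_index")
    link.to_csv(outdir / "index_item_effects.csv", index=False)

    vc = summaries[summaries["condition"] == "videoconference"]
    f2f = summaries[summaries["condition"] == "face_to_face"]
    table = linkstats.average_condition_test(vc, f2f)
    table.to_csv(outdir / "average_condition_tests.csv", index=False)

    outputs = [outdir / p for p in
               ("index_summaries.csv", "index_item_effects.csv", "average_condition_tests.csv")]
    _append_manifest(outdir, config, "link", outputs)
    return outputs


def stage_report(config: PipelineConfig, outdir: Path) -> list:
    lines = [f"pipeline report (config {config.config_hash()})", ""]
    for name in ("average_condition_tests.csv", "zef_condition_tests.csv", "index_item_effects.csv"):
        path = outdir / name
        if path.exists():
            df = pd.read_csv(path)
            lines.append(f"== {name} ==")
            lines.append(df.to_string(index=False, max_rows=40))
            lines.append("")
    out = outdir / "report.txt"
    out.write_text("\n".join(lines))
    _append_manifest(outdir, config, "report", [out])
    return [out]


_STAGE_FN = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "features": stage_features,
    "erp": stage_erp,
    "hrv": stage_hrv,
    "scores": stage_scores,
    "link": stage_link,
    "report": stage_report,
}


def run_stage(stage: str, config: PipelineConfig, outdir) -> list:
    if stage not in _STAGE_FN:
        raise ValueError(f"unknown stage {stage!r}; available: {STAGES}")
    return _STAGE_FN[stage](config, Path(outdir))


def run_all(config: PipelineConfig, outdir) -> None:
    for stage in STAGES:
        run_stage(stage, config, outdir)


__all__ = [
    "PipelineConfig",
    "FIXTURE_PROFILES",
    "STAGES",
    "make_fixture",
    "run_stage",
    "run_all",
]
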