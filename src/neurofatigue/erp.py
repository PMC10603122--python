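"""Oddball ERP pipeline: epoching, amplitude rejection, grand averages,
onset-latency estimation and time-point-wise random-intercept models.

Model conventions (frozen for reproducibility):

* phase model - amplitude ~ phase + (1 | subject), phase coded 0 = before,
  1 = after; fit independently at every time sample; BH correction across
  time samples within one channel;
* item models - after-amplitude ~ before-amplitude [+ item_before]
  + item_after + (1 | subject); the item_after coefficient divided by the
  residual SD is the standardized effect; BH across time samples within
  one model x item family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_adjust, fit_random_intercept
from .types import EpochSet, ErpWaveform, EventStream, Recording

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = (-0.2, 0.8)
REJECT_UV = 100.0

#: Component search windows (s) for onset/peak scoring.
COMPONENT_WINDOWS = {
    "N2": (0.20, 0.35),
    "P3a": (0.25, 0.50),
    "P300": (0.30, 0.70),
}


def epoch(
    recording: Recording,
    events: EventStream,
    window: tuple = DEFAULT_WINDOW,
    label: str = "target",
    baseline: tuple | None = (-0.2, 0.0),
    subject=None,
    phase: str | None = None,
    condition: str | None = None,
) -> EpochSet:
    """Cut stimulus-locked trials for events carrying ``label``.

    Events whose window would run past either end of the recording are
    dropped (logged). Baseline correction subtracts the per-trial,
    per-channel mean over ``baseline`` (pre-stimulus by default).
    """
    sfreq = recording.sfreq
    sel = events.select(label)
    i0 = int(round(window[0] * sfreq))
    i1 = int(round(window[1] * sfreq))
    times = np.arange(i0, i1) / sfreq
    trials = []
    for onset in sel.onsets:
        c = int(round(onset * sfreq))
        if c + i0 < 0 or c + i1 > recording.n_samples:
            logger.info("dropping event at %.3fs: epoch window out of span", onset)
            continue
        trials.append(recording.data[:, c + i0 : c + i1])
    if not trials:
        raise ValueError("no events left a complete epoch inside the recording")
    data = np.stack(trials)
    if baseline is not None:
        bmask = (times >= baseline[0]) & (times < baseline[1])
        if not bmask.any():
            raise ValueError("baseline interval outside the epoch window")
        data = data - data[:, :, bmask].mean(axis=2, keepdims=True)
    return EpochSet(
        data=data,
        times=times,
        channels=recording.channels,
        labels=np.array([label] * len(trials), dtype=object),
        subject=subject,
        phase=phase,
        condition=condition,
    )


def reject_amplitude(epochs: EpochSet, threshold: float = REJECT_UV) -> EpochSet:
    """Mask out trials exceeding ``threshold`` microvolts (absolute) on any
    channel or time point. Idempotent; combines with the existing mask."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    peak = np.abs(epochs.data).max(axis=(1, 2))
    retained = epochs.retained & (peak <= threshold)
    return EpochSet(
        data=epochs.data,
        times=epochs.times,
        channels=epochs.channels,
        labels=epochs.labels,
        subject=epochs.subject,
        phase=epochs.phase,
        condition=epochs.condition,
        retained=retained,
    )


def subject_average(epochs: EpochSet) -> np.ndarray:
    """Mean over retained trials, shape (n_channels, n_times)."""
    if epochs.n_retained == 0:
        raise ValueError("no retained trials to average")
    return epochs.retained_data().mean(axis=0)


def grand_average(epoch_sets: list[EpochSet]) -> dict:
    """Subject averages first, then an unweighted average across subjects.

    Subjects with zero retained trials are excluded (logged). Returns
    ``{channel: ErpWaveform}``.
    """
    if not epoch_sets:
        raise ValueError("no epoch sets supplied")
    ref = epoch_sets[0]
    per_subject = []
    for es in epoch_sets:
        if es.channels != ref.channels or not np.allclose(es.times, ref.times):
            raise ValueError("epoch sets differ in channels or time axis")
        if es.n_retained == 0:
            logger.warning("subject %r has no retained trials; excluded", es.subject)
            continue
        per_subject.append(subject_average(es))
    if not per_subject:
        raise ValueError("no subject with retained trials")
    ga = np.mean(per_subject, axis=0)
    return {
        ch: ErpWaveform(ch, ref.times, ga[i], n_trials_averaged=len(per_subject))
        for i, ch in enumerate(ref.channels)
    }


def onset_latency(
    waveform: ErpWaveform,
    component_window: tuple,
    baseline_window: tuple = (-0.2, 0.0),
    min_duration: float = 0.010,
    sd_factor: float = 2.0,
) -> float:
    """Earliest time in the component window where the amplitude departs
    from zero by more than ``sd_factor`` pre-stimulus SDs and stays
    departed for at least ``min_duration``. NaN when never met."""
    t = waveform.times
    if component_window[0] < t[0] or component_window[1] > t[-1] + 1e-9:
        raise ValueError("waveform does not cover the component window")
    base = waveform.amplitude[(t >= baseline_window[0]) & (t < baseline_window[1])]
    thresh = max(sd_factor * base.std(), 1e-12)
    dt = t[1] - t[0]
    need = max(int(np.ceil(min_duration / dt)), 1)
    cmask = (t >= component_window[0]) & (t <= component_window[1])
    idx = np.flatnonzero(cmask)
    above = np.abs(waveform.amplitude) > thresh
    run = 0
    for i in idx:
        if above[i]:
            run += 1
            if run >= need:
                return float(t[i - need + 1])
        else:
            run = 0
    logger.info("onset criterion never met on %s", waveform.channel)
    return float("nan")


# ---------------------------------------------------------------------------
# time-resolved mixed models


@dataclass
class TimeResolvedEffect:
    """Tidy container for one mass-univariate model family."""

    table: pd.DataFrame  # time_s, estimate, std_effect, p, p_adj, fallback
    model: str
    channel: str | None = None
    item: str | None = None

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return self.table["p_adj"].to_numpy() < alpha


def _stack_phase(before: np.ndarray, after: np.ndarray):
    n_subj = before.shape[0]
    endog = np.concatenate([before, after], axis=0)  # (2*n_subj, n_times)
    phase = np.concatenate([np.zeros(n_subj), np.ones(n_subj)])
    groups = np.concatenate([np.arange(n_subj)] * 2)
    return endog, phase, groups


def fit_phase_lme(
    before: np.ndarray,
    after: np.ndarray,
    times: np.ndarray,
    channel: str | None = None,
    model_id: str = "phase",
) -> TimeResolvedEffect:
    """Amplitude ~ phase + (1 | subject) at every time sample.

    ``before``/``after`` are (n_subjects, n_times) subject-average
    waveforms on a common time axis.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after must pair up per subject")
    endog, phase, groups = _stack_phase(before, after)
    rows = []
    for k, t in enumerate(np.asarray(times, dtype=float)):
        y = endog[:, k]
        if np.ptp(y) == 0:
            rows.append((t, 0.0, 0.0, 1.0, False))
            continue
        res = fit_random_intercept(y, pd.DataFrame({"phase": phase}), groups)
        est = float(res.params["phase"])
        std = est / res.resid_sd if res.resid_sd > 0 else np.sign(est) * np.inf
        rows.append((t, est, std, float(res.pvalues["phase"]), res.used_fallback))
    table = pd.DataFrame(rows, columns=["time_s", "estimate", "std_effect", "p", "fallback"])
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return TimeResolvedEffect(table, model=model_id, channel=channel)


def fit_item_lme(
    after: np.ndarray,
    before: np.ndarray,
    times: np.ndarray,
    groups: np.ndarray,
    item_after: np.ndarray,
    item_before: np.ndarray | None = None,
    model_id: str = "item_mood",
    item: str | None = None,
) -> TimeResolvedEffect:
    """after(t) ~ before(t) [+ item_before] + item_after + (1 | subject).

    Rows are observations (e.g., subject x channel waveforms, as when all
    channels are pooled); ``groups`` carries the subject of each row. Item
    scores must already be z-normalized across all subjects/conditions.
    The reported effect is the item_after coefficient divided by the
    residual SD.
    """
    after = np.asarray(after, dtype=float)
    before = np.asarray(before, dtype=float)
    item_after = np.asarray(item_after, dtype=float)
    if after.shape != before.shape or after.shape[0] != len(item_after):
        raise ValueError("after, before and item scores must align row-wise")
    if np.ptp(item_after) == 0:
        raise ValueError("item_after is constant; effect undefined")
    rows = []
    for k, t in enumerate(np.asarray(times, dtype=float)):
        exog = {"erp_before": before[:, k], "item_after": item_after}
        if item_before is not None:
            exog["item_before"] = np.asarray(item_before, dtype=float)
        res = fit_random_intercept(after[:, k], pd.DataFrame(exog), groups)
        est = float(res.params["item_after"])
        std = est / res.resid_sd if res.resid_sd > 0 else np.sign(est) * np.inf
        rows.append((t, est, std, float(res.pvalues["item_after"]), res.used_fallback))
    table = pd.DataFrame(rows, columns=["time_s", "estimate", "std_effect", "p", "fallback"])
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return TimeResolvedEffect(table, model=model_id, item=item)


__all__ = [
    "DEFAULT_WINDOW",
    "REJECT_UV",
    "COMPONENT_WINDOWS",
    "TimeResolvedEffect",
    "epoch",
    "reject_amplitude",
    "subject_average",
    "grand_average",
    "onset_latency",
    "fit_phase_lme",
    "fit_item_lme",
]
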