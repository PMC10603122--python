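"""Oddball stimulus sequence generation."""

from __future__ import annotations

import numpy as np

from ..types import EventStream

TARGET = "target"
STANDARD = "standard"


def generate_oddball_sequence(
    n_events: int,
    p_target: float,
    seed: int,
    isi: float = 1.0,
    stimulus_duration: float = 0.5,
    start: float = 1.0,
) -> EventStream:
    """Randomized rare-target sequence with an exact target count.

    Parameters
    ----------
    n_events : int
        Total number of stimuli.
    p_target : float
        Target proportion; ``n_events * p_target`` must be an integer, so
        the target count is forced rather than binomial.
    seed : int
        Seeds the order randomization only.
    isi : float
        Onset-to-onset interval in seconds (fixed).
    stimulus_duration : float
        Presentation duration attached to every event.
    start : float
        Onset of the first event, leaving room for a pre-stimulus window.
    """
    if not 0 < p_target < 1:
        raise ValueError("p_target must lie strictly between 0 and 1")
    if n_events < 1:
        raise ValueError("n_events must be positive")
    n_target_f = n_events * p_target
    n_target = int(round(n_target_f))
    if abs(n_target_f - n_target) > 1e-9:
        raise ValueError(
            f"n_events * p_target = {n_target_f:g} is not an integer; "
            "choose a count/proportion pair with an exact target count"
        )
    labels = np.array([TARGET] * n_target + [STANDARD] * (n_events - n_target), dtype=object)
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    onsets = start + isi * np.arange(n_events)
    durations = np.full(n_events, float(stimulus_duration))
    return EventStream(onsets, labels, durations)
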