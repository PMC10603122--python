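"""Ordinal questionnaire generation via a thresholded latent-trait model.

Each item response is ``1 + #{thresholds crossed}`` of a latent utility
``loading * fatigue + noise``: fatigue-congruent items load +1, pleasant
mood items -1. The videoconference condition shifts the post-lecture
latent state by ``latent_fatigue_effect`` standard units.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..types import GroundTruth
from .config import CONDITIONS, SimulationConfig

BMIS_PLEASANT = (
    "lively", "happy", "caring", "content", "peppy", "calm", "loving", "active",
)
BMIS_UNPLEASANT = (
    "sad", "tired", "gloomy", "jittery", "drowsy", "grouchy", "nervous", "fed_up",
)
BMIS_ITEMS = BMIS_PLEASANT + BMIS_UNPLEASANT

ZEF_ITEMS = tuple(f"zef{i:02d}" for i in range(1, 19))
#: Five dimensions of three items each; the remaining three stated items
#: cannot be assigned from the instrument description and only contribute
#: to the overall mean.
ZEF_DIMENSIONS = {
    "general": ZEF_ITEMS[0:3],
    "visual": ZEF_ITEMS[3:6],
    "social": ZEF_ITEMS[6:9],
    "motivational": ZEF_ITEMS[9:12],
    "emotional": ZEF_ITEMS[12:15],
}
ZEF_UNASSIGNED = ZEF_ITEMS[15:18]

BMIS_THRESHOLDS = (-1.0, 0.0, 1.0)  # 4-point scale
ZEF_THRESHOLDS = (-1.5, -0.5, 0.5, 1.5)  # 5-point scale

_BMIS_LOADING = np.array([-1.0] * len(BMIS_PLEASANT) + [1.0] * len(BMIS_UNPLEASANT))
_ZEF_LOADING = np.ones(len(ZEF_ITEMS))


def _ordinal(u: np.ndarray, thresholds) -> np.ndarray:
    score = np.ones(u.shape, dtype=int)
    for tau in thresholds:
        score += (u > tau).astype(int)
    return score


def generate_questionnaires(
    config: SimulationConfig,
    latent_baseline: np.ndarray | None = None,
    bmis_thresholds=BMIS_THRESHOLDS,
    zef_thresholds=ZEF_THRESHOLDS,
    noise_sd: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate BMIS (before/after, both conditions) and ZEF (after, both
    conditions) item tables for all subjects.

    Parameters
    ----------
    latent_baseline : ndarray, optional
        Per-subject latent fatigue at baseline; drawn N(0, 0.8) when
        omitted.
    noise_sd : float
        Item-level latent noise SD (1.0 = standard probit scale).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 30])
    n = config.n_subjects
    if latent_baseline is None:
        latent_baseline = 0.8 * rng.standard_normal(n)
    latent_baseline = np.asarray(latent_baseline, dtype=float)
    if latent_baseline.shape != (n,):
        raise ValueError(f"latent_baseline must have shape ({n},)")
    if not np.all(np.isfinite(latent_baseline)):
        raise ValueError("latent values must be finite")

    latent_after = {
        "videoconference": latent_baseline + config.latent_fatigue_effect,
        "face_to_face": latent_baseline.copy(),
    }

    bmis_rows, zef_rows = [], []
    for cond in CONDITIONS:
        for phase in ("before", "after"):
            L = latent_baseline if phase == "before" else latent_after[cond]
            eps = noise_sd * rng.standard_normal((n, len(BMIS_ITEMS)))
            scores = _ordinal(L[:, None] * _BMIS_LOADING[None, :] + eps, bmis_thresholds)
            for s in range(n):
                row = {"subject": s, "condition": cond, "phase": phase}
                row.update(dict(zip(BMIS_ITEMS, scores[s])))
                bmis_rows.append(row)
        eps = noise_sd * rng.standard_normal((n, len(ZEF_ITEMS)))
        scores = _ordinal(
            latent_after[cond][:, None] * _ZEF_LOADING[None, :] + eps, zef_thresholds
        )
        for s in range(n):
            row = {"subject": s, "condition": cond}
            row.update(dict(zip(ZEF_ITEMS, scores[s])))
            zef_rows.append(row)

    truth = GroundTruth(
        latent_fatigue={
            "baseline": latent_baseline.copy(),
            "after": {k: v.copy() for k, v in latent_after.items()},
            "effect": config.latent_fatigue_effect,
        }
    )
    return pd.DataFrame(bmis_rows), pd.DataFrame(zef_rows), truth
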