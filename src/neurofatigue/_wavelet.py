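"""Minimal periodized orthogonal discrete wavelet transform.

Only what the artifact-thresholding step needs: multilevel analysis /
synthesis with perfect reconstruction for Haar and Daubechies-4 filters.
Signals of arbitrary length are edge-padded to a multiple of 2**level and
truncated after reconstruction.
"""

from __future__ import annotations

import numpy as np

_DB4_LO = np.array(
    [
        0.23037781330885523,
        0.7148465705525415,
        0.6308807679295904,
        -0.02798376941698385,
        -0.18703481171888114,
        0.030841381835986965,
        0.032883011666982945,
        -0.010597401784997278,
    ]
)
_HAAR_LO = np.array([1.0, 1.0]) / np.sqrt(2.0)

FILTERS = {"db4": _DB4_LO, "haar": _HAAR_LO}


def _qmf(lo: np.ndarray) -> np.ndarray:
    # hi[k] = (-1)^k * lo[N-1-k]
    return lo[::-1] * (-1.0) ** np.arange(len(lo))


def _analysis_step(x: np.ndarray, f: np.ndarray) -> np.ndarray:
    n, L = len(x), len(f)
    idx = (np.arange(0, n, 2)[:, None] + np.arange(L)[None, :]) % n
    return x[idx] @ f


def _synthesis_step(a: np.ndarray, d: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    n, L = 2 * len(a), len(lo)
    idx = (2 * np.arange(len(a))[:, None] + np.arange(L)[None, :]) % n
    x = np.zeros(n)
    np.add.at(x, idx, a[:, None] * lo[None, :])
    np.add.at(x, idx, d[:, None] * hi[None, :])
    return x


def wavedec(x: np.ndarray, wavelet: str = "db4", level: int = 5) -> tuple[list, int]:
    """Multilevel periodized DWT.

    Returns ``(coeffs, original_length)`` with ``coeffs = [aL, dL, ..., d1]``.
    """
    if wavelet not in FILTERS:
        raise ValueError(f"unknown wavelet {wavelet!r}; have {sorted(FILTERS)}")
    x = np.asarray(x, dtype=float)
    n0 = len(x)
    block = 2**level
    if n0 < block:
        raise ValueError(f"signal of length {n0} too short for level {level}")
    if n0 % block:
        x = np.concatenate([x, np.full(block - n0 % block, x[-1])])
    lo = FILTERS[wavelet]
    hi = _qmf(lo)
    details = []
    a = x
    for _ in range(level):
        d = _analysis_step(a, hi)
        a = _analysis_step(a, lo)
        details.append(d)
    return [a] + details[::-1], n0


def waverec(coeffs: list, n0: int, wavelet: str = "db4") -> np.ndarray:
    """Inverse of :func:`wavedec`."""
    lo = FILTERS[wavelet]
    hi = _qmf(lo)
    a = coeffs[0]
    for d in coeffs[1:]:
        a = _synthesis_step(a, d, lo, hi)
    return a[:n0]


def threshold_above(
    x: np.ndarray,
    threshold: float | None = None,
    wavelet: str = "db4",
    level: int = 5,
    scale: float = 1.0,
) -> tuple[np.ndarray, int]:
    """Zero every wavelet coefficient whose magnitude *exceeds* threshold.

    This is the inverse of denoising shrinkage: large (artifact-dominated)
    coefficients are removed while sub-threshold structure is retained.
    When ``threshold`` is None the universal threshold
    ``scale * sigma * sqrt(2 ln n)`` is used, with sigma robustly estimated
    from the finest detail level (MAD / 0.6745).

    Returns ``(reconstructed signal, number of zeroed coefficients)``.
    """
    coeffs, n0 = wavedec(x, wavelet, level)
    if threshold is None:
        finest = coeffs[-1]
        sigma = np.median(np.abs(finest - np.median(finest))) / 0.6745
        threshold = scale * sigma * np.sqrt(2.0 * np.log(max(n0, 2)))
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n_zeroed = 0
    out = []
    for c in coeffs:
        mask = np.abs(c) > threshold
        n_zeroed += int(mask.sum())
        c = c.copy()
        c[mask] = 0.0
        out.append(c)
    return waverec(out, n0, wavelet), n_zeroed
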