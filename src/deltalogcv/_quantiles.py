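"""Shared empirical-quantile helpers for simulation-based intervals."""

from __future__ import annotations

import numpy as np

MIN_DRAWS = 100


def equal_tailed_bounds(draws, level: float) -> tuple[float, float]:
    """(alpha/2, 1-alpha/2) empirical quantiles, linear interpolation.

    The linear-interpolation convention (numpy's default) interpolates
    between order statistics at h = (K-1)q + 1.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 1 or draws.size < MIN_DRAWS:
        raise ValueError(f"need a 1-d vector of at least {MIN_DRAWS} draws")
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    lo, hi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def hpd_bounds(draws, level: float) -> tuple[float, float]:
    """Shortest contiguous window of sorted draws holding ceil(level*K) draws.

    Ties between equally short windows are broken toward the leftmost one.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 1 or draws.size < MIN_DRAWS:
        raise ValueError(f"need a 1-d vector of at least {MIN_DRAWS} draws")
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    k = draws.size
    m = int(np.ceil(level * k))
    m = min(max(m, 1), k)
    srt = np.sort(draws)
    widths = srt[m - 1 :] - srt[: k - m + 1]
    i = int(np.argmin(widths))  # argmin returns the first (leftmost) minimum
    return float(srt[i]), float(srt[i + m - 1])
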