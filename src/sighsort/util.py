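"""Small shared numerics."""

from __future__ import annotations

import numpy as np

__all__ = ["moving_average", "median_abs_deviation"]


def moving_average(x: np.ndarray, span: int) -> np.ndarray:
    """Centered moving average with truncated windows at the edges.

    For even ``span`` the window is one sample heavier on the leading side
    (``[i - span//2 + 1, i + span//2]``).  Length is preserved.
    """
    if span < 1:
        raise ValueError("span must be >= 1")
    x = np.asarray(x, dtype=float)
    kernel = np.ones(span)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def median_abs_deviation(x: np.ndarray, scale: float = 1.0) -> float:
    """Median absolute deviation about the median.

    ``scale`` defaults to 1 (no Gaussian consistency factor); pass 1.4826
    for a normal-consistent estimate.
    """
    x = np.asarray(x, dtype=float)
    return scale * float(np.median(np.abs(x - np.median(x))))
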