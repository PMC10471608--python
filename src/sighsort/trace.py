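"""Uniformly sampled single-channel signal container.

A :class:`Trace` holds an integrated population-activity or integrated EMG
signal: a 1-D array of amplitudes, a sampling rate and a time origin.  All
downstream operations (burst detection, onset location, shape extraction)
address the trace by time in seconds; sample indexing is 0-based and windows
are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trace"]


@dataclass
class Trace:
    """A uniformly sampled single-channel signal.

    Parameters
    ----------
    samples : ndarray
        Signal amplitudes (a.u.), one per sample.  Must be finite and contain
        at least two samples.
    sampling_rate : float
        Samples per second; must be positive.
    t0 : float, optional
        Time (s) of the first sample.  Default 0.
    channel : str, optional
        Free-text channel label (e.g. ``"preBotC"``, ``"dia-EMG"``).
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0
    channel: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("trace needs a 1-D array of at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    # -- geometry -----------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        """Total covered time span in seconds (n_samples / rate)."""
        return self.n_samples * self.dt

    @property
    def t_end(self) -> float:
        """Time just past the final sample (half-open end of the trace)."""
        return self.t0 + self.duration

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) * self.dt

    def index_at(self, t: float) -> int:
        """Nearest sample index for time ``t`` (clipped to valid range)."""
        i = int(round((t - self.t0) * self.sampling_rate))
        return min(max(i, 0), self.n_samples - 1)

    def time_at(self, i: int) -> float:
        return self.t0 + i * self.dt

    def slice(self, start: float, end: float) -> np.ndarray:
        """Samples in the half-open time window ``[start, end)``."""
        i0 = max(0, int(np.ceil((start - self.t0) * self.sampling_rate - 1e-9)))
        i1 = min(self.n_samples, int(np.ceil((end - self.t0) * self.sampling_rate - 1e-9)))
        return self.samples[i0:i1]
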