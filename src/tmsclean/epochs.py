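"""Epoched multichannel data container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray


@dataclass
class EpochedData:
    """Channels x samples x trials voltage array with a uniform time axis.

    ``data`` is in μV, ``fs`` in samples/s, ``times`` in ms relative to the
    stimulus.  ``meta`` carries provenance (seeds, config hashes, cleaning
    history) and is preserved verbatim through I/O.
    """

    data: NDArray[np.float64]
    fs: float
    times: NDArray[np.float64]
    labels: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (channels, samples, trials)")
        n_ch, n_s, _ = self.data.shape
        if len(self.labels) != n_ch:
            raise ValueError("label count does not match channel count")
        if self.times.shape != (n_s,):
            raise ValueError("times length does not match sample count")
        dt = np.diff(self.times)
        if n_s > 1 and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("times must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        self.labels = tuple(self.labels)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def time_mask(self, t_min_ms: float, t_max_ms: float) -> NDArray[np.bool_]:
        return (self.times >= t_min_ms) & (self.times <= t_max_ms)

    def copy_with(self, data: np.ndarray, **meta_updates) -> "EpochedData":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return EpochedData(data, self.fs, self.times.copy(), self.labels, meta)

    def average(self) -> NDArray[np.float64]:
        """Trial-averaged response, channels x samples."""
        return self.data.mean(axis=2)


def epoch_times(t_start_ms: float, t_end_ms: float, fs: float) -> NDArray[np.float64]:
    """Uniform time axis [t_start, t_end) in ms at sampling rate ``fs``."""
    n = int(round((t_end_ms - t_start_ms) * fs / 1000.0))
    return t_start_ms + np.arange(n) * 1000.0 / fs
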