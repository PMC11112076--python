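"""Zero-phase FIR filtering helpers shared by the generator and the cleaners."""

from __future__ import annotations

import numpy as np
from scipy import signal


def _numtaps(n_samples: int, requested: int) -> int:
    """Odd tap count, capped so mirror padding stays within the epoch."""
    cap = 2 * (n_samples - 1) + 1
    taps = min(requested, cap)
    return taps if taps % 2 == 1 else taps - 1


def fir_filter_epochs(
    data: np.ndarray, fs: float, cutoff_hz: float, kind: str, numtaps: int = 401
) -> np.ndarray:
    """Zero-phase windowed-sinc FIR filter along the sample axis.

    ``data`` is (channels, samples, trials); edges are mirror-padded by half
    the filter length so the linear-phase delay cancels exactly.
    """
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, fs/2)")
    if kind not in ("lowpass", "highpass"):
        raise ValueError("kind must be 'lowpass' or 'highpass'")
    n_ch, n_s, n_tr = data.shape
    taps = _numtaps(n_s, numtaps)
    h = signal.firwin(taps, cutoff_hz, pass_zero=(kind == "lowpass"), fs=fs)
    half = taps // 2
    pad = half
    x = data.transpose(0, 2, 1).reshape(n_ch * n_tr, n_s)
    xp = np.pad(x, ((0, 0), (pad, pad)), mode="reflect")
    y = signal.fftconvolve(xp, h[None, :], mode="same")[:, pad:-pad]
    return y.reshape(n_ch, n_tr, n_s).transpose(0, 2, 1)
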