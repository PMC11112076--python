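"""Artifact-characterization operators for measured (or measured-like) data.

These are the tools used to ask "what do real muscle artifacts look like":
SVD extraction of the dominant early artifact component, inter-trial
coherence of its trial time courses, minimum-norm montage extrapolation,
pulse-interval zeroing/interpolation, and signal-space angle distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import PchipInterpolator

from .artifact_sim import signal_space_angles_deg
from .epochs import EpochedData
from .headmodel import LeadField

__all__ = [
    "ArtifactProfile",
    "extract_artifact_component",
    "itc",
    "mne_extrapolate",
    "zero_pulse_interval",
    "interpolate_interval",
    "angle_distribution",
    "characterize_dataset",
]


@dataclass
class ArtifactProfile:
    topography: np.ndarray          # (channels,), unit norm
    trial_timecourses: np.ndarray   # (trials, samples), full epoch
    itc: np.ndarray | None = None   # (freqs, times) in [0, 1]
    itc_freqs_hz: np.ndarray | None = None
    angle_samples_deg: np.ndarray | None = None


def extract_artifact_component(
    data: EpochedData, window_ms: tuple[float, float] = (0.0, 50.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Dominant spatial component of the early window.

    SVD of the trial-concatenated windowed data; returns the first left
    singular vector (sign fixed so its largest-|value| element is positive)
    and the per-trial time courses u1' Y_k over the full epoch.
    """
    mask = data.time_mask(*window_ms)
    if not mask.any():
        raise ValueError(f"window {window_ms} contains no samples")
    X = data.data[:, mask, :]
    X = X.transpose(0, 2, 1).reshape(X.shape[0], -1)
    U, _, _ = np.linalg.svd(X, full_matrices=False)
    u1 = U[:, 0]
    if u1[np.argmax(np.abs(u1))] < 0:
        u1 = -u1
    timecourses = np.einsum("c,csn->ns", u1, data.data)
    return u1, timecourses


def _morlet_wavelet(f_hz: float, fs: float, n_cycles: float) -> np.ndarray:
    sigma_t = n_cycles / (2.0 * np.pi * f_hz)
    t = np.arange(-5 * sigma_t, 5 * sigma_t + 1.0 / fs, 1.0 / fs)
    return np.exp(2j * np.pi * f_hz * t) * np.exp(-(t**2) / (2 * sigma_t**2))


def itc(
    trial_timecourses: np.ndarray,
    fs: float,
    freqs_hz: np.ndarray,
    n_cycles: float = 5.0,
) -> np.ndarray:
    """Inter-trial coherence (phase-locking factor), freqs x times in [0, 1].

    Morlet-wavelet phase per trial; ITC(f, t) is the magnitude of the
    trial-averaged unit phasor.  1 means perfect phase alignment; for N
    independent uniform phases the expected value is ~ sqrt(pi)/(2 sqrt(N)).
    """
    X = np.atleast_2d(np.asarray(trial_timecourses, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("ITC requires at least 2 trials")
    out = np.empty((len(freqs_hz), X.shape[1]))
    for i, f in enumerate(np.asarray(freqs_hz, dtype=float)):
        w = _morlet_wavelet(f, fs, n_cycles)
        analytic = signal.fftconvolve(X, w[None, :], mode="same")
        mag = np.abs(analytic)
        phasors = analytic / np.where(mag > 0, mag, 1.0)
        out[i] = np.abs(phasors.mean(axis=0))
    return out


def mne_extrapolate(
    data_small: EpochedData,
    leadfield_small: LeadField,
    leadfield_full: LeadField,
    lambda_rel: float = 1e-5,
) -> EpochedData:
    """Minimum-norm montage extrapolation.

    Tikhonov-regularized source estimate X = L' (L L' + lambda I)^-1 Y with
    lambda = lambda_rel * trace(L L'), re-projected through the full-montage
    lead field.  Both lead fields must share the source space.
    """
    if lambda_rel <= 0:
        raise ValueError("lambda_rel must be positive")
    L = leadfield_small.gain
    if L.shape[0] != data_small.n_channels:
        raise ValueError("small lead field does not match data channels")
    if leadfield_full.gain.shape[1] != L.shape[1]:
        raise ValueError("lead fields must share a source space")
    G = L @ L.T
    lam = lambda_rel * np.trace(G)
    W = leadfield_full.gain @ L.T @ np.linalg.inv(G + lam * np.eye(L.shape[0]))
    out = np.einsum("dc,csn->dsn", W, data_small.data)
    return EpochedData(
        out, data_small.fs, data_small.times.copy(),
        leadfield_full.montage.labels,
        meta={**data_small.meta, "mne_extrapolated": True, "lambda_rel": lambda_rel},
    )


def _interval_mask(data: EpochedData, interval_ms: tuple[float, float]) -> np.ndarray:
    mask = data.time_mask(*interval_ms)
    if not mask.any():
        raise ValueError(f"interval {interval_ms} contains no samples")
    idx = np.flatnonzero(mask)
    if idx[0] == 0 or idx[-1] == data.n_samples - 1:
        raise ValueError("interval touches the epoch edge; no boundary samples")
    return mask


def zero_pulse_interval(
    data: EpochedData, interval_ms: tuple[float, float] = (-1.0, 5.0)
) -> EpochedData:
    """Replace the pulse-artifact interval with exact zeros."""
    mask = _interval_mask(data, interval_ms)
    out = data.data.copy()
    out[:, mask, :] = 0.0
    return data.copy_with(out, zeroed_interval_ms=list(interval_ms))


def interpolate_interval(
    data: EpochedData, interval_ms: tuple[float, float] = (-1.0, 5.0)
) -> EpochedData:
    """Fill the interval with shape-preserving piecewise-cubic interpolation.

    Monotone (PCHIP) interpolation through the samples outside the interval,
    applied per channel and trial; reproduces linear signals exactly and
    introduces no new extrema inside the gap.
    """
    mask = _interval_mask(data, interval_ms)
    keep = ~mask
    t_keep = data.times[keep]
    out = data.data.copy()
    n_ch, _, n_tr = out.shape
    flat = out.transpose(0, 2, 1).reshape(n_ch * n_tr, -1)
    interp = PchipInterpolator(t_keep, flat[:, keep], axis=1, extrapolate=False)
    flat[:, mask] = interp(data.times[mask])
    out = flat.reshape(n_ch, n_tr, -1).transpose(0, 2, 1)
    return data.copy_with(out, interpolated_interval_ms=list(interval_ms))


def angle_distribution(
    topography: np.ndarray,
    data: EpochedData,
    window_ms: tuple[float, float] = (0.0, 100.0),
) -> dict:
    """Angles between a topography and every trial/time potential pattern.

    Returns per-trial-per-time angles (degrees) plus violin-style summaries
    (median, mean, whiskers at the 2.5/97.5 percentiles).  Zero-norm vectors
    are excluded and counted.
    """
    u = np.asarray(topography, dtype=float)
    if abs(np.linalg.norm(u) - 1.0) > 1e-6:
        raise ValueError("topography must be unit norm")
    mask = data.time_mask(*window_ms)
    if not mask.any():
        raise ValueError(f"window {window_ms} contains no samples")
    X = data.data[:, mask, :]
    V = X.reshape(X.shape[0], -1)
    angles = signal_space_angles_deg(u, V)
    n_bad = int(np.isnan(angles).sum())
    if n_bad:
        warnings.warn(f"{n_bad} zero-norm patterns excluded from angle distribution")
    valid = angles[~np.isnan(angles)]
    return {
        "angles_deg": angles.reshape(X.shape[1], X.shape[2]),
        "median_deg": float(np.median(valid)),
        "mean_deg": float(np.mean(valid)),
        "whiskers_deg": (
            float(np.percentile(valid, 2.5)),
            float(np.percentile(valid, 97.5)),
        ),
        "n_excluded": n_bad,
    }


def characterize_dataset(
    data: EpochedData,
    window_ms: tuple[float, float] = (0.0, 50.0),
    itc_freqs_hz: np.ndarray | None = None,
    clean_reference: EpochedData | None = None,
) -> ArtifactProfile:
    """Full characterization: extract, ITC, and angle distribution.

    If ``clean_reference`` is given (simulations), angles are computed
    against the clean neuronal patterns rather than the corrupted data.
    """
    if itc_freqs_hz is None:
        itc_freqs_hz = np.geomspace(10.0, min(250.0, data.fs / 2 * 0.9), 12)
    u1, tcs = extract_artifact_component(data, window_ms)
    coh = itc(tcs, data.fs, itc_freqs_hz)
    angle_target = clean_reference if clean_reference is not None else data
    dist = angle_distribution(u1, angle_target, (0.0, 100.0))
    return ArtifactProfile(
        topography=u1,
        trial_timecourses=tcs,
        itc=coh,
        itc_freqs_hz=np.asarray(itc_freqs_hz, dtype=float),
        angle_samples_deg=dist["angles_deg"],
    )
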