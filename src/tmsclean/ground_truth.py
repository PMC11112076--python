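"""Synthetic clean evoked-potential datasets used as simulation ground truth.

The generator builds a plausible stimulus-locked multichannel response:
Gaussian-windowed sinusoid deflections from a handful of cortical dipoles,
spatially correlated ongoing background activity with a 1/f amplitude
spectrum, and a little white sensor noise (which keeps the data full rank for
ICA).  Everything is low-passed, baseline-corrected and finally calibrated so
the maximum global mean field amplitude of the trial average hits the target.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import headmodel
from ._signal import fir_filter_epochs
from .epochs import EpochedData, epoch_times

__all__ = [
    "GroundTruthConfig",
    "generate_ground_truth",
    "compute_gmfa",
    "baseline_correct",
    "neuronal_head_model",
    "cortical_sources",
]


def neuronal_head_model(series_terms: int = 60) -> headmodel.SphericalHeadModel:
    """Head model shared by the generator and source-informed reconstruction.

    Skull contrast 1/50 (classic three-sphere convention).  Artifact
    topographies use a *different* (electrode-jittered, contrast-varied)
    model; see :mod:`tmsclean.artifact_sim`.
    """
    return headmodel.SphericalHeadModel(series_terms=series_terms)


# Fixed evoked dipoles: right motor region plus midline/contralateral spread.
_ATOM_DIRECTIONS = np.array(
    [
        [0.55, -0.15, 0.82],   # right M1-ish
        [0.35, 0.10, 0.93],
        [0.10, -0.30, 0.95],   # midline central/parietal
        [0.00, 0.45, 0.89],    # frontal midline
        [-0.30, -0.10, 0.95],  # contralateral spread
        [0.20, -0.60, 0.77],   # parietal
    ]
)


def cortical_sources(n_sources: int = 6, radius_mm: float = 68.0) -> headmodel.SourceSpace:
    """Fixed superficial dipoles generating the evoked deflections."""
    if not 1 <= n_sources <= len(_ATOM_DIRECTIONS):
        raise ValueError(f"n_sources must be 1..{len(_ATOM_DIRECTIONS)}")
    dirs = _ATOM_DIRECTIONS[:n_sources]
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    oris = []
    for d in dirs:
        e1, e2 = headmodel._tangent_basis(d)
        oris.append((0.8 * e1 + 0.6 * e2))
    oris = np.array(oris)
    oris /= np.linalg.norm(oris, axis=1, keepdims=True)
    return headmodel.SourceSpace(radius_mm * dirs, oris)


@dataclass(frozen=True)
class GroundTruthConfig:
    n_channels: int = 60
    n_trials: int = 173
    t_start_ms: float = -50.0
    t_end_ms: float = 150.0
    fs: float = 5000.0
    n_sources: int = 6
    peak_latencies_ms: tuple[float, ...] = (15.0, 30.0, 45.0, 60.0, 100.0, 180.0)
    peak_freqs_hz: tuple[float, ...] = (40.0, 30.0, 22.0, 15.0, 10.0, 8.0)
    peak_widths_ms: tuple[float, ...] = (6.0, 8.0, 10.0, 14.0, 20.0, 30.0)
    # dominant early complex, as in typical motor-cortex evoked responses
    peak_rel_amplitudes: tuple[float, ...] = (4.5, 1.0, 0.8, 0.6, 0.5, 0.4)
    amp_jitter_sd: float = 0.15
    latency_jitter_sd_ms: float = 1.5
    noise_rms_uv: float = 1.0         # white sensor noise, pre-calibration
    source_noise_rms_uv: float = 2.5  # 1/f background through the lead field
    broadband_noise_rms_uv: float = 0.1  # amplifier noise floor, not low-passed
    lowpass_hz: float = 80.0
    gmfa_target_uv: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.t_start_ms < 0.0 < self.t_end_ms):
            raise ValueError("epoch must straddle the stimulus at t = 0")
        if not 0.0 < self.lowpass_hz < self.fs / 2:
            raise ValueError("lowpass_hz must lie in (0, fs/2)")
        for name in (
            "n_channels", "n_trials", "fs", "n_sources", "amp_jitter_sd",
            "latency_jitter_sd_ms", "noise_rms_uv", "source_noise_rms_uv",
            "gmfa_target_uv",
        ):
            if getattr(self, name) <= 0 and name not in ("amp_jitter_sd",):
                raise ValueError(f"{name} must be positive")
        k = len(self.peak_latencies_ms)
        if not (
            len(self.peak_freqs_hz) == len(self.peak_widths_ms)
            == len(self.peak_rel_amplitudes) == k >= self.n_sources
        ):
            raise ValueError("peak parameter lists must match and cover n_sources")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _one_over_f_noise(rng: np.random.Generator, n_rows: int, n_samples: int,
                      fs: float, f_max: float) -> np.ndarray:
    """Rows of unit-RMS noise with amplitude spectrum ~ 1/f up to ``f_max``."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.zeros_like(freqs)
    band = (freqs > 0) & (freqs <= f_max)
    shape[band] = 1.0 / np.maximum(freqs[band], 2.0)
    spec = (rng.standard_normal((n_rows, freqs.size))
            + 1j * rng.standard_normal((n_rows, freqs.size))) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x / np.maximum(rms, 1e-300)


def generate_ground_truth(config: GroundTruthConfig) -> EpochedData:
    """Generate one clean epoched dataset; bit-reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    times = epoch_times(config.t_start_ms, config.t_end_ms, config.fs)
    n_s = times.size
    n_ch, n_tr = config.n_channels, config.n_trials

    montage = headmodel.build_montage_1020(n_ch)
    model = neuronal_head_model()
    atoms_ss = cortical_sources(config.n_sources)
    L_atoms = headmodel.compute_leadfield(model, atoms_ss, montage).gain

    # evoked deflections: per source, Gaussian-windowed sinusoid with trial
    # jitter in amplitude and latency
    rel_amp = np.asarray(config.peak_rel_amplitudes[: config.n_sources])
    source_ts = np.zeros((config.n_sources, n_s, n_tr))
    for k in range(config.n_sources):
        tau = config.peak_latencies_ms[k]
        f = config.peak_freqs_hz[k]
        w = config.peak_widths_ms[k]
        amp = rel_amp[k] * (1.0 + config.amp_jitter_sd * rng.standard_normal(n_tr))
        dtau = config.latency_jitter_sd_ms * rng.standard_normal(n_tr)
        t = times[:, None] - (tau + dtau)[None, :]
        source_ts[k] = amp[None, :] * np.exp(-0.5 * (t / w) ** 2) * np.sin(
            2e-3 * np.pi * f * t
        )
    neural = np.einsum("ck,ksn->csn", L_atoms, source_ts)

    # calibrate the evoked part first so the noise floor below is expressed
    # in (approximately) final μV units
    g0 = compute_gmfa_array(neural.mean(axis=2))
    neural *= config.gmfa_target_uv / max(g0.max(), 1e-300)

    # spatially correlated 1/f background through random superficial dipoles
    n_noise = 24
    noise_dirs = rng.standard_normal((n_noise, 3))
    noise_dirs /= np.linalg.norm(noise_dirs, axis=1, keepdims=True)
    noise_oris = rng.standard_normal((n_noise, 3))
    noise_oris /= np.linalg.norm(noise_oris, axis=1, keepdims=True)
    L_noise = headmodel.compute_leadfield(
        model, headmodel.SourceSpace(65.0 * noise_dirs, noise_oris), montage
    ).gain
    bg = _one_over_f_noise(rng, n_noise * n_tr, n_s, config.fs, config.lowpass_hz)
    bg = bg.reshape(n_noise, n_tr, n_s).transpose(0, 2, 1)
    bg_ch = np.einsum("ck,ksn->csn", L_noise, bg)
    ch_rms = np.sqrt(np.mean(bg_ch**2))
    bg_ch *= config.source_noise_rms_uv / max(ch_rms, 1e-300)

    sensor = config.noise_rms_uv * rng.standard_normal((n_ch, n_s, n_tr))

    data = neural + bg_ch + sensor
    data = fir_filter_epochs(data, config.fs, config.lowpass_hz, "lowpass")
    # a small broadband amplifier-noise floor escapes the low-pass; it keeps
    # the spatial structure of the high-frequency band noise-like, as in a
    # real recording
    data += config.broadband_noise_rms_uv * rng.standard_normal(data.shape)
    out = EpochedData(
        data, config.fs, times, montage.labels,
        meta={"generator": "ground_truth", "seed": config.seed,
              "config_digest": config.digest()},
    )
    out = baseline_correct(out)
    # final exact calibration of the trial-average GMFA maximum
    g = compute_gmfa(out)
    out.data *= config.gmfa_target_uv / g.max()
    return out


def compute_gmfa_array(average: np.ndarray) -> np.ndarray:
    """GMFA of a channels x samples average: spatial std per time point."""
    if average.shape[0] < 2:
        raise ValueError("GMFA requires at least 2 channels")
    return average.std(axis=0, ddof=0)


def compute_gmfa(data: EpochedData) -> np.ndarray:
    """Global mean field amplitude (μV) of the trial-averaged response."""
    return compute_gmfa_array(data.average())


def baseline_correct(
    data: EpochedData, window_ms: tuple[float, float] = (-50.0, -5.0)
) -> EpochedData:
    """Subtract the per-channel, per-trial mean over the baseline window."""
    mask = data.time_mask(*window_ms)
    if not mask.any():
        raise ValueError(f"baseline window {window_ms} contains no samples")
    base = data.data[:, mask, :].mean(axis=1, keepdims=True)
    return data.copy_with(data.data - base, baseline_window_ms=list(window_ms))
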