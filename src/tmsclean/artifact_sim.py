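"""Parametric scalp-muscle artifact simulation.

One artifact realization is a rank-1 spatiotemporal pattern: a fixed scalp
topography (a lead-field column of a right-lateral tangential dipole) times
trial-specific time courses built from a Daubechies-4 wavelet,

    a_i(t) = (1 - alpha) * phi(t) + alpha * S_i * phi(t - phi_i),

with random sign S_i and random translation phi_i in [0, 10] ms.  alpha = 0
gives perfectly stimulus-locked trials; alpha = 1 fully randomized phase.

The wavelet is constructed from scratch (spectral factorization of the
Daubechies polynomial followed by the cascade algorithm) and compressed so
its support spans the first 20 ms of the epoch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from math import comb

import numpy as np
from numpy.typing import NDArray

from . import headmodel
from .epochs import EpochedData, epoch_times

__all__ = [
    "ArtifactCondition",
    "ArtifactRealization",
    "ArtifactTopographyBank",
    "AMPLITUDES_UV",
    "ALPHA_GRID",
    "wavelet_prototype",
    "simulate_timecourses",
    "make_topography",
    "scale_to_p2p",
    "superpose",
    "simulate_realization",
    "topography_angle_profile",
    "signal_space_angles_deg",
    "condition_grid",
]

WAVELET_SUPPORT_MS = 20.0
MAX_SHIFT_MS = 10.0

AMPLITUDES_UV: tuple[float, ...] = (50.0, 250.0, 1000.0)
ALPHA_GRID: tuple[float, ...] = tuple(np.round(np.linspace(0.0, 1.0, 11), 10))


# --------------------------------------------------------------------------
# Daubechies-4 wavelet from first principles
# --------------------------------------------------------------------------


def _daubechies_filter(p: int = 4) -> np.ndarray:
    """Orthonormal Daubechies scaling filter with ``p`` vanishing moments.

    Spectral factorization: roots of z^(p-1) * B((2 - z - 1/z)/4) inside the
    unit circle give the minimal-phase factor; p zeros at z = -1 complete the
    filter.  Returns 2p taps with sum sqrt(2).
    """
    b = [comb(p - 1 + k, k) for k in range(p)]
    poly = np.zeros(2 * p - 1)  # degree 2(p-1), high -> low
    base = np.array([-0.25, 0.5, -0.25])  # z*y(z) = (2z - z^2 - 1)/4
    for k, bk in enumerate(b):
        term = np.array([1.0])
        for _ in range(k):
            term = np.convolve(term, base)
        # multiply by z^(p-1-k), then align into the full-length array
        term = np.concatenate([term, np.zeros(p - 1 - k)])
        poly += bk * np.concatenate([np.zeros(2 * p - 1 - term.size), term])
    roots = np.roots(poly)
    inside = roots[np.abs(roots) < 1.0]
    q = np.real(np.poly(inside))
    lp = np.array([1.0])
    for _ in range(p):
        lp = np.convolve(lp, [0.5, 0.5])
    h = np.convolve(lp, q)
    h = h * (np.sqrt(2.0) / h.sum())
    return h


def _wavelet_filter(h: np.ndarray) -> np.ndarray:
    g = h[::-1].copy()
    g[1::2] *= -1.0
    return g


@lru_cache(maxsize=4)
def _db4_wavelet_fine(level: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Samples of the db4 wavelet function on a fine dyadic grid.

    Cascade algorithm: start from the wavelet filter and refine ``level - 1``
    times with the scaling filter.  Returns (t, psi) with t rescaled to
    [0, WAVELET_SUPPORT_MS] and psi normalized to unit peak amplitude.
    """
    h = _daubechies_filter(4)
    x = _wavelet_filter(h)
    for _ in range(level - 1):
        up = np.zeros(2 * x.size - 1)
        up[::2] = x
        x = np.sqrt(2.0) * np.convolve(up, h)
    t = np.linspace(0.0, WAVELET_SUPPORT_MS, x.size)
    x = x / np.max(np.abs(x))
    return t, x


def _sample_wavelet(times_ms: np.ndarray, shift_ms: float = 0.0) -> np.ndarray:
    """phi(t - shift) on an arbitrary grid; exactly zero outside the support."""
    ft, fv = _db4_wavelet_fine()
    tt = np.asarray(times_ms, dtype=float) - shift_ms
    out = np.interp(tt, ft, fv, left=0.0, right=0.0)
    out[(tt < 0.0) | (tt > WAVELET_SUPPORT_MS)] = 0.0
    return out


def wavelet_prototype(fs: float = 5000.0, times_ms: np.ndarray | None = None) -> np.ndarray:
    """The artifact time-course prototype sampled on the epoch grid.

    Onset at t = 0, main deflection confined to the first 20 ms, unit peak
    amplitude, zero elsewhere.
    """
    if times_ms is None:
        times_ms = epoch_times(-50.0, 150.0, fs)
    return _sample_wavelet(np.asarray(times_ms, dtype=float))


# --------------------------------------------------------------------------
# Conditions and realizations
# --------------------------------------------------------------------------


def _validate_contrast(contrast: float) -> float:
    arr = np.asarray(headmodel.CONTRASTS)
    j = int(np.argmin(np.abs(arr - contrast)))
    if abs(arr[j] - contrast) > 1e-9:
        raise ValueError(
            f"contrast {contrast} not in the tested set "
            f"{{1, 1/20, ..., 1/200}}"
        )
    return float(arr[j])


@dataclass(frozen=True)
class ArtifactCondition:
    """One cell of the condition grid."""

    alpha: float
    contrast: float
    amplitude_uv: float = 250.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        object.__setattr__(self, "contrast", _validate_contrast(self.contrast))
        if self.amplitude_uv <= 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class ArtifactRealization:
    """A sampled artifact: unit-norm topography, trial time courses, scale."""

    topography: NDArray[np.float64]       # (n_channels,), unit norm
    timecourses: NDArray[np.float64]      # (n_trials, n_samples)
    signs: NDArray[np.int_]               # (n_trials,)
    shifts_ms: NDArray[np.float64]        # (n_trials,)
    scale: float                          # μV multiplier
    times_ms: NDArray[np.float64]
    condition: ArtifactCondition | None = None
    source_index: int | None = None

    def __post_init__(self) -> None:
        u = np.asarray(self.topography, dtype=float)
        if abs(np.linalg.norm(u) - 1.0) > 1e-9:
            raise ValueError("topography must be unit norm")
        if not np.all(np.isin(np.asarray(self.signs), (-1, 1))):
            raise ValueError("signs must be +-1")
        s = np.asarray(self.shifts_ms, dtype=float)
        if s.size and (s.min() < 0.0 or s.max() > MAX_SHIFT_MS):
            raise ValueError(f"shifts must lie in [0, {MAX_SHIFT_MS}] ms")

    def to_array(self) -> NDArray[np.float64]:
        """(channels, samples, trials) artifact voltages in μV."""
        return self.scale * np.einsum(
            "c,is->csi", self.topography, self.timecourses
        )


def simulate_timecourses(
    alpha: float,
    n_trials: int,
    seed: int | np.random.Generator,
    fs: float = 5000.0,
    times_ms: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trial time courses, signs and shifts for one realization.

    Returns ``(timecourses, signs, shifts_ms)`` with timecourses shaped
    (n_trials, n_samples).  The translation is continuous-uniform on
    [0, 10] ms, evaluated by interpolating the fine dyadic wavelet grid, so
    the compact support is preserved exactly.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if times_ms is None:
        times_ms = epoch_times(-50.0, 150.0, fs)
    times_ms = np.asarray(times_ms, dtype=float)
    signs = rng.choice((-1, 1), size=n_trials)
    shifts = rng.uniform(0.0, MAX_SHIFT_MS, size=n_trials)
    base = _sample_wavelet(times_ms)
    tc = np.empty((n_trials, times_ms.size))
    for i in range(n_trials):
        tc[i] = (1.0 - alpha) * base + alpha * signs[i] * _sample_wavelet(
            times_ms, shifts[i]
        )
    return tc, signs, shifts


class ArtifactTopographyBank:
    """Lead-field topographies of the 9 artifact dipoles at each contrast.

    Uses a head model whose electrodes are tangentially jittered relative to
    the montage used everywhere else, so the reconstruction stage never sees
    the exact forward model that generated the artifacts.
    """

    def __init__(
        self,
        n_channels: int = 60,
        electrode_jitter_mm: float = 5.0,
        jitter_seed: int = 777,
        source_seed: int = 101,
        series_terms: int = 60,
    ) -> None:
        base = headmodel.build_montage_1020(n_channels)
        self.montage = headmodel.perturb_montage(
            base, electrode_jitter_mm, 92.0, jitter_seed
        )
        self.montage = headmodel.ElectrodeMontage(base.labels, self.montage.positions)
        self.sources = headmodel.sample_artifact_sources(source_seed)
        self._series_terms = series_terms
        self._cache: dict[float, np.ndarray] = {}

    def topographies(self, contrast: float) -> np.ndarray:
        """(n_channels, 9) unit-norm average-referenced topographies."""
        contrast = _validate_contrast(contrast)
        if contrast not in self._cache:
            model = headmodel.SphericalHeadModel(
                series_terms=self._series_terms
            ).with_skull_contrast(contrast)
            gain = headmodel.compute_leadfield(model, self.sources, self.montage).gain
            gain = gain / np.linalg.norm(gain, axis=0, keepdims=True)
            self._cache[contrast] = gain
        return self._cache[contrast]

    def topography(self, contrast: float, source_index: int) -> np.ndarray:
        if not 0 <= source_index < self.sources.n_sources:
            raise ValueError("source_index must be in 0..8")
        return self.topographies(contrast)[:, source_index]


_DEFAULT_BANK: ArtifactTopographyBank | None = None


def default_topography_bank() -> ArtifactTopographyBank:
    global _DEFAULT_BANK
    if _DEFAULT_BANK is None:
        _DEFAULT_BANK = ArtifactTopographyBank()
    return _DEFAULT_BANK


def make_topography(
    contrast: float,
    source_index: int,
    bank: ArtifactTopographyBank | None = None,
) -> np.ndarray:
    """Unit-norm average-referenced artifact topography for one dipole."""
    bank = bank or default_topography_bank()
    return bank.topography(contrast, source_index)


def scale_to_p2p(
    topography: np.ndarray,
    timecourses: np.ndarray,
    target_uv: float,
    **kwargs,
) -> ArtifactRealization:
    """Choose the μV scale so the largest channel/trial peak-to-peak equals
    ``target_uv`` exactly."""
    u = np.asarray(topography, dtype=float)
    tc = np.asarray(timecourses, dtype=float)
    p2p = tc.max(axis=1) - tc.min(axis=1)
    raw = np.max(np.abs(u)) * p2p.max()
    if raw <= 0:
        raise ValueError("artifact is identically zero; cannot scale")
    defaults = dict(
        signs=np.ones(tc.shape[0], dtype=int),
        shifts_ms=np.zeros(tc.shape[0]),
        times_ms=np.arange(tc.shape[1], dtype=float),
    )
    defaults.update(kwargs)
    return ArtifactRealization(
        topography=u / np.linalg.norm(u),
        timecourses=tc,
        scale=float(target_uv / raw) * np.linalg.norm(u),
        **defaults,
    )


def simulate_realization(
    condition: ArtifactCondition,
    times_ms: np.ndarray,
    fs: float,
    n_trials: int,
    bank: ArtifactTopographyBank | None = None,
    source_index: int | None = None,
    rng: np.random.Generator | None = None,
) -> ArtifactRealization:
    """Sample one full artifact realization for a grid condition."""
    rng = rng or np.random.default_rng(condition.seed)
    bank = bank or default_topography_bank()
    if source_index is None:
        source_index = int(rng.integers(0, bank.sources.n_sources))
    u = bank.topography(condition.contrast, source_index)
    tc, signs, shifts = simulate_timecourses(
        condition.alpha, n_trials, rng, fs=fs, times_ms=times_ms
    )
    return scale_to_p2p(
        u, tc, condition.amplitude_uv,
        signs=signs, shifts_ms=shifts, times_ms=np.asarray(times_ms, float),
        condition=condition, source_index=source_index,
    )


def superpose(ground_truth: EpochedData, artifact: ArtifactRealization) -> EpochedData:
    """Add the artifact to the clean data (elementwise, with provenance)."""
    art = artifact.to_array()
    if art.shape != ground_truth.data.shape:
        raise ValueError(
            f"artifact shape {art.shape} does not match data {ground_truth.data.shape}"
        )
    meta = {}
    if artifact.condition is not None:
        c = artifact.condition
        meta = {
            "artifact_alpha": c.alpha,
            "artifact_contrast": c.contrast,
            "artifact_amplitude_uv": c.amplitude_uv,
            "artifact_seed": c.seed,
            "artifact_source_index": artifact.source_index,
        }
    return ground_truth.copy_with(ground_truth.data + art, **meta)


# --------------------------------------------------------------------------
# Signal-space angles
# --------------------------------------------------------------------------


def signal_space_angles_deg(u: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    """Angles (degrees, [0, 180]) between ``u`` and each column of ``vectors``.

    Columns with zero norm yield NaN (and a warning from the caller).
    """
    u = np.asarray(u, dtype=float)
    V = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(V, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (u @ V) / (np.linalg.norm(u) * norms)
    out = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    out[norms == 0] = np.nan
    return out


def topography_angle_profile(
    topography: np.ndarray,
    data: EpochedData,
    window_ms: tuple[float, float] = (0.0, 100.0),
) -> dict:
    """Angles between an artifact topography and the trial-averaged data.

    Returns the per-time-point angles inside the window and their 5th
    percentile (the "minimum angle" summary).
    """
    mask = data.time_mask(*window_ms)
    if not mask.any():
        raise ValueError(f"window {window_ms} contains no samples")
    avg = data.average()[:, mask]
    angles = signal_space_angles_deg(topography, avg)
    n_bad = int(np.isnan(angles).sum())
    if n_bad:
        warnings.warn(f"{n_bad} zero-norm time points excluded from angle profile")
    valid = angles[~np.isnan(angles)]
    return {
        "times_ms": data.times[mask],
        "angles_deg": angles,
        "p5_deg": float(np.percentile(valid, 5.0)),
        "n_excluded": n_bad,
    }


def median_minimum_angle(
    data: EpochedData,
    contrast: float,
    bank: ArtifactTopographyBank | None = None,
    window_ms: tuple[float, float] = (0.0, 100.0),
) -> float:
    """Median across the 9 artifact topographies of the 5th-percentile angle."""
    bank = bank or default_topography_bank()
    p5 = [
        topography_angle_profile(bank.topography(contrast, j), data, window_ms)["p5_deg"]
        for j in range(bank.sources.n_sources)
    ]
    return float(np.median(p5))


def condition_grid(
    amplitude_uv: float = 250.0,
    alphas: tuple[float, ...] = ALPHA_GRID,
    contrasts: tuple[float, ...] = headmodel.CONTRASTS,
) -> list[ArtifactCondition]:
    """The full crossing of variability and topography conditions."""
    return [
        ArtifactCondition(alpha=a, contrast=c, amplitude_uv=amplitude_uv)
        for a in alphas
        for c in contrasts
    ]
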