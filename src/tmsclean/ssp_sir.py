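"""Signal-space projection with source-informed reconstruction.

Pipeline: high-pass the data at 100 Hz (where evoked neuronal content is
assumed absent, so what survives is artifact plus noise), take the SVD of the
concatenated early window to get an orthonormal artifact basis, project the
selected dimension(s) out of the raw data, and re-estimate the neuronal
signals through a lead-field model to undo the spatial distortion the
projector introduces.  The cleaned segment is spliced back into the original
data inside the suppression window with a running-median blend at the seams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from ._signal import fir_filter_epochs
from .epochs import EpochedData
from .headmodel import LeadField

__all__ = [
    "ArtifactBasis",
    "Projector",
    "SIROperator",
    "CleaningResult",
    "highpass_filter",
    "estimate_artifact_basis",
    "select_artifact_dim",
    "make_projector",
    "make_sir_operator",
    "sir_reconstruct",
    "apply_windowed",
    "clean_dataset_ssp_sir",
]

HIGHPASS_HZ = 100.0
BASIS_WINDOW_MS = (-10.0, 30.0)
BLEND_MS = 10.0


@dataclass(frozen=True)
class ArtifactBasis:
    U: NDArray[np.float64]                # channels x channels, orthonormal
    singular_values: NDArray[np.float64]  # non-increasing
    selected_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        U = np.asarray(self.U, dtype=float)
        if np.linalg.norm(U.T @ U - np.eye(U.shape[1])) > 1e-8:
            raise ValueError("basis columns must be orthonormal")
        s = np.asarray(self.singular_values, dtype=float)
        if np.any(np.diff(s) > 1e-9 * max(s[0], 1.0)):
            raise ValueError("singular values must be non-increasing")

    @property
    def k(self) -> int:
        return len(self.selected_indices)


@dataclass(frozen=True)
class Projector:
    """Orthogonal projector onto the complement of the artifact subspace."""

    P: NDArray[np.float64]
    k: int

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if np.linalg.norm(P - P.T) > 1e-9 or np.linalg.norm(P @ P - P) > 1e-9:
            raise ValueError("projector must be symmetric and idempotent")


@dataclass(frozen=True)
class SIROperator:
    """Spatial filter M = L (PL)^+ P built with a truncated pseudoinverse."""

    M: NDArray[np.float64]
    truncation_rank: int
    sv_rel_threshold: float


def highpass_filter(data: EpochedData, cutoff_hz: float = HIGHPASS_HZ) -> EpochedData:
    """Zero-phase FIR high-pass of every channel and trial."""
    out = fir_filter_epochs(data.data, data.fs, cutoff_hz, "highpass")
    return data.copy_with(out, highpass_hz=cutoff_hz)


def estimate_artifact_basis(
    data: EpochedData, window_ms: tuple[float, float] = BASIS_WINDOW_MS
) -> ArtifactBasis:
    """SVD of the trial-concatenated channels x time matrix in the window.

    ``data`` should already be high-pass filtered; the left singular vectors
    span the candidate artifact topographies.
    """
    mask = data.time_mask(*window_ms)
    if not mask.any():
        raise ValueError(f"window {window_ms} contains no samples")
    X = data.data[:, mask, :]
    X = X.transpose(0, 2, 1).reshape(X.shape[0], -1)
    # rows (channels) < columns here, so the economy SVD already yields the
    # full channels x channels U
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    return ArtifactBasis(U, s)


def select_artifact_dim(
    basis: ArtifactBasis,
    known_topography: np.ndarray | None = None,
    k: int = 1,
) -> tuple[int, ...]:
    """Indices of the artifact dimensions to project out.

    Simulation mode (known topography given): the single singular vector with
    the largest absolute cosine similarity to the known artifact topography;
    ties break toward the lowest index.  General mode: the top ``k`` vectors
    by singular value.
    """
    if known_topography is None:
        return tuple(range(k))
    u = np.asarray(known_topography, dtype=float)
    if abs(np.linalg.norm(u) - 1.0) > 1e-6:
        raise ValueError("known topography must be unit norm")
    sims = np.abs(basis.U.T @ u)
    return (int(np.argmax(sims)),)


def make_projector(basis: ArtifactBasis, indices: tuple[int, ...]) -> Projector:
    """P = I - sum of outer products of the selected singular vectors."""
    n = basis.U.shape[0]
    if len(indices) >= n:
        raise ValueError("cannot project out every channel dimension")
    if any(not 0 <= i < n for i in indices):
        raise ValueError("invalid basis index")
    Uk = basis.U[:, list(indices)]
    P = np.eye(n) - Uk @ Uk.T
    return Projector(P, len(indices))


def make_sir_operator(
    projector: Projector, leadfield: LeadField, sv_rel_threshold: float = 1e-3
) -> SIROperator:
    """Assemble M = L (PL)^+ P, truncating small singular values of PL."""
    L = leadfield.gain
    if not np.any(L):
        raise ValueError("degenerate (all-zero) lead field")
    P = projector.P
    PL = P @ L
    U, s, Vt = np.linalg.svd(PL, full_matrices=False)
    keep = s >= sv_rel_threshold * s[0]
    rank = int(keep.sum())
    PL_pinv = (Vt[keep].T / s[keep]) @ U[:, keep].T
    M = L @ PL_pinv @ P
    return SIROperator(M, rank, sv_rel_threshold)


def sir_reconstruct(
    projector: Projector, leadfield: LeadField, data: EpochedData,
    sv_rel_threshold: float = 1e-3,
) -> EpochedData:
    """Apply the source-informed reconstruction filter to every sample."""
    if leadfield.gain.shape[0] != data.n_channels:
        raise ValueError("lead field channels do not match data")
    op = make_sir_operator(projector, leadfield, sv_rel_threshold)
    out = np.einsum("dc,csn->dsn", op.M, data.data)
    return data.copy_with(out, sir_truncation_rank=op.truncation_rank)


def _running_median(x: np.ndarray, half: int, lo: int, hi: int) -> np.ndarray:
    """Running median of the time axis of (channels, samples, trials) data,
    evaluated only for sample indices in [lo, hi)."""
    n = x.shape[1]
    out = np.empty((x.shape[0], hi - lo, x.shape[2]))
    for j, s in enumerate(range(lo, hi)):
        a, b = max(0, s - half), min(n, s + half + 1)
        out[:, j, :] = np.median(x[:, a:b, :], axis=1)
    return out


def apply_windowed(
    original: EpochedData,
    cleaned: EpochedData,
    window_ms: tuple[float, float] = BASIS_WINDOW_MS,
    blend_ms: float = BLEND_MS,
) -> EpochedData:
    """Use the cleaned data inside the window, the original outside.

    A running median of length ``blend_ms`` smooths the splice: it is applied
    to the correction signal (cleaned minus original, which is zero outside
    the window) over +-blend_ms/2 around each window edge, so the step the
    splice introduces is softened while identical inputs pass through
    bit-exactly.  Samples farther than blend_ms/2 + half-filter from any edge
    are bit-identical to their source segment.
    """
    if original.data.shape != cleaned.data.shape:
        raise ValueError("original and cleaned data shapes differ")
    mask = original.time_mask(*window_ms)
    if not mask.any():
        raise ValueError(f"window {window_ms} lies outside the epoch")
    diff = np.zeros_like(original.data)
    diff[:, mask, :] = cleaned.data[:, mask, :] - original.data[:, mask, :]
    out = original.data.copy()
    out[:, mask, :] = cleaned.data[:, mask, :]

    half = int(round(blend_ms * original.fs / 1000.0)) // 2  # odd length 2*half+1
    zone = int(round(blend_ms / 2.0 * original.fs / 1000.0))
    idx = np.flatnonzero(mask)
    edges = []
    if idx[0] > 0:
        edges.append(idx[0])
    if idx[-1] < mask.size - 1:
        edges.append(idx[-1] + 1)
    for e in edges:
        lo, hi = max(0, e - zone), min(mask.size, e + zone + 1)
        out[:, lo:hi, :] = original.data[:, lo:hi, :] + _running_median(
            diff, half, lo, hi
        )
    return original.copy_with(
        out, ssp_sir_window_ms=list(window_ms), blend_ms=blend_ms
    )


@dataclass
class CleaningResult:
    """Cleaned data plus provenance of the cleaning decision."""

    data: EpochedData
    method: str
    info: dict


def clean_dataset_ssp_sir(
    corrupted: EpochedData,
    leadfield: LeadField,
    known_topography: np.ndarray | None = None,
    window_ms: tuple[float, float] = BASIS_WINDOW_MS,
    blend_ms: float = BLEND_MS,
    highpass_hz: float = HIGHPASS_HZ,
    sv_rel_threshold: float = 1e-3,
) -> CleaningResult:
    """Full SSP-SIR cleaning of an epoched dataset.

    The artifact basis is estimated from all trials concatenated (the
    projector is then a single spatial filter, so per-trial application is
    the same linear map on every trial).  Data and lead field are
    average-referenced before projection so both live in the same reference
    frame.
    """
    spatial_mean = corrupted.data.mean(axis=0, keepdims=True)
    work = corrupted.copy_with(corrupted.data - spatial_mean)
    hp = highpass_filter(work, highpass_hz)
    basis = estimate_artifact_basis(hp, window_ms)
    indices = select_artifact_dim(basis, known_topography)
    projector = make_projector(basis, indices)
    cleaned = sir_reconstruct(projector, leadfield, work, sv_rel_threshold)
    blended = apply_windowed(work, cleaned, window_ms, blend_ms)
    # the projected topographies are average-referenced, so the spatial-mean
    # channel carries no artifact; restore it to stay in the input reference
    blended = blended.copy_with(blended.data + spatial_mean)
    info = {
        "k": len(indices),
        "selected_indices": list(indices),
        "projector_rank": corrupted.n_channels - len(indices),
        "singular_values": basis.singular_values,
    }
    if known_topography is not None:
        info["selection_abs_cos"] = float(
            abs(np.dot(basis.U[:, indices[0]], known_topography))
        )
    return CleaningResult(blended, "ssp_sir", info)
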