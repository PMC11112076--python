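"""ICA-based cleaning: FastICA on concatenated trials, single-component
subtraction.

The decomposition uses the symmetric (parallel) FastICA fixed-point scheme
with the tanh contrast after whitening.  In simulation mode the artifact
component is the one whose mixing-matrix column best matches the known
artifact topography (absolute cosine similarity); exactly one component is
removed per run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .epochs import EpochedData
from .ssp_sir import CleaningResult

__all__ = [
    "ICADecomposition",
    "concatenate_trials",
    "unconcatenate_trials",
    "fastica_decompose",
    "select_artifact_component",
    "remove_component",
    "clean_dataset_ica",
]


@dataclass
class ICADecomposition:
    """Mixing matrix, source time courses and the removed channel means.

    ``mixing @ sources + mean`` reconstructs the input matrix (up to the
    stated tolerance) when the component count equals the data rank.
    """

    mixing: NDArray[np.float64]   # channels x components
    sources: NDArray[np.float64]  # components x (samples*trials)
    mean: NDArray[np.float64]     # per-channel mean removed in centering
    converged: bool
    seed: int | None
    n_iter: int


def concatenate_trials(data: EpochedData) -> np.ndarray:
    """Trial-major channels x (samples*trials) matrix.

    Column order: all samples of trial 1, then trial 2, ...  The inverse is
    :func:`unconcatenate_trials`; the round trip is lossless.
    """
    n_ch, n_s, n_tr = data.data.shape
    return data.data.transpose(0, 2, 1).reshape(n_ch, n_s * n_tr)


def unconcatenate_trials(matrix: np.ndarray, n_samples: int) -> np.ndarray:
    n_ch, width = matrix.shape
    if width % n_samples:
        raise ValueError("matrix width is not a multiple of n_samples")
    n_tr = width // n_samples
    return matrix.reshape(n_ch, n_tr, n_samples).transpose(0, 2, 1)


def fastica_decompose(
    matrix: np.ndarray,
    n_components: int = 60,
    seed: int | None = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
    fit_stride: int | None = None,
) -> ICADecomposition:
    """Symmetric FastICA with tanh contrast on a channels x time matrix.

    If the data rank is below ``n_components`` the component count is reduced
    with a warning.  ``fit_stride`` estimates the unmixing on every
    ``fit_stride``-th column (the model treats columns as iid, so subsampled
    estimation is statistically equivalent) and then applies it to all
    columns; ``None`` picks a stride capping the fit at ~45k columns.
    """
    X = np.asarray(matrix, dtype=float)
    n_ch, n_cols = X.shape
    rank = np.linalg.matrix_rank(X - X.mean(axis=1, keepdims=True))
    if rank < n_components:
        warnings.warn(
            f"data rank {rank} < requested {n_components} components; reducing"
        )
        n_components = rank
    if fit_stride is None:
        fit_stride = max(1, n_cols // 45_000)

    ica = FastICA(
        n_components=n_components,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ica.fit(X[:, ::fit_stride].T)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False

    mean = ica.mean_.copy()
    sources = ica.transform(X.T).T  # components x columns, full data
    mixing = ica.mixing_.copy()
    return ICADecomposition(
        mixing=mixing,
        sources=sources,
        mean=mean,
        converged=converged,
        seed=seed,
        n_iter=int(ica.n_iter_),
    )


def select_artifact_component(
    decomp: ICADecomposition, known_topography: np.ndarray
) -> int:
    """Index of the mixing column most similar (|cos|) to the topography."""
    u = np.asarray(known_topography, dtype=float)
    if abs(np.linalg.norm(u) - 1.0) > 1e-6:
        raise ValueError("known topography must be unit norm")
    A = decomp.mixing
    norms = np.linalg.norm(A, axis=0)
    sims = np.abs(u @ A) / np.where(norms > 0, norms, 1.0)
    return int(np.argmax(sims))  # argmax takes the lowest index on ties


def remove_component(
    data: EpochedData, decomp: ICADecomposition, index: int
) -> CleaningResult:
    """Subtract one component's spatiotemporal contribution from the data."""
    if not 0 <= index < decomp.mixing.shape[1]:
        raise ValueError("component index out of range")
    contribution = np.outer(decomp.mixing[:, index], decomp.sources[index])
    cleaned = concatenate_trials(data) - contribution
    out = data.copy_with(
        unconcatenate_trials(cleaned, data.n_samples),
        ica_removed_component=index,
    )
    return CleaningResult(out, "ica", {"removed_index": index})


def clean_dataset_ica(
    corrupted: EpochedData,
    known_topography: np.ndarray,
    seed: int | None = 0,
    n_components: int = 60,
    max_iter: int = 1000,
    tol: float = 1e-6,
    fit_stride: int | None = None,
) -> CleaningResult:
    """FastICA cleaning: decompose, match one component, subtract it."""
    X = concatenate_trials(corrupted)
    decomp = fastica_decompose(
        X, n_components=min(n_components, corrupted.n_channels),
        seed=seed, max_iter=max_iter, tol=tol, fit_stride=fit_stride,
    )
    idx = select_artifact_component(decomp, known_topography)
    result = remove_component(corrupted, decomp, idx)
    A = decomp.mixing[:, idx]
    result.info.update(
        converged=decomp.converged,
        n_iter=decomp.n_iter,
        selection_abs_cos=float(
            abs(np.dot(A / np.linalg.norm(A), known_topography))
        ),
    )
    return result
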