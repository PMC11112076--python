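"""Three-layer concentric-sphere EEG forward model.

Provides the idealized 10-20 electrode montage, a layered spherical conductor
solved per spherical-harmonic order, lead-field assembly, and the fixed set of
nine right-lateral tangential dipoles used to draw artifact topographies.

Conventions: head-centred Cartesian coordinates, +x right, +y anterior,
+z superior.  Electrode positions are unit vectors on the scalp sphere; dipole
positions are in millimetres; lead-field gains are in microvolts per nA*m of
dipole moment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "ElectrodeMontage",
    "SphericalHeadModel",
    "SourceSpace",
    "LeadField",
    "ConvergenceError",
    "CONTRASTS",
    "build_montage_1020",
    "perturb_montage",
    "forward_potential",
    "compute_leadfield",
    "sample_artifact_sources",
    "shell_source_space",
]

#: Skull-to-skin/brain conductivity contrasts of the condition grid.
CONTRASTS: tuple[float, ...] = (1.0,) + tuple(1.0 / x for x in range(20, 201, 20))

_BASE_CONDUCTIVITY_S_M = 0.33  # absolute brain conductivity behind the relative units


class ConvergenceError(RuntimeError):
    """Raised when the truncated harmonic series has not converged."""


# --------------------------------------------------------------------------
# Montage
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ElectrodeMontage:
    """Named electrode positions on the unit scalp sphere."""

    labels: tuple[str, ...]
    positions: NDArray[np.float64]  # (n_channels, 3), unit norm

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_labels, 3)")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("electrode positions must be unit vectors")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def subset(self, labels: list[str]) -> "ElectrodeMontage":
        idx = [self.index(lab) for lab in labels]
        return ElectrodeMontage(tuple(labels), self.positions[idx])

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("label,x,y,z\n")
            for lab, p in zip(self.labels, self.positions):
                fh.write(f"{lab},{p[0]:.12f},{p[1]:.12f},{p[2]:.12f}\n")

    @staticmethod
    def from_csv(path) -> "ElectrodeMontage":
        labels, rows = [], []
        with open(path) as fh:
            header = fh.readline().strip().split(",")
            if header != ["label", "x", "y", "z"]:
                raise ValueError("montage CSV must have header label,x,y,z")
            for line in fh:
                parts = line.strip().split(",")
                if len(parts) != 4:
                    continue
                labels.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        return ElectrodeMontage(tuple(labels), np.asarray(rows))


def _sph(inclination_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit vector from inclination (angle from Cz) and azimuth (from anterior
    midline, positive to the right)."""
    th = np.deg2rad(inclination_deg)
    az = np.deg2rad(azimuth_deg)
    return np.array([np.sin(th) * np.sin(az), np.sin(th) * np.cos(az), np.cos(th)])


# Outer ring: the 10% circle at 72 deg inclination, 18 deg azimuth steps.
_RING_AZIMUTH = {
    "Fpz": 0, "Fp2": 18, "AF8": 36, "F8": 54, "FT8": 72, "T8": 90,
    "TP8": 108, "P8": 126, "PO8": 144, "O2": 162, "Oz": 180,
    "O1": -162, "PO7": -144, "P7": -126, "TP7": -108, "T7": -90,
    "FT7": -72, "F7": -54, "AF7": -36, "Fp1": -18,
}

# Midline: (inclination, azimuth)
_MIDLINE = {
    "Fpz": (72, 0), "AFz": (54, 0), "Fz": (36, 0), "FCz": (18, 0), "Cz": (0, 0),
    "CPz": (18, 180), "Pz": (36, 180), "POz": (54, 180), "Oz": (72, 180),
}

# Interior rows: (left ring endpoint, midline label, right ring endpoint,
#                 interior labels left->right excluding endpoints/midline)
_ROWS = [
    ("AF7", "AFz", "AF8", ["AF3"], ["AF4"]),
    ("F7", "Fz", "F8", ["F5", "F3", "F1"], ["F2", "F4", "F6"]),
    ("FT7", "FCz", "FT8", ["FC5", "FC3", "FC1"], ["FC2", "FC4", "FC6"]),
    ("T7", "Cz", "T8", ["C5", "C3", "C1"], ["C2", "C4", "C6"]),
    ("TP7", "CPz", "TP8", ["CP5", "CP3", "CP1"], ["CP2", "CP4", "CP6"]),
    ("P7", "Pz", "P8", ["P5", "P3", "P1"], ["P2", "P4", "P6"]),
    ("PO7", "POz", "PO8", ["PO3"], ["PO4"]),
]

_MONTAGE_30_LABELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "PO3", "PO4", "O1", "Oz", "O2",
]


def _arc_interior(p_end: np.ndarray, p_mid: np.ndarray, n_interior: int) -> list[np.ndarray]:
    """Equally spaced points on the circular arc from ``p_end`` to ``p_mid``.

    The arc lies on the circle cut by the plane through the row's three
    defining electrodes; for interior rows that circle is a great circle only
    for the central (C) row.  Points are returned end -> mid, exclusive.
    """
    # The full row circle is defined by (left, mid, right); by left/right
    # mirror symmetry (x -> -x) its centre lies in the x=0-mirrored pair, so
    # interpolating each half independently on the end--mid plane-circle is
    # equivalent to equal division of the full arc.  We compute the circle
    # through p_end, p_mid and the mirror of p_end.
    p_other = p_end * np.array([-1.0, 1.0, 1.0])
    a, b, c = p_end, p_mid, p_other
    n = np.cross(b - a, c - a)
    nn = np.dot(n, n)
    center = a + (
        np.dot(c - a, c - a) * np.cross(np.cross(b - a, c - a), b - a)
        + np.dot(b - a, b - a) * np.cross(c - a, np.cross(b - a, c - a))
    ) / (2.0 * nn)
    e1 = a - center
    rho = np.linalg.norm(e1)
    e1 = e1 / rho
    axis = n / np.sqrt(nn)
    e2 = np.cross(axis, e1)
    ang_mid = np.arctan2(np.dot(b - center, e2), np.dot(b - center, e1))
    if ang_mid < 0:  # orient so the arc end->mid has positive angle
        e2, ang_mid = -e2, -ang_mid
    pts = []
    for k in range(1, n_interior + 1):
        ang = ang_mid * k / (n_interior + 1)
        p = center + rho * (np.cos(ang) * e1 + np.sin(ang) * e2)
        pts.append(p / np.linalg.norm(p))
    return pts


def _full_grid() -> dict[str, np.ndarray]:
    pos: dict[str, np.ndarray] = {}
    for lab, az in _RING_AZIMUTH.items():
        pos[lab] = _sph(72, az)
    for lab, (inc, az) in _MIDLINE.items():
        pos[lab] = _sph(inc, az)
    for left, mid, right, llabs, rlabs in _ROWS:
        # arc points run endpoint -> midline; llabs are listed lateral->medial,
        # rlabs medial->lateral
        for lab, p in zip(llabs, _arc_interior(pos[left], pos[mid], len(llabs))):
            pos[lab] = p
        for lab, p in zip(rlabs[::-1], _arc_interior(pos[right], pos[mid], len(rlabs))):
            pos[lab] = p
    return pos


def _montage_60_labels() -> list[str]:
    grid = _full_grid()
    order = [lab for lab in grid if lab != "AFz"]
    # stable anterior-to-posterior, left-to-right ordering
    def key(lab):
        p = grid[lab]
        return (-round(p[1], 6), round(p[0], 6))
    return sorted(order, key=key)


def build_montage_1020(n_channels: int = 60) -> ElectrodeMontage:
    """Deterministic idealized 10-20/10-10 montage.

    Supports the default 60-channel layout (full 10-10 grid minus AFz and Iz)
    and a standard 30-channel subset used for montage-extrapolation tests.
    """
    grid = _full_grid()
    if n_channels == 60:
        labels = _montage_60_labels()
    elif n_channels == 30:
        labels = list(_MONTAGE_30_LABELS)
    else:
        raise ValueError(f"unsupported channel count: {n_channels} (use 60 or 30)")
    positions = np.array([grid[lab] for lab in labels])
    positions /= np.linalg.norm(positions, axis=1, keepdims=True)
    return ElectrodeMontage(tuple(labels), positions)


def perturb_montage(
    montage: ElectrodeMontage, jitter_mm: float, scalp_radius_mm: float, seed: int
) -> ElectrodeMontage:
    """Tangentially jitter electrodes by ~``jitter_mm`` on the scalp sphere.

    Used to build a second, slightly different head model so that artifact
    topographies and the reconstruction model do not share an identical
    forward solution.
    """
    rng = np.random.default_rng(seed)
    pos = montage.positions.copy()
    for i in range(pos.shape[0]):
        r = pos[i]
        # random tangential direction
        v = rng.standard_normal(3)
        v -= np.dot(v, r) * r
        v /= np.linalg.norm(v)
        ang = jitter_mm / scalp_radius_mm
        pos[i] = np.cos(ang) * r + np.sin(ang) * v
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return ElectrodeMontage(montage.labels, pos)


# --------------------------------------------------------------------------
# Head model and forward solution
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SphericalHeadModel:
    """Three concentric spheres (brain, skull, scalp).

    ``conductivities`` are relative (brain = scalp = 1 by convention); the
    absolute scale is fixed internally so gains come out in μV per nA*m.
    """

    radii_mm: tuple[float, float, float] = (80.0, 85.0, 92.0)
    conductivities: tuple[float, float, float] = (1.0, 1.0 / 50.0, 1.0)
    series_terms: int = 60

    def __post_init__(self) -> None:
        r = self.radii_mm
        if not (r[0] < r[1] < r[2]):
            raise ValueError("radii must be strictly increasing")
        if min(self.conductivities) <= 0:
            raise ValueError("conductivities must be positive")
        if self.series_terms < 20:
            raise ValueError("series_terms must be >= 20")

    def with_skull_contrast(self, contrast: float) -> "SphericalHeadModel":
        return replace(self, conductivities=(1.0, float(contrast), 1.0))


def _surface_transfer(model: SphericalHeadModel, b_scaled: float) -> np.ndarray:
    """Per-order surface-potential coefficients T_n, n = 1..series_terms.

    Solves, for each harmonic order, the boundary-value problem of the
    three-layer sphere (radii scaled to the scalp radius) with a unit
    interior-source coefficient b^(n-1); T_n multiplies
    [n m_r P_n + m_t P_n^1 cos(phi)] in the surface potential.
    """
    s1, s2, s3 = model.conductivities
    r1, r2, _ = (np.asarray(model.radii_mm) / model.radii_mm[2]).tolist()
    N = model.series_terms
    T = np.empty(N)
    for n in range(1, N + 1):
        src = b_scaled ** (n - 1)
        # unknowns: A1, A2, B2, A3, B3
        A = np.zeros((5, 5))
        rhs = np.zeros(5)
        # V continuous at r1
        A[0] = [r1**n, -(r1**n), -(r1 ** -(n + 1)), 0, 0]
        rhs[0] = -src * r1 ** -(n + 1)
        # sigma dV/dr continuous at r1
        A[1] = [
            s1 * n * r1 ** (n - 1),
            -s2 * n * r1 ** (n - 1),
            s2 * (n + 1) * r1 ** -(n + 2),
            0,
            0,
        ]
        rhs[1] = s1 * (n + 1) * src * r1 ** -(n + 2)
        # V continuous at r2
        A[2] = [0, r2**n, r2 ** -(n + 1), -(r2**n), -(r2 ** -(n + 1))]
        # sigma dV/dr continuous at r2
        A[3] = [
            0,
            s2 * n * r2 ** (n - 1),
            -s2 * (n + 1) * r2 ** -(n + 2),
            -s3 * n * r2 ** (n - 1),
            s3 * (n + 1) * r2 ** -(n + 2),
        ]
        # insulating outer surface (rho = 1)
        A[4] = [0, 0, 0, n, -(n + 1)]
        x = np.linalg.solve(A, rhs)
        T[n - 1] = x[3] + x[4]  # A3 + B3 at rho = 1
    return T


def _legendre_terms(cosg: np.ndarray, n_terms: int) -> tuple[np.ndarray, np.ndarray]:
    """P_n(cosg) and sin(g)*P_n'(cosg) for n = 1..n_terms, vectorized.

    The second factor equals the associated Legendre function P_n^1 without
    the Condon-Shortley phase, which is the convention the dipole expansion
    uses.
    """
    x = cosg
    sing = np.sqrt(np.clip(1.0 - x * x, 0.0, None))
    P = np.empty((n_terms + 1,) + x.shape)
    dP = np.empty_like(P)
    P[0], dP[0] = 1.0, 0.0
    P[1], dP[1] = x, 1.0
    for n in range(1, n_terms):
        P[n + 1] = ((2 * n + 1) * x * P[n] - n * P[n - 1]) / (n + 1)
        dP[n + 1] = dP[n - 1] + (2 * n + 1) * P[n]
    return P[1:], sing * dP[1:]


def _forward_many(
    model: SphericalHeadModel,
    dipole_pos_mm: np.ndarray,
    dipole_moment: np.ndarray,
    electrode_pos: np.ndarray,
    check_convergence: bool = True,
) -> np.ndarray:
    """Potentials (μV) at unit-sphere electrode positions for one dipole."""
    p = np.asarray(dipole_pos_mm, dtype=float)
    m = np.asarray(dipole_moment, dtype=float)
    E = np.atleast_2d(np.asarray(electrode_pos, dtype=float))
    R1, _, R3 = model.radii_mm
    b = float(np.linalg.norm(p))
    if b >= R1:
        raise ValueError("dipole must lie strictly inside the brain sphere")
    if not np.any(m):
        return np.zeros(E.shape[0])
    if b < 1e-9:
        rhat = np.array([0.0, 0.0, 1.0])
        m_r = 0.0
    else:
        rhat = p / b
        m_r = float(np.dot(m, rhat))
    t_vec = m - m_r * rhat
    m_t = float(np.linalg.norm(t_vec))
    that = t_vec / m_t if m_t > 1e-15 * np.linalg.norm(m) else np.zeros(3)

    cosg = np.clip(E @ rhat, -1.0, 1.0)
    e_t = E - np.outer(cosg, rhat)
    e_norm = np.linalg.norm(e_t, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosphi = np.where(e_norm > 1e-12, (e_t @ that) / np.where(e_norm > 0, e_norm, 1.0), 0.0)

    T = _surface_transfer(model, b / R3)
    Pn, Pn1 = _legendre_terms(cosg, model.series_terms)
    n_idx = np.arange(1, model.series_terms + 1)[:, None]
    terms = T[:, None] * (n_idx * m_r * Pn + m_t * cosphi[None, :] * Pn1)
    series = terms.sum(axis=0)
    if check_convergence:
        tail = np.max(np.abs(terms[-1]))
        scale = max(np.max(np.abs(series)), 1e-300)
        if tail / scale > 1e-3:
            raise ConvergenceError(
                f"harmonic series not converged at {model.series_terms} terms "
                f"(tail/series = {tail / scale:.2e}); increase series_terms or "
                "move the dipole deeper"
            )
    sigma_si = _BASE_CONDUCTIVITY_S_M * model.conductivities[0]
    r3_m = R3 * 1e-3
    # moment in nA*m, output in μV
    return series * 1e-9 / (4.0 * np.pi * sigma_si * r3_m**2) * 1e6


def forward_potential(
    model: SphericalHeadModel,
    dipole_pos_mm,
    dipole_moment,
    electrode_pos,
) -> float:
    """Scalp potential (μV) of a single dipole at a single electrode.

    ``dipole_pos_mm`` in mm inside the brain sphere; ``dipole_moment`` in
    nA*m; ``electrode_pos`` a unit vector on the scalp sphere.
    """
    out = _forward_many(model, dipole_pos_mm, dipole_moment, np.atleast_2d(electrode_pos))
    return float(out[0])


# --------------------------------------------------------------------------
# Source spaces and lead fields
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SourceSpace:
    """Dipole positions (mm) and unit orientations, one dipole per row."""

    positions_mm: NDArray[np.float64]
    orientations: NDArray[np.float64]

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions_mm, dtype=float))
        ori = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        if pos.shape != ori.shape or pos.shape[1] != 3:
            raise ValueError("positions and orientations must both be (n, 3)")
        if not np.allclose(np.linalg.norm(ori, axis=1), 1.0, atol=1e-9):
            raise ValueError("orientations must be unit vectors")
        object.__setattr__(self, "positions_mm", pos)
        object.__setattr__(self, "orientations", ori)

    @property
    def n_sources(self) -> int:
        return self.positions_mm.shape[0]


@dataclass(frozen=True)
class LeadField:
    """Gain matrix (channels x sources, μV per nA*m)."""

    gain: NDArray[np.float64]
    montage: ElectrodeMontage
    source_space: SourceSpace
    average_reference: bool = True

    def __post_init__(self) -> None:
        g = np.asarray(self.gain, dtype=float)
        if not np.all(np.isfinite(g)):
            raise ValueError("lead field contains non-finite entries")
        if g.shape != (self.montage.n_channels, self.source_space.n_sources):
            raise ValueError("gain shape does not match montage/source space")
        if self.average_reference and np.max(np.abs(g.sum(axis=0))) > 1e-9 * max(
            1.0, np.max(np.abs(g))
        ):
            raise ValueError("average-referenced gain columns must sum to 0")
        object.__setattr__(self, "gain", g)


def compute_leadfield(
    model: SphericalHeadModel,
    source_space: SourceSpace,
    montage: ElectrodeMontage,
    average_reference: bool = True,
) -> LeadField:
    """Assemble the gain matrix column by column from the forward solution."""
    n_ch, n_src = montage.n_channels, source_space.n_sources
    gain = np.empty((n_ch, n_src))
    for j in range(n_src):
        gain[:, j] = _forward_many(
            model,
            source_space.positions_mm[j],
            source_space.orientations[j],
            montage.positions,
        )
    if average_reference:
        gain -= gain.mean(axis=0, keepdims=True)
    return LeadField(gain, montage, source_space, average_reference)


def _tangent_basis(rhat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(rhat, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(ref, rhat)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(rhat, e1)
    return e1, e2


def sample_artifact_sources(seed: int, radius_mm: float = 70.0) -> SourceSpace:
    """Nine superficial, right-lateral, tangentially oriented dipoles.

    Positions form a 3x3 angular fan over the right side of the head with a
    small seeded jitter; tangential orientation angles are drawn from the
    seeded generator.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    positions, orientations = [], []
    for inc in (55.0, 75.0, 95.0):          # from vertex: upper to ear level
        for az in (55.0, 90.0, 125.0):      # from anterior midline, right side
            inc_j = inc + rng.uniform(-4.0, 4.0)
            az_j = az + rng.uniform(-4.0, 4.0)
            rhat = _sph(inc_j, az_j)
            e1, e2 = _tangent_basis(rhat)
            psi = rng.uniform(0.0, 2.0 * np.pi)
            ori = np.cos(psi) * e1 + np.sin(psi) * e2
            positions.append(radius_mm * rhat)
            orientations.append(ori / np.linalg.norm(ori))
    pos = np.array(positions)
    assert np.all(pos[:, 0] > 0.0)  # all on the right by construction
    return SourceSpace(pos, np.array(orientations))


def shell_source_space(n_points: int = 200, radius_mm: float = 70.0) -> SourceSpace:
    """Fibonacci-spiral shell of free-orientation dipoles (3 per location).

    This is the generic source model used for source-informed reconstruction
    and minimum-norm extrapolation.
    """
    i = np.arange(n_points)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    theta = 2.0 * np.pi * i / golden
    rho = np.sqrt(1.0 - z * z)
    dirs = np.stack([rho * np.cos(theta), rho * np.sin(theta), z], axis=1)
    pos = np.repeat(radius_mm * dirs, 3, axis=0)
    ori = np.tile(np.eye(3), (n_points, 1))
    return SourceSpace(pos, ori)
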