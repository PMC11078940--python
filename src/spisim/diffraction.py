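"""Reciprocal-space diffraction intensities from damage snapshots.

Intensities are formed on an oversampled cubic q-grid in Thomson units
(single-electron scattering = 1):

    I(q) = |Σ_j f_j(q) e^{i q·r_j}|²  +  Σ_j S_j(q)  +  N_free,

where f_j is the (damage-modified) elastic form factor of atom j's current
ion state, S_j its incoherent scattering function, and every free electron
inside the sampling box contributes one Thomson unit of structureless
background.  The undamaged reference keeps only the coherent term with
neutral form factors.  Polarization and obliquity factors are left out of
reciprocal-space volumes and applied only when projecting onto a detector.

The full-period resolution convention d = 2π/q is used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import h5py
import numpy as np
from numba import njit
from .atomic_data import IonState, bound_form_factor, incoherent_scattering_function
from .constants import HC_KEV_A, R_E_SQ
from .dynamics import Trajectory
from .molecule_io import AtomRecords
from .pulse import PulseProfile, interval_weights


@dataclass(frozen=True)
class ReciprocalGrid:
    """Cubic, zero-centred q-grid with odd per-axis voxel count."""

    dq: float           # Å⁻¹ voxel spacing, 2π/(s·D)
    q_edge: float       # Å⁻¹, 2π/d_edge
    oversampling: float
    extent: float       # D, molecule extent (Å)
    d_edge: float       # edge full-period resolution (Å)

    @property
    def n_half(self) -> int:
        return int(math.ceil(self.q_edge / self.dq))

    @property
    def n_per_axis(self) -> int:
        return 2 * self.n_half + 1

    @property
    def axis(self) -> np.ndarray:
        return self.dq * np.arange(-self.n_half, self.n_half + 1)

    @property
    def shape(self) -> tuple[int, int, int]:
        n = self.n_per_axis
        return (n, n, n)

    def q_magnitude(self) -> np.ndarray:
        ax = self.axis
        return np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2
                       + ax[None, None, :] ** 2)


@dataclass
class IntensityVolume:
    """Per-voxel intensity (Thomson units) on a :class:`ReciprocalGrid`."""

    grid: ReciprocalGrid
    intensity: np.ndarray
    normalization: str = "raw"    # "raw" or "per_incident_photon"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.grid.shape:
            raise ValueError("intensity shape does not match grid")
        if self.intensity.min() < 0:
            raise ValueError("negative intensity")

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("intensity", data=self.intensity)
            d.attrs["normalization"] = self.normalization
            for k in ("dq", "q_edge", "oversampling", "extent", "d_edge"):
                d.attrs[k] = getattr(self.grid, k)

    @classmethod
    def from_hdf5(cls, path) -> "IntensityVolume":
        with h5py.File(path, "r") as f:
            d = f["intensity"]
            grid = ReciprocalGrid(*(float(d.attrs[k]) for k in
                                    ("dq", "q_edge", "oversampling", "extent", "d_edge")))
            return cls(grid, d[()], str(d.attrs["normalization"]))


def build_qgrid(D: float, oversampling: float, d_edge: float) -> ReciprocalGrid:
    """Oversampled cubic grid: Δq = 2π/(s·D), |q| up to q_edge = 2π/d_edge."""
    if not (D > d_edge > 0):
        raise ValueError("need extent D > edge resolution d_edge > 0")
    if oversampling < 1:
        raise ValueError("oversampling must be ≥ 1")
    return ReciprocalGrid(
        dq=2.0 * math.pi / (oversampling * D),
        q_edge=2.0 * math.pi / d_edge,
        oversampling=oversampling,
        extent=D,
        d_edge=d_edge,
    )


# ---------------------------------------------------------------------------
# structure factors


@njit(cache=True)
def _group_structure_factors(pos, group, n_groups, ax):
    """Σ_{j∈g} e^{i q·r_j} per group on the cubic grid, via separable phases."""
    m = ax.shape[0]
    F = np.zeros((n_groups, m, m, m), dtype=np.complex128)
    ex = np.empty(m, dtype=np.complex128)
    ey = np.empty(m, dtype=np.complex128)
    ez = np.empty(m, dtype=np.complex128)
    for j in range(pos.shape[0]):
        g = group[j]
        for i in range(m):
            ex[i] = np.exp(1j * ax[i] * pos[j, 0])
            ey[i] = np.exp(1j * ax[i] * pos[j, 1])
            ez[i] = np.exp(1j * ax[i] * pos[j, 2])
        for a in range(m):
            exa = ex[a]
            for b in range(m):
                exy = exa * ey[b]
                for c in range(m):
                    F[g, a, b, c] += exy * ez[c]
    return F


def _ion_groups(elem_idx, occupations, elements):
    """Group atoms by (element, bound count); return labels and IonStates."""
    bound = occupations.sum(axis=1)
    keys = elem_idx * 1000 + bound
    uniq, group = np.unique(keys, return_inverse=True)
    states = []
    for key in uniq:
        e, nb = int(key) // 1000, int(key) % 1000
        el = elements[e]
        # a representative occupation vector with the right bound count:
        # fill from the innermost shell (only f(0)=n_bound matters here)
        occ = []
        left = nb
        for full in el.neutral_occupations:
            take = min(full, left)
            occ.append(take)
            left -= take
        states.append(IonState(el, tuple(occ)))
    return group, states


def _intensity_from_atoms(pos, group, states, grid: ReciprocalGrid,
                          n_free_inside: int = 0, coherent_only: bool = False
                          ) -> np.ndarray:
    qmag = grid.q_magnitude()
    F = _group_structure_factors(np.ascontiguousarray(pos, dtype=np.float64),
                                 np.ascontiguousarray(group, dtype=np.int64),
                                 len(states), grid.axis)
    amp = np.zeros(grid.shape, dtype=np.complex128)
    compton = np.zeros(grid.shape)
    for g, st in enumerate(states):
        amp += bound_form_factor(st, qmag) * F[g]
        if not coherent_only:
            counts = int((group == g).sum())
            compton += counts * incoherent_scattering_function(st, qmag)
    I = np.abs(amp) ** 2
    if not coherent_only:
        I += compton + float(n_free_inside)
    return I


def _free_electrons_inside(epos: np.ndarray, center: np.ndarray,
                           grid: ReciprocalGrid) -> int:
    """Free electrons within the real-space sampling box (side s·D)."""
    if len(epos) == 0:
        return 0
    half = grid.oversampling * grid.extent / 2.0
    inside = np.all(np.abs(epos - center) <= half, axis=1)
    return int(inside.sum())


def snapshot_intensity(traj: Trajectory, k: int, grid: ReciprocalGrid,
                       frame: str = "reference") -> IntensityVolume:
    """Damage-modified intensity of snapshot ``k`` of a trajectory.

    ``frame="reference"`` rotates positions back to the unrotated molecular
    frame so that volumes from differently oriented realizations share one
    frame; ``frame="lab"`` uses the positions as simulated.
    """
    if frame == "reference":
        pos = traj.positions_in_reference_frame(k)
        epos = traj.electrons_in_reference_frame(k)
    elif frame == "lab":
        pos = traj.positions[k]
        epos = traj.electron_positions[k]
    else:
        raise ValueError(f"unknown frame {frame!r}")
    group, states = _ion_groups(traj.elem_idx, traj.occupations[k], traj.elements)
    nfree = _free_electrons_inside(epos, traj.rotation_center, grid)
    I = _intensity_from_atoms(pos, group, states, grid, nfree)
    return IntensityVolume(grid, I, "raw")


def ideal_intensity(records: AtomRecords, grid: ReciprocalGrid, table
                    ) -> IntensityVolume:
    """Elastic-only intensity of the undamaged, neutral molecule."""
    from .atomic_data import element_data

    symbols = sorted(set(records.symbols.tolist()))
    elements = tuple(element_data(table, s) for s in symbols)
    elem_idx = np.array([symbols.index(s) for s in records.symbols])
    occ = np.array([elements[i].neutral_occupations +
                    (0,) * (max(e.n_shells for e in elements) - elements[i].n_shells)
                    for i in elem_idx])
    group, states = _ion_groups(elem_idx, occ, elements)
    I = _intensity_from_atoms(records.coords, group, states, grid,
                              coherent_only=True)
    return IntensityVolume(grid, I, "raw")


def time_integrated_intensity(traj: Trajectory, pulse: PulseProfile,
                              grid: ReciprocalGrid, frame: str = "reference"
                              ) -> IntensityVolume:
    """Pulse-weighted sum of snapshot intensities per incident photon.

    Each snapshot is weighted by the photon content of its equal-photon
    interval; the sum is divided by the total photon count.
    """
    w = interval_weights(pulse, traj.n_snapshots)
    if len(w) != traj.n_snapshots:
        raise ValueError("snapshot count does not match weight count")
    acc = np.zeros(grid.shape)
    for k in range(traj.n_snapshots):
        acc += w[k] * snapshot_intensity(traj, k, grid, frame).intensity
    return IntensityVolume(grid, acc / pulse.total_photons, "per_incident_photon")


def random_rotation(seed: int) -> np.ndarray:
    """Uniform random rotation on SO(3) as a unit quaternion (x, y, z, w)."""
    rng = np.random.default_rng(seed)
    u1, u2, u3 = rng.random(3)
    # Shoemake's subgroup-algorithm construction
    a, b = math.sqrt(1.0 - u1), math.sqrt(u1)
    return np.array([a * math.sin(2 * math.pi * u2),
                     a * math.cos(2 * math.pi * u2),
                     b * math.sin(2 * math.pi * u3),
                     b * math.cos(2 * math.pi * u3)])


# ---------------------------------------------------------------------------
# detector projection


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat detector downstream of the interaction point."""

    distance_m: float
    pixel_pitch_um: float
    n_pixels: tuple[int, int]
    photon_energy_keV: float

    def pixel_q(self) -> np.ndarray:
        """Scattering vector (Å⁻¹) of each pixel on the Ewald sphere."""
        ny, nx = self.n_pixels
        pitch = self.pixel_pitch_um * 1e-6
        ys = (np.arange(ny) - (ny - 1) / 2.0) * pitch
        xs = (np.arange(nx) - (nx - 1) / 2.0) * pitch
        X, Y = np.meshgrid(xs, ys)
        L = self.distance_m
        norm = np.sqrt(X**2 + Y**2 + L**2)
        k = 2.0 * math.pi * self.photon_energy_keV / HC_KEV_A
        q = np.stack([k * X / norm, k * Y / norm, k * (L / norm - 1.0)], axis=-1)
        return q

    def solid_angles(self) -> np.ndarray:
        """Pixel solid angle with the cos³θ obliquity factor."""
        ny, nx = self.n_pixels
        pitch = self.pixel_pitch_um * 1e-6
        ys = (np.arange(ny) - (ny - 1) / 2.0) * pitch
        xs = (np.arange(nx) - (nx - 1) / 2.0) * pitch
        X, Y = np.meshgrid(xs, ys)
        L = self.distance_m
        cos3 = (L / np.sqrt(X**2 + Y**2 + L**2)) ** 3
        return pitch**2 / L**2 * cos3


def detector_image(volume: IntensityVolume, geometry: DetectorGeometry,
                   fluence: float, rng: np.random.Generator | None = None,
                   polarization: str = "x") -> tuple[np.ndarray, np.ndarray]:
    """Expected and Poisson-sampled photon counts on a detector.

    ``fluence`` is the time-integrated photon fluence (photons/Å²).  The
    intensity volume is interpolated on the Ewald sphere and multiplied by
    the Thomson cross section, pixel solid angle and polarization factor.
    Returns ``(expected, counts)``.
    """
    from scipy.interpolate import RegularGridInterpolator

    q = geometry.pixel_q()
    ax = volume.grid.axis
    interp = RegularGridInterpolator((ax, ax, ax), volume.intensity,
                                     bounds_error=False, fill_value=0.0)
    I_q = interp(q.reshape(-1, 3)).reshape(q.shape[:2])
    k = 2.0 * math.pi * geometry.photon_energy_keV / HC_KEV_A
    sin2 = np.clip((q[..., 0] ** 2 + q[..., 1] ** 2 + q[..., 2] ** 2)
                   / (4.0 * k**2), 0.0, 1.0)
    cos_t = 1.0 - 2.0 * sin2              # cos 2θ_scatt via |q| = 2k sin θ
    if polarization == "x":
        # horizontal linear polarization: 1 − sin²(2θ)cos²φ approximated
        phi = np.arctan2(q[..., 1], q[..., 0])
        pol = 1.0 - (1.0 - cos_t**2) * np.cos(phi) ** 2
    else:
        pol = 0.5 * (1.0 + cos_t**2)       # unpolarized
    expected = I_q * R_E_SQ * geometry.solid_angles() * fluence * pol
    rng = rng or np.random.default_rng()
    counts = rng.poisson(expected)
    return expected, counts
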