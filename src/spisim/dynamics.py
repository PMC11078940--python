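"""Stochastic ionization dynamics coupled to Coulomb-only MD.

One *realization* evolves a molecule through an X-ray pulse: a Monte-Carlo
scheme fires photoionization, Auger decay and electron-impact (collisional)
ionization events, while classical molecular dynamics propagates all
charged particles under mutually repulsive softened Coulomb forces.
Chemical bonds are ignored — they break early in the exposure — so neutral
atoms feel and exert nothing.

Electrons born above a configurable kinetic energy (photoelectrons at
~4.7 keV, Auger electrons at a few hundred eV) cross the sample in
attoseconds, far below the MD timescale; they are transported ballistically
in a single pass — straight-line impact-parameter sampling of collisional
ionization along the exit path, then an escape-barrier check — and only
sub-threshold (trapped/slow) electrons are explicit MD particles.  The MD
time step adapts to the fastest explicit particle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np
from numba import njit
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .atomic_data import ElementData, IonState, element_data, load_element_table
from .constants import AMU, BOHR, COULOMB_K, C_LIGHT, M_ELECTRON, RYDBERG
from .molecule_io import AtomRecords, center_of_mass
from .pulse import PulseProfile, peak_fluence_rate, snapshot_times


@dataclass
class DynamicsConfig:
    """Numerical knobs of the damage-dynamics integrator."""

    soften_ion: float = 0.1        # Å, Coulomb softening, ion–ion pairs
    soften_electron: float = 1.0   # Å, softening of any pair with an electron
    c_disp: float = 0.25           # max displacement per step, units of soften
    dt_max: float = 0.02           # fs, step cap when nothing moves fast
    dt_min: float = 2.0e-5         # fs, hard floor on the adaptive step
    macro_dt: float = 0.01         # fs, Monte-Carlo operator-splitting step
    fast_electron_eV: float = 200.0  # ballistic-transport threshold
    birth_offset: float = 0.3      # Å, electron birth distance from its ion
    escape_radius_factor: float = 3.0   # × molecule radius
    flux_cut: float = 1e-4         # start integration at this cum. fraction
    speed_cap: float = C_LIGHT / 10.0   # instability diagnostic
    opening_angle: float = 0.5     # tree MAC when the tree solver is used
    tree_threshold: int = 3000     # switch direct → tree above this count


class MDInstabilityError(RuntimeError):
    """A particle exceeded the speed cap — the integration blew up."""


# ---------------------------------------------------------------------------
# element lookup tables flattened to arrays for vectorized MC


class _SystemTables:
    """Per-element data reindexed as dense arrays (element × shell)."""

    def __init__(self, elements: tuple[ElementData, ...]):
        self.elements = elements
        S = max(el.n_shells for el in elements)
        E = len(elements)
        self.n_shell_max = S
        self.Z = np.array([el.Z for el in elements])
        self.mass = np.array([el.mass_amu for el in elements]) * AMU
        self.occ_neutral = np.zeros((E, S), dtype=np.int64)
        self.binding = np.full((E, S), np.inf)
        self.sigma_photo = np.zeros((E, S))
        self.auger_rate = np.array([el.auger_rate_per_K_hole for el in elements])
        self.auger_energy = np.array([el.mean_auger_energy for el in elements])
        self.photon_energy_eV = elements[0].photon_energy_keV * 1e3
        for e, el in enumerate(elements):
            ns = el.n_shells
            self.occ_neutral[e, :ns] = el.neutral_occupations
            self.binding[e, :ns] = el.binding_energies
            self.sigma_photo[e, :ns] = el.photo_cross_sections


@dataclass
class SystemState:
    """Atoms, explicit free electrons and the escape ledger at one time."""

    pos: np.ndarray                 # (n, 3) Å
    vel: np.ndarray                 # (n, 3) Å/fs
    occ: np.ndarray                 # (n, S) int64 shell occupations
    elem_idx: np.ndarray            # (n,) index into tables.elements
    tables: _SystemTables
    epos: np.ndarray                # (m, 3) explicit free electrons
    evel: np.ndarray                # (m, 3)
    n_escaped: int = 0
    time: float = 0.0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    @property
    def n_atoms(self) -> int:
        return len(self.pos)

    @property
    def n_electrons(self) -> int:
        return len(self.epos)

    @property
    def charges(self) -> np.ndarray:
        """Per-atom integer charge Z − bound."""
        return self.tables.Z[self.elem_idx] - self.occ.sum(axis=1)

    def ion_state(self, i: int) -> IonState:
        el = self.tables.elements[self.elem_idx[i]]
        return IonState(el, tuple(int(x) for x in self.occ[i, : el.n_shells]))

    def charge_balance(self) -> int:
        """Σ atom charges − explicit electrons − escaped; 0 when conserved."""
        return int(self.charges.sum()) - self.n_electrons - self.n_escaped


@dataclass
class Trajectory:
    """Snapshots of one realization plus its provenance."""

    times: np.ndarray                       # (k,) fs, strictly increasing
    positions: list                         # k × (n, 3)
    occupations: list                       # k × (n, S)
    electron_positions: list                # k × (m_k, 3)
    n_escaped: np.ndarray                   # (k,)
    initial_positions: np.ndarray           # (n, 3) before the pulse
    elem_idx: np.ndarray
    elements: tuple[ElementData, ...]
    orientation: np.ndarray                 # quaternion (x, y, z, w)
    rotation_center: np.ndarray             # (3,)
    seed: int
    pulse: PulseProfile

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("snapshot times must be strictly increasing")

    @property
    def n_snapshots(self) -> int:
        return len(self.times)

    def symbols(self) -> np.ndarray:
        return np.array([self.elements[i].symbol for i in self.elem_idx])

    def positions_in_reference_frame(self, k: int) -> np.ndarray:
        """Snapshot k rotated back to the unrotated molecular frame."""
        rot = Rotation.from_quat(self.orientation).inv()
        c = self.rotation_center
        return rot.apply(self.positions[k] - c) + c

    def electrons_in_reference_frame(self, k: int) -> np.ndarray:
        rot = Rotation.from_quat(self.orientation).inv()
        c = self.rotation_center
        ep = self.electron_positions[k]
        return rot.apply(ep - c) + c if len(ep) else ep


# ---------------------------------------------------------------------------
# initialization


def initialize_system(records: AtomRecords, orientation: np.ndarray,
                      seed: int, table=None) -> SystemState:
    """Neutral atoms at rest, rotated about the center of mass.

    ``orientation`` is a unit quaternion in scalar-last (x, y, z, w) order.
    """
    orientation = np.asarray(orientation, dtype=float)
    if not math.isclose(np.linalg.norm(orientation), 1.0, rel_tol=1e-9):
        raise ValueError("orientation must be a unit quaternion")
    if table is None:
        table = load_element_table(4.96)
    symbols = sorted(set(records.symbols.tolist()))
    elements = tuple(element_data(table, s) for s in symbols)
    sym_to_idx = {s: i for i, s in enumerate(symbols)}
    elem_idx = np.array([sym_to_idx[s] for s in records.symbols])
    tables = _SystemTables(elements)
    com = center_of_mass(records)
    rot = Rotation.from_quat(orientation)
    pos = rot.apply(records.coords - com) + com
    occ = tables.occ_neutral[elem_idx].copy()
    return SystemState(
        pos=pos,
        vel=np.zeros_like(pos),
        occ=occ,
        elem_idx=elem_idx,
        tables=tables,
        epos=np.zeros((0, 3)),
        evel=np.zeros((0, 3)),
        rng=np.random.default_rng(seed),
    )


# ---------------------------------------------------------------------------
# force evaluation


@njit(cache=True, fastmath=True)
def _direct_forces(pos, q, soft):
    """Pairwise softened Coulomb; pair softening = max of the two lengths."""
    n = pos.shape[0]
    f = np.zeros((n, 3))
    for i in range(n):
        qi = q[i]
        if qi == 0.0:
            continue
        si = soft[i]
        for j in range(i + 1, n):
            qj = q[j]
            if qj == 0.0:
                continue
            sij = si if si > soft[j] else soft[j]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz + sij * sij
            s = COULOMB_K * qi * qj / (r2 * np.sqrt(r2))
            fx = dx * s
            fy = dy * s
            fz = dz * s
            f[i, 0] += fx
            f[i, 1] += fy
            f[i, 2] += fz
            f[j, 0] -= fx
            f[j, 1] -= fy
            f[j, 2] -= fz
    return f


def _gather(state: SystemState):
    """Stack atoms + electrons into flat particle arrays."""
    pos = np.vstack([state.pos, state.epos])
    vel = np.vstack([state.vel, state.evel])
    q = np.concatenate([state.charges.astype(float),
                        -np.ones(state.n_electrons)])
    mass = np.concatenate([state.tables.mass[state.elem_idx],
                           np.full(state.n_electrons, M_ELECTRON)])
    return pos, vel, q, mass


def _soften_array(n_atoms: int, n_electrons: int, cfg: DynamicsConfig,
                  soften=None) -> np.ndarray:
    """Per-particle softening lengths (atoms then electrons)."""
    if soften is not None:
        return np.full(n_atoms + n_electrons, float(soften))
    return np.concatenate([np.full(n_atoms, cfg.soften_ion),
                           np.full(n_electrons, cfg.soften_electron)])


def compute_forces_direct(state: SystemState, soften=None,
                          config: DynamicsConfig | None = None) -> np.ndarray:
    """Exact pairwise softened Coulomb forces (eV/Å), atoms then electrons.

    ``soften`` overrides the per-species config softening with one scalar
    (0 gives the bare Coulomb law).
    """
    cfg = config or DynamicsConfig()
    pos, _, q, _ = _gather(state)
    soft = _soften_array(state.n_atoms, state.n_electrons, cfg, soften)
    return _direct_forces(np.ascontiguousarray(pos), q, soft)


def compute_forces_tree(state: SystemState, opening_angle: float = 0.5,
                        soften: float = 0.1) -> np.ndarray:
    """Barnes–Hut approximation of :func:`compute_forces_direct`.

    The tree uses one uniform softening length for all pairs.
    """
    from .tree import barnes_hut_forces

    pos, _, q, _ = _gather(state)
    return barnes_hut_forces(pos, q, soften, opening_angle)


def total_energy(state: SystemState, soften=None,
                 config: DynamicsConfig | None = None) -> float:
    """Kinetic + pairwise softened Coulomb potential energy (eV)."""
    cfg = config or DynamicsConfig()
    pos, vel, q, mass = _gather(state)
    soft = _soften_array(state.n_atoms, state.n_electrons, cfg, soften)
    kin = 0.5 * float(np.sum(mass * np.sum(vel**2, axis=1)))
    charged = np.flatnonzero(q)
    pot = 0.0
    for a, i in enumerate(charged):
        j = charged[a + 1:]
        sij = np.maximum(soft[i], soft[j])
        d2 = np.sum((pos[j] - pos[i]) ** 2, axis=1) + sij**2
        pot += float(np.sum(COULOMB_K * q[i] * q[j] / np.sqrt(d2)))
    return kin + pot


# ---------------------------------------------------------------------------
# MD propagation


@njit(cache=True, fastmath=True)
def _advance(pos, vel, mass, q, soft, t_span, c_disp, dt_max, dt_min, vcap):
    """Velocity-Verlet over t_span; returns -1.0 on instability.

    The step is chosen once per call (constant over the span, which the
    caller keeps short) from a per-particle displacement bound c·s_i/v_i
    and a free-fall bound c·√(s_i·m_i/F_i), so that close electron–ion
    encounters are resolved while the near-symplectic character of
    constant-step Verlet is retained.
    """
    n = pos.shape[0]
    f = _direct_forces(pos, q, soft)
    dt = dt_max
    for i in range(n):
        v2 = vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
        v = np.sqrt(v2)
        if v > vcap:
            return -1.0
        if v > 0.0:
            lim = c_disp * soft[i] / v
            if lim < dt:
                dt = lim
        fmag2 = f[i, 0] ** 2 + f[i, 1] ** 2 + f[i, 2] ** 2
        if fmag2 > 0.0:
            lim = c_disp * np.sqrt(soft[i] * mass[i] / np.sqrt(fmag2))
            if lim < dt:
                dt = lim
    if dt < dt_min:
        dt = dt_min
    n_steps = int(np.ceil(t_span / dt))
    dt = t_span / n_steps
    for _ in range(n_steps):
        for i in range(n):
            im = 0.5 * dt / mass[i]
            vel[i, 0] += f[i, 0] * im
            vel[i, 1] += f[i, 1] * im
            vel[i, 2] += f[i, 2] * im
            pos[i, 0] += vel[i, 0] * dt
            pos[i, 1] += vel[i, 1] * dt
            pos[i, 2] += vel[i, 2] * dt
        f = _direct_forces(pos, q, soft)
        for i in range(n):
            im = 0.5 * dt / mass[i]
            vel[i, 0] += f[i, 0] * im
            vel[i, 1] += f[i, 1] * im
            vel[i, 2] += f[i, 2] * im
    return t_span


def md_step(state: SystemState, dt: float,
            config: DynamicsConfig | None = None, soften=None) -> SystemState:
    """One velocity-Verlet step of all mobile particles; advances time."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    cfg = config or DynamicsConfig()
    pos, vel, q, mass = _gather(state)
    soft = _soften_array(state.n_atoms, state.n_electrons, cfg, soften)
    f = _direct_forces(np.ascontiguousarray(pos), q, soft)
    vel += 0.5 * dt * f / mass[:, None]
    pos += dt * vel
    f = _direct_forces(np.ascontiguousarray(pos), q, soft)
    vel += 0.5 * dt * f / mass[:, None]
    n = state.n_atoms
    state.pos, state.vel = pos[:n], vel[:n]
    state.epos, state.evel = pos[n:], vel[n:]
    state.time += dt
    return state


def _md_advance_span(state: SystemState, t_span: float, cfg: DynamicsConfig) -> None:
    """Advance only the *mobile* particles (charged atoms + electrons)."""
    charged_atoms = np.flatnonzero(state.charges != 0)
    n_c = len(charged_atoms)
    m = state.n_electrons
    if n_c + m == 0:
        state.time += t_span
        return
    pos = np.vstack([state.pos[charged_atoms], state.epos])
    vel = np.vstack([state.vel[charged_atoms], state.evel])
    q = np.concatenate([state.charges[charged_atoms].astype(float), -np.ones(m)])
    mass = np.concatenate([state.tables.mass[state.elem_idx[charged_atoms]],
                           np.full(m, M_ELECTRON)])
    soft = _soften_array(n_c, m, cfg)
    out = 0.0
    remaining = t_span
    while remaining > 1e-12 and out >= 0.0:
        h = min(cfg.macro_dt, remaining)
        out = _advance(pos, vel, mass, q, soft, h,
                       cfg.c_disp, cfg.dt_max, cfg.dt_min, cfg.speed_cap)
        remaining -= h
    if out < 0:
        vmax = float(np.max(np.linalg.norm(vel, axis=1)))
        raise MDInstabilityError(
            f"particle speed {vmax:.1f} Å/fs exceeded the cap "
            f"{cfg.speed_cap:.1f} Å/fs at t = {state.time:.3f} fs "
            f"({n_c} charged atoms, {m} electrons)")
    state.pos[charged_atoms] = pos[:n_c]
    state.vel[charged_atoms] = vel[:n_c]
    state.epos = pos[n_c:]
    state.evel = vel[n_c:]
    state.time += t_span


# ---------------------------------------------------------------------------
# Monte-Carlo ionization processes


def _isotropic(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _spawn_electrons(state: SystemState, at: np.ndarray, KE: np.ndarray,
                     offset: float) -> np.ndarray:
    """Append electrons near positions ``at`` with isotropic velocities.

    Returns the kinetic energies actually assigned (for fast-electron
    post-processing by the caller)."""
    n = len(at)
    if n == 0:
        return np.zeros(0)
    rng = state.rng
    dirs = _isotropic(rng, n)
    speed = np.sqrt(2.0 * np.maximum(KE, 0.0) / M_ELECTRON)
    state.epos = np.vstack([state.epos, at + offset * _isotropic(rng, n)])
    state.evel = np.vstack([state.evel, dirs * speed[:, None]])
    return KE


def mc_photoionize(state: SystemState, fluence_rate: float, dt: float,
                   rng: np.random.Generator | None = None,
                   birth_offset: float = 0.3) -> SystemState:
    """Fire per-atom, per-shell photoionization with P = 1−exp(−σΦdt).

    Ejected electrons get KE = photon energy − binding energy, isotropic
    direction, birth at a small random offset from the parent atom.
    """
    if fluence_rate < 0:
        raise ValueError("fluence rate must be ≥ 0")
    if fluence_rate == 0.0 or dt <= 0:
        return state
    rng = rng or state.rng
    tb = state.tables
    occ_n = tb.occ_neutral[state.elem_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(occ_n > 0, state.occ / np.maximum(occ_n, 1), 0.0)
    sigma = tb.sigma_photo[state.elem_idx] * frac
    p = -np.expm1(-sigma * fluence_rate * dt)
    fired = rng.random(p.shape) < p
    if not fired.any():
        return state
    atoms, shells = np.nonzero(fired)
    state.occ[atoms, shells] -= 1
    KE = tb.photon_energy_eV - tb.binding[state.elem_idx[atoms], shells]
    _spawn_electrons(state, state.pos[atoms], KE, birth_offset)
    return state


def mc_auger(state: SystemState, dt: float,
             rng: np.random.Generator | None = None,
             birth_offset: float = 0.3) -> SystemState:
    """Fire Auger decay of K-shell holes with P = 1−exp(−Γdt).

    A valence electron fills the hole and a second one is ejected with the
    element's mean Auger energy: bound count drops by one.
    """
    rng = rng or state.rng
    tb = state.tables
    occ_n = tb.occ_neutral[state.elem_idx]
    n_holes = occ_n[:, 0] - state.occ[:, 0]
    outer = state.occ.sum(axis=1) - state.occ[:, 0]
    rate = np.where((n_holes > 0) & (outer >= 2),
                    n_holes * tb.auger_rate[state.elem_idx], 0.0)
    p = -np.expm1(-rate * dt)
    fired = np.flatnonzero(rng.random(len(p)) < p)
    if len(fired) == 0:
        return state
    for a in fired:
        state.occ[a, 0] += 1
        removed = 0
        for s in range(state.occ.shape[1] - 1, 0, -1):
            take = min(2 - removed, state.occ[a, s])
            state.occ[a, s] -= take
            removed += take
            if removed == 2:
                break
    KE = tb.auger_energy[state.elem_idx[fired]]
    _spawn_electrons(state, state.pos[fired], KE, birth_offset)
    return state


@njit(cache=True)
def _beb_sigma_shells(binding, occ, KE):
    """Per-shell BEB cross sections (Å²) for one atom's current state."""
    S = binding.shape[0]
    out = np.zeros(S)
    for i in range(S):
        B = binding[i]
        N = occ[i]
        if N <= 0 or not (KE > B) or not np.isfinite(B):
            continue
        t = KE / B
        lnt = np.log(t)
        pref = 4.0 * np.pi * BOHR**2 * N * (RYDBERG / B) ** 2
        out[i] = pref / (t + 2.0) * (
            0.5 * lnt * (1.0 - 1.0 / t**2) + 1.0 - 1.0 / t - lnt / (t + 1.0)
        )
    return out


def mc_collisional(state: SystemState, dt: float,
                   rng: np.random.Generator | None = None,
                   birth_offset: float = 0.3) -> SystemState:
    """Impact-parameter collisional ionization by explicit free electrons.

    Neighbor atoms along each electron's straight path during ``dt`` are
    found with a k-d tree; an ionization fires when the path passes an atom
    within the total-cross-section impact parameter b = √(σ_tot/π), the
    ionized shell is sampled ∝ σ_shell, the incident electron loses the
    binding energy and the secondary is born at rest at the atom.  At most
    one event per electron per step.
    """
    m = state.n_electrons
    if m == 0 or dt <= 0:
        return state
    rng = rng or state.rng
    tb = state.tables
    kdt = cKDTree(state.pos)
    speeds = np.linalg.norm(state.evel, axis=1)
    KEs = 0.5 * M_ELECTRON * speeds**2
    min_binding = tb.binding[state.elem_idx].min()
    active = np.flatnonzero(KEs > min_binding)
    if len(active) == 0:
        return state
    r_search = speeds[active] * dt + 2.0
    hits = kdt.query_ball_point(state.epos[active], r_search)
    new_at, new_ke = [], []
    for e, cand in zip(active, hits):
        if not cand:
            continue
        KE = 0.5 * M_ELECTRON * float(state.evel[e] @ state.evel[e])
        speed = math.sqrt(2.0 * KE / M_ELECTRON)
        if speed == 0.0:
            continue
        u = state.evel[e] / speed
        L = speed * dt
        cand = np.asarray(cand)
        d = state.pos[cand] - state.epos[e]
        proj = d @ u
        inside = (proj >= 0.0) & (proj <= L)
        if not inside.any():
            continue
        cand = cand[inside]
        b2 = np.sum(d[inside] ** 2, axis=1) - proj[inside] ** 2
        order = np.argsort(proj[inside])
        for k in order:
            a = cand[k]
            ei = state.elem_idx[a]
            sig = _beb_sigma_shells(tb.binding[ei], state.occ[a], KE)
            sig_tot = sig.sum()
            if sig_tot <= 0.0:
                continue
            if b2[k] < sig_tot / math.pi:
                shell = rng.choice(len(sig), p=sig / sig_tot)
                state.occ[a, shell] -= 1
                B = tb.binding[ei, shell]
                KE_new = KE - B
                state.evel[e] = u * math.sqrt(2.0 * max(KE_new, 0.0) / M_ELECTRON)
                new_at.append(state.pos[a])
                new_ke.append(0.0)
                break
    if new_at:
        _spawn_electrons(state, np.array(new_at), np.array(new_ke), birth_offset)
    return state


# ---------------------------------------------------------------------------
# fast-electron ballistic transport and escape


def _ballistic_transport(state: SystemState, first_new: int,
                         center: np.ndarray, escape_R: float,
                         cfg: DynamicsConfig) -> None:
    """Process electrons with KE above threshold created since ``first_new``.

    Each fast electron flies straight out of the escape sphere, ionizing
    atoms it passes within the BEB impact parameter (losing the binding
    energy each time, secondaries born at rest).  If its energy drops below
    the threshold it is handed back to the MD; otherwise it escapes when it
    can climb the monopole Coulomb barrier of the net cluster charge.
    """
    rng = state.rng
    tb = state.tables
    idx = first_new
    while idx < state.n_electrons:
        v = state.evel[idx]
        KE = 0.5 * M_ELECTRON * float(v @ v)
        if KE <= cfg.fast_electron_eV:
            idx += 1
            continue
        x = state.epos[idx].copy()
        speed = math.sqrt(2.0 * KE / M_ELECTRON)
        u = v / speed
        # exit length from x along u out of the escape sphere
        rel = x - center
        bq = float(rel @ u)
        cq = float(rel @ rel) - escape_R**2
        L = -bq + math.sqrt(max(bq * bq - cq, 0.0))
        d = state.pos - x
        proj = d @ u
        b2 = np.sum(d**2, axis=1) - proj**2
        cand = np.flatnonzero((proj > 0) & (proj < L) & (b2 < 4.0))
        alive = True
        for a in cand[np.argsort(proj[cand])]:
            ei = state.elem_idx[a]
            sig = _beb_sigma_shells(tb.binding[ei], state.occ[a], KE)
            sig_tot = sig.sum()
            if sig_tot <= 0.0 or b2[a] >= sig_tot / math.pi:
                continue
            shell = rng.choice(len(sig), p=sig / sig_tot)
            state.occ[a, shell] -= 1
            KE -= tb.binding[ei, shell]
            # secondary at rest beside the ion (processed later if ever fast)
            state.epos = np.vstack([state.epos,
                                    state.pos[a] + cfg.birth_offset * _isotropic(rng, 1)[0]])
            state.evel = np.vstack([state.evel, np.zeros((1, 3))])
            if KE <= cfg.fast_electron_eV:
                # hand back to MD at the interaction point
                state.epos[idx] = state.pos[a] + cfg.birth_offset * _isotropic(rng, 1)[0]
                state.evel[idx] = u * math.sqrt(2.0 * max(KE, 0.0) / M_ELECTRON)
                alive = False
                break
        if alive:
            q_net = int(state.charges.sum()) - (state.n_electrons - 1) - state.n_escaped
            barrier = COULOMB_K * max(q_net, 0) / escape_R
            if KE > barrier:
                state.n_escaped += 1
                # drop electron idx
                mask = np.ones(state.n_electrons, dtype=bool)
                mask[idx] = False
                state.epos = state.epos[mask]
                state.evel = state.evel[mask]
                continue  # do not advance idx: array shifted
            # too slow to leave: park it at the sphere edge, heading out
            state.epos[idx] = x + L * u
            state.evel[idx] = u * math.sqrt(2.0 * max(KE, 0.0) / M_ELECTRON)
        idx += 1


def _apply_escapes(state: SystemState, center: np.ndarray, escape_R: float,
                   cfg: DynamicsConfig) -> None:
    """Move unbound electrons beyond the escape radius to the ledger."""
    if state.n_electrons == 0:
        return
    r = np.linalg.norm(state.epos - center, axis=1)
    far = np.flatnonzero(r > escape_R)
    if len(far) == 0:
        return
    pos, _, q, _ = _gather(state)
    n = state.n_atoms
    drop = []
    for e in far:
        KE = 0.5 * M_ELECTRON * float(state.evel[e] @ state.evel[e])
        others = np.delete(np.arange(len(q)), n + e)
        d = np.linalg.norm(pos[others] - state.epos[e], axis=1)
        pot = float(np.sum(COULOMB_K * (-1.0) * q[others]
                           / np.sqrt(d**2 + cfg.soften_electron**2)))
        if KE + pot > 0:
            drop.append(e)
    if drop:
        mask = np.ones(state.n_electrons, dtype=bool)
        mask[drop] = False
        state.epos = state.epos[mask]
        state.evel = state.evel[mask]
        state.n_escaped += len(drop)


# ---------------------------------------------------------------------------
# the realization loop


def run_realization(records: AtomRecords, pulse: PulseProfile,
                    orientation: np.ndarray, seed: int,
                    n_snapshots: int = 10,
                    config: DynamicsConfig | None = None,
                    table=None) -> Trajectory:
    """Evolve one stochastic realization and record ``n_snapshots`` snapshots.

    Snapshots sit at the median-photon times of equal-photon-content
    intervals of the pulse, so time integration of diffraction images can
    weight each snapshot by its interval's photon count.
    """
    cfg = config or DynamicsConfig()
    if table is None:
        table = load_element_table(pulse.photon_energy_keV)
    state = initialize_system(records, orientation, seed, table)
    com = center_of_mass(records)
    radius = float(np.max(np.linalg.norm(state.pos - com, axis=1)))
    escape_R = cfg.escape_radius_factor * max(radius, 1.0)
    initial_positions = state.pos.copy()

    snap_t = snapshot_times(pulse, n_snapshots)
    cum = np.cumsum(pulse.flux) * pulse.dt
    i0 = int(np.searchsorted(cum, cfg.flux_cut * pulse.total_photons))
    t_start = min(float(pulse.t[i0]), float(snap_t[0]) - pulse.dt)
    t_end = float(snap_t[-1])
    state.time = t_start

    snaps_pos, snaps_occ, snaps_e, snaps_nesc, rec_t = [], [], [], [], []
    next_snap = 0
    while state.time < t_end - 1e-9:
        t_next = min(state.time + cfg.macro_dt, t_end)
        if next_snap < n_snapshots:
            t_next = min(t_next, float(snap_t[next_snap]))
        h = t_next - state.time
        flu = float(peak_fluence_rate(pulse, state.time + 0.5 * h))
        n_before = state.n_electrons
        mc_photoionize(state, flu, h, birth_offset=cfg.birth_offset)
        mc_auger(state, h, birth_offset=cfg.birth_offset)
        _ballistic_transport(state, n_before, com, escape_R, cfg)
        mc_collisional(state, h, birth_offset=cfg.birth_offset)
        _md_advance_span(state, h, cfg)
        _apply_escapes(state, com, escape_R, cfg)
        if next_snap < n_snapshots and state.time >= float(snap_t[next_snap]) - 1e-9:
            rec_t.append(state.time)
            snaps_pos.append(state.pos.copy())
            snaps_occ.append(state.occ.copy())
            snaps_e.append(state.epos.copy())
            snaps_nesc.append(state.n_escaped)
            next_snap += 1
    assert state.charge_balance() == 0, "charge conservation violated"

    return Trajectory(
        times=np.array(rec_t),
        positions=snaps_pos,
        occupations=snaps_occ,
        electron_positions=snaps_e,
        n_escaped=np.array(snaps_nesc),
        initial_positions=initial_positions,
        elem_idx=state.elem_idx.copy(),
        elements=state.tables.elements,
        orientation=np.asarray(orientation, dtype=float),
        rotation_center=com,
        seed=seed,
        pulse=pulse,
    )


# ---------------------------------------------------------------------------
# HDF5 serialization


def save_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory to HDF5: /snapshots/<k>/..., /meta/..."""
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["seed"] = traj.seed
        meta.attrs["quaternion"] = traj.orientation
        meta.attrs["rotation_center"] = traj.rotation_center
        meta.attrs["symbols"] = traj.symbols().tolist()
        meta.attrs["photon_energy_keV"] = traj.pulse.photon_energy_keV
        meta.attrs["total_photons"] = traj.pulse.total_photons
        meta.attrs["focus_fwhm_nm"] = traj.pulse.focus_fwhm_nm
        meta.create_dataset("pulse_t", data=traj.pulse.t)
        meta.create_dataset("pulse_flux", data=traj.pulse.flux)
        meta.create_dataset("initial_positions", data=traj.initial_positions)
        snaps = f.create_group("snapshots")
        for k in range(traj.n_snapshots):
            g = snaps.create_group(str(k))
            g.attrs["time"] = traj.times[k]
            g.attrs["n_escaped"] = int(traj.n_escaped[k])
            g.create_dataset("positions", data=traj.positions[k])
            g.create_dataset("occupations", data=traj.occupations[k])
            g.create_dataset("electrons", data=traj.electron_positions[k])


def load_trajectory(path, table=None) -> Trajectory:
    with h5py.File(path, "r") as f:
        meta = f["meta"]
        pulse = PulseProfile(
            meta["pulse_t"][()], meta["pulse_flux"][()],
            float(meta.attrs["photon_energy_keV"]),
            float(meta.attrs["total_photons"]),
            tuple(meta.attrs["focus_fwhm_nm"]),
        )
        if table is None:
            table = load_element_table(pulse.photon_energy_keV)
        symbols = list(meta.attrs["symbols"])
        uniq = sorted(set(symbols))
        elements = tuple(element_data(table, s) for s in uniq)
        elem_idx = np.array([uniq.index(s) for s in symbols])
        ks = sorted(f["snapshots"].keys(), key=int)
        times, positions, occupations, electrons, nesc = [], [], [], [], []
        for k in ks:
            g = f["snapshots"][k]
            times.append(float(g.attrs["time"]))
            nesc.append(int(g.attrs["n_escaped"]))
            positions.append(g["positions"][()])
            occupations.append(g["occupations"][()])
            electrons.append(g["electrons"][()])
        return Trajectory(
            times=np.array(times), positions=positions,
            occupations=occupations, electron_positions=electrons,
            n_escaped=np.array(nesc),
            initial_positions=meta["initial_positions"][()],
            elem_idx=elem_idx, elements=elements,
            orientation=np.array(meta.attrs["quaternion"]),
            rotation_center=np.array(meta.attrs["rotation_center"]),
            seed=int(meta.attrs["seed"]), pulse=pulse,
        )
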