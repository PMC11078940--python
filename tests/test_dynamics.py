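"""Monte-Carlo ionization + molecular dynamics: identities and oracles."""

import math

import numpy as np
import pytest

from spisim.constants import COULOMB_K, M_ELECTRON
from spisim.dynamics import (
    DynamicsConfig,
    compute_forces_direct,
    compute_forces_tree,
    initialize_system,
    load_trajectory,
    md_step,
    mc_auger,
    mc_collisional,
    mc_photoionize,
    run_realization,
    save_trajectory,
    total_energy,
)
from spisim.dynamics import _md_advance_span
from spisim.molecule_io import AtomRecords
from spisim.pulse import gaussian_profile
from spisim.diffraction import random_rotation

IDENTITY_Q = np.array([0.0, 0.0, 0.0, 1.0])


def _carbon_system(table, coords, charge_per_atom=0):
    rec = AtomRecords(np.array(["C"] * len(coords)), np.asarray(coords, float))
    st = initialize_system(rec, IDENTITY_Q, 0, table)
    for _ in range(charge_per_atom):
        for s in (2, 1, 0):
            movable = st.occ[:, s] > 0
            st.occ[movable, s] -= 1
            break
    return st


# ---------------------------------------------------------------------------
# initialization


def test_initialize_identity_and_isometry(small_cluster, table):
    st = initialize_system(small_cluster, IDENTITY_Q, 0, table)
    np.testing.assert_allclose(st.pos, small_cluster.coords, atol=1e-12)
    assert st.n_electrons == 0
    assert np.all(st.charges == 0)
    assert np.all(st.vel == 0)

    quat = random_rotation(5)
    st2 = initialize_system(small_cluster, quat, 0, table)
    from scipy.spatial.distance import pdist
    np.testing.assert_allclose(pdist(st2.pos), pdist(small_cluster.coords),
                               atol=1e-10)


def test_initialize_rotation_involution(small_cluster, table):
    """A 180° rotation about z applied twice restores the coordinates."""
    half_turn = np.array([0.0, 0.0, 1.0, 0.0])
    st = initialize_system(small_cluster, half_turn, 0, table)
    rec2 = AtomRecords(small_cluster.symbols, st.pos)
    st2 = initialize_system(rec2, half_turn, 0, table)
    np.testing.assert_allclose(st2.pos, small_cluster.coords, atol=1e-9)


def test_initialize_rejects_non_unit_quaternion(small_cluster, table):
    with pytest.raises(ValueError):
        initialize_system(small_cluster, np.array([1.0, 1.0, 0.0, 0.0]), 0, table)


# ---------------------------------------------------------------------------
# forces


def test_neutral_system_has_no_forces(small_cluster, table):
    st = initialize_system(small_cluster, IDENTITY_Q, 0, table)
    assert np.all(compute_forces_direct(st) == 0.0)


def test_two_unit_charges_coulomb_constant(table):
    st = _carbon_system(table, [[0, 0, 0], [1.0, 0, 0]])
    st.occ[:, 2] -= 1     # two C⁺ ions, 1 Å apart
    f = compute_forces_direct(st, soften=0.0)
    assert np.linalg.norm(f[0]) == pytest.approx(COULOMB_K)
    np.testing.assert_allclose(f[0], -f[1], atol=1e-12)
    assert f[1][0] > 0     # repulsion along +x on the right-hand charge


def test_forces_sum_to_zero(table, rng):
    st = _carbon_system(table, rng.uniform(-5, 5, (30, 3)))
    st.occ[:, 2] -= rng.integers(0, 3, 30).astype(np.int64) // 2
    st.epos = rng.uniform(-5, 5, (10, 3))
    st.evel = np.zeros((10, 3))
    f = compute_forces_direct(st)
    np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-9)


def test_tree_forces_match_direct_through_state(table, rng):
    st = _carbon_system(table, rng.uniform(-8, 8, (60, 3)))
    st.occ[:, 2] -= 1
    st.epos = rng.uniform(-8, 8, (40, 3))
    st.evel = np.zeros((40, 3))
    fd = compute_forces_direct(st, soften=0.1)
    ft = compute_forces_tree(st, opening_angle=0.2, soften=0.1)
    active = np.linalg.norm(fd, axis=1) > 0
    err = (np.linalg.norm(ft - fd, axis=1)[active]
           / np.linalg.norm(fd, axis=1)[active])
    assert err.max() < 1e-2


# ---------------------------------------------------------------------------
# MD stepping


def test_ballistic_motion_without_charges(small_cluster, table):
    st = initialize_system(small_cluster, IDENTITY_Q, 0, table)
    v = np.full_like(st.vel, 0.3)
    st.vel = v.copy()
    x0 = st.pos.copy()
    md_step(st, 0.5)
    np.testing.assert_allclose(st.pos, x0 + 0.5 * v, atol=1e-12)
    assert st.time == pytest.approx(0.5)


def test_circular_orbit_radius_conserved(table):
    """Electron on a circular orbit around a C⁺ ion keeps its radius."""
    st = _carbon_system(table, [[0.0, 0.0, 0.0]])
    st.occ[0, 2] -= 1
    r = 2.0
    soft = 0.5
    v = math.sqrt(COULOMB_K * r**2 / (M_ELECTRON * (r**2 + soft**2) ** 1.5))
    st.epos = np.array([[r, 0.0, 0.0]])
    st.evel = np.array([[0.0, v, 0.0]])
    period = 2 * math.pi * r / v
    dt = period / 2000
    # pin the heavy ion by zeroing its kick: use mass ratio ~ 2e5, fine
    for _ in range(2000):
        md_step(st, dt, soften=soft)
    radius = np.linalg.norm(st.epos[0] - st.pos[0])
    assert radius == pytest.approx(r, rel=1e-3)


def test_energy_conservation_over_pulse_duration(table, rng):
    """< 1e-3 relative energy drift over 9 fs with no ionization events."""
    rec = AtomRecords(np.array(["C"] * 30), rng.uniform(-8, 8, (30, 3)))
    st = initialize_system(rec, IDENTITY_Q, 0, table)
    st.occ[:, 2] -= 1          # 30 C⁺: Coulomb explosion begins
    st.epos = rng.uniform(-8, 8, (10, 3))
    st.evel = rng.normal(0, 3, (10, 3))
    cfg = DynamicsConfig()
    e0 = total_energy(st)
    _md_advance_span(st, 9.0, cfg)
    e1 = total_energy(st)
    assert abs(e1 - e0) / abs(e0) < 1e-3


# ---------------------------------------------------------------------------
# Monte-Carlo processes


def test_photoionize_zero_fluence_is_identity(small_cluster, table):
    st = initialize_system(small_cluster, IDENTITY_Q, 1, table)
    occ0 = st.occ.copy()
    mc_photoionize(st, 0.0, 0.01)
    np.testing.assert_array_equal(st.occ, occ0)
    assert st.n_electrons == 0


def test_photoionize_poisson_fraction(table):
    """Ionized fraction after σ·∫F dt = 0.1 matches 1 − e^(−0.1)."""
    n = 10000
    rec = AtomRecords(np.array(["C"] * n),
                      np.arange(3 * n, dtype=float).reshape(n, 3) * 50.0)
    st = initialize_system(rec, IDENTITY_Q, 99, table)
    sigma_tot = sum(table["C"].photo_cross_sections)
    fluence = 0.1 / sigma_tot     # per fs, applied for 1 fs in 10 slices
    for _ in range(10):
        mc_photoionize(st, fluence, 0.1)
    frac = np.mean(st.charges > 0)
    p = 1 - math.exp(-0.1)
    sd = math.sqrt(p * (1 - p) / n)
    assert abs(frac - p) < 4 * sd


def test_photoelectron_kinetic_energy(table):
    rec = AtomRecords(np.array(["C"]), np.zeros((1, 3)))
    st = initialize_system(rec, IDENTITY_Q, 7, table)
    # drive the K shell hard so the first event is a 1s ionization
    st.rng = np.random.default_rng(0)
    while st.n_electrons == 0:
        st.occ[0] = [2, 0, 0]
        mc_photoionize(st, 1e7, 0.1)
    ke = 0.5 * M_ELECTRON * float(st.evel[0] @ st.evel[0])
    assert ke == pytest.approx(4960.0 - table["C"].binding_energies[0], rel=1e-9)


def test_auger_survival_and_charge_conservation(table):
    """K-hole survival after one lifetime ≈ e⁻¹; each decay frees one electron."""
    n = 5000
    rec = AtomRecords(np.array(["C"] * n),
                      np.arange(3 * n, dtype=float).reshape(n, 3) * 50.0)
    st = initialize_system(rec, IDENTITY_Q, 123, table)
    st.occ[:, 0] = 1              # one K hole per atom
    bound0 = st.occ.sum()
    tau = 1.0 / table["C"].auger_rate_per_K_hole
    n_slices = 40
    for _ in range(n_slices):
        mc_auger(st, tau / n_slices)
    survived = np.sum(st.occ[:, 0] == 1)
    p = math.exp(-1.0)
    sd = math.sqrt(p * (1 - p) / n)
    assert abs(survived / n - p) < 4 * sd
    decayed = n - survived
    assert st.occ.sum() == bound0 - decayed          # net loss of 1 per decay
    assert st.n_electrons == decayed                 # all freed electrons present
    # balance stays at the n hand-made holes: decays free one electron each
    assert st.charge_balance() == n


def test_no_auger_without_core_holes(small_cluster, table):
    st = initialize_system(small_cluster, IDENTITY_Q, 3, table)
    occ0 = st.occ.copy()
    mc_auger(st, 10.0)
    np.testing.assert_array_equal(st.occ, occ0)


def test_collisional_below_threshold_is_silent(table):
    st = _carbon_system(table, [[0.0, 0.0, 0.0]])
    st.epos = np.array([[-5.0, 0.0, 0.0]])
    slow = math.sqrt(2 * 5.0 / M_ELECTRON)   # 5 eV < B(2p)
    st.evel = np.array([[slow, 0.0, 0.0]])
    occ0 = st.occ.copy()
    mc_collisional(st, 1.0)
    np.testing.assert_array_equal(st.occ, occ0)


def test_collisional_head_on_hit_fires(table):
    st = _carbon_system(table, [[0.0, 0.0, 0.0]])
    st.epos = np.array([[-1.0, 0.0, 0.0]])
    v = math.sqrt(2 * 100.0 / M_ELECTRON)    # 100 eV electron aimed dead-on
    st.evel = np.array([[v, 0.0, 0.0]])
    mc_collisional(st, 2.0 / v * 1.0)
    assert st.occ.sum() == 5
    assert st.n_electrons == 2               # secondary born at the atom


def test_collisional_rate_matches_kinetic_theory(table):
    """Event rate in a cold uniform gas ≈ n·σ_tot·v·dt."""
    from spisim.atomic_data import collisional_cross_section

    rng = np.random.default_rng(7)
    n_atoms = 1500
    L = 40.0
    coords = rng.uniform(-L / 2, L / 2, (n_atoms, 3))
    density = n_atoms / L**3
    KE = 100.0
    sigma_tot = collisional_cross_section(table["C"].neutral_state(), KE).sum()
    v = math.sqrt(2 * KE / M_ELECTRON)
    dt = 0.05
    expected_p = density * sigma_tot * v * dt
    n_trials = 10000
    hits = 0
    batch = 500
    for start in range(0, n_trials, batch):
        st = _carbon_system(table, coords)
        st.epos = rng.uniform(-L / 4, L / 4, (batch, 3))
        dirs = rng.normal(size=(batch, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        st.evel = dirs * v
        st.rng = np.random.default_rng(start)
        bound0 = st.occ.sum()
        mc_collisional(st, dt)
        hits += bound0 - st.occ.sum()
    p_hat = hits / n_trials
    sd = math.sqrt(expected_p * (1 - expected_p) / n_trials)
    assert abs(p_hat - expected_p) < 4 * sd + 0.02 * expected_p


# ---------------------------------------------------------------------------
# full realizations


def test_zero_photon_pulse_is_static(small_cluster, table):
    p = gaussian_profile(9.0, 0.0, 256)
    traj = run_realization(small_cluster, p, IDENTITY_Q, seed=4, table=table)
    assert traj.n_snapshots == 10
    for k in range(10):
        np.testing.assert_array_equal(traj.positions[k], traj.initial_positions)
        assert traj.occupations[k].sum() == sum(
            el.Z for el in (traj.elements[i] for i in traj.elem_idx))
        assert len(traj.electron_positions[k]) == 0


def test_realization_determinism(small_cluster, nominal_pulse, table):
    quat = random_rotation(8)
    a = run_realization(small_cluster, nominal_pulse, quat, seed=21, table=table)
    b = run_realization(small_cluster, nominal_pulse, quat, seed=21, table=table)
    np.testing.assert_array_equal(a.times, b.times)
    for k in range(a.n_snapshots):
        np.testing.assert_array_equal(a.positions[k], b.positions[k])
        np.testing.assert_array_equal(a.occupations[k], b.occupations[k])
    assert np.all(a.n_escaped == b.n_escaped)


def test_realization_charge_monotone_and_conserved(small_cluster,
                                                   nominal_pulse, table):
    traj = run_realization(small_cluster, nominal_pulse, random_rotation(1),
                           seed=5, table=table)
    bound = np.array([occ.sum() for occ in traj.occupations])
    assert np.all(np.diff(bound) <= 0)        # ionization only removes electrons
    assert bound[-1] < bound[0]               # the nominal pulse does damage
    # ledger + explicit electrons account for every removed electron
    z_total = sum(el.Z for el in (traj.elements[i] for i in traj.elem_idx))
    for k in range(traj.n_snapshots):
        removed = z_total - traj.occupations[k].sum()
        assert removed >= len(traj.electron_positions[k])
        assert removed >= traj.n_escaped[k]


def test_trajectory_hdf5_round_trip(tmp_path, small_cluster, nominal_pulse, table):
    traj = run_realization(small_cluster, nominal_pulse, random_rotation(2),
                           seed=6, table=table)
    f = tmp_path / "traj.h5"
    save_trajectory(traj, f)
    back = load_trajectory(f, table)
    np.testing.assert_allclose(back.times, traj.times)
    for k in range(traj.n_snapshots):
        np.testing.assert_allclose(back.positions[k], traj.positions[k])
        np.testing.assert_array_equal(back.occupations[k], traj.occupations[k])
    np.testing.assert_allclose(back.orientation, traj.orientation)
    assert back.seed == traj.seed
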