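"""Ensemble statistics: hand-value oracles and estimator consistency."""

import math

import numpy as np
import pytest

from spisim.analysis import (
    orientation_damage_test,
    r_factor_curve,
    radial_profile,
    shell_average,
    species_bound_electrons,
    species_displacement,
    subset_convergence,
    total_final_ionization,
    voxel_ensemble_stats,
    write_curve,
)
from spisim.diffraction import IntensityVolume, build_qgrid
from spisim.dynamics import run_realization
from spisim.molecule_io import AtomRecords
from spisim.pulse import gaussian_profile
from spisim.synthetic import iid_volume_ensemble

IDENTITY_Q = np.array([0.0, 0.0, 0.0, 1.0])


@pytest.fixture(scope="module")
def static_trajs(table):
    """Three identical undamaged trajectories of a tiny C/O cluster."""
    rec = AtomRecords(np.array(["C", "C", "O", "H"]),
                      np.array([[0.0, 0, 0], [3.0, 0, 0],
                                [0, 3.0, 0], [0, 0, 3.0]]))
    pulse = gaussian_profile(9.0, 0.0, 128)
    return [run_realization(rec, pulse, IDENTITY_Q, seed=s, table=table)
            for s in range(3)]


@pytest.fixture(scope="module")
def small_grid():
    return build_qgrid(10.0, 2.0, 4.0)


# ---------------------------------------------------------------------------
# per-species time series and profiles


def test_bound_electrons_static(static_trajs):
    ts = species_bound_electrons(static_trajs, "C")
    np.testing.assert_allclose(ts.mean, 6.0)
    np.testing.assert_allclose(ts.sem, 0.0)
    ts_o = species_bound_electrons(static_trajs, "O")
    np.testing.assert_allclose(ts_o.mean, 8.0)


def test_bound_electrons_hand_ensemble(static_trajs):
    """Hand-modified occupations reproduce the arithmetic mean."""
    import copy
    trajs = [copy.deepcopy(t) for t in static_trajs[:2]]
    for k in range(trajs[0].n_snapshots):
        trajs[0].occupations[k][0, 2] = 0     # C atom 0 → 4 electrons
    # C means: traj0 (4+6)/2 = 5, traj1 6 → ensemble 5.5
    ts = species_bound_electrons(trajs, "C")
    np.testing.assert_allclose(ts.mean, 5.5)


def test_species_validation(static_trajs):
    with pytest.raises(ValueError):
        species_bound_electrons(static_trajs, "Zn")
    with pytest.raises(ValueError):
        species_bound_electrons([], "C")


def test_displacement_static_and_translated(static_trajs):
    ts = species_displacement(static_trajs, "C")
    np.testing.assert_allclose(ts.mean, 0.0)
    import copy
    t = copy.deepcopy(static_trajs[0])
    for k in range(t.n_snapshots):
        t.positions[k] = t.initial_positions + np.array([1.0, 2.0, 2.0])
    ts2 = species_displacement([t], "C")
    np.testing.assert_allclose(ts2.mean, 3.0)     # |(1,2,2)| for every atom


def test_radial_profile_two_shells(table):
    """Two radial shells with hand-set bound counts give two exact levels."""
    inner = [[1.5, 0, 0], [-1.5, 0, 0], [0, 1.5, 0], [0, -1.5, 0]]
    outer = [[9.0, 0, 0], [-9.0, 0, 0], [0, 9.0, 0], [0, -9.0, 0]]
    rec = AtomRecords(np.array(["C"] * 8), np.array(inner + outer, float))
    pulse = gaussian_profile(9.0, 0.0, 128)
    traj = run_realization(rec, pulse, IDENTITY_Q, seed=0, table=table)
    for k in range(traj.n_snapshots):
        traj.occupations[k][:4, 2] = 0       # inner atoms doubly ionized
    prof = radial_profile([traj], "C", "bound_electrons", n_bins=2)
    np.testing.assert_allclose(prof.mean, [4.0, 6.0])
    assert list(prof.counts) == [4, 4]
    # displacement of a static trajectory is identically zero
    prof_d = radial_profile([traj], "C", "displacement", n_bins=2)
    np.testing.assert_allclose(prof_d.mean, 0.0)
    with pytest.raises(ValueError):
        radial_profile([traj], "C", "velocity")


# ---------------------------------------------------------------------------
# voxel statistics, shells, R-factor


def test_voxel_stats_hand_values(small_grid):
    shape = small_grid.shape
    vols = [IntensityVolume(small_grid, np.full(shape, v)) for v in (1.0, 2.0, 3.0)]
    mean, sd, rel = voxel_ensemble_stats(vols)
    np.testing.assert_allclose(mean, 2.0)
    np.testing.assert_allclose(sd, 1.0)
    np.testing.assert_allclose(rel, 0.5)
    same = [IntensityVolume(small_grid, np.full(shape, 2.0))] * 3
    _, sd0, rel0 = voxel_ensemble_stats(same)
    np.testing.assert_allclose(sd0, 0.0)
    np.testing.assert_allclose(rel0, 0.0)
    with pytest.raises(ValueError):
        voxel_ensemble_stats(vols[:1])


def test_voxel_stats_match_two_pass_reference(small_grid, rng):
    vols = iid_volume_ensemble(small_grid, 30, 0.2, seed=5)
    stack = np.stack([v.intensity for v in vols])
    mean, sd, rel = voxel_ensemble_stats(vols)
    # independent two-pass computation
    mu = stack.sum(axis=0) / len(vols)
    var = ((stack - mu) ** 2).sum(axis=0) / (len(vols) - 1)
    np.testing.assert_allclose(mean, mu, rtol=1e-12)
    np.testing.assert_allclose(sd, np.sqrt(var), rtol=1e-10)


def test_shell_average_constant_and_linear(small_grid):
    const = np.full(small_grid.shape, 7.0)
    q, means, counts = shell_average(const, small_grid, 5)
    np.testing.assert_allclose(means[counts > 0], 7.0)
    qmag = small_grid.q_magnitude()
    q2, means2, counts2 = shell_average(qmag, small_grid, 5)
    ok = counts2 > 0
    np.testing.assert_allclose(means2[ok], q2[ok], atol=small_grid.q_edge / 5)


def test_shell_average_friedel_invariance(small_grid, rng):
    vals = rng.random(small_grid.shape)
    sym = vals + vals[::-1, ::-1, ::-1]
    _, m1, _ = shell_average(sym, small_grid, 6)
    _, m2, _ = shell_average(sym[::-1, ::-1, ::-1], small_grid, 6)
    np.testing.assert_allclose(m1, m2, rtol=1e-12)


def test_r_factor_identities(small_grid):
    shape = small_grid.shape
    base = np.full(shape, 4.0)
    ideal = IntensityVolume(small_grid, base)
    same = r_factor_curve(IntensityVolume(small_grid, base.copy()), ideal, 5)
    np.testing.assert_allclose(same.r[same.counts > 0], 0.0)
    np.testing.assert_allclose(same.r_cumulative[-1], 0.0)
    # uniform 4× intensity ratio → amplitudes doubled → R = 1
    quad = r_factor_curve(IntensityVolume(small_grid, 4.0 * base), ideal, 5)
    np.testing.assert_allclose(quad.r[quad.counts > 0], 1.0, rtol=1e-12)
    # scale invariance: multiplying both volumes changes nothing
    a = IntensityVolume(small_grid, 4.0 * base)
    scaled = r_factor_curve(IntensityVolume(small_grid, 40.0 * base),
                            IntensityVolume(small_grid, 10.0 * base), 5)
    np.testing.assert_allclose(scaled.r[scaled.counts > 0], 1.0, rtol=1e-12)
    # resolution labels follow d = 2π/q
    np.testing.assert_allclose(quad.d_centers, 2 * math.pi / quad.q_centers)


def test_r_factor_hand_example():
    """Bin with ideal I ∈ {1,4} half-and-half, damaged ≡ 1 → R = 1/3.

    Per pair of voxels: numerator |1−1| + |1−2| = 1, denominator 1 + 2 = 3.
    """
    grid = build_qgrid(4.0, 1.0, 2.1)     # 3³ grid, q_edge ≈ 2.99
    ideal = np.ones(grid.shape)
    damaged = np.ones(grid.shape)
    c = grid.n_half
    # the |q| = dq shell holds exactly the 6 face voxels; set 3 of them to 4
    ideal[c + 1, c, c] = 4.0
    ideal[c - 1, c, c] = 4.0
    ideal[c, c + 1, c] = 4.0
    n_bins = 5                            # isolates the face-voxel shell
    curve = r_factor_curve(IntensityVolume(grid, damaged),
                           IntensityVolume(grid, ideal), n_bins=n_bins)
    edges = np.linspace(0, grid.q_edge * (1 + 1e-12), n_bins + 1)
    which = np.digitize(grid.dq, edges) - 1
    assert curve.counts[which] == 6
    assert curve.r[which] == pytest.approx(1.0 / 3.0)


def test_grid_mismatch_rejected(small_grid):
    other = build_qgrid(12.0, 2.0, 4.0)
    a = IntensityVolume(small_grid, np.ones(small_grid.shape))
    b = IntensityVolume(other, np.ones(other.shape))
    with pytest.raises(ValueError):
        r_factor_curve(a, b)
    with pytest.raises(ValueError):
        voxel_ensemble_stats([a, b])


# ---------------------------------------------------------------------------
# convergence and orientation tests


def test_subset_convergence_identical_volumes(small_grid):
    vols = iid_volume_ensemble(small_grid, 30, 0.0, seed=2)
    out = subset_convergence(vols, [4, 9], n_resamples=10, seed=0)
    assert out["sizes"][4]["worst"] == pytest.approx(0.0, abs=1e-12)
    assert out["sizes"][9]["worst"] == pytest.approx(0.0, abs=1e-12)


def test_subset_convergence_tracks_sqrt_N(small_grid):
    """iid volumes with known noise follow the σ/√N CLT scaling."""
    rel_sd = 0.2
    vols = iid_volume_ensemble(small_grid, 120, rel_sd, seed=9)
    out = subset_convergence(vols, [4, 9, 16], n_resamples=60, seed=1)
    for N in (4, 9, 16):
        got = out["sizes"][N]["worst"]
        clt = rel_sd / math.sqrt(N)
        assert abs(got - clt) / clt < 0.2
    # monotone decrease with N
    worsts = [out["sizes"][N]["worst"] for N in (4, 9, 16)]
    assert worsts[0] > worsts[1] > worsts[2]


def test_subset_size_validation(small_grid):
    vols = iid_volume_ensemble(small_grid, 5, 0.1, seed=0)
    with pytest.raises(ValueError):
        subset_convergence(vols, [10], n_resamples=5, seed=0)


def test_orientation_test_calibration(rng):
    """Type-I error ≈ the nominal level for same-distribution groups."""
    rejections = 0
    n_runs = 300
    for r in range(n_runs):
        groups = [rng.normal(50, 5, 8) for _ in range(4)]
        _, _, negligible = orientation_damage_test(groups, alpha=0.05)
        rejections += not negligible
    rate = rejections / n_runs
    assert rate < 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_runs)


def test_orientation_test_edge_cases(rng):
    const = [np.full(6, 10.0) for _ in range(3)]
    stat, p, negligible = orientation_damage_test(const)
    assert negligible and p == 1.0
    shifted = [rng.normal(0, 1, 10), rng.normal(10, 1, 10)]
    _, _, negligible = orientation_damage_test(shifted)
    assert not negligible
    with pytest.raises(ValueError):
        orientation_damage_test([np.ones(3), np.ones(3)])
    with pytest.raises(ValueError):
        orientation_damage_test([np.ones(10)])


def test_total_final_ionization(static_trajs):
    assert total_final_ionization(static_trajs[0]) == 0


def test_write_curve(tmp_path):
    f = tmp_path / "curve.tsv"
    write_curve(f, {"q": [1.0, 2.0], "r": [0.1, 0.2]})
    data = np.loadtxt(f)
    np.testing.assert_allclose(data, [[1.0, 0.1], [2.0, 0.2]])
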