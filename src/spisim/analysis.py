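"""Ensemble statistics over many damage realizations.

Implements the statistical pipeline that turns trajectory ensembles and
reciprocal-space volumes into the quantities of interest: per-species
bound-electron and displacement time series, radial damage profiles at the
pulse maximum, per-voxel relative standard deviation averaged on constant-q
shells, the resolution-binned R-factor against the undamaged reference,
realization-count convergence of the mean image, and a rank-based check
that damage does not depend on molecule orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .diffraction import IntensityVolume, ReciprocalGrid
from .dynamics import Trajectory


@dataclass
class TimeSeries:
    """Mean of a per-atom quantity vs snapshot time with standard errors."""

    t: np.ndarray
    mean: np.ndarray
    sem: np.ndarray


@dataclass
class Profile:
    """Radially binned mean of a per-atom quantity."""

    r_centers: np.ndarray
    mean: np.ndarray
    counts: np.ndarray


def _species_mask(traj: Trajectory, species: str) -> np.ndarray:
    mask = traj.symbols() == species
    if not mask.any():
        raise ValueError(f"species {species!r} not present in trajectory")
    return mask


def species_bound_electrons(trajectories: list[Trajectory], species: str
                            ) -> TimeSeries:
    """Mean bound electrons per atom of one species vs time.

    Averaged over atoms within each realization, then over realizations;
    the standard error is across realizations.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    t = trajectories[0].times
    per_real = []
    for traj in trajectories:
        mask = _species_mask(traj, species)
        per_real.append([traj.occupations[k][mask].sum(axis=1).mean()
                         for k in range(traj.n_snapshots)])
    arr = np.asarray(per_real)
    sem = arr.std(axis=0, ddof=1) / math.sqrt(len(arr)) if len(arr) > 1 \
        else np.zeros(arr.shape[1])
    return TimeSeries(t, arr.mean(axis=0), sem)


def species_displacement(trajectories: list[Trajectory], species: str
                         ) -> TimeSeries:
    """Mean |r(t) − r(start)| per species vs time, lab frame."""
    if not trajectories:
        raise ValueError("need at least one trajectory")
    t = trajectories[0].times
    per_real = []
    for traj in trajectories:
        mask = _species_mask(traj, species)
        r0 = traj.initial_positions[mask]
        per_real.append([np.linalg.norm(traj.positions[k][mask] - r0, axis=1).mean()
                         for k in range(traj.n_snapshots)])
    arr = np.asarray(per_real)
    sem = arr.std(axis=0, ddof=1) / math.sqrt(len(arr)) if len(arr) > 1 \
        else np.zeros(arr.shape[1])
    return TimeSeries(t, arr.mean(axis=0), sem)


def radial_profile(trajectories: list[Trajectory], species: str,
                   quantity: str, n_bins: int = 10,
                   t_zero: float = 0.0) -> Profile:
    """Radial binning of bound electrons or displacement at time zero.

    Radii are initial distances from the molecule's center of mass; the
    snapshot nearest ``t_zero`` is used.  Bins are equal-width from 0 to
    the maximum radius; empty bins carry NaN means and zero counts.
    """
    if quantity not in ("bound_electrons", "displacement"):
        raise ValueError(f"unknown quantity {quantity!r}")
    values, radii = [], []
    for traj in trajectories:
        mask = _species_mask(traj, species)
        k = int(np.argmin(np.abs(traj.times - t_zero)))
        r = np.linalg.norm(traj.initial_positions[mask]
                           - traj.rotation_center, axis=1)
        if quantity == "bound_electrons":
            v = traj.occupations[k][mask].sum(axis=1)
        else:
            v = np.linalg.norm(traj.positions[k][mask]
                               - traj.initial_positions[mask], axis=1)
        values.append(v)
        radii.append(r)
    values = np.concatenate(values)
    radii = np.concatenate(radii)
    edges = np.linspace(0.0, radii.max() * (1 + 1e-12), n_bins + 1)
    which = np.clip(np.digitize(radii, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=values, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Profile(centers, mean, counts)


# ---------------------------------------------------------------------------
# reciprocal-space statistics


def voxel_ensemble_stats(volumes: list[IntensityVolume]
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel mean, sample SD (n−1) and relative SD over an ensemble.

    Voxels with zero mean get NaN relative SD (flagged, excluded from
    shell averages downstream).
    """
    if len(volumes) < 2:
        raise ValueError("need at least two volumes")
    grid = volumes[0].grid
    for v in volumes[1:]:
        if v.grid != grid:
            raise ValueError("volumes are on different grids")
    stack = np.stack([v.intensity for v in volumes])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(mean > 0, sd / mean, np.nan)
    return mean, sd, rel


def shell_average(values: np.ndarray, grid: ReciprocalGrid, n_shells: int = 20
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unweighted mean over voxels in equal-width |q| shells.

    Returns (q_centers, shell means, voxel counts).  NaN voxels are
    excluded from their shell's average and count.
    """
    if n_shells < 2:
        raise ValueError("need at least 2 shells")
    qmag = grid.q_magnitude().ravel()
    vals = np.asarray(values, dtype=float).ravel()
    edges = np.linspace(0.0, grid.q_edge * (1 + 1e-12), n_shells + 1)
    inside = qmag <= grid.q_edge
    ok = inside & np.isfinite(vals)
    which = np.clip(np.digitize(qmag[ok], edges) - 1, 0, n_shells - 1)
    counts = np.bincount(which, minlength=n_shells)
    sums = np.bincount(which, weights=vals[ok], minlength=n_shells)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, means, counts


@dataclass
class RFactorCurve:
    """R vs full-period resolution, bin-wise and cumulative."""

    q_centers: np.ndarray
    d_centers: np.ndarray        # 2π/q
    r: np.ndarray
    r_cumulative: np.ndarray     # up to (finer than) each bin's outer edge
    counts: np.ndarray


def r_factor_curve(mean_damaged: IntensityVolume, ideal: IntensityVolume,
                   n_bins: int = 20) -> RFactorCurve:
    """Amplitude R-factor per resolution bin.

    R = Σ|√I_damaged − √I_ideal| / Σ√I_ideal over voxels in each
    equal-width |q| bin (labelled by d = 2π/q), plus the cumulative
    variant including all voxels up to each bin's outer q edge.  Both
    volumes must share a grid and normalization convention.
    """
    if mean_damaged.grid != ideal.grid:
        raise ValueError("volumes are on different grids")
    grid = ideal.grid
    qmag = grid.q_magnitude().ravel()
    a_dam = np.sqrt(mean_damaged.intensity.ravel())
    a_id = np.sqrt(ideal.intensity.ravel())
    edges = np.linspace(0.0, grid.q_edge * (1 + 1e-12), n_bins + 1)
    inside = qmag <= grid.q_edge
    which = np.clip(np.digitize(qmag[inside], edges) - 1, 0, n_bins - 1)
    num = np.bincount(which, weights=np.abs(a_dam - a_id)[inside],
                      minlength=n_bins)
    den = np.bincount(which, weights=a_id[inside], minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, np.nan)
    num_c = np.cumsum(num)
    den_c = np.cumsum(den)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_cum = np.where(den_c > 0, num_c / den_c, np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(divide="ignore"):
        d_centers = 2.0 * math.pi / centers
    return RFactorCurve(centers, d_centers, r, r_cum, counts)


def subset_convergence(volumes: list[IntensityVolume], subset_sizes,
                       n_resamples: int = 30, seed: int = 0,
                       n_shells: int = 10) -> dict:
    """Relative SD of the N-realization mean image vs N.

    For each subset size N, random N-subsets are drawn, their mean volumes
    computed, and the SD of those means across resamples — relative to the
    full-ensemble mean — is shell-averaged.  The central-limit prediction
    (per-realization relative SD divided by √N) is reported alongside.
    """
    subset_sizes = list(subset_sizes)
    if max(subset_sizes) > len(volumes):
        raise ValueError("subset size exceeds the number of volumes")
    rng = np.random.default_rng(seed)
    grid = volumes[0].grid
    stack = np.stack([v.intensity for v in volumes])
    full_mean = stack.mean(axis=0)
    _, _, rel_single = voxel_ensemble_stats(volumes)
    q_centers, clt_shell, _ = shell_average(rel_single, grid, n_shells)
    out = {"q_centers": q_centers, "sizes": {}}
    for N in subset_sizes:
        means = np.empty((n_resamples,) + grid.shape)
        for r in range(n_resamples):
            pick = rng.choice(len(volumes), size=N, replace=False)
            means[r] = stack[pick].mean(axis=0)
        sd = means.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(full_mean > 0, sd / full_mean, np.nan)
        _, shell_rel, _ = shell_average(rel, grid, n_shells)
        out["sizes"][N] = {
            "shell_rel_sd": shell_rel,
            "worst": float(np.nanmax(shell_rel)),
            "clt_shell": clt_shell / math.sqrt(N),
            "clt_worst": float(np.nanmax(clt_shell)) / math.sqrt(N),
        }
    return out


def orientation_damage_test(groups: list[np.ndarray], alpha: float = 0.05
                            ) -> tuple[float, float, bool]:
    """Kruskal–Wallis comparison of total final ionization across orientations.

    ``groups`` holds, per orientation, the total final ionization of each
    realization.  Returns (statistic, p-value, negligible-flag); the flag
    is True when the test does *not* reject at level ``alpha``, i.e. damage
    is consistent with being orientation-independent.
    """
    if len(groups) < 2:
        raise ValueError("need at least two orientation groups")
    if any(len(g) < 5 for g in groups):
        raise ValueError("need at least five realizations per group")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if np.ptp(np.concatenate(groups)) == 0:
        return 0.0, 1.0, True  # identical constants: trivially no rejection
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p), bool(p >= alpha)


def total_final_ionization(traj: Trajectory) -> int:
    """Total electrons removed from atoms by the last snapshot."""
    neutral = sum(el.Z for el in
                  (traj.elements[i] for i in traj.elem_idx))
    return int(neutral - traj.occupations[-1].sum())


def write_curve(path, columns: dict) -> None:
    """Write named columns as a delimited text table with a header."""
    names = list(columns)
    arr = np.column_stack([np.asarray(columns[n], dtype=float) for n in names])
    np.savetxt(path, arr, header="\t".join(names), delimiter="\t")
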