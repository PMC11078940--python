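"""Synthetic inputs: biomolecule-like clusters and seeded volume ensembles.

The production inputs (a deposited ribosome structure, measured SASE pulse
sets) are too large or unavailable for desk-scale work, so every test input
is generated here: random atomic clusters with biomolecular stoichiometry
and packing, tiny structures with closed-form diffraction, and iid
reciprocal-space volume ensembles with controlled voxel noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .diffraction import IntensityVolume, ReciprocalGrid
from .molecule_io import AtomRecords

#: approximate stoichiometry of a ribonucleoprotein assembly
RIBOSOME_FRACTIONS = {"H": 0.41, "C": 0.27, "N": 0.10, "O": 0.20, "P": 0.02}

#: typical atomic number density of a biomolecule (atoms/Å³, H included)
BIOMOLECULE_DENSITY = 0.1


@dataclass(frozen=True)
class ClusterSpec:
    """Recipe for a random biomolecule-like atomic cluster."""

    n_atoms: int
    radius: float                          # Å, ball radius
    fractions: dict = field(default_factory=lambda: dict(RIBOSOME_FRACTIONS))
    min_separation: float = 1.5            # Å
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_atoms < 2:
            raise ValueError("need at least 2 atoms")
        if self.min_separation <= 0:
            raise ValueError("min separation must be positive")
        if not math.isclose(sum(self.fractions.values()), 1.0, rel_tol=1e-9):
            raise ValueError("element fractions must sum to 1")


def radius_for_density(n_atoms: int, density: float = BIOMOLECULE_DENSITY
                       ) -> float:
    """Ball radius holding ``n_atoms`` at a given number density."""
    return (3.0 * n_atoms / (4.0 * math.pi * density)) ** (1.0 / 3.0)


def toy_molecule(spec: ClusterSpec) -> AtomRecords:
    """Random cluster in a ball with enforced minimum separation.

    Rejection sampling; element symbols are drawn multinomially from the
    spec's fractions.  Deterministic per seed.  Raises if the packing is
    infeasible within a bounded number of attempts.
    """
    volume_ratio = spec.n_atoms * spec.min_separation**3 / spec.radius**3
    if volume_ratio > 3.0:   # ~half the close-packing limit for a ball
        raise ValueError(f"infeasible packing: n·s³/R³ = {volume_ratio:.2f}")
    rng = np.random.default_rng(spec.seed)
    pts = np.empty((spec.n_atoms, 3))
    n_placed = 0
    attempts = 0
    max_attempts = 400 * spec.n_atoms
    while n_placed < spec.n_atoms:
        if attempts >= max_attempts:
            raise ValueError(f"packing failed after {max_attempts} attempts "
                             f"({n_placed}/{spec.n_atoms} placed)")
        attempts += 1
        p = rng.uniform(-spec.radius, spec.radius, 3)
        if p @ p > spec.radius**2:
            continue
        if n_placed and np.min(np.sum((pts[:n_placed] - p) ** 2, axis=1)) \
                < spec.min_separation**2:
            continue
        pts[n_placed] = p
        n_placed += 1
    symbols = rng.choice(list(spec.fractions), size=spec.n_atoms,
                         p=list(spec.fractions.values()))
    return AtomRecords(symbols, pts)


def exact_fixtures() -> dict[str, AtomRecords]:
    """Tiny structures with closed-form ideal diffraction.

    - ``single_carbon``: one C at the origin — I(q) = f_C(q)².
    - ``carbon_pair``: two C atoms 10 Å apart along x — coherent term
      4 f² at q = 2π/10 x̂ (in phase) and 0 at q = π/10 x̂ (antiphase).
    - ``carbon_cubic``: 3×3×3 simple-cubic carbon lattice, a = 3 Å —
      Laue peaks I = 27² f² at q = (2π/a)·integer triples.
    """
    single = AtomRecords(np.array(["C"]), np.zeros((1, 3)))
    pair = AtomRecords(np.array(["C", "C"]),
                       np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]]))
    a = 3.0
    grid = np.array([[i, j, k] for i in range(3) for j in range(3)
                     for k in range(3)], dtype=float) * a
    grid -= grid.mean(axis=0)
    cubic = AtomRecords(np.array(["C"] * 27), grid)
    return {"single_carbon": single, "carbon_pair": pair, "carbon_cubic": cubic}


def iid_volume_ensemble(grid: ReciprocalGrid, n: int, rel_sd: float,
                        seed: int = 0, base: np.ndarray | None = None
                        ) -> list[IntensityVolume]:
    """iid volumes: base intensity × lognormal multiplicative voxel noise.

    The lognormal is parameterized to unit mean and relative SD ``rel_sd``
    per voxel, matching the statistical structure the shell/convergence
    analysis assumes.  Deterministic per seed.
    """
    if n < 2:
        raise ValueError("need at least 2 volumes")
    if rel_sd < 0:
        raise ValueError("relative SD must be ≥ 0")
    if base is None:
        qmag = grid.q_magnitude()
        base = 1e4 / (1.0 + (4.0 * qmag / grid.q_edge) ** 4) + 1.0
    rng = np.random.default_rng(seed)
    if rel_sd == 0.0:
        return [IntensityVolume(grid, base.copy()) for _ in range(n)]
    s2 = math.log1p(rel_sd**2)
    mu = -0.5 * s2
    out = []
    for _ in range(n):
        noise = rng.lognormal(mean=mu, sigma=math.sqrt(s2), size=grid.shape)
        out.append(IntensityVolume(grid, base * noise))
    return out
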