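"""Read/write molecular structures and compute geometric summaries.

Structures come in as classic PDB or PDBx/mmCIF (large assemblies are
distributed as mmCIF only); all models and chains are flattened into one
atom set, because the simulator images the entire deposited assembly.
Only the first alternate-location conformer is kept.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist


@dataclass
class AtomRecords:
    """Flat per-atom element symbols and Cartesian coordinates (Å)."""

    symbols: np.ndarray            # (n,) unicode
    coords: np.ndarray             # (n, 3) float64
    ids: list | None = None        # optional per-atom record identifiers

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype="U4")
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.symbols) != len(self.coords):
            raise ValueError("symbols and coords length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.symbols)


def read_structure(path, include_hydrogens: bool = True) -> AtomRecords:
    """Read a PDB or mmCIF file into :class:`AtomRecords`.

    One record per atom across all models and chains; element symbols come
    from the element column with gemmi's atom-name fallback.  Alternate
    locations beyond the first conformer are dropped.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to parse {path}: {exc}") from exc
    st.remove_alternative_conformations()
    symbols, coords, ids = [], [], []
    unknown: set[str] = set()
    for model in st:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    el = atom.element
                    if el.atomic_number == 0:
                        unknown.add(atom.name)
                        continue
                    if not include_hydrogens and el.is_hydrogen:
                        continue
                    symbols.append("H" if el.is_hydrogen else el.name)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    ids.append((model.num, chain.name, residue.seqid.num, atom.name))
    if unknown:
        raise ValueError(f"atoms with unresolvable element in {path}: {sorted(unknown)}")
    return AtomRecords(np.array(symbols), np.array(coords, dtype=float), ids)


def write_structure(records: AtomRecords, path) -> None:
    """Write records as a minimal single-chain PDB file."""
    with open(path, "w") as fh:
        for i, (sym, xyz) in enumerate(zip(records.symbols, records.coords), start=1):
            name = sym.rjust(2) if len(sym) == 2 else f" {sym}".ljust(3)
            fh.write(
                f"ATOM  {i % 100000:5d} {name:<4s} UNK A{(i - 1) % 10000:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                f"          {sym:>2s}\n"
            )
        fh.write("END\n")


def element_counts(records: AtomRecords) -> dict[str, int]:
    """Number of atoms per element symbol."""
    if len(records) == 0:
        raise ValueError("empty records")
    return dict(Counter(records.symbols.tolist()))


def max_pairwise_distance(records: AtomRecords) -> float:
    """Exact maximum atom–atom separation (Å).

    For large sets the diameter is found on the convex hull (exact: the
    farthest pair is always a pair of hull vertices); degenerate geometries
    fall back to the O(n²) scan.
    """
    pts = records.coords
    if len(pts) < 2:
        raise ValueError("need at least 2 atoms")
    if len(pts) > 500:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass  # flat/collinear input: brute force below
    return float(pdist(pts).max())


def center_of_mass(records: AtomRecords) -> np.ndarray:
    """Mass-weighted mean position (Å), standard atomic masses."""
    if len(records) == 0:
        raise ValueError("empty records")
    masses = np.array([gemmi.Element(s).weight for s in records.symbols])
    return masses @ records.coords / masses.sum()
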