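"""Molecular geometry container, XYZ I/O and distance-based bond perception.

Coordinates are stored in bohr everywhere inside the package; XYZ files use
the de-facto Angstrom convention and are converted on read/write.  Charge and
spin multiplicity default to a neutral closed shell and may be overridden in
the XYZ comment line as ``charge=<int> mult=<int>``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .elements import (
    ANGSTROM_PER_BOHR,
    BOHR_PER_ANGSTROM,
    ElementError,
    atomic_number,
    covalent_radius,
)

__all__ = ["Molecule", "MoleculeError", "XYZParseError", "read_xyz", "write_xyz", "perceive_bonds"]

MIN_INTERATOMIC_DISTANCE = 0.5  # bohr


class MoleculeError(ValueError):
    pass


class XYZParseError(ValueError):
    pass


@dataclass(frozen=True)
class Molecule:
    """Atoms, Cartesian coordinates in bohr, total charge/multiplicity, bonds.

    ``bonds`` is a sorted tuple of index pairs (i < j); the adjacency it
    induces is symmetric by construction.
    """

    symbols: tuple[str, ...]
    coords: np.ndarray  # (natoms, 3), bohr
    charge: int = 0
    multiplicity: int = 1
    bonds: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (len(self.symbols), 3):
            raise MoleculeError(
                f"coords shape {coords.shape} does not match {len(self.symbols)} atoms"
            )
        if not np.all(np.isfinite(coords)):
            raise MoleculeError("non-finite coordinates")
        object.__setattr__(self, "coords", coords)
        for sym in self.symbols:
            atomic_number(sym)  # raises ElementError on unknown symbols
        n = len(self.symbols)
        if n > 1:
            d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() < MIN_INTERATOMIC_DISTANCE:
                i, j = np.unravel_index(np.argmin(d), d.shape)
                raise MoleculeError(
                    f"atoms {i} and {j} are {d[i, j]:.3f} bohr apart "
                    f"(< {MIN_INTERATOMIC_DISTANCE} bohr)"
                )
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise MoleculeError(f"invalid bond ({i}, {j})")
        object.__setattr__(
            self, "bonds", tuple(sorted(tuple(sorted(b)) for b in set(map(tuple, self.bonds))))
        )

    @property
    def natoms(self) -> int:
        return len(self.symbols)

    @property
    def numbers(self) -> np.ndarray:
        return np.array([atomic_number(s) for s in self.symbols])

    @property
    def adjacency(self) -> tuple[tuple[int, ...], ...]:
        """Per-atom tuple of bonded neighbour indices (symmetric)."""
        nbrs: list[list[int]] = [[] for _ in range(self.natoms)]
        for i, j in self.bonds:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return tuple(tuple(sorted(x)) for x in nbrs)

    def neighbors(self, idx: int) -> tuple[int, ...]:
        if not 0 <= idx < self.natoms:
            raise IndexError(f"atom index {idx} out of range for {self.natoms} atoms")
        return self.adjacency[idx]

    def center_of_nuclear_charge(self) -> np.ndarray:
        z = self.numbers.astype(float)
        return (z[:, None] * self.coords).sum(axis=0) / z.sum()

    def translated(self, shift) -> "Molecule":
        return replace(self, coords=self.coords + np.asarray(shift, dtype=float))

    def n_electrons(self) -> int:
        return int(self.numbers.sum()) - self.charge


_COMMENT_RE = re.compile(r"(charge|mult)\s*=\s*(-?\d+)")


def read_xyz(source: str | Path) -> Molecule:
    """Parse an XYZ document (path or literal text); Angstrom -> bohr.

    The comment line may carry ``charge=<int> mult=<int>`` overrides.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and source.strip() and "\n" not in source
        and Path(source).is_file()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    lines = text.splitlines()
    if not lines:
        raise XYZParseError("empty XYZ document")
    try:
        natoms = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise XYZParseError(f"line 1: expected an atom count, got {lines[0]!r}") from None
    if natoms < 1:
        raise XYZParseError(f"line 1: atom count must be positive, got {natoms}")
    if len(lines) < natoms + 2:
        raise XYZParseError(f"expected {natoms + 2} lines, got {len(lines)}")
    comment = lines[1]
    charge, mult = 0, 1
    for key, val in _COMMENT_RE.findall(comment):
        if key == "charge":
            charge = int(val)
        else:
            mult = int(val)
    symbols: list[str] = []
    coords = np.empty((natoms, 3))
    for k in range(natoms):
        lineno = k + 3
        parts = lines[k + 2].split()
        if len(parts) < 4:
            raise XYZParseError(f"line {lineno}: expected 'El x y z', got {lines[k + 2]!r}")
        sym = parts[0]
        try:
            atomic_number(sym)
        except ElementError:
            raise ElementError(f"line {lineno}: unknown element symbol {sym!r}") from None
        try:
            coords[k] = [float(p) for p in parts[1:4]]
        except ValueError:
            raise XYZParseError(f"line {lineno}: malformed coordinates in {lines[k + 2]!r}") from None
        symbols.append(sym)
    return Molecule(tuple(symbols), coords * BOHR_PER_ANGSTROM, charge=charge, multiplicity=mult)


def write_xyz(mol: Molecule, path: str | Path | None = None, comment: str | None = None) -> str:
    """Serialize to XYZ text (Angstrom); optionally write to ``path``."""
    if comment is None:
        comment = f"charge={mol.charge} mult={mol.multiplicity}"
    rows = [str(mol.natoms), comment]
    ang = mol.coords * ANGSTROM_PER_BOHR
    for sym, (x, y, z) in zip(mol.symbols, ang):
        rows.append(f"{sym:<3s} {x: 20.12f} {y: 20.12f} {z: 20.12f}")
    text = "\n".join(rows) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def perceive_bonds(mol: Molecule, scale: float = 1.2) -> Molecule:
    """Bond i-j iff |R_i - R_j| <= scale * (r_cov(i) + r_cov(j)).

    Isolated atoms are fine; self-bonds never occur.
    """
    rcov = np.array([covalent_radius(s) for s in mol.symbols])
    bonds: list[tuple[int, int]] = []
    for i in range(mol.natoms):
        for j in range(i + 1, mol.natoms):
            dij = float(np.linalg.norm(mol.coords[i] - mol.coords[j]))
            if dij <= scale * (rcov[i] + rcov[j]):
                bonds.append((i, j))
    return replace(mol, bonds=tuple(bonds))
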