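"""Chemical-environment atom typing over the molecular bond graph.

Each atom is mapped to a canonical key that selects its scheme parameter
(alpha-bar_CE / beta-bar_CE) from an environment-differentiated table.  Heavy
atoms are typed by their element plus the sorted multiset of first-shell
neighbour elements; hydrogens, whose parameters must transfer between
molecules, additionally carry the sorted multiset of second-shell elements
(elements two bonds away).  Keys depend only on connectivity, so they are
invariant under isometries and atom relabelling.
"""

from __future__ import annotations

from dataclasses import dataclass

from .molecule import Molecule

__all__ = ["EnvironmentKey", "classify_atom", "classify_molecule"]


@dataclass(frozen=True)
class EnvironmentKey:
    element: str
    shell1: tuple[str, ...]
    shell2: tuple[str, ...] | None  # populated only for hydrogen

    @property
    def tag(self) -> str:
        s1 = ",".join(self.shell1)
        if self.shell2 is None:
            return f"{self.element}[{s1}]"
        return f"{self.element}[{s1}][{','.join(self.shell2)}]"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.tag


def classify_atom(mol: Molecule, idx: int) -> EnvironmentKey:
    """Canonical environment key of atom ``idx`` (bonds must be perceived).

    Atoms with no bonds get empty shells, which is a valid key.
    """
    if not 0 <= idx < mol.natoms:
        raise IndexError(f"atom index {idx} out of range for {mol.natoms} atoms")
    nbrs = mol.neighbors(idx)
    shell1 = tuple(sorted(mol.symbols[j] for j in nbrs))
    element = mol.symbols[idx]
    if element != "H":
        return EnvironmentKey(element, shell1, None)
    second: list[str] = []
    for j in nbrs:
        for k in mol.neighbors(j):
            if k != idx:
                second.append(mol.symbols[k])
    return EnvironmentKey(element, shell1, tuple(sorted(second)))


def classify_molecule(mol: Molecule) -> dict[int, EnvironmentKey]:
    """Environment key for every atom; ``len(set(...))`` counts distinct types."""
    return {i: classify_atom(mol, i) for i in range(mol.natoms)}
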