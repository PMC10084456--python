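"""Gaussian cube export of scalar fields derived from current tensors.

The two comment lines carry the field provenance (scheme, parameter,
component) so exported volumes remain self-describing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .molecule import Molecule

__all__ = ["write_cube", "regular_grid"]


def regular_grid(origin, shape, step):
    """Points of a regular cube grid; origin/step in bohr."""
    origin = np.asarray(origin, dtype=float)
    nx, ny, nz = shape
    sx, sy, sz = (step, step, step) if np.isscalar(step) else step
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    pts = origin + np.stack(
        [ii * sx, jj * sy, kk * sz], axis=-1
    ).reshape(-1, 3)
    return pts


def write_cube(
    path: str | Path,
    mol: Molecule,
    values: np.ndarray,
    origin,
    shape,
    step,
    comment: str = "scalar field",
    provenance: str = "",
) -> None:
    """Write ``values`` (flattened x-fastest-last, i.e. z innermost) as a cube."""
    origin = np.asarray(origin, dtype=float)
    nx, ny, nz = shape
    sx, sy, sz = (step, step, step) if np.isscalar(step) else step
    vals = np.asarray(values, dtype=float).reshape(nx, ny, nz)
    lines = [comment, provenance]
    lines.append(f"{mol.natoms:5d} {origin[0]:12.6f} {origin[1]:12.6f} {origin[2]:12.6f}")
    lines.append(f"{nx:5d} {sx:12.6f} {0.0:12.6f} {0.0:12.6f}")
    lines.append(f"{ny:5d} {0.0:12.6f} {sy:12.6f} {0.0:12.6f}")
    lines.append(f"{nz:5d} {0.0:12.6f} {0.0:12.6f} {sz:12.6f}")
    for z, xyz in zip(mol.numbers, mol.coords):
        lines.append(
            f"{int(z):5d} {float(z):12.6f} {xyz[0]:12.6f} {xyz[1]:12.6f} {xyz[2]:12.6f}"
        )
    for i in range(nx):
        for j in range(ny):
            row = vals[i, j]
            for s in range(0, nz, 6):
                lines.append(" ".join(f"{v:13.5e}" for v in row[s : s + 6]))
    Path(path).write_text("\n".join(lines) + "\n")
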