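"""Biot-Savart shielding integration over the Becke partition.

The shielding tensor of nucleus N is the volume integral of the current
density tensor contracted with the Biot-Savart geometric kernel,

    sigma_{gl}^N = -(1/c) eps_{g d n} int J_{d l}(r) (R_N - r)_n / |R_N - r|^3 d3r,

reported in ppm (x 1e6); the isotropic component sigma_Av is a third of the
trace.  All nuclei are integrated in a single pass over one molecular grid.
When a per-atom parameter table is supplied, the current inside each Becke
cell I_A uses atom A's parameter via the precomputed unit-parameter kernel
(total = dz1 + param_A * K on A's points), which is exactly the single-run
multi-parameter integration scheme; foreign-cell cross-talk is suppressed by
the partition weight w_A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .becke import MolecularGrid, molecular_grid
from .currents import SchemeMisuseError, _EPS, _dz1_from, _ingredients, _unit_kernel_from
from .elements import SPEED_OF_LIGHT
from .envtype import classify_atom
from .molecule import Molecule

__all__ = [
    "ShieldingResult",
    "ParameterLookupError",
    "shielding_density",
    "integrate_tensor",
    "resolve_atom_parameters",
    "integrate_shielding_all_nuclei",
]

_PPM = 1.0e6


class ParameterLookupError(KeyError):
    pass


def _geometric_kernel(points: np.ndarray, R_N: np.ndarray) -> np.ndarray:
    """G[p, g, d] = eps_{g d n} (R_N - r)_n / |R_N - r|^3, zeroed at R_N."""
    u = R_N[None, :] - points
    d3 = np.linalg.norm(u, axis=1) ** 3
    ok = d3 > 1e-30
    inv = np.zeros_like(d3)
    inv[ok] = 1.0 / d3[ok]
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} grid point(s) coincide with nucleus at {R_N}; "
            "integrand set to 0 there (measure-zero exclusion)"
        )
    return np.einsum("gdn,pn,p->pgd", _EPS, u, inv)


def shielding_density(tensor: np.ndarray, points: np.ndarray, R_N: np.ndarray) -> np.ndarray:
    """Isotropic shielding density Sigma_Av^N(r) in ppm / bohr^3.

    The per-point Biot-Savart integrand whose volume integral is sigma_Av^N.
    """
    G = _geometric_kernel(np.atleast_2d(points), np.asarray(R_N, dtype=float))
    return -(_PPM / (3.0 * SPEED_OF_LIGHT)) * np.einsum("pgd,pdg->p", G, tensor)


def integrate_tensor(
    tensor: np.ndarray, points: np.ndarray, weights: np.ndarray, R_N: np.ndarray
) -> np.ndarray:
    """Full 3x3 shielding tensor (ppm) of nucleus N from a gridded field."""
    G = _geometric_kernel(np.atleast_2d(points), np.asarray(R_N, dtype=float))
    return -(_PPM / SPEED_OF_LIGHT) * np.einsum("p,pgd,pdl->gl", weights, G, tensor)


@dataclass
class ShieldingResult:
    molecule: Molecule
    scheme: str
    atom_parameters: np.ndarray  # (natoms,) parameter used inside each Becke cell
    tensors: np.ndarray  # (natoms, 3, 3), ppm
    grid_spec: dict

    @property
    def sigma_av(self) -> np.ndarray:
        return np.trace(self.tensors, axis1=1, axis2=2) / 3.0

    def to_records(self) -> list[dict]:
        out = []
        for i, sym in enumerate(self.molecule.symbols):
            out.append(
                dict(
                    nucleus=i,
                    element=sym,
                    scheme=self.scheme,
                    parameter=float(self.atom_parameters[i]),
                    sigma_av=float(self.sigma_av[i]),
                    tensor=self.tensors[i].tolist(),
                )
            )
        return out


def resolve_atom_parameters(mol: Molecule, table, scheme: str) -> np.ndarray:
    """Per-atom parameter vector from a scalar, per-atom map, or key table.

    Lookup order per atom: explicit atom index, environment-key tag, element
    symbol.  A missing parameter raises naming the atom and its key; a
    non-negative value warns (both alpha and beta must be lower than zero to
    keep the tropicity of the diamagnetic vortex).
    """
    if np.isscalar(table):
        vals = np.full(mol.natoms, float(table))
    else:
        vals = np.empty(mol.natoms)
        has_bonds = len(mol.bonds) > 0 or mol.natoms == 1
        for i, sym in enumerate(mol.symbols):
            tag = classify_atom(mol, i).tag if has_bonds else None
            if i in table:
                vals[i] = float(table[i])
            elif tag is not None and tag in table:
                vals[i] = float(table[tag])
            elif sym in table:
                vals[i] = float(table[sym])
            else:
                raise ParameterLookupError(
                    f"no {scheme} parameter for atom {i} ({sym}, key {tag!r})"
                )
    if scheme in ("GRRO", "GPRO") and np.any(vals >= 0.0):
        bad = np.nonzero(vals >= 0.0)[0]
        if np.any(vals[bad] > 0.0):
            warnings.warn(
                f"non-negative {scheme} parameter(s) for atom(s) {bad.tolist()}: "
                "alpha and beta must both be lower than zero to keep the "
                "tropicity of the diamagnetic vortex"
            )
    return vals


def integrate_shielding_all_nuclei(
    state,
    parameters=None,
    scheme: str = "GRRO",
    grid: MolecularGrid | None = None,
    rho_cut: float = 1e-10,
    grid_kwargs: dict | None = None,
) -> ShieldingResult:
    """All nuclear shielding tensors in one pass over one molecular grid.

    ``parameters``: scalar (uniform), mapping (atom index / environment tag /
    element -> value), or None (DZ1).  Within the single-center integral I_A
    the current field uses atom A's parameter.
    """
    mol = state.molecule
    if grid is None:
        grid = molecular_grid(mol, **(grid_kwargs or {}))
    if scheme in ("CO",):
        raise SchemeMisuseError("use scheme DZ1/GRRO/GPRO for single-pass integration")
    if scheme == "DZ1" or parameters is None:
        atom_params = np.zeros(mol.natoms)
        scheme_out = "DZ1"
    else:
        atom_params = resolve_atom_parameters(mol, parameters, scheme)
        scheme_out = scheme

    pts, w = grid.points, grid.weights
    rho, grad, KL, KP = _ingredients(state, pts)
    tensor = _dz1_from(pts, state.r0, KL, KP)
    if scheme_out != "DZ1":
        kern = _unit_kernel_from(rho, grad, KP, scheme_out, rho_cut)
        for ia, sl in enumerate(grid.atom_slices):
            tensor[sl] += atom_params[ia] * kern[sl]

    tensors = np.empty((mol.natoms, 3, 3))
    for n in range(mol.natoms):
        tensors[n] = integrate_tensor(tensor, pts, w, mol.coords[n])
    return ShieldingResult(mol, scheme_out, atom_params, tensors, dict(grid.spec))
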