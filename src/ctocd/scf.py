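"""Restricted Hartree-Fock ground state with DIIS acceleration.

Only closed shells are supported; every system treated by the shielding
pipeline is a closed-shell singlet.  The SCF is deterministic: the core
Hamiltonian guess and a fixed iteration schedule give bitwise-reproducible
orbitals for identical inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .basis import Basis
from .integrals import (
    eri_tensor,
    kinetic_matrix,
    nuclear_attraction_matrix,
    overlap_matrix,
)
from .molecule import Molecule

__all__ = ["SCFResult", "ConvergenceError", "OpenShellError", "run_rhf"]


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


class OpenShellError(ValueError):
    pass


@dataclass
class SCFResult:
    energy: float  # hartree, electronic + nuclear repulsion
    mo_coeff: np.ndarray  # (nao, nmo)
    mo_energy: np.ndarray  # (nmo,)
    nocc: int
    overlap: np.ndarray
    eri: np.ndarray
    converged: bool
    n_iter: int


def nuclear_repulsion(mol: Molecule) -> float:
    z = mol.numbers.astype(float)
    e = 0.0
    for i in range(mol.natoms):
        for j in range(i + 1, mol.natoms):
            e += z[i] * z[j] / np.linalg.norm(mol.coords[i] - mol.coords[j])
    return e


def run_rhf(mol: Molecule, basis: Basis, tol: float = 1e-10, max_iter: int = 200) -> SCFResult:
    nelec = mol.n_electrons()
    if mol.multiplicity != 1 or nelec % 2:
        raise OpenShellError(
            f"open-shell input (n_elec={nelec}, mult={mol.multiplicity}) is unsupported"
        )
    nocc = nelec // 2
    S = overlap_matrix(basis)
    T = kinetic_matrix(basis)
    V = nuclear_attraction_matrix(basis, mol)
    eri = eri_tensor(basis)
    h = T + V
    enuc = nuclear_repulsion(mol)

    def fock(D):
        J = np.einsum("mnls,ls->mn", eri, D, optimize=True)
        K = np.einsum("mlns,ls->mn", eri, D, optimize=True)
        return h + J - 0.5 * K

    eps, C = sla.eigh(h, S)
    D = 2.0 * C[:, :nocc] @ C[:, :nocc].T
    energy = 0.0
    trace: list[float] = []
    diis_F: list[np.ndarray] = []
    diis_E: list[np.ndarray] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        F = fock(D)
        err = F @ D @ S - S @ D @ F
        diis_F.append(F)
        diis_E.append(err)
        if len(diis_F) > 8:
            diis_F.pop(0)
            diis_E.pop(0)
        if len(diis_F) > 1:
            m = len(diis_F)
            Bm = -np.ones((m + 1, m + 1))
            Bm[m, m] = 0.0
            for a in range(m):
                for b in range(m):
                    Bm[a, b] = np.vdot(diis_E[a], diis_E[b])
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            try:
                w = np.linalg.solve(Bm, rhs)[:m]
                F = sum(wi * Fi for wi, Fi in zip(w, diis_F))
            except np.linalg.LinAlgError:
                pass
        eps, C = sla.eigh(F, S)
        D_new = 2.0 * C[:, :nocc] @ C[:, :nocc].T
        e_new = 0.5 * np.sum(D_new * (h + fock(D_new))) + enuc
        de = abs(e_new - energy)
        dd = np.max(np.abs(D_new - D))
        trace.append(e_new)
        D, energy = D_new, e_new
        if de < tol and dd < np.sqrt(tol):
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"SCF did not converge in {max_iter} iterations (dE={de:.2e})", trace
        )
    return SCFResult(energy, C, eps, nocc, S, eri, converged, it)
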