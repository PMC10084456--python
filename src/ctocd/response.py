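"""Magnetic response backend: perturbed orbitals and per-point current kernels.

A :class:`ResponseState` bundles the converged ground state with the coupled
perturbed Hartree-Fock (CPHF) response to the six purely imaginary one-electron
perturbations the CTOCD construction needs: the three components of the
angular-momentum operator about a common origin r0 and the three components of
the linear-momentum operator.  Both operators are written H' = i*O with O a
real antisymmetric AO matrix; for such perturbations the first-order density
is imaginary and antisymmetric, the Coulomb response vanishes, and the CPHF
equations reduce to the (A - B) linear system

    sum_bj [ (e_a - e_i) d_ab d_ij - (ab|ij) + (aj|ib) ] V_bj = -O_ai

solved densely (the occupied-virtual dimension is tiny here).  The per-point
paramagnetic current kernel of a solved perturbation is

    K(r) = -2 sum_i [ psi_i(r) grad(vt_i)(r) - vt_i(r) grad(psi_i)(r) ],

with vt_i = sum_a V_ai psi_a, so every CTOCD current becomes a pointwise
contraction of six cached kernel fields -- the structure that makes the total
current exactly linear in the scheme parameter.

Conventions: atomic units; perturbations carry the physical prefactor 1/(2c)
(vector potential A = B x (r - r0)/2, c = 137.035999), so ``l_kernel`` is the
paramagnetic current per unit magnetic field component and ``p_kernel`` is the
current response per unit (1/(2c)) P_gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import Basis, build_basis
from .elements import SPEED_OF_LIGHT
from .integrals import angular_momentum_matrices, derivative_matrices
from .molecule import Molecule
from .scf import SCFResult, run_rhf

__all__ = ["ResponseState", "build_response_state", "UnsupportedMethodError"]


class UnsupportedMethodError(ValueError):
    pass


def _cphf_solve(scf: SCFResult, O_ao: np.ndarray) -> np.ndarray:
    """Solve the imaginary-perturbation CPHF equations for several RHS.

    ``O_ao``: (nrhs, nao, nao) real antisymmetric operator matrices.
    Returns V with shape (nrhs, nvirt, nocc).
    """
    C, eps, nocc = scf.mo_coeff, scf.mo_energy, scf.nocc
    nmo = C.shape[1]
    nvir = nmo - nocc
    Co, Cv = C[:, :nocc], C[:, nocc:]
    # MO-transformed ERIs needed: (ab|ij) and (aj|ib)
    eri = scf.eri
    abij = np.einsum("ma,nb,mnls,li,sj->abij", Cv, Cv, eri, Co, Co, optimize=True)
    ajib = np.einsum("ma,nj,mnls,li,sb->ajib", Cv, Co, eri, Co, Cv, optimize=True)
    de = eps[nocc:, None] - eps[None, :nocc]  # (nvir, nocc)
    M = np.zeros((nvir, nocc, nvir, nocc))
    idx_a, idx_i = np.arange(nvir), np.arange(nocc)
    M[idx_a[:, None], idx_i[None, :], idx_a[:, None], idx_i[None, :]] = de
    M -= abij.transpose(0, 2, 1, 3)  # -(ab|ij) -> index order a,i,b,j
    M += ajib.transpose(0, 2, 3, 1)  # +(aj|ib) -> a,i,b,j
    Mflat = M.reshape(nvir * nocc, nvir * nocc)
    nrhs = O_ao.shape[0]
    V = np.empty((nrhs, nvir, nocc))
    rhs = np.empty((nrhs, nvir * nocc))
    for k in range(nrhs):
        Ovo = Cv.T @ O_ao[k] @ Co
        rhs[k] = -Ovo.reshape(-1)
    sol = np.linalg.solve(Mflat, rhs.T).T
    for k in range(nrhs):
        V[k] = sol[k].reshape(nvir, nocc)
    return V


@dataclass
class ResponseState:
    """Converged ground state plus magnetic/momentum response kernels."""

    molecule: Molecule
    basis: Basis
    basis_name: str
    functional_name: str
    scf: SCFResult
    r0: np.ndarray  # common origin for the angular-momentum kernels
    V_L: np.ndarray  # (3, nvir, nocc) response to (1/2c) L_beta about r0
    V_P: np.ndarray  # (3, nvir, nocc) response to (1/2c) P_gamma
    scf_tol: float
    response_tol: float
    _chunk: int = field(default=20000, repr=False)

    @property
    def n_electrons(self) -> int:
        return self.molecule.n_electrons()

    @property
    def scf_energy(self) -> float:
        return self.scf.energy

    # -- point evaluators -------------------------------------------------
    def _mo_values(self, points):
        vals, grads = self.basis.evaluate(points)
        return vals, grads

    def density(self, points) -> tuple[np.ndarray, np.ndarray]:
        """(rho, grad rho) at the given points; rho >= 0 by construction."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rho = np.empty(pts.shape[0])
        grad = np.empty((pts.shape[0], 3))
        Co = self.scf.mo_coeff[:, : self.scf.nocc]
        for s in range(0, pts.shape[0], self._chunk):
            sl = slice(s, s + self._chunk)
            vals, grads = self._mo_values(pts[sl])
            psi = vals @ Co  # (np, nocc)
            dpsi = np.einsum("pmg,mi->pig", grads, Co)
            rho[sl] = 2.0 * np.einsum("pi,pi->p", psi, psi)
            grad[sl] = 4.0 * np.einsum("pi,pig->pg", psi, dpsi)
        return rho, grad

    def _kernel(self, points, V: np.ndarray) -> np.ndarray:
        """Paramagnetic current field of one solved perturbation; (npts, 3)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.empty((pts.shape[0], 3))
        nocc = self.scf.nocc
        Co = self.scf.mo_coeff[:, :nocc]
        CvV = self.scf.mo_coeff[:, nocc:] @ V  # (nao, nocc)
        for s in range(0, pts.shape[0], self._chunk):
            sl = slice(s, s + self._chunk)
            vals, grads = self._mo_values(pts[sl])
            psi = vals @ Co
            vt = vals @ CvV
            dpsi = np.einsum("pmg,mi->pig", grads, Co)
            dvt = np.einsum("pmg,mi->pig", grads, CvV)
            out[sl] = -2.0 * (
                np.einsum("pi,pig->pg", psi, dvt) - np.einsum("pi,pig->pg", vt, dpsi)
            )
        return out

    def l_kernel(self, points) -> np.ndarray:
        """(3, npts, 3): paramagnetic current per unit B_beta, origin r0."""
        return np.stack([self._kernel(points, self.V_L[b]) for b in range(3)])

    def p_kernel(self, points) -> np.ndarray:
        """(3, npts, 3): current response per unit (1/2c) P_gamma."""
        return np.stack([self._kernel(points, self.V_P[g]) for g in range(3)])

    def current_ingredients(self, points):
        """Everything the CTOCD constructions need, in one AO-evaluation pass.

        Returns ``(rho, grad_rho, KL, KP)`` with kernel shapes (3, npts, 3).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        npts = pts.shape[0]
        nocc = self.scf.nocc
        Co = self.scf.mo_coeff[:, :nocc]
        Cv = self.scf.mo_coeff[:, nocc:]
        Vmats = [Cv @ self.V_L[b] for b in range(3)] + [Cv @ self.V_P[g] for g in range(3)]
        rho = np.empty(npts)
        grad = np.empty((npts, 3))
        K = np.empty((6, npts, 3))
        for s in range(0, npts, self._chunk):
            sl = slice(s, s + self._chunk)
            vals, grads = self._mo_values(pts[sl])
            psi = vals @ Co
            dpsi = np.einsum("pmg,mi->pig", grads, Co)
            rho[sl] = 2.0 * np.einsum("pi,pi->p", psi, psi)
            grad[sl] = 4.0 * np.einsum("pi,pig->pg", psi, dpsi)
            for k, CvV in enumerate(Vmats):
                vt = vals @ CvV
                dvt = np.einsum("pmg,mi->pig", grads, CvV)
                K[k, sl] = -2.0 * (
                    np.einsum("pi,pig->pg", psi, dvt) - np.einsum("pi,pig->pg", vt, dpsi)
                )
        return rho, grad, K[:3], K[3:]

    def l_kernel_about(self, points, origin) -> np.ndarray:
        """Angular-momentum kernel for an arbitrary common origin.

        Uses L(r0') = L(r0) - (r0' - r0) x P and linearity of the CPHF solve,
        so no new response equations are needed.
        """
        origin = np.asarray(origin, dtype=float)
        KL = self.l_kernel(points)
        shift = origin - self.r0
        if np.allclose(shift, 0.0):
            return KL
        KP = self.p_kernel(points)
        eb = np.eye(3)
        for b in range(3):
            coef = np.cross(eb[b], shift)  # [e_b x (r0'-r0)]_gamma
            KL[b] -= np.einsum("g,gpd->pd", coef, KP)
        return KL


def build_response_state(
    mol: Molecule,
    basis_name: str = "sto-3g",
    functional_name: str = "hf",
    scf_tol: float = 1e-10,
    response_tol: float = 1e-8,
    r0: np.ndarray | None = None,
) -> ResponseState:
    """Ground state + converged response for all six operator components.

    The electronic-structure level is restricted Hartree-Fock; requesting any
    density functional raises :class:`UnsupportedMethodError`.
    """
    if functional_name.lower() not in ("hf", "rhf", "hartree-fock"):
        raise UnsupportedMethodError(
            f"functional {functional_name!r} unavailable: this backend implements "
            "restricted Hartree-Fock only"
        )
    basis = build_basis(mol, basis_name)
    scf = run_rhf(mol, basis, tol=scf_tol)
    if r0 is None:
        r0 = mol.center_of_nuclear_charge()
    r0 = np.asarray(r0, dtype=float)
    pref = -1.0 / (2.0 * SPEED_OF_LIGHT)
    l_ao = angular_momentum_matrices(basis, r0)  # <mu|(r-r0) x grad|nu>
    d_ao = derivative_matrices(basis)  # <mu|grad|nu>
    # H' = (1/2c) B.L = i * [-(1/2c) l];  H' = (1/2c) P_g = i * [-(1/2c) d_g]
    O = np.concatenate([pref * l_ao, pref * d_ao], axis=0)
    V = _cphf_solve(scf, O)
    return ResponseState(
        molecule=mol,
        basis=basis,
        basis_name=basis_name,
        functional_name="hf",
        scf=scf,
        r0=r0,
        V_L=V[:3],
        V_P=V[3:],
        scf_tol=scf_tol,
        response_tol=response_tol,
    )
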