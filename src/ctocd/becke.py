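"""Becke multicenter partition and atom-centered quadrature grids.

The fuzzy-cell weights use the iterated cutoff polynomial p(x) = (3x - x^3)/2
applied k times to the confocal elliptical coordinate of each atom pair, with
optional Bragg-Slater size adjustment of the cell boundaries.  The weights
form an exact partition of unity at every point, which is what lets a single
molecular integral be decomposed into single-center integrals I_A -- and,
downstream, lets each I_A carry its own scheme parameter.

Radial quadrature: Gauss-Legendre nodes mapped by r = R (1+x)/(1-x), which
crowds points near the nucleus where the Biot-Savart kernel concentrates
weight.  Angular quadrature: product Gauss-Legendre (cos theta) x uniform
(phi), exact for spherical harmonics up to the selected degree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elements import bragg_slater_radius
from .molecule import Molecule

__all__ = ["becke_weights", "radial_grid", "angular_grid", "molecular_grid", "MolecularGrid"]


def _cutoff(mu: np.ndarray, k: int) -> np.ndarray:
    f = mu
    for _ in range(k):
        f = 0.5 * f * (3.0 - f * f)
    return f


def becke_weights(
    mol: Molecule, points: np.ndarray, k: int = 3, radii_mode: str = "bragg-slater"
) -> np.ndarray:
    """Relative weights w_A(r); shape (natoms, npts); sums to 1 everywhere."""
    if k < 1:
        raise ValueError(f"smoothing iteration count k must be >= 1, got {k}")
    if radii_mode not in ("bragg-slater", "uniform"):
        raise ValueError(f"radii_mode must be 'bragg-slater' or 'uniform', got {radii_mode!r}")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = mol.natoms
    if n == 1:
        return np.ones((1, pts.shape[0]))
    rA = np.linalg.norm(pts[None, :, :] - mol.coords[:, None, :], axis=-1)  # (natoms, npts)
    if radii_mode == "bragg-slater":
        radii = np.array([bragg_slater_radius(s) for s in mol.symbols])
    else:
        radii = np.ones(n)
    P = np.ones((n, pts.shape[0]))
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            Rab = np.linalg.norm(mol.coords[a] - mol.coords[b])
            mu = (rA[a] - rA[b]) / Rab
            chi = radii[a] / radii[b]
            u = (chi - 1.0) / (chi + 1.0)
            aab = np.clip(u / (u * u - 1.0), -0.5, 0.5)
            nu = mu + aab * (1.0 - mu * mu)
            P[a] *= 0.5 * (1.0 - _cutoff(nu, k))
    return P / P.sum(axis=0, keepdims=True)


def radial_grid(n: int, scale: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Mapped radial nodes and weights for int_0^inf f(r) r^2 dr.

    Returns (r, w) with the r^2 Jacobian folded into w.
    """
    if n < 2:
        raise ValueError("need at least 2 radial points")
    x, wx = np.polynomial.legendre.leggauss(n)
    r = scale * (1.0 + x) / (1.0 - x)
    dr = 2.0 * scale / (1.0 - x) ** 2
    return r, wx * dr * r * r


def angular_grid(n_theta: int = 20, n_phi: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Unit-sphere product quadrature; weights sum to 4 pi.

    Exact for spherical harmonics up to degree min(2*n_theta - 1, n_phi - 1).
    """
    if n_theta < 1:
        raise ValueError("need at least 1 polar node")
    if n_phi is None:
        n_phi = 2 * n_theta
    ct, wt = np.polynomial.legendre.leggauss(n_theta)
    st = np.sqrt(1.0 - ct * ct)
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    u = np.empty((n_theta * n_phi, 3))
    w = np.empty(n_theta * n_phi)
    idx = 0
    for i in range(n_theta):
        u[idx : idx + n_phi, 0] = st[i] * np.cos(phi)
        u[idx : idx + n_phi, 1] = st[i] * np.sin(phi)
        u[idx : idx + n_phi, 2] = ct[i]
        w[idx : idx + n_phi] = wt[i] * 2.0 * np.pi / n_phi
        idx += n_phi
    return u, w


@dataclass
class MolecularGrid:
    """Atom-centered product grids with combined quadrature x partition weights.

    ``atom_slices[A]`` selects the points of the single-center integral I_A;
    ``weights`` already includes w_A, so sum(w * F) over all points is the
    Becke-decomposed molecular integral of F.
    """

    molecule: Molecule
    points: np.ndarray  # (npts, 3)
    weights: np.ndarray  # (npts,)
    atom_slices: tuple[slice, ...]
    spec: dict

    @property
    def npts(self) -> int:
        return self.points.shape[0]

    def integrate(self, values: np.ndarray) -> float | np.ndarray:
        return np.tensordot(self.weights, values, axes=(0, 0))


def molecular_grid(
    mol: Molecule,
    radial_n: int = 90,
    n_theta: int = 18,
    n_phi: int | None = None,
    k: int = 3,
    radii_mode: str = "bragg-slater",
    r_max: float = 30.0,
) -> MolecularGrid:
    """Becke-weighted molecular quadrature grid over all atoms."""
    u, wang = angular_grid(n_theta, n_phi)
    all_pts, all_w, slices = [], [], []
    start = 0
    for ia, sym in enumerate(mol.symbols):
        scale = bragg_slater_radius(sym) if radii_mode == "bragg-slater" else 1.0
        scale = max(scale, 0.4)
        r, wr = radial_grid(radial_n, scale)
        keep = r <= r_max
        r, wr = r[keep], wr[keep]
        pts = mol.coords[ia] + r[:, None, None] * u[None, :, :]  # (nr, nang, 3)
        pts = pts.reshape(-1, 3)
        w = (wr[:, None] * wang[None, :]).reshape(-1)
        wbecke = becke_weights(mol, pts, k=k, radii_mode=radii_mode)[ia]
        all_pts.append(pts)
        all_w.append(w * wbecke)
        slices.append(slice(start, start + pts.shape[0]))
        start += pts.shape[0]
    spec = dict(radial_n=radial_n, n_theta=n_theta, n_phi=n_phi, k=k,
                radii_mode=radii_mode, r_max=r_max)
    return MolecularGrid(mol, np.vstack(all_pts), np.concatenate(all_w),
                         tuple(slices), spec)
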