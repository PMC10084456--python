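"""Deterministic small-molecule geometries and analytic one-electron states.

Geometries are standard textbook equilibrium structures (bond lengths in
Angstrom cited inline); nothing is optimized at build time, so every fixture
is bit-reproducible.  The analytic states (normalized s-type Gaussian or
hydrogenic 1s density, zero paramagnetic response) plug into the current and
shielding machinery in place of a computed response state and make the Lamb
shielding available in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elements import BOHR_PER_ANGSTROM, SPEED_OF_LIGHT
from .molecule import Molecule

__all__ = ["make_fixture", "available_fixtures", "AnalyticState", "make_analytic_state"]


def _deg(x):
    return np.deg2rad(x)


def _rot(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _tetra_pair(u1: np.ndarray, u2: np.ndarray, half_angle_deg: float = 54.25):
    """Two unit vectors completing an approximate tetrahedron given two bonds."""
    b = -(u1 + u2)
    b = b / np.linalg.norm(b)
    n = np.cross(u1, u2)
    n = n / np.linalg.norm(n)
    h = _deg(half_angle_deg)
    return np.cos(h) * b + np.sin(h) * n, np.cos(h) * b - np.sin(h) * n


def _water() -> np.ndarray:
    # O-H 0.9572 A, H-O-H 104.52 deg (gas-phase equilibrium)
    d, th = 0.9572, _deg(104.52)
    return np.array([[0, 0, 0], [d, 0, 0], [d * np.cos(th), d * np.sin(th), 0]])


def _ammonia() -> np.ndarray:
    # N-H 1.0116 A, H-N-H 106.7 deg
    d, hnh = 1.0116, _deg(106.7)
    # three H on a cone about z; polar angle: sin(theta) = sin(hnh/2)/sin(60 deg)
    theta = np.arcsin(np.sin(hnh / 2) / np.sin(_deg(60)))
    rows = [[0, 0, 0]]
    for k in range(3):
        phi = 2 * np.pi * k / 3
        rows.append(
            [d * np.sin(theta) * np.cos(phi), d * np.sin(theta) * np.sin(phi), -d * np.cos(theta)]
        )
    return np.array(rows)


def _methane() -> np.ndarray:
    # C-H 1.087 A, exact tetrahedral directions
    d = 1.087 / np.sqrt(3)
    return np.array(
        [[0, 0, 0], [d, d, d], [d, -d, -d], [-d, d, -d], [-d, -d, d]]
    )


def _glycine() -> tuple[tuple[str, ...], np.ndarray]:
    """Neutral glycine H2N-CH2-COOH; heavy atoms planar, textbook bond lengths.

    Order: N, Ca, C, O(=), O(H), H(O), Ha1, Ha2, Hn1, Hn2.
    """
    ca = np.zeros(3)
    c = ca + 1.52 * np.array([1.0, 0, 0])  # Ca-C 1.52 A
    un = np.array([np.cos(_deg(110)), np.sin(_deg(110)), 0.0])
    n = ca + 1.45 * un  # Ca-N 1.45 A
    # carboxyl group in the xy plane
    back = np.array([-1.0, 0, 0])
    d_oc = _rot(np.array([0, 0, 1.0]), _deg(-123)) @ back  # C=O at 123 deg from C-Ca
    o1 = c + 1.21 * d_oc
    d_oh = _rot(np.array([0, 0, 1.0]), _deg(+113)) @ back  # C-O(H) on the other side
    o2 = c + 1.36 * d_oh
    # hydroxyl H: C-O-H 106 deg, in plane, anti to C=O
    u_co = (o2 - c) / np.linalg.norm(o2 - c)
    d_h = _rot(np.array([0, 0, 1.0]), _deg(180 - 106)) @ u_co
    ho = o2 + 0.97 * d_h
    # alpha hydrogens out of plane
    h1d, h2d = _tetra_pair((c - ca) / np.linalg.norm(c - ca), un)
    ha1 = ca + 1.09 * h1d
    ha2 = ca + 1.09 * h2d
    # amine hydrogens: pyramidal nitrogen
    u_nc = (ca - n) / np.linalg.norm(ca - n)
    hn1d, hn2d = _tetra_pair(u_nc, np.array([0, 0, 1.0]) * 0.0 + np.array([np.cos(_deg(200)), np.sin(_deg(200)), 0.0]))
    hn1 = n + 1.01 * hn1d
    hn2 = n + 1.01 * hn2d
    syms = ("N", "C", "C", "O", "O", "H", "H", "H", "H", "H")
    coords = np.array([n, ca, c, o1, o2, ho, ha1, ha2, hn1, hn2])
    return syms, coords


def _alanine() -> tuple[tuple[str, ...], np.ndarray]:
    """Neutral alanine: glycine with one alpha hydrogen replaced by a methyl.

    Order: N, Ca, C, O(=), O(H), H(O), Cb, Ha, Hn1, Hn2, Hb1, Hb2, Hb3.
    """
    gsyms, g = _glycine()
    n, ca, c = g[0], g[1], g[2]
    dirs = g[6] - ca, g[7] - ca  # former alpha-H directions
    cb = ca + 1.53 * dirs[0] / np.linalg.norm(dirs[0])
    ha = g[7]
    # methyl hydrogens: staggered about the Ca-Cb axis
    axis = (cb - ca) / np.linalg.norm(cb - ca)
    ref = np.cross(axis, np.array([0, 0, 1.0]))
    ref = ref / np.linalg.norm(ref)
    hb = []
    for k in range(3):
        d = _rot(axis, 2 * np.pi * k / 3) @ (
            np.cos(_deg(180 - 110.5)) * axis + np.sin(_deg(180 - 110.5)) * ref
        )
        hb.append(cb + 1.09 * d)
    syms = ("N", "C", "C", "O", "O", "H", "C", "H", "H", "H", "H", "H", "H")
    coords = np.array([n, ca, c, g[3], g[4], g[5], cb, ha, g[8], g[9], *hb])
    return syms, coords


_SIMPLE = {
    "H2": (("H", "H"), np.array([[0, 0, 0], [0, 0, 0.7414]])),  # R_e 0.7414 A
    "He": (("He",), np.zeros((1, 3))),
    "H2O": (("O", "H", "H"), _water()),
    "NH3": (("N", "H", "H", "H"), _ammonia()),
    "CH4": (("C", "H", "H", "H", "H"), _methane()),
    "HCN": (("H", "C", "N"), np.array([[0, 0, -1.064], [0, 0, 0], [0, 0, 1.156]])),
    "CO": (("C", "O"), np.array([[0, 0, 0], [0, 0, 1.128]])),
    "N2": (("N", "N"), np.array([[0, 0, 0], [0, 0, 1.0977]])),
}


def available_fixtures() -> tuple[str, ...]:
    return tuple(_SIMPLE) + ("glycine", "alanine")


def make_fixture(name: str) -> Molecule:
    """Standard textbook geometry by name; bonds are left unperceived."""
    if name in _SIMPLE:
        syms, ang = _SIMPLE[name]
    elif name == "glycine":
        syms, ang = _glycine()
    elif name == "alanine":
        syms, ang = _alanine()
    else:
        raise ValueError(f"unknown fixture {name!r}; available: {available_fixtures()}")
    return Molecule(tuple(syms), np.asarray(ang, dtype=float) * BOHR_PER_ANGSTROM)


@dataclass(frozen=True)
class AnalyticState:
    """Closed-form spherical density with zero paramagnetic response.

    ``gaussian``: rho = n_e * (2a/pi)^(3/2) exp(-2 a r^2) (normalized s-type
    orbital with exponent a); ``hydrogenic``: rho = n_e * (Z^3/pi) exp(-2 Z r)
    with Z = exponent.  Duck-types the response-state evaluation surface, so
    current and shielding code runs on it unchanged.
    """

    kind: str
    exponent: float
    n_elec: float = 1.0
    center: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.kind not in ("gaussian", "hydrogenic"):
            raise ValueError(f"kind must be 'gaussian' or 'hydrogenic', got {self.kind!r}")
        if self.exponent <= 0:
            raise ValueError("exponent must be positive")
        c = np.zeros(3) if self.center is None else np.asarray(self.center, dtype=float)
        object.__setattr__(self, "center", c)

    @property
    def molecule(self) -> Molecule:
        sym = "He" if self.kind == "gaussian" else "H"
        return Molecule((sym,), self.center.reshape(1, 3))

    @property
    def r0(self) -> np.ndarray:
        return self.center

    @property
    def n_electrons(self) -> float:
        return self.n_elec

    def density(self, points):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = pts - self.center
        r2 = np.einsum("pi,pi->p", d, d)
        if self.kind == "gaussian":
            a = self.exponent
            rho = self.n_elec * (2.0 * a / np.pi) ** 1.5 * np.exp(-2.0 * a * r2)
            grad = -4.0 * a * rho[:, None] * d
        else:
            z = self.exponent
            r = np.sqrt(r2)
            rho = self.n_elec * z**3 / np.pi * np.exp(-2.0 * z * r)
            rs = np.where(r > 1e-300, r, 1.0)
            grad = -2.0 * z * rho[:, None] * d / rs[:, None]
        return rho, grad

    def l_kernel(self, points):
        return np.zeros((3, np.atleast_2d(points).shape[0], 3))

    p_kernel = l_kernel

    def l_kernel_about(self, points, origin):
        return self.l_kernel(points)

    def mean_inverse_r(self) -> float:
        """Density integral of 1/r (enters the Lamb formula) in closed form."""
        if self.kind == "gaussian":
            return self.n_elec * 2.0 * np.sqrt(2.0 * self.exponent / np.pi)
        return self.n_elec * self.exponent

    def lamb_shielding(self) -> float:
        """Diamagnetic (Lamb) isotropic shielding in ppm: (1e6/3c^2) <1/r>."""
        return 1.0e6 / (3.0 * SPEED_OF_LIGHT**2) * self.mean_inverse_r()


def make_analytic_state(kind: str, exponent: float, n_elec: float = 1.0,
                        center=None) -> AnalyticState:
    return AnalyticState(kind, exponent, n_elec, None if center is None else np.asarray(center))
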