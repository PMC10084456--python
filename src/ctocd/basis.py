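"""Contracted Gaussian basis sets and AO evaluation on point grids.

Built-in sets:

* ``sto-3g`` -- standard minimal basis (H, He, C, N, O data pinned below).
* ``et-sp`` -- even-tempered uncontracted s+p set for H and He with *matched*
  s and p exponents.  Multiplying any s function by a Cartesian coordinate
  lands exactly on a p function of the same exponent, so the basis is closed
  under the position operator acting on the occupied space; this is the
  property that lets the paramagnetic momentum response reproduce the
  diamagnetic (Larmor) current, which the ipsocentric d(r)=r scheme relies on.

Only s and p shells are supported; that covers every system this package
targets at its electronic-structure level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .molecule import Molecule

__all__ = ["Shell", "Basis", "build_basis", "available_basis_sets"]

_STO3G_S_COEF = np.array([0.15432897, 0.53532814, 0.44463454])
_STO3G_SP_CS = np.array([-0.09996723, 0.39951283, 0.70011547])
_STO3G_SP_CP = np.array([0.15591627, 0.60768372, 0.39195739])

# element -> list of (l, exponents, coefficients)
_STO3G: dict[str, list[tuple[int, np.ndarray, np.ndarray]]] = {
    "H": [(0, np.array([3.42525091, 0.62391373, 0.16885540]), _STO3G_S_COEF)],
    "He": [(0, np.array([6.36242139, 1.15892300, 0.31364979]), _STO3G_S_COEF)],
    "C": [
        (0, np.array([71.6168370, 13.0450960, 3.5305122]), _STO3G_S_COEF),
        (0, np.array([2.9412494, 0.6834831, 0.2222899]), _STO3G_SP_CS),
        (1, np.array([2.9412494, 0.6834831, 0.2222899]), _STO3G_SP_CP),
    ],
    "N": [
        (0, np.array([99.1061690, 18.0523120, 4.8856602]), _STO3G_S_COEF),
        (0, np.array([3.7804559, 0.8784966, 0.2857144]), _STO3G_SP_CS),
        (1, np.array([3.7804559, 0.8784966, 0.2857144]), _STO3G_SP_CP),
    ],
    "O": [
        (0, np.array([130.7093200, 23.8088610, 6.4436083]), _STO3G_S_COEF),
        (0, np.array([5.0331513, 1.1695961, 0.3803890]), _STO3G_SP_CS),
        (1, np.array([5.0331513, 1.1695961, 0.3803890]), _STO3G_SP_CP),
    ],
}


def _even_tempered(center: float, ratio: float, n: int) -> np.ndarray:
    return center * ratio ** np.arange(n)


def _et_sp(element: str) -> list[tuple[int, np.ndarray, np.ndarray]]:
    if element == "He":
        zetas = _even_tempered(0.12, 3.0, 9)
    elif element == "H":
        zetas = _even_tempered(0.055, 3.0, 8)
    else:
        raise ValueError(f"basis 'et-sp' is defined only for H and He, not {element!r}")
    shells = [(0, np.array([z]), np.array([1.0])) for z in zetas]
    shells += [(1, np.array([z]), np.array([1.0])) for z in zetas]
    return shells


_CART_COMPONENTS = {0: [(0, 0, 0)], 1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)]}


def _primitive_norm(a: float, lmn: tuple[int, int, int]) -> float:
    l, m, n = lmn
    num = (2 * a / np.pi) ** 0.75 * (4 * a) ** ((l + m + n) / 2)
    from scipy.special import factorial2

    den = np.sqrt(
        float(factorial2(max(2 * l - 1, 1))) *
        float(factorial2(max(2 * m - 1, 1))) *
        float(factorial2(max(2 * n - 1, 1)))
    )
    return num / den


@dataclass(frozen=True)
class Shell:
    atom: int
    l: int
    center: np.ndarray  # (3,)
    exps: np.ndarray  # (K,)
    coefs: np.ndarray  # (K,) contraction coefficients times primitive norms

    @property
    def components(self) -> list[tuple[int, int, int]]:
        return _CART_COMPONENTS[self.l]

    @property
    def nfunc(self) -> int:
        return len(self.components)


@dataclass(frozen=True)
class Basis:
    name: str
    shells: tuple[Shell, ...]

    @property
    def nao(self) -> int:
        return sum(sh.nfunc for sh in self.shells)

    def ao_offsets(self) -> list[int]:
        offs, acc = [], 0
        for sh in self.shells:
            offs.append(acc)
            acc += sh.nfunc
        return offs

    def evaluate(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """AO values and Cartesian gradients at ``points``.

        Returns ``(vals, grads)`` with shapes (npts, nao) and (npts, nao, 3).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        npts = pts.shape[0]
        vals = np.empty((npts, self.nao))
        grads = np.empty((npts, self.nao, 3))
        iao = 0
        for sh in self.shells:
            d = pts - sh.center  # (npts, 3)
            r2 = np.einsum("pi,pi->p", d, d)
            radial = sh.coefs[None, :] * np.exp(-np.outer(r2, sh.exps))  # (npts, K)
            rsum = radial.sum(axis=1)
            # d(radial)/dx = -2 a x * radial summed over primitives
            dr = -2.0 * (radial * sh.exps[None, :]).sum(axis=1)  # scalar part of gradient
            if sh.l == 0:
                vals[:, iao] = rsum
                grads[:, iao, :] = d * dr[:, None]
                iao += 1
            else:  # l == 1: components x, y, z
                for comp in range(3):
                    x = d[:, comp]
                    vals[:, iao] = x * rsum
                    g = d * (x * dr)[:, None]
                    g[:, comp] += rsum
                    grads[:, iao, :] = g
                    iao += 1
        return vals, grads


def available_basis_sets() -> tuple[str, ...]:
    return ("sto-3g", "et-sp")


def build_basis(mol: Molecule, name: str = "sto-3g") -> Basis:
    key = name.lower()
    shells: list[Shell] = []
    for ia, sym in enumerate(mol.symbols):
        if key == "sto-3g":
            try:
                defs = _STO3G[sym]
            except KeyError:
                raise ValueError(
                    f"basis 'sto-3g' data not available for element {sym!r} "
                    f"(available: {sorted(_STO3G)})"
                ) from None
        elif key == "et-sp":
            defs = _et_sp(sym)
        else:
            raise ValueError(f"unknown basis set {name!r}; available: {available_basis_sets()}")
        for l, exps, coefs in defs:
            lmn0 = (l, 0, 0) if l else (0, 0, 0)
            norms = np.array([_primitive_norm(a, lmn0) for a in exps])
            c = coefs * norms
            # normalize the contracted function to unit self-overlap
            ee = exps[:, None] + exps[None, :]
            from scipy.special import factorial2

            df = float(factorial2(max(2 * l - 1, 1)))
            s_self = (np.pi ** 1.5 * df / 2 ** l) * np.sum(
                c[:, None] * c[None, :] / ee ** (l + 1.5)
            )
            c = c / np.sqrt(s_self)
            shells.append(Shell(ia, l, mol.coords[ia].copy(), exps.copy(), c))
    return Basis(key, tuple(shells))
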