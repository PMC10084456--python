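"""Molecular integrals over contracted Cartesian Gaussians (McMurchie-Davidson).

Provides overlap, kinetic, nuclear-attraction and two-electron repulsion
integrals, plus the matrix elements needed by the magnetic response:
derivatives <mu|d/dr_g|nu> and angular momentum <mu|[(r-O) x grad]_g|nu>.
Hermite expansion coefficients are built by the standard two-term recurrences;
the Coulomb kernel uses the Boys function evaluated through the regularized
lower incomplete gamma function.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammainc, gammaln

from .basis import Basis, Shell

__all__ = [
    "overlap_matrix",
    "kinetic_matrix",
    "nuclear_attraction_matrix",
    "eri_tensor",
    "derivative_matrices",
    "angular_momentum_matrices",
]


def boys(nmax: int, T: float) -> np.ndarray:
    """F_n(T) for n = 0..nmax."""
    n = np.arange(nmax + 1)
    if T < 1e-13:
        return 1.0 / (2 * n + 1)
    a = n + 0.5
    return np.exp(gammaln(a)) * gammainc(a, T) / (2.0 * T ** a)


def _e_tables(la: int, lb: int, A: np.ndarray, B: np.ndarray, a: float, b: float):
    """Hermite expansion coefficients E[i, j, t] for each Cartesian dimension.

    Table sizes (la+1, lb+1, la+lb+1); E[0,0,0] carries the Gaussian product
    prefactor exp(-mu*(A-B)^2) of that dimension.
    """
    p = a + b
    mu = a * b / p
    P = (a * A + b * B) / p
    out = []
    for dim in range(3):
        PA = P[dim] - A[dim]
        PB = P[dim] - B[dim]
        E = np.zeros((la + 1, lb + 1, la + lb + 2))
        E[0, 0, 0] = np.exp(-mu * (A[dim] - B[dim]) ** 2)
        for i in range(la):
            for t in range(i + 2):
                E[i + 1, 0, t] = (
                    (E[i, 0, t - 1] / (2 * p) if t >= 1 else 0.0)
                    + PA * E[i, 0, t]
                    + (t + 1) * E[i, 0, t + 1]
                )
        for j in range(lb):
            for i in range(la + 1):
                for t in range(i + j + 2):
                    E[i, j + 1, t] = (
                        (E[i, j, t - 1] / (2 * p) if t >= 1 else 0.0)
                        + PB * E[i, j, t]
                        + (t + 1) * E[i, j, t + 1]
                    )
        out.append(E)
    return out, p, P


def _hermite_coulomb(tmax: int, umax: int, vmax: int, p: float, PC: np.ndarray) -> np.ndarray:
    """R_{tuv}(p, PC) Hermite Coulomb integrals, R[t, u, v]."""
    nmax = tmax + umax + vmax
    T = p * float(PC @ PC)
    F = boys(nmax, T)
    memo: dict[tuple[int, int, int, int], float] = {}

    def R(n: int, t: int, u: int, v: int) -> float:
        if t < 0 or u < 0 or v < 0:
            return 0.0
        key = (n, t, u, v)
        if key in memo:
            return memo[key]
        if t == u == v == 0:
            val = (-2.0 * p) ** n * F[n]
        elif t > 0:
            val = (t - 1) * R(n + 1, t - 2, u, v) + PC[0] * R(n + 1, t - 1, u, v)
        elif u > 0:
            val = (u - 1) * R(n + 1, t, u - 2, v) + PC[1] * R(n + 1, t, u - 1, v)
        else:
            val = (v - 1) * R(n + 1, t, u, v - 2) + PC[2] * R(n + 1, t, u, v - 1)
        memo[key] = val
        return val

    out = np.empty((tmax + 1, umax + 1, vmax + 1))
    for t in range(tmax + 1):
        for u in range(umax + 1):
            for v in range(vmax + 1):
                out[t, u, v] = R(0, t, u, v)
    return out


def _pair_blocks(sha: Shell, shb: Shell):
    """Iterate primitive pairs of a shell pair with their E tables.

    Tables are built with the ket angular index extended by 2 so kinetic and
    derivative 1D integrals can index j+2.
    """
    la, lb = sha.l, shb.l
    for ca, a in zip(sha.coefs, sha.exps):
        for cb, b in zip(shb.coefs, shb.exps):
            E, p, P = _e_tables(la, lb + 2, sha.center, shb.center, a, b)
            yield ca * cb, a, b, p, P, E


def _one_electron(basis: Basis, kind: str, mol=None, origin=None):
    """Shared driver for S, T, V, derivative and angular-momentum matrices."""
    nao = basis.nao
    offs = basis.ao_offsets()
    nmat = 3 if kind in ("deriv", "angmom") else 1
    out = np.zeros((nmat, nao, nao))
    for isha, sha in enumerate(basis.shells):
        for ishb, shb in enumerate(basis.shells):
            if kind in ("overlap", "kinetic") and ishb < isha:
                continue
            oa, ob = offs[isha], offs[ishb]
            block = np.zeros((nmat, sha.nfunc, shb.nfunc))
            for cc, a, b, p, P, E in _pair_blocks(sha, shb):
                sq = np.sqrt(np.pi / p)

                def S1(dim, i, j):
                    return E[dim][i, j, 0] * sq

                def D1(dim, i, j):
                    v = -2.0 * b * S1(dim, i, j + 1)
                    if j >= 1:
                        v += j * S1(dim, i, j - 1)
                    return v

                def K1(dim, i, j):
                    v = -2.0 * b * (2 * j + 1) * S1(dim, i, j) + 4.0 * b * b * S1(dim, i, j + 2)
                    if j >= 2:
                        v += j * (j - 1) * S1(dim, i, j - 2)
                    return -0.5 * v

                def M1(dim, i, j):
                    return (E[dim][i, j, 1] + (P[dim] - origin[dim]) * E[dim][i, j, 0]) * sq

                if kind == "nuclear":
                    tmax = sha.l + shb.l
                    charges = mol.numbers
                    Rsum = None
                    Rs = []
                    for Z, Rc in zip(charges, mol.coords):
                        Rs.append((-float(Z)) * _hermite_coulomb(tmax, tmax, tmax, p, P - Rc))
                    Rsum = np.sum(Rs, axis=0) * (2.0 * np.pi / p)

                for ia, (ax, ay, az) in enumerate(sha.components):
                    for jb, (bx, by, bz) in enumerate(shb.components):
                        if kind == "overlap":
                            block[0, ia, jb] += cc * S1(0, ax, bx) * S1(1, ay, by) * S1(2, az, bz)
                        elif kind == "kinetic":
                            block[0, ia, jb] += cc * (
                                K1(0, ax, bx) * S1(1, ay, by) * S1(2, az, bz)
                                + S1(0, ax, bx) * K1(1, ay, by) * S1(2, az, bz)
                                + S1(0, ax, bx) * S1(1, ay, by) * K1(2, az, bz)
                            )
                        elif kind == "nuclear":
                            acc = 0.0
                            for t in range(ax + bx + 1):
                                for u in range(ay + by + 1):
                                    for v in range(az + bz + 1):
                                        acc += (
                                            E[0][ax, bx, t]
                                            * E[1][ay, by, u]
                                            * E[2][az, bz, v]
                                            * Rsum[t, u, v]
                                        )
                            block[0, ia, jb] += cc * acc
                        elif kind == "deriv":
                            lv = (ax, ay, az)
                            lb_ = (bx, by, bz)
                            s = [S1(d, lv[d], lb_[d]) for d in range(3)]
                            for g in range(3):
                                fac = D1(g, lv[g], lb_[g])
                                prod = fac
                                for d in range(3):
                                    if d != g:
                                        prod *= s[d]
                                block[g, ia, jb] += cc * prod
                        else:  # angmom: [(r-O) x grad]_g
                            lv = (ax, ay, az)
                            lb_ = (bx, by, bz)
                            s = [S1(d, lv[d], lb_[d]) for d in range(3)]
                            m = [M1(d, lv[d], lb_[d]) for d in range(3)]
                            dd = [D1(d, lv[d], lb_[d]) for d in range(3)]
                            for g, (u, v) in enumerate(((1, 2), (2, 0), (0, 1))):
                                w = 3 - u - v  # the remaining dimension
                                block[g, ia, jb] += cc * (
                                    m[u] * dd[v] * s[w] - m[v] * dd[u] * s[w]
                                )
            out[:, oa : oa + sha.nfunc, ob : ob + shb.nfunc] += block
            if kind in ("overlap", "kinetic") and ishb > isha:
                out[:, ob : ob + shb.nfunc, oa : oa + sha.nfunc] += np.transpose(
                    block, (0, 2, 1)
                )
    return out


def overlap_matrix(basis: Basis) -> np.ndarray:
    return _one_electron(basis, "overlap")[0]


def kinetic_matrix(basis: Basis) -> np.ndarray:
    return _one_electron(basis, "kinetic")[0]


def nuclear_attraction_matrix(basis: Basis, mol) -> np.ndarray:
    return _one_electron(basis, "nuclear", mol=mol)[0]


def derivative_matrices(basis: Basis) -> np.ndarray:
    """D[g] = <mu|d/dr_g|nu>; real antisymmetric for a decaying basis."""
    return _one_electron(basis, "deriv")


def angular_momentum_matrices(basis: Basis, origin: np.ndarray) -> np.ndarray:
    """l[g] = <mu|[(r-O) x grad]_g|nu> (the angular momentum operator is -i*l)."""
    return _one_electron(basis, "angmom", origin=np.asarray(origin, dtype=float))


def eri_tensor(basis: Basis) -> np.ndarray:
    """Full (mu nu | la si) electron-repulsion tensor in chemists' notation."""
    nao = basis.nao
    offs = basis.ao_offsets()
    eri = np.zeros((nao, nao, nao, nao))
    shells = basis.shells
    ns = len(shells)

    # precompute primitive-pair data per shell pair
    pair_data: dict[tuple[int, int], list] = {}
    for i in range(ns):
        for j in range(i, ns):
            plist = []
            for ca, a in zip(shells[i].coefs, shells[i].exps):
                for cb, b in zip(shells[j].coefs, shells[j].exps):
                    E, p, P = _e_tables(shells[i].l, shells[j].l, shells[i].center,
                                        shells[j].center, a, b)
                    plist.append((ca * cb, p, P, E))
            pair_data[(i, j)] = plist

    done = set()
    for i in range(ns):
        for j in range(i, ns):
            for k in range(ns):
                for l in range(k, ns):
                    key = tuple(sorted([(i, j), (k, l)]))
                    if key in done:
                        continue
                    done.add(key)
                    sha, shb, shc, shd = shells[i], shells[j], shells[k], shells[l]
                    na, nb, nc, nd = sha.nfunc, shb.nfunc, shc.nfunc, shd.nfunc
                    block = np.zeros((na, nb, nc, nd))
                    tmax_b = sha.l + shb.l
                    tmax_k = shc.l + shd.l
                    for cab, p, P, Eb in pair_data[(i, j)]:
                        for ccd, q, Q, Ek in pair_data[(k, l)]:
                            omega = p * q / (p + q)
                            pref = 2.0 * np.pi ** 2.5 / (p * q * np.sqrt(p + q))
                            R = _hermite_coulomb(tmax_b + tmax_k, tmax_b + tmax_k,
                                                 tmax_b + tmax_k, omega, P - Q)
                            for ia, (ax, ay, az) in enumerate(sha.components):
                                for jb, (bx, by, bz) in enumerate(shb.components):
                                    EA = np.einsum(
                                        "t,u,v->tuv",
                                        Eb[0][ax, bx, : ax + bx + 1],
                                        Eb[1][ay, by, : ay + by + 1],
                                        Eb[2][az, bz, : az + bz + 1],
                                    )
                                    for kc, (cx, cy, cz) in enumerate(shc.components):
                                        for ld, (dx, dy, dz) in enumerate(shd.components):
                                            acc = 0.0
                                            for tt in range(cx + dx + 1):
                                                Ex = Ek[0][cx, dx, tt]
                                                if Ex == 0.0:
                                                    continue
                                                for uu in range(cy + dy + 1):
                                                    Ey = Ek[1][cy, dy, uu]
                                                    if Ey == 0.0:
                                                        continue
                                                    for vv in range(cz + dz + 1):
                                                        Ez = Ek[2][cz, dz, vv]
                                                        if Ez == 0.0:
                                                            continue
                                                        sgn = (-1.0) ** (tt + uu + vv)
                                                        sub = R[tt:, uu:, vv:][
                                                            : EA.shape[0], : EA.shape[1], : EA.shape[2]
                                                        ]
                                                        acc += sgn * Ex * Ey * Ez * float(
                                                            np.sum(EA * sub)
                                                        )
                                            block[ia, jb, kc, ld] += cab * ccd * pref * acc
                    _scatter_eri(eri, block, offs, (i, j, k, l),
                                 (na, nb, nc, nd))
    return eri


def _scatter_eri(eri, block, offs, idx, sizes):
    i, j, k, l = idx
    na, nb, nc, nd = sizes
    oa, ob, oc, od = offs[i], offs[j], offs[k], offs[l]
    sl = (slice(oa, oa + na), slice(ob, ob + nb), slice(oc, oc + nc), slice(od, od + nd))
    eri[sl[0], sl[1], sl[2], sl[3]] = block
    eri[sl[1], sl[0], sl[2], sl[3]] = block.transpose(1, 0, 2, 3)
    eri[sl[0], sl[1], sl[3], sl[2]] = block.transpose(0, 1, 3, 2)
    eri[sl[1], sl[0], sl[3], sl[2]] = block.transpose(1, 0, 3, 2)
    eri[sl[2], sl[3], sl[0], sl[1]] = block.transpose(2, 3, 0, 1)
    eri[sl[3], sl[2], sl[0], sl[1]] = block.transpose(3, 2, 0, 1)
    eri[sl[2], sl[3], sl[1], sl[0]] = block.transpose(2, 3, 1, 0)
    eri[sl[3], sl[2], sl[1], sl[0]] = block.transpose(3, 2, 1, 0)
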