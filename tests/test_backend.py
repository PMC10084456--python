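"""Electronic-structure backend: SCF against an independent s-orbital oracle,
density evaluation, response kernels and their invariances."""

import numpy as np
import pytest
from scipy.special import erf

from ctocd.fixtures import make_fixture
from ctocd.molecule import Molecule
from ctocd.response import UnsupportedMethodError, build_response_state
from ctocd.scf import OpenShellError


# ----- independent brute-force RHF for s-type Gaussians only ----------------

_EXP = np.array([3.42525091, 0.62391373, 0.16885540])
_COEF = np.array([0.15432897, 0.53532814, 0.44463454])


def _f0(t):
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t)
    m = t > 1e-13
    out[m] = 0.5 * np.sqrt(np.pi / t[m]) * erf(np.sqrt(t[m]))
    return out


def _brute_force_h2_energy(R: float) -> float:
    """STO-3G H2 RHF energy from closed-form s-Gaussian formulas and a plain
    Roothaan loop -- shares no code with the package's integral engine."""
    centers = np.array([[0.0, 0, 0], [0, 0, R]])
    prims = []  # (coef*norm, exponent, center)
    for A in centers:
        for c, a in zip(_COEF, _EXP):
            prims.append((c * (2 * a / np.pi) ** 0.75, a, A))
    nb = 2

    def block(f):
        M = np.zeros((nb, nb))
        for i in range(nb):
            for j in range(nb):
                acc = 0.0
                for ci, ai, Ai in prims[3 * i : 3 * i + 3]:
                    for cj, aj, Aj in prims[3 * j : 3 * j + 3]:
                        acc += ci * cj * f(ai, Ai, aj, Aj)
                M[i, j] = acc
        return M

    def s_int(a, A, b, B):
        p = a + b
        return (np.pi / p) ** 1.5 * np.exp(-a * b / p * np.sum((A - B) ** 2))

    def t_int(a, A, b, B):
        p = a + b
        mu = a * b / p
        r2 = np.sum((A - B) ** 2)
        return mu * (3 - 2 * mu * r2) * s_int(a, A, b, B)

    def v_int(a, A, b, B):
        p = a + b
        P = (a * A + b * B) / p
        pre = -2 * np.pi / p * np.exp(-a * b / p * np.sum((A - B) ** 2))
        return pre * sum(_f0(p * np.sum((P - C) ** 2)) for C in centers)

    S, T, V = block(s_int), block(t_int), block(v_int)
    # normalize contracted functions
    d = 1 / np.sqrt(np.diag(S))
    S, T, V = (d[:, None] * M * d[None, :] for M in (S, T, V))

    eri = np.zeros((nb, nb, nb, nb))
    for i in range(nb):
        for j in range(nb):
            for k in range(nb):
                for l in range(nb):
                    acc = 0.0
                    for ci, ai, Ai in prims[3 * i : 3 * i + 3]:
                        for cj, aj, Aj in prims[3 * j : 3 * j + 3]:
                            p = ai + aj
                            P = (ai * Ai + aj * Aj) / p
                            kab = np.exp(-ai * aj / p * np.sum((Ai - Aj) ** 2))
                            for ck, ak, Ak in prims[3 * k : 3 * k + 3]:
                                for cl, al, Al in prims[3 * l : 3 * l + 3]:
                                    q = ak + al
                                    Q = (ak * Ak + al * Al) / q
                                    kcd = np.exp(-ak * al / q * np.sum((Ak - Al) ** 2))
                                    w = p * q / (p + q)
                                    acc += (
                                        ci * cj * ck * cl * kab * kcd
                                        * 2 * np.pi**2.5 / (p * q * np.sqrt(p + q))
                                        * _f0(w * np.sum((P - Q) ** 2))
                                    )
                    eri[i, j, k, l] = acc * d[i] * d[j] * d[k] * d[l]

    import scipy.linalg as sla

    h = T + V
    C = None
    Dm = np.zeros((nb, nb))
    E = 0.0
    for _ in range(60):
        F = h + np.einsum("mnls,ls->mn", eri, Dm) - 0.5 * np.einsum("mlns,ls->mn", eri, Dm)
        _, C = sla.eigh(F, S)
        Dm = 2 * np.outer(C[:, 0], C[:, 0])
        E = 0.5 * np.sum(Dm * (h + F)) + 1.0 / R
    return E


def test_h2_scf_energy_matches_independent_oracle():
    R = 1.4
    mol = Molecule(("H", "H"), np.array([[0.0, 0, 0], [0, 0, R]]))
    state = build_response_state(mol, "sto-3g")
    assert state.scf_energy == pytest.approx(_brute_force_h2_energy(R), abs=1e-8)


# ----- density and kernels ---------------------------------------------------

def test_helium_l_kernels_vanish(he_state, rng):
    """Spherical closed shell with origin at the nucleus has no L response."""
    pts = rng.normal(size=(40, 3))
    assert np.abs(he_state.l_kernel(pts)).max() < 1e-10


def test_density_normalization_h2o(h2o_state, h2o_grid):
    rho, _ = h2o_state.density(h2o_grid.points)
    assert h2o_grid.integrate(rho) == pytest.approx(10.0, abs=1e-6)


def test_density_gradient_matches_finite_difference(h2o_state, rng):
    pts = rng.normal(scale=1.2, size=(20, 3))
    rho, grad = h2o_state.density(pts)
    h = 1e-4
    for d in range(3):
        dp = np.zeros(3)
        dp[d] = h
        num = (h2o_state.density(pts + dp)[0] - h2o_state.density(pts - dp)[0]) / (2 * h)
        np.testing.assert_allclose(num, grad[:, d], rtol=1e-4, atol=1e-9)


def test_density_tail_and_cusp(h2o_state, rng):
    far = np.array([[50.0, 0, 0]])
    assert h2o_state.density(far)[0][0] < 1e-12
    sample = np.vstack([h2o_state.molecule.coords, rng.normal(scale=1.0, size=(50, 3))])
    rho, _ = h2o_state.density(sample)
    assert rho.argmax() < 3  # maximal at a nuclear position among sampled points
    assert np.all(rho >= 0)


def test_rigid_translation_leaves_fields_unchanged(h2o_state, rng):
    shift = np.array([1.7, -2.3, 0.9])
    mol2 = h2o_state.molecule.translated(shift)
    st2 = build_response_state(mol2, "sto-3g", r0=h2o_state.r0 + shift)
    pts = rng.normal(scale=1.5, size=(25, 3))
    rho1, g1 = h2o_state.density(pts)
    rho2, g2 = st2.density(pts + shift)
    np.testing.assert_allclose(rho1, rho2, atol=1e-8)
    np.testing.assert_allclose(g1, g2, atol=1e-8)
    np.testing.assert_allclose(
        h2o_state.l_kernel(pts), st2.l_kernel(pts + shift), atol=1e-8
    )


def test_response_is_deterministic(h2o_mol, h2o_state):
    st2 = build_response_state(h2o_mol, "sto-3g")
    np.testing.assert_allclose(st2.V_L, h2o_state.V_L, atol=1e-10)
    np.testing.assert_allclose(st2.V_P, h2o_state.V_P, atol=1e-10)
    assert st2.scf_energy == pytest.approx(h2o_state.scf_energy, abs=1e-12)


def test_combined_ingredients_match_individual_evaluators(h2o_state, rng):
    pts = rng.normal(scale=1.5, size=(15, 3))
    rho, grad, KL, KP = h2o_state.current_ingredients(pts)
    rho2, grad2 = h2o_state.density(pts)
    np.testing.assert_allclose(rho, rho2, atol=1e-14)
    np.testing.assert_allclose(KL, h2o_state.l_kernel(pts), atol=1e-14)
    np.testing.assert_allclose(KP, h2o_state.p_kernel(pts), atol=1e-14)


def test_open_shell_and_unknown_functional_errors():
    doublet = Molecule(("H",), np.zeros((1, 3)), multiplicity=2)
    with pytest.raises(OpenShellError):
        build_response_state(doublet, "sto-3g")
    with pytest.raises(UnsupportedMethodError):
        build_response_state(make_fixture("He"), "sto-3g", functional_name="b3lyp")
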