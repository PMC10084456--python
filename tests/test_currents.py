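"""CTOCD current tensors: scheme limits, parameter linearity, solenoidality,
origin independence, and closed-form oracles on atoms."""

import numpy as np
import pytest

from ctocd.currents import (
    HARRIS_CINA_BETA,
    CurrentField,
    SchemeMisuseError,
    SchemeParameter,
    co_current,
    ctocd_delta_paramagnetic,
    ctocd_diamagnetic,
    divergence_map,
    dz1_current,
    total_current,
    unit_parameter_kernel,
)
from ctocd.elements import SPEED_OF_LIGHT as C_AU
from ctocd.fixtures import make_analytic_state
from ctocd.response import build_response_state


def _shell_points(state, rng, n=30, rho_min=1e-6, scale=1.5):
    pts = rng.normal(scale=scale, size=(8 * n, 3))
    rho, _ = state.density(pts)
    return pts[rho > rho_min][:n]


def _larmor_tensor(rho, rel):
    """Independent assembly of -(1/2c) rho B x (r - r0) via explicit cross
    products (oracle for the diamagnetic closed form)."""
    out = np.empty((len(rho), 3, 3))
    for b, e in enumerate(np.eye(3)):
        out[:, :, b] = -rho[:, None] / (2 * C_AU) * np.cross(e, rel)
    return out


def test_helium_co_current_is_pure_larmor(he_state, rng):
    """Closed-shell atom, origin at nucleus: paramagnetic part vanishes and the
    diamagnetic tensor is the Larmor closed form built from rho alone."""
    pts = rng.normal(size=(25, 3))
    para = co_current(he_state, pts, component="paramagnetic").tensor
    assert np.abs(para).max() < 1e-10
    rho, _ = he_state.density(pts)
    np.testing.assert_allclose(
        co_current(he_state, pts).tensor, _larmor_tensor(rho, pts), atol=1e-12
    )


def test_hydrogenic_toy_state_matches_analytic_first_order_current(rng):
    state = make_analytic_state("hydrogenic", 1.3)
    pts = rng.normal(size=(20, 3))
    rho, _ = state.density(pts)
    np.testing.assert_allclose(
        co_current(state, pts).tensor, _larmor_tensor(rho, pts), atol=1e-14
    )


def test_co_total_depends_on_origin_in_finite_basis(h2o_state, rng):
    """The CO defect: shifting the vector-potential origin changes the total."""
    pts = _shell_points(h2o_state, rng)
    t1 = co_current(h2o_state, pts).tensor
    t2 = co_current(h2o_state, pts, origin=h2o_state.r0 + np.array([3.0, 0, 0])).tensor
    assert np.abs(t1 - t2).max() > 1e-6


def test_dz1_is_the_zero_parameter_limit(h2o_state, rng):
    pts = _shell_points(h2o_state, rng)
    dz1 = dz1_current(h2o_state, pts).tensor
    grro0 = total_current(h2o_state, pts, SchemeParameter("GRRO", alpha=0.0)).tensor
    gpro0 = total_current(h2o_state, pts, SchemeParameter("GPRO", beta=0.0)).tensor
    np.testing.assert_allclose(grro0, dz1, atol=1e-12)
    np.testing.assert_allclose(gpro0, dz1, atol=1e-12)


def test_ctocd_fields_independent_of_backend_origin(h2o_mol, h2o_state, rng):
    st2 = build_response_state(h2o_mol, "sto-3g", r0=h2o_state.r0 + np.array([2.0, -1.0, 4.0]))
    pts = _shell_points(h2o_state, rng)
    np.testing.assert_allclose(
        dz1_current(h2o_state, pts).tensor, dz1_current(st2, pts).tensor, atol=1e-8
    )
    p = SchemeParameter("GRRO", alpha=-0.01)
    np.testing.assert_allclose(
        total_current(h2o_state, pts, p).tensor, total_current(st2, pts, p).tensor, atol=1e-8
    )


def test_diamagnetic_term_proportional_to_parameter(h2o_state, rng):
    pts = _shell_points(h2o_state, rng)
    t1 = ctocd_diamagnetic(h2o_state, pts, SchemeParameter("GRRO", alpha=-0.02)).tensor
    t2 = ctocd_diamagnetic(h2o_state, pts, SchemeParameter("GRRO", alpha=-0.04)).tensor
    np.testing.assert_allclose(t2, 2.0 * t1, rtol=0, atol=1e-15)


def test_gpro_diamagnetic_matches_thomas_fermi_closed_form(h2o_state, rng):
    """beta = -0.0174 (Harris-Cina): the term must equal the direct formula
    -(1/2c) beta rho^(-2/3) B x grad(rho) assembled independently."""
    pts = _shell_points(h2o_state, rng)
    rho, grad = h2o_state.density(pts)
    beta = HARRIS_CINA_BETA
    expect = np.empty((len(pts), 3, 3))
    for b, e in enumerate(np.eye(3)):
        expect[:, :, b] = -beta / (2 * C_AU) * rho[:, None] ** (-2 / 3) * np.cross(e, grad)
    got = ctocd_diamagnetic(h2o_state, pts, SchemeParameter("GPRO", beta=beta)).tensor
    np.testing.assert_allclose(got, expect, rtol=1e-12, atol=1e-18)
    assert beta == pytest.approx(-0.0174, abs=5e-5)


def test_delta_paramagnetic_zero_at_zero_and_linear(h2o_state, rng):
    pts = _shell_points(h2o_state, rng)
    z = ctocd_delta_paramagnetic(h2o_state, pts, SchemeParameter("GRRO", alpha=0.0)).tensor
    assert np.abs(z).max() == 0.0
    t1 = ctocd_delta_paramagnetic(h2o_state, pts, SchemeParameter("GRRO", alpha=-0.015)).tensor
    t2 = ctocd_delta_paramagnetic(h2o_state, pts, SchemeParameter("GRRO", alpha=-0.030)).tensor
    np.testing.assert_allclose(t2, 2.0 * t1, rtol=0, atol=1e-15)


def test_delta_paramagnetic_single_point_brute_force(h2o_state):
    """Rebuild the contraction with (d(r) - r) x B weights at one point."""
    pt = np.array([[0.7, 0.4, -0.2]])
    alpha = -0.02
    rho, grad = h2o_state.density(pt)
    KP = h2o_state.p_kernel(pt)  # (3, 1, 3)
    shift = alpha * grad[0] / rho[0]  # r - d(r) = f grad(ln rho)
    expect = np.zeros((1, 3, 3))
    for b, e in enumerate(np.eye(3)):
        w = np.cross(e, -shift)  # B x (d - r) = -B x (f grad ln rho) ... sign below
        for g in range(3):
            expect[0, :, b] += -w[g] * KP[g, 0, :]
    got = ctocd_delta_paramagnetic(h2o_state, pt, SchemeParameter("GRRO", alpha=alpha)).tensor
    np.testing.assert_allclose(got, expect, atol=1e-12)


def test_unit_parameter_kernel_reconstruction(h2o_state, rng):
    pts = _shell_points(h2o_state, rng)
    K = unit_parameter_kernel(h2o_state, pts, "GRRO").tensor
    base = total_current(h2o_state, pts, SchemeParameter("GRRO", alpha=0.0)).tensor
    direct = total_current(h2o_state, pts, SchemeParameter("GRRO", alpha=-0.137)).tensor
    np.testing.assert_allclose(base + (-0.137) * K, direct, atol=1e-12)


def test_kernel_extraction_is_probe_independent(h2o_state, rng):
    """K from two different parameter pairs agrees: the kernel is intrinsic."""
    pts = _shell_points(h2o_state, rng, n=20)

    def extract(p1, p2):
        t1 = total_current(h2o_state, pts, SchemeParameter("GPRO", beta=p1)).tensor
        t2 = total_current(h2o_state, pts, SchemeParameter("GPRO", beta=p2)).tensor
        return (t2 - t1) / (p2 - p1)

    np.testing.assert_allclose(
        extract(-0.01, -0.05), extract(-0.02, -0.11), atol=1e-10
    )


def test_kernel_suppressed_in_density_tail(h2o_state):
    far = np.array([[0.0, 0.0, 40.0]])  # rho ~ e^{-r^2} << rho_cut
    K = unit_parameter_kernel(h2o_state, far, "GPRO").tensor
    assert np.abs(K).max() == 0.0


def test_three_point_linearity_of_the_field(h2o_state, rng):
    """The central claim: any field value at p2 is the linear interpolation
    of the fields at p1 and p3."""
    pts = _shell_points(h2o_state, rng)
    p1, p2, p3 = -0.004, -0.01, -0.019
    t = {
        p: total_current(h2o_state, pts, SchemeParameter("GRRO", alpha=p)).tensor
        for p in (p1, p2, p3)
    }
    lam = (p2 - p1) / (p3 - p1)
    interp = (1 - lam) * t[p1] + lam * t[p3]
    scale = np.abs(t[p2]).max()
    assert np.abs(interp - t[p2]).max() <= 1e-10 * scale


def test_divergence_of_analytic_solenoid():
    """Exact solenoidal field (curl of a vector potential) has zero divergence."""

    def ev(p):
        p = np.atleast_2d(p)
        r2 = np.einsum("pi,pi->p", p, p)
        psi = np.exp(-0.5 * r2)
        out = np.zeros((p.shape[0], 3, 3))
        for b in range(3):
            # J = grad(psi) x e_b  (divergence-free for any psi)
            out[:, :, b] = np.cross(-psi[:, None] * p, np.eye(3)[b])
        return out

    pts = np.random.default_rng(7).normal(size=(40, 3))
    f = CurrentField(pts, ev(pts), "CO", None, "test", ev)
    assert np.abs(divergence_map(f, 1e-3, order=4)).max() < 1e-8


def test_co_diamagnetic_divergence_pattern(he_state, rng):
    """For an atomic CO diamagnetic field, div J = -(1/2c) grad(rho).(B x r)."""
    pts = _shell_points(he_state, rng, n=20, scale=1.0)
    f = co_current(he_state, pts, component="diamagnetic")
    div = divergence_map(f, 1e-3, order=4)
    rho, grad = he_state.density(pts)
    expect = np.stack(
        [-np.einsum("pi,pi->p", grad, np.cross(np.eye(3)[b], pts)) for b in range(3)], axis=1
    ) / (2 * C_AU)
    np.testing.assert_allclose(div, expect, atol=1e-8)


def test_grro_gpro_diamagnetic_is_divergenceless(h2o_state, rng):
    pts = _shell_points(h2o_state, rng, n=40)
    for param in (SchemeParameter("GRRO", alpha=-0.01), SchemeParameter("GPRO", beta=-0.05)):
        f = ctocd_diamagnetic(h2o_state, pts, param)
        div = divergence_map(f, 1e-3, order=4)
        assert np.abs(div).max() < 1e-6 * np.abs(f.tensor).max()


def test_scheme_misuse_and_bad_step():
    with pytest.raises(SchemeMisuseError):
        SchemeParameter("XX")
    with pytest.raises(SchemeMisuseError):
        SchemeParameter("GRRO")  # alpha missing
    with pytest.raises(SchemeMisuseError):
        ctocd_diamagnetic(None, np.zeros((1, 3)), SchemeParameter("DZ1"))
    f = CurrentField(np.zeros((1, 3)), np.zeros((1, 3, 3)), "DZ1", None, "total",
                     lambda p: np.zeros((np.atleast_2d(p).shape[0], 3, 3)))
    with pytest.raises(ValueError):
        divergence_map(f, h=0.0)
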