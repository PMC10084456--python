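"""First-order induced current-density tensors for the CO, DZ1, GRRO and GPRO schemes.

All fields are stored as per-point 3x3 tensors ``tensor[p, delta, beta] =
dJ_delta/dB_beta`` (atomic units of current density per unit field), so no
explicit field magnitude ever appears.

Scheme summary (shift function d(r) of the continuous origin transformation):

* CO    -- fixed common origin r0'; origin-dependent in a finite basis.
* DZ1   -- d(r) = r (ipsocentric); the diamagnetic term vanishes identically.
* GRRO  -- d(r) = r - alpha * grad(ln rho).
* GPRO  -- d(r) = r - beta * rho^(-2/3) * grad(ln rho).

The GPRO exponent follows from requiring f(rho) * grad(ln rho) to carry the
dimension of a length: [grad ln rho] = 1/L and [rho^(-2/3)] = L^2 in atomic
units.  With this form the merged diamagnetic term is
-(3 beta / 2c) B x grad(rho^(1/3)), which reproduces the Thomas-Fermi current
of Harris and Cina when beta = -1/(6 (3 pi^2)^(2/3)) = -0.0174.

Both GRRO and GPRO totals are *exactly* linear in their parameter:
``total(p) = dz1 + p * unit_parameter_kernel``; the kernel is computed once
and reused for any parameter value and for per-atom parameter switching.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np

from .elements import SPEED_OF_LIGHT

__all__ = [
    "HARRIS_CINA_BETA",
    "SchemeParameter",
    "CurrentField",
    "co_current",
    "dz1_current",
    "ctocd_diamagnetic",
    "ctocd_delta_paramagnetic",
    "unit_parameter_kernel",
    "total_current",
    "divergence_map",
]

#: Thomas-Fermi (Harris-Cina) value of the GPRO parameter, -1/(6 (3 pi^2)^(2/3))
HARRIS_CINA_BETA = -1.0 / (6.0 * (3.0 * np.pi**2) ** (2.0 / 3.0))

_SCHEMES = ("CO", "DZ1", "GRRO", "GPRO")

# Levi-Civita tensor
_EPS = np.zeros((3, 3, 3))
for _i, _j, _k in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
    _EPS[_i, _j, _k] = 1.0
    _EPS[_k, _j, _i] = -1.0


class SchemeMisuseError(ValueError):
    pass


@dataclass(frozen=True)
class SchemeParameter:
    """Scheme selector plus the single parameter the scheme reads.

    ``alpha`` (GRRO, atomic units) and ``beta`` (GPRO, dimensionless) should
    both be negative to keep the tropicity of the diamagnetic vortex near
    nuclei; ``rho_cut`` suppresses the grad(ln rho) shift in density tails.
    """

    scheme: str
    alpha: float | None = None
    beta: float | None = None
    rho_cut: float = 1e-10

    def __post_init__(self):
        if self.scheme not in _SCHEMES:
            raise SchemeMisuseError(f"unknown scheme {self.scheme!r}; one of {_SCHEMES}")
        if self.scheme == "GRRO" and self.alpha is None:
            raise SchemeMisuseError("GRRO requires alpha")
        if self.scheme == "GPRO" and self.beta is None:
            raise SchemeMisuseError("GPRO requires beta")

    @property
    def value(self) -> float:
        if self.scheme == "GRRO":
            return float(self.alpha)
        if self.scheme == "GPRO":
            return float(self.beta)
        return 0.0

    def with_value(self, v: float) -> "SchemeParameter":
        if self.scheme == "GRRO":
            return replace(self, alpha=v)
        if self.scheme == "GPRO":
            return replace(self, beta=v)
        return self


@dataclass
class CurrentField:
    """Per-point current-density tensor with provenance and a re-evaluator.

    ``evaluator`` rebuilds the same field on arbitrary points (closure over
    the response state), which is what the divergence map differentiates.
    """

    points: np.ndarray  # (npts, 3)
    tensor: np.ndarray  # (npts, 3, 3): [delta, beta]
    scheme: str
    parameter: float | None
    component: str  # total | diamagnetic | paramagnetic | delta | kernel
    evaluator: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.tensor)):
            raise ValueError("non-finite current tensor")

    def at(self, points: np.ndarray) -> np.ndarray:
        if self.evaluator is None:
            raise ValueError("field has no evaluator closure")
        return self.evaluator(np.atleast_2d(points))


def _dia_tensor(rho: np.ndarray, rel: np.ndarray) -> np.ndarray:
    """Larmor-type term -(1/2c) rho * B x (r - origin) as a unit-B tensor."""
    # (B x u)_delta per unit B_beta = eps[delta, beta, nu] u_nu
    return -(1.0 / (2.0 * SPEED_OF_LIGHT)) * np.einsum("dbn,pn,p->pdb", _EPS, rel, rho)


def _contract_p(coef: np.ndarray, KP: np.ndarray) -> np.ndarray:
    """sum_gamma coef[p, beta, gamma] * KP[gamma, p, delta] -> (npts, 3, 3)."""
    return np.einsum("pbg,gpd->pdb", coef, KP)


def _cross_coef(u: np.ndarray) -> np.ndarray:
    """coef[p, beta, gamma] = [e_beta x u(p)]_gamma = eps[gamma, beta, nu] u_nu."""
    return np.einsum("gbn,pn->pbg", _EPS, u)


def co_current(state, points, origin=None, component: str = "total") -> CurrentField:
    """Common-origin current: conventional paramagnetic + diamagnetic terms.

    Origin defaults to the state's r0.  In a finite basis the total depends
    on the origin choice -- the defect the CTOCD schemes remove.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    origin = state.r0 if origin is None else np.asarray(origin, dtype=float)

    shift = origin - np.asarray(state.r0, dtype=float)

    def ev(p):
        p = np.atleast_2d(p)
        rho, _, KL, KP = _ingredients(state, p)
        dia = _dia_tensor(rho, p - origin)
        if component == "diamagnetic":
            return dia
        para = np.transpose(KL, (1, 2, 0))  # [p, delta, beta]
        if np.any(shift != 0.0):
            # L(r0') = L(r0) - (r0' - r0) x P
            coef = np.broadcast_to(_cross_coef(shift[None, :]), (p.shape[0], 3, 3))
            para = para - _contract_p(coef, KP)
        if component == "paramagnetic":
            return para
        return dia + para

    return CurrentField(pts, ev(pts), "CO", None, component, ev)


def _ingredients(state, pts):
    if hasattr(state, "current_ingredients"):
        return state.current_ingredients(pts)
    rho, grad = state.density(pts)
    return rho, grad, state.l_kernel(pts), state.p_kernel(pts)


def _dz1_from(pts, r0, KL, KP) -> np.ndarray:
    para = np.transpose(KL, (1, 2, 0))
    return para - _contract_p(_cross_coef(pts - r0), KP)


def _unit_kernel_from(rho, grad, KP, scheme: str, rho_cut: float) -> np.ndarray:
    """dia + delta contributions at unit parameter value."""
    probe = SchemeParameter(scheme, alpha=1.0, beta=1.0, rho_cut=rho_cut)
    s, gradln, mask = _shift_shape(rho, grad, probe)
    dia = -(1.0 / (2.0 * SPEED_OF_LIGHT)) * np.einsum(
        "dbn,pn,p->pdb", _EPS, np.where(mask[:, None], grad, 0.0), s
    )
    coef = _cross_coef(gradln) * s[:, None, None]
    return dia + _contract_p(coef, KP)


def dz1_current(state, points) -> CurrentField:
    """Ipsocentric d(r) = r current; the alpha = beta = 0 limit of GRRO/GPRO.

    Independent of the backend origin r0 by the operator identity
    L(r) = L(r0) - (r - r0) x P and linearity of the response.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))

    def ev(p):
        p = np.atleast_2d(p)
        _, _, KL, KP = _ingredients(state, p)
        return _dz1_from(p, state.r0, KL, KP)

    return CurrentField(pts, ev(pts), "DZ1", None, "total", ev)


def _shift_shape(rho: np.ndarray, grad: np.ndarray, param: SchemeParameter):
    """(s, gradlnrho, mask): scheme shape factor and the tail-suppressed shift."""
    mask = rho >= param.rho_cut
    safe = np.where(mask, rho, 1.0)
    gradln = np.where(mask[:, None], grad / safe[:, None], 0.0)
    if param.scheme == "GRRO":
        s = np.where(mask, 1.0, 0.0)
    else:  # GPRO
        s = np.where(mask, safe ** (-2.0 / 3.0), 0.0)
    return s, gradln, mask


def ctocd_diamagnetic(state, points, param: SchemeParameter) -> CurrentField:
    """Merged divergenceless diamagnetic term -(1/2c) f(rho) B x grad(rho).

    Strictly proportional to alpha (GRRO) or beta (GPRO); exactly solenoidal
    because it is B x grad(scalar).
    """
    if param.scheme not in ("GRRO", "GPRO"):
        raise SchemeMisuseError(f"diamagnetic CTOCD term undefined for scheme {param.scheme}")
    pts = np.atleast_2d(np.asarray(points, dtype=float))

    def ev(p):
        p = np.atleast_2d(p)
        rho, grad = state.density(p)
        s, _, mask = _shift_shape(rho, grad, param)
        f = param.value * s
        # -(1/2c) f(rho) (B x grad rho): tensor eps[d, b, n] grad_n
        return -(1.0 / (2.0 * SPEED_OF_LIGHT)) * np.einsum(
            "dbn,pn,p->pdb", _EPS, np.where(mask[:, None], grad, 0.0), f
        )

    return CurrentField(pts, ev(pts), param.scheme, param.value, "diamagnetic", ev)


def ctocd_delta_paramagnetic(state, points, param: SchemeParameter) -> CurrentField:
    """Extra paramagnetic term from the origin shift, contracted with the
    momentum-response kernels: + f(rho) [B x grad(ln rho)]_gamma K_P^gamma.

    Linear in the parameter; zero wherever rho < rho_cut.
    """
    if param.scheme not in ("GRRO", "GPRO"):
        raise SchemeMisuseError(f"delta term undefined for scheme {param.scheme}")
    pts = np.atleast_2d(np.asarray(points, dtype=float))

    def ev(p):
        p = np.atleast_2d(p)
        rho, grad = state.density(p)
        s, gradln, _ = _shift_shape(rho, grad, param)
        KP = state.p_kernel(p)
        coef = _cross_coef(gradln) * (param.value * s)[:, None, None]
        return _contract_p(coef, KP)

    return CurrentField(pts, ev(pts), param.scheme, param.value, "delta", ev)


def unit_parameter_kernel(state, points, scheme: str, rho_cut: float = 1e-10) -> CurrentField:
    """Field K with total(p) = total(0) + p * K exactly, for any p.

    Computed once per grid and reused for parameter sweeps and for per-atom
    parameter switching during single-pass shielding integration.
    """
    if scheme not in ("GRRO", "GPRO"):
        raise SchemeMisuseError(f"parameter kernel undefined for scheme {scheme!r}")

    def ev(p):
        p = np.atleast_2d(p)
        rho, grad = state.density(p)
        KP = state.p_kernel(p)
        return _unit_kernel_from(rho, grad, KP, scheme, rho_cut)

    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return CurrentField(pts, ev(pts), scheme, 1.0, "kernel", ev)


def total_current(state, points, param: SchemeParameter) -> CurrentField:
    """Total induced current tensor of the requested scheme."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if param.scheme == "CO":
        f = co_current(state, pts)
        return replace(f, scheme="CO")
    if param.scheme == "DZ1":
        return dz1_current(state, pts)
    val = param.value

    def ev(p):
        p = np.atleast_2d(p)
        rho, grad, KL, KP = _ingredients(state, p)
        base = _dz1_from(p, state.r0, KL, KP)
        return base + val * _unit_kernel_from(rho, grad, KP, param.scheme, param.rho_cut)

    return CurrentField(pts, ev(pts), param.scheme, val, "total", ev)


def divergence_map(field: CurrentField, h: float = 1e-3, order: int = 2) -> np.ndarray:
    """Central-difference divergence of each column (unit-B component) of the
    tensor; shape (npts, 3), one value per B direction.

    ``order`` selects the 2nd-order 2-point or 4th-order 4-point stencil; the
    latter pushes the truncation error of the check well below the 1e-6
    solenoidality tolerance near nuclear cusps.
    """
    if h <= 0:
        raise ValueError(f"step h must be positive, got {h}")
    if order not in (2, 4):
        raise ValueError("stencil order must be 2 or 4")
    pts = field.points
    div = np.zeros((pts.shape[0], 3))
    for d in range(3):
        dp = np.zeros(3)
        dp[d] = h
        if order == 2:
            div += (field.at(pts + dp)[:, d, :] - field.at(pts - dp)[:, d, :]) / (2.0 * h)
        else:
            div += (
                -field.at(pts + 2 * dp)[:, d, :]
                + 8.0 * field.at(pts + dp)[:, d, :]
                - 8.0 * field.at(pts - dp)[:, d, :]
                + field.at(pts - 2 * dp)[:, d, :]
            ) / (12.0 * h)
    return div
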