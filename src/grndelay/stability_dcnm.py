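"""Linear stability and Hopf bifurcation of the complete (4-variable) model.

Linearisation about an equilibrium yields

``(lambda+gamma_a)(lambda+gamma_b)(lambda+delta_a)(lambda+delta_b)
  + D_c * exp(-lambda*tau) = 0``,

i.e. ``lambda**4 + A*lambda**3 + B*lambda**2 + C*lambda + D
+ D_c*exp(-lambda*tau) = 0`` with (A, B, C, D) the elementary symmetric
polynomials of the four decay rates and ``D_c`` (``d_dcnm``) the loop gain
``m_a*m_b*k_a*k_b`` times the product of the two Hill slopes at the
equilibrium — equivalently ``gamma_a*gamma_b`` times the reduced model's
coupling strength.

At ``tau = 0`` stability is decided by the Routh-Hurwitz minors of the
quartic; for positive parameters the first two are automatically positive
and the last, ``Delta_4 = (D + D_c)*(A*B*C - A**2*(D + D_c)) - C**2``,
is the binding condition.  For ``tau > 0``, purely imaginary roots
``i*omega`` require ``z = omega**2`` to be a positive root of the quartic

``g(z) = z**4 + a*z**3 + b*z**2 + c*z + d``,
``a = A**2 - 2B``, ``b = B**2 + 2D - 2AC``, ``c = C**2 - 2BD``,
``d = D**2 - D_c**2``,

and the corresponding delays follow from the (cos, sin) pair

``omega**4 - B*omega**2 + D = -D_c*cos(omega*tau)``,
``-A*omega**3 + C*omega     =  D_c*sin(omega*tau)``.

The smallest positive such delay is ``tau_0``; the crossing speed there has
the sign of ``g'(omega0**2)``.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

import numpy as np

from .models import GRNParams
from .steadystate import SteadyState
from .stability_dsnm import HOPF, STABLE_ALL_TAU, d_dsnm

__all__ = [
    "DCNMStabilityReport",
    "UNSTABLE_AT_ZERO",
    "d_dcnm",
    "dcnm_coefficients",
    "dcnm_char",
    "routh_hurwitz_tau0",
    "dcnm_crossing_quartic",
    "dcnm_critical_delays",
    "dcnm_transversality",
]

UNSTABLE_AT_ZERO = "unstable-at-tau0"

_GPRIME_DEGENERATE_TOL = 1e-10


@dataclass(frozen=True)
class DCNMStabilityReport:
    """Outcome of the complete model's stability analysis at one equilibrium.

    ``tau_table`` maps each positive quartic root ``z_k`` (by index into
    ``crossing_roots``) to its increasing sequence of crossing delays; the
    verdict uses only ``tau0 = min_k tau_k,0``.  When the equilibrium is
    already unstable at ``tau = 0`` (Routh-Hurwitz failure) the crossing
    analysis is skipped and the classification is ``unstable-at-tau0``.
    """

    coeffs: tuple[float, float, float, float]
    d_dcnm: float
    routh: tuple[float, float, float, float]
    stable_at_zero: bool
    classification: str
    g_coeffs: tuple[float, float, float, float] | None = None
    crossing_roots: tuple[float, ...] = ()
    omegas: tuple[float, ...] = ()
    tau_table: tuple[tuple[float, ...], ...] = ()
    tau0: float | None = None
    omega0: float | None = None
    gprime_sign: int | None = None
    gprime_value: float | None = None
    degenerate_crossing: bool = False
    char_residual: float | None = None


def dcnm_coefficients(params: GRNParams) -> tuple[float, float, float, float]:
    """(A, B, C, D): elementary symmetric polynomials e1..e4 of the decay
    rates (gamma_a, gamma_b, delta_a, delta_b)."""
    ga, gb, da, db = params.gamma_a, params.gamma_b, params.delta_a, params.delta_b
    A = ga + gb + da + db
    B = ga * gb + ga * da + ga * db + gb * da + gb * db + da * db
    C = ga * gb * da + ga * gb * db + ga * da * db + gb * da * db
    D = ga * gb * da * db
    return A, B, C, D


def d_dcnm(params: GRNParams, ss: SteadyState) -> float:
    """Delayed coupling strength of the complete model:
    ``gamma_a*gamma_b`` times the reduced model's ``D`` (the mRNA stages
    contribute their degradation rates to the loop gain)."""
    return params.gamma_a * params.gamma_b * d_dsnm(params, ss)


def dcnm_char(
    lam: complex, params: GRNParams, dc: float, tau: float
) -> complex:
    A, B, C, D = dcnm_coefficients(params)
    return (
        lam**4 + A * lam**3 + B * lam**2 + C * lam + D
        + dc * cmath.exp(-lam * tau)
    )


def routh_hurwitz_tau0(
    params: GRNParams, ss: SteadyState
) -> tuple[bool, tuple[float, float, float, float]]:
    """Routh-Hurwitz minors of the zero-delay quartic and the verdict.

    Standard Hurwitz determinants for ``lambda**4 + A lambda**3 + B lambda**2
    + C lambda + E`` with ``E = D + D_c``:
    ``Delta_1 = A``, ``Delta_2 = A*B - C``,
    ``Delta_3 = A*B*C - C**2 - A**2*E``, ``Delta_4 = E*Delta_3``.
    For positive rates ``Delta_1, Delta_2, E > 0`` automatically, so
    ``Delta_3 > 0`` (equivalently ``Delta_4 > 0``) alone decides stability
    at ``tau = 0``.
    """
    A, B, C, D = dcnm_coefficients(params)
    dc = d_dcnm(params, ss)
    E = D + dc
    d1 = A
    d2 = A * B - C
    d3 = A * B * C - C * C - A * A * E
    d4 = E * d3
    return d3 > 0.0, (d1, d2, d3, d4)


def dcnm_crossing_quartic(
    params: GRNParams, ss: SteadyState, root_tol: float = 1e-8
) -> tuple[tuple[float, float, float, float], list[float]]:
    """Coefficients (a, b, c, d) of the crossing quartic ``g(z)`` and its
    strictly positive real roots (ascending, Newton-polished)."""
    A, B, C, D = dcnm_coefficients(params)
    dc = d_dcnm(params, ss)
    a = A * A - 2.0 * B
    b = B * B + 2.0 * D - 2.0 * A * C
    c = C * C - 2.0 * B * D
    d = D * D - dc * dc
    coeffs = np.array([1.0, a, b, c, d])
    deriv = np.polyder(coeffs)
    roots = []
    for r in np.roots(coeffs):
        if abs(r.imag) > root_tol * max(1.0, abs(r.real)):
            continue
        z = r.real
        for _ in range(8):
            fz, dz = np.polyval(coeffs, z), np.polyval(deriv, z)
            if dz == 0:
                break
            z -= fz / dz
        if z > root_tol:
            roots.append(float(z))
    roots.sort()
    # collapse near-duplicates (double roots)
    dedup: list[float] = []
    for z in roots:
        if not dedup or abs(z - dedup[-1]) > 1e-9 * max(1.0, z):
            dedup.append(z)
    return (a, b, c, d), dedup


def dcnm_transversality(
    g_coeffs: tuple[float, float, float, float], z0: float
) -> tuple[int, float]:
    """Sign and value of ``g'(z0)``, the crossing-speed factor at the first
    crossing (Hopf transversality requires ``g'(z0) > 0``)."""
    a, b, c, _ = g_coeffs
    gp = 4.0 * z0**3 + 3.0 * a * z0**2 + 2.0 * b * z0 + c
    if abs(gp) <= _GPRIME_DEGENERATE_TOL:
        return 0, gp
    return (1 if gp > 0 else -1), gp


def dcnm_critical_delays(
    params: GRNParams,
    ss: SteadyState,
    j_max: int = 3,
) -> DCNMStabilityReport:
    """Full stability classification of the complete model at ``ss``.

    Runs the zero-delay Routh-Hurwitz check, extracts positive roots of the
    crossing quartic, resolves each crossing angle with atan2 from the
    (cos, sin) pair (the printed principal-arctangent form is quadrant
    ambiguous), tabulates ``tau_k,j = (angle_k + 2*pi*j)/omega_k`` and takes
    the minimum as ``tau_0``.
    """
    A, B, C, D = dcnm_coefficients(params)
    dc = d_dcnm(params, ss)
    stable0, deltas = routh_hurwitz_tau0(params, ss)
    base = dict(
        coeffs=(A, B, C, D), d_dcnm=dc, routh=deltas, stable_at_zero=stable0
    )
    if not stable0:
        return DCNMStabilityReport(classification=UNSTABLE_AT_ZERO, **base)
    g_coeffs, zs = dcnm_crossing_quartic(params, ss)
    if not zs:
        return DCNMStabilityReport(
            classification=STABLE_ALL_TAU, g_coeffs=g_coeffs, **base
        )
    omegas = [math.sqrt(z) for z in zs]
    table: list[tuple[float, ...]] = []
    for w in omegas:
        cosv = -(w**4 - B * w * w + D) / dc
        sinv = (-A * w**3 + C * w) / dc
        ang = math.atan2(sinv, cosv)
        if ang <= 0.0:
            ang += 2.0 * math.pi
        table.append(tuple((ang + 2.0 * math.pi * j) / w for j in range(j_max + 1)))
    k0 = min(range(len(zs)), key=lambda k: table[k][0])
    tau0 = table[k0][0]
    omega0 = omegas[k0]
    sign, gp = dcnm_transversality(g_coeffs, zs[k0])
    resid = abs(dcnm_char(1j * omega0, params, dc, tau0))
    return DCNMStabilityReport(
        classification=HOPF,
        g_coeffs=g_coeffs,
        crossing_roots=tuple(zs),
        omegas=tuple(omegas),
        tau_table=tuple(table),
        tau0=tau0,
        omega0=omega0,
        gprime_sign=sign,
        gprime_value=gp,
        degenerate_crossing=(sign == 0),
        char_residual=resid,
        **base,
    )
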