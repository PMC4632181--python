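"""Linear stability and Hopf bifurcation of the reduced (two-protein) model.

Linearising about an equilibrium ``(p_a, p_b)`` gives the transcendental
characteristic equation

``(lambda + delta_a)(lambda + delta_b) + D * exp(-lambda*tau) = 0``,

where the coupling strength ``D`` (``d_dsnm``) is the product of the two
regulation slopes at the equilibrium.  At ``tau = 0`` the equation is a
stable quadratic, so instability can only arise through a pair of complex
eigenvalues crossing the imaginary axis.  Substituting ``lambda = i*omega``
and splitting into real and imaginary parts,

``omega**2 - delta_a*delta_b = D*cos(omega*tau)``,
``(delta_a + delta_b)*omega   = D*sin(omega*tau)``,

whose squared sum is the quadratic ``h(z) = z**2 + (delta_a**2 +
delta_b**2)*z + delta_a**2*delta_b**2 - D**2`` in ``z = omega**2``.  A real
crossing frequency exists iff ``delta_a*delta_b < D``; the dichotomy is:

* ``delta_a*delta_b >= D``: stable for every delay;
* ``delta_a*delta_b <  D``: stable for ``tau < tau_0``, Hopf at ``tau_0``,
  unstable beyond — the crossing is always left-to-right (``h'(z0) > 0``),
  so stability is never regained.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

from .models import GRNParams
from .steadystate import SteadyState

__all__ = [
    "DSNMStabilityReport",
    "d_dsnm",
    "dsnm_char",
    "dsnm_critical_frequency",
    "dsnm_critical_delays",
    "dsnm_transversality",
]

STABLE_ALL_TAU = "stable-all-tau"
HOPF = "hopf"

_FORM_AGREE_RTOL = 1e-10


@dataclass(frozen=True)
class DSNMStabilityReport:
    """Outcome of the reduced model's stability analysis at one equilibrium.

    ``tau0_list`` holds the delays at which the characteristic equation has
    the purely imaginary root pair ``+-i*omega0``; consecutive entries are
    spaced by one full period ``2*pi/omega0`` (both the cosine and sine
    conditions must hold, not merely their ratio).  Only the first entry
    decides stability: the crossing speed is positive, so eigenvalues never
    return to the left half-plane.
    """

    d_dsnm: float
    classification: str
    omega0: float | None = None
    tau0_list: tuple[float, ...] = ()
    transversality_sign: int | None = None
    transversality_value: float | None = None
    char_residual: float | None = None
    degenerate: bool = False

    @property
    def tau0(self) -> float | None:
        return self.tau0_list[0] if self.tau0_list else None


def d_dsnm(params: GRNParams, ss: SteadyState) -> float:
    """Equilibrium coupling strength ``D`` of the reduced model.

    Two algebraically equivalent expressions exist: the raw product of the
    regulation slopes scaled by ``k'_a k'_b``, and the form simplified with
    the fixed-point relations,
    ``n_a n_b delta_a delta_b * [p_a^na/(theta_a^na + p_a^na)] *
    [theta_b^nb/(theta_b^nb + p_b^nb)]``.
    Both are evaluated and must agree to relative 1e-10.
    """
    na, nb = params.n_a, params.n_b
    pa, pb = ss.p_a_bar, ss.p_b_bar
    tA, tB = params.theta_a**na, params.theta_b**nb
    if pa == 0.0:
        return 0.0
    lum = params.lumped
    d_raw = (
        lum.kprime_a * lum.kprime_b * na * nb * tA * tB
        * pa ** (na - 1) * pb ** (nb - 1)
        / ((tA + pa**na) ** 2 * (tB + pb**nb) ** 2)
    )
    d_simple = (
        na * nb * params.delta_a * params.delta_b
        * (pa**na / (tA + pa**na)) * (tB / (tB + pb**nb))
    )
    if not math.isclose(d_raw, d_simple, rel_tol=_FORM_AGREE_RTOL):
        raise ArithmeticError(
            f"coupling-strength forms disagree: {d_raw!r} vs {d_simple!r}; "
            "the supplied state is not an equilibrium of these parameters"
        )
    return d_simple


def dsnm_char(lam: complex, params: GRNParams, d: float, tau: float) -> complex:
    """Characteristic function of the reduced model."""
    return (lam + params.delta_a) * (lam + params.delta_b) + d * cmath.exp(-lam * tau)


def dsnm_critical_frequency(params: GRNParams, d: float) -> float | None:
    """Crossing frequency ``omega0`` (closed form), or None when the
    equilibrium is stable for every delay (``delta_a*delta_b >= D``)."""
    da, db = params.delta_a, params.delta_b
    if d <= 0 or da * db >= d:
        return None
    s = da * da + db * db
    disc = s * s - 4.0 * (da * da * db * db - d * d)
    z0 = 0.5 * (-s + math.sqrt(disc))
    return math.sqrt(z0)


def _crossing_angle(omega: float, params: GRNParams, d: float) -> float:
    """Angle ``omega*tau`` in (0, 2*pi] at which both crossing conditions
    hold; computed with atan2 from the (cos, sin) pair, which fixes the
    quadrant that a principal arctangent leaves ambiguous."""
    da, db = params.delta_a, params.delta_b
    cosv = (omega * omega - da * db) / d
    sinv = (da + db) * omega / d
    ang = math.atan2(sinv, cosv)
    if ang <= 0.0:
        ang += 2.0 * math.pi
    return ang


def dsnm_transversality(
    params: GRNParams, d: float, omega0: float
) -> tuple[int, float]:
    """Sign and raw value of the eigenvalue crossing speed at ``tau_0,n``.

    The sign equals that of ``h'(omega0**2) = 2*omega0**2 + delta_a**2 +
    delta_b**2 - 2*delta_a*delta_b + ...``; written in the reported form
    ``[2*(omega0**2 - delta_a*delta_b) + (delta_a+delta_b)**2] / D**2``,
    which is strictly positive whenever a crossing exists.
    """
    da, db = params.delta_a, params.delta_b
    raw = (2.0 * (omega0 * omega0 - da * db) + (da + db) ** 2) / (d * d)
    return (1 if raw > 0 else (-1 if raw < 0 else 0)), raw


def dsnm_critical_delays(
    params: GRNParams,
    ss: SteadyState,
    n_max: int = 3,
) -> DSNMStabilityReport:
    """Full stability classification of the reduced model at ``ss``.

    When ``delta_a*delta_b < D`` the report carries the crossing frequency,
    the delays ``tau_0 + 2*pi*n/omega0`` for ``n = 0..n_max``, the
    transversality sign (always +1) and the characteristic residual at
    ``(i*omega0, tau_0)``.
    """
    d = d_dsnm(params, ss)
    if d == 0.0:
        return DSNMStabilityReport(
            d_dsnm=0.0, classification=STABLE_ALL_TAU, degenerate=True
        )
    omega0 = dsnm_critical_frequency(params, d)
    if omega0 is None:
        return DSNMStabilityReport(d_dsnm=d, classification=STABLE_ALL_TAU)
    if omega0 == 0.0:
        raise ArithmeticError(
            "degenerate zero crossing frequency: lambda = 0 cannot solve the "
            "characteristic equation for positive parameters"
        )
    ang = _crossing_angle(omega0, params, d)
    taus = tuple(
        (ang + 2.0 * math.pi * n) / omega0 for n in range(n_max + 1)
    )
    sign, raw = dsnm_transversality(params, d, omega0)
    resid = abs(dsnm_char(1j * omega0, params, d, taus[0]))
    return DSNMStabilityReport(
        d_dsnm=d,
        classification=HOPF,
        omega0=omega0,
        tau0_list=taus,
        transversality_sign=sign,
        transversality_value=raw,
        char_residual=resid,
    )
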