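"""Equilibria of the two-gene network.

Both the complete and the reduced model share the same equilibria
``(r_a, r_b, p_a, p_b)`` (delays do not move fixed points).  Eliminating
``r_a, r_b, p_b`` leaves a single polynomial equation for the equilibrium
protein concentration ``p_a``.  Writing ``S = theta_a**n_a + p_a**n_a``, the
fixed-point conditions

``p_a = phi_a * h+(p_b; theta_b, n_b)``,  ``p_b = phi_b * theta_a**n_a / S``

combine (after clearing denominators by ``S**n_b``) into

``theta_b**n_b * p_a * S**n_b
  + phi_b**n_b * theta_a**(n_a*n_b) * (p_a - phi_a) = 0``,

a degree ``n_a*n_b + 1`` polynomial whose left-hand side is strictly
increasing on ``p_a >= 0`` and negative at 0 whenever ``phi_a, phi_b > 0``,
so exactly one positive root exists for fully positive parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .models import GRNParams, hill_activation, hill_inhibition

__all__ = ["SteadyState", "steady_state_polynomial", "solve_steady_states"]

logger = logging.getLogger(__name__)

#: A polynomial root counts as real when |Im| <= REAL_TOL * max(1, |Re|),
#: and as nonnegative when Re >= -CLAMP_TOL (then clamped to 0).
REAL_TOL = 1e-8
CLAMP_TOL = 1e-12
RESIDUAL_TOL = 1e-9


@dataclass(frozen=True)
class SteadyState:
    """A nonnegative equilibrium with its fixed-point residual.

    ``residual`` is the max-norm of the four stationarity conditions of the
    complete model evaluated at the equilibrium.  The mRNA components follow
    from the proteins: ``r_i = (delta_i / k_i) * p_i``.
    """

    r_a_bar: float
    r_b_bar: float
    p_a_bar: float
    p_b_bar: float
    residual: float

    def as_dcnm_state(self) -> np.ndarray:
        return np.array([self.r_a_bar, self.r_b_bar, self.p_a_bar, self.p_b_bar])

    def as_dsnm_state(self) -> np.ndarray:
        return np.array([self.p_a_bar, self.p_b_bar])


def steady_state_polynomial(params: GRNParams) -> np.ndarray:
    """Coefficients (descending powers) of the equilibrium polynomial in p_a.

    Built exactly from the binomial expansion of
    ``p * (theta_a**n_a + p**n_a)**n_b``; degree ``n_a*n_b + 1``.
    """
    na, nb = params.n_a, params.n_b
    tA = params.theta_a**na
    tB = params.theta_b**nb
    lum = params.lumped
    deg = na * nb + 1
    coeffs = np.zeros(deg + 1)
    # theta_b^nb * sum_k C(nb,k) tA^k p^{na*(nb-k)+1}
    from math import comb

    for k in range(nb + 1):
        power = na * (nb - k) + 1
        coeffs[deg - power] += tB * comb(nb, k) * tA**k
    scale = lum.phi_b**nb * tA**nb
    coeffs[deg - 1] += scale          # + phi_b^nb tA^nb * p
    coeffs[deg] -= scale * lum.phi_a  # - phi_a phi_b^nb tA^nb
    return coeffs


def _polish_root(coeffs: np.ndarray, x: float, iters: int = 8) -> float:
    """Newton refinement of a real polynomial root."""
    d = np.polyder(coeffs)
    for _ in range(iters):
        fx = np.polyval(coeffs, x)
        dx = np.polyval(d, x)
        if dx == 0:
            break
        step = fx / dx
        x -= step
        if abs(step) <= 1e-15 * max(1.0, abs(x)):
            break
    return x


def _equilibrium_residual(params: GRNParams, state: np.ndarray) -> float:
    """Max-norm of the stationarity conditions of the complete model."""
    r_a, r_b, p_a, p_b = state
    res = np.array([
        params.m_a * hill_activation(p_b, params.theta_b, params.n_b)
        - params.gamma_a * r_a,
        params.m_b * hill_inhibition(p_a, params.theta_a, params.n_a)
        - params.gamma_b * r_b,
        params.k_a * r_a - params.delta_a * p_a,
        params.k_b * r_b - params.delta_b * p_b,
    ])
    return float(np.max(np.abs(res)))


def solve_steady_states(
    params: GRNParams,
    residual_tol: float = RESIDUAL_TOL,
    real_tol: float = REAL_TOL,
) -> list[SteadyState]:
    """All nonnegative equilibria, sorted by increasing ``p_a``.

    Roots of the equilibrium polynomial are found as companion-matrix
    eigenvalues (``numpy.roots``), Newton-polished, filtered to the real
    nonnegative axis and back-substituted.  Every returned equilibrium is
    verified against the stationarity conditions; a violation above
    ``residual_tol`` raises.
    """
    lum = params.lumped
    na = params.n_a
    tA = params.theta_a**na
    if lum.phi_a * lum.phi_b == 0.0:
        # One of the genes is switched off; the cascade collapses to the
        # unique fixed point with p_a = 0.
        p_a = 0.0
        p_b = lum.phi_b
        state = np.array([
            params.delta_a / params.k_a * p_a,
            params.delta_b / params.k_b * p_b,
            p_a,
            p_b,
        ])
        return [SteadyState(*state, _equilibrium_residual(params, state))]

    coeffs = steady_state_polynomial(params)
    roots = np.roots(coeffs)
    out: list[SteadyState] = []
    seen: list[float] = []
    for root in roots:
        if abs(root.imag) > real_tol * max(1.0, abs(root.real)):
            continue
        x = root.real
        if x < -CLAMP_TOL:
            continue
        x = _polish_root(coeffs, max(x, 0.0))
        x = max(x, 0.0)
        if any(abs(x - s) <= 1e-10 * max(1.0, abs(s)) for s in seen):
            continue
        seen.append(x)
        p_b = lum.phi_b * tA / (tA + x**na)
        state = np.array([
            params.delta_a / params.k_a * x,
            params.delta_b / params.k_b * p_b,
            x,
            p_b,
        ])
        resid = _equilibrium_residual(params, state)
        if resid > residual_tol:
            raise ArithmeticError(
                f"equilibrium residual {resid:.3e} exceeds {residual_tol:.1e} "
                f"at p_a = {x!r}; polynomial root not a fixed point"
            )
        out.append(SteadyState(*state, resid))
    if not out:
        logger.warning(
            "no nonnegative equilibrium found for %s; for positive parameters "
            "one positive root is guaranteed by a sign change — check inputs",
            params,
        )
    out.sort(key=lambda s: s.p_a_bar)
    return out
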