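"""Core model definitions for the two-gene activator-inhibitor network.

The motif consists of two genes *a* and *b*: protein P_b activates
transcription of gene *a*, protein P_a represses transcription of gene *b*,
and neither gene regulates itself.  Two deterministic descriptions are
provided:

* the *complete* model (DCNM): four equations for the mRNA concentrations
  ``r_a, r_b`` and protein concentrations ``p_a, p_b``, with discrete delays
  for transcription (``tau_ra, tau_rb``) and translation (``tau_pa,
  tau_pb``);
* the *simplified* model (DSNM): a quasi-steady-state reduction to the two
  protein equations, in which the four delays lump into a single combined
  delay ``tau = tau_ra + tau_pa + tau_rb + tau_pb``.

Regulation is described by Hill functions with threshold ``theta`` (the
protein concentration at half-maximal regulation) and integer steepness
coefficient ``n``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Mapping, NamedTuple

import numpy as np

__all__ = [
    "GRNParams",
    "DelaySpec",
    "LumpedRates",
    "StateDCNM",
    "StateDSNM",
    "DelayedDCNM",
    "hill_activation",
    "hill_inhibition",
    "dcnm_rhs",
    "dsnm_rhs",
]


@dataclass(frozen=True)
class GRNParams:
    """Kinetic and regulatory parameters of the two-gene motif.

    Rates use inverse-time units, ``m_*`` and thresholds use concentration
    units; ``n_*`` are dimensionless positive integers.

    Parameters
    ----------
    m_a, m_b
        Maximum transcription rates (concentration/time).  Zero is allowed
        (gene switched off); negative values are rejected.
    k_a, k_b
        Translation rates (1/time), strictly positive.
    gamma_a, gamma_b
        mRNA degradation rates (1/time), strictly positive.
    delta_a, delta_b
        Protein degradation rates (1/time), strictly positive.
    theta_a, theta_b
        Hill thresholds (concentration), strictly positive.
    n_a, n_b
        Hill coefficients, integers >= 1.
    """

    m_a: float
    m_b: float
    k_a: float
    k_b: float
    gamma_a: float
    gamma_b: float
    delta_a: float
    delta_b: float
    theta_a: float
    theta_b: float
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        for name in ("m_a", "m_b"):
            v = getattr(self, name)
            if not (v >= 0.0) or not math.isfinite(v):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        for name in (
            "k_a", "k_b", "gamma_a", "gamma_b",
            "delta_a", "delta_b", "theta_a", "theta_b",
        ):
            v = getattr(self, name)
            if not (v > 0.0) or not math.isfinite(v):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        for name in ("n_a", "n_b"):
            v = getattr(self, name)
            if isinstance(v, float) and not v.is_integer():
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
            iv = int(v)
            if iv < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
            object.__setattr__(self, name, iv)

    @property
    def lumped(self) -> "LumpedRates":
        """Effective protein-production rates and equilibrium scales."""
        kprime_a = self.m_a * self.k_a / self.gamma_a
        kprime_b = self.m_b * self.k_b / self.gamma_b
        return LumpedRates(
            kprime_a=kprime_a,
            kprime_b=kprime_b,
            phi_a=kprime_a / self.delta_a,
            phi_b=kprime_b / self.delta_b,
        )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "GRNParams":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown parameter fields: {sorted(unknown)}")
        missing = known - set(mapping)
        if missing:
            raise ValueError(f"missing parameter fields: {sorted(missing)}")
        return cls(**dict(mapping))

    def replace(self, **changes: float) -> "GRNParams":
        d = self.to_dict()
        d.update(changes)
        return GRNParams(**d)


class LumpedRates(NamedTuple):
    """Derived composite rates.

    ``kprime_i = m_i * k_i / gamma_i`` is the protein production rate of the
    reduced model; ``phi_i = kprime_i / delta_i`` sets the scale of the
    equilibrium protein concentration.
    """

    kprime_a: float
    kprime_b: float
    phi_a: float
    phi_b: float


@dataclass(frozen=True)
class DelaySpec:
    """Transcriptional and translational delays (time units, each >= 0).

    The linear stability of either model depends on the delays only through
    their sum, exposed as :attr:`tau`.
    """

    tau_ra: float = 0.0
    tau_rb: float = 0.0
    tau_pa: float = 0.0
    tau_pb: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tau_ra", "tau_rb", "tau_pa", "tau_pb"):
            v = getattr(self, name)
            if not (v >= 0.0) or not math.isfinite(v):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def tau(self) -> float:
        """Combined (lumped) delay tau_ra + tau_pa + tau_rb + tau_pb."""
        return self.tau_ra + self.tau_pa + self.tau_rb + self.tau_pb

    @property
    def tau_max(self) -> float:
        return max(self.tau_ra, self.tau_rb, self.tau_pa, self.tau_pb)

    @classmethod
    def lumped(cls, tau: float) -> "DelaySpec":
        """A spec whose whole delay sits on one channel; for the reduced
        model only the sum matters, so this is the canonical constructor."""
        return cls(tau_ra=tau)


class StateDCNM(NamedTuple):
    """State of the complete model: two mRNAs and two proteins."""

    r_a: float
    r_b: float
    p_a: float
    p_b: float


class StateDSNM(NamedTuple):
    """State of the reduced model: the two proteins."""

    p_a: float
    p_b: float


class DelayedDCNM(NamedTuple):
    """The four lagged quantities entering the complete model's right-hand
    side: each equation sees exactly one delayed argument."""

    p_b_lag_ra: float  # p_b(t - tau_ra), drives transcription of gene a
    p_a_lag_rb: float  # p_a(t - tau_rb), represses transcription of gene b
    r_a_lag_pa: float  # r_a(t - tau_pa), template for translation of P_a
    r_b_lag_pb: float  # r_b(t - tau_pb), template for translation of P_b


def _hill_ratio_pow(p, theta, n):
    """(p/theta)**n computed overflow-safely for scalar or array p."""
    x = np.asarray(p, dtype=float) / theta
    # For x > 1 work with the reciprocal so x**n never overflows.
    with np.errstate(over="ignore"):
        return x, np.where(x <= 1.0, x**n, np.inf)


def hill_activation(p, theta: float, n: int):
    """Increasing Hill function ``p**n / (p**n + theta**n)``.

    Equals 0 at ``p = 0``, 1/2 at ``p = theta`` and tends to 1 as
    ``p -> inf``.  Computed from the ratio ``p/theta`` so that large Hill
    coefficients and wide parameter scans cannot overflow.
    """
    if theta <= 0:
        raise ValueError(f"theta must be > 0, got {theta!r}")
    if int(n) != n or n < 1:
        raise ValueError(f"n must be an integer >= 1, got {n!r}")
    n = int(n)
    x = np.asarray(p, dtype=float) / theta
    if np.any(x < 0):
        raise ValueError("protein concentration must be >= 0")
    small = x <= 1.0
    xs = np.where(small, x, 1.0)        # safe base for x**n
    inv = np.where(small, 1.0, 1.0 / np.where(small, 1.0, x))
    num = xs**n
    low = num / (1.0 + num)             # x <= 1 branch
    high = 1.0 / (1.0 + inv**n)         # x > 1 branch: 1/(1+(theta/p)**n)
    out = np.where(small, low, high)
    return float(out) if np.isscalar(p) or np.ndim(p) == 0 else out


def hill_inhibition(p, theta: float, n: int):
    """Decreasing Hill function ``theta**n / (p**n + theta**n)``;
    the exact complement ``1 - hill_activation``."""
    return 1.0 - hill_activation(p, theta, n)


def dcnm_rhs(
    current: StateDCNM | Iterable[float],
    delayed: DelayedDCNM | Iterable[float],
    params: GRNParams,
) -> np.ndarray:
    """Right-hand side of the complete delayed model.

    ``current`` carries (r_a, r_b, p_a, p_b) at time *t*; ``delayed`` the
    four lagged quantities (see :class:`DelayedDCNM`).  With all delays zero
    (``delayed`` equal to the corresponding current components) this is the
    undelayed complete model.
    """
    r_a, r_b, p_a, p_b = current
    pb_ra, pa_rb, ra_pa, rb_pb = delayed
    return np.array([
        params.m_a * hill_activation(pb_ra, params.theta_b, params.n_b)
        - params.gamma_a * r_a,
        params.m_b * hill_inhibition(pa_rb, params.theta_a, params.n_a)
        - params.gamma_b * r_b,
        params.k_a * ra_pa - params.delta_a * p_a,
        params.k_b * rb_pb - params.delta_b * p_b,
    ])


def dsnm_rhs(
    current: StateDSNM | Iterable[float],
    delayed_pa: float,
    params: GRNParams,
) -> np.ndarray:
    """Right-hand side of the reduced delayed model.

    After the quasi-steady-state reduction and a time shift of ``p_b``, the
    combined delay ``tau`` acts only on ``p_a`` in the repression term, while
    the activation of ``p_a`` by ``p_b`` is instantaneous:

    ``p_a' = k'_a h+(p_b) - delta_a p_a``
    ``p_b' = k'_b h-(p_a(t - tau)) - delta_b p_b``
    """
    p_a, p_b = current
    lum = params.lumped
    return np.array([
        lum.kprime_a * hill_activation(p_b, params.theta_b, params.n_b)
        - params.delta_a * p_a,
        lum.kprime_b * hill_inhibition(delayed_pa, params.theta_a, params.n_a)
        - params.delta_b * p_b,
    ])
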