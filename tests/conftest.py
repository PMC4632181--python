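"""Shared fixtures: the two published parameter sets used throughout."""

import pytest

from grndelay import GRNParams, solve_steady_states


def _unit_rates(**kw) -> GRNParams:
    base = dict(
        m_a=1.0, m_b=1.0, k_a=1.0, k_b=1.0, gamma_a=1.0, gamma_b=1.0,
        delta_a=1.0, delta_b=1.0, theta_a=1.0, theta_b=1.0, n_a=3, n_b=3,
    )
    base.update(kw)
    return GRNParams(**base)


@pytest.fixture(scope="session")
def symmetric_params() -> GRNParams:
    """Symmetric set: m_a = m_b = 2.35, theta = 1, n = 3, unit rates."""
    return _unit_rates(m_a=2.35, m_b=2.35)


@pytest.fixture(scope="session")
def asymmetric_params() -> GRNParams:
    """Asymmetric set: m_a = 0.6, m_b = 0.3, theta = 0.21, n = 3, unit rates."""
    return _unit_rates(m_a=0.6, m_b=0.3, theta_a=0.21, theta_b=0.21)


@pytest.fixture(scope="session")
def sharp_threshold_params() -> GRNParams:
    """m = 2.35 with the low threshold theta = 0.21 (strong coupling)."""
    return _unit_rates(m_a=2.35, m_b=2.35, theta_a=0.21, theta_b=0.21)


def _positive_equilibrium(params):
    states = [s for s in solve_steady_states(params) if s.p_a_bar > 0]
    assert len(states) == 1
    return states[0]


@pytest.fixture(scope="session")
def symmetric_ss(symmetric_params):
    return _positive_equilibrium(symmetric_params)


@pytest.fixture(scope="session")
def asymmetric_ss(asymmetric_params):
    return _positive_equilibrium(asymmetric_params)


@pytest.fixture(scope="session")
def sharp_threshold_ss(sharp_threshold_params):
    return _positive_equilibrium(sharp_threshold_params)
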