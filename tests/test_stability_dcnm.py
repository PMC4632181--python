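"""Complete-model stability analysis: quartic coefficients, Routh-Hurwitz,
the crossing quartic, critical delays, and transversality.

Frozen reference values for the asymmetric published set (m_a = 0.6,
m_b = 0.3, theta = 0.21, n = 3, unit rates), computed with 50-digit
arithmetic (equilibrium -> D_c -> closed-form quartic root (z+1)^4 = D_c^2
-> quadrant-resolved crossing delay):

    D_c    = 2.7223189522742377880
    omega0 = 0.80619174899068836150
    tau0   = 0.53036092866622008732
"""

import numpy as np
import pytest

from grndelay import (
    GRNParams,
    d_dcnm,
    d_dsnm,
    dcnm_coefficients,
    dcnm_critical_delays,
    dcnm_crossing_quartic,
    dsnm_critical_delays,
    generate_fixture_params,
    oracle_rightmost_root,
    routh_hurwitz_tau0,
    solve_steady_states,
)
from grndelay.stability_dcnm import UNSTABLE_AT_ZERO, dcnm_char
from grndelay.stability_dsnm import HOPF, STABLE_ALL_TAU

DC_REF = 2.7223189522742377880
OMEGA0_REF = 0.80619174899068836150
TAU0_REF = 0.53036092866622008732


def test_coefficients_unit_rates(symmetric_params):
    assert dcnm_coefficients(symmetric_params) == (4.0, 6.0, 4.0, 1.0)


def test_coefficients_match_polynomial_expansion_oracle():
    """(A,B,C,D) are the coefficients of prod(lambda + rate); compared with
    numpy's polynomial-from-roots expansion."""
    rng = np.random.default_rng(2)
    for _ in range(25):
        ga, gb, da, db = rng.uniform(0.2, 4, 4)
        params = GRNParams(
            m_a=1, m_b=1, k_a=1, k_b=1, gamma_a=ga, gamma_b=gb,
            delta_a=da, delta_b=db, theta_a=1, theta_b=1, n_a=2, n_b=2,
        )
        expansion = np.poly([-ga, -gb, -da, -db])  # leading 1, then A,B,C,D
        np.testing.assert_allclose(
            dcnm_coefficients(params), expansion[1:], rtol=1e-12
        )


def test_coupling_strength_is_mrna_scaled_reduced_coupling():
    """D_c = gamma_a*gamma_b*D: the mRNA stages multiply the loop gain.
    Verified against tau=0 Jacobian eigenvalues through the quartic."""
    rng = np.random.default_rng(8)
    for _ in range(10):
        params, _ = generate_fixture_params(int(rng.integers(1 << 30)), "hopf")
        (ss,) = [s for s in solve_steady_states(params) if s.p_a_bar > 0]
        dc = d_dcnm(params, ss)
        assert dc == pytest.approx(
            params.gamma_a * params.gamma_b * d_dsnm(params, ss), rel=1e-12
        )


def test_routh_hurwitz_verdict_matches_eigenvalue_oracle():
    """Stability at tau=0 from the Routh-Hurwitz minors must agree with the
    sign of the largest real part of the quartic's roots (companion-matrix
    oracle), across 50 random parameter draws."""
    rng = np.random.default_rng(17)
    checked = 0
    for _ in range(50):
        params, _ = generate_fixture_params(int(rng.integers(1 << 30)), "near-boundary")
        positive = [s for s in solve_steady_states(params) if s.p_a_bar > 0]
        ss = positive[0]
        stable, deltas = routh_hurwitz_tau0(params, ss)
        A, B, C, D = dcnm_coefficients(params)
        dc = d_dcnm(params, ss)
        roots = np.roots([1.0, A, B, C, D + dc])
        oracle_stable = max(roots.real) < 0
        assert stable == oracle_stable
        assert deltas[0] > 0 and deltas[1] > 0  # automatic for positive rates
        if stable:
            assert deltas[2] > 0  # Delta_4 > 0 implies Delta_3 > 0
        checked += 1
    assert checked == 50


def test_crossing_quartic_roots_match_grid_scan(asymmetric_params, asymmetric_ss):
    """Positive roots z_k of g(z) are exactly where |P(i*omega)| = D_c on a
    fine frequency grid (minima of the squared characteristic modulus)."""
    (a, b, c, d), zs = dcnm_crossing_quartic(asymmetric_params, asymmetric_ss)
    assert len(zs) == 1  # simple Hopf for this set
    for z in zs:
        assert abs(np.polyval([1.0, a, b, c, d], z)) < 1e-8
    # independent scan of |quartic(i w)|^2 - D_c^2
    A, B, C, D = dcnm_coefficients(asymmetric_params)
    dc = d_dcnm(asymmetric_params, asymmetric_ss)
    w = np.linspace(1e-3, 5, 20000)
    lhs = (w**4 - B * w**2 + D) ** 2 + (-A * w**3 + C * w) ** 2 - dc**2
    sign_changes = np.nonzero(np.diff(np.sign(lhs)))[0]
    assert len(sign_changes) == len(zs)
    w_cross = w[sign_changes[0]]
    assert np.sqrt(zs[0]) == pytest.approx(w_cross, abs=1e-3)


def test_published_asymmetric_set_critical_delay(
    asymmetric_params, asymmetric_ss
):
    rep = dcnm_critical_delays(asymmetric_params, asymmetric_ss)
    assert rep.classification == HOPF
    assert rep.stable_at_zero
    assert rep.d_dcnm == pytest.approx(DC_REF, abs=1e-12)
    assert rep.omega0 == pytest.approx(OMEGA0_REF, abs=1e-12)
    assert rep.tau0 == pytest.approx(TAU0_REF, abs=1e-12)
    assert rep.char_residual < 1e-12
    assert rep.gprime_sign == +1
    # closed form for unit rates: (z+1)^4 = D_c^2
    assert rep.crossing_roots[0] == pytest.approx(np.sqrt(DC_REF) - 1, rel=1e-12)


def test_tau_table_spacing_full_period(asymmetric_params, asymmetric_ss):
    rep = dcnm_critical_delays(asymmetric_params, asymmetric_ss, j_max=4)
    for zs, taus in zip(rep.crossing_roots, rep.tau_table):
        w = np.sqrt(zs)
        np.testing.assert_allclose(np.diff(taus), 2 * np.pi / w, rtol=1e-12)
        for tau in taus:
            assert abs(
                dcnm_char(1j * w, asymmetric_params, rep.d_dcnm, tau)
            ) < 1e-9


def test_strong_coupling_set_unstable_at_zero_delay(
    sharp_threshold_params, sharp_threshold_ss
):
    """With m = 2.35 and theta = 0.21 the complete model oscillates already
    without delay: Routh-Hurwitz fails and the crossing analysis is skipped.
    In particular the complete model is never 'stable for all delays' where
    the reduced model has a Hopf delay."""
    rep = dcnm_critical_delays(sharp_threshold_params, sharp_threshold_ss)
    assert rep.classification == UNSTABLE_AT_ZERO
    assert not rep.stable_at_zero
    assert rep.tau0 is None
    # eigenvalue oracle confirms
    A, B, C, D = rep.coeffs
    roots = np.roots([1.0, A, B, C, D + rep.d_dcnm])
    assert max(roots.real) > 0
    dsnm_rep = dsnm_critical_delays(sharp_threshold_params, sharp_threshold_ss)
    assert dsnm_rep.classification == HOPF
    assert rep.classification != STABLE_ALL_TAU


def test_rightmost_root_changes_sign_across_tau0(
    asymmetric_params, asymmetric_ss
):
    rep = dcnm_critical_delays(asymmetric_params, asymmetric_ss)
    below = oracle_rightmost_root(
        "dcnm", asymmetric_params, asymmetric_ss, rep.tau0 - 0.05
    )
    above = oracle_rightmost_root(
        "dcnm", asymmetric_params, asymmetric_ss, rep.tau0 + 0.05
    )
    assert below.real < 0 < above.real


def test_critical_delay_decreases_with_transcription_rate(asymmetric_params):
    """Along the published low-threshold slice, faster transcription of the
    inhibitor destabilises: tau_0 falls monotonically as m_a grows."""
    taus = []
    for m_a in (0.4, 0.6, 0.8, 1.0):
        params = asymmetric_params.replace(m_a=m_a)
        (ss,) = [s for s in solve_steady_states(params) if s.p_a_bar > 0]
        rep = dcnm_critical_delays(params, ss)
        assert rep.classification == HOPF
        taus.append(rep.tau0)
    assert all(t1 > t2 for t1, t2 in zip(taus, taus[1:]))


def test_quasi_steady_state_limit_recovers_reduced_delay(symmetric_params):
    """Speeding mRNA turnover 100x (with translation rescaled so the
    effective production k' is unchanged) moves the complete model's
    critical delay to within 5% of the reduced model's."""
    (ss,) = [s for s in solve_steady_states(symmetric_params) if s.p_a_bar > 0]
    tau_dsnm = dsnm_critical_delays(symmetric_params, ss).tau0
    fast = symmetric_params.replace(
        gamma_a=100.0, gamma_b=100.0, k_a=100.0, k_b=100.0
    )
    (ss_fast,) = [s for s in solve_steady_states(fast) if s.p_a_bar > 0]
    # equilibrium proteins unchanged by the rescaling
    assert ss_fast.p_a_bar == pytest.approx(ss.p_a_bar, rel=1e-10)
    rep = dcnm_critical_delays(fast, ss_fast)
    assert rep.classification == HOPF
    assert rep.tau0 == pytest.approx(tau_dsnm, rel=0.05)
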