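"""Stability machinery at both model levels."""

import numpy as np
import pytest

from sgm.local_circuit import gamma_kernel_transform
from sgm.params import LocalCircuitParams, NetworkParams
from sgm.stability import (alpha0_stability, alpha_boundary,
                           classify_macroscopic_regime, critical_gei,
                           jw_boundary, macro_char_matrix, mesoscopic_char_poly,
                           mesoscopic_poles, poles_of, routh_hurwitz)
from sgm.synth import SynthSpec, synth_connectome


def random_local(rng):
    return LocalCircuitParams(
        tau_e=rng.uniform(0.005, 0.02), tau_i=rng.uniform(0.005, 0.02),
        g_ei=rng.uniform(0.001, 0.8), g_ii=rng.uniform(1.0, 2.5))


class TestCharPoly:
    def test_degree_ten_and_monic(self, rng):
        for _ in range(10):
            cp = mesoscopic_char_poly(random_local(rng))
            assert cp.degree == 10
            assert cp.coeffs[0] == 1.0

    def test_gei_zero_factorizes(self):
        """Without cross-coupling the roots are the union of the two brackets'."""
        p = LocalCircuitParams(tau_e=0.012, tau_i=0.003, g_ei=1e-300, g_ii=0.5)
        te, ti = p.t_e, p.t_i
        qe = np.polymul(np.polyadd(np.polymul([1, 0], np.polymul([1, te], [1, te])),
                                   [p.g_ee * te**3]), np.polymul([1, ti], [1, ti]))
        qi = np.polymul(np.polyadd(np.polymul([1, 0], np.polymul([1, ti], [1, ti])),
                                   [p.g_ii * ti**3]), np.polymul([1, te], [1, te]))
        expected = np.sort_complex(np.concatenate([np.roots(qe), np.roots(qi)]))
        got = np.sort_complex(mesoscopic_poles(p).roots)
        np.testing.assert_allclose(got, expected, rtol=1e-6, atol=1e-6)

    def test_coefficients_match_interpolation_oracle(self, rng):
        """Evaluate det(sI - A(s)) * (s+te)^4 (s+ti)^4 pointwise and fit."""
        p = random_local(rng)
        te, ti = p.t_e, p.t_i

        def det_cleared(s):
            Fe = gamma_kernel_transform(p.tau_e, s)
            Fi = gamma_kernel_transform(p.tau_i, s)
            det = ((s + p.g_ee * Fe / p.tau_e) * (s + p.g_ii * Fi / p.tau_i)
                   + p.g_ei**2 / (p.tau_e * p.tau_i) * (Fe * Fi) ** 2)
            return det * (s + te) ** 4 * (s + ti) ** 4

        # 11 sample points on a circle scaled to the root magnitudes
        z = (te + ti) * np.exp(2j * np.pi * np.arange(11) / 11)
        V = np.vander(z, 11)
        coeffs = np.linalg.solve(V, det_cleared(z))
        np.testing.assert_allclose(coeffs.real, mesoscopic_char_poly(p).coeffs,
                                   rtol=1e-8, atol=1e-8 * max(te, ti) ** 10)
        assert np.max(np.abs(coeffs.imag)) < 1e-8 * np.max(np.abs(coeffs))


class TestMesoscopicPoles:
    @pytest.mark.parametrize("gei,expected", [
        (0.4, "stable"), (1.0, "unstable")])
    def test_reference_gain_classification(self, gei, expected):
        p = LocalCircuitParams(tau_e=0.012, tau_i=0.003, g_ei=gei, g_ii=0.5)
        assert mesoscopic_poles(p).classification == expected

    def test_borderline_gain_is_nearly_marginal(self):
        p = LocalCircuitParams(tau_e=0.012, tau_i=0.003, g_ei=0.52, g_ii=0.5)
        assert abs(mesoscopic_poles(p).max_real) < 0.1  # rad/s, vs ~4 when stable

    def test_one_conjugate_pair_crosses_at_transition(self):
        below = mesoscopic_poles(LocalCircuitParams(tau_e=0.012, tau_i=0.003,
                                                    g_ei=0.5, g_ii=0.5))
        above = mesoscopic_poles(LocalCircuitParams(tau_e=0.012, tau_i=0.003,
                                                    g_ei=0.55, g_ii=0.5))
        assert int(np.sum(below.roots.real > 0)) == 0
        assert int(np.sum(above.roots.real > 0)) == 2
        crossing = above.roots[above.roots.real > 0]
        assert np.all(np.abs(crossing.imag) > 0)  # oscillatory instability


class TestRouthHurwitz:
    def test_known_stable_cubic(self):
        _, changes = routh_hurwitz([1, 6, 11, 6])  # roots -1, -2, -3
        assert changes == 0

    def test_alpha0_cubic_condition(self):
        tau_e = 0.012
        for tau_G, stable in ((0.012, True), (0.005, False)):
            cubic = [1, 2 / tau_e, 1 / tau_e**2, 1 / (tau_e**2 * tau_G)]
            _, changes = routh_hurwitz(cubic)
            assert (changes == 0) == stable

    def test_sign_changes_count_rhp_roots_on_random_polynomials(self, rng):
        """Companion-matrix root count is the independent oracle."""
        checked = 0
        while checked < 200:
            deg = rng.integers(3, 11)
            roots = rng.uniform(-5, 5, deg) + 1j * rng.uniform(-5, 5, deg) * (rng.random(deg) < 0.5)
            # make conjugate-closed real polynomial: use real coefficient draw instead
            coeffs = rng.standard_normal(deg + 1)
            if coeffs[0] == 0:
                continue
            r = np.roots(coeffs)
            if np.min(np.abs(r.real)) < 1e-6:  # skip near-marginal draws
                continue
            _, changes = routh_hurwitz(coeffs)
            assert changes == int(np.sum(r.real > 0))
            checked += 1

    def test_zero_pivot_epsilon_fallback(self):
        # s^4 + s^3 + 2 s^2 + 2 s + 3 has a zero first-column pivot
        with pytest.warns(UserWarning, match="zero pivot"):
            _, changes = routh_hurwitz([1, 1, 2, 2, 3])
        r = np.roots([1, 1, 2, 2, 3])
        assert changes == int(np.sum(r.real > 0))

    def test_zero_row_auxiliary_fallback(self):
        # (s^2+1)(s+1) = s^3 + s^2 + s + 1 produces an all-zero row
        with pytest.warns(UserWarning, match="zero row"):
            _, changes = routh_hurwitz([1, 1, 1, 1])
        assert changes == 0  # no open-RHP roots (pair on the axis)


class TestCriticalGei:
    def test_matches_grid_scan_oracle(self):
        g = critical_gei(g_ii=0.5, tau_e=0.012, tau_i=0.003, bracket=(0.4, 1.0))
        # independent 1e-4-step scan
        grid = np.arange(0.4, 1.0, 1e-4)
        signs = [mesoscopic_poles(LocalCircuitParams(
            tau_e=0.012, tau_i=0.003, g_ei=x, g_ii=0.5)).max_real > 0 for x in grid]
        scan = grid[int(np.argmax(signs))]
        assert abs(g - scan) <= 2e-4

    def test_bisection_contract(self):
        g = critical_gei(g_ii=0.5, tau_e=0.012, tau_i=0.003, bracket=(0.4, 1.0))
        lo = mesoscopic_poles(LocalCircuitParams(tau_e=0.012, tau_i=0.003,
                                                 g_ei=g - 1e-3, g_ii=0.5)).max_real
        hi = mesoscopic_poles(LocalCircuitParams(tau_e=0.012, tau_i=0.003,
                                                 g_ei=g + 1e-3, g_ii=0.5)).max_real
        assert lo < 0 < hi

    def test_rejects_bad_bracket(self):
        with pytest.raises(ValueError):
            critical_gei(bracket=(0.1, 0.2))


class TestAlpha0Boundary:
    def test_analytic_condition(self):
        assert alpha0_stability(0.012, 0.012)[0]       # 2 tau_G > tau_e
        assert not alpha0_stability(0.012, 0.005)[0]

    def test_cubic_marginal_at_half_tau_e(self):
        """At tau_G = tau_e/2 the cubic has a purely imaginary root pair."""
        tau_e = 0.012
        _, cubic = alpha0_stability(tau_e, tau_e / 2)
        roots = np.roots(cubic.coeffs)
        marginal = roots[np.argsort(roots.real)][-2:]
        assert np.max(np.abs(marginal.real)) < 1e-6 / tau_e
        assert np.allclose(np.abs(marginal.imag), 1 / tau_e, rtol=1e-9)


class TestAlphaBoundary:
    def test_two_node_ring(self):
        conn = synth_connectome(SynthSpec(N=2, density=1.0, seed=0))
        assert alpha_boundary(conn) == pytest.approx(1.0, abs=1e-12)

    def test_random_connectome_boundary_is_one(self, small_conn):
        assert alpha_boundary(small_conn) == pytest.approx(1.0, abs=1e-10)


class TestJwBoundary:
    def test_alpha_to_zero_limit_recovers_half_tau_e(self, small_conn):
        b = jw_boundary(LocalCircuitParams(tau_e=0.012, tau_i=0.003),
                        1e-9, small_conn, v=5.0)
        assert b.tau_G == pytest.approx(0.006, rel=1e-3)
        assert b.omega == pytest.approx(1 / 0.012, rel=1e-3)

    def test_plugin_residual_of_determinant(self, small_conn):
        local = LocalCircuitParams(tau_e=0.012, tau_i=0.003)
        b = jw_boundary(local, 0.5, small_conn, v=5.0)
        net = NetworkParams(tau_G=b.tau_G, alpha=0.5, v=5.0)
        M = macro_char_matrix(1j * b.omega, local, net, small_conn)
        detM = np.linalg.det(M)
        # det factorizes over modes; one factor vanishes, so |det| is tiny
        # relative to the product of typical factor magnitudes
        typical = np.prod(np.abs(np.linalg.eigvals(M))[np.abs(np.linalg.eigvals(M)) > 1e-6])
        assert abs(detM) <= 1e-8 * max(typical, 1.0)

    def test_boundary_separates_growth_from_decay(self, small_conn):
        from sgm.stability import network_max_real
        local = LocalCircuitParams(tau_e=0.012, tau_i=0.003)
        b = jw_boundary(local, 0.5, small_conn, v=5.0)
        above = network_max_real(local, NetworkParams(tau_G=1.1 * b.tau_G, alpha=0.5, v=5.0),
                                 small_conn)
        below = network_max_real(local, NetworkParams(tau_G=0.9 * b.tau_G, alpha=0.5, v=5.0),
                                 small_conn)
        assert above < 0 < below


class TestDetFactorization:
    def test_det_M_equals_product_over_modes(self, rng):
        """det M(s) = prod_k (s + F_e lambda_k / tau_G), lambda_k eig of L(s)."""
        conn = synth_connectome(SynthSpec(N=8, density=0.7, seed=11))
        local = LocalCircuitParams(tau_e=0.012, tau_i=0.003)
        net = NetworkParams(tau_G=0.012, alpha=0.8, v=5.0)
        for _ in range(5):
            s = complex(rng.uniform(-30, 30), rng.uniform(10, 300))
            M = macro_char_matrix(s, local, net, conn)
            Fe = gamma_kernel_transform(local.tau_e, s)
            C_star = conn.C * np.exp(-s * conn.delays(net.v))
            lam = np.linalg.eigvals(np.eye(conn.N) - net.alpha * C_star)
            prod = np.prod(s + Fe * lam / net.tau_G)
            assert abs(np.linalg.det(M) - prod) <= 1e-8 * abs(prod)


class TestRegimeClassification:
    @pytest.mark.parametrize("tau_G,alpha,code", [
        (0.02, 0.8, 1), (0.006, 0.8, 2), (0.03, 1.3, 3), (0.004, 1.3, 4)])
    def test_four_regimes(self, conn20, tau_G, alpha, code):
        local = LocalCircuitParams(tau_e=0.012, tau_i=0.003)
        net = NetworkParams(tau_G=tau_G, alpha=alpha, v=5.0)
        assert classify_macroscopic_regime(local, net, conn20).code == code

    def test_roots_and_routh_agree_on_classification(self, rng):
        """Both mesoscopic stability routes give the same verdict."""
        for _ in range(100):
            p = random_local(rng)
            ps = mesoscopic_poles(p)
            if abs(ps.max_real) < 1e-3:
                continue  # marginal draws are ambiguous under either method
            _, changes = routh_hurwitz(mesoscopic_char_poly(p).coeffs)
            assert (changes > 0) == (ps.classification == "unstable")
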