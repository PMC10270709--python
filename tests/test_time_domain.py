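"""Numerical inverse Laplace, simulations, and trajectory-shape analysis."""

import numpy as np
import pytest

from sgm.params import LocalCircuitParams, NetworkParams
from sgm.stability import mesoscopic_poles
from sgm.time_domain import (TimeSeries, classify_trajectory, default_time_grid,
                             inverse_laplace, simulate_impulse, simulate_noise)

T_GRID = default_time_grid()

# (transform, closed-form inverse, max abs tolerance on (0, 0.3])
ANALYTIC_PAIRS = [
    (lambda s: 1 / (s + 10), lambda t: np.exp(-10 * t), 1e-6),
    (lambda s: 1 / (s + 100), lambda t: np.exp(-100 * t), 1e-6),
    (lambda s: (2 * np.pi * 10) / (s**2 + (2 * np.pi * 10) ** 2),
     lambda t: np.sin(2 * np.pi * 10 * t), 1e-5),
    (lambda s: s / (s**2 + (2 * np.pi * 10) ** 2),
     lambda t: np.cos(2 * np.pi * 10 * t), 1e-5),
    (lambda s: 1 / s, lambda t: np.ones_like(t), 1e-6),
    (lambda s: 1 / s**2, lambda t: t, 1e-7),
    (lambda s: 2 / s**3, lambda t: t**2, 1e-7),
    (lambda s: 1 / (s + 5) ** 2, lambda t: t * np.exp(-5 * t), 1e-7),
    (lambda s: (s + 3) / ((s + 3) ** 2 + 50**2),
     lambda t: np.exp(-3 * t) * np.cos(50 * t), 1e-5),
    (lambda s: 50 / ((s + 3) ** 2 + 50**2),
     lambda t: np.exp(-3 * t) * np.sin(50 * t), 1e-5),
]


class TestInverseLaplace:
    @pytest.mark.parametrize("fn,closed,tol", ANALYTIC_PAIRS)
    def test_analytic_pairs(self, fn, closed, tol):
        vals, reliable = inverse_laplace(fn, T_GRID)
        assert reliable == T_GRID[-1]
        assert np.max(np.abs(vals[0] - closed(T_GRID))) < tol

    def test_vector_valued_transform(self):
        vals, _ = inverse_laplace(lambda s: np.array([1 / (s + 1), 1 / (s + 2)]), T_GRID)
        assert vals.shape == (2, T_GRID.size)
        np.testing.assert_allclose(vals[0], np.exp(-T_GRID), atol=1e-6)
        np.testing.assert_allclose(vals[1], np.exp(-2 * T_GRID), atol=1e-6)

    def test_rejects_bad_grid(self):
        with pytest.raises(ValueError):
            inverse_laplace(lambda s: 1 / s, np.array([0.0, 0.1]))

    def test_growing_transform_with_shifted_contour(self):
        vals, _ = inverse_laplace(lambda s: 1 / (s - 8), T_GRID, sigma=9.0)
        assert np.max(np.abs(vals[0] - np.exp(8 * T_GRID))) < 1e-5


class TestImpulseSimulation:
    def test_stable_envelope_slope_matches_dominant_pole(self, fig1_stable):
        """Log-envelope decay of the impulse response equals the dominant
        pole's real part (the pole-decay oracle)."""
        ts = simulate_impulse("meso", fig1_stable)
        y = ts.y[0]
        d = np.diff(y)
        ext = np.flatnonzero(np.sign(d[1:]) * np.sign(d[:-1]) < 0) + 1
        slope = np.polyfit(ts.t[ext], np.log(np.abs(y[ext])), 1)[0]
        assert slope == pytest.approx(mesoscopic_poles(fig1_stable).max_real, rel=0.05)

    @pytest.mark.parametrize("gei,expected", [
        (0.4, "damped"), (0.52, "limit_cycle"), (1.0, "growing_amplitude")])
    def test_reference_gain_trajectories(self, gei, expected):
        p = LocalCircuitParams(tau_e=0.012, tau_i=0.003, g_ei=gei, g_ii=0.5)
        assert classify_trajectory(simulate_impulse("meso", p)) == expected

    def test_macro_levels_return_regional_channels(self, small_conn, fig1_stable):
        net = NetworkParams(tau_G=0.015, alpha=0.5, v=10.0)
        for level in ("macro_only", "macro_meso"):
            ts = simulate_impulse(level, fig1_stable, net, small_conn)
            assert ts.y.shape == (small_conn.N, T_GRID.size)
            assert np.all(np.isfinite(ts.y))

    def test_macro_requires_connectome(self, fig1_stable):
        with pytest.raises(ValueError):
            simulate_impulse("macro_only", fig1_stable)


class TestNoiseSimulation:
    def test_seed_reproducibility(self, fig1_stable):
        a = simulate_noise("meso", fig1_stable, duration=2.0, seed=9)
        b = simulate_noise("meso", fig1_stable, duration=2.0, seed=9)
        np.testing.assert_array_equal(a.y, b.y)
        c = simulate_noise("meso", fig1_stable, duration=2.0, seed=10)
        assert not np.array_equal(a.y, c.y)

    def test_output_spectrum_matches_transfer_magnitude(self, fig1_stable):
        """Welch spectrum of the noise-driven output follows |H|^2."""
        import scipy.signal

        from sgm.local_circuit import local_transfer
        ts = simulate_noise("meso", fig1_stable, duration=60.0, fs=600.0, seed=5)
        f, pxx = scipy.signal.welch(ts.y[0], fs=600.0, nperseg=4096)
        sel = (f >= 2) & (f <= 45)
        H2 = np.abs(local_transfer(fig1_stable, 2j * np.pi * f[sel]).H_e) ** 2
        assert np.corrcoef(pxx[sel], H2)[0, 1] > 0.95

    def test_stable_and_borderline_noise_runs_both_oscillate_bounded(self):
        """Driven by noise, damped and limit-cycle circuits both just look
        oscillatory; neither runs away."""
        for gei in (0.4, 0.52):
            p = LocalCircuitParams(tau_e=0.012, tau_i=0.003, g_ei=gei, g_ii=0.5)
            ts = simulate_noise("meso", p, duration=5.0, seed=1)
            y = ts.y[0]
            assert np.max(np.abs(y)) < 1e3
            zero_crossings = np.sum(np.sign(y[1:]) != np.sign(y[:-1]))
            assert zero_crossings > 50

    def test_refuses_unstable_parameters(self):
        p = LocalCircuitParams(tau_e=0.012, tau_i=0.003, g_ei=1.0, g_ii=0.5)
        with pytest.raises(ValueError, match="unstable"):
            simulate_noise("meso", p, duration=1.0)
        out = simulate_noise("meso", p, duration=1.0, force=True)
        assert out.y.shape[1] == 600


class TestTrajectoryClassification:
    def _ts(self, y):
        return TimeSeries(t=T_GRID, y=y[None, :], channel_names=("x",),
                          input_kind="impulse", reliable_until=T_GRID[-1])

    @pytest.mark.parametrize("make,expected", [
        (lambda t: np.exp(-t / 0.05) * np.sin(2 * np.pi * 20 * t), "damped"),
        (lambda t: np.exp(+t / 0.05) * np.sin(2 * np.pi * 20 * t), "growing_amplitude"),
        (lambda t: np.sin(2 * np.pi * 20 * t), "limit_cycle"),
        (lambda t: 5 * t + 0.3 * np.exp(-t / 0.2) * np.sin(2 * np.pi * 20 * t), "growing_mean"),
        (lambda t: 5 * t + 0.3 * np.exp(t / 0.1) * np.sin(2 * np.pi * 20 * t), "growing_both"),
    ])
    def test_analytic_shapes(self, make, expected):
        assert classify_trajectory(self._ts(make(T_GRID))) == expected

    def test_flat_oscillation_free_signal_is_indeterminate(self):
        assert classify_trajectory(self._ts(0.5 * np.ones_like(T_GRID))) == "indeterminate"

    def test_pure_ramp_is_growing_mean(self):
        assert classify_trajectory(self._ts(0.5 + 5.0 * T_GRID)) == "growing_mean"

    def test_agrees_with_pole_classification_on_resolvable_draws(self, rng):
        """Pole stability and window-limited trajectory shape agree whenever
        the dominant mode is oscillatory, fast enough to resolve in 0.3 s,
        and actually expressed in the impulse response (checked via
        contour-integral residues)."""
        from sgm.local_circuit import local_transfer

        def residues(p, roots):
            th = np.exp(2j * np.pi * np.arange(32) / 32)
            out = []
            for r in roots:
                s = r + 1e-3 * max(1, abs(r)) * th
                out.append(abs(np.mean((s - r) * local_transfer(p, s).H_e)))
            return np.array(out)

        agree = tot = 0
        while tot < 50:
            p = LocalCircuitParams(
                tau_e=rng.uniform(0.005, 0.02), tau_i=rng.uniform(0.005, 0.02),
                g_ei=rng.uniform(0.001, 0.8), g_ii=rng.uniform(1.0, 2.5))
            ps = mesoscopic_poles(p)
            i_dom = int(np.argmax(ps.roots.real))
            if abs(ps.max_real) < 4 or abs(ps.roots[i_dom].imag) < 2 * np.pi * 8:
                continue
            contrib = residues(p, ps.roots) * np.exp(ps.roots.real * 0.18)
            if contrib[i_dom] < 2.0 * (contrib.sum() - 2 * contrib[i_dom]):
                continue
            lab = classify_trajectory(simulate_impulse("meso", p))
            if lab == "indeterminate":
                continue
            tot += 1
            agree += ((ps.classification == "stable" and lab in ("damped", "limit_cycle"))
                      or (ps.classification == "unstable" and lab.startswith("growing")))
        assert agree / tot >= 0.9

    def test_macro_regimes_match_trajectory_shapes(self, conn20):
        """The four-regime map and the simulated impulse responses tell the
        same story on cells with clear margins."""
        from collections import Counter

        from sgm.stability import classify_macroscopic_regime
        local = LocalCircuitParams(tau_e=0.012, tau_i=0.003)
        expected = {(0.02, 0.8): (1, {"damped"}),
                    (0.006, 0.8): (2, {"growing_amplitude", "growing_both"}),
                    (0.03, 1.3): (3, {"growing_mean"}),
                    (0.004, 1.3): (4, {"growing_amplitude", "growing_both", "growing_mean"})}
        for (tau_G, alpha), (code, labels) in expected.items():
            net = NetworkParams(tau_G=tau_G, alpha=alpha, v=5.0)
            assert classify_macroscopic_regime(local, net, conn20).code == code
            ts = simulate_impulse("macro_only", local, net, conn20)
            votes = Counter(classify_trajectory(ts, channel=c) for c in range(conn20.N))
            top = votes.most_common(1)[0][0]
            assert top in labels
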