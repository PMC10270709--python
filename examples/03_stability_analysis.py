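"""Two-level stability analysis.

Local level: the degree-10 characteristic polynomial gives the poles; a
bisection locates the critical cross-population gain.  Network level: the
coupling boundary alpha = 1 (exact, from the Perron eigenvalue) and the
j-omega boundary in tau_G (numerical root finding per eigenmode), which
together classify the four dynamical regimes.
"""

from sgm import (LocalCircuitParams, NetworkParams, SynthSpec, alpha_boundary,
                 classify_macroscopic_regime, critical_gei, jw_boundary,
                 mesoscopic_poles, synth_connectome)

g_star = critical_gei(g_ii=0.5, tau_e=0.012, tau_i=0.003, bracket=(0.1, 1.0))
print(f"critical g_ei = {g_star:.4f} (damped below, growing above)")
for g in (0.4, 1.0):
    ps = mesoscopic_poles(LocalCircuitParams(tau_e=0.012, tau_i=0.003,
                                             g_ei=g, g_ii=0.5))
    print(f"  g_ei={g}: dominant pole real part {ps.max_real:+.1f} rad/s "
          f"-> {ps.classification}")

conn = synth_connectome(SynthSpec(N=20, density=0.3, seed=1))
print(f"alpha boundary (det(I - alpha C) = 0): {alpha_boundary(conn):.6f}")
local = LocalCircuitParams(tau_e=0.012, tau_i=0.003)
b = jw_boundary(local, alpha=0.8, conn=conn, v=5.0)
print(f"j-omega boundary at alpha=0.8: tau_G* = {b.tau_G * 1e3:.2f} ms "
      f"(crossing at {b.omega / 6.2832:.1f} Hz)")
for tau_G, alpha in ((0.02, 0.8), (0.006, 0.8), (0.03, 1.3), (0.004, 1.3)):
    r = classify_macroscopic_regime(local, NetworkParams(tau_G=tau_G, alpha=alpha,
                                                         v=5.0), conn)
    print(f"  tau_G={tau_G * 1e3:.0f} ms, alpha={alpha}: regime {r.code} "
          f"({r.meso_part} oscillations, {r.mean_part} mean)")
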