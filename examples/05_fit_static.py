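"""Static parameter estimation: invert a spectrum back to its parameters.

A synthetic connectome and a noise-free observed spectrum generated at
known parameters; dual annealing then recovers all seven free parameters
by maximizing the mean cortical Pearson correlation.
"""

import warnings

import numpy as np

from sgm import SynthSpec, fit_static, synth_connectome, synth_static_psd

spec = SynthSpec(N=12, seed=3)  # truth: tau_e=12 ms, g_ei=0.3, alpha=0.8, ...
conn = synth_connectome(spec)
freqs = np.arange(2.0, 45.5, 0.5)
obs, truth = synth_static_psd(spec, conn, freqs=freqs, check_stability=False)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    fit = fit_static(obs, conn, seed=11, freqs=freqs, maxiter=120)

print(f"mean cortical Pearson r = {fit.r_mean:.4f} "
      f"({fit.optimizer_meta['nfev']} objective evaluations)")
print(f"{'parameter':>8} {'truth':>8} {'fitted':>8}")
for name in ("tau_e", "tau_i", "g_ei", "g_ii"):
    print(f"{name:>8} {getattr(truth['local'], name):8.4f} "
          f"{getattr(fit.local, name):8.4f}")
for name in ("tau_G", "alpha", "v"):
    print(f"{name:>8} {getattr(truth['net'], name):8.4f} "
          f"{getattr(fit.net, name):8.4f}")
print("On noise-free input every free parameter returns close to its "
      "generating value; r = 1 means the spectra overlay exactly.")
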