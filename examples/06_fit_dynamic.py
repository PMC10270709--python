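"""Dynamic (windowed) estimation: tracking coupling changes over time.

Windowed spectra are generated with a planted jump in (alpha, g_ei, g_ii)
halfway through the record; per-window fits recover the trajectory, the
switch counter flags the jump, and a Fisher-z paired t-test shows the
dynamic fits beat a single static parameter set.
"""

import warnings

import numpy as np

from sgm import (SynthSpec, compare_static_dynamic, count_switches, fit_dynamic,
                 fit_static, synth_connectome, synth_dynamic_windows)
from sgm.fitting import static_r_per_window

truths = [(0.3, 0.25, 1.4)] * 6 + [(0.9, 0.45, 1.9)] * 6  # jump at window 6
spec = SynthSpec(N=12, seed=3, window_truths=tuple(truths))
conn = synth_connectome(spec)
freqs = np.arange(2.0, 45.5, 1.0)
wins, _ = synth_dynamic_windows(spec, conn, freqs=freqs)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    static = fit_static(wins.mean(axis=0), conn, seed=5, freqs=freqs, maxiter=60)
    dyn = fit_dynamic(wins, static, conn, seed=7, freqs=freqs, maxiter=60)
    r_static = static_r_per_window(static, wins, conn, freqs)

print("window:  " + "  ".join(f"{i:5d}" for i in range(12)))
print("alpha:   " + "  ".join(f"{a:5.2f}" for a in dyn.alpha))
print(f"alpha switches (jump > 0.5): {count_switches(dyn.alpha)} (planted: 1)")
t, p = compare_static_dynamic(r_static, dyn.r_mean)
print(f"dynamic vs static goodness of fit: t = {t:.1f}, one-sided p = {p:.2e}")
print("The recovered alpha trajectory reproduces the planted step, and the "
      "paired test confirms window-wise parameters explain the drifting "
      "spectra better than any single static set.")
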