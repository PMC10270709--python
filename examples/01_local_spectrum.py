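"""Local circuit spectrum: where the alpha and beta peaks come from.

A single region's excitatory/inhibitory loop already produces a structured
power spectrum.  With the canonical gains the transfer-function magnitude
shows a primary alpha-band peak and a secondary beta-band peak.
"""

from sgm import DEFAULT_FREQS, LocalCircuitParams, find_spectral_peaks, local_psd

params = LocalCircuitParams(tau_e=0.01, tau_i=0.005, g_ei=0.25, g_ii=1.5)
psd = local_psd(params, DEFAULT_FREQS)

print(f"local-circuit PSD over {DEFAULT_FREQS[0]:.0f}-{DEFAULT_FREQS[-1]:.0f} Hz, "
      f"range {psd.min():.1f} to {psd.max():.1f} dB")
for peak in find_spectral_peaks(psd, DEFAULT_FREQS):
    print(f"  rank {peak.rank}: {peak.frequency:.1f} Hz ({peak.band}), "
          f"{peak.height_db:.1f} dB")
print("The rank-1 peak sits in the alpha band (8-12 Hz); the secondary peak "
      "in beta comes from the faster inhibitory loop.")
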