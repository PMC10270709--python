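# Methods

## Model

The package implements a two-level linear model of regional brain
activity. At the *local* (mesoscopic) level a single region's excitatory
and inhibitory populations interact through Gamma-shaped ensemble
kernels, `F(s) = (1/τ²)/(s + 1/τ)²` (unit DC gain), with gains g_ee = 1,
g_ei, g_ii and time constants τ_e, τ_i. In the Laplace domain this is the
2×2 system `(sI − A(s)) [X_e, X_i]ᵀ = [P, P]ᵀ` with

    A(s) = [ −g_ee F_e/τ_e     +g_ei F_e F_i/τ_e ]
           [ −g_ei F_e F_i/τ_i  −g_ii F_i/τ_i    ]

whose Cramer solution is exactly the closed forms used throughout
(`F1 = g_ei F_e F_i`, `F2 = s + g_ii F_i/τ_i`, `F3 = s + g_ee F_e/τ_e`).
The cross-coupling enters through the *product* of both kernels scaled by
the time constants; this convention is the one consistent with the
characteristic polynomial below and with the observed critical coupling
(g_ei* ≈ 0.52 at g_ii = 0.5, τ_e = 12 ms, τ_i = 3 ms), and the linear
solve and the printed closed forms are verified against each other to
1e-10 in the tests.

At the *macroscopic* level, long-range excitatory signals on a
row-degree-normalized connectome C with distances D obey a delayed
integro-differential equation; in the frequency domain the delays become
phase factors and the response is the closed form over the complex
Laplacian 𝓛(ω) = I − αC*(ω). `network_transfer` evaluates it two ways —
an eigenmode sum with *oblique* projectors (U and U⁻¹, since 𝓛 is
non-normal and U^H ≠ U⁻¹ in general) and a direct batched linear solve —
and the two agree to ≤1e-8 relative error by test; the solve is the
default inside fitting loops because it is an order of magnitude cheaper.

## Stability

Local: clearing kernel denominators turns det(sI − A(s)) into the monic
degree-10 polynomial

    {[s(s+t_e)² + g_ee t_e³](s+t_i)²} · {[s(s+t_i)² + g_ii t_i³](s+t_e)²}
        + g_ei² t_e⁵ t_i⁵,        t_e = 1/τ_e, t_i = 1/τ_i,

built by exact coefficient convolution and checked against an
evaluation–interpolation oracle. Roots come from the companion matrix;
|max real part| ≤ 1e-6 rad/s is classified as a limit cycle (configurable;
the choice only matters within a vanishing parameter sliver). Roots
coinciding with the cleared factors (s = −t_e, −t_i, which reappear as
g_ei → 0) are flagged `spurious`; they are always in the left half plane.
The Routh–Hurwitz array is implemented with the standard epsilon
substitution for zero pivots and the auxiliary-polynomial derivative for
zero rows (both warn), and is validated against the companion-matrix root
count on hundreds of random polynomials.

Network: det M(s) with M(s) = (s + F_e/τ_G)I − (α/τ_G)F_e C*(s)
factorizes over the eigenvalues λ_k(s) of 𝓛(s) as
∏_k (s + F_e λ_k/τ_G) (verified numerically to 1e-8). Two boundaries
matter. (i) s = 0: det(I − αC) first vanishes at α = 1 for connected
row-stochastic C (Perron); crossing it makes the *mean* of the
oscillations grow. (ii) s = jω: per mode, `jω + τ_G⁻¹ λ_k(jω) F_e(jω) = 0`
is solved for (τ_G, ω) with the hybrid Powell method (xtol 1e-12,
≤10 000 evaluations); eigenvalues are tracked across ω by nearest-value
continuation. Seeding is informed rather than blind: at each seed
frequency every mode predicts its own crossing τ_G from
jωτ_G = −λF_e, and only near-real positive predictions are pursued. The
largest converged positive τ_G over modes is the boundary; below it the
oscillation *amplitude* grows. The boundary was cross-validated on
synthetic connectomes against an argument-principle (winding-number)
count of right-half-plane roots and against `network_max_real`, a
complex-plane root finder for the dominant network pole. The four regime
codes combine the two boundaries: 1 stable, 2 amplitude-growing (α ≤ 1,
low τ_G), 3 mean-growing (α > 1), 4 both.

On the synthetic connectome family the jω boundary at α ≈ 0.8 sits near
τ_G ≈ 11–16 ms, higher than for dense template connectomes; denser graphs
concentrate the Laplacian spectrum and stabilize. Regime demonstrations
in tests/examples therefore pick cells relative to the *computed*
boundary, not absolute template values.

## Time domain

Trajectories are obtained by numerically inverting the closed-form
transforms with a vectorized de Hoog–Knight–Stokes routine
(quotient-difference table + continued-fraction evaluation with the
remainder acceleration). Numerical choices that matter:

- the time grid is inverted in decade chunks, each with its own Fourier
  period T = 2·max(t) — single-period evaluation loses accuracy for
  t ≪ T;
- series order default M = 48 so the node frequencies (2Mπ/T ≈ 500 rad/s
  on the default 0.3 s window) cover the model's spectral content; too
  small an order silently truncates gamma-band poles;
- the contour abscissa σ is placed just right of the dominant pole
  (exactly known locally; via `network_max_real` for network runs). Too
  large a σ amplifies roundoff by e^(σt), too small a one misses growing
  modes.

Accuracy is validated against ten closed-form transform pairs (≤1e-5 /
1e-6 max error on (0, 0.3]) and against exact partial-fraction solutions.
The default horizon is 0.3 s at 1 ms: beyond a fraction of a second the
method degrades for near-marginal oscillatory transforms (the reference
high-precision implementation fails there too), which bounds what any
trajectory-based analysis here can claim.

Noise-driven runs are synthesized in the frequency domain
(Y = H·P with P complex white Gaussian, inverse FFT) rather than through
the inverse Laplace path: for a stable LTI system the two are
statistically equivalent, the synthesis is exact and fast, and it is
validated by Welch-spectrum agreement with |H|² (r > 0.95). Unstable
parameter sets have no stationary response and are refused unless forced.

`classify_trajectory` labels impulse responses damped / limit_cycle /
growing_amplitude / growing_mean / growing_both. Consecutive extrema
triples give local mean (y_k + 2y_{k+1} + y_{k+2})/4 and amplitude
|y_k − 2y_{k+1} + y_{k+2}|/4 (the triple cancels the first-order bias a
decaying envelope puts on max/min midpoints); the log-amplitude and mean
are regressed on the later extrema so transients do not bias the
dominant-mode trend, envelopes below 1e-6 of their peak are treated as
inversion noise, and ±2 % per period is the flatness band. Nearly
non-oscillatory signals fall back to a cubic-trend verdict. A 0.3 s
window cannot certify asymptotic stability in general: when two mode
pairs decay at similar rates (beating) or the dominant mode carries a
tiny residue, the window's verdict legitimately differs from the pole
verdict. The agreement property test therefore samples parameter draws
whose dominant mode is oscillatory (≥8 Hz), fast (|Re s| ≥ 4 s⁻¹) and
actually expressed (contour-integral residues dominate at mid-window),
and requires ≥90 % agreement there.

## Fitting

Goodness of fit is the per-region Pearson correlation between modeled and
observed dB spectra across 2–45 Hz, averaged over cortical regions
(zero-variance regions excluded with a warning). Static fits free
(τ_e, τ_i, τ_G, α, v, g_ei, g_ii) inside fixed box bounds
(τ's 5–20 ms, α 0.1–1, v 5–20 m/s, g_ei 0.001–0.8, g_ii 1–2.5) with dual
annealing, one run per initial guess (three guesses; out-of-bound guesses
are clipped with a warning rather than silently accepted) and the
best-r run kept. Dynamic fits freeze the time constants and speed at
their static estimates — biophysical constraints without second-scale
dynamics — and refit (α, g_ei, g_ii) per ~5 s window, each window fitted
independently from the same three guesses. `maxiter` defaults to 500; the
test suite and acceptance script run at 60–120 with a 12-region
connectome and 0.5–1 Hz grids, which this problem's smooth noise-free
objective converges well within (recovery ≤ a few percent).

The Morlet time–frequency utility uses per-frequency Gaussian width
w·fs/(2πf) samples (w is the width parameter; wavelet support capped at
the record length), window-averages the squared magnitude in
non-overlapping 5 s windows, and reports 10·log10 power. With very large
w the effective time resolution exceeds the window length; tests use
w ≈ 6 so that step changes remain localized. A Thomson multitaper PSD
(time-bandwidth 4, 7 tapers) is provided for raw static records.

Downstream summaries: `count_switches` counts consecutive-window jumps
strictly exceeding 0.5 (default); `stability_timeline` emits the
four-code pattern (local circuit stable/unstable × α interior / at its
upper bound, "at the bound" meaning within 1e-6 of the active bound, or
α ≥ 1 when the bound is relaxed above 1); `compare_static_dynamic`
applies Fisher's z = atanh(r) and a one-sided paired t-test that dynamic
fits correlate better.

## Synthetic data

`synth_connectome` draws region coordinates uniformly in a 150 mm box,
connects pairs with a distance-biased probability (geometric family;
Erdős–Rényi available), weights edges |N(0,1)|·e^(−d/3·scale), symmetrizes
and row-normalizes; disconnected draws are retried with an incremented
sub-seed. Defaults N = 86 with a 68-region cortical mask and density 0.6,
giving distance-correlated weights and pairwise distances spanning tens
to ~200 mm, like tractography-derived templates. Observed spectra are the
forward model itself at known truth parameters (defaults: τ_e = 12 ms,
τ_i = 10 ms, g_ei = 0.3, g_ii = 1.5, τ_G = 15 ms, α = 0.8, v = 10 m/s, a
stable interior point of the fit box), plus optional iid Gaussian noise
in dB on an independent substream, so noiseless content is seed-stable
across noise settings. What this does *not* emulate: tractography biases,
beamformer leakage and spatially correlated measurement noise, 1/f
background, or region-specific local parameters — parameter-recovery
results on synthetic data therefore demonstrate the estimator's
correctness, not its field performance on empirical MEG.

## Known limitations

- The jω boundary is found by local root finding from informed seeds; it
  is an approximation and can in principle miss a crossing on unusual
  connectomes (the winding-number check exists as an independent audit
  tool in the test suite's methodology).
- Inverse-Laplace horizons beyond ~0.3 s are unreliable near limit
  cycles; trajectory classification inherits the window limitations
  described above.
- Pearson-r fitting is insensitive to per-region dB offsets and overall
  scale by construction; absolute power is not modeled.
- Zero-degree (disconnected) connectome rows are kept as all-zero rows
  and flagged, not dropped.
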