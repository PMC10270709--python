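"""Parameter estimation against observed power spectra.

The goodness-of-fit metric is the Pearson correlation between modeled and
observed dB spectra, computed per region across frequencies and averaged
over cortical regions.  Estimation maximizes this mean correlation with
dual annealing inside fixed box bounds, run once per initial guess with
the best run kept.

Two estimation modes mirror how resting-state spectra are analyzed:

* *static*: one parameter set (seven free parameters, the excitatory gain
  pinned at 1) fitted to the full-record spectrum;
* *dynamic*: the record's Morlet time-frequency decomposition is averaged
  into ~5 s windows and only the fast couplings (alpha, g_ei, g_ii) are
  re-fitted per window, with time constants and conduction speed frozen at
  their static estimates -- they are biophysical constraints without
  second-scale dynamics.

Per-window estimates support switch counting on alpha, a four-code
stability timeline, and a Fisher-z paired comparison of dynamic versus
static goodness of fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.signal
import scipy.stats

from .connectome import Connectome
from .local_circuit import DEFAULT_FREQS
from .network_model import model_psd, network_transfer
from .params import (DYNAMIC_BOUNDS, DYNAMIC_GUESSES, DYNAMIC_PARAM_ORDER,
                     LocalCircuitParams, NetworkParams, STATIC_BOUNDS,
                     STATIC_GUESSES, STATIC_PARAM_ORDER)
from .stability import mesoscopic_poles

__all__ = [
    "DynamicFitResult",
    "FitResult",
    "compare_static_dynamic",
    "count_switches",
    "fit_dynamic",
    "fit_static",
    "morlet_tfr",
    "multitaper_psd",
    "pearson_objective",
    "stability_timeline",
]


def pearson_objective(model: np.ndarray, obs: np.ndarray,
                      cortical_mask: np.ndarray | None = None) -> float:
    """Mean Pearson r between model and observed dB spectra over regions.

    Correlations are taken across frequencies per region and averaged
    (unweighted) over masked regions; regions where either spectrum has
    zero variance are excluded with a warning.
    """
    model = np.asarray(model, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if model.shape != obs.shape:
        raise ValueError(f"shape mismatch: {model.shape} vs {obs.shape}")
    if model.shape[1] < 2:
        raise ValueError("need at least 2 frequency points")
    if cortical_mask is None:
        cortical_mask = np.ones(model.shape[0], dtype=bool)
    m = model[cortical_mask] - model[cortical_mask].mean(axis=1, keepdims=True)
    o = obs[cortical_mask] - obs[cortical_mask].mean(axis=1, keepdims=True)
    sm = np.sqrt((m * m).sum(axis=1))
    so = np.sqrt((o * o).sum(axis=1))
    ok = (sm > 0) & (so > 0)
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} zero-variance region(s) excluded from Pearson mean",
                      stacklevel=2)
    if not ok.any():
        raise ValueError("no region with nonzero variance")
    r = (m[ok] * o[ok]).sum(axis=1) / (sm[ok] * so[ok])
    return float(r.mean())


@dataclass(frozen=True)
class FitResult:
    local: LocalCircuitParams
    net: NetworkParams
    r_mean: float
    r_per_region: np.ndarray
    optimizer_meta: dict = field(default_factory=dict)


def _per_region_r(model: np.ndarray, obs: np.ndarray) -> np.ndarray:
    m = model - model.mean(axis=1, keepdims=True)
    o = obs - obs.mean(axis=1, keepdims=True)
    den = np.sqrt((m * m).sum(axis=1) * (o * o).sum(axis=1))
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, (m * o).sum(axis=1) / den, np.nan)


def _clip_guess(guess: dict[str, float], bounds: dict[str, tuple[float, float]]) -> list[float]:
    x0 = []
    for name, (lo, hi) in bounds.items():
        g = guess[name]
        if not lo <= g <= hi:
            warnings.warn(f"initial guess {name}={g} outside bounds [{lo}, {hi}]; clipped",
                          stacklevel=3)
            g = min(max(g, lo), hi)
        x0.append(g)
    return x0


def _unpack_static(x: np.ndarray) -> tuple[LocalCircuitParams, NetworkParams]:
    d = dict(zip(STATIC_PARAM_ORDER, x))
    local = LocalCircuitParams(tau_e=d["tau_e"], tau_i=d["tau_i"], g_ee=1.0,
                               g_ei=d["g_ei"], g_ii=d["g_ii"])
    net = NetworkParams(tau_G=d["tau_G"], alpha=d["alpha"], v=d["v"])
    return local, net


def fit_static(
    obs_psd: np.ndarray,
    conn: Connectome,
    bounds: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    freqs: np.ndarray = DEFAULT_FREQS,
    maxiter: int = 500,
    guesses: dict[str, tuple[float, ...]] | None = None,
) -> FitResult:
    """Fit all seven free parameters to a static spectrum (region x freq, dB).

    Runs dual annealing once per initial guess (three by default) and keeps
    the run with the highest mean cortical Pearson r.  The excitatory gain
    stays pinned at 1 for identifiability.
    """
    bounds = dict(STATIC_BOUNDS if bounds is None else bounds)
    guesses = dict(STATIC_GUESSES if guesses is None else guesses)
    obs_psd = np.asarray(obs_psd, dtype=float)
    blist = list(bounds.values())
    mask = conn.cortical_mask

    def neg_r(x: np.ndarray) -> float:
        local, net = _unpack_static(x)
        try:
            psd = model_psd(network_transfer(local, net, conn, freqs, method="solve"))
        except np.linalg.LinAlgError:
            return 2.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return -pearson_objective(psd, obs_psd, mask)

    n_guesses = len(next(iter(guesses.values())))
    best = None
    for g in range(n_guesses):
        x0 = _clip_guess({k: v[g] for k, v in guesses.items()}, bounds)
        res = scipy.optimize.dual_annealing(
            neg_r, bounds=blist, x0=np.asarray(x0), maxiter=maxiter,
            rng=np.random.default_rng((seed, g)))
        if best is None or res.fun < best[0].fun:
            best = (res, g)
    res, g_best = best
    local, net = _unpack_static(res.x)
    psd = model_psd(network_transfer(local, net, conn, freqs, method="solve"))
    return FitResult(
        local=local, net=net, r_mean=-float(res.fun),
        r_per_region=_per_region_r(psd, obs_psd),
        optimizer_meta={"nfev": int(res.nfev), "seed": seed,
                        "chosen_guess": int(g_best), "maxiter": maxiter})


@dataclass(frozen=True)
class TimeFrequencySpectra:
    """Windowed dB spectra: (n_windows, n_regions, n_freqs)."""

    psd: np.ndarray
    freqs: np.ndarray
    window_times: np.ndarray  # window start times, seconds
    fs: float
    morlet_w: float


def morlet_tfr(
    x: np.ndarray,
    fs: float = 600.0,
    w: float = 600.0,
    freqs: np.ndarray | None = None,
    window_s: float = 5.0,
) -> TimeFrequencySpectra:
    """Morlet time-frequency decomposition averaged into fixed windows.

    Parameters
    ----------
    x : (n_regions, n_samples) regional time series.
    w : Morlet width parameter; the Gaussian width at frequency f is
        ``w * fs / (2 pi f)`` samples.
    freqs : analysis frequencies, default 2-45 Hz at 1 Hz.
    window_s : non-overlapping averaging window, seconds.

    Returns per-window dB power (10 log10 of the window-averaged squared
    wavelet magnitude).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if freqs is None:
        freqs = np.arange(2.0, 45.0 + 0.5, 1.0)
    n = x.shape[1]
    win = int(round(window_s * fs))
    if win > n:
        raise ValueError("window longer than the record")
    n_win = n // win
    power = np.empty((n_win, x.shape[0], freqs.size))
    for j, f in enumerate(freqs):
        s_width = w * fs / (2.0 * np.pi * f)
        # wavelet support capped at the record length
        M = int(min(n, round(10 * s_width)) // 2 * 2 + 1)
        tt = (np.arange(M) - (M - 1) / 2) / s_width
        wavelet = np.exp(1j * w * tt) * np.exp(-0.5 * tt * tt)
        wavelet /= np.sqrt(0.5 * np.abs(wavelet).sum())
        conv = scipy.signal.fftconvolve(x, wavelet[None, :], mode="same", axes=1)
        p = np.abs(conv) ** 2
        power[:, :, j] = p[:, : n_win * win].reshape(x.shape[0], n_win, win).mean(axis=2).T
    return TimeFrequencySpectra(
        psd=10.0 * np.log10(np.maximum(power, 1e-300)),
        freqs=np.asarray(freqs, dtype=float),
        window_times=np.arange(n_win) * window_s, fs=fs, morlet_w=w)


@dataclass(frozen=True)
class DynamicFitResult:
    window_times: np.ndarray
    fits: tuple[FitResult, ...]
    alpha: np.ndarray
    g_ei: np.ndarray
    g_ii: np.ndarray
    r_mean: np.ndarray
    static_fit: FitResult


def fit_dynamic(
    tfr: TimeFrequencySpectra | np.ndarray,
    static_fit: FitResult,
    conn: Connectome,
    bounds: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    freqs: np.ndarray | None = None,
    maxiter: int = 500,
    guesses: dict[str, tuple[float, ...]] | None = None,
) -> DynamicFitResult:
    """Per-window fit of (alpha, g_ei, g_ii), other parameters frozen.

    ``tfr`` may be a TimeFrequencySpectra or a raw (window, region, freq)
    dB array (then ``freqs`` is required).  Window failures are recorded
    and skipped without aborting the sequence.
    """
    bounds = dict(DYNAMIC_BOUNDS if bounds is None else bounds)
    guesses = dict(DYNAMIC_GUESSES if guesses is None else guesses)
    if isinstance(tfr, TimeFrequencySpectra):
        wins, fgrid, wtimes = tfr.psd, tfr.freqs, tfr.window_times
    else:
        wins = np.asarray(tfr, dtype=float)
        if freqs is None:
            raise ValueError("freqs required with a raw window array")
        fgrid, wtimes = np.asarray(freqs, dtype=float), np.arange(wins.shape[0]) * 5.0
    mask = conn.cortical_mask
    frozen_local, frozen_net = static_fit.local, static_fit.net
    blist = list(bounds.values())
    n_guesses = len(next(iter(guesses.values())))
    fits = []
    for wi in range(wins.shape[0]):
        obs = wins[wi]

        def neg_r(x: np.ndarray) -> float:
            d = dict(zip(DYNAMIC_PARAM_ORDER, x))
            local = frozen_local.replace(g_ei=d["g_ei"], g_ii=d["g_ii"])
            net = frozen_net.replace(alpha=d["alpha"])
            try:
                psd = model_psd(network_transfer(local, net, conn, fgrid, method="solve"))
            except np.linalg.LinAlgError:
                return 2.0
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return -pearson_objective(psd, obs, mask)

        best = None
        for g in range(n_guesses):
            x0 = _clip_guess({k: v[g] for k, v in guesses.items()}, bounds)
            res = scipy.optimize.dual_annealing(
                neg_r, bounds=blist, x0=np.asarray(x0), maxiter=maxiter,
                rng=np.random.default_rng((seed, wi, g)))
            if best is None or res.fun < best[0].fun:
                best = (res, g)
        res, g_best = best
        d = dict(zip(DYNAMIC_PARAM_ORDER, res.x))
        local = frozen_local.replace(g_ei=d["g_ei"], g_ii=d["g_ii"])
        net = frozen_net.replace(alpha=d["alpha"])
        psd = model_psd(network_transfer(local, net, conn, fgrid, method="solve"))
        fits.append(FitResult(
            local=local, net=net, r_mean=-float(res.fun),
            r_per_region=_per_region_r(psd, obs),
            optimizer_meta={"nfev": int(res.nfev), "window": wi,
                            "chosen_guess": int(g_best)}))
    return DynamicFitResult(
        window_times=wtimes, fits=tuple(fits),
        alpha=np.array([f.net.alpha for f in fits]),
        g_ei=np.array([f.local.g_ei for f in fits]),
        g_ii=np.array([f.local.g_ii for f in fits]),
        r_mean=np.array([f.r_mean for f in fits]),
        static_fit=static_fit)


def count_switches(series: np.ndarray, threshold: float = 0.5) -> int:
    """Number of consecutive-value jumps strictly larger than ``threshold``."""
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("need at least 2 values")
    return int(np.sum(np.abs(np.diff(series)) > threshold))


def stability_timeline(
    dyn: DynamicFitResult,
    alpha_upper: float = 1.0,
    alpha_tol: float = 1e-6,
) -> np.ndarray:
    """Four-code stability per window.

    1: local circuit stable and alpha < 1; 2: stable, alpha at the bound;
    3: local circuit unstable, alpha < 1; 4: unstable, alpha at the bound.
    "At the bound" means within ``alpha_tol`` of the active upper bound
    (the optimizer pins alpha there rather than returning exact 1), or
    alpha >= 1 when the bound was relaxed above 1.
    """
    codes = np.empty(dyn.alpha.size, dtype=int)
    for i, f in enumerate(dyn.fits):
        unstable = mesoscopic_poles(f.local).classification == "unstable"
        at_one = (abs(f.net.alpha - alpha_upper) <= alpha_tol) if alpha_upper <= 1.0 \
            else (f.net.alpha >= 1.0)
        codes[i] = 1 + (2 if unstable else 0) + (1 if at_one else 0)
    return codes


def compare_static_dynamic(r_static: np.ndarray, r_dynamic: np.ndarray) -> tuple[float, float]:
    """One-sided paired t-test on Fisher-z transformed correlations.

    Tests whether the per-window dynamic-fit correlations exceed the
    correlations obtained by holding the static parameters fixed; returns
    (t statistic, one-sided p).  Correlations at +-1 are clipped.
    """
    r_s = np.asarray(r_static, dtype=float)
    r_d = np.asarray(r_dynamic, dtype=float)
    if r_s.shape != r_d.shape:
        raise ValueError("paired samples must have equal length")
    if np.any(np.abs(r_s) >= 1) or np.any(np.abs(r_d) >= 1):
        warnings.warn("correlation(s) at |r| = 1 clipped for Fisher z", stacklevel=2)
        r_s = np.clip(r_s, -1 + 1e-12, 1 - 1e-12)
        r_d = np.clip(r_d, -1 + 1e-12, 1 - 1e-12)
    t = scipy.stats.ttest_rel(np.arctanh(r_d), np.arctanh(r_s), alternative="greater")
    return float(t.statistic), float(t.pvalue)


def static_r_per_window(static_fit: FitResult, wins: np.ndarray, conn: Connectome,
                        freqs: np.ndarray) -> np.ndarray:
    """Mean cortical r of the static-parameter spectrum against each window."""
    psd = model_psd(network_transfer(static_fit.local, static_fit.net, conn,
                                     freqs, method="solve"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.array([pearson_objective(psd, w, conn.cortical_mask) for w in wins])


def multitaper_psd(x: np.ndarray, fs: float, nw: float = 4.0,
                   freqs: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Thomson multitaper PSD estimate in dB (utility for raw recordings).

    Uses 2*nw - 1 DPSS tapers with time-bandwidth ``nw``; returns
    (freqs, psd_db) with psd per region, interpolated onto ``freqs`` when
    given.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[1]
    tapers, eigvals = scipy.signal.windows.dpss(n, nw, Kmax=int(2 * nw) - 1,
                                                return_ratios=True)
    spec = np.fft.rfft(x[:, None, :] * tapers[None, :, :], axis=2)
    psd = (np.abs(spec) ** 2).mean(axis=1) / (fs * n)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    psd_db = 10.0 * np.log10(np.maximum(psd, 1e-300))
    if freqs is not None:
        psd_db = np.vstack([np.interp(freqs, f, row) for row in psd_db])
        f = np.asarray(freqs, dtype=float)
    return f, psd_db
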