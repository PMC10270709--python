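"""Transient behavior by numerical inverse Laplace transform.

The model is solved in closed form in the Laplace domain, so time courses
are obtained by numerically inverting transfer functions rather than by
integrating delay differential equations.  The inversion uses the de Hoog,
Knight and Stokes quotient-difference accelerated Fourier-series method,
vectorized over vector-valued transforms (one component per region).

Numerical inversion is only trustworthy over a short horizon - a fraction
of a second here - especially near limit cycles, where the persistent
oscillations make the series hard to accelerate.  The default window of
0-0.3 s is ample to see whether oscillations damp down, persist, or blow
up in mean or amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .connectome import Connectome
from .local_circuit import local_transfer
from .params import LocalCircuitParams, NetworkParams
from .stability import (classify_macroscopic_regime, macro_char_matrix,
                        mesoscopic_poles, network_max_real)

__all__ = [
    "TimeSeries",
    "classify_trajectory",
    "default_time_grid",
    "inverse_laplace",
    "simulate_impulse",
    "simulate_noise",
]

Level = Literal["meso", "macro_only", "macro_meso"]


def default_time_grid(t_max: float = 0.3, dt: float = 1e-3) -> np.ndarray:
    """Default simulation grid: (0, 0.3] s at 1 ms (t = 0 excluded)."""
    return np.arange(dt, t_max + dt / 2, dt)


@dataclass(frozen=True)
class TimeSeries:
    t: np.ndarray
    y: np.ndarray  # (n_channels, n_times); channels are populations or regions
    channel_names: tuple[str, ...]
    input_kind: str
    reliable_until: float


def _dehoog(F: Callable[[complex], np.ndarray], t: np.ndarray, degree: int,
            sigma: float, tol: float) -> np.ndarray:
    """de Hoog-Knight-Stokes inversion on a shared Fourier period.

    ``F`` maps a complex s to a scalar or 1-D array; the quotient-difference
    table and continued fraction are evaluated elementwise, so all
    components share the same s-evaluations.
    """
    t = np.asarray(t, dtype=float)
    T = 2.0 * t.max()
    M = degree
    gamma = sigma - np.log(tol) / (2.0 * T)
    s_nodes = gamma + 1j * np.pi * np.arange(2 * M + 1) / T
    a = np.stack([np.atleast_1d(np.asarray(F(s), dtype=complex)) for s in s_nodes])
    ncomp = a.shape[1]
    a[0] *= 0.5

    # quotient-difference scheme for the continued-fraction coefficients
    e = np.zeros((2 * M + 1, M + 1, ncomp), dtype=complex)
    q = np.zeros((2 * M + 1, M + 2, ncomp), dtype=complex)
    with np.errstate(divide="ignore", invalid="ignore"):
        q[: 2 * M, 1] = a[1:] / a[:-1]
        for r in range(1, M + 1):
            imax = 2 * (M - r) + 1
            e[:imax, r] = q[1 : imax + 1, r] - q[:imax, r] + e[1 : imax + 1, r - 1]
            if r < M:
                q[: imax - 1, r + 1] = (
                    q[1:imax, r] * e[1:imax, r] / e[: imax - 1, r])
    d = np.zeros((2 * M + 1, ncomp), dtype=complex)
    d[0] = a[0]
    d[1::2] = -q[0, 1 : M + 1]
    d[2::2] = -e[0, 1 : M + 1]
    d = np.nan_to_num(d)

    # continued fraction A/B at z = exp(i pi t / T), with the de Hoog
    # remainder acceleration for the last level
    z = np.exp(1j * np.pi * t / T)[:, None]  # (nt, 1)
    A_prev = np.zeros((t.size, ncomp), dtype=complex)
    A = np.broadcast_to(d[0], (t.size, ncomp)).copy()
    B_prev = np.ones((t.size, ncomp), dtype=complex)
    B = np.ones((t.size, ncomp), dtype=complex)
    for n in range(1, 2 * M):
        A, A_prev = A + d[n] * z * A_prev, A
        B, B_prev = B + d[n] * z * B_prev, B
    h2M = 0.5 * (1.0 + (d[2 * M - 1] - d[2 * M]) * z)
    with np.errstate(invalid="ignore"):
        R2M = -h2M * (1.0 - np.sqrt(1.0 + d[2 * M] * z / h2M**2))
    A, B = A + R2M * A_prev, B + R2M * B_prev
    vals = (np.exp(gamma * t)[:, None] / T) * (A / B).real
    return vals.T  # (ncomp, nt)


def inverse_laplace(
    fn: Callable[[complex], complex | np.ndarray],
    t_grid: np.ndarray,
    degree: int = 48,
    sigma: float = 0.0,
    tol: float = 1e-10,
) -> tuple[np.ndarray, float]:
    """Numerically invert a Laplace transform on a positive time grid.

    Parameters
    ----------
    fn : transform, analytic to the right of its poles; may return a 1-D
        array (inverted componentwise on shared evaluations).
    t_grid : strictly positive times in seconds.
    degree : series order M (2M+1 transform evaluations).
    sigma : abscissa shift; set at or above the largest pole real part for
        growing solutions.

    Returns
    -------
    (values, reliable_until) : values with shape (n_components, n_times);
    ``reliable_until`` is the last time before any non-finite value (the
    inversion horizon), equal to ``t_grid[-1]`` when all values are finite.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.size == 0 or np.any(t <= 0):
        raise ValueError("t_grid must be non-empty and strictly positive")
    # The series loses accuracy for t far below the Fourier period T = 2 max(t),
    # so the grid is inverted in decade chunks, each with its own period.
    order = np.argsort(t)
    chunks: list[np.ndarray] = []
    start = 0
    for i in range(1, order.size + 1):
        if i == order.size or t[order[i]] > 10.0 * t[order[start]]:
            chunks.append(order[start:i])
            start = i
    vals = np.empty(0)
    for idx in chunks:
        part = _dehoog(fn, t[idx], degree=degree, sigma=sigma, tol=tol)
        if vals.size == 0:
            vals = np.empty((part.shape[0], t.size))
        vals[:, idx] = part
    finite = np.all(np.isfinite(vals), axis=0)
    if finite.all():
        return vals, float(t[-1])
    first_bad = int(np.argmin(finite))
    reliable = float(t[first_bad - 1]) if first_bad > 0 else 0.0
    vals = np.where(np.isfinite(vals), vals, 0.0)
    return vals, reliable


def _macro_transfer_vec(local, net, conn, meso_input: bool):
    ones = np.ones(conn.N, dtype=complex)

    def F(s: complex) -> np.ndarray:
        M = macro_char_matrix(s, local, net, conn)
        x = np.linalg.solve(M, ones)
        if meso_input:
            tf = local_transfer(local, s)
            x = x * (tf.H_e + tf.H_i)[0]
        return x

    return F


def simulate_impulse(
    level: Level,
    local: LocalCircuitParams,
    net: NetworkParams | None = None,
    conn: Connectome | None = None,
    t_grid: np.ndarray | None = None,
    degree: int = 48,
    sigma: float | None = None,
) -> TimeSeries:
    """Impulse response at one of three cascade levels.

    ``meso``: the two local populations x_e, x_i with p(t) an impulse.
    ``macro_only``: regional responses with the local input replaced by an
    impulse.  ``macro_meso``: the full cascade, p(t) an impulse.
    The abscissa shift defaults to just right of the dominant pole so that
    growing solutions invert cleanly.
    """
    if t_grid is None:
        t_grid = default_time_grid()
    if level == "meso":
        if sigma is None:
            sigma = max(0.0, mesoscopic_poles(local).max_real) + 1.0

        def F(s):
            tf = local_transfer(local, s)
            return np.array([tf.H_e[0], tf.H_i[0]])

        y, reliable = inverse_laplace(F, t_grid, degree=degree, sigma=sigma)
        return TimeSeries(t=t_grid, y=y, channel_names=("x_e", "x_i"),
                          input_kind="impulse", reliable_until=reliable)
    if net is None or conn is None:
        raise ValueError("macro levels require net and conn")
    if sigma is None:
        # contour just right of the dominant pole: a larger shift amplifies
        # series roundoff by exp(sigma t), a smaller one misses growing modes
        sigma = max(0.0, network_max_real(local, net, conn)) + 1.0
        if level == "macro_meso":
            sigma = max(sigma, mesoscopic_poles(local).max_real + 1.0)
    F = _macro_transfer_vec(local, net, conn, meso_input=(level == "macro_meso"))
    y, reliable = inverse_laplace(F, t_grid, degree=degree, sigma=sigma)
    return TimeSeries(t=t_grid, y=y, channel_names=tuple(conn.labels),
                      input_kind="impulse", reliable_until=reliable)


def simulate_noise(
    level: Level,
    local: LocalCircuitParams,
    net: NetworkParams | None = None,
    conn: Connectome | None = None,
    duration: float = 10.0,
    fs: float = 600.0,
    seed: int | np.random.Generator = 0,
    force: bool = False,
) -> TimeSeries:
    """Stationary response to Gaussian white noise input.

    For a stable linear time-invariant system the noise-driven output is
    synthesized in the frequency domain: Y(omega) = H(omega) P(omega) with
    P complex Gaussian of flat expected power, then inverse FFT.  Unstable
    parameter sets have no stationary response and are refused unless
    ``force`` is set.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    s = 2j * np.pi * freqs

    if level == "meso":
        if not force and mesoscopic_poles(local).classification == "unstable":
            raise ValueError("unstable local circuit has no stationary noise response")
        tf = local_transfer(local, s)
        H = np.vstack([tf.H_e, tf.H_i])
        names = ("x_e", "x_i")
    else:
        if net is None or conn is None:
            raise ValueError("macro levels require net and conn")
        if not force:
            meso_bad = (level == "macro_meso"
                        and mesoscopic_poles(local).classification == "unstable")
            if meso_bad or classify_macroscopic_regime(local, net, conn).code != 1:
                raise ValueError("unstable model has no stationary noise response")
        Fvec = _macro_transfer_vec(local, net, conn, meso_input=(level == "macro_meso"))
        H = np.stack([Fvec(si) for si in s], axis=1)
        names = tuple(conn.labels)

    P = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)) / np.sqrt(2.0)
    P[0] = P[0].real
    if n % 2 == 0:
        P[-1] = P[-1].real
    y = np.fft.irfft(H * P, n=n, axis=1) * np.sqrt(n)
    t = np.arange(n) / fs
    return TimeSeries(t=t, y=y, channel_names=names, input_kind="noise",
                      reliable_until=float(t[-1]))


def _extrema(y: np.ndarray) -> np.ndarray:
    d = np.diff(y)
    return np.flatnonzero(np.sign(d[1:]) * np.sign(d[:-1]) < 0) + 1


def classify_trajectory(
    ts: TimeSeries,
    channel: int = 0,
    rel_slope_tol: float = 0.02,
) -> str:
    """Shape classification of an impulse-response trajectory.

    Returns one of ``damped``, ``limit_cycle``, ``growing_amplitude``,
    ``growing_mean``, ``growing_both`` or ``indeterminate`` (too few
    oscillation extrema inside the reliable window).

    Oscillation-dominated trajectories are judged from their extrema:
    consecutive extrema triples give a local mean (y_k + 2 y_{k+1} +
    y_{k+2})/4 and a local amplitude |y_k - 2 y_{k+1} + y_{k+2}|/4 (the
    triple weighting cancels the first-order bias a decaying envelope puts
    on a simple max/min midpoint).  The amplitude is regressed
    log-linearly against time on the later triples, so fast transient
    modes do not bias the dominant-mode trend; the mean linearly, scaled
    by the oscillation amplitude.  Relative slopes within
    ``rel_slope_tol`` per (half-)period count as flat (limit cycle /
    bounded mean).  Trajectories with fewer than 5 extrema are judged on
    their cubic trend alone: clear growth is a growing mean, clear decay
    is damped, anything else indeterminate.
    """
    keep = ts.t <= ts.reliable_until
    t, y = ts.t[keep], ts.y[channel, keep]
    if t.size < 16:
        return "indeterminate"
    ext = _extrema(y)
    if ext.size < 5:
        # (nearly) non-oscillatory: only the trend can be judged
        trend = np.polyval(np.polyfit(t, y, 3), t)
        ref = float(np.max(np.abs(y)))
        rate = (trend[-1] - trend[0]) / ref if ref > 0 else 0.0
        if rate > rel_slope_tol:
            return "growing_mean"
        if rate < -rel_slope_tol and abs(y[-1]) < 0.1 * ref:
            return "damped"
        return "indeterminate"
    period = 2.0 * float(np.median(np.diff(t[ext])))
    ye = y[ext]
    t_pair = t[ext[1:-1]]
    m_pair = 0.25 * (ye[:-2] + 2.0 * ye[1:-1] + ye[2:])
    a_pair = 0.25 * np.abs(ye[:-2] - 2.0 * ye[1:-1] + ye[2:])
    # ignore triples once the envelope falls to the numerical-inversion
    # noise floor (relative ~1e-8): below it extrema are noise, not signal
    pos = a_pair > 1e-6 * float(a_pair.max(initial=0.0))
    if pos.sum() < 3:
        return "indeterminate"
    t_pair, m_pair, a_pair = t_pair[pos], m_pair[pos], a_pair[pos]
    pos = np.ones(t_pair.size, dtype=bool)
    late = pos & (t_pair >= t_pair[0] + 0.4 * (t_pair[-1] - t_pair[0]))
    if late.sum() < 3:
        late = pos
    slope = np.polyfit(t_pair[late], np.log(a_pair[late]), 1)[0]
    amp_rate = slope * period
    a_scale = float(np.median(a_pair[pos]))
    # the mean trend is also judged on the late window: a decaying hump
    # transient rises early without any growing mean mode behind it
    late_m = t_pair >= t_pair[0] + 0.4 * (t_pair[-1] - t_pair[0])
    if late_m.sum() < 3:
        late_m = np.ones(t_pair.size, dtype=bool)
    mslope = np.polyfit(t_pair[late_m], m_pair[late_m], 1)[0]
    mean_rate = mslope * period / a_scale if a_scale > 0 else 0.0
    # a mean verdict needs enough triples to average out envelope leakage
    mean_growing = mean_rate > rel_slope_tol and t_pair.size >= 6

    amp_growing = amp_rate > rel_slope_tol
    if mean_growing and amp_growing:
        return "growing_both"
    if mean_growing:
        return "growing_mean"
    if amp_growing:
        return "growing_amplitude"
    if amp_rate < -rel_slope_tol:
        return "damped"
    return "limit_cycle"
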