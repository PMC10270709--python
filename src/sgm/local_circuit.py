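"""Mesoscopic excitatory/inhibitory circuit in the frequency domain.

A single region hosts an excitatory and an inhibitory neural population
whose ensemble impulse responses are Gamma-shaped,

    f(t) = (t / tau^2) * exp(-t / tau),   Laplace:  F(s) = (1/tau^2) / (s + 1/tau)^2,

with unit DC gain.  Linearizing the population interactions gives, in the
Laplace/Fourier domain, a 2x2 linear system for the excitatory and
inhibitory responses (X_e, X_i) to a common noise input P:

    (s I - A(s)) [X_e, X_i]^T = [P, P]^T,

    A(s) = [[-g_ee F_e / tau_e,   +g_ei F_e F_i / tau_e],
            [-g_ei F_e F_i / tau_i, -g_ii F_i / tau_i ]].

Solving with P = 1 yields the transfer functions H_e, H_i, and the local
spectrum H_local = H_e + H_i.  The equivalent closed forms use the
intermediates F1 = g_ei F_e F_i, F2 = s + g_ii F_i / tau_i,
F3 = s + g_ee F_e / tau_e:

    H_e = (F2 + F1/tau_e) / (F2 F3 + F1^2/(tau_e tau_i)),
    H_i = (F3 - F1/tau_i) / (F2 F3 + F1^2/(tau_e tau_i)).

Both routes are implemented; the linear solve is the normative one and the
closed form is kept as an internal cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .params import LocalCircuitParams

__all__ = [
    "BAND_EDGES",
    "DEFAULT_FREQS",
    "LocalTransfer",
    "SpectralPeak",
    "default_frequency_grid",
    "find_spectral_peaks",
    "gamma_kernel_transform",
    "local_psd",
    "local_transfer",
]

#: Canonical electrophysiology band edges in Hz, clipped to the 2-45 Hz
#: analysis window (delta is open below, gamma above, in full-band usage).
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (2.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 45.0),
}


def default_frequency_grid(fmin: float = 2.0, fmax: float = 45.0, df: float = 0.1) -> np.ndarray:
    """Analysis frequency grid in Hz (default 2-45 Hz at 0.1 Hz)."""
    n = int(round((fmax - fmin) / df))
    return fmin + df * np.arange(n + 1)


#: Default 2-45 Hz grid at 0.1 Hz resolution.
DEFAULT_FREQS = default_frequency_grid()


def gamma_kernel_transform(tau: float, s: complex | np.ndarray) -> complex | np.ndarray:
    """Laplace transform of the Gamma ensemble kernel, (1/tau^2)/(s + 1/tau)^2.

    Parameters
    ----------
    tau : time constant in seconds, strictly positive.
    s : Laplace variable in rad/s; pass ``1j * omega`` for the steady-state
        (Fourier) response.  Scalar or array.

    Returns
    -------
    The complex kernel response; exactly 1 at s = 0 (unit DC gain).
    """
    if not tau > 0:
        raise ValueError(f"tau must be strictly positive, got {tau!r}")
    t = 1.0 / tau
    return (t * t) / ((np.asarray(s, dtype=complex) + t) ** 2) if np.ndim(s) else (t * t) / ((complex(s) + t) ** 2)


@dataclass(frozen=True)
class LocalTransfer:
    """Transfer-function evaluation of the local circuit at one or more s."""

    s: np.ndarray
    F_e: np.ndarray
    F_i: np.ndarray
    F1: np.ndarray
    F2: np.ndarray
    F3: np.ndarray
    H_e: np.ndarray
    H_i: np.ndarray

    @property
    def H_local(self) -> np.ndarray:
        return self.H_e + self.H_i


def _system_matrix(params: LocalCircuitParams, s: np.ndarray):
    """Entries of (s I - A(s)) as broadcastable arrays (a, b, c, d)."""
    F_e = gamma_kernel_transform(params.tau_e, s)
    F_i = gamma_kernel_transform(params.tau_i, s)
    a = s + params.g_ee * F_e / params.tau_e
    b = -params.g_ei * F_e * F_i / params.tau_e
    c = params.g_ei * F_e * F_i / params.tau_i
    d = s + params.g_ii * F_i / params.tau_i
    return F_e, F_i, a, b, c, d


def local_transfer(params: LocalCircuitParams, s: complex | Sequence[complex] | np.ndarray) -> LocalTransfer:
    """Solve the 2x2 circuit system for H_e, H_i at Laplace points ``s``.

    Raises
    ------
    ZeroDivisionError
        If ``s`` sits exactly on a pole of the transfer function (the 2x2
        system is singular there).
    """
    s_arr = np.atleast_1d(np.asarray(s, dtype=complex))
    F_e, F_i, a, b, c, d = _system_matrix(params, s_arr)
    det = a * d - b * c
    if np.any(det == 0):
        raise ZeroDivisionError("transfer function evaluated exactly at a pole")
    # Cramer's rule for (sI - A) [He, Hi]^T = [1, 1]^T
    H_e = (d - b) / det
    H_i = (a - c) / det
    F1 = params.g_ei * F_e * F_i
    F2 = s_arr + params.g_ii * F_i / params.tau_i
    F3 = s_arr + params.g_ee * F_e / params.tau_e
    return LocalTransfer(s=s_arr, F_e=F_e, F_i=F_i, F1=F1, F2=F2, F3=F3, H_e=H_e, H_i=H_i)


def local_transfer_closed_form(params: LocalCircuitParams, s) -> tuple[np.ndarray, np.ndarray]:
    """H_e, H_i via the printed closed forms (cross-check of the solve)."""
    s_arr = np.atleast_1d(np.asarray(s, dtype=complex))
    F_e = gamma_kernel_transform(params.tau_e, s_arr)
    F_i = gamma_kernel_transform(params.tau_i, s_arr)
    F1 = params.g_ei * F_e * F_i
    F2 = s_arr + params.g_ii * F_i / params.tau_i
    F3 = s_arr + params.g_ee * F_e / params.tau_e
    den = F2 * F3 + F1 * F1 / (params.tau_e * params.tau_i)
    return (F2 + F1 / params.tau_e) / den, (F3 - F1 / params.tau_i) / den


def local_psd(params: LocalCircuitParams, freqs: Sequence[float] | np.ndarray = DEFAULT_FREQS) -> np.ndarray:
    """Local-circuit power spectrum in dB: 20 log10 |H_local(2 pi f j)|.

    The input-noise spectral weight is flat (white noise), so the PSD is the
    transfer-function magnitude itself on the dB scale.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("frequency grid is empty")
    tf = local_transfer(params, 2j * np.pi * freqs)
    return 20.0 * np.log10(np.abs(tf.H_local))


@dataclass(frozen=True)
class SpectralPeak:
    frequency: float
    band: str
    rank: int
    height_db: float


def band_of(freq: float, edges: dict[str, tuple[float, float]] = BAND_EDGES) -> str:
    """Label a frequency with its band; ties at an edge go to the lower band."""
    for name, (lo, hi) in edges.items():
        if lo <= freq <= hi:
            return name
    return "out-of-band"


def find_spectral_peaks(
    psd: np.ndarray,
    freqs: np.ndarray,
    band_edges: dict[str, tuple[float, float]] = BAND_EDGES,
) -> list[SpectralPeak]:
    """Locate local maxima of a dB spectrum and label them by band.

    A peak is a grid point strictly higher than both neighbors (endpoints
    cannot be peaks).  Peaks are ranked by height; rank 1 is the primary
    peak.  Equal heights break toward the lower frequency.  A monotone
    spectrum yields an empty list.
    """
    psd = np.asarray(psd, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if psd.shape != freqs.shape:
        raise ValueError("psd and freqs must have the same shape")
    if psd.size >= 2 and not np.all(np.diff(freqs) > 0):
        raise ValueError("freqs must be strictly increasing")
    if psd.size < 3:
        return []
    interior = np.arange(1, psd.size - 1)
    is_peak = (psd[interior] > psd[interior - 1]) & (psd[interior] > psd[interior + 1])
    idx = interior[is_peak]
    # sort by height descending, lower frequency first on ties
    order = sorted(range(idx.size), key=lambda i: (-psd[idx[i]], freqs[idx[i]]))
    return [
        SpectralPeak(frequency=float(freqs[idx[i]]), band=band_of(float(freqs[idx[i]]), band_edges),
                     rank=r + 1, height_db=float(psd[idx[i]]))
        for r, i in enumerate(order)
    ]
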