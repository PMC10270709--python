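"""Macroscopic delayed network model and its closed-form spectrum.

Long-range excitatory signals x_k(t) on a structural connectome obey

    dx/dt = -(1/tau_G) f_e * x + (alpha/tau_G) f_e * C x(t - d/v) + x_local(t),

where f_e is the excitatory Gamma kernel and C the row-degree-normalized
connectivity.  In the frequency domain the delays become phase factors,
C*(omega) = [c_jk exp(-j omega d_jk / v)], and the dynamics collapse onto
the complex Laplacian L(omega) = I - alpha C*(omega).  The steady-state
regional response to the common local input H_local(omega) P(omega) is

    X(omega) = (j omega I + tau_G^{-1} F_e(omega) L(omega))^{-1} 1 H_local P,

equivalently an eigenmode sum over L's eigenpairs.  L is generally
non-normal, so the eigenmode sum uses the oblique projectors built from U
and U^{-1}; the direct linear solve is the normative result and the two are
verified to agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.linalg

from .connectome import Connectome
from .local_circuit import DEFAULT_FREQS, find_spectral_peaks, gamma_kernel_transform, local_transfer
from .params import LocalCircuitParams, NetworkParams

__all__ = [
    "NetworkOperator",
    "RegionalSpectrum",
    "complex_laplacian",
    "delayed_connectivity",
    "model_psd",
    "network_transfer",
    "peak_frequency_map",
]

InputKind = Literal["sgm_local", "exp_decay", "impulse"]


def delayed_connectivity(conn: Connectome, v: float, s: complex) -> np.ndarray:
    """Delayed connectivity C*(s) = [c_jk exp(-s d_jk / v)] at Laplace point s.

    For the steady-state (Fourier) operator pass ``s = 1j * omega``; at
    omega = 0 or in the infinite-speed limit this returns C itself.
    """
    tau = conn.delays(v)
    return conn.C * np.exp(-complex(s) * tau)


@dataclass(frozen=True)
class NetworkOperator:
    """Complex Laplacian L = I - alpha C* with its eigendecomposition."""

    C_star: np.ndarray
    alpha: float
    L: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns u_k
    eigenvectors_inv: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return self.eigenvectors @ np.diag(self.eigenvalues) @ self.eigenvectors_inv


def complex_laplacian(C_star: np.ndarray, alpha: float) -> NetworkOperator:
    """Form L = I - alpha C* and eigendecompose it (general, non-Hermitian)."""
    C_star = np.asarray(C_star, dtype=complex)
    if C_star.ndim != 2 or C_star.shape[0] != C_star.shape[1]:
        raise ValueError(f"C_star must be square, got shape {C_star.shape}")
    L = np.eye(C_star.shape[0], dtype=complex) - alpha * C_star
    lam, U = scipy.linalg.eig(L)
    U_inv = scipy.linalg.inv(U)
    return NetworkOperator(C_star=C_star, alpha=float(alpha), L=L,
                           eigenvalues=lam, eigenvectors=U, eigenvectors_inv=U_inv)


@dataclass(frozen=True)
class RegionalSpectrum:
    """Complex frequency response per region (N x F) on a Hz grid."""

    X: np.ndarray
    freqs: np.ndarray
    input_kind: str


def _input_spectrum(local: LocalCircuitParams, s: np.ndarray, input_kind: InputKind) -> np.ndarray:
    if input_kind == "sgm_local":
        return local_transfer(local, s).H_local
    if input_kind == "exp_decay":  # Fourier/Laplace transform of exp(-t)
        return 1.0 / (s + 1.0)
    if input_kind == "impulse":
        return np.ones_like(s)
    raise ValueError(f"unknown input_kind {input_kind!r}")


def network_transfer(
    local: LocalCircuitParams,
    net: NetworkParams,
    conn: Connectome,
    freqs: np.ndarray = DEFAULT_FREQS,
    input_kind: InputKind = "sgm_local",
    method: Literal["eig", "solve"] = "eig",
) -> RegionalSpectrum:
    """Closed-form regional frequency response X(omega) for each region.

    ``method="eig"`` evaluates the eigenmode sum
    X = sum_k P_k 1 / (j omega + tau_G^{-1} lambda_k F_e) * H_in, with
    oblique projectors P_k from the eigendecomposition of L(omega);
    ``method="solve"`` solves the defining linear system directly.  The two
    agree to numerical precision and the solve is cheaper for fitting loops.

    Raises a ``ZeroDivisionError`` if some mode satisfies
    j omega + tau_G^{-1} lambda_k F_e = 0 on the grid (marginal mode).
    """
    freqs = np.asarray(freqs, dtype=float)
    s_grid = 2j * np.pi * freqs
    H_in = _input_spectrum(local, s_grid, input_kind)
    N = conn.N
    X = np.empty((N, freqs.size), dtype=complex)
    ones = np.ones(N, dtype=complex)
    tau = conn.delays(net.v)
    if method == "solve":
        # batched over the frequency grid: one LU solve per frequency
        Fe = gamma_kernel_transform(local.tau_e, s_grid)
        C_star = conn.C[None, :, :] * np.exp(-s_grid[:, None, None] * tau[None, :, :])
        A = (-net.alpha / net.tau_G) * Fe[:, None, None] * C_star
        idx = np.arange(N)
        A[:, idx, idx] += (s_grid + Fe / net.tau_G)[:, None]
        rhs = np.broadcast_to(ones, (freqs.size, N))[..., None]
        X = (np.linalg.solve(A, rhs)[..., 0] * H_in[:, None]).T
        return RegionalSpectrum(X=X, freqs=freqs, input_kind=input_kind)
    for m, s in enumerate(s_grid):
        Fe = gamma_kernel_transform(local.tau_e, s)
        C_star = conn.C * np.exp(-s * tau)
        op = complex_laplacian(C_star, net.alpha)
        denom = s + op.eigenvalues * Fe / net.tau_G
        if np.any(denom == 0):
            raise ZeroDivisionError(f"marginal network mode at f={freqs[m]} Hz")
        coeffs = (op.eigenvectors_inv @ ones) / denom
        X[:, m] = (op.eigenvectors @ coeffs) * H_in[m]
    return RegionalSpectrum(X=X, freqs=freqs, input_kind=input_kind)


def model_psd(spec: RegionalSpectrum | np.ndarray, floor: float = 1e-30) -> np.ndarray:
    """Power spectral density in dB: 20 log10 |X| elementwise (N x F).

    Magnitudes below ``floor`` are clipped (with a warning) to avoid -inf.
    """
    X = spec.X if isinstance(spec, RegionalSpectrum) else np.asarray(spec)
    mag = np.abs(X)
    if np.any(mag < floor):
        import warnings

        warnings.warn("degenerate spectrum: zero magnitudes clipped for dB conversion", stacklevel=2)
        mag = np.maximum(mag, floor)
    return 20.0 * np.log10(mag)


def peak_frequency_map(
    local: LocalCircuitParams,
    tau_G_grid: np.ndarray,
    alpha_grid: np.ndarray,
    conn: Connectome,
    v: float = 5.0,
    freqs: np.ndarray = DEFAULT_FREQS,
    input_kind: InputKind = "exp_decay",
):
    """Primary-peak frequency of the mean cortical PSD over a (tau_G, alpha) grid.

    Cells where the macroscopic model is unstable (per the two-level
    boundary analysis) are NaN, mirroring the white region of a stability
    map.  Returns an array of shape (len(tau_G_grid), len(alpha_grid)).
    """
    from .stability import classify_macroscopic_regime, jw_boundary

    tau_G_grid = np.asarray(tau_G_grid, dtype=float)
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    out = np.full((tau_G_grid.size, alpha_grid.size), np.nan)
    mask = conn.cortical_mask
    # the jw boundary depends on alpha (not tau_G); compute once per column
    for j, alpha in enumerate(alpha_grid):
        boundary = jw_boundary(local, alpha, conn, v)
        for i, tau_G in enumerate(tau_G_grid):
            net = NetworkParams(tau_G=tau_G, alpha=alpha, v=v)
            regime = classify_macroscopic_regime(local, net, conn, boundary=boundary)
            if regime.code != 1:
                continue
            spec = network_transfer(local, net, conn, freqs, input_kind, method="solve")
            psd = model_psd(spec)[mask].mean(axis=0)
            peaks = find_spectral_peaks(psd, freqs)
            if peaks:
                out[i, j] = peaks[0].frequency
    return out
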