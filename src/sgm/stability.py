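"""Two-level stability analysis of the spectral graph model.

Local circuit (mesoscopic) level
    The poles of the 2x2 transfer function are the zeros of
    det(sI - A(s)).  Clearing the Gamma-kernel denominators turns the
    determinant into a degree-10 real polynomial in s,

        {[s(s+t_e)^2 + g_ee t_e^3](s+t_i)^2} {[s(s+t_i)^2 + g_ii t_i^3](s+t_e)^2}
            + g_ei^2 t_e^5 t_i^5,

    with t_e = 1/tau_e, t_i = 1/tau_i.  Any root in the open right half
    plane means growing oscillations; roots on the axis mean a limit
    cycle.  The Routh-Hurwitz tabular criterion provides an independent
    right-half-plane root count.

Network (macroscopic) level
    Stability is governed by the roots of det M(s) with
    M(s) = (s + F_e(s)/tau_G) I - (alpha/tau_G) F_e(s) C*(s), which
    factorizes over the eigenvalues lambda_k(s) of the complex Laplacian
    L(s) = I - alpha C*(s) as prod_k (s + F_e(s) lambda_k(s) / tau_G).
    Two boundaries matter: s = 0 crossings occur exactly at alpha = 1 for
    a connected row-stochastic connectome (Perron eigenvalue), and
    s = j omega crossings are found per mode by root finding in
    (tau_G, omega).  Crossing the alpha = 1 line makes the *mean* of the
    oscillations grow; dropping tau_G below the j-omega boundary makes
    their *amplitude* grow, giving four regimes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize

from .connectome import Connectome
from .local_circuit import gamma_kernel_transform
from .params import LocalCircuitParams, NetworkParams

__all__ = [
    "CharPoly",
    "MacroRegime",
    "PoleSet",
    "alpha0_stability",
    "alpha_boundary",
    "classify_macroscopic_regime",
    "critical_gei",
    "jw_boundary",
    "macro_char_matrix",
    "mesoscopic_char_poly",
    "mesoscopic_poles",
    "routh_hurwitz",
]

#: |max real part| below this (rad/s) classifies a limit cycle.
MARGINAL_TOL = 1e-6


@dataclass(frozen=True)
class CharPoly:
    """Real characteristic polynomial, coefficients in descending degree."""

    coeffs: np.ndarray
    t_e: float
    t_i: float

    @property
    def degree(self) -> int:
        return len(self.coeffs) - 1

    def __call__(self, s):
        return np.polyval(self.coeffs, s)


@dataclass(frozen=True)
class PoleSet:
    roots: np.ndarray
    max_real: float
    classification: str  # stable | limit_cycle | unstable
    tolerance: float
    spurious: np.ndarray  # roots coinciding with cleared kernel denominators


@dataclass(frozen=True)
class MacroRegime:
    """One of the four macroscopic regimes.

    code 1: stable (alpha <= 1, tau_G above the j-omega boundary)
    code 2: amplitude-growing (alpha <= 1, tau_G below the boundary)
    code 3: mean-growing (alpha > 1, tau_G above the boundary)
    code 4: both growing (alpha > 1, tau_G below the boundary)
    """

    code: int
    meso_part: str  # damped | growing-amplitude
    mean_part: str  # bounded | growing
    tau_G_boundary: float


def mesoscopic_char_poly(params: LocalCircuitParams) -> CharPoly:
    """Degree-10 characteristic polynomial of the local circuit.

    Built by exact coefficient convolution; monic by construction (the
    product of two monic quintics).
    """
    te, ti = params.t_e, params.t_i
    spte2 = np.polymul([1.0, te], [1.0, te])
    spti2 = np.polymul([1.0, ti], [1.0, ti])
    bracket_e = np.polyadd(np.polymul([1.0, 0.0], spte2), [params.g_ee * te**3])
    bracket_i = np.polyadd(np.polymul([1.0, 0.0], spti2), [params.g_ii * ti**3])
    quintic_e = np.polymul(bracket_e, spti2)
    quintic_i = np.polymul(bracket_i, spte2)
    coeffs = np.polyadd(np.polymul(quintic_e, quintic_i),
                        [params.g_ei**2 * te**5 * ti**5])
    return CharPoly(coeffs=np.asarray(coeffs, dtype=float), t_e=te, t_i=ti)


def _classify(max_real: float, tol: float) -> str:
    if max_real > tol:
        return "unstable"
    if max_real < -tol:
        return "stable"
    return "limit_cycle"


def poles_of(poly: CharPoly | np.ndarray, tol: float = MARGINAL_TOL,
             t_e: float | None = None, t_i: float | None = None) -> PoleSet:
    """Roots of a characteristic polynomial with stability classification."""
    if isinstance(poly, CharPoly):
        coeffs, t_e, t_i = poly.coeffs, poly.t_e, poly.t_i
    else:
        coeffs = np.asarray(poly, dtype=float)
    roots = np.roots(coeffs)  # companion-matrix eigenvalues
    max_real = float(np.max(roots.real))
    spurious = np.zeros(roots.shape, dtype=bool)
    # When g_ei -> 0 the cleared kernel denominators (s + t_e)^2 (s + t_i)^2
    # reappear as roots; they are always in the left half plane.
    for t in (t_e, t_i):
        if t is not None:
            spurious |= np.abs(roots + t) < 1e-9 * t
    return PoleSet(roots=roots, max_real=max_real,
                   classification=_classify(max_real, tol), tolerance=tol,
                   spurious=spurious)


def mesoscopic_poles(params: LocalCircuitParams, tol: float = MARGINAL_TOL) -> PoleSet:
    """All ten transfer-function poles of the local circuit."""
    return poles_of(mesoscopic_char_poly(params), tol=tol)


def routh_hurwitz(coeffs, eps_scale: float = 1e-12) -> tuple[np.ndarray, int]:
    """Routh array and the count of open-right-half-plane roots.

    Parameters
    ----------
    coeffs : real polynomial coefficients, descending degree, nonzero lead.

    Returns
    -------
    (array, sign_changes) : the (n+1) x m Routh array, and the number of
    sign changes in its first column, which equals the number of roots with
    positive real part for polynomials without imaginary-axis roots.

    A zero first-column pivot is replaced by a signed epsilon (relative to
    the largest magnitude in its row); an entirely zero row is replaced by
    the derivative of its auxiliary polynomial.  Both fallbacks emit a
    warning since the count is then only a limit statement.
    """
    c = np.asarray(coeffs, dtype=float)
    c = np.trim_zeros(c, "f")
    if c.size == 0:
        raise ValueError("zero polynomial")
    n = c.size - 1
    if n == 0:
        return np.array([[c[0]]]), 0
    m = (n + 2) // 2
    R = np.zeros((n + 1, m))
    R[0, : c[0::2].size] = c[0::2]
    R[1, : c[1::2].size] = c[1::2]
    for i in range(2, n + 1):
        upper = R[i - 2]
        prev = R[i - 1]
        if np.all(prev == 0):
            # auxiliary polynomial from the row above; degree n - i + 2
            deg = n - i + 2
            aux_pows = np.arange(deg, -1, -2)
            deriv = upper[: aux_pows.size] * aux_pows
            prev = R[i - 1] = np.concatenate([deriv, np.zeros(m - deriv.size)])
            warnings.warn("Routh array: zero row replaced by auxiliary-polynomial derivative",
                          stacklevel=2)
        pivot = prev[0]
        if pivot == 0:
            pivot = eps_scale * max(1.0, np.max(np.abs(prev)))
            warnings.warn("Routh array: zero pivot replaced by epsilon", stacklevel=2)
        for j in range(m - 1):
            R[i, j] = (pivot * upper[j + 1] - upper[0] * prev[j + 1]) / pivot
        if i == 2 and R[1, 0] == 0:
            R[1, 0] = eps_scale * max(1.0, np.max(np.abs(R[1])))
    first = R[:, 0].copy()
    first[first == 0] = eps_scale
    signs = np.sign(first)
    sign_changes = int(np.sum(signs[:-1] != signs[1:]))
    return R, sign_changes


def critical_gei(
    g_ii: float = 0.5,
    tau_e: float = 0.012,
    tau_i: float = 0.003,
    bracket: tuple[float, float] = (0.1, 1.0),
    xtol: float = 1e-4,
) -> float:
    """Critical cross-population gain where damped oscillations become growing.

    Bisection on the maximum real part of the local circuit's poles as a
    function of g_ei; the bracket must straddle the sign change.
    """

    def max_real(g):
        p = LocalCircuitParams(tau_e=tau_e, tau_i=tau_i, g_ei=g, g_ii=g_ii)
        return mesoscopic_poles(p).max_real

    lo, hi = bracket
    flo, fhi = max_real(lo), max_real(hi)
    if not (flo < 0 < fhi):
        raise ValueError(
            f"bracket {bracket} does not straddle the stability transition "
            f"(max real parts {flo:.3g}, {fhi:.3g})")
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        if max_real(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def alpha0_stability(tau_e: float, tau_G: float) -> tuple[bool, CharPoly]:
    """Stability of the uncoupled (alpha = 0) macroscopic subsystem.

    The characteristic cubic is s^3 + (2/tau_e) s^2 + (1/tau_e^2) s
    + 1/(tau_e^2 tau_G); Routh-Hurwitz reduces it to the analytic
    condition 2 tau_G > tau_e.
    """
    if not (tau_e > 0 and tau_G > 0):
        raise ValueError("tau_e and tau_G must be strictly positive")
    cubic = CharPoly(
        coeffs=np.array([1.0, 2.0 / tau_e, 1.0 / tau_e**2, 1.0 / (tau_e**2 * tau_G)]),
        t_e=1.0 / tau_e, t_i=np.nan)
    return 2.0 * tau_G > tau_e, cubic


def alpha_boundary(conn: Connectome, imag_tol: float = 1e-9) -> float:
    """Smallest alpha > 0 at which I - alpha C becomes singular.

    Equals 1 / (largest real eigenvalue of C); for any connected
    row-degree-normalized C the Perron eigenvalue is 1, so the boundary is
    exactly alpha = 1.
    """
    mu = scipy.linalg.eigvals(conn.C)
    real_mu = mu.real[(np.abs(mu.imag) <= imag_tol * max(1.0, np.max(np.abs(mu)))) & (mu.real > 0)]
    if real_mu.size == 0:
        raise ValueError("C has no positive real eigenvalue; no alpha boundary")
    deg = conn.C.sum(axis=1)
    if np.any(deg == 0):
        warnings.warn("disconnected rows present: alpha boundary may have multiplicity > 1",
                      stacklevel=2)
    return float(1.0 / np.max(real_mu))


def macro_char_matrix(s: complex, local: LocalCircuitParams, net: NetworkParams,
                      conn: Connectome) -> np.ndarray:
    """M(s) = (s + F_e(s)/tau_G) I - (alpha/tau_G) F_e(s) C*(s)."""
    Fe = gamma_kernel_transform(local.tau_e, s)
    C_star = conn.C * np.exp(-complex(s) * conn.delays(net.v))
    N = conn.N
    return (s + Fe / net.tau_G) * np.eye(N, dtype=complex) - (net.alpha / net.tau_G) * Fe * C_star


@dataclass(frozen=True)
class JwBoundary:
    tau_G: float
    omega: float
    mode_index: int
    residual: float


def _mode_eigenvalue(conn: Connectome, alpha: float, v: float, omega: float,
                     lam_ref: complex) -> complex:
    """Eigenvalue of L(j omega) continued from lam_ref (nearest tracking)."""
    C_star = conn.C * np.exp(-1j * omega * conn.delays(v))
    lam = scipy.linalg.eigvals(np.eye(conn.N) - alpha * C_star)
    return lam[np.argmin(np.abs(lam - lam_ref))]


def jw_boundary(
    local: LocalCircuitParams,
    alpha: float,
    conn: Connectome,
    v: float = 5.0,
    init: tuple[float, float] | None = None,
    tau_G_seeds: np.ndarray | None = None,
    omega_seeds_hz: tuple[float, ...] = (5.0, 8.0, 10.0, 12.0, 15.0),
    xtol: float = 1e-12,
    maxfev: int = 10000,
) -> JwBoundary:
    """Critical graph time constant where a network mode crosses s = j omega.

    For each eigenmode lambda_k of the complex Laplacian the factorized
    characteristic condition is

        j omega + tau_G^{-1} lambda_k(j omega) F_e(j omega) = 0,

    two real equations in the two unknowns (tau_G, omega), solved with the
    hybrid Powell method (xtol 1e-12, at most ``maxfev`` evaluations) from a
    multi-start grid of seeds; eigenvalues are tracked across omega by
    nearest-value continuation.  The largest converged positive tau_G over
    all modes and seeds is the stability boundary: for tau_G above it no
    mode can sit on the imaginary axis.
    """
    delays = conn.delays(v)

    # candidate starts: at each seed omega, each eigenmode predicts its own
    # crossing tau_G from j w tau_G = -lambda Fe; modes whose prediction is
    # far from the positive real axis cannot cross near that omega
    candidates: list[tuple[float, float, complex]] = []
    if init is not None:
        tg0, w0 = init
        C0 = conn.C * np.exp(-1j * w0 * delays)
        lam0 = scipy.linalg.eigvals(np.eye(conn.N) - alpha * C0)
        candidates = [(tg0, w0, lam) for lam in lam0]
    else:
        if tau_G_seeds is not None:
            grid = [(tg, 2 * np.pi * f) for tg in tau_G_seeds for f in omega_seeds_hz]
        else:
            grid = [(None, 2 * np.pi * f) for f in omega_seeds_hz]
        for tg0, w0 in grid:
            C0 = conn.C * np.exp(-1j * w0 * delays)
            lam0 = scipy.linalg.eigvals(np.eye(conn.N) - alpha * C0)
            Fe0 = gamma_kernel_transform(local.tau_e, 1j * w0)
            pred = 1j * lam0 * Fe0 / w0
            for lam, tg_pred in zip(lam0, pred):
                if tg0 is not None:
                    candidates.append((tg0, w0, lam))
                elif tg_pred.real > 0 and abs(tg_pred.imag) < tg_pred.real:
                    candidates.append((float(tg_pred.real), w0, lam))
    best: JwBoundary | None = None

    for k, (tg0, w0, lam_start) in enumerate(candidates):
        lam_ref = [lam_start]

        def residual(x, lam_ref=lam_ref):
            tau_G, omega = x
            lam = _mode_eigenvalue(conn, alpha, v, omega, lam_ref[0])
            lam_ref[0] = lam
            Fe = gamma_kernel_transform(local.tau_e, 1j * omega)
            val = 1j * omega * tau_G + lam * Fe  # scaled by tau_G
            return [val.real, val.imag]

        sol = scipy.optimize.root(residual, x0=[tg0, w0], method="hybr",
                                  options={"xtol": xtol, "maxfev": maxfev})
        tau_G_c, omega_c = sol.x
        if not sol.success or tau_G_c <= 0 or omega_c <= 0:
            continue
        # plug-in residual on the unscaled per-mode condition
        lam = _mode_eigenvalue(conn, alpha, v, omega_c, lam_ref[0])
        Fe = gamma_kernel_transform(local.tau_e, 1j * omega_c)
        res = abs(1j * omega_c + lam * Fe / tau_G_c)
        if res > 1e-8 * max(1.0, omega_c):
            continue
        if best is None or tau_G_c > best.tau_G:
            best = JwBoundary(tau_G=float(tau_G_c), omega=float(omega_c),
                              mode_index=int(k), residual=float(res))
    if best is None:
        raise RuntimeError(
            "jw_boundary: no imaginary-axis crossing found from any seed; "
            "try supplying an initial guess near the expected boundary")
    return best


def network_max_real(
    local: LocalCircuitParams,
    net: NetworkParams,
    conn: Connectome,
    omega_seeds_hz: tuple[float, ...] = (0.5, 2.0, 5.0, 8.0, 10.0, 12.0, 15.0, 25.0, 40.0),
) -> float:
    """Largest real part over the dominant network poles.

    Solves the per-mode characteristic condition
    s + tau_G^{-1} lambda_k(s) F_e(s) = 0 as a two-unknown root find in
    (Re s, Im s) from multi-start seeds on the imaginary axis, tracking
    eigenvalues by nearest-value continuation.  The maximum over converged
    roots estimates the decay/growth rate of the slowest network mode.
    """
    delays = conn.delays(net.v)
    best = -np.inf
    for f0 in omega_seeds_hz:
        w0 = 2 * np.pi * f0
        C0 = conn.C * np.exp(-1j * w0 * delays)
        lam0 = scipy.linalg.eigvals(np.eye(conn.N) - net.alpha * C0)
        for k in range(conn.N):
            lam_ref = [lam0[k]]

            def residual(x, lam_ref=lam_ref):
                s = complex(x[0], x[1])
                C_star = conn.C * np.exp(-s * delays)
                lam = scipy.linalg.eigvals(np.eye(conn.N) - net.alpha * C_star)
                lam = lam[np.argmin(np.abs(lam - lam_ref[0]))]
                lam_ref[0] = lam
                val = s * net.tau_G + lam * gamma_kernel_transform(local.tau_e, s)
                return [val.real, val.imag]

            sol = scipy.optimize.root(residual, x0=[0.0, w0], method="hybr",
                                      options={"xtol": 1e-10, "maxfev": 2000})
            if sol.success and abs(complex(*residual(sol.x))) < 1e-8:
                best = max(best, float(sol.x[0]))
    if not np.isfinite(best):
        raise RuntimeError("network_max_real: no pole converged from any seed")
    return best


def classify_macroscopic_regime(
    local: LocalCircuitParams,
    net: NetworkParams,
    conn: Connectome,
    boundary: JwBoundary | None = None,
) -> MacroRegime:
    """Four-regime classification of the macroscopic model.

    The mean of the oscillations grows iff alpha > 1 (the s = 0 boundary);
    their amplitude grows iff tau_G is below the j-omega boundary at this
    alpha.  A precomputed boundary may be passed to amortize grid sweeps.
    """
    if boundary is None:
        boundary = jw_boundary(local, net.alpha, conn, net.v)
    amplitude_growing = net.tau_G < boundary.tau_G
    mean_growing = net.alpha > 1.0
    code = 1 + (1 if amplitude_growing else 0) + (2 if mean_growing else 0)
    return MacroRegime(
        code=code,
        meso_part="growing-amplitude" if amplitude_growing else "damped",
        mean_part="growing" if mean_growing else "bounded",
        tau_G_boundary=boundary.tau_G,
    )


def stability_map(
    local: LocalCircuitParams,
    conn: Connectome,
    tau_G_grid: np.ndarray,
    alpha_grid: np.ndarray,
    v: float = 5.0,
) -> np.ndarray:
    """Regime codes over a (tau_G, alpha) grid; shape (len(tau_G), len(alpha))."""
    out = np.zeros((len(tau_G_grid), len(alpha_grid)), dtype=int)
    for j, alpha in enumerate(alpha_grid):
        b = jw_boundary(local, alpha, conn, v)
        for i, tau_G in enumerate(tau_G_grid):
            net = NetworkParams(tau_G=tau_G, alpha=alpha, v=v)
            out[i, j] = classify_macroscopic_regime(local, net, conn, boundary=b).code
    return out
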