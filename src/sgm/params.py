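"""Model parameters for the spectral graph model (SGM).

The model has two levels. The *local circuit* (mesoscopic) level describes
one region's excitatory/inhibitory population pair, governed by Gamma-shaped
ensemble kernels with time constants ``tau_e``, ``tau_i`` and dimensionless
neural gains ``g_ee``, ``g_ei``, ``g_ii``.  The *network* (macroscopic) level
couples long-range excitatory signals across a structural connectome through
a graph time constant ``tau_G``, a global coupling constant ``alpha`` and a
conduction speed ``v``.

``g_ee`` is pinned to 1 by convention: only the ratio of gains is
identifiable from the shape of the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace


@dataclass(frozen=True)
class LocalCircuitParams:
    """The five mesoscopic constants (``tau_e``, ``tau_i`` in seconds)."""

    tau_e: float = 0.012
    tau_i: float = 0.003
    g_ee: float = 1.0
    g_ei: float = 0.4
    g_ii: float = 0.5

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ValueError(f"{f.name} must be strictly positive, got {v!r}")

    @property
    def t_e(self) -> float:
        """Inverse excitatory time constant 1/tau_e (1/s)."""
        return 1.0 / self.tau_e

    @property
    def t_i(self) -> float:
        """Inverse inhibitory time constant 1/tau_i (1/s)."""
        return 1.0 / self.tau_i

    def replace(self, **changes) -> "LocalCircuitParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class NetworkParams:
    """The three macroscopic constants.

    tau_G : graph characteristic time constant, seconds
    alpha : global coupling constant, dimensionless
    v     : cortico-cortical conduction speed, m/s
    """

    tau_G: float = 0.012
    alpha: float = 0.8
    v: float = 5.0

    def __post_init__(self) -> None:
        for f in fields(self):
            val = getattr(self, f.name)
            if not val > 0:
                raise ValueError(f"{f.name} must be strictly positive, got {val!r}")

    def replace(self, **changes) -> "NetworkParams":
        return replace(self, **changes)


# Optimization box bounds and initial guesses for static spectrum fitting.
# Order of guesses matters: each fit is run once per initial guess and the
# best Pearson-r solution is kept.
STATIC_BOUNDS: dict[str, tuple[float, float]] = {
    "tau_e": (0.005, 0.02),
    "tau_i": (0.005, 0.02),
    "alpha": (0.1, 1.0),
    "v": (5.0, 20.0),
    "g_ei": (0.001, 0.8),
    "g_ii": (1.0, 2.5),
    "tau_G": (0.005, 0.02),
}

STATIC_GUESSES: dict[str, tuple[float, float, float]] = {
    "tau_e": (0.012, 0.018, 0.006),
    "tau_i": (0.003, 0.01, 0.018),  # 0.003 lies outside the box; clipped on use
    "alpha": (1.0, 0.5, 0.1),
    "v": (5.0, 10.0, 18.0),
    "g_ei": (0.2, 0.1, 0.3),
    "g_ii": (1.0, 1.5, 0.5),  # 0.5 lies outside the box; clipped on use
    "tau_G": (0.006, 0.01, 0.018),
}

# Dynamic (windowed) fitting frees only the fast biophysical couplings.
DYNAMIC_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (0.1, 1.0),
    "g_ei": (0.001, 0.8),
    "g_ii": (1.0, 2.5),
}

DYNAMIC_GUESSES: dict[str, tuple[float, float, float]] = {
    "alpha": (1.0, 0.5, 0.1),
    "g_ei": (0.2, 0.1, 0.3),
    "g_ii": (1.0, 1.5, 0.5),
}

STATIC_PARAM_ORDER = tuple(STATIC_BOUNDS)
DYNAMIC_PARAM_ORDER = tuple(DYNAMIC_BOUNDS)
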