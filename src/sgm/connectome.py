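"""Structural connectome container and validation.

A connectome is a pair of N x N matrices on a fixed region ordering: a
nonnegative connectivity matrix ``C`` whose rows are normalized by the row
degree (each nonzero-degree row sums to 1), and a symmetric inter-regional
fiber distance matrix ``D`` in millimeters with zero diagonal.  A boolean
``cortical_mask`` marks the regions entering spectral goodness-of-fit
averages (68 of 86 in the Desikan-Killiany atlas convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

ROW_SUM_TOL = 1e-12
SYMMETRY_TOL = 1e-9


class ConnectomeError(ValueError):
    """Raised when a connectome fails structural validation."""


def normalize_rows(C: np.ndarray) -> np.ndarray:
    """Normalize each row of a nonnegative matrix by its degree (row sum).

    Zero-degree rows are left as all zeros.
    """
    C = np.asarray(C, dtype=float)
    deg = C.sum(axis=1)
    out = C.copy()
    nz = deg > 0
    out[nz] = out[nz] / deg[nz, None]
    return out


@dataclass(frozen=True)
class Connectome:
    C: np.ndarray
    D: np.ndarray
    labels: tuple[str, ...] = ()
    cortical_mask: np.ndarray | None = None

    def __post_init__(self):
        C = np.asarray(self.C, dtype=float)
        D = np.asarray(self.D, dtype=float)
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "D", D)
        n = C.shape[0]
        if C.ndim != 2 or C.shape != (n, n):
            raise ConnectomeError(f"C must be square, got shape {C.shape}")
        if D.shape != (n, n):
            raise ConnectomeError(f"D shape {D.shape} does not match C shape {C.shape}")
        if np.any(C < 0):
            raise ConnectomeError("C has negative weights")
        if np.max(np.abs(D - D.T)) > SYMMETRY_TOL * max(1.0, np.max(np.abs(D))):
            raise ConnectomeError("D is not symmetric within tolerance")
        if np.any(np.abs(np.diag(D)) > 0):
            raise ConnectomeError("D diagonal must be zero")
        deg = C.sum(axis=1)
        bad = (deg > 0) & (np.abs(deg - 1.0) > 1e-6)
        if np.any(bad):
            raise ConnectomeError(
                "C rows are not degree-normalized (row sums deviate from 1); "
                "use normalize_rows or load with normalize=True"
            )
        if not self.labels:
            object.__setattr__(self, "labels", tuple(f"region_{i}" for i in range(n)))
        elif len(self.labels) != n:
            raise ConnectomeError("labels length does not match matrix size")
        if self.cortical_mask is None:
            object.__setattr__(self, "cortical_mask", np.ones(n, dtype=bool))
        else:
            mask = np.asarray(self.cortical_mask, dtype=bool)
            if mask.shape != (n,):
                raise ConnectomeError("cortical_mask length does not match matrix size")
            object.__setattr__(self, "cortical_mask", mask)
        if np.any(deg == 0):
            warnings.warn("connectome contains zero-degree (disconnected) rows", stacklevel=2)

    @property
    def N(self) -> int:
        return self.C.shape[0]

    def delays(self, v: float) -> np.ndarray:
        """Inter-regional delays d_jk / v in seconds (distances in mm, v in m/s)."""
        if not v > 0:
            raise ValueError("conduction speed v must be strictly positive")
        return (self.D / 1000.0) / v

    def validation_report(self) -> dict:
        """Structural summary: row sums, symmetry error, degree statistics."""
        deg = self.C.sum(axis=1)
        return {
            "n_regions": self.N,
            "n_cortical": int(np.sum(self.cortical_mask)),
            "row_sum_max_dev": float(np.max(np.abs(deg - 1.0))) if self.N else 0.0,
            "zero_degree_rows": [int(i) for i in np.flatnonzero(deg == 0)],
            "D_asymmetry": float(np.max(np.abs(self.D - self.D.T))),
            "D_max_mm": float(np.max(self.D)),
            "C_min": float(np.min(self.C)),
        }
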