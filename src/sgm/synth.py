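"""Synthetic connectomes and spectra with known ground truth.

Real structural connectomes pair distance-correlated fiber weights with
inter-regional distances spanning tens to ~150 mm.  The generator draws
random 3-D region coordinates inside a brain-sized box, connects regions
with a random geometric/Erdos-Renyi mixture whose edge weights decay with
distance (|Gaussian| x exp(-d/scale)), and row-degree-normalizes the
result.  Observed spectra are produced by the forward model itself at
known parameters, optionally with additive Gaussian noise on the dB scale,
so estimation code can be validated against ground truth without any
downloaded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import Connectome, normalize_rows
from .local_circuit import DEFAULT_FREQS
from .network_model import model_psd, network_transfer
from .params import LocalCircuitParams, NetworkParams
from .stability import classify_macroscopic_regime, mesoscopic_poles

__all__ = ["SynthSpec", "synth_connectome", "synth_static_psd", "synth_dynamic_windows"]


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic dataset; the seed fully determines it."""

    N: int = 86
    density: float = 0.6
    distance_scale: float = 150.0  # mm; box edge for region coordinates
    seed: int = 0
    local: LocalCircuitParams = field(default_factory=lambda: LocalCircuitParams(
        tau_e=0.012, tau_i=0.01, g_ei=0.3, g_ii=1.5))
    net: NetworkParams = field(default_factory=lambda: NetworkParams(
        tau_G=0.015, alpha=0.8, v=10.0))
    noise_db: float = 0.0
    window_truths: tuple[tuple[float, float, float], ...] = ()  # (alpha, g_ei, g_ii) per window
    graph: str = "geometric"  # or "erdos-renyi"
    cortical_fraction: float = 68.0 / 86.0


def synth_connectome(spec: SynthSpec, max_retries: int = 20) -> Connectome:
    """Random connected weighted connectome with realistic distances.

    Edges are kept with probability ``density`` (distance-biased for the
    geometric family); weights are |Gaussian| damped by exp(-d/scale/3).
    Disconnected draws are regenerated with an incremented sub-seed.
    """
    if spec.N < 2:
        raise ValueError("need at least 2 regions")
    if not 0 < spec.density <= 1:
        raise ValueError("density must be in (0, 1]")
    for attempt in range(max_retries):
        rng = np.random.default_rng((spec.seed, attempt))
        coords = rng.uniform(0.0, spec.distance_scale, size=(spec.N, 3))
        D = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        iu = np.triu_indices(spec.N, k=1)
        if spec.graph == "geometric":
            # nearer pairs connect more readily: threshold on distance-skewed u
            p_edge = spec.density * 2.0 * np.exp(-D[iu] / spec.distance_scale)
            keep = rng.uniform(size=iu[0].size) < np.clip(p_edge, 0.0, 1.0)
        else:
            keep = rng.uniform(size=iu[0].size) < spec.density
        w = np.abs(rng.standard_normal(iu[0].size)) * np.exp(-D[iu] / (3.0 * spec.distance_scale))
        w = np.where(keep, w, 0.0)
        W = np.zeros((spec.N, spec.N))
        W[iu] = w
        W = W + W.T
        if _connected(W):
            n_cort = int(round(spec.cortical_fraction * spec.N))
            mask = np.zeros(spec.N, dtype=bool)
            mask[:n_cort] = True
            labels = tuple(
                (f"ctx_{i}" if mask[i] else f"subctx_{i}") for i in range(spec.N))
            return Connectome(C=normalize_rows(W), D=D, labels=labels, cortical_mask=mask)
    raise RuntimeError(f"no connected graph in {max_retries} attempts; raise density")


def _connected(W: np.ndarray) -> bool:
    n = W.shape[0]
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in np.flatnonzero(W[i] > 0):
            if not seen[j]:
                seen[j] = True
                stack.append(int(j))
    return bool(seen.all())


def _noise(rng: np.random.Generator, shape, noise_db: float) -> np.ndarray:
    return noise_db * rng.standard_normal(shape) if noise_db > 0 else np.zeros(shape)


def synth_static_psd(
    spec: SynthSpec,
    conn: Connectome,
    freqs: np.ndarray = DEFAULT_FREQS,
    check_stability: bool = True,
) -> tuple[np.ndarray, dict]:
    """Observed-style static PSD (region x frequency, dB) plus truth record.

    The noiseless PSD is the forward model at the spec's true parameters;
    noise is an independent stream keyed off the spec seed, so two specs
    differing only in ``noise_db`` share the same underlying spectrum.
    """
    if check_stability:
        if mesoscopic_poles(spec.local).classification == "unstable":
            raise ValueError("true local circuit is unstable; refusing to synthesize")
        if classify_macroscopic_regime(spec.local, spec.net, conn).code != 1:
            raise ValueError("true network parameters are unstable; refusing to synthesize")
    psd = model_psd(network_transfer(spec.local, spec.net, conn, freqs, method="solve"))
    rng = np.random.default_rng((spec.seed, 10_001))
    obs = psd + _noise(rng, psd.shape, spec.noise_db)
    truth = {"local": spec.local, "net": spec.net, "noise_db": spec.noise_db}
    return obs, truth


def synth_dynamic_windows(
    spec: SynthSpec,
    conn: Connectome,
    freqs: np.ndarray = DEFAULT_FREQS,
    check_stability: bool = True,
) -> tuple[np.ndarray, list[dict]]:
    """Windowed PSDs (window x region x frequency, dB) from per-window truths.

    Each window's (alpha, g_ei, g_ii) comes from ``spec.window_truths``
    (time constants and speed frozen at the spec's static truth), emulating
    a ~5 s time-frequency cadence; planted jumps in alpha support
    switch-count validation.
    """
    if not spec.window_truths:
        raise ValueError("spec.window_truths is empty")
    rng = np.random.default_rng((spec.seed, 20_001))
    out = []
    truths = []
    for w, (alpha, g_ei, g_ii) in enumerate(spec.window_truths):
        local = spec.local.replace(g_ei=g_ei, g_ii=g_ii)
        net = spec.net.replace(alpha=alpha)
        if check_stability and mesoscopic_poles(local).classification == "unstable":
            raise ValueError(f"window {w} truth is locally unstable")
        psd = model_psd(network_transfer(local, net, conn, freqs, method="solve"))
        out.append(psd + _noise(rng, psd.shape, spec.noise_db))
        truths.append({"alpha": alpha, "g_ei": g_ei, "g_ii": g_ii})
    return np.stack(out), truths
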