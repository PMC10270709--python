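"""File formats: connectomes (CSV/HDF5), spectra (TSV/HDF5), run configs (JSON).

CSV/TSV keep everything human-readable and diff-friendly; HDF5 is the
canonical binary container for full datasets.  Region order is the file
order; no atlas semantics are enforced beyond the cortical mask.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .connectome import Connectome, ConnectomeError, normalize_rows

log = logging.getLogger("sgm")

__all__ = [
    "RunConfig",
    "read_connectome",
    "read_psd",
    "write_connectome",
    "write_psd",
    "write_timeseries",
]


def write_connectome(conn: Connectome, path: str | Path) -> None:
    """Write a connectome to HDF5 (.h5/.hdf5) or a CSV pair.

    The CSV form writes ``<stem>.csv`` (connectivity, labels as header)
    and ``<stem>_dist.csv`` (distances); the cortical mask is encoded by a
    ``ctx_`` label prefix.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("C", data=conn.C)
            f.create_dataset("D", data=conn.D)
            f.create_dataset("labels", data=np.array(conn.labels, dtype="S"))
            f.create_dataset("cortical_mask", data=conn.cortical_mask)
        return
    labels = list(conn.labels)
    pd.DataFrame(conn.C, columns=labels).to_csv(path, index=False)
    pd.DataFrame(conn.D, columns=labels).to_csv(
        path.with_name(path.stem + "_dist" + path.suffix), index=False)


def read_connectome(path: str | Path, normalize: bool = False) -> Connectome:
    """Load and validate a connectome from HDF5 or CSV.

    With ``normalize=True`` rows are degree-normalized on load (logged);
    otherwise matrices whose rows do not sum to 1 are rejected.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            C = np.asarray(f["C"])
            D = np.asarray(f["D"])
            labels = tuple(s.decode() for s in f["labels"][()]) if "labels" in f else ()
            mask = np.asarray(f["cortical_mask"]) if "cortical_mask" in f else None
    else:
        df = pd.read_csv(path)
        if not all(df.dtypes.apply(lambda d: np.issubdtype(d, np.number))):
            raise ConnectomeError(f"{path}: non-numeric entries in connectivity matrix")
        C = df.to_numpy(dtype=float)
        if C.shape[0] != C.shape[1]:
            raise ConnectomeError(
                f"{path}: matrix is {C.shape[0]} x {C.shape[1]}, expected square")
        labels = tuple(str(c) for c in df.columns)
        dpath = path.with_name(path.stem + "_dist" + path.suffix)
        if dpath.exists():
            D = pd.read_csv(dpath).to_numpy(dtype=float)
        else:
            log.warning("no distance file %s; assuming zero distances", dpath)
            D = np.zeros_like(C)
        mask = np.array([lbl.startswith("ctx") or lbl.startswith("L_") or lbl.startswith("R_")
                         for lbl in labels])
        if not mask.any():
            mask = None
    if normalize:
        log.info("row-degree normalizing connectivity on load")
        C = normalize_rows(C)
    return Connectome(C=C, D=D, labels=labels, cortical_mask=mask)


def write_psd(psd: np.ndarray, freqs: np.ndarray, path: str | Path,
              labels: tuple[str, ...] | None = None) -> None:
    """Write a (region x frequency) dB spectrum as TSV (header = Hz) or HDF5."""
    path = Path(path)
    psd = np.atleast_2d(np.asarray(psd))
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("psd", data=psd)
            f.create_dataset("freqs", data=np.asarray(freqs))
            if labels:
                f.create_dataset("labels", data=np.array(labels, dtype="S"))
        return
    idx = list(labels) if labels else [f"region_{i}" for i in range(psd.shape[0])]
    df = pd.DataFrame(psd, index=idx, columns=[repr(float(f)) for f in freqs])
    df.to_csv(path, sep="\t", index_label="region")


def read_psd(path: str | Path) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Read a (region x frequency) dB spectrum; returns (psd, freqs, labels)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            psd = np.asarray(f["psd"])
            freqs = np.asarray(f["freqs"])
            labels = tuple(s.decode() for s in f["labels"][()]) if "labels" in f else ()
        return psd, freqs, labels
    df = pd.read_csv(path, sep="\t", index_col=0)
    return (df.to_numpy(dtype=float), np.array([float(c) for c in df.columns]),
            tuple(str(i) for i in df.index))


def write_timeseries(t: np.ndarray, y: np.ndarray, path: str | Path,
                     labels: tuple[str, ...] | None = None) -> None:
    """Write trajectories as TSV: a time column plus one column per channel."""
    y = np.atleast_2d(np.asarray(y))
    cols = list(labels) if labels else [f"ch_{i}" for i in range(y.shape[0])]
    df = pd.DataFrame(y.T, columns=cols)
    df.insert(0, "time_s", np.asarray(t))
    df.to_csv(Path(path), sep="\t", index=False)


@dataclass
class RunConfig:
    """JSON-backed run configuration; unknown keys are rejected on load."""

    connectome: str | None = None
    seed: int = 0
    freq_min: float = 2.0
    freq_max: float = 45.0
    freq_step: float = 0.1
    out_dir: str = "."
    log_level: str = "INFO"
    params: dict = field(default_factory=dict)
    bounds: dict = field(default_factory=dict)
    tolerances: dict = field(default_factory=dict)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    def freqs(self) -> np.ndarray:
        n = int(round((self.freq_max - self.freq_min) / self.freq_step))
        return self.freq_min + self.freq_step * np.arange(n + 1)
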