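"""Connectome containers and I/O.

The spatial substrate of the whole-brain model is a weighted, directed
region-by-region matrix of connection strengths (tracer-style, normalised to
[0, 1]) together with a matrix of tract lengths in millimetres.  Tract
lengths divided by a conduction speed give inter-regional signal delays,
which the network integrator uses as integer multiples of its step size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Connectome",
    "DelayTable",
    "ConnectomeValidationError",
    "load_connectome",
    "save_connectome",
    "compute_delays",
]


class ConnectomeValidationError(ValueError):
    """Raised when a connectome violates its structural invariants."""


@dataclass(frozen=True)
class Connectome:
    """Weighted directed connectome with tract lengths.

    ``weights[n, m]`` is the strength of the projection from source region
    ``m`` onto target region ``n``, unitless in [0, 1].  ``tract_lengths``
    is in millimetres.  The diagonal is forced to zero (no self-coupling).
    """

    weights: np.ndarray
    tract_lengths: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        W = np.asarray(self.weights, dtype=float)
        L = np.asarray(self.tract_lengths, dtype=float)
        _validate_matrices(W, L)
        if np.any(np.diag(W) != 0):
            warnings.warn("non-zero diagonal weights set to 0 (no self-coupling)")
            W = W.copy()
            np.fill_diagonal(W, 0.0)
        labels = list(self.labels) if self.labels else [f"roi_{i}" for i in range(W.shape[0])]
        if len(labels) != W.shape[0]:
            raise ConnectomeValidationError(
                f"{len(labels)} labels for {W.shape[0]} regions"
            )
        object.__setattr__(self, "weights", W)
        object.__setattr__(self, "tract_lengths", L)
        object.__setattr__(self, "labels", labels)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class DelayTable:
    """Inter-regional delays as integer multiples of the integration step."""

    delays_steps: np.ndarray
    speed: float  # m/s
    dt: float  # ms

    @property
    def max_delay(self) -> int:
        return int(self.delays_steps.max()) if self.delays_steps.size else 0


def _validate_matrices(W: np.ndarray, L: np.ndarray) -> None:
    for name, M in (("weights", W), ("tract_lengths", L)):
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ConnectomeValidationError(f"{name} matrix is not square: shape {M.shape}")
        bad = np.argwhere(~np.isfinite(M))
        if bad.size:
            raise ConnectomeValidationError(f"{name}[{tuple(bad[0])}] is not finite")
    if W.shape != L.shape:
        raise ConnectomeValidationError(
            f"weights {W.shape} and tract_lengths {L.shape} differ in size"
        )
    neg = np.argwhere(W < 0)
    if neg.size:
        raise ConnectomeValidationError(f"negative weight at {tuple(neg[0])}")
    over = np.argwhere(W > 1)
    if over.size:
        n, m = over[0]
        raise ConnectomeValidationError(
            f"weight {W[n, m]:g} at ({n}, {m}) exceeds 1; pass rescale=True to normalise"
        )
    negl = np.argwhere(L < 0)
    if negl.size:
        raise ConnectomeValidationError(f"negative tract length at {tuple(negl[0])}")


def load_connectome(path, *, rescale: bool = False) -> Connectome:
    """Load a connectome from a ``.npz`` archive or a pair of CSV/TSV files.

    For CSV/TSV input, ``path`` points at the weight matrix and a sibling
    file with suffix ``_lengths`` holds the tract lengths (same delimiter).
    An optional header row carries region labels.  ``rescale=True`` divides
    weights by their maximum before validation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"connectome file not found: {path}")
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as arc:
            W = np.asarray(arc["weights"], dtype=float)
            L = np.asarray(arc["tract_lengths"], dtype=float)
            labels = [str(x) for x in arc["labels"]] if "labels" in arc else []
    else:
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        W, labels = _read_matrix(path, sep)
        lpath = path.with_name(path.stem + "_lengths" + path.suffix)
        if not lpath.exists():
            raise FileNotFoundError(f"tract-length file not found: {lpath}")
        L, _ = _read_matrix(lpath, sep)
    if rescale and W.size and np.nanmax(W) > 0:
        W = W / np.nanmax(W)
    return Connectome(weights=W, tract_lengths=L, labels=labels)


def _read_matrix(path: Path, sep: str) -> tuple[np.ndarray, list[str]]:
    head = pd.read_csv(path, sep=sep, header=None, nrows=1)
    has_header = head.iloc[0].map(lambda v: isinstance(v, str)).any()
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    labels = [str(c) for c in df.columns] if has_header else []
    return df.to_numpy(dtype=float), labels


def save_connectome(c: Connectome, path) -> Path:
    """Write a connectome to a compressed archive (round-trips bit-exactly)."""
    path = Path(path)
    np.savez_compressed(
        path,
        weights=c.weights,
        tract_lengths=c.tract_lengths,
        labels=np.asarray(c.labels),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def compute_delays(c: Connectome, speed: float = 4.0, dt: float = 1.0) -> DelayTable:
    """Convert tract lengths to integer-step delays.

    ``delay = l[mm] / speed[m/s]`` gives milliseconds directly
    (mm / (m/s) = ms); dividing by the step ``dt`` (ms) and rounding to the
    nearest integer (ties to even) gives steps.
    """
    if speed <= 0:
        raise ValueError(f"conduction speed must be positive, got {speed}")
    if dt <= 0:
        raise ValueError(f"step size must be positive, got {dt}")
    delay_ms = c.tract_lengths / speed
    steps = np.rint(delay_ms / dt).astype(np.int64)
    return DelayTable(delays_steps=steps, speed=speed, dt=dt)


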