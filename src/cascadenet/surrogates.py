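"""Null models for BOLD dynamics.

Three surrogates, ordered by how much structure they keep:

* ``time_shuffle`` — one random permutation of frames applied to all
  regions; destroys temporal order, keeps every instantaneous FC and hence
  the static FC exactly.
* ``phase_randomize(preserve_cross_spectrum=True)`` — adds one shared
  random phase per frequency to every region's Fourier transform; imposes
  strict stationarity while preserving each region's power spectrum, all
  cross-spectral phase differences and thus the static FC.
* ``phase_randomize(preserve_cross_spectrum=False)`` — independent phase
  draws per region; additionally destroys inter-regional correlations and
  normalises the fat tail of the co-activation amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .hemodynamics import BoldSeries

__all__ = ["SurrogateConfig", "time_shuffle", "phase_randomize", "surrogate_stream"]


@dataclass(frozen=True)
class SurrogateConfig:
    kind: str = "phase_independent"  # time_shuffle | phase_uniform | phase_independent
    n_surrogates: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("time_shuffle", "phase_uniform", "phase_independent"):
            raise ValueError(f"unknown surrogate kind {self.kind!r}")
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")


def time_shuffle(B: BoldSeries, seed=0, rng=None) -> BoldSeries:
    """Permute frame order jointly across regions."""
    rng = np.random.default_rng(seed) if rng is None else rng
    perm = rng.permutation(B.n_frames)
    return BoldSeries(B=B.B[:, perm], TR=B.TR, burn_in_frames=B.burn_in_frames)


def phase_randomize(B: BoldSeries, preserve_cross_spectrum: bool = True,
                    seed=0, rng=None) -> BoldSeries:
    """Phase-randomised surrogate (real-valued by Hermitian symmetry).

    DC is untouched; for even lengths the Nyquist bin keeps phase 0.  With
    ``preserve_cross_spectrum`` a single phase draw is applied to all
    regions, otherwise each region gets an independent draw.
    """
    if B.n_frames < 8:
        raise ValueError("need at least 8 frames for phase randomisation")
    rng = np.random.default_rng(seed) if rng is None else rng
    X = np.asarray(B.B, dtype=float)
    n_regions, T = X.shape
    F = np.fft.rfft(X, axis=1)
    n_bins = F.shape[1]
    # bins whose phase may be rotated: exclude DC and (for even T) Nyquist
    hi = n_bins - 1 if T % 2 == 0 else n_bins
    n_free = hi - 1
    if preserve_cross_spectrum:
        phases = rng.uniform(0, 2 * np.pi, size=n_free)[None, :]
    else:
        phases = rng.uniform(0, 2 * np.pi, size=(n_regions, n_free))
    F[:, 1:hi] *= np.exp(1j * phases)
    Y = np.fft.irfft(F, n=T, axis=1)
    return BoldSeries(B=Y, TR=B.TR, burn_in_frames=B.burn_in_frames)


def surrogate_stream(B: BoldSeries, cfg: SurrogateConfig) -> Iterator[BoldSeries]:
    """Lazily yield ``cfg.n_surrogates`` surrogates from independent
    substreams of a single seeded generator (constant memory)."""
    root = np.random.default_rng(cfg.seed)
    for _ in range(cfg.n_surrogates):
        sub = np.random.default_rng(root.integers(0, 2**63))
        if cfg.kind == "time_shuffle":
            yield time_shuffle(B, rng=sub)
        elif cfg.kind == "phase_uniform":
            yield phase_randomize(B, preserve_cross_spectrum=True, rng=sub)
        else:
            yield phase_randomize(B, preserve_cross_spectrum=False, rng=sub)
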