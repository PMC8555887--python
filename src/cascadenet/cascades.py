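"""Neuronal cascades and avalanches from fast neuroelectric signals.

Each region's signal is z-scored over the analysed segment and binarised at
|z| > 3 (two-sided); avalanches are maximal runs of consecutive samples
with at least one active region.  Summing the binary raster over regions
gives the deviation magnitude; Gaussian-smoothing that count (kernel SD =
one BOLD TR by default) and bin-averaging down to the BOLD frame rate gives
the slow cascade signal, which can be compared directly with BOLD
co-activation amplitudes.  Cascades are therefore the slow clustering of
fast avalanches.

Node classification (D / U / J / D* / U*) summarises how each simulated
region uses its bistability: permanently down, permanently up, regularly
jumping, or mostly-stable with rare >3-sigma excursions (the starred
classes, which seed the large cascades).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .neural_mass import NodeParams, fixed_points
from .network import RawTimeseries

__all__ = [
    "CascadeConfig", "CascadeSignal", "AvalancheCatalog", "Avalanche",
    "NodeClassification", "binarize", "cascade_magnitude",
    "smooth_downsample", "detect_avalanches", "classify_nodes",
    "cascade_signal_from_raw",
]


class DegenerateSignalError(ValueError):
    pass


@dataclass(frozen=True)
class CascadeConfig:
    """Parameters of the cascade extraction.

    ``kernel_width`` is the SD of the Gaussian smoother in seconds (the
    BOLD TR by default); set ``kernel_is_fwhm=True`` to interpret it as the
    full width at half maximum instead.
    """

    z_threshold: float = 3.0
    kernel_width: float = 2.0  # s
    target_rate: float = 0.5  # Hz, BOLD frame rate
    kernel_is_fwhm: bool = False

    def __post_init__(self):
        if self.z_threshold <= 0 or self.kernel_width <= 0:
            raise ValueError("z_threshold and kernel_width must be positive")


@dataclass(frozen=True)
class CascadeSignal:
    magnitude_raw: np.ndarray  # per fast sample, region count
    magnitude_bold: np.ndarray  # smoothed + downsampled to the BOLD clock
    fast_rate: float  # Hz
    config: CascadeConfig


@dataclass(frozen=True)
class Avalanche:
    start_sample: int
    lifetime_samples: int
    size: int
    regions: frozenset


@dataclass(frozen=True)
class AvalancheCatalog:
    avalanches: list[Avalanche] = field(default_factory=list)

    def __len__(self):
        return len(self.avalanches)

    def __iter__(self):
        return iter(self.avalanches)


@dataclass(frozen=True)
class NodeClassification:
    labels: list[str]  # D | U | J | D* | U*
    up_occupancy: np.ndarray
    n_threshold_crossings: np.ndarray  # excursions with |z| > 3
    n_state_jumps: np.ndarray


def binarize(X: np.ndarray, cfg: CascadeConfig = CascadeConfig()) -> np.ndarray:
    """Two-sided threshold raster: 1 where |z| exceeds ``z_threshold``.

    z-scores use the population SD of each region over the whole analysed
    segment (per-trial standardisation).
    """
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateSignalError(f"region {bad[0]} is constant")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    return (np.abs(Z) > cfg.z_threshold).astype(np.uint8)


def cascade_magnitude(raster: np.ndarray) -> np.ndarray:
    """Number of simultaneously deviating regions per sample."""
    return np.asarray(raster).sum(axis=0)


def smooth_downsample(magnitude: np.ndarray, cfg: CascadeConfig,
                      fast_rate: float) -> np.ndarray:
    """Gaussian-smooth the fast magnitude and average into TR bins.

    The kernel SD is ``kernel_width`` seconds expressed in fast samples
    (truncated at 4 SD, reflective boundaries); a constant input is mapped
    to itself.  Downsampling averages consecutive bins of
    ``fast_rate / target_rate`` samples (decimation-free, so it is robust
    to phase alignment between the fast and BOLD clocks).
    """
    if cfg.target_rate > fast_rate:
        raise ValueError("target rate exceeds the fast sampling rate")
    width_s = cfg.kernel_width
    if cfg.kernel_is_fwhm:
        width_s = width_s / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma = width_s * fast_rate
    sm = gaussian_filter1d(np.asarray(magnitude, dtype=float), sigma=sigma,
                           mode="reflect", truncate=4.0)
    bin_len = int(round(fast_rate / cfg.target_rate))
    n_bins = sm.size // bin_len
    if n_bins == 0:
        raise ValueError("signal shorter than one BOLD frame")
    return sm[: n_bins * bin_len].reshape(n_bins, bin_len).mean(axis=1)


def detect_avalanches(raster: np.ndarray) -> AvalancheCatalog:
    """Maximal runs of consecutive samples with any active region."""
    raster = np.asarray(raster)
    active = raster.any(axis=0)
    padded = np.concatenate(([False], active, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    avs = []
    for s, e in zip(starts, ends):
        regions = frozenset(np.flatnonzero(raster[:, s:e].any(axis=1)).tolist())
        avs.append(Avalanche(start_sample=int(s), lifetime_samples=int(e - s),
                             size=len(regions), regions=regions))
    return AvalancheCatalog(avalanches=avs)


def cascade_signal_from_raw(X: np.ndarray, fast_rate: float,
                            cfg: CascadeConfig = CascadeConfig()) -> CascadeSignal:
    """Full pipeline: binarise, region-sum, smooth, downsample."""
    raster = binarize(X, cfg)
    mag = cascade_magnitude(raster)
    mb = smooth_downsample(mag, cfg, fast_rate)
    return CascadeSignal(magnitude_raw=mag, magnitude_bold=mb,
                         fast_rate=fast_rate, config=cfg)


def _count_excursions(z: np.ndarray, thr: float, min_samples: int = 1) -> int:
    """Number of contiguous |z|>thr excursions lasting >= min_samples."""
    above = np.abs(z) > thr
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return int(np.sum(edges[1::2] - edges[::2] >= min_samples))


def _count_jumps_hysteresis(r: np.ndarray, low: float, high: float) -> int:
    """Up/down transitions with a hysteresis band [low, high]."""
    state = r[0] > 0.5 * (low + high)
    jumps = 0
    for x in r:
        if state and x < low:
            state = False
            jumps += 1
        elif not state and x > high:
            state = True
            jumps += 1
    return jumps


def classify_nodes(raw: RawTimeseries, p: NodeParams = NodeParams(),
                   z_threshold: float = 3.0, eps: float = 0.01,
                   theta_j: float = 0.1, hysteresis: float = 0.2,
                   min_duration_s: float = 60.0,
                   min_excursion_ms: float = 20.0) -> NodeClassification:
    """Label each simulated region as D, U, J, D* or U*.

    Occupancy uses a rate threshold at the midpoint between the uncoupled
    down and up equilibrium rates; starred classes are those with at least
    one |z| > ``z_threshold`` excursion of the firing rate sustained for
    ``min_excursion_ms`` (single-sample noise spikes are not state events).
    ``eps``,
    ``theta_j`` and the ``hysteresis`` band (as a fraction of the
    equilibrium rate gap) are package conventions; the classes themselves
    are defined qualitatively.
    """
    b = raw.burn_in_samples()
    if (raw.n_samples - b) / raw.rate_hz < min_duration_s:
        raise ValueError(f"need >= {min_duration_s}s after burn-in for occupancy")
    pp = fixed_points(p, I=0.0)
    stable = [e for e in pp.equilibria if e.kind.startswith("stable")]
    if len(stable) < 2:
        raise ValueError("node classification requires bistability at I=0")
    r_dn, r_up = stable[0].r_star, stable[-1].r_star
    mid = 0.5 * (r_dn + r_up)
    band = hysteresis * (r_up - r_dn)
    R = np.asarray(raw.r[:, b:], dtype=float)
    sd = R.std(axis=1)
    sd[sd == 0] = 1.0
    Z = (R - R.mean(axis=1, keepdims=True)) / sd[:, None]

    labels, occs, crossings, jumps = [], [], [], []
    for i in range(R.shape[0]):
        occ = float(np.mean(R[i] > mid))
        min_samp = max(1, int(round(min_excursion_ms * raw.rate_hz / 1000.0)))
        ncross = _count_excursions(Z[i], z_threshold, min_samp)
        njump = _count_jumps_hysteresis(R[i], mid - band / 2, mid + band / 2)
        if ncross >= 1:
            lab = "U*" if occ >= 0.5 else "D*"
        elif occ > 1 - eps:
            lab = "U"
        elif occ < eps:
            lab = "D"
        elif min(occ, 1 - occ) > theta_j:
            lab = "J"
        else:
            # occupancy in the narrow band between eps and theta_j without
            # 3-sigma events: nearest stable class
            lab = "D" if occ < 0.5 else "U"
        labels.append(lab)
        occs.append(occ)
        crossings.append(ncross)
        jumps.append(njump)
    return NodeClassification(labels=labels, up_occupancy=np.array(occs),
                              n_threshold_crossings=np.array(crossings),
                              n_state_jumps=np.array(jumps))
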