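"""Synthetic stand-ins for the study's data.

Two generators:

* :func:`generate_connectome` builds tracer-like connectomes — directed,
  modular, with log-normally distributed weights max-normalised to [0, 1]
  and tract lengths given by Euclidean distances of random region
  coordinates in a box.  The heavy-tailed weights give regions strongly
  heterogeneous in-strengths, which is what lets the coupled network split
  into persistently-up and persistently-down subsets.

* :func:`generate_planted_trial` emulates a simultaneous EEG/fMRI trial
  with known ground truth: unit-variance background noise per region at the
  fast rate, supra-threshold cascade events at Poisson times (a random
  region subset steps up by a set z-amplitude for 50-200 ms, with 10 ms
  ramps), and a BOLD counterpart in which a controllable fraction
  (``coupling``) of the events drives the involved regions through the
  package's own hemodynamic model, plus independent frame noise.  The truth
  table lists event times, regions, coupling flags and the planted
  hemodynamic lag, so recovery experiments can score the analysis pipeline
  end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import Connectome
from .hemodynamics import BoldSeries, HemodynamicParams, _balloon_rk4, impulse_response

__all__ = [
    "SynthConnectomeSpec", "PlantedTrialSpec",
    "generate_connectome", "generate_planted_trial", "demo_connectome",
]


@dataclass(frozen=True)
class SynthConnectomeSpec:
    """Tracer-like connectome parameters.

    Densities are probabilities of a directed edge existing within /
    between modules; nonzero weights are log-normal (``weight_mu``,
    ``weight_sigma`` on the log scale) then divided by the maximum.
    """

    n_regions: int = 104
    n_modules: int = 4
    intra_density: float = 0.8
    inter_density: float = 0.3
    weight_mu: float = -3.5
    weight_sigma: float = 1.2
    intra_weight_boost: float = 2.0  # added to weight_mu inside modules:
    # tracer connectomes have within-system projections roughly an order of
    # magnitude stronger than between-system ones
    box_mm: float = 40.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.intra_density <= 1 and 0 <= self.inter_density <= 1):
            raise ValueError("densities must lie in [0, 1]")
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")


def generate_connectome(spec: SynthConnectomeSpec = SynthConnectomeSpec()) -> Connectome:
    rng = np.random.default_rng(spec.seed)
    n = spec.n_regions
    module = np.arange(n) % spec.n_modules
    same = module[:, None] == module[None, :]
    density = np.where(same, spec.intra_density, spec.inter_density)
    mask = rng.random((n, n)) < density
    np.fill_diagonal(mask, False)
    mu = np.where(same, spec.weight_mu + spec.intra_weight_boost, spec.weight_mu)
    W = np.zeros((n, n))
    W[mask] = rng.lognormal(mu[mask], spec.weight_sigma)
    if W.max() > 0:
        W = W / W.max()
    coords = rng.uniform(0, spec.box_mm, size=(n, 3))
    diff = coords[:, None, :] - coords[None, :, :]
    L = np.sqrt((diff**2).sum(axis=2))
    labels = [f"region_{i:03d}_m{module[i]}" for i in range(n)]
    return Connectome(weights=W, tract_lengths=L, labels=labels)


def demo_connectome(n_regions: int = 104, seed: int = 0) -> Connectome:
    """The package's default synthetic substrate (fixed generator settings)."""
    return generate_connectome(SynthConnectomeSpec(n_regions=n_regions, seed=seed))


@dataclass(frozen=True)
class PlantedTrialSpec:
    """Ground-truth trial parameters (defaults emulate a human EEG/fMRI
    trial: 200 Hz source-space EEG against TR = 1.94 s BOLD)."""

    n_regions: int = 68
    duration: float = 300.0  # s
    fast_rate: float = 200.0  # Hz
    TR: float = 1.94  # s
    event_rate: float = 3.0  # events / min
    event_region_fraction: float = 0.25
    event_z_amplitude: float = 6.0
    hemodynamic_lag: int = 0  # extra pure delay, BOLD frames
    coupling: float = 1.0
    eeg_noise: float = 1.0  # background SD (amplitude units)
    bold_noise: float = 0.1  # frame-noise SD relative to the HRF peak
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.coupling <= 1):
            raise ValueError("coupling must lie in [0, 1]")
        if self.event_z_amplitude <= 0:
            raise ValueError("event_z_amplitude must be positive")


def _event_pulse(n_samples: int, ramp_samples: int) -> np.ndarray:
    """Rectangular pulse with linear 10 ms ramps."""
    pulse = np.ones(n_samples)
    r = min(ramp_samples, n_samples // 2)
    if r > 0:
        ramp = np.linspace(0, 1, r + 2)[1:-1]
        pulse[:r] = ramp
        pulse[-r:] = ramp[::-1]
    return pulse


def generate_planted_trial(spec: PlantedTrialSpec = PlantedTrialSpec()):
    """Return ``(eeg, bold, truth)``.

    ``eeg`` is a region-by-sample array at ``fast_rate``; ``bold`` a
    :class:`BoldSeries`; ``truth`` a DataFrame with one row per planted
    event (onset time/sample, duration, regions, whether BOLD-coupled) and
    the planted lag in frames stored in ``truth.attrs``.

    Changing ``coupling`` alone leaves the EEG bit-identical: the EEG, the
    coupling mask and the BOLD noise use independent child seeds.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_eeg, rng_mask, rng_bold = (np.random.default_rng(s) for s in ss.spawn(3))

    n_fast = int(round(spec.duration * spec.fast_rate))
    n = spec.n_regions
    eeg = rng_eeg.normal(0, spec.eeg_noise, size=(n, n_fast))

    n_events = rng_eeg.poisson(spec.event_rate * spec.duration / 60.0)
    onsets = np.sort(rng_eeg.uniform(0, spec.duration, size=n_events))
    durations = rng_eeg.uniform(0.05, 0.2, size=n_events)  # 50-200 ms
    n_ev_regions = max(1, int(round(spec.event_region_fraction * n)))
    ramp = int(round(0.010 * spec.fast_rate))

    covered = np.zeros(n_fast, dtype=bool)
    rows = []
    drive = np.zeros((n, n_fast))  # neural drive of *coupled* events only
    coupled_mask = rng_mask.random(n_events) < spec.coupling
    for k in range(n_events):
        s0 = int(round(onsets[k] * spec.fast_rate))
        length = max(1, int(round(durations[k] * spec.fast_rate)))
        s1 = min(n_fast, s0 + length)
        if s1 <= s0:
            continue
        regions = rng_eeg.choice(n, size=n_ev_regions, replace=False)
        pulse = _event_pulse(s1 - s0, ramp)
        eeg[regions, s0:s1] += spec.event_z_amplitude * pulse[None, :]
        covered[s0:s1] = True
        if coupled_mask[k]:
            drive[regions, s0:s1] += pulse[None, :]
        rows.append({
            "onset_s": onsets[k], "onset_sample": s0,
            "duration_s": durations[k],
            "regions": ",".join(map(str, sorted(regions.tolist()))),
            "bold_coupled": bool(coupled_mask[k]),
        })
    if covered.mean() > 0.5:
        raise ValueError(
            f"events cover {covered.mean():.0%} of samples; lower event_rate"
        )

    hp = HemodynamicParams(TR=spec.TR)
    dt_s = 1.0 / spec.fast_rate
    B_full = _balloon_rk4(drive, dt_s, hp.kappa, hp.gamma, hp.tau0, hp.alpha,
                          hp.E0, hp.V0, hp.k1, hp.k2, hp.k3)
    frame_step = int(round(spec.TR * spec.fast_rate))
    B = B_full[:, frame_step - 1 :: frame_step]
    if spec.hemodynamic_lag > 0:
        B = np.concatenate(
            [np.zeros((n, spec.hemodynamic_lag)), B[:, : -spec.hemodynamic_lag]],
            axis=1,
        )
    t_ir, ir = impulse_response(hp)
    hrf_peak_s = float(t_ir[int(np.argmax(ir))])
    noise_scale = spec.bold_noise * float(np.max(np.abs(ir)))
    B = B + rng_bold.normal(0, noise_scale, size=B.shape)
    bold = BoldSeries(B=B, TR=spec.TR, burn_in_frames=0)

    truth = pd.DataFrame(rows, columns=["onset_s", "onset_sample", "duration_s",
                                        "regions", "bold_coupled"])
    truth.attrs["planted_lag_frames"] = int(round(hrf_peak_s / spec.TR)) + spec.hemodynamic_lag
    truth.attrs["hrf_peak_s"] = hrf_peak_s
    return eeg, bold, truth
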