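"""Balloon-Windkessel hemodynamic forward model.

Maps a fast neural drive to a slow BOLD signal through the canonical
four-state system (vasodilatory signal s, blood inflow f, venous volume v,
deoxyhemoglobin content q)::

    ds/dt = u(t) - kappa * s - gamma * (f - 1)
    df/dt = s
    tau0 * dv/dt = f - v**(1/alpha)
    tau0 * dq/dt = f * (1 - (1 - E0)**(1/f)) / E0 - v**(1/alpha) * q / v

    BOLD = V0 * (k1 * (1 - q) + k2 * (1 - q/v) + k3 * (1 - v))

The drive u(t) is the per-region z-scored membrane potential (the raw
potential is negative at rest; the hemodynamic system expects a
zero-baseline input), integrated with fixed-step RK4 at the raw sampling
rate and subsampled at each TR boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .network import RawTimeseries

__all__ = ["HemodynamicParams", "BoldSeries", "bold_transform", "impulse_response"]


class HemodynamicError(RuntimeError):
    pass


@dataclass(frozen=True)
class HemodynamicParams:
    """Canonical constants (Friston-style defaults); rates in 1/s, times in s."""

    kappa: float = 0.65
    gamma: float = 0.41
    tau0: float = 0.98
    alpha: float = 0.32
    E0: float = 0.4
    V0: float = 0.04
    k1: float = 7 * 0.4
    k2: float = 2.0
    k3: float = 2 * 0.4 - 0.2
    TR: float = 2.0

    def __post_init__(self):
        if min(self.kappa, self.gamma, self.tau0, self.TR) <= 0:
            raise ValueError("rates and times must be positive")
        if not (0 < self.E0 < 1):
            raise ValueError("E0 must be in (0, 1)")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")


@dataclass(frozen=True)
class BoldSeries:
    """Region-by-frame BOLD (unitless signal change) at the TR rate."""

    B: np.ndarray  # region x frame
    TR: float  # s
    burn_in_frames: int = 0  # frames already dropped from B

    @property
    def n_regions(self) -> int:
        return self.B.shape[0]

    @property
    def n_frames(self) -> int:
        return self.B.shape[1]


@njit(cache=True)
def _balloon_rk4(U, dt_s, kappa, gamma, tau0, alpha, E0, V0, k1, k2, k3):
    n, T = U.shape
    B = np.empty((n, T))
    ia = 1.0 / alpha
    for i in range(n):
        s = 0.0
        f = 1.0
        v = 1.0
        q = 1.0
        for t in range(T):
            u = U[i, t]
            # RK4 on the 4-state system with drive held constant over dt
            s1, f1, v1, q1 = _deriv(u, s, f, v, q, kappa, gamma, tau0, ia, E0)
            s2, f2, v2, q2 = _deriv(u, s + 0.5 * dt_s * s1, f + 0.5 * dt_s * f1,
                                    v + 0.5 * dt_s * v1, q + 0.5 * dt_s * q1,
                                    kappa, gamma, tau0, ia, E0)
            s3, f3, v3, q3 = _deriv(u, s + 0.5 * dt_s * s2, f + 0.5 * dt_s * f2,
                                    v + 0.5 * dt_s * v2, q + 0.5 * dt_s * q2,
                                    kappa, gamma, tau0, ia, E0)
            s4, f4, v4, q4 = _deriv(u, s + dt_s * s3, f + dt_s * f3,
                                    v + dt_s * v3, q + dt_s * q3,
                                    kappa, gamma, tau0, ia, E0)
            s += dt_s * (s1 + 2 * s2 + 2 * s3 + s4) / 6.0
            f += dt_s * (f1 + 2 * f2 + 2 * f3 + f4) / 6.0
            v += dt_s * (v1 + 2 * v2 + 2 * v3 + v4) / 6.0
            q += dt_s * (q1 + 2 * q2 + 2 * q3 + q4) / 6.0
            if v < 1e-6:
                v = 1e-6
            if q < 1e-6:
                q = 1e-6
            if f < 1e-6:
                f = 1e-6
            if not (np.isfinite(s) and np.isfinite(v) and np.isfinite(q)):
                B[i, 0] = np.nan
                B[i, min(1, T - 1)] = t
                return B
            B[i, t] = V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
    return B


@njit(cache=True, inline="always")
def _deriv(u, s, f, v, q, kappa, gamma, tau0, ia, E0):
    if f < 1e-6:
        f = 1e-6
    if v < 1e-6:
        v = 1e-6
    ds = u - kappa * s - gamma * (f - 1.0)
    df = s
    via = v ** ia
    dv = (f - via) / tau0
    dq = (f * (1.0 - (1.0 - E0) ** (1.0 / f)) / E0 - via * q / v) / tau0
    return ds, df, dv, dq


def _zscore_drive(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0  # constant drive -> zero input (resting steady state)
    return (X - mu) / sd


def bold_transform(raw: RawTimeseries, hp: HemodynamicParams = HemodynamicParams(),
                   drive: str = "V_zscored", burn_in_frames: int = 10) -> BoldSeries:
    """Integrate the hemodynamic system per region and sample at the TR.

    ``drive`` selects the z-scored membrane potential (default) or the
    z-scored firing rate.  The first ``burn_in_frames`` frames are dropped
    to discard the hemodynamic transient.
    """
    if drive == "V_zscored":
        U = _zscore_drive(np.asarray(raw.V, dtype=float))
    elif drive == "r_zscored":
        U = _zscore_drive(np.asarray(raw.r, dtype=float))
    else:
        raise ValueError(f"unknown drive {drive!r}")
    dt_s = raw.dt_record / 1000.0
    frame_step = int(round(hp.TR / dt_s))
    if U.shape[1] < 2 * frame_step:
        raise ValueError(
            f"need at least 2 TR of data ({2 * frame_step} samples), got {U.shape[1]}"
        )
    B_full = _balloon_rk4(U, dt_s, hp.kappa, hp.gamma, hp.tau0, hp.alpha,
                          hp.E0, hp.V0, hp.k1, hp.k2, hp.k3)
    if np.isnan(B_full[:, 0]).any():
        i = int(np.flatnonzero(np.isnan(B_full[:, 0]))[0])
        raise HemodynamicError(f"hemodynamic state diverged in region {i}")
    # sample at TR boundaries: frames at raw indices frame_step-1, 2*frame_step-1, ...
    B = B_full[:, frame_step - 1 :: frame_step]
    if burn_in_frames >= B.shape[1]:
        raise ValueError("burn_in_frames leaves no BOLD frames")
    return BoldSeries(B=np.ascontiguousarray(B[:, burn_in_frames:]),
                      TR=hp.TR, burn_in_frames=burn_in_frames)


def impulse_response(hp: HemodynamicParams = HemodynamicParams(),
                     dt_s: float = 0.01, duration_s: float = 30.0,
                     impulse_s: float = 0.1):
    """BOLD response to a brief unit impulse; returns (t_seconds, response).

    Used by the synthetic-data generator to plant a self-consistent
    hemodynamic lag: the peak latency of this curve is the expected lag
    between a neural event and its BOLD expression.
    """
    T = int(round(duration_s / dt_s))
    U = np.zeros((1, T))
    U[0, : max(1, int(round(impulse_s / dt_s)))] = 1.0
    B = _balloon_rk4(U, dt_s, hp.kappa, hp.gamma, hp.tau0, hp.alpha,
                     hp.E0, hp.V0, hp.k1, hp.k2, hp.k3)
    t = (np.arange(T) + 1) * dt_s
    return t, B[0]
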