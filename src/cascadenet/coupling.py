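"""Cascade-to-BOLD-co-activation coupling statistics.

The lagged cross-correlation between the slow cascade magnitude C(t) and
the co-activation amplitude R(t) (the RSS of the edge series) quantifies
whether strong neuroelectric deviations precede strong BOLD co-activation.
The lag convention is ``rho(l) = Pearson(C(t), R(t - l))`` on the
overlapping support, so a *negative* lag compares the cascade with later
BOLD — hemodynamics makes the profile peak at negative lags.

Significance is assessed against surrogate BOLD ensembles: for each
surrogate the edge series, RSS and lag profile are recomputed from scratch
and the mean, maximum and variance of the profile build null distributions;
one-sided p-values use the standard +1 permutation correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fc import edge_timeseries, rss
from .hemodynamics import BoldSeries
from .surrogates import SurrogateConfig, surrogate_stream

__all__ = [
    "LagCorrelationProfile", "NullTestResult",
    "lagged_crosscorr", "profile_stats", "surrogate_null_test", "cohort_average",
]


@dataclass(frozen=True)
class LagCorrelationProfile:
    lags: np.ndarray  # frame offsets, -L..L
    rho: np.ndarray
    zero_variance_flag: bool = False

    @property
    def peak_lag(self) -> int:
        return int(self.lags[int(np.argmax(self.rho))])


@dataclass(frozen=True)
class NullTestResult:
    observed: dict  # mean / max / variance of the observed profile
    null: dict  # stat name -> array of surrogate values
    p_values: dict  # stat name -> one-sided exceedance p
    kind: str
    n_surrogates: int


def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0, True
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb)), False


def lagged_crosscorr(C: np.ndarray, R: np.ndarray, max_lag: int = 15) -> LagCorrelationProfile:
    """Correlation profile over lags -max_lag..max_lag (frames).

    Computed on the overlapping segment only (no zero padding); a
    zero-variance overlap yields rho = 0 with a flag.
    """
    C = np.asarray(C, dtype=float)
    R = np.asarray(R, dtype=float)
    if C.shape != R.shape:
        raise ValueError(f"length mismatch: {C.shape} vs {R.shape}")
    if C.size < 3 * max_lag:
        raise ValueError(f"need >= {3 * max_lag} frames for max_lag={max_lag}")
    lags = np.arange(-max_lag, max_lag + 1)
    rho = np.empty(lags.size)
    flag = False
    for k, l in enumerate(lags):
        if l < 0:
            a, b = C[: l or None], R[-l:]
        elif l > 0:
            a, b = C[l:], R[:-l]
        else:
            a, b = C, R
        rho[k], f = _pearson(a, b)
        flag |= f
    return LagCorrelationProfile(lags=lags, rho=rho, zero_variance_flag=flag)


def profile_stats(profile: LagCorrelationProfile) -> dict:
    return {
        "mean": float(np.mean(profile.rho)),
        "max": float(np.max(profile.rho)),
        "variance": float(np.var(profile.rho)),
    }


def surrogate_null_test(C: np.ndarray, B: BoldSeries,
                        cfg: SurrogateConfig = SurrogateConfig(),
                        max_lag: int = 15) -> NullTestResult:
    """Test the observed profile statistics against one surrogate ensemble."""
    observed = profile_stats(lagged_crosscorr(C, rss(edge_timeseries(B)), max_lag))
    null = {k: np.empty(cfg.n_surrogates) for k in observed}
    for i, S in enumerate(surrogate_stream(B, cfg)):
        stats = profile_stats(lagged_crosscorr(C, rss(edge_timeseries(S)), max_lag))
        for k in null:
            null[k][i] = stats[k]
    p = {
        k: float((1 + np.sum(null[k] >= observed[k])) / (1 + cfg.n_surrogates))
        for k in observed
    }
    return NullTestResult(observed=observed, null=null, p_values=p,
                          kind=cfg.kind, n_surrogates=cfg.n_surrogates)


def cohort_average(profiles: list[LagCorrelationProfile],
                   fisher_z: bool = False) -> tuple[LagCorrelationProfile, np.ndarray]:
    """Lag-wise mean profile and per-lag SD across trials.

    Trials must share the lag grid.  ``fisher_z`` averages arctanh-
    transformed correlations and maps the mean back through tanh.
    """
    if not profiles:
        raise ValueError("no profiles")
    lags = profiles[0].lags
    for p in profiles[1:]:
        if not np.array_equal(p.lags, lags):
            raise ValueError("profiles have different lag grids")
    R = np.array([p.rho for p in profiles])
    if fisher_z:
        Z = np.arctanh(np.clip(R, -1 + 1e-12, 1 - 1e-12))
        mean = np.tanh(Z.mean(axis=0))
    else:
        mean = R.mean(axis=0)
    sd = R.std(axis=0)
    return LagCorrelationProfile(lags=lags, rho=mean), sd
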