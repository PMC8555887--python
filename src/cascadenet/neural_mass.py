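"""Exact mean-field model of a quadratic integrate-and-fire population.

A brain region is modelled by the exact thermodynamic limit of infinitely
many all-to-all coupled QIF neurons with Lorentzian-distributed
excitabilities.  The population state is the mean firing rate ``r`` and the
mean membrane potential ``V``::

    tau_c * dr/dt = Delta / pi + 2 r V
    tau_c * dV/dt = V**2 + eta + J r - pi**2 r**2 + I

With the default parameters (J=14.5, eta=-4.6, Delta=0.7, tau_c=1) a
decoupled node (I=0) is bistable: a low-rate "down" stable node coexists
with a high-rate "up" stable focus, separated by a saddle.  An external
current I shifts the V-nullcline branches apart, moving the separatrix and
eventually annihilating the down state in a saddle-node bifurcation.

The reduction preserves an analytic Kuramoto order parameter through the
conformal map ``Z = (1 - conj(w)) / (1 + conj(w))`` with ``w = pi r + i V``,
so the internal synchrony of the population remains observable.

A finite-size QIF ensemble integrator is included as an independent check
that the mean-field fixed points are recovered in the large-N limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "NodeParams",
    "Equilibrium",
    "PhasePortrait",
    "KuramotoState",
    "QifEnsembleParams",
    "drift",
    "fixed_points",
    "nullclines",
    "kuramoto",
    "simulate_qif_ensemble",
]


@dataclass(frozen=True)
class NodeParams:
    """Parameters of a single mean-field node (all unitless; tau_c in the
    simulation's time unit)."""

    J: float = 14.5
    eta: float = -4.6
    Delta: float = 0.7
    tau_c: float = 1.0

    def __post_init__(self):
        if self.Delta <= 0:
            raise ValueError("Delta must be positive")
        if self.tau_c <= 0:
            raise ValueError("tau_c must be positive")


@dataclass(frozen=True)
class Equilibrium:
    r_star: float
    V_star: float
    kind: str  # stable_node | stable_focus | saddle | unstable_node | unstable_focus
    eigenvalues: tuple[complex, complex]
    marginal: bool = False


@dataclass(frozen=True)
class PhasePortrait:
    input_current: float
    equilibria: list[Equilibrium] = field(default_factory=list)

    @property
    def n_equilibria(self) -> int:
        return len(self.equilibria)

    def to_dict(self) -> dict:
        return {
            "input_current": self.input_current,
            "equilibria": [
                {
                    "r": e.r_star,
                    "V": e.V_star,
                    "kind": e.kind,
                    "eigenvalues": [[l.real, l.imag] for l in e.eigenvalues],
                    "marginal": e.marginal,
                }
                for e in self.equilibria
            ],
        }


@dataclass(frozen=True)
class KuramotoState:
    K: float
    theta: float
    Z: complex
    w: complex


def drift(r, V, I, p: NodeParams = NodeParams()):
    """Vector field of the mean-field node; accepts scalars or arrays."""
    r = np.asarray(r, dtype=float)
    V = np.asarray(V, dtype=float)
    dr = (p.Delta / math.pi + 2.0 * r * V) / p.tau_c
    dV = (V * V + p.eta + p.J * r - math.pi**2 * r * r + I) / p.tau_c
    if dr.ndim == 0:
        return float(dr), float(dV)
    return dr, dV


def _rate_equation(r, p: NodeParams, I: float):
    """Fixed-point condition after substituting the r-nullcline
    V = -Delta / (2 pi r) into dV/dt = 0."""
    return p.Delta**2 / (4 * math.pi**2 * r * r) + p.eta + p.J * r - math.pi**2 * r * r + I


def fixed_points(p: NodeParams = NodeParams(), I: float = 0.0,
                 r_max: float = 10.0, n_grid: int = 4000) -> PhasePortrait:
    """Locate all equilibria of a node at external current ``I``.

    On the r-nullcline V = -Delta/(2 pi r), so equilibria are the positive
    roots of a single function of r.  Roots are bracketed by a sign-change
    scan over a log-spaced grid on [1e-6, r_max] and polished by bisection,
    then classified by the eigenvalues of the Jacobian
    ``[[2V, 2r], [J - 2 pi^2 r, 2V]] / tau_c``.
    """
    grid = np.geomspace(1e-6, r_max, n_grid)
    vals = _rate_equation(grid, p, I)
    roots = []
    for i in range(len(grid) - 1):
        a, b = grid[i], grid[i + 1]
        fa, fb = vals[i], vals[i + 1]
        if fa == 0.0:
            roots.append(a)
        elif fa * fb < 0:
            for _ in range(200):
                m = 0.5 * (a + b)
                fm = _rate_equation(m, p, I)
                if fm == 0.0 or (b - a) < 1e-14:
                    break
                if fa * fm < 0:
                    b = m
                else:
                    a, fa = m, fm
            roots.append(0.5 * (a + b))
    if vals[-1] == 0.0:
        roots.append(grid[-1])
    equilibria = []
    for r_star in roots:
        V_star = -p.Delta / (2 * math.pi * r_star)
        jac = np.array(
            [[2 * V_star, 2 * r_star],
             [p.J - 2 * math.pi**2 * r_star, 2 * V_star]]
        ) / p.tau_c
        lam = np.linalg.eigvals(jac)
        equilibria.append(_classify(r_star, V_star, lam))
    equilibria.sort(key=lambda e: e.r_star)
    return PhasePortrait(input_current=I, equilibria=equilibria)


def _classify(r_star, V_star, lam, tol=1e-9) -> Equilibrium:
    re = np.real(lam)
    im = np.imag(lam)
    marginal = bool(np.any(np.abs(re) < tol))
    complex_pair = bool(np.any(np.abs(im) > tol))
    if complex_pair:
        kind = "stable_focus" if re[0] < 0 else "unstable_focus"
    elif re[0] * re[1] < 0:
        kind = "saddle"
    else:
        kind = "stable_node" if re[0] < 0 else "unstable_node"
    if marginal and kind == "unstable_node":
        kind = "stable_node"  # nearest class at a saddle-node point
    return Equilibrium(
        r_star=float(r_star),
        V_star=float(V_star),
        kind=kind,
        eigenvalues=(complex(lam[0]), complex(lam[1])),
        marginal=marginal,
    )


def nullclines(p: NodeParams = NodeParams(), I: float = 0.0,
               r_range: np.ndarray | None = None):
    """Return the r-nullcline and the two branches of the V-nullcline.

    The r-nullcline is ``V = -Delta / (2 pi r)``.  The V-nullcline is the
    locus ``V^2 = -(eta + J r - pi^2 r^2 + I)``; where the right-hand side
    is negative the branch is absent (NaN).
    """
    if r_range is None:
        r_range = np.linspace(1e-3, 3.0, 400)
    r = np.asarray(r_range, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r_range must be positive")
    v_r = -p.Delta / (2 * math.pi * r)
    rhs = -(p.eta + p.J * r - math.pi**2 * r * r + I)
    v_plus = np.where(rhs >= 0, np.sqrt(np.clip(rhs, 0, None)), np.nan)
    return (r, v_r), (r, v_plus, -v_plus)


def kuramoto(r, V) -> KuramotoState:
    """Analytic Kuramoto order parameter of the population.

    ``w = pi r + i V``; ``Z = (1 - conj(w)) / (1 + conj(w))``.  For r >= 0,
    w lies in the right half-plane and the Moebius map sends it into the
    closed unit disk, so the synchrony K = |Z| is in [0, 1].
    """
    w = complex(math.pi * float(r), float(V))
    if not (np.isfinite(w.real) and np.isfinite(w.imag)):
        raise ValueError("non-finite (r, V)")
    denom = 1 + w.conjugate()
    if abs(denom) < 1e-15:
        raise ValueError("Kuramoto map pole at w = -1 (unreachable for r >= 0)")
    Z = (1 - w.conjugate()) / denom
    return KuramotoState(K=abs(Z), theta=math.atan2(Z.imag, Z.real), Z=Z, w=w)


@dataclass(frozen=True)
class QifEnsembleParams:
    """Finite-size QIF ensemble used as an oracle for the mean-field limit.

    The membrane-potential average excludes neurons inside a short
    refractory window around reset, where the divergence to +inf / reset to
    -inf makes the raw average ill-defined.
    """

    n_neurons: int = 10_000
    V_peak: float = 100.0
    eta_center: float = -4.6
    eta_width: float = 0.7
    J: float = 14.5
    tau_d: float = 1.0  # exponential rate-smoothing time, in tau_c units
    dt: float = 2.5e-4  # integration step, in tau_c units
    seed: int = 0
    eta_sampling: str = "quantile"  # quantile (stratified) | random

    def __post_init__(self):
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if self.V_peak <= 0:
            raise ValueError("V_peak must be positive")
        if self.tau_d <= 0:
            raise ValueError("tau_d must be positive")

    @property
    def V_reset(self) -> float:
        return -self.V_peak


@njit(cache=True)
def _qif_loop(V, eta, J, I_of_t, dt, V_peak, V_reset, tau_d, refrac_steps, s0):
    n_steps = I_of_t.shape[0]
    n = V.shape[0]
    r_hat = np.zeros(n_steps)
    V_hat = np.zeros(n_steps)
    s = s0  # smoothed population rate (synaptic activation)
    hold = np.zeros(n, dtype=np.int64)  # remaining refractory steps
    for t in range(n_steps):
        spikes = 0
        for i in range(n):
            if hold[i] > 0:
                hold[i] -= 1
                continue
            V[i] += dt * (V[i] * V[i] + eta[i] + J * s + I_of_t[t])
            if V[i] >= V_peak:
                V[i] = V_reset
                hold[i] = refrac_steps
                spikes += 1
        inst_rate = spikes / (n * dt)
        s += dt * (inst_rate - s) / tau_d
        vsum = 0.0
        vcount = 0
        for i in range(n):
            if hold[i] == 0:
                vsum += V[i]
                vcount += 1
        r_hat[t] = s
        V_hat[t] = vsum / vcount if vcount > 0 else 0.0
    return r_hat, V_hat


def simulate_qif_ensemble(p: QifEnsembleParams, I_of_t, V0=None, r0: float = 0.0):
    """Euler-integrate a finite QIF ensemble; returns (r_hat, V_hat).

    ``I_of_t`` is the homogeneous external current per step.  Excitabilities
    are drawn once from a Lorentzian(eta_center, eta_width).  The rate is
    the per-step spike fraction smoothed with an exponential kernel of time
    constant ``tau_d``; after a reset the neuron is held for two steps and
    excluded from the V average.

    To start near a mean-field state (V0, r0), pass both: membrane
    potentials are drawn from the stationary Lorentzian of centre ``V0``
    and half-width ``pi * r0`` (the mean-field ansatz), and the recurrent
    drive is seeded at ``r0`` so the up state does not collapse while the
    rate estimate warms up.
    """
    I_of_t = np.asarray(I_of_t, dtype=float)
    rng = np.random.default_rng(p.seed)
    # Lorentzian excitabilities by inverse CDF.  The default stratified
    # quantile grid (u at bin midpoints) removes the heavy-tail sampling
    # noise of random draws, whose rate contribution has divergent
    # variance; random draws are clipped at the 1e-4 tail for stability.
    if p.eta_sampling == "quantile":
        u = (np.arange(p.n_neurons) + 0.5) / p.n_neurons
        rng.shuffle(u)
    else:
        u = rng.uniform(1e-4, 1 - 1e-4, size=p.n_neurons)
    eta = p.eta_center + p.eta_width * np.tan(math.pi * (u - 0.5))
    if V0 is None:
        V = rng.uniform(-2.0, 0.0, size=p.n_neurons)
    else:
        u2 = rng.uniform(0.005, 0.995, size=p.n_neurons)
        V = float(V0) + math.pi * r0 * np.tan(math.pi * (u2 - 0.5))
        V = np.clip(V, 0.9 * p.V_reset, 0.9 * p.V_peak)
    # stability: the fastest (most excitable) neuron must take at least ~8
    # Euler steps per inter-spike interval (ISI ~ pi / sqrt(c) at drive c)
    c_max = float(np.max(eta)) + abs(p.J) * 2.0 + (float(np.max(np.abs(I_of_t))) if I_of_t.size else 0.0)
    if c_max > 0 and p.dt > math.pi / (8.0 * math.sqrt(c_max)):
        raise ValueError(
            f"dt={p.dt} too large: the fastest neuron would take fewer than "
            "8 steps per inter-spike interval; reduce dt"
        )
    # After a threshold crossing the analytic trajectory still needs
    # ~1/V_peak to diverge to +inf and another 1/V_peak to return from
    # -inf; holding the neuron for 2/V_peak (and excluding it from the
    # V average) reproduces that transit and keeps the Lorentzian-tail
    # average symmetric.
    refrac_steps = max(1, int(round(2.0 / (p.V_peak * p.dt))))
    r_hat, V_hat = _qif_loop(
        V.astype(np.float64), eta.astype(np.float64), p.J, I_of_t,
        p.dt, p.V_peak, p.V_reset, p.tau_d, refrac_steps, float(r0),
    )
    return r_hat, V_hat
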