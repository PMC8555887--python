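# Methods

## Model

Each brain region is an exact mean-field reduction of infinitely many
all-to-all coupled quadratic integrate-and-fire (QIF) neurons with
Lorentzian-distributed excitabilities (centre `eta`, half-width `Delta`).
The population state is the mean firing rate `r` and mean membrane
potential `V`:

    tau_c dr/dt = Delta/pi + 2 r V
    tau_c dV/dt = V^2 + eta + J r - pi^2 r^2 + I(t)

Defaults `J = 14.5`, `eta = -4.6`, `Delta = 0.7`, `tau_c = 1` place a
decoupled node (`I = 0`) in a bistable configuration: a low-rate stable
node ("down", r* ≈ 0.057), a saddle (r* ≈ 0.452) and a high-rate stable
focus ("up", r* ≈ 1.008, eigenvalues ≈ −0.22 ± 3.30i).  An input current
moves the two lobes of the V-nullcline apart; the down state and the saddle
annihilate in a saddle-node bifurcation between I = 2 and I = 3, so
sufficiently driven regions lose the down state entirely.  The reduction
carries an analytic Kuramoto order parameter, `Z = (1 − conj(w))/(1 +
conj(w))` with `w = pi r + iV`, so population synchrony remains observable.

Regions are coupled over a weighted directed connectome by an additive
current `I_n(t) = G Σ_m W_nm r_m(t − τ_nm)`, with delays τ = tract length /
conduction speed (default 4 m/s).  Since rates are non-negative, all
interactions are excitatory; what differentiates regions is their
in-strength and module membership.

## Time conventions and integration

The model is nondimensional except for `tau_c`; one recorded sample
corresponds to 1 ms (1000 Hz "simulated EEG"), and 2000 samples to one
2-s BOLD frame.  Delays and noise live on the 1 ms grid.  Inside each
recorded millisecond the deterministic drift is advanced with 40 explicit
substeps (h = 0.025): the up-state focus makes the plain explicit Euler
step unstable for h ≳ 0.042, while h = 0.025 is comfortably inside the
stability region; a stochastic-Heun-style variant is available through
`SimConfig(scheme="heun")`.  One Gaussian increment of standard deviation
`noise · sqrt(dt)` per recorded step is added to both state equations
(splitting scheme: fine-stepped drift, coarse-stepped diffusion).  After
each kick the rate is clamped at zero (the mean-field rate is non-negative
by construction) and |V| is capped at 100 — the QIF peak value, beyond
which a population-average potential has no meaning.  Without the cap,
rare compounded kicks can push V past the point where the `V^2` term wins
the race against the stabilising `−pi^2 r^2` term for many milliseconds;
the resulting giant excursion is formally bounded but numerically stiff.
State overflow beyond that is reported as a simulation error with the step
and region; parameter sweeps record such cells as NaN and continue.

History for the delayed coupling is held constant at the initial condition;
a configurable burn-in (default 10 s) is discarded from every downstream
statistic.

## Hemodynamics

BOLD is generated by the canonical four-state balloon model (vasodilatory
signal, inflow, venous volume, deoxyhemoglobin), with constants
kappa = 0.65 s⁻¹, gamma = 0.41 s⁻¹, tau0 = 0.98 s, alpha = 0.32, E0 = 0.4,
V0 = 0.04, k1 = 7·E0, k2 = 2, k3 = 2·E0 − 0.2, all overridable.  The drive
is the per-region z-scored membrane potential (raw V is negative at rest;
the hemodynamic system wants a zero-baseline input); a rate drive is
offered as an option, and the choice is recorded in output metadata.
Integration is fixed-step RK4 at the raw rate with states floored at 1e-6;
the output is sampled at each TR boundary (default TR = 2 s) and the first
10 frames are dropped as hemodynamic transient.  The impulse response
peaks ~4–5 s after a brief stimulus, which the synthetic-data generator
uses as its planted lag.

## Functional dynamics

All z-scores use the population SD so that the time average of an edge
co-activation series `E_nm(t) = z_n(t) z_m(t)` equals the Pearson
correlation of the pair exactly (asserted to 1e-10 in tests).  dFC_e
correlates iFC frames; dFC_w correlates windowed FCs (window 60 s, step
2 s, left-anchored, partial trailing window dropped, z-scored within each
window); the switching index is the variance of the strict upper triangle
of dFC_w.  Zero-variance frames or windows would make a Pearson
correlation undefined; they are mapped to 0 with a warning flag so sweeps
over frozen dynamics do not crash.  Event analysis thresholds the RSS of
the edge series at its 98th percentile, events strictly above (linear
interpolation between order statistics), so a constant RSS yields zero
events.

## Cascades and avalanches

Fast signals are z-scored per region over the analysed segment and
binarised two-sided at |z| > 3.  Avalanches are maximal runs of
consecutive samples with ≥ 1 active region; size counts distinct regions.
The cascade signal is the region-summed raster convolved with a Gaussian
kernel — "width = one TR" is interpreted as the SD (a FWHM interpretation
is available) — truncated at 4 SD with reflective boundaries, then
averaged into TR bins rather than decimated, which makes the BOLD-clock
signal insensitive to the phase alignment between the fast clock and the
frame grid.

Node classes: up-state occupancy is measured against the midpoint between
the uncoupled down and up equilibrium rates.  U/D are occupancy > 0.99 /
< 0.01 without 3σ events, J has intermediate occupancy (regular jumping),
and D*/U* have at least one 3σ excursion sustained for ≥ 20 ms.  The
sustain requirement exists because per-sample |z| > 3 is reached by plain
noise in any long record; a state event must persist beyond the millisecond
noise scale.  All thresholds are package conventions, configurable.

## Surrogates and coupling statistics

Frame shuffling permutes columns jointly across regions (static FC exactly
preserved).  Phase randomization adds uniform random phases per frequency
(DC and, for even lengths, the Nyquist bin untouched, Hermitian symmetry
preserved): one shared draw across regions preserves the cross-spectrum and
hence the static FC and the chi-square-like fat tail of the RSS
distribution; independent draws per region destroy inter-regional
correlation and normalise that tail.  Surrogate ensembles are generated
lazily from spawned substreams (constant memory in ensemble size).

The lag profile is `rho(l) = Pearson(C(t), R(t−l))` on the overlapping
support (no padding); negative lags compare the cascade with later BOLD, so
hemodynamics puts the peak at negative lags.  Null tests recompute edge
series → RSS → profile per surrogate and use one-sided p-values with the
+1 permutation correction; profile means across trials are plain averages
with a Fisher-z option.

## Synthetic data

The connectome generator emulates tracer matrices: directed, modular
(default 4 modules, intra/inter edge densities 0.8/0.3), log-normal
weights (sigma = 1.2 on the log scale) with intra-module projections one
order of magnitude stronger (log-mean boost +2), max-normalised to [0, 1];
tract lengths are Euclidean distances of uniform random coordinates in a
40 mm box.  The modular weight boost matters dynamically: it lets state
jumps recruit whole modules, which concentrates slow variance in a few
principal components and co-modulates deviation counts — both properties
of the empirical system this generator stands in for.  What it does not
emulate: spatial weight-distance coupling, hemispheric homotopy, and any
biophysical EEG spectrum (1/f, rhythms); planted-trial tests therefore
validate the pipeline's statistics, not its behaviour on spectrally
realistic EEG.

Planted trials: unit-variance Gaussian background per region at 200 Hz;
events at Poisson times (default 3/min) activate a random quarter of the
regions for 50–200 ms at z-amplitude 6 with 10 ms linear ramps; a fraction
`coupling` of events drives the involved regions through the package's own
balloon model (so the planted lag is self-consistent with the pipeline
under test), sampled at TR = 1.94 s, plus frame noise scaled to the
impulse-response peak.  The EEG branch, the coupling mask and the BOLD
noise use independent child seeds, so changing `coupling` leaves the EEG
bit-identical.  A generation request whose events would cover more than
half of all samples is rejected as over-dense.

## Working points and problem sizes

The full-scale experiments run on the packaged 104-region synthetic
connectome (seed 0).  The regime sweep locates two standard cells, frozen
in `cascadenet.regimes` and re-verified by occupancy labels on every run:
bistable `G = 1.55, noise = 0.055` from an all-up start (a strict subset
of regions stays up and a sizeable J class jumps regularly; from an
all-down start, low noise cannot seed that configuration in finite time —
the regime is hysteretic), and monostable `G = 1.2, noise = 0.25` from a
down start (no region sustains the up state longer than 5 s).  The
bistable coupling experiment uses 600 s of simulated time; the monostable
one and the PCA experiment use 1200 s, the former because its much weaker
correlation needs the longer record for a stable estimate.  The QIF
oracle uses 10⁴ stratified neurons for 80 tau_c.  These sizes keep a full
acceptance run in the tens of minutes on one CPU while leaving the slow
FC statistics well-sampled.

In this implementation the monostable regime's up-state visits are short
(< 100 ms): the cascade signal has no slow rate modulation of its own, so
the hemodynamic delay strongly attenuates the zero-lag cascade↔RSS
correlation (≈ 0.2–0.3, against a lag-profile peak of ≈ 0.4–0.46 at −1…−2
frames).  The directional ordering (bistable ≫ monostable > 0) is stable
across seeds; the absolute monostable value is sensitive to how the noise
produces up-state excursions and should be read as a lower bound on what
slower excursion dynamics would give.

## QIF ensemble oracle

The finite-size ensemble draws excitabilities on a stratified quantile
grid by default: random Lorentzian draws give the ensemble rate a
heavy-tailed sampling distribution (the top 0.5 % of neurons carry ~40 %
of the down-state rate), so stratification removes most cross-seed
variance without biasing the mean.  After a threshold crossing at
V_peak = 100 the neuron is held for 2/V_peak time units — the analytic
transit to +∞ and back from −∞ — and excluded from the V average during
the hold, which keeps the truncated-Lorentzian average symmetric.  The
residual up-state rate bias is ≈ −0.4 % (finite V_peak, finite N, Euler
step 2.5e-4), within the < 1 % headroom expected of the V_peak = 100
approximation.

## Known limitations

* Heterogeneous per-node parameters are out of scope (one `NodeParams` is
  shared), matching the homogeneous tuning of the modelled system.
* The separatrix is characterised by its fixed points and basin probing,
  not computed as a curve.
* High-noise cells (noise ≥ 0.3 at G ≥ 1) can overflow the rate variable
  through numerically stiff giant excursions; they are reported as errors
  rather than silently clipped.
* Avalanche size/duration power laws are not fitted.
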