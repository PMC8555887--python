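# cascadenet

Whole-brain network modelling and analysis of **neuronal cascades**: the
hypothesis that rare, large deviations of fast neuroelectric activity —
clustered avalanches of regional state changes — drive the slow bursts of
BOLD co-activation that shape resting-state functional connectivity and
its dynamics.

The package is aimed at computational neuroscientists who want a tested,
self-contained implementation of this pipeline that runs end-to-end on
synthetic data: no tracer database, EEG recordings or fMRI scans are
required, but the analysis branch accepts any pre-parcellated region×time
arrays.

## What is inside

**Model.** Each region is the exact mean-field limit of infinitely many
all-to-all coupled QIF neurons with Lorentzian excitabilities
(Montbrió-type reduction):

    τ_c ṙ = Δ/π + 2 r V
    τ_c V̇ = V² + η + J r − π² r² + I(t)

With defaults (J = 14.5, η = −4.6, Δ = 0.7) each node is bistable — a
quiet "down" state and a depolarised "up" focus.  Regions are coupled over
a weighted, directed connectome through delayed excitatory currents
I_n(t) = G Σ_m W_nm r_m(t − τ_nm), integrated stochastically at a 1 ms
resolution (`network`), and mapped to BOLD at TR = 2 s by a
Balloon–Windkessel stage (`hemodynamics`).

**Analysis.** Edge co-activation series E_nm(t) = z_n(t)·z_m(t) and their
RSS amplitude, static FC, edge-centric and windowed dynamic FC with the
switching index, 98th-percentile co-activation event statistics, leading-
eigenvector functional hubs, PCA modes (`fc`); ±3σ binarisation, avalanche
catalogues, the slow cascade-magnitude signal, and D/U/J/D*/U* node
classification (`cascades`); frame-shuffle and two phase-randomisation
null models (`surrogates`); lagged cascade↔RSS cross-correlation with
surrogate significance tests (`coupling`).

**Synthetic data.** Tracer-like modular log-normal connectomes and
planted-coupling EEG+BOLD trials with ground-truth event tables
(`synthetic`), used by the test-suite to score the pipeline's recovery of
known structure.

## Worked example

```python
import numpy as np
import cascadenet as cn
from cascadenet import regimes
from cascadenet.pipeline import aligned_cascade_and_rss

c = cn.demo_connectome(n_regions=104, seed=0)      # packaged synthetic substrate
cfg = cn.SimConfig(G=regimes.BISTABLE["G"], noise=regimes.BISTABLE["N"],
                   init=regimes.BISTABLE["init"], duration=600.0, seed=1)
raw = cn.simulate_network(c, cn.NodeParams(), cfg)  # (r, V) at 1000 Hz
bold = cn.bold_transform(raw, cn.HemodynamicParams())
C, R, E = aligned_cascade_and_rss(raw, bold)        # BOLD-clock cascade + RSS
print("zero-lag cascade-RSS correlation:", round(float(np.corrcoef(C, R)[0, 1]), 3))
```

On this configuration the script prints

```
zero-lag cascade-RSS correlation: 0.92
```

i.e. in the bistable regime the slow cascade signal — how many regions are
deviating beyond 3σ, smoothed to the BOLD clock — explains most of the
global co-activation amplitude.  Running the same pipeline at the
monostable working point (`regimes.MONOSTABLE`) drops the correlation to
roughly 0.25: only brief noise-driven excursions remain, so the cascade
signal loses its slow structure and the hemodynamic delay attenuates the
zero-lag agreement (see `docs/methods.md`).

A command-line interface mirrors the library
(`cascadenet simulate | sweep | bold | fc | cascades | surrogate | couple |
synth | run-insilico | run-empirical`).

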