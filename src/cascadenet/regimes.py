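"""Standard working points of the packaged demo connectome.

Located with :func:`cascadenet.network.sweep_regimes` on the 104-region
synthetic tracer-like connectome (seed 0): at high global coupling and low
noise a strict subset of regions sustains the up state with occasional
jumps (bistable regime); at lower coupling and stronger noise no region
sustains the up state and only transient noise-driven excursions occur
(monostable regime).  Runs at these points should re-verify the regime
with :func:`cascadenet.network.label_regime`, which both the acceptance
script and the acceptance tests do.
"""

BISTABLE = {"G": 1.55, "N": 0.055, "init": "up"}
MONOSTABLE = {"G": 1.2, "N": 0.25, "init": "down"}
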