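# Height-fluctuation spectrum of a flat patch (memtube spectrum)
# <|h_q|^2> = kT / [A (kappa q^4 + gamma q^2)] for the resolved low-q modes.
kappa: 20.0
gamma: 0.0
patch: 145.0
target_edge: 7.8     # ~400 vertices
frozen_boundary: false
warmup: 8000
n_samples: 1100
stride: 20
seed: 0
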