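# Tilted-membrane single-filament bending transition (memtube fpt)
# Reduced master-equation model: rate ladder k_on(n) = k_on,0 P_bend,
# first-passage distribution to the bent growing state, and the MFPT
# heat map over (theta, L0).
theta: 45.0
L0: 60.0
kappa: 20.0
gamma: 0.01
L_p: 15000.0
patch: 160.0
k_off: 0.01
theta_range: [25.0, 35.0, 45.0, 55.0]
L0_range: [45.0, 55.0, 65.0, 75.0]
seed: 0
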