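# Single rigid filament polymerization ratchet (memtube grow)
# Irreversible growth against the membrane; acceptance tracks
# exp(-f(L) delta_fil / kT).  Set k_off: 0.01 for the stalling variant
# (steady state at k_on(n)/k_on,0 = k_off/k_on,0 = 1e-2).
N_fil: 1
kappa: 20.0
gamma: 0.01          # canonical membrane with explicit tension
patch: 140.0
depth: 40.0          # base distance below the membrane plane, nm
k_off: 0.0
nu: 100.0            # configurational sweeps per 1/k_on,0
t_max: 300.0
seed: 0
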