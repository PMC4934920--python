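# Orientation-disorder bundling runs (memtube analyze)
# Filament base polar angles drawn from a Gaussian of width std_deg;
# final state is classified (bundled / unbundled / failed) and the
# barbed-end alignment profile a(L) is written per 10 nm height bin.
N_fil: 10
std_deg: 20.0
depth: 50.0
patch: 160.0
z: 0.0034
nu: 100.0
t_max: 2500.0
stop_height: 260.0
seed: 0
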