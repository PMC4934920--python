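# Ten-filament bundling and tube formation (memtube grow)
# Desk-scale defaults; the reference study conditions are N_fil = 10,
# L_p = 15 um, k_off/k_on,0 = 1e-2, bases 50 nm below the membrane,
# tube threshold 260 nm.  Set center_frozen: true for the screening
# variant with one extra immobilized node at the patch center.
N_fil: 10
std_deg: 0.0
depth: 50.0
patch: 160.0
z: 0.0034            # gamma ~ 0.01 kT/nm^2 after calibration
L_p: 15000.0
k_off: 0.01
nu: 100.0
t_max: 2500.0
stop_height: 260.0
center_frozen: false
seed: 0
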