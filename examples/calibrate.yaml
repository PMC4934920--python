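# Fugacity -> surface tension calibration (memtube calibrate)
# gamma(z) by thermodynamic integration of <V>, anchored by one pulled-tube
# radius; fits z = C exp(-gamma/(rho kT)).
kappa: 20.0          # bending rigidity, kT
patch: 160.0         # patch edge, nm
z_values: [0.0015, 0.0022, 0.0034, 0.005]
anchor_z: 0.0034     # tube-radius anchor point
sweeps: 4000         # <V> sampling sweeps per z
seed: 0
anchor:              # pull_tube settings for the anchor
  Lx: 180.0
  L_hold: 85.0
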