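# Membrane tube pulling (memtube pull-tube)
# Equilibrium radius R0 = sqrt(kappa/(2 gamma)) and plateau force
# f0 = 2 pi sqrt(2 kappa gamma); z = 0.0034 maps to gamma ~ 0.01 kT/nm^2
# under the calibration in calibrate.yaml.
kappa: 20.0
z: 0.0034
patch: 200.0
L_hold: 150.0
seed: 0
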