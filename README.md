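# memtube

Monte Carlo simulation of membrane-tube formation by polymerizing actin
filaments, with a reduced first-passage theory of membrane-mediated
filament bundling.

Cells push out tubular protrusions (filopodia) by polymerizing stiff actin
filaments against a comparatively soft lipid membrane.  In reconstituted
systems such tubes emerge even without bundling proteins: the membrane
itself mediates an effective attraction that collects individually growing
filaments into a tight, cooperatively growing bundle.  `memtube` provides
the simulation machinery to study this process at the level of a
fluctuating membrane patch and discrete filaments, for researchers in
membrane biophysics and cytoskeletal mechanics.

## Model

- **Membrane** — a dynamically triangulated, periodic patch of hard beads
  (diameter 5 nm) with tethered edges and edge-flip fluidity, governed by
  the discretized Helfrich energy `E = Σ_v [(κ/2)(2H_v)² + γ] A_v` with
  bending rigidity κ (k_BT) and tension γ (k_BT/nm²).
- **Lipid reservoir** — grand-canonical vertex insertion/removal moves at
  fugacity z let the patch area grow at constant tension, as when a tube
  draws lipid from a vesicle.  For an incompressible fluid membrane
  `z = C exp(−γ/(ρ k_BT))`; the package measures this mapping by
  thermodynamic integration of ⟨V⟩(z) anchored by a pulled-tube radius.
- **Tubes** — an equilibrium membrane tube has radius `R₀ = √(κ/(2γ))` and
  asymptotic pulling force `f₀ = 2π√(2κγ)`; both closed forms serve as
  validation targets.
- **Filaments** — discretized worm-like chains (bead spacing
  δ_fil = 2.7 nm per monomer, bead diameter 10 nm, persistence length
  L_p = 15 µm) with fixed base segments, sampled by pivot and crankshaft
  rotations.
- **Growth** — kinetic Monte Carlo polymerization at attempt rate k_on,0
  (the time unit) and depolymerization k_off (k_off/k_on,0 = 10⁻²),
  sterically gated by the instantaneous membrane shape: a single filament
  behaves as a Brownian ratchet with
  `k_on(n)/k_on,0 ≈ exp(−f(L) δ_fil/k_BT)`.
- **Bundling theory** — a tagged filament below a tilted membrane
  (angle θ, distance L₀) grows freely to the contact length, then waits
  for rare bending fluctuations; the effective rates
  `k_on(n) = k_on,0 P_bend(n→n+1)` define a birth–death master equation
  whose first-passage time to the bent, freely growing state predicts the
  bundling waiting time — and varies by orders of magnitude across
  (θ, L₀).

## Worked example

Pull a membrane tube from a flat patch at a fugacity calibrated to
γ ≈ 0.01 k_BT/nm² and compare with the closed forms:

```python
from memtube.analysis import pull_tube
import numpy as np

res = pull_tube(z=0.00353, kappa=20.0, Lx=200.0, L_hold=130.0,
                ramp_sweeps_per_nm=140, relax_sweeps=16000,
                n_samples=150, sample_stride=30,
                exchange_fraction=0.4, seed=42)
print(f"R = {res['R']:.1f} nm   (R0 = {np.sqrt(20/(2*0.01)):.1f} nm)")
print(f"f = {res['force']:.2f} kT/nm (f0 = {2*np.pi*np.sqrt(2*20*0.01):.2f})")
print(f"f*R/(2*pi*kappa) = {res['force']*res['R']/(2*np.pi*20):.2f}")
```

output (about four minutes on one CPU; stochastic, ±a few %):

```
R = 28.0 nm   (R0 = 31.6 nm)
f = 4.36 kT/nm (f0 = 3.97)
f*R/(2*pi*kappa) = 0.97
```

The tube radius inverts to the membrane tension via γ = κ/(2R²); both
observables sit ~10% from the asymptotic closed forms because a
desk-scale tube of finite length still carries part of the nucleation
overshoot and is still slowly exchanging area with the reservoir, while
the length-independent mechanical identity f·R = 2πκ already holds to a
few percent.

The reduced bundling model, at the reference scenario (θ = 45°,
L₀ = 60 nm):

```python
from memtube.ratemodel import TiltScenario, build_ladder, first_passage_stats

s = TiltScenario(theta=45.0, L0=60.0, patch=120.0)
fp = first_passage_stats(build_ladder(s, k_off=0.01))
print(f"MFPT = {fp['mfpt']:.0f} / k_on,0")
```

prints `MFPT = 130 / k_on,0`, which direct membrane+filament simulations
of the same scenario reproduce within replica scatter
(`memtube.experiments.tilted_first_passage`).

## Command line

`memtube calibrate|spectrum|pull-tube|grow|fpt|analyze <config.yaml>` —
one YAML config per experiment; see `examples/` for ready-made configs of
the standard experiments (spectrum, calibration, tube pulling, the
single-filament ratchet, 10-filament bundling with and without an extra
frozen adhesion node, the tilted-membrane first-passage scenario, and
orientation-disordered growth).  Outputs are CSV/JSONL observables,
OFF/PLY/VTK mesh frames and a JSON manifest; column schemas are documented
in `docs/schema.md`.

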