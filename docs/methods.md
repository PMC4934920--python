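# Methods

`memtube` simulates a fluctuating fluid membrane patch coupled to
stochastically polymerizing semiflexible filaments, and a reduced
birth–death theory for the filament-bundling transition.  This note
documents the models, the numerical choices, and what the desk-scale test
experiments do and do not demonstrate.  Energies are in units of k_BT,
lengths in nm, times in units of the polymerization attempt time 1/k_on,0.

## Membrane model

The membrane is a dynamically triangulated surface: beads of hard-core
diameter d_mem = 5 nm connected into a triangulation that is periodic in x
and y (genus-1 under the wrap, V − E + F = 0) and free in z.  Edge lengths
are confined to tether bounds [a_min, a_max]; edge flips make the surface a
fluid.  The elastic energy is the discretized Helfrich form

    E = Σ_v [ (κ/2)(2H_v)² + γ ] A_v ,

with the cotangent mean-curvature vector K_v (|K_v| = 2|H_v|, signed by the
vertex normal) and barycentric vertex areas A_v.  On a refining sphere the
discrete bending energy converges to the continuum value 8πκ, and a flat
patch has exactly zero bending energy; these are the property tests that
fix the discretization, rather than any particular formula being mandated.

### Tether and hard-core parameters

Defaults: a_min = d_mem = 5 nm, a_max = 13 nm, build target edge ≈ 9.5 nm.
A tighter conventional choice a_max = √3·a_min is incompatible with
grand-canonical centroid insertion: a vertex inserted at the centroid of a
triangle with edges ≤ √3·a_min always creates edges shorter than a_min, so
no insertion could ever be accepted.  The wider window restores a finite
insertion acceptance (~5–10% in the tense regime).  The price is that
tethers alone no longer guarantee strict self-avoidance; membrane bead
hard cores are therefore checked explicitly against the topological
2-ring in the hot path (sufficient for the small displacements allowed),
and exhaustively by the `constraint_check` predicate.  Filament beads
(d_fil = 10 nm) cannot pass through any triangle with edges ≤ 13 nm, so
membrane–filament penetration is excluded geometrically.

### Grand-canonical vertex exchange

Lipid-reservoir coupling: vertex insertion into a uniformly chosen triangle
at its centroid plus an isotropic Gaussian offset (σ = 1 nm), removal of a
uniformly chosen *removable* vertex — mobile and 3-coordinated, the exact
inverse of a centroid split.  With φ(δ) the Gaussian proposal density
(times a 1 nm³ reference volume), F the triangle count of the originating
state and N₃′ the removable count of the target state, acceptance is

    insert:  min[1, z e^{−ΔE} F / (N₃′ φ(δ))]
    remove:  min[1, z⁻¹ e^{−ΔE} N₃ φ(δ) / F′] ,

which satisfies detailed balance w.r.t. the grand-canonical weight
z^V e^{−E}.  The tests verify this three ways: the pair-product identity
of forward/reverse acceptance ratios, an exact histogram-reweighting
relation between stationary V-distributions at two fugacities
(ln P ratios linear in V with slope ln z₂/z₁), and — absolutely — the
consistency of the calibrated tension with pulled-tube mechanics.

Insertion/removal are attempted with equal frequency, 0.1·V attempts each
per sweep, alongside V displacement and V flip attempts.  The displacement
amplitude is tuned to 30–50% acceptance during warm-up only and then
frozen (continued tuning would break detailed balance).

### Tension control and calibration

In grand-canonical runs the explicit γ·A term is switched off; tension is
controlled by z alone (including both would double-count the area cost).
Canonical (fixed-V) runs use the explicit γ term.  The mapping
z = C exp(−γ/(ρ k_BT)) is measured in two steps:

1. *Relative* tensions by thermodynamic integration: at fixed projected
   area A_p, dΩ/d ln z = −⟨V⟩ and γ = Ω/A_p, so γ differences follow from
   the cheap, self-averaging ⟨V⟩(z).  Note dγ/d ln z = −⟨V⟩/A_p: constant
   ρ in the exponential mapping is equivalent to an approximately
   z-independent projected vertex density, and ρ *is* that density
   (≈ 0.013 nm⁻² here).
2. One *absolute* anchor from a pulled-tube radius, γ = κ/(2R²).

The constant C absorbs the proposal normalization (σ, the reference
volume) and is therefore specific to this package's insertion scheme; its
numerical value is not comparable across implementations, while ρ is
physical.  The low-q spectrum route to γ is implemented as a secondary
method but is statistically much weaker at desk scale: the tension signal
lives in the slowest modes, whose integrated autocorrelation times (10³–10⁴
sweeps for the lowest mode of a ~400-vertex patch) defeat short runs.

### Fluctuation spectrum and the effective tension

The height-fluctuation spectrum of a fixed-V patch follows the continuum
form kT/[A(κq⁴ + γq²)], but γ here is the patch's *fluctuation tension*,
which at these small sizes is set by the vertex density and differs
measurably from both the bare Hamiltonian γ and (by finite-size
corrections) the mechanical frame tension; at the build density used it is
of order +0.02 k_BT/nm², enough to visibly suppress the lowest resolved
modes (κq² ∼ 0.03–0.1 there).  The spectrum validation therefore holds κ
fixed and fits γ as a single nuisance parameter, testing the q⁻⁴ backbone
and functional form; tube mechanics (f·R = 2πκ) independently pins κ, and
the thermodynamic-integration route pins the frame tension.  The grid
estimator itself was validated against synthetic Gaussian fields with a
known spectrum (unbiased to ≲10%) and against a direct nonuniform Fourier
sum on identical configurations (agreement to ~1%).

### Frame pinning

Growth experiments pin three equidistant boundary vertices, which fixes
the membrane frame relative to the filament anchors.  For strong point
loads (tube pulling by an external spring) three-point pinning is
insufficient: the sheet "tents" upward as a quasi-rigid body, paying only
localized dimple energy at the pinned points, and no clean tube forms.
Tube experiments therefore freeze the whole boundary frame of the periodic
cell (the y = 0 row and x = 0 column), a clamped-frame boundary condition
under which the pulled tube equilibrates to the expected closed-form
radius and force.  The pinning choice is per-experiment configuration.

### Tube pulling

A vertical harmonic spring (stiffness 2 k_BT/nm²) acts on the mean height
of a ~10 nm vertex disk at the patch center; its anchor is ramped at
~1 nm per 100–120 sweeps and then held.  Tube height L is the maximum
membrane height over the frozen plane; the radius R is a Kasa circle fit
to the vertices with height in [L/3, 2L/3], unwrapped around the apex.
Force is the time-averaged spring force.  The closed forms
R₀ = √(κ/(2γ)) and f₀ = 2π√(2κγ) (equivalently f₀R₀ = 2πκ) are the
validation targets; at the held extensions used here (L/R ≈ 4–5) the
measured force still contains part of the finite-length overshoot that
precedes the asymptotic plateau (≈ +10%), and both observables breathe
slowly as area exchanges with the reservoir.  Tube runs therefore use an
elevated exchange attempt rate, and reported errors come from a
Flyvbjerg–Petersen blocking analysis rather than naive block averages,
which underestimate these correlated series.

## Filaments

Discrete worm-like chains: one bead per polymerization step,
δ_fil = 2.7 nm, bead diameter 10 nm (overlapping beads give a smooth
excluded tube), bending energy (L_p/δ)Σ(1 − t̂_i·t̂_{i+1}) with
L_p = 15 µm for actin.  The base segment (beads 0–1) is immutable.  Moves
are terminal pivots and crankshaft rotations of 2–6-segment interior arcs;
both are exact rigid rotations, preserving segment lengths to machine
precision.  Validation: tangent correlations ⟨t̂(0)·t̂(s)⟩ = e^{−s/L_p}
and clamped-cantilever tip variance ℓ³/(3L_p) against an independent
normal-coordinate sampler.  Consecutive beads are 2.7 nm apart but carry
10 nm hard cores, so same-chain pairs within 4 indices are exempt from the
self-exclusion test; distinct chains are always tested.

## Growth kinetics

Reactions use the standard n-fold Gillespie scheme: waiting times
exponential with total rate N_fil(k_on,0 + k_off), uniform filament
choice, channel ∝ rate.  A polymerization attempt appends a bead along the
barbed-end tangent (growth "locks in" curvature) and is accepted iff
excluded volume permits it in the instantaneous configuration; otherwise
the attempt is a null event and time still advances.  Depolymerization
removes the barbed bead; the base monomer never depolymerizes.  Defaults
follow in-vitro actin conditions, k_off/k_on,0 = 10⁻².

Between reactions, ν·Δt configurational sweeps run, with membrane and
filament moves interleaved in proportion to their degree-of-freedom
counts.  The default ν = 100 sweeps per 1/k_on,0 makes the local
(gap-gating) membrane modes decorrelate between successive attempts at the
patch sizes used; the suite checks that doubling ν leaves the
single-filament stall height unchanged within error.  The slowest patch
modes are *not* fully equilibrated between events at this ν — they
represent the long-wavelength fluctuations that in vivo would be damped by
the surrounding network, and the gating physics is local.

## Reduced bundling model

A tagged filament under a tilted membrane is summarized by the relative
angle θ and the vertical base–membrane distance L₀.  Growth is free up to
the contact index n_c = ⌊L₀/(δ cos θ) − 1⌋.  Beyond contact, the
constrained ground state of the chain (planar bending in the tilt plane,
beads below the plane) is computed by SLSQP with analytic gradients; the
absorbing state n* is the first length whose ground-state tip tangent is
parallel to the plane, after which growth is unimpeded.

P_bend(n→n+1) is a saddle-point estimate over the two softest modes: the
chain may bend (WLC energy) and the membrane may lift locally as a single
Gaussian mode of variance σ_m² (the discrete Helfrich mode sum of the
patch, i.e. stiffness k_BT/σ_m²).  The activation barrier ΔE*(n) is the
excess free energy of the constrained minimum that additionally
accommodates one more bead below the (lifted) plane, and
P_bend = e^{−ΔE*}; zero required clearance gives exactly 1.  Fluctuation
prefactors are neglected — compliance is defined by agreement with the
direct membrane+filament simulation of the same scenario, which the suite
checks at θ = 45°, L₀ = 60 nm with reduced replicas.  The geometric
clearance reported by `required_gap` deliberately uses the *pure-bending*
ground state (membrane at its mean plane), so that geometry and
energetics stay separately testable.

The rate ladder k_on(n) = k_on,0·P_bend feeds the birth–death master
equation with a reflecting boundary at n = 1 (the base cannot
depolymerize) and absorption at n*.  It is integrated with LSODA at tight
tolerance; p(τ_FP) is the absorbed-mass flux, and the MFPT is additionally
computed by the exact recursion T_k = (1 + k_off T_{k−1})/k_on(k),
MFPT = Σ T_k — the two agree to 10⁻⁶ relative.  Over the mapped (θ, L₀)
plane the MFPT spans many orders of magnitude; it diverges in the head-on
limit θ → 0 (no bent escape state) and decreases with θ through the
mapped range θ ≲ 45–50°.  At larger tilt *and* large L₀ a shallow
non-monotonicity appears (contact comes earlier, adding many
weakly-blocked steps); the monotonicity property is therefore asserted on
the θ ≤ 45° range.

When comparing the reduced model against the full simulation, the
simulation places the filament base at −(L₀ + 7.5 nm): the 7.5 nm
membrane–filament contact clearance ((d_mem + d_fil)/2) is where the
effective barrier plane sits, so the reduced model's L₀ measures base to
*barrier*, not base to bead centers of the sheet.

## Desk-scale study conditions

The reference study conditions are: κ = 20 k_BT, γ ≃ 0.01 k_BT/nm²
(γ ∈ {0.005, 0.01, 0.02} for force–extension), patches 200–300 nm,
L_p = 15 µm, δ_fil = 2.7 nm, k_off/k_on,0 = 10⁻², N_fil = 10 filaments
anchored 50 nm below the membrane, 50 trajectories per ensemble, and a
260 nm tube-height threshold.  The example configs in `examples/` encode
these.  The automated test experiments run the same physics at reduced
problem sizes chosen once as desk-scale defaults: patches 100–200 nm,
400-vertex spectra, single tubes instead of force–extension families,
6–10 replicas for first-passage statistics, 6 filaments / 60–80 nm tube
thresholds / 3 paired trajectories for the bundling and frozen-node
screening comparisons (which are therefore ordinal, not quantitative).
What the passing tests show: the elastic model, the grand-canonical
ensemble, the closed-form tube mechanics, the ratchet force–velocity
relation, the master-equation machinery, and the direction and rough
magnitude of the bundling and screening effects.  What they do not show:
ensemble-converged waiting-time distributions, 260 nm tubes, or
bundle-size statistics at the reference filament density.

## Known limitations

- Self-avoidance is enforced by hard cores plus local checks, not by the
  tether geometry alone; extreme deformations finer than the 2-ring scale
  could in principle self-intersect.
- The spectrum-based tension estimator is biased at desk-scale run lengths
  (slow low-q modes); the thermodynamic-integration route is preferred.
- P_bend neglects fluctuation prefactors and out-of-plane bending paths;
  the simulated first-passage times at the reference scenario sit within
  the replica scatter of the prediction, which is the claimed accuracy.
- MC time is quasi-dynamics: the mapping to physical time enters only
  through ν, and hydrodynamics is absent.
- No spontaneous curvature, Gaussian-curvature term, twist, severing,
  capping, branching, or crosslinkers; concentration enters only through
  k_on,0.
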