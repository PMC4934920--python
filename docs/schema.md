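# Output file schemas

All lengths in nm, energies in k_BT, forces in k_BT/nm, tensions in
k_BT/nm², times in units of 1/k_on,0.  Frame indices are 0-based.  Heights
are measured relative to the plane of the frozen boundary nodes (z = 0 of
the initial flat patch).

## `*.csv` observable tables

### calibration (`memtube calibrate`)
| column | meaning |
|---|---|
| z | fugacity of the implicit lipid reservoir |
| gamma | inferred surface tension |
| gamma_err | 1σ error (TI propagation + anchor radius error) |
| stable | 1 if gamma > 0 (tube-sustaining), 0 otherwise; 0 rows are excluded from the (C, ρ) fit |

### spectrum (`memtube spectrum`)
| column | meaning |
|---|---|
| mode_x, mode_y | integer mode indices (n_x, n_y) |
| q | wavevector magnitude 2π·|n|/L |
| amp | ⟨\|h_q\|²⟩ with h_q = (1/N) Σ_j h_j e^{−iq·r_j} |
| amp_err | jackknife standard error |

### tube (`memtube pull-tube`)
Single-row table with `force`, `force_err`, `R`, `R_err`, `L`,
`tension_R` (= κ/(2R²)), `V`, `z`, `kappa`.

### first passage (`memtube fpt`)
`*.ptau.csv`: `t`, `p` — first-passage-time density p(τ_FP).
`*.map.csv`: `L0`, `theta` (degrees), `mfpt`.

### alignment (`memtube analyze`)
| column | meaning |
|---|---|
| L | lower edge of the 10 nm height bin |
| a | \|Σ ô_i\|/N over filament segments in the bin |
| n_segments | number of segments in the bin |

## `*.events.jsonl` growth event log
One JSON object per reaction event:
`{"t": ..., "filament": ..., "event": "on"|"on-rejected"|"off"|"off-null",
"n": monomer count after the event, "height": membrane max height}`.
Times are strictly increasing; contour length changes only at events, by
±δ_fil = 2.7 nm.

## `*.filaments.csv`
`frame, filament, node, x, y, z` — bead coordinates per filament.

## Mesh frames
OFF / PLY (via trimesh) for exchange; legacy ASCII VTK for visualization
pipelines.

## `*.manifest.json`
Written next to every output: creation time, package version, seed, the
full configuration, and headline results of the run.
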