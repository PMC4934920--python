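"""Drivers for the coupled membrane + filament experiments.

Each driver assembles a membrane patch, filaments and a growth simulation
for one of the standard numerical experiments: the single-rigid-filament
polymerization ratchet, the tilted-membrane single-filament bending
transition, and the multi-filament bundling / tube-formation runs with or
without an extra immobilized membrane node.
"""

from __future__ import annotations

import numpy as np

from .analysis import generate_initial_condition, tube_metrics
from .energy import MembraneParams
from .filament import Filament
from .growth import EV_ON, EV_ON_NULL, GrowthParams, GrowthSim
from .mesh import build_flat_patch
from .montecarlo import MembraneMC, MoveSchedule
from .ratemodel import TiltScenario

#: vertical clearance at which a filament bead contacts the membrane sheet
CONTACT_OFFSET = 7.5  # (d_mem + d_fil) / 2, nm


def ratchet_experiment(z=None, gamma=0.01, kappa=20.0, Lx=140.0,
                       target_edge=9.5, depth=40.0, k_off=0.0, nu=100.0,
                       t_max=400.0, seed=0, max_events=None,
                       stop_height=1e9):
    """Single rigid filament growing against the membrane patch.

    The filament is vertical, its base ``depth`` nm below the flat patch;
    depolymerization is off by default (irreversible ratchet).  The membrane
    is canonical with explicit tension ``gamma`` unless a fugacity ``z`` is
    given, in which case it is grand canonical.  Returns the growth
    trajectory and the simulation object.
    """
    mesh = build_flat_patch(Lx, Lx, target_edge, frozen_boundary="frame")
    p = MembraneParams(kappa=kappa, gamma=0.0 if z else gamma,
                       z=z or 0.0)
    fil = Filament(base=[Lx / 2, Lx / 2, -depth], orientation=[0, 0, 1],
                   n=1, L_p=1e9)
    mc = MembraneMC(mesh, p, MoveSchedule(), seed=seed, filaments=[fil])
    mc.warmup(300)
    g = GrowthParams(k_off=k_off, nu=nu, t_max=t_max, seed=seed + 1,
                     rigid=True, stop_height=stop_height)
    sim = GrowthSim(mc, g)
    traj = sim.run(max_events=max_events)
    return traj, sim


def tilted_first_passage(scenario: TiltScenario, Lx=160.0, target_edge=9.5,
                         k_off=0.01, nu=100.0, t_max=2000.0, seed=0,
                         tip_tol_deg=10.0):
    """One replica of the tilted-membrane single-filament simulation.

    The membrane fluctuates about the flat plane z = 0 (canonical, explicit
    tension, three frozen boundary nodes); the filament base sits at
    z = -(L0 + 7.5) so that its effective contact barrier (bead clearance
    7.5 nm below the membrane beads) lies the scenario's L0 above the base.
    The run ends when the barbed-end tangent is within ``tip_tol_deg`` of
    the membrane plane — the bent-and-growing state — or at t_max.
    Returns (tau_FP or nan, trajectory, sim).
    """
    th = np.radians(scenario.theta)
    mesh = build_flat_patch(Lx, Lx, target_edge, frozen_boundary=True)
    p = MembraneParams(kappa=scenario.kappa, gamma=scenario.gamma, z=0.0)
    base = np.array([Lx * 0.35, Lx / 2, -(scenario.L0 + CONTACT_OFFSET)])
    fil = Filament(base=base, orientation=[np.sin(th), 0.0, np.cos(th)],
                   n=1, L_p=scenario.L_p, delta=scenario.delta)
    mc = MembraneMC(mesh, p, MoveSchedule(), seed=seed, filaments=[fil])
    mc.warmup(300)
    g = GrowthParams(k_off=k_off, nu=nu, t_max=t_max, seed=seed + 1,
                     stop_height=1e9)
    sim = GrowthSim(mc, g)
    cos_tol = np.cos(np.radians(90.0 - tip_tol_deg))
    times, evs, lens = [], [], []
    tau = np.nan
    while sim.t < t_max:
        t, fi, code = sim.step()
        times.append(t)
        evs.append(code)
        lens.append(int(sim.mc.fb.n[0]))
        n = int(sim.mc.fb.n[0])
        tang = sim.mc.fb.pos[0, n] - sim.mc.fb.pos[0, n - 1]
        tang /= np.linalg.norm(tang)
        if tang[2] <= cos_tol:
            tau = t
            break
    sim.mc.sync_filaments()
    traj = {"t": np.array(times), "event": np.array(evs),
            "n": np.array(lens)}
    return tau, traj, sim


def bundling_experiment(N_fil=10, std_deg=0.0, depth=50.0, Lx=160.0,
                        target_edge=9.5, z=0.0034, kappa=20.0, L_p=15000.0,
                        k_off=0.01, nu=100.0, t_max=2000.0,
                        stop_height=260.0, center_frozen=False, seed=0,
                        ic=None, snapshot_stride=0):
    """Multi-filament bundling / tube-formation run.

    Filaments are anchored at uniformly random lateral positions ``depth``
    nm below the membrane, oriented with Gaussian polar-angle spread
    ``std_deg``; the membrane is grand canonical at fugacity ``z`` with
    three frozen boundary nodes, plus (optionally) one extra immobilized
    node at the patch center which screens membrane-mediated attractions.
    Passing a pre-built ``ic`` reuses identical filament initial conditions
    across the frozen / unconstrained pair of runs.
    """
    mesh = build_flat_patch(Lx, Lx, target_edge, frozen_boundary=True)
    if center_frozen:
        ids = mesh.vertex_ids
        d2 = ((mesh.m.pos[ids, 0] - Lx / 2) ** 2
              + (mesh.m.pos[ids, 1] - Lx / 2) ** 2)
        mesh.freeze_vertex(int(ids[int(np.argmin(d2))]))
    p = MembraneParams(kappa=kappa, gamma=0.0, z=z)
    if ic is None:
        ic = generate_initial_condition(N_fil, std_deg, depth, Lx,
                                        seed=seed + 7)
    fils = ic.make_filaments(L_p=L_p)
    mc = MembraneMC(mesh, p, MoveSchedule(exchange_fraction=0.2),
                    seed=seed, filaments=fils)
    mc.warmup(300)
    g = GrowthParams(k_off=k_off, nu=nu, t_max=t_max, seed=seed + 1,
                     stop_height=stop_height,
                     snapshot_stride=snapshot_stride)
    sim = GrowthSim(mc, g)
    traj = sim.run()
    return traj, sim, ic


def acceptance_vs_height(traj, base_depth, delta=2.7, bin_nm=5.0):
    """Pooled on-attempt acceptance fraction binned by tip height."""
    sel = np.isin(traj.event, [EV_ON, EV_ON_NULL])
    n = traj.length[sel]
    # tip height just before the attempt: (n - accepted) monomers above base
    grew = (traj.event[sel] == EV_ON).astype(int)
    h = (n - grew) * delta - base_depth
    acc = traj.event[sel] == EV_ON
    edges = np.arange(np.floor(h.min()), h.max() + bin_nm, bin_nm)
    hs, fr, cnt = [], [], []
    for k in range(len(edges) - 1):
        m = (h >= edges[k]) & (h < edges[k + 1])
        if m.sum() == 0:
            continue
        hs.append(0.5 * (edges[k] + edges[k + 1]))
        fr.append(float(acc[m].mean()))
        cnt.append(int(m.sum()))
    return np.array(hs), np.array(fr), np.array(cnt)
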