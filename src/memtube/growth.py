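"""Kinetic Monte Carlo (de)polymerization coupled to configurational MC.

Reactions follow the standard n-fold (Gillespie) scheme: with N_fil
filaments, attempt times are exponential with total rate
N_fil (k_on,0 + k_off); the reacting filament is uniform and the channel is
chosen proportional to the rates.  A polymerization attempt appends one
monomer (delta_fil = 2.7 nm) along the barbed-end tangent and is accepted
iff excluded volume permits it in the *current* configuration — i.e. iff
the membrane's fluctuating shape can accommodate the addition; otherwise it
is a null event (time still advances).  Depolymerization removes the barbed
bead unconditionally (the base segment never depolymerizes).

Between reactions, nu * dt configurational sweeps of membrane and filament
moves are executed, interleaved in proportion to their degree-of-freedom
counts; nu couples the MC quasi-dynamics timescale to reaction time (unit
1/k_on,0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from ._kernels import FilBuf
from .energy import constraint_check
from .montecarlo import MembraneMC

EV_ON = 0        # polymerization accepted
EV_ON_NULL = 1   # polymerization blocked by excluded volume
EV_OFF = 2       # depolymerization
EV_OFF_NULL = 3  # depolymerization refused (single-monomer filament)


@dataclass
class GrowthParams:
    k_on0: float = 1.0        # attempt rate; sets the time unit
    k_off: float = 0.01       # depolymerization rate (k_off/k_on,0 = 1e-2)
    nu: float = 100.0         # configurational sweeps per unit reaction time
    t_max: float = 1000.0
    seed: int = 0
    stop_height: float = 260.0   # tube-formed reporting threshold, nm
    rigid: bool = False          # skip filament bending moves (L_p -> inf)
    snapshot_stride: int = 0     # events between snapshots; 0 = none

    def __post_init__(self):
        if self.k_on0 < 0 or self.k_off < 0:
            raise ValueError("rates must be >= 0")
        if self.nu <= 0:
            raise ValueError("nu must be positive")


@dataclass
class GrowthTrajectory:
    times: np.ndarray
    filament: np.ndarray
    event: np.ndarray
    length: np.ndarray          # monomer count of the reacting filament
    height: np.ndarray          # membrane max height at the event, nm
    snapshots: list = field(default_factory=list)
    stopped: str = "t_max"

    def contour_length(self, fi, delta=2.7):
        """(t, L) trace of filament fi's contour length."""
        sel = self.filament == fi
        ev = self.event[sel]
        t = self.times[sel]
        n = self.length[sel]
        return t, n * delta

    def acceptance_by_length(self, fi=None):
        """On-attempt acceptance fraction per monomer count."""
        sel = np.isin(self.event, [EV_ON, EV_ON_NULL])
        if fi is not None:
            sel &= self.filament == fi
        n = self.length[sel]
        acc = self.event[sel] == EV_ON
        out = {}
        for nn, aa in zip(n, acc):
            a, b = out.get(nn, (0, 0))
            out[nn] = (a + int(aa), b + 1)
        return {k: v[0] / v[1] for k, v in sorted(out.items())}, out


class GrowthSim:
    """Event-driven growth of filaments against the fluctuating membrane."""

    def __init__(self, mc: MembraneMC, params: GrowthParams):
        self.mc = mc
        self.p = params
        self.rng = np.random.default_rng(params.seed)
        self.t = 0.0
        self._sweep_debt = 0.0
        ok, viol = constraint_check(mc.mesh, mc.params, mc.filaments)
        if not ok:
            raise ValueError(f"initial state violates constraints: {viol}")

    # ------------------------------------------------------------- events

    def kmc_event(self):
        """Draw (dt, filament, channel); channel is 'on' or 'off'."""
        N = len(self.mc.filaments)
        if N == 0:
            raise ValueError("need at least one filament")
        rtot = N * (self.p.k_on0 + self.p.k_off)
        if rtot == 0:
            return np.inf, -1, "none"
        dt = self.rng.exponential(1.0 / rtot)
        fi = int(self.rng.random() * N)
        p_on = self.p.k_on0 / (self.p.k_on0 + self.p.k_off)
        channel = "on" if self.rng.random() < p_on else "off"
        return dt, fi, channel

    def attempt_polymerize(self, fi):
        """Sterically gated growth of filament fi; True iff accepted."""
        mc = self.mc
        fb = mc.fb
        n = int(fb.n[fi])
        if n + 1 >= fb.pos.shape[1]:
            self._grow_buffer()
            fb = mc.fb
        tip = fb.pos[fi, n]
        tang = fb.pos[fi, n] - fb.pos[fi, n - 1]
        tang = tang / np.linalg.norm(tang)
        f0 = mc.filaments[0]
        new = tip + f0.delta * tang
        mesh = mc.mesh
        dmix = 0.5 * (mc.params.d_mem + mc.params.d_fil)
        dummy = np.empty(1, np.int32)
        if not K.point_clear_membrane(mesh.m, new[0], new[1], new[2], dmix,
                                      dummy, 0):
            return False
        if not K.point_clear_filaments(fb, len(mc.filaments), new[0], new[1],
                                       new[2], mc.params.d_fil, fi, n - 3,
                                       mesh.Lx, mesh.Ly):
            return False
        fb.pos[fi, n + 1] = new
        fb.n[fi] = n + 1
        mc.filaments[fi].n = n + 1
        return True

    def depolymerize(self, fi):
        fb = self.mc.fb
        if fb.n[fi] < 2:
            return False
        fb.n[fi] -= 1
        self.mc.filaments[fi].n = int(fb.n[fi])
        return True

    def _grow_buffer(self):
        fb = self.mc.fb
        cap = fb.pos.shape[1] * 2
        nb = FilBuf(
            pos=np.zeros((fb.pos.shape[0], cap, 3)),
            n=fb.n.copy(),
            scratch=np.zeros((cap, 3)),
        )
        nb.pos[:, : fb.pos.shape[1]] = fb.pos
        self.mc.fb = nb

    # ---------------------------------------------------------------- run

    def _advance(self, dt):
        """Run nu * dt configurational sweeps (fractional part carried)."""
        self._sweep_debt += self.p.nu * dt
        n = int(self._sweep_debt)
        self._sweep_debt -= n
        if n == 0:
            return
        mc = self.mc
        V = mc.mesh.n_vertices
        gc = mc.params.z > 0
        nx = int(round(mc.schedule.exchange_fraction * V)) if gc else 0
        nfil = 0 if self.p.rigid else sum(
            max(int(f.n) - 1, 0) for f in mc.filaments)
        prm = mc.prm
        for _ in range(n):
            K.run_moves(mc.mesh.m, mc.fb, len(mc.filaments), prm, mc.rng,
                        mc.counters, V, V, nx, nx, nfil)

    def height(self):
        ids = self.mc.mesh.vertex_ids
        return float(self.mc.mesh.m.pos[ids, 2].max())

    def step(self):
        """Advance to the next reaction; returns (t, fi, event_code)."""
        dt, fi, channel = self.kmc_event()
        self._advance(dt)
        self.t += dt
        if channel == "on":
            ok = self.attempt_polymerize(fi)
            code = EV_ON if ok else EV_ON_NULL
        else:
            ok = self.depolymerize(fi)
            code = EV_OFF if ok else EV_OFF_NULL
        return self.t, fi, code

    def run(self, max_events=None):
        """Event loop until t_max, the stop height, or max_events."""
        p = self.p
        times, fils, evs, lens, hts = [], [], [], [], []
        snaps = []
        stopped = "t_max"
        i = 0
        while self.t < p.t_max:
            if max_events is not None and i >= max_events:
                stopped = "max_events"
                break
            t, fi, code = self.step()
            h = self.height()
            times.append(t)
            fils.append(fi)
            evs.append(code)
            lens.append(int(self.mc.fb.n[fi]))
            hts.append(h)
            if p.snapshot_stride and i % p.snapshot_stride == 0:
                snaps.append(self._snapshot())
            if h >= p.stop_height:
                stopped = "tube"
                break
            i += 1
        self.mc.sync_filaments()
        return GrowthTrajectory(
            times=np.array(times), filament=np.array(fils),
            event=np.array(evs), length=np.array(lens),
            height=np.array(hts), snapshots=snaps, stopped=stopped)

    def _snapshot(self):
        mesh = self.mc.mesh
        return {
            "t": self.t,
            "positions": mesh.positions(),
            "faces": mesh.faces(),
            "filaments": [f.nodes.copy()
                          for f in self.mc.sync_filaments()],
        }
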