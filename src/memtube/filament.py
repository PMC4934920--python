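"""Discretized worm-like-chain filaments with fixed bases.

A filament with ``n`` monomers is a chain of ``n + 1`` beads at fixed spacing
delta_fil = 2.7 nm (one bead per monomer-sized segment).  The base segment
(beads 0 and 1) is immutable in both position and orientation, representing
anchoring of the filament in the underlying network.  Bending energy is the
standard discrete WLC Hamiltonian

    E = (L_p / delta_fil) * sum_i (1 - t_i . t_{i+1})   [k_BT]

with unit tangents t_i and persistence length L_p (15 um for actin).
Configurational moves are terminal free rotations (pivot) and crankshaft
rotations of interior arcs; both are exact rigid rotations, so segment
lengths are preserved to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from ._kernels import FilBuf

DELTA_FIL = 2.7   # nm added per polymerization event
D_FIL = 10.0      # filament bead hard-core diameter, nm


class FilamentError(ValueError):
    pass


@dataclass
class Filament:
    """State of one discretized filament."""

    base: np.ndarray              # base bead position (nm)
    orientation: np.ndarray       # unit base tangent
    n: int = 1                    # monomer count (= segment count)
    delta: float = DELTA_FIL
    L_p: float = 15000.0          # persistence length, nm
    d: float = D_FIL
    nodes: np.ndarray = None      # (n+1, 3) bead positions

    def __post_init__(self):
        self.base = np.asarray(self.base, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        nrm = np.linalg.norm(self.orientation)
        if nrm == 0:
            raise FilamentError("zero base orientation")
        self.orientation = self.orientation / nrm
        if self.n < 1:
            raise FilamentError("n must be >= 1")
        if self.nodes is None:
            s = np.arange(self.n + 1)[:, None] * self.delta
            self.nodes = self.base[None, :] + s * self.orientation[None, :]
        self.nodes = np.asarray(self.nodes, dtype=float)

    @property
    def barbed_end(self):
        return self.nodes[-1]

    @property
    def tip_tangent(self):
        t = self.nodes[-1] - self.nodes[-2]
        return t / np.linalg.norm(t)

    @property
    def contour_length(self):
        return self.n * self.delta

    def copy(self):
        return Filament(self.base.copy(), self.orientation.copy(), self.n,
                        self.delta, self.L_p, self.d, self.nodes.copy())


def wlc_bend_energy(f: Filament):
    """Discrete WLC bending energy in k_BT."""
    if f.n < 2:
        return 0.0
    t = np.diff(f.nodes, axis=0)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    return float((f.L_p / f.delta) * np.sum(1.0 - np.einsum("ij,ij->i",
                                                            t[:-1], t[1:])))


def grow(f: Filament):
    """Append one monomer along the barbed-end tangent (locks in curvature)."""
    g = f.copy()
    new = g.nodes[-1] + g.delta * g.tip_tangent
    g.nodes = np.vstack([g.nodes, new])
    g.n += 1
    return g


def shrink(f: Filament):
    """Remove the barbed-end bead; the base segment is never removed."""
    if f.n < 2:
        raise FilamentError("cannot shrink a single-monomer filament")
    g = f.copy()
    g.nodes = g.nodes[:-1].copy()
    g.n -= 1
    return g


# ------------------------------------------------- buffers for the kernels

def pack_filaments(filaments, cap=None):
    """Pack a list of filaments into the flat kernel buffer."""
    nfil = len(filaments)
    if nfil == 0:
        return K.empty_filbuf()
    cap = cap or max(max(f.n for f in filaments) + 1 + 64, 128)
    fb = FilBuf(
        pos=np.zeros((nfil, cap, 3)),
        n=np.zeros(nfil, dtype=np.int32),
        scratch=np.zeros((cap, 3)),
    )
    for i, f in enumerate(filaments):
        fb.pos[i, : f.n + 1] = f.nodes
        fb.n[i] = f.n
    return fb


def unpack_filaments(fb, filaments):
    """Write kernel-buffer coordinates back into the Filament objects."""
    for i, f in enumerate(filaments):
        f.n = int(fb.n[i])
        f.nodes = fb.pos[i, : f.n + 1].copy()
    return filaments


_DUMMY_MESH = None


def _dummy_mesh():
    """A far-away minimal mesh so filament-only kernels can run membrane-free."""
    global _DUMMY_MESH
    if _DUMMY_MESH is None:
        from .mesh import build_flat_patch

        _DUMMY_MESH = build_flat_patch(1e6, 1e6, 1.2e5,
                                       frozen_boundary=False)
        _DUMMY_MESH.m.pos[:, 2] = 1e9
    return _DUMMY_MESH


def filament_mc_step(f: Filament, membrane=None, others=(), amplitude=0.3,
                     rng=None):
    """One Metropolis pivot/crankshaft move on ``f``; returns accepted flag.

    ``membrane`` is a :class:`~memtube.mesh.TriMesh` or None; ``others`` are
    other filaments entering the steric test.
    """
    rng = rng if rng is not None else np.random.default_rng()
    fils = [f] + list(others)
    fb = pack_filaments(fils)
    mesh = membrane if membrane is not None else _dummy_mesh()
    prm = np.zeros(12)
    prm[K.P_AMIN], prm[K.P_AMAX] = 5.0, 13.0
    prm[K.P_DMEM], prm[K.P_DFIL] = 5.0, f.d
    prm[K.P_AMPFIL] = amplitude
    prm[K.P_LP], prm[K.P_DELTA] = f.L_p, f.delta
    acc = K.try_fil_move(mesh.m, fb, len(fils), 0, prm, rng,
                         membrane is not None)
    if acc:
        unpack_filaments(fb, fils)
    return bool(acc)


def sample_free_filament(f: Filament, n_moves, amplitude=0.3, rng=None,
                         sample_every=None):
    """MC-sample a membrane-free filament; yields node snapshots.

    Used for thermal-ensemble checks (tangent correlations, tip variance).
    """
    rng = rng if rng is not None else np.random.default_rng()
    fb = pack_filaments([f])
    mesh = _dummy_mesh()
    prm = np.zeros(12)
    prm[K.P_AMIN], prm[K.P_AMAX] = 5.0, 13.0
    prm[K.P_DMEM], prm[K.P_DFIL] = 5.0, 0.0  # no sterics for ideal WLC checks
    prm[K.P_AMPFIL] = amplitude
    prm[K.P_LP], prm[K.P_DELTA] = f.L_p, f.delta
    counters = np.zeros(12, np.int64)
    out = []
    stride = sample_every or max(1, n_moves // 200)
    nblocks = n_moves // stride
    for _ in range(nblocks):
        K.run_moves(mesh.m, fb, 1, prm, rng, counters, 0, 0, 0, 0, stride)
        out.append(fb.pos[0, : fb.n[0] + 1].copy())
    unpack_filaments(fb, [f])
    acc = counters[K.C_FIL + 1] / max(counters[K.C_FIL], 1)
    return out, float(acc)
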