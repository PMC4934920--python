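"""Membrane energetics: discrete Helfrich bending + tension, hard constraints,
and the external pulling potential.

The Hamiltonian is the discretized Helfrich form

    E = sum_v [ (kappa/2) (2 H_v)^2 + gamma ] A_v

with H_v the signed discrete mean curvature (cotangent scheme) and A_v the
barycentric vertex area.  kappa is the bending rigidity in k_BT, gamma the
surface tension in k_BT/nm^2.  In grand-canonical runs the area cost is
controlled by the fugacity z alone and gamma is set to zero to avoid double
counting (the two routes are linked by z = C exp(-gamma/(rho k_BT))).

Hard constraints: tether bounds [a_min, a_max] on every edge, hard-core
diameters d_mem (membrane beads) and d_fil (filament beads), mixed pairs at
(d_mem + d_fil)/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .mesh import MeshError, TriMesh, TopologyMove


@dataclass
class MembraneParams:
    kappa: float = 20.0          # bending rigidity, k_BT
    gamma: float = 0.0           # explicit surface tension, k_BT/nm^2
    z: float = 0.0               # fugacity of the implicit lipid reservoir
    rho: float | None = None     # fitted lateral density, 1/nm^2
    C: float | None = None       # fitted calibration constant of z(gamma)
    a_min: float = 5.0           # tether lower bound, nm (= d_mem)
    a_max: float = 13.0          # tether upper bound, nm
    d_mem: float = 5.0           # membrane bead hard-core diameter, nm
    d_fil: float = 10.0          # filament bead hard-core diameter, nm

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not self.a_min < self.a_max:
            raise ValueError("a_min must be < a_max")
        if self.d_mem > self.a_min:
            raise ValueError("d_mem must not exceed a_min")


@dataclass
class PullingSpring:
    """Vertical harmonic spring acting on the mean height of a vertex disk."""

    attachment: np.ndarray       # vertex ids
    anchor: float                # anchor height, nm
    stiffness: float             # k_BT/nm^2

    def __post_init__(self):
        self.attachment = np.asarray(self.attachment, dtype=np.int64)
        if self.stiffness < 0:
            raise ValueError("stiffness must be >= 0")


def install_spring(mesh: TriMesh, spring: PullingSpring):
    """Register the spring on the mesh buffers so MC moves see its energy."""
    m = mesh.m
    if len(spring.attachment) == 0:
        raise MeshError("empty attachment set")
    m.att[:] = 0
    m.att[spring.attachment] = 1
    m.spring[0] = spring.stiffness
    m.spring[1] = spring.anchor
    m.spring[2] = float(m.pos[spring.attachment, 2].sum())
    m.spring[3] = float(len(spring.attachment))
    # attachment vertices must not be removable while the spring is active
    for v in spring.attachment:
        K.n3_fix(m, np.int64(v))


def spring_energy_force(mesh: TriMesh):
    """(energy, instantaneous force) of the installed spring."""
    m = mesh.m
    if m.spring[3] == 0:
        return 0.0, 0.0
    zbar = m.spring[2] / m.spring[3]
    ext = m.spring[1] - zbar
    return 0.5 * m.spring[0] * ext * ext, m.spring[0] * ext


def pulling_force(mesh: TriMesh, spring: PullingSpring):
    """Harmonic pulling energy and force of ``spring`` on the current shape.

    force = stiffness x mean vertical extension of the attachment set below
    the anchor; positive when the spring pulls the membrane upward.
    Time-averaging is the caller's business.
    """
    if len(spring.attachment) == 0:
        raise MeshError("empty attachment set")
    zbar = float(mesh.m.pos[spring.attachment, 2].mean())
    ext = spring.anchor - zbar
    return 0.5 * spring.stiffness * ext * ext, spring.stiffness * ext


def total_energy(mesh: TriMesh, p: MembraneParams, spring=None):
    """Total membrane energy in k_BT (bending + tension [+ spring])."""
    e = float(K.total_bend_tension(mesh.m, p.kappa, p.gamma))
    if spring is not None:
        e += pulling_force(mesh, spring)[0]
    return e


def bending_energy(mesh: TriMesh, p: MembraneParams):
    return float(K.total_bend_tension(mesh.m, p.kappa, 0.0))


def energy_delta(mesh: TriMesh, change, p: MembraneParams):
    """Energy change of a proposed move, touching only its neighborhood.

    ``change`` is either ``(vertex_id, new_xyz)`` for a displacement or a
    :class:`TopologyMove`.  The mesh is returned to its original state.
    """
    m = mesh.m
    if isinstance(change, TopologyMove):
        if change.kind == "vertex_insert":
            t = int(change.target)
            vs = np.array(list(m.tri[t]), np.int32)
            e0 = K.local_energy(m, vs, 3, p.kappa, p.gamma)
            rec = mesh.apply_topology_move(change)
            vs4 = np.append(vs, np.int32(rec[1]))
            e1 = K.local_energy(m, vs4, 4, p.kappa, p.gamma)
            mesh.undo(rec)
            return float(e1 - e0)
        if change.kind == "vertex_remove":
            v = int(change.target)
            a, b, c = K.ordered_ring3(m, np.int64(v))
            vs = np.array([a, b, c, v], np.int32)
            e0 = K.local_energy(m, vs, 4, p.kappa, p.gamma)
            rec = mesh.apply_topology_move(change)
            e1 = K.local_energy(m, vs, 3, p.kappa, p.gamma)
            mesh.undo(rec)
            return float(e1 - e0)
        # edge flip
        i, j = change.target
        rec = mesh.apply_topology_move(change)
        _, (_, _, l, k, _, _) = rec
        vs = np.array([i, j, k, l], np.int32)
        e1 = K.local_energy(m, vs, 4, p.kappa, p.gamma)
        mesh.undo(rec)
        e0 = K.local_energy(m, vs, 4, p.kappa, p.gamma)
        return float(e1 - e0)
    v, new_xyz = change
    v = int(v)
    if m.frozen[v]:
        raise MeshError(f"vertex {v} is frozen")
    ring = np.empty(K.MAXDEG, np.int32)
    nr = K.ring_of(m, np.int64(v), ring)
    vs = np.concatenate(([np.int32(v)], ring[:nr]))
    e0 = K.local_energy(m, vs, nr + 1, p.kappa, p.gamma)
    old = m.pos[v].copy()
    m.pos[v, 0] = new_xyz[0] % mesh.Lx
    m.pos[v, 1] = new_xyz[1] % mesh.Ly
    m.pos[v, 2] = new_xyz[2]
    e1 = K.local_energy(m, vs, nr + 1, p.kappa, p.gamma)
    m.pos[v] = old
    return float(e1 - e0)


def constraint_check(mesh: TriMesh, p: MembraneParams, filaments=()):
    """Exhaustive hard-constraint predicate.

    Fails iff any edge length is outside [a_min, a_max], any non-identical
    membrane bead pair is closer than d_mem, any membrane-filament bead pair
    closer than (d_mem + d_fil)/2, or any bead pair on distinct filaments
    (or distant along one chain) closer than d_fil.  Returns
    ``(ok, first_violation_or_None)``.
    """
    ids = mesh.vertex_ids
    pos = mesh.m.pos[ids]
    tri = mesh.faces()
    # edge lengths
    edges = np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    dr = mesh.minimum_image(mesh.m.pos[edges[:, 1]] - mesh.m.pos[edges[:, 0]])
    elen = np.linalg.norm(dr, axis=1)
    bad = np.where((elen < p.a_min - 1e-9) | (elen > p.a_max + 1e-9))[0]
    if len(bad):
        i, j = edges[bad[0]]
        return False, ("edge_length", int(i), int(j), float(elen[bad[0]]))
    # membrane bead pairs
    d = _pair_dist(pos, pos, mesh.Lx, mesh.Ly)
    np.fill_diagonal(d, np.inf)
    ii, jj = np.unravel_index(np.argmin(d), d.shape)
    if d[ii, jj] < p.d_mem - 1e-9:
        return False, ("membrane_overlap", int(ids[ii]), int(ids[jj]),
                       float(d[ii, jj]))
    fil_nodes = [np.asarray(f.nodes) for f in filaments]
    for fi, fa in enumerate(fil_nodes):
        dmf = _pair_dist(pos, fa, mesh.Lx, mesh.Ly)
        if dmf.size and dmf.min() < 0.5 * (p.d_mem + p.d_fil) - 1e-9:
            return False, ("membrane_filament", fi, float(dmf.min()))
        for gi in range(fi, len(fil_nodes)):
            dff = _pair_dist(fa, fil_nodes[gi], mesh.Lx, mesh.Ly)
            if fi == gi:
                n = len(fa)
                ix = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
                dff = np.where(ix <= 4, np.inf, dff)
            if dff.size and dff.min() < p.d_fil - 1e-9:
                return False, ("filament_filament", fi, gi, float(dff.min()))
    return True, None


def _pair_dist(a, b, Lx, Ly):
    d = a[:, None, :] - b[None, :, :]
    d[..., 0] -= Lx * np.round(d[..., 0] / Lx)
    d[..., 1] -= Ly * np.round(d[..., 1] / Ly)
    return np.linalg.norm(d, axis=-1)
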