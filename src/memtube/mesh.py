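"""Periodic dynamically triangulated surface.

The membrane is a square patch, periodic in x and y (a genus-1 surface under
the periodic wrap, so V - E + F = 0), embedded in 3-space with unbounded z.
Vertices are hard beads connected by tethers; the triangulation is made fluid
by edge flips and coupled to an implicit lipid reservoir by vertex
insertion/removal moves (see :mod:`memtube.montecarlo`).

Units: nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from ._kernels import MAXDEG, MeshBuf


@dataclass
class TopologyMove:
    """A proposed discrete change of the triangulation.

    kind: one of ``edge_flip``, ``vertex_insert``, ``vertex_remove``.
    target: vertex id (remove), triangle id (insert), or vertex-id pair (flip).
    coords: proposed (x, y, z) for inserts.
    """

    kind: str
    target: object
    coords: tuple | None = None


class MeshError(ValueError):
    pass


class TriMesh:
    """Dynamically triangulated periodic membrane patch."""

    def __init__(self, positions, triangles, Lx, Ly, frozen=(), capacity=None):
        positions = np.asarray(positions, dtype=np.float64)
        triangles = np.asarray(triangles, dtype=np.int32)
        nv = len(positions)
        nf = len(triangles)
        capV = capacity or max(4 * nv, nv + 64)
        capF = 2 * capV
        m = MeshBuf(
            pos=np.zeros((capV, 3)),
            tri=np.zeros((capF, 3), np.int32),
            v2t=np.full((capV, MAXDEG), -1, np.int32),
            v2tn=np.zeros(capV, np.int32),
            frozen=np.zeros(capV, np.uint8),
            att=np.zeros(capV, np.uint8),
            valive=np.zeros(capV, np.uint8),
            talive=np.zeros(capF, np.uint8),
            vlist=np.full(capV, -1, np.int32),
            vposl=np.full(capV, -1, np.int32),
            mlist=np.full(capV, -1, np.int32),
            mposl=np.full(capV, -1, np.int32),
            tlist=np.full(capF, -1, np.int32),
            tposl=np.full(capF, -1, np.int32),
            n3l=np.full(capV, -1, np.int32),
            n3posl=np.full(capV, -1, np.int32),
            vfree=np.zeros(capV, np.int32),
            tfree=np.zeros(capF, np.int32),
            meta=np.zeros(8, np.int64),
            box=np.array([float(Lx), float(Ly)]),
            spring=np.zeros(4),
        )
        m.pos[:nv] = positions
        m.pos[:nv, 0] %= Lx
        m.pos[:nv, 1] %= Ly
        m.tri[:nf] = triangles
        m.valive[:nv] = 1
        m.talive[:nf] = 1
        for v in frozen:
            m.frozen[v] = 1
        m.vlist[:nv] = np.arange(nv, dtype=np.int32)
        m.vposl[:nv] = np.arange(nv, dtype=np.int32)
        m.tlist[:nf] = np.arange(nf, dtype=np.int32)
        m.tposl[:nf] = np.arange(nf, dtype=np.int32)
        mob = np.array([v for v in range(nv) if not m.frozen[v]], np.int32)
        m.mlist[: len(mob)] = mob
        m.mposl[mob] = np.arange(len(mob), dtype=np.int32)
        m.meta[0] = nv
        m.meta[1] = nf
        m.meta[2] = len(mob)
        # free stacks hold unused slots, top of stack at the end
        m.vfree[: capV - nv] = np.arange(capV - 1, nv - 1, -1, dtype=np.int32)
        m.meta[4] = capV - nv
        m.tfree[: capF - nf] = np.arange(capF - 1, nf - 1, -1, dtype=np.int32)
        m.meta[5] = capF - nf
        # incident-triangle lists
        for t in range(nf):
            for k in range(3):
                v = triangles[t, k]
                m.v2t[v, m.v2tn[v]] = t
                m.v2tn[v] += 1
        if m.v2tn[:nv].max(initial=0) > MAXDEG:
            raise MeshError("vertex degree exceeds supported maximum")
        self.m = m
        for v in range(nv):
            K.n3_fix(m, v)
        self._frozen_ref = {int(v): m.pos[v].copy() for v in frozen}

    # ------------------------------------------------------------ queries

    @property
    def n_vertices(self):
        return int(self.m.meta[0])

    @property
    def n_faces(self):
        return int(self.m.meta[1])

    @property
    def n_edges(self):
        # every edge bounds exactly 2 of F triangles with 3 edges each
        return 3 * self.n_faces // 2

    @property
    def euler_characteristic(self):
        return self.n_vertices - self.n_edges + self.n_faces

    @property
    def Lx(self):
        return float(self.m.box[0])

    @property
    def Ly(self):
        return float(self.m.box[1])

    @property
    def vertex_ids(self):
        return np.sort(self.m.vlist[: self.n_vertices].copy())

    @property
    def frozen_ids(self):
        ids = self.vertex_ids
        return ids[self.m.frozen[ids] == 1]

    def positions(self, ids=None):
        if ids is None:
            ids = self.vertex_ids
        return self.m.pos[ids].copy()

    def faces(self):
        tl = np.sort(self.m.tlist[: self.n_faces].copy())
        return self.m.tri[tl].copy()

    def degree(self, v):
        return int(self.m.v2tn[v])

    def neighbors(self, v):
        out = np.empty(MAXDEG, np.int32)
        n = K.ring_of(self.m, np.int64(v), out)
        return np.sort(out[:n].copy())

    def minimum_image(self, dr):
        dr = np.array(dr, dtype=float, copy=True)
        for ax, L in ((0, self.Lx), (1, self.Ly)):
            dr[..., ax] -= L * np.round(dr[..., ax] / L)
        return dr

    def total_area(self):
        return float(K.total_area(self.m))

    def vertex_geometry(self, v):
        """Per-vertex (area, signed mean curvature, unit normal).

        The barycentric area partition satisfies sum_v A_v = total area; the
        mean curvature is half the norm of the cotangent mean-curvature
        vector, signed by its projection on the vertex normal.
        """
        m = self.m
        if not (0 <= v < len(m.valive)) or not m.valive[v]:
            raise MeshError(f"vertex {v} does not exist")
        if m.v2tn[v] < 3:
            raise MeshError(f"vertex {v} has an incomplete one-ring")
        A, Kx, Ky, Kz, nx, ny, nz = K.vertex_bend_area(m, np.int64(v))
        nrm = np.array([nx, ny, nz])
        nn = np.linalg.norm(nrm)
        if nn < 1e-14:
            raise MeshError(f"degenerate normal at vertex {v}")
        nrm /= nn
        kvec = np.array([Kx, Ky, Kz])
        H = 0.5 * float(np.dot(kvec, nrm))
        return float(A), H, nrm

    def freeze_vertex(self, v):
        """Immobilize vertex v for the rest of the run (e.g. an adhesion
        point); it leaves the mobile and removable candidate lists and its
        coordinates become part of the frozen reference."""
        m = self.m
        v = int(v)
        if not m.valive[v]:
            raise MeshError(f"vertex {v} does not exist")
        if m.frozen[v]:
            return
        m.frozen[v] = 1
        if m.mposl[v] >= 0:
            m.meta[2] = K._list_remove(m.mlist, m.mposl, m.meta[2],
                                       np.int64(v))
        K.n3_fix(m, np.int64(v))
        self._frozen_ref[v] = m.pos[v].copy()

    # ----------------------------------------------------- topology moves

    def apply_topology_move(self, move: TopologyMove):
        """Apply a topology move; returns an undo record.

        Raises :class:`MeshError` (state unchanged) if the move is invalid:
        degenerate/duplicate simplices, a frozen or non-removable target, or
        an edge flip that would duplicate an existing edge.
        """
        m = self.m
        if move.kind == "edge_flip":
            i, j = move.target
            t = t2 = -1
            for it in range(m.v2tn[i]):
                tt = m.v2t[i, it]
                tv = list(m.tri[tt])
                if j in tv:
                    # directed edge (i, j) appears in exactly one triangle
                    if tv[(tv.index(i) + 1) % 3] == j:
                        t = tt
                    else:
                        t2 = tt
            if t < 0 or t2 < 0:
                raise MeshError(f"edge ({i},{j}) not found")
            tv = list(m.tri[t])
            k = [w for w in tv if w not in (i, j)][0]
            l = [w for w in m.tri[t2] if w not in (i, j)][0]
            if m.v2tn[i] < 4 or m.v2tn[j] < 4:
                raise MeshError("flip would create a vertex of degree < 3")
            if m.v2tn[k] >= MAXDEG or m.v2tn[l] >= MAXDEG:
                raise MeshError("flip would exceed the degree cap")
            if K.edge_exists(m, np.int64(k), np.int64(l)):
                raise MeshError("flip would duplicate an existing edge")
            K.apply_flip(m, t, t2, i, j, k, l)
            return ("edge_flip", (t, t2, l, k, i, j))
        if move.kind == "vertex_insert":
            t = int(move.target)
            if not m.talive[t]:
                raise MeshError(f"triangle {t} does not exist")
            a, b, c = m.tri[t]
            if any(m.v2tn[w] >= MAXDEG for w in (a, b, c)):
                raise MeshError("insert would exceed the degree cap")
            if m.meta[4] < 1 or m.meta[5] < 2:
                raise MeshError("mesh capacity exhausted")
            x, y, z = move.coords
            vn = K.apply_insert(m, t, float(x), float(y), float(z))
            return ("vertex_insert", int(vn))
        if move.kind == "vertex_remove":
            v = int(move.target)
            if not m.valive[v]:
                raise MeshError(f"vertex {v} does not exist")
            if m.frozen[v]:
                raise MeshError(f"vertex {v} is frozen")
            if m.v2tn[v] != 3:
                raise MeshError("only 3-coordinated vertices are removable")
            a, b, c = K.ordered_ring3(m, np.int64(v))
            if any(m.v2tn[w] < 4 for w in (a, b, c)):
                raise MeshError("removal would create a vertex of degree < 3")
            for it in range(m.v2tn[a]):
                tt = m.v2t[a, it]
                tv = set(m.tri[tt])
                if b in tv and c in tv:
                    raise MeshError("removal would duplicate a triangle")
            x, y, z = (float(q) for q in m.pos[v])
            t_kept = K.apply_remove(m, np.int64(v))
            return ("vertex_remove", (int(t_kept), x, y, z))
        raise MeshError(f"unknown move kind {move.kind!r}")

    def undo(self, record):
        kind, data = record
        m = self.m
        if kind == "edge_flip":
            K.apply_flip(m, *data)
        elif kind == "vertex_insert":
            K.apply_remove(m, np.int64(data))
        elif kind == "vertex_remove":
            t_kept, x, y, z = data
            K.apply_insert(m, t_kept, x, y, z)

    # --------------------------------------------------------- validation

    def validate(self):
        """Recompute all invariants from scratch; raises on inconsistency."""
        m = self.m
        nv, nf = self.n_vertices, self.n_faces
        vids = set(int(v) for v in self.m.vlist[:nv])
        tids = [int(t) for t in self.m.tlist[:nf]]
        assert len(vids) == nv and len(set(tids)) == nf
        edges = {}
        for t in tids:
            tv = [int(w) for w in m.tri[t]]
            assert len(set(tv)) == 3, "degenerate triangle"
            assert all(w in vids for w in tv)
            for k in range(3):
                e = (tv[k], tv[(k + 1) % 3])
                assert e not in edges, f"duplicate directed edge {e}"
                edges[e] = t
        for (i, j) in edges:
            assert (j, i) in edges, f"unpaired edge ({i},{j})"
        ne = len(edges) // 2
        assert nv - ne + nf == 0, "Euler characteristic != 0"
        # incident-triangle lists match the triangle table
        from collections import defaultdict

        v2t_ref = defaultdict(set)
        for t in tids:
            for w in m.tri[t]:
                v2t_ref[int(w)].add(t)
        for v in vids:
            got = set(int(t) for t in m.v2t[v, : m.v2tn[v]])
            assert got == v2t_ref[v], f"v2t mismatch at {v}"
        # removable-candidate list
        n3_ref = {
            v
            for v in vids
            if m.v2tn[v] == 3 and not m.frozen[v] and not m.att[v]
        }
        got = set(int(v) for v in m.n3l[: m.meta[3]])
        assert got == n3_ref, "removable-vertex list inconsistent"
        # frozen vertices never move
        for v, ref in self._frozen_ref.items():
            assert np.array_equal(m.pos[v], ref), f"frozen vertex {v} moved"
        return True


def build_flat_patch(Lx, Ly, target_edge, seed=0, frozen_boundary=True,
                     capacity_factor=4.0):
    """Near-uniform flat triangulation of a periodic Lx x Ly patch at z = 0.

    The patch tiles a triangular lattice onto the periodic box; the row count
    must come out even for a consistent wrap, and the realized edge lengths
    must stay within ~20% of ``target_edge`` or the box is rejected as
    non-tileable.

    ``frozen_boundary`` selects the frame constraint: ``True`` freezes three
    equidistant vertices on the y=0 boundary row (the default used for
    filament-growth runs), ``"frame"`` freezes the whole y=0 row and x=0
    column (a stiff clamped frame for strong point loads such as tube
    pulling, where 3-point pinning would let the sheet tent upwards), and
    ``False`` leaves the patch unpinned (spectrum runs).
    """
    if Lx <= 0 or Ly <= 0 or target_edge <= 0:
        raise MeshError("box lengths and target edge must be positive")
    nx = max(3, int(round(Lx / target_edge)))
    ny = max(4, int(round(Ly / (target_edge * np.sqrt(3) / 2))))
    if ny % 2:
        ny += 1 if (Ly / (target_edge * np.sqrt(3) / 2)) > ny else -1
    ax = Lx / nx
    ay = Ly / ny
    edge_row = ax
    edge_diag = np.hypot(ax / 2, ay)
    for e in (edge_row, edge_diag):
        if not (0.8 * target_edge <= e <= 1.25 * target_edge):
            raise MeshError(
                f"target_edge {target_edge} nm not tileable on "
                f"{Lx} x {Ly} nm box (realized edges {edge_row:.2f}, "
                f"{edge_diag:.2f} nm)"
            )
    pos = np.zeros((nx * ny, 3))
    idx = lambda i, j: (j % ny) * nx + (i % nx)
    for j in range(ny):
        for i in range(nx):
            pos[idx(i, j), 0] = (i + 0.5 * (j % 2)) * ax
            pos[idx(i, j), 1] = j * ay
    tris = []
    for j in range(ny):
        for i in range(nx):
            if j % 2 == 0:
                tris.append((idx(i, j), idx(i + 1, j), idx(i, j + 1)))
                tris.append((idx(i + 1, j), idx(i + 1, j + 1), idx(i, j + 1)))
            else:
                tris.append((idx(i, j), idx(i + 1, j + 1), idx(i, j + 1)))
                tris.append((idx(i, j), idx(i + 1, j), idx(i + 1, j + 1)))
    frozen = ()
    if frozen_boundary == "frame":
        frozen = tuple(
            sorted(
                {idx(i, 0) for i in range(nx)}
                | {idx(0, j) for j in range(ny)}
            )
        )
    elif frozen_boundary:
        frozen = tuple(idx(int(round(f * nx)) % nx, 0) for f in (0, 1 / 3, 2 / 3))
        if len(set(frozen)) != 3:
            frozen = tuple(idx(i, 0) for i in (0, nx // 3, 2 * nx // 3))
    mesh = TriMesh(
        pos,
        np.array(tris, np.int32),
        Lx,
        Ly,
        frozen=frozen,
        capacity=int(capacity_factor * nx * ny),
    )
    return mesh
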