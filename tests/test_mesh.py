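"""Topology and geometry of the periodic triangulated surface."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memtube import _kernels as K
from memtube.mesh import MeshError, TopologyMove, TriMesh, build_flat_patch


def test_flat_patch_counts_and_flatness():
    mesh = build_flat_patch(250.0, 250.0, 8.0)
    assert mesh.euler_characteristic == 0
    assert np.all(mesh.positions()[:, 2] == 0.0)
    assert len(mesh.frozen_ids) == 3
    # area partition reproduces the box area at zero temperature
    assert mesh.total_area() == pytest.approx(250.0 * 250.0, rel=1e-6)


def test_flat_patch_determinism():
    a = build_flat_patch(160.0, 160.0, 9.5, seed=7)
    b = build_flat_patch(160.0, 160.0, 9.5, seed=7)
    assert np.array_equal(a.positions(), b.positions())
    assert np.array_equal(a.faces(), b.faces())


def test_non_tileable_edge_rejected():
    with pytest.raises(MeshError):
        build_flat_patch(100.0, 100.0, 40.0)
    with pytest.raises(MeshError):
        build_flat_patch(-5.0, 100.0, 8.0)


def test_insert_remove_inverse(flat_mesh):
    mesh = flat_mesh
    v0, e0, f0 = mesh.n_vertices, mesh.n_edges, mesh.n_faces
    pos0 = mesh.positions()
    t = int(mesh.m.tlist[0])
    a, b, c = mesh.m.tri[t]
    cen = mesh.m.pos[[a, b, c]].mean(axis=0)
    rec = mesh.apply_topology_move(
        TopologyMove("vertex_insert", t, tuple(cen + [0.1, -0.2, 0.3])))
    assert (mesh.n_vertices, mesh.n_edges, mesh.n_faces) == (v0 + 1, e0 + 3,
                                                            f0 + 2)
    mesh.validate()
    vn = rec[1]
    mesh.apply_topology_move(TopologyMove("vertex_remove", vn))
    assert (mesh.n_vertices, mesh.n_edges, mesh.n_faces) == (v0, e0, f0)
    assert np.allclose(mesh.positions(), pos0)
    mesh.validate()


def test_euler_bookkeeping_from_scratch(flat_mesh):
    """V/E/F recomputed from the raw triangle table after an insertion."""
    mesh = flat_mesh
    t = int(mesh.m.tlist[5])
    cen = mesh.m.pos[mesh.m.tri[t]].mean(axis=0)
    mesh.apply_topology_move(TopologyMove("vertex_insert", t, tuple(cen)))
    tri = mesh.faces()
    verts = np.unique(tri)
    edges = np.unique(np.sort(np.concatenate(
        [tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]]), axis=1), axis=0)
    assert len(verts) == mesh.n_vertices
    assert len(edges) == mesh.n_edges
    assert len(tri) == mesh.n_faces
    assert len(verts) - len(edges) + len(tri) == 0


def test_edge_flip_conserves_counts(flat_mesh):
    mesh = flat_mesh
    t = int(mesh.m.tlist[0])
    i, j = int(mesh.m.tri[t, 0]), int(mesh.m.tri[t, 1])
    v0, e0, f0 = mesh.n_vertices, mesh.n_edges, mesh.n_faces
    rec = mesh.apply_topology_move(TopologyMove("edge_flip", (i, j)))
    assert (mesh.n_vertices, mesh.n_edges, mesh.n_faces) == (v0, e0, f0)
    mesh.validate()
    mesh.undo(rec)
    mesh.validate()


def test_flip_guards(flat_mesh):
    mesh = flat_mesh
    # flipping an edge of a freshly inserted degree-3 vertex must be
    # rejected (it would drop the vertex below degree 3)
    t = int(mesh.m.tlist[0])
    a = int(mesh.m.tri[t, 0])
    cen = mesh.m.pos[mesh.m.tri[t]].mean(axis=0)
    rec = mesh.apply_topology_move(
        TopologyMove("vertex_insert", t, tuple(cen)))
    vn = rec[1]
    with pytest.raises(MeshError):
        mesh.apply_topology_move(TopologyMove("edge_flip", (vn, a)))
    # flipping a stale (non-existent) edge also raises, state unchanged
    with pytest.raises(MeshError):
        mesh.apply_topology_move(TopologyMove("edge_flip", (vn, vn + 10**6)))
    mesh.validate()


def test_remove_frozen_vertex_rejected():
    mesh = build_flat_patch(120.0, 120.0, 9.5)
    frozen = int(mesh.frozen_ids[0])
    with pytest.raises(MeshError):
        mesh.apply_topology_move(TopologyMove("vertex_remove", frozen))


def test_vertex_geometry_flat_and_sum(flat_mesh):
    mesh = flat_mesh
    ids = mesh.vertex_ids
    areas = []
    for v in ids[:25]:
        A, H, n = mesh.vertex_geometry(int(v))
        assert abs(H) < 1e-6
        assert abs(abs(n[2]) - 1.0) < 1e-9
        areas.append(A)
    total = sum(mesh.vertex_geometry(int(v))[0] for v in ids)
    assert total == pytest.approx(mesh.Lx * mesh.Ly, rel=1e-9)


def test_sphere_curvature_converges(sphere_mesh):
    """Cotangent mean curvature approaches 1/R on a refining sphere."""
    ids = sphere_mesh.vertex_ids
    Hs = np.array([sphere_mesh.vertex_geometry(int(v))[1] for v in ids])
    assert np.median(Hs) == pytest.approx(1.0 / 50.0, rel=0.02)
    assert np.all(Hs > 0)  # signed consistently w.r.t. outward normals


def test_topology_move_fuzz():
    """Manifoldness and Euler characteristic survive random move storms."""
    from memtube.energy import MembraneParams
    from memtube.montecarlo import MembraneMC, MoveSchedule

    mesh = build_flat_patch(100.0, 100.0, 9.5)
    p = MembraneParams(kappa=15.0, gamma=0.0, z=0.003)
    mc = MembraneMC(mesh, p, MoveSchedule(exchange_fraction=0.3), seed=42)
    mc.run(120)  # ~1e5 attempted moves including GC exchanges
    mesh.validate()
    assert mesh.euler_characteristic == 0


def test_incremental_vs_scratch_area():
    from memtube.energy import MembraneParams
    from memtube.montecarlo import MembraneMC, MoveSchedule

    mesh = build_flat_patch(100.0, 100.0, 9.5)
    p = MembraneParams(kappa=15.0, gamma=0.0, z=0.002)
    mc = MembraneMC(mesh, p, MoveSchedule(exchange_fraction=0.2), seed=3)
    mc.run(50)
    # per-vertex areas summed two ways
    ids = mesh.vertex_ids
    s = sum(mesh.vertex_geometry(int(v))[0] for v in ids)
    assert s == pytest.approx(mesh.total_area(), rel=1e-9)


@given(st.floats(-300, 300), st.floats(-300, 300), st.floats(-50, 50))
@settings(max_examples=50, deadline=None)
def test_minimum_image_symmetry(dx, dy, dz):
    mesh = build_flat_patch(120.0, 120.0, 9.5)
    d = mesh.minimum_image(np.array([dx, dy, dz]))
    dneg = mesh.minimum_image(-np.array([dx, dy, dz]))
    assert np.allclose(d, -dneg)
    assert abs(d[0]) <= 60.0 + 1e-9 and abs(d[1]) <= 60.0 + 1e-9
    assert d[2] == dz


def test_minimum_image_triangle_inequality(rng):
    mesh = build_flat_patch(120.0, 120.0, 9.5)
    pts = rng.uniform(-200, 200, size=(30, 3))
    for _ in range(100):
        i, j, k = rng.integers(0, 30, 3)
        dij = np.linalg.norm(mesh.minimum_image(pts[i] - pts[j]))
        djk = np.linalg.norm(mesh.minimum_image(pts[j] - pts[k]))
        dik = np.linalg.norm(mesh.minimum_image(pts[i] - pts[k]))
        assert dik <= dij + djk + 1e-9


def test_freeze_vertex_bookkeeping(flat_mesh):
    mesh = flat_mesh
    v = int(mesh.m.mlist[0])
    mesh.freeze_vertex(v)
    assert mesh.m.frozen[v] == 1
    assert mesh.m.mposl[v] == -1
    mesh.validate()
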