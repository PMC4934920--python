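"""Metropolis and grand-canonical sampling engine."""

import numpy as np
import pytest

from memtube import _kernels as K
from memtube.energy import MembraneParams, total_energy
from memtube.mesh import TopologyMove, build_flat_patch
from memtube.montecarlo import (CalibrationCurve, MembraneMC, MoveSchedule,
                                measure_spectrum)


def test_vertex_count_conserved_without_exchange():
    mesh = build_flat_patch(100.0, 100.0, 9.5)
    p = MembraneParams(kappa=20.0, gamma=0.0, z=0.0)
    mc = MembraneMC(mesh, p, MoveSchedule(), seed=5)
    v0 = mesh.n_vertices
    mc.run(40)
    assert mesh.n_vertices == v0
    assert mc.counters[K.C_INS] == 0 and mc.counters[K.C_REM] == 0


def test_zero_fugacity_rejects_all_insertions():
    mesh = build_flat_patch(100.0, 100.0, 9.5)
    p = MembraneParams(kappa=20.0, gamma=0.0, z=0.0)
    mc = MembraneMC(mesh, p, MoveSchedule(), seed=5)
    v0 = mesh.n_vertices
    for _ in range(200):
        assert not mc.gc_exchange_step("insert")
    assert mesh.n_vertices == v0
    assert mc.counters[K.C_INS + 1] == 0


def test_frozen_vertices_bit_identical_across_run():
    mesh = build_flat_patch(100.0, 100.0, 9.5)
    frozen = mesh.frozen_ids
    ref = mesh.m.pos[frozen].copy()
    p = MembraneParams(kappa=20.0, gamma=0.0, z=0.003)
    mc = MembraneMC(mesh, p, MoveSchedule(exchange_fraction=0.2), seed=5)
    mc.run(150)
    assert np.array_equal(mesh.m.pos[frozen], ref)
    mesh.validate()


def test_rejected_single_steps_leave_state_unchanged():
    mesh = build_flat_patch(100.0, 100.0, 9.5)
    p = MembraneParams(kappa=20.0, gamma=0.0, z=1e-12)
    mc = MembraneMC(mesh, p, MoveSchedule(amplitude=1e-9), seed=5)
    pos0 = mesh.positions()
    f0 = mesh.faces()
    # near-zero amplitude displacements are null proposals: always accepted
    acc = [mc.metropolis_step("displace") for _ in range(50)]
    assert all(acc)
    drift = mesh.minimum_image(mesh.positions() - pos0)
    assert np.abs(drift).max() < 1e-6
    # near-zero fugacity: insertions always rejected, mesh untouched
    for _ in range(50):
        mc.gc_exchange_step("insert")
    assert np.array_equal(mesh.faces(), f0)


def test_gc_acceptance_pair_is_detailed_balanced(rng):
    """A_ins(s->s') / A_rem(s'->s) equals the grand-canonical measure ratio
    times the proposal ratio, computed from scratch on both sides."""
    mesh = build_flat_patch(100.0, 100.0, 9.5)
    ids = mesh.vertex_ids
    mob = ids[mesh.m.frozen[ids] == 0]
    mesh.m.pos[mob, 2] += 0.5 * rng.standard_normal(len(mob))
    p = MembraneParams(kappa=20.0, gamma=0.0, z=0.0021)
    sigma = 1.0
    for t in [int(mesh.m.tlist[k]) for k in (0, 7, 19)]:
        cen = (mesh.m.pos[mesh.m.tri[t]]).mean(axis=0)
        delta = rng.normal(0, sigma, 3)
        x = tuple(cen + delta)
        E0 = total_energy(mesh, p)
        F0 = mesh.n_faces
        rec = mesh.apply_topology_move(TopologyMove("vertex_insert", t, x))
        vn = rec[1]
        E1 = total_energy(mesh, p)
        N3p = int(mesh.m.meta[3])
        phi = (2 * np.pi * sigma**2) ** -1.5 * np.exp(
            -0.5 * (delta**2).sum() / sigma**2)
        # forward and reverse Metropolis-Hastings ratios
        r_ins = p.z * np.exp(-(E1 - E0)) * F0 / (N3p * phi)
        r_rem = np.exp(-(E0 - E1)) * N3p * phi / (p.z * F0)
        assert r_ins * r_rem == pytest.approx(1.0, rel=1e-9)
        mesh.undo(rec)
        assert total_energy(mesh, p) == pytest.approx(E0, rel=1e-10)


def test_gc_reweighting_histogram_oracle():
    """Stationary V histograms at two fugacities obey
    ln P_z2(V) - ln P_z1(V) = V ln(z2/z1) + const (GC measure check)."""
    z1, z2 = 0.002, 0.0032
    hists = {}
    for z in (z1, z2):
        mesh = build_flat_patch(80.0, 80.0, 9.5)
        p = MembraneParams(kappa=20.0, gamma=0.0, z=z)
        mc = MembraneMC(mesh, p, MoveSchedule(exchange_fraction=0.3),
                        seed=21)
        mc.warmup(1500)
        h = {}
        for _ in range(9000):
            mc.run(2)
            V = mesh.n_vertices
            h[V] = h.get(V, 0) + 1
        hists[z] = h
    common = [V for V in set(hists[z1]) & set(hists[z2])
              if hists[z1][V] > 40 and hists[z2][V] > 40]
    assert len(common) >= 4
    Vs = np.array(sorted(common))
    lr = np.log([hists[z2][V] / hists[z1][V] for V in Vs])
    slope = np.polyfit(Vs, lr, 1)[0]
    assert slope == pytest.approx(np.log(z2 / z1), abs=0.12)


def test_warmup_tunes_amplitude_into_window():
    mesh = build_flat_patch(100.0, 100.0, 9.5)
    p = MembraneParams(kappa=20.0, gamma=0.0, z=0.0)
    mc = MembraneMC(mesh, p, MoveSchedule(amplitude=0.05), seed=2)
    mc.warmup(900, blocks=30)
    acc = mc.run(60)["displace"]
    assert 0.2 < acc < 0.65
    amp_frozen = mc.schedule.amplitude
    mc.run(50)
    assert mc.schedule.amplitude == amp_frozen


def test_gc_mean_area_stationary_and_monotone_in_z():
    means = []
    for z in (0.0015, 0.004):
        mesh = build_flat_patch(90.0, 90.0, 9.5)
        p = MembraneParams(kappa=20.0, gamma=0.0, z=z)
        mc = MembraneMC(mesh, p, MoveSchedule(exchange_fraction=0.3),
                        seed=8)
        mc.warmup(1200)
        vs = []
        for _ in range(600):
            mc.run(3)
            vs.append(mesh.n_vertices)
        means.append(np.mean(vs))
        # stationarity: first and second half agree within a few vertices
        a, b = np.mean(vs[:300]), np.mean(vs[300:])
        assert abs(a - b) < 6.0
    assert means[1] > means[0]


def test_calibration_curve_fit_self_consistency():
    rho, C = 0.013, 0.002
    gam = np.array([0.004, 0.008, 0.012, 0.02])
    z = C * np.exp(-gam / rho)
    curve = CalibrationCurve(z=z, gamma=gam,
                             gamma_err=np.full(4, 1e-4),
                             stable=np.ones(4, bool)).fit()
    assert curve.rho == pytest.approx(rho, rel=1e-6)
    assert curve.C == pytest.approx(C, rel=1e-6)
    assert curve.z_for_gamma(0.01) == pytest.approx(
        C * np.exp(-0.01 / rho), rel=1e-6)


def test_spectrum_zero_temperature_is_silent():
    mesh = build_flat_patch(120.0, 120.0, 9.5, frozen_boundary=False)
    p = MembraneParams(kappa=20.0, gamma=0.0, z=0.0)
    mc = MembraneMC(mesh, p, MoveSchedule(amplitude=1e-12), seed=1)
    spec = measure_spectrum(mc, 10, 1)
    assert np.all(spec["mean"] < 1e-16)
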