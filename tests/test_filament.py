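"""Worm-like-chain filaments: energetics, moves, growth operations."""

import numpy as np
import pytest

from memtube.filament import (DELTA_FIL, Filament, FilamentError,
                              filament_mc_step, grow,
                              sample_free_filament, shrink, wlc_bend_energy)


def _straight(n=10, L_p=15000.0):
    return Filament(base=[0, 0, 0], orientation=[0, 0, 1], n=n, L_p=L_p)


def test_straight_filament_has_zero_energy():
    assert wlc_bend_energy(_straight(20)) == pytest.approx(0.0, abs=1e-12)
    assert wlc_bend_energy(_straight(1)) == 0.0


def test_single_joint_energy_formula():
    f = _straight(2, L_p=100.0)
    phi = 0.3
    f.nodes[2] = f.nodes[1] + DELTA_FIL * np.array(
        [np.sin(phi), 0.0, np.cos(phi)])
    expect = (100.0 / DELTA_FIL) * (1 - np.cos(phi))
    assert wlc_bend_energy(f) == pytest.approx(expect, rel=1e-12)


def test_wlc_energy_rotation_invariant(rng):
    f = _straight(12, L_p=300.0)
    for i in range(2, 13):
        # random thermal-ish kinks
        ax = rng.standard_normal(3)
        ax /= np.linalg.norm(ax)
        f.nodes[i] = f.nodes[i - 1] + DELTA_FIL * (
            0.9 * (f.nodes[i - 1] - f.nodes[i - 2]) / DELTA_FIL
            + 0.45 * np.cross(ax, (f.nodes[i - 1] - f.nodes[i - 2]) / DELTA_FIL))
        f.nodes[i] = f.nodes[i - 1] + DELTA_FIL * (
            (f.nodes[i] - f.nodes[i - 1])
            / np.linalg.norm(f.nodes[i] - f.nodes[i - 1]))
    e0 = wlc_bend_energy(f)
    th = 0.7
    Rz = np.array([[np.cos(th), -np.sin(th), 0],
                   [np.sin(th), np.cos(th), 0], [0, 0, 1]])
    g = f.copy()
    g.nodes = f.nodes @ Rz.T
    assert wlc_bend_energy(g) == pytest.approx(e0, rel=1e-10)


def test_grow_then_shrink_restores(rng):
    f = _straight(6)
    # bend the tip so growth direction is non-trivial
    f.nodes[6] = f.nodes[5] + DELTA_FIL * np.array([0.3, 0.1, 0.94868330])
    f.nodes[6] = f.nodes[5] + DELTA_FIL * (
        (f.nodes[6] - f.nodes[5]) / np.linalg.norm(f.nodes[6] - f.nodes[5]))
    g = grow(f)
    assert g.n == 7
    # new segment continues the barbed-end tangent exactly
    t_old = (f.nodes[6] - f.nodes[5]) / DELTA_FIL
    t_new = (g.nodes[7] - g.nodes[6]) / DELTA_FIL
    assert np.allclose(t_old, t_new, atol=1e-12)
    h = shrink(g)
    assert h.n == f.n and np.allclose(h.nodes, f.nodes)


def test_straight_growth_stays_straight():
    f = _straight(1)
    for _ in range(10):
        f = grow(f)
    assert f.n == 11
    assert f.contour_length == pytest.approx(11 * DELTA_FIL)
    assert np.allclose(np.diff(f.nodes, axis=0),
                       np.tile([0, 0, DELTA_FIL], (11, 1)))


def test_shrink_below_one_monomer_raises():
    with pytest.raises(FilamentError):
        shrink(_straight(1))


def test_segment_lengths_and_base_exact_after_many_moves():
    f = _straight(30, L_p=100.0)
    base0 = f.nodes[:2].copy()
    out, acc = sample_free_filament(f, 40000, amplitude=0.5,
                                    rng=np.random.default_rng(3))
    assert acc > 0.2
    seg = np.linalg.norm(np.diff(f.nodes, axis=0), axis=1)
    assert np.allclose(seg, DELTA_FIL, rtol=1e-12)
    assert np.array_equal(f.nodes[:2], base0)


def test_rigid_limit_keeps_filament_straight():
    """L_p -> inf: every bending proposal is rejected; only zero-angle
    moves (crankshaft of a straight arc about its own chord) pass, which
    leave the shape untouched -- the filament behaves rigid."""
    f = _straight(12, L_p=1e9)
    nodes0 = f.nodes.copy()
    rng = np.random.default_rng(0)
    for _ in range(150):
        filament_mc_step(f, amplitude=0.3, rng=rng)
    assert np.allclose(f.nodes, nodes0, atol=1e-9)
    assert wlc_bend_energy(f) == pytest.approx(0.0, abs=1e-9)


def test_tangent_correlation_matches_wlc():
    """<t(0).t(s)> = exp(-s/L_p) for the thermal ensemble (3 sigma)."""
    L_p = 60.0
    f = _straight(24, L_p=L_p)
    snaps, acc = sample_free_filament(f, 250000, amplitude=0.9,
                                      rng=np.random.default_rng(11),
                                      sample_every=250)
    snaps = snaps[200:]
    smax = 8
    corr = np.zeros(smax)
    for nodes in snaps:
        t = np.diff(nodes, axis=0)
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        for s in range(smax):
            corr[s] += np.mean(np.einsum("ij,ij->i", t[: len(t) - s],
                                         t[s:]))
    corr /= len(snaps)
    s_nm = np.arange(smax) * DELTA_FIL
    expect = np.exp(-s_nm / L_p)
    # effective sample count is modest; allow a generous 3-sigma band
    n_eff = len(snaps) / 4
    sig = (1 - expect**2) / np.sqrt(n_eff) + 0.01
    assert np.all(np.abs(corr - expect) < 3 * sig)


def test_tip_variance_matches_cantilever_oracle():
    """MC tip variance of a stiff clamped filament agrees with independent
    normal-coordinate sampling of the same discrete WLC Hamiltonian."""
    L_p = 2000.0
    n = 12
    rng = np.random.default_rng(5)
    # oracle: joint angles are independent Gaussians in the stiff limit;
    # sample small-angle kinks directly from the Boltzmann weight
    kT_kink = DELTA_FIL / L_p   # variance of each planar kink component
    reps = 4000
    tips = np.zeros(reps)
    for r in range(reps):
        kinksx = rng.normal(0, np.sqrt(kT_kink), n - 1)
        # transverse displacement accumulates lever arms
        x = 0.0
        angle = 0.0
        for i in range(n - 1):
            angle += kinksx[i]
            x += DELTA_FIL * angle
        tips[r] = x
    var_oracle = tips.var()
    f = _straight(n, L_p=L_p)
    snaps, acc = sample_free_filament(f, 300000, amplitude=0.25,
                                      rng=np.random.default_rng(17),
                                      sample_every=150)
    snaps = snaps[400:]
    xs = np.array([s[-1][0] for s in snaps])
    var_mc = xs.var()
    assert var_mc == pytest.approx(var_oracle, rel=0.35)


def test_base_validation():
    with pytest.raises(FilamentError):
        Filament(base=[0, 0, 0], orientation=[0, 0, 0])
    with pytest.raises(FilamentError):
        Filament(base=[0, 0, 0], orientation=[0, 0, 1], n=0)
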