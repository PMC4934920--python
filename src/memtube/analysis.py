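"""Observables, experiment drivers, filament classification and statistics.

Heights are measured relative to the plane of the frozen boundary nodes
(z = 0 of the initial flat patch).  Energies k_BT, lengths nm, times 1/k_on,0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import (MembraneParams, PullingSpring, install_spring,
                     spring_energy_force)
from .filament import DELTA_FIL, Filament
from .mesh import build_flat_patch
from .montecarlo import MembraneMC, MoveSchedule


# ------------------------------------------------------------ tube metrics

@dataclass
class TubeMetrics:
    L: float                      # tube height, nm
    R: float                      # tube radius, nm (nan when no tube)
    tension: float                # inferred kappa/(2 R^2), k_BT/nm^2
    axis_xy: tuple = (0.0, 0.0)   # lateral tube axis position
    has_tube: bool = True
    bundle: list = field(default_factory=list)


def _kasa_circle(x, y):
    A = np.c_[2 * x, 2 * y, np.ones(len(x))]
    b = x * x + y * y
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0], sol[1]
    return cx, cy, float(np.sqrt(sol[2] + cx * cx + cy * cy))


def tube_metrics(mesh, kappa, axis_hint=None):
    """Height, radius, and inferred tension of a membrane protrusion.

    L is the maximum height above the frozen-boundary plane; R is a best-fit
    vertical cylinder (Kasa circle fit) through the vertices with height in
    [L/3, 2L/3], unwrapped around the protrusion apex.  When L is below
    twice the patch roughness no tube is reported.
    """
    ids = mesh.vertex_ids
    zz = mesh.m.pos[ids, 2]
    L = float(zz.max())
    rough = float(np.sqrt(np.mean(zz**2)))
    apex = ids[int(np.argmax(zz))]
    if axis_hint is None:
        cx0, cy0 = float(mesh.m.pos[apex, 0]), float(mesh.m.pos[apex, 1])
    else:
        cx0, cy0 = axis_hint
    sel = (zz > L / 3) & (zz < 2 * L / 3)
    # a thermally rough flat sheet has max height ~ 3-4 rms and stays below
    # ~10 nm; a developed tube dominates the patch rms, so the rms test
    # only applies to short protrusions
    if (L < 25.0 and L < 4.0 * max(rough, 1e-9)) or sel.sum() < 6:
        return TubeMetrics(L=L, R=np.nan, tension=np.nan,
                           axis_xy=(cx0, cy0), has_tube=False)
    x = mesh.m.pos[ids, 0][sel]
    y = mesh.m.pos[ids, 1][sel]
    x = x - mesh.Lx * np.round((x - cx0) / mesh.Lx)
    y = y - mesh.Ly * np.round((y - cy0) / mesh.Ly)
    cx, cy, R = _kasa_circle(x, y)
    return TubeMetrics(L=L, R=R, tension=kappa / (2 * R * R),
                       axis_xy=(cx % mesh.Lx, cy % mesh.Ly), has_tube=True)


def tube_metrics_points(points, kappa):
    """Tube metrics from a bare point cloud (no periodic unwrap)."""
    points = np.asarray(points, dtype=float)
    zz = points[:, 2]
    L = float(zz.max())
    sel = (zz > L / 3) & (zz < 2 * L / 3)
    cx, cy, R = _kasa_circle(points[sel, 0], points[sel, 1])
    return TubeMetrics(L=L, R=R, tension=kappa / (2 * R * R),
                       axis_xy=(cx, cy))


def blocking_error(x):
    """Autocorrelation-aware standard error by iterated pair blocking.

    Successively averages neighbouring samples and takes the largest
    naive standard error across blocking levels (the plateau of the
    blocking analysis); robust for correlated time series.
    """
    x = np.asarray(x, dtype=float)
    best = 0.0
    while len(x) >= 8:
        best = max(best, float(x.std(ddof=1) / np.sqrt(len(x))))
        if len(x) % 2:
            x = x[:-1]
        x = 0.5 * (x[0::2] + x[1::2])
    return best


# -------------------------------------------------------- tube experiments

def pull_tube(z, kappa=20.0, Lx=180.0, target_edge=9.5, L_hold=85.0,
              stiffness=2.0, ramp_sweeps_per_nm=120, relax_sweeps=4000,
              n_samples=200, sample_stride=30, seed=0, exchange_fraction=0.3,
              params=None, return_mc=False):
    """Pull a membrane tube from a grand-canonical flat patch.

    A vertical harmonic spring acts on a ~10 nm disk of vertices at the
    patch center; its anchor is ramped slowly to ``L_hold`` and the system
    is relaxed and sampled at fixed anchor.  The boundary frame (y=0 row and
    x=0 column) is frozen so the point load cannot tent the sheet upward.
    Returns time-averaged force, radius, and their errors.
    """
    mesh = build_flat_patch(Lx, Lx, target_edge, frozen_boundary="frame")
    p = params or MembraneParams(kappa=kappa, gamma=0.0, z=z)
    ids = mesh.vertex_ids
    cx = cy = Lx / 2
    d2 = (mesh.m.pos[ids, 0] - cx) ** 2 + (mesh.m.pos[ids, 1] - cy) ** 2
    att = ids[d2 < 100.0]
    install_spring(mesh, PullingSpring(att, 0.0, stiffness))
    mc = MembraneMC(mesh, p,
                    MoveSchedule(exchange_fraction=exchange_fraction),
                    seed=seed)
    mc.warmup(600)
    nsteps = int(np.ceil(L_hold))
    for step in range(nsteps):
        mesh.m.spring[1] = L_hold * (step + 1) / nsteps
        mc.run(ramp_sweeps_per_nm)
    mc.run(relax_sweeps)
    fs, Rs, Ls = [], [], []
    for _ in range(n_samples):
        mc.run(sample_stride)
        _, f = spring_energy_force(mesh)
        tm = tube_metrics(mesh, kappa, axis_hint=(cx, cy))
        fs.append(f)
        Rs.append(tm.R)
        Ls.append(tm.L)
    fs = np.array(fs)
    Rs = np.array(Rs)
    out = {
        "z": z, "kappa": kappa, "L": float(np.mean(Ls)),
        "force": float(fs.mean()),
        "force_err": blocking_error(fs),
        "R": float(np.nanmean(Rs)),
        "R_err": blocking_error(Rs[np.isfinite(Rs)]),
        "V": mesh.n_vertices,
    }
    out["tension_R"] = kappa / (2 * out["R"] ** 2)
    if return_mc:
        out["mc"] = mc
    return out


def force_extension(z, L_targets, kappa=20.0, Lx=180.0, hold_sweeps=3500,
                    n_samples=120, sample_stride=25, seed=0, **kw):
    """Time-averaged pulling force at a sequence of held extensions.

    The anchor is ramped between successive targets on one system; the
    curve rises, peaks near the tube-nucleation extension, then decays
    toward the asymptotic plateau 2 pi sqrt(2 kappa gamma).
    """
    L_targets = np.sort(np.asarray(L_targets, dtype=float))
    res = pull_tube(z, kappa=kappa, Lx=Lx, L_hold=float(L_targets[0]),
                    relax_sweeps=hold_sweeps, n_samples=n_samples,
                    sample_stride=sample_stride, seed=seed, return_mc=True,
                    **kw)
    mc = res.pop("mc")
    mesh = mc.mesh
    curve = [dict(res, L_target=float(L_targets[0]))]
    for Lt in L_targets[1:]:
        L_prev = mesh.m.spring[1]
        nsteps = int(np.ceil(Lt - L_prev))
        for step in range(max(nsteps, 1)):
            mesh.m.spring[1] = L_prev + (Lt - L_prev) * (step + 1) / max(nsteps, 1)
            mc.run(100)
        mc.run(hold_sweeps)
        fs, Rs, Ls = [], [], []
        for _ in range(n_samples):
            mc.run(sample_stride)
            _, f = spring_energy_force(mesh)
            tm = tube_metrics(mesh, kappa, axis_hint=(mesh.Lx / 2, mesh.Ly / 2))
            fs.append(f)
            Rs.append(tm.R)
            Ls.append(tm.L)
        fs = np.array(fs)
        nb = 8
        fblk = np.array([b.mean() for b in np.array_split(fs, nb)])
        curve.append({
            "z": z, "kappa": kappa, "L_target": float(Lt),
            "L": float(np.mean(Ls)), "force": float(fs.mean()),
            "force_err": float(fblk.std(ddof=1) / np.sqrt(nb)),
            "R": float(np.nanmean(Rs)), "V": mesh.n_vertices,
        })
    return curve, mc


# -------------------------------------------------------- classification

@dataclass
class FilamentClassification:
    labels: list                 # per-filament: 'bundled' | 'unbundled' | 'failed'

    def count(self, label):
        return sum(1 for x in self.labels if x == label)


def classify_filaments(filaments, metrics: TubeMetrics, Lx=None, Ly=None,
                       r_factor=1.5, h_factor=0.5, fail_angle=90.0):
    """Three-way classification at an analysis frame.

    bundled: barbed end within ``r_factor * R`` of the tube axis and above
    ``h_factor * L``; failed: barbed-end tangent polar angle exceeds
    ``fail_angle`` (growing away from the membrane); unbundled: the rest.
    Thresholds are analysis parameters, not physics.
    """
    labels = []
    cx, cy = metrics.axis_xy
    cosfail = np.cos(np.radians(fail_angle))
    for f in filaments:
        tang = f.tip_tangent
        if tang[2] < cosfail - 1e-12:
            labels.append("failed")
            continue
        tip = f.barbed_end
        dx, dy = tip[0] - cx, tip[1] - cy
        if Lx:
            dx -= Lx * np.round(dx / Lx)
        if Ly:
            dy -= Ly * np.round(dy / Ly)
        r = np.hypot(dx, dy)
        if (metrics.has_tube and np.isfinite(metrics.R)
                and r <= r_factor * metrics.R
                and tip[2] >= h_factor * metrics.L):
            labels.append("bundled")
        else:
            labels.append("unbundled")
    return FilamentClassification(labels)


def alignment_profile(filaments, dL=10.0, z_range=None):
    """Segment-orientation alignment a(L) = |sum_i o_i| / N per height bin.

    o_i are unit orientation vectors of filament segments whose midpoint
    height lies in [L, L + dL); empty bins are skipped (NaN).
    """
    segs = []
    for f in filaments:
        t = np.diff(f.nodes, axis=0)
        h = 0.5 * (f.nodes[:-1, 2] + f.nodes[1:, 2])
        t = t / np.linalg.norm(t, axis=1, keepdims=True)
        segs.append((h, t))
    hs = np.concatenate([s[0] for s in segs])
    ts = np.vstack([s[1] for s in segs])
    lo = z_range[0] if z_range else np.floor(hs.min() / dL) * dL
    hi = z_range[1] if z_range else hs.max()
    edges = np.arange(lo, hi + dL, dL)
    out_L, out_a, out_n = [], [], []
    for k in range(len(edges) - 1):
        sel = (hs >= edges[k]) & (hs < edges[k + 1])
        n = int(sel.sum())
        out_L.append(edges[k])
        out_n.append(n)
        out_a.append(np.nan if n == 0 else
                     float(np.linalg.norm(ts[sel].sum(axis=0)) / n))
    return np.array(out_L), np.array(out_a), np.array(out_n)


# ------------------------------------------------------- initial condition

@dataclass
class InitialCondition:
    base_positions: np.ndarray   # (N, 3)
    orientations: np.ndarray     # (N, 3) unit vectors
    seed: int
    polar_deg: np.ndarray = None  # signed Gaussian polar-angle draws

    def make_filaments(self, L_p=15000.0, n=1, delta=DELTA_FIL):
        return [Filament(b, o, n=n, L_p=L_p, delta=delta)
                for b, o in zip(self.base_positions, self.orientations)]


def generate_initial_condition(N_fil, std_deg, depth, box, seed=0,
                               min_spacing=10.0, margin=0.15,
                               max_tries=2000):
    """Seeded random filament layout below the membrane.

    Lateral base positions are uniform in the (margin-inset) box with
    pairwise spacing >= ``min_spacing``; polar angles are Gaussian with
    standard deviation ``std_deg`` (std = 0 reproduces the perpendicular
    ensemble); azimuths are uniform.  ``depth`` is the vertical distance of
    the bases below the membrane plane z = 0.
    """
    if N_fil < 1 or std_deg < 0:
        raise ValueError("need N_fil >= 1 and std >= 0")
    rng = np.random.default_rng(seed)
    Lx, Ly = (box, box) if np.isscalar(box) else box
    pts = []
    tries = 0
    lo_x, hi_x = margin * Lx, (1 - margin) * Lx
    lo_y, hi_y = margin * Ly, (1 - margin) * Ly
    while len(pts) < N_fil:
        if tries > max_tries:
            raise ValueError(
                f"cannot place {N_fil} filaments with spacing "
                f"{min_spacing} nm in a {Lx} x {Ly} box")
        tries += 1
        cand = np.array([rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y),
                         -float(depth)])
        ok = all(np.hypot(*(cand[:2] - p[:2])) >= min_spacing for p in pts)
        if ok:
            pts.append(cand)
    ors, pols = [], []
    for _ in range(N_fil):
        pol = rng.normal(0.0, np.radians(std_deg)) if std_deg > 0 else 0.0
        azi = rng.uniform(0, 2 * np.pi)
        pols.append(np.degrees(pol))
        pol = abs(pol)
        ors.append([np.sin(pol) * np.cos(azi), np.sin(pol) * np.sin(azi),
                    np.cos(pol)])
    return InitialCondition(np.array(pts), np.array(ors), seed,
                            np.array(pols))
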