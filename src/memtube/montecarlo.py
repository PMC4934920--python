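"""Metropolis / grand-canonical sampling engine for the membrane.

Moves per sweep (defaults follow the schedule design): V vertex displacement
attempts, V edge-flip attempts and, when the fugacity z is positive,
0.1 V insertion and 0.1 V removal attempts (insert and remove always attempted
with equal frequency, as detailed balance of the pair requires).  Filament
configurational moves, when filaments are coupled in, are interleaved in
proportion to their degree-of-freedom count.

Grand-canonical acceptance: insertion of a vertex at centroid + Gaussian
offset delta into a uniformly chosen triangle is accepted with

    min[1, z * exp(-dE) * F / (N3' * phi(delta))]

and removal of a uniformly chosen removable (mobile, 3-coordinated) vertex
with the reciprocal expression, where F is the triangle count of the state
proposed *from*, N3' the removable-vertex count of the state proposed *to*,
and phi the Gaussian proposal density times a 1 nm^3 reference volume.  This
satisfies detailed balance w.r.t. the grand-canonical weight z^V exp(-E).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .energy import MembraneParams
from .filament import pack_filaments, unpack_filaments
from .mesh import TriMesh


@dataclass
class MoveSchedule:
    """Relative attempt frequencies and proposal amplitudes."""

    disp_per_vertex: float = 1.0
    flip_per_vertex: float = 1.0
    exchange_fraction: float = 0.1   # insert (= remove) attempts per vertex
    amplitude: float = 1.2           # displacement half-width, nm
    sigma_insert: float = 1.0        # Gaussian insertion offset width, nm
    fil_amplitude: float = 0.25      # filament rotation half-width, rad
    seed: int = 0

    def __post_init__(self):
        if min(self.disp_per_vertex, self.flip_per_vertex,
               self.exchange_fraction) < 0:
            raise ValueError("attempt frequencies must be >= 0")


class MembraneMC:
    """Sampling engine owning a mesh, optional filaments, and an RNG."""

    def __init__(self, mesh: TriMesh, params: MembraneParams,
                 schedule: MoveSchedule | None = None, seed=None,
                 filaments=None):
        self.mesh = mesh
        self.params = params
        self.schedule = schedule or MoveSchedule()
        if seed is None:
            seed = self.schedule.seed
        self.rng = np.random.default_rng(seed)
        self.filaments = list(filaments) if filaments else []
        self.fb = pack_filaments(self.filaments)
        self.counters = np.zeros(12, np.int64)
        self._tuned = False

    # ------------------------------------------------------------ plumbing

    @property
    def prm(self):
        p, s = self.params, self.schedule
        prm = np.zeros(12)
        prm[K.P_KAPPA] = p.kappa
        prm[K.P_GAMMA] = p.gamma
        prm[K.P_Z] = p.z
        prm[K.P_AMIN] = p.a_min
        prm[K.P_AMAX] = p.a_max
        prm[K.P_DMEM] = p.d_mem
        prm[K.P_DFIL] = p.d_fil
        prm[K.P_AMP] = s.amplitude
        prm[K.P_SIG] = s.sigma_insert
        prm[K.P_AMPFIL] = s.fil_amplitude
        if self.filaments:
            prm[K.P_LP] = self.filaments[0].L_p
            prm[K.P_DELTA] = self.filaments[0].delta
        return prm

    def _sweep_counts(self, gc=None):
        V = self.mesh.n_vertices
        s = self.schedule
        gc = (self.params.z > 0) if gc is None else gc
        nx = int(round(s.exchange_fraction * V)) if gc else 0
        nfil = sum(max(f.n - 1, 0) for f in self.filaments)
        return (int(round(s.disp_per_vertex * V)),
                int(round(s.flip_per_vertex * V)), nx, nx, nfil)

    def sync_filaments(self):
        unpack_filaments(self.fb, self.filaments)
        return self.filaments

    # ------------------------------------------------------------ stepping

    def metropolis_step(self, kind=None):
        """One displacement or flip attempt; returns accepted flag."""
        kind = kind or ("displace" if self.rng.random() < 0.5 else "flip")
        if kind == "displace":
            self.counters[K.C_DISP] += 1
            acc = K.try_displace(self.mesh.m, self.fb, len(self.filaments),
                                 self.prm, self.rng)
            self.counters[K.C_DISP + 1] += acc
        else:
            self.counters[K.C_FLIP] += 1
            acc = K.try_flip(self.mesh.m, self.prm, self.rng)
            self.counters[K.C_FLIP + 1] += acc
        return bool(acc)

    def gc_exchange_step(self, kind=None):
        """One grand-canonical insertion or removal attempt."""
        kind = kind or ("insert" if self.rng.random() < 0.5 else "remove")
        if kind == "insert":
            self.counters[K.C_INS] += 1
            acc = K.try_insert(self.mesh.m, self.fb, len(self.filaments),
                               self.prm, self.rng)
            self.counters[K.C_INS + 1] += acc
        else:
            self.counters[K.C_REM] += 1
            acc = K.try_remove(self.mesh.m, self.fb, len(self.filaments),
                               self.prm, self.rng)
            self.counters[K.C_REM + 1] += acc
        return bool(acc)

    def run(self, n_sweeps, gc=None):
        """Run whole sweeps; returns the per-move-type acceptance fractions."""
        before = self.counters.copy()
        nd, nf, ni, nr, nfil = self._sweep_counts(gc)
        prm = self.prm
        for _ in range(int(n_sweeps)):
            K.run_moves(self.mesh.m, self.fb, len(self.filaments), prm,
                        self.rng, self.counters, nd, nf, ni, nr, nfil)
        d = self.counters - before
        with np.errstate(invalid="ignore", divide="ignore"):
            return {
                "displace": d[K.C_DISP + 1] / max(d[K.C_DISP], 1),
                "flip": d[K.C_FLIP + 1] / max(d[K.C_FLIP], 1),
                "insert": d[K.C_INS + 1] / max(d[K.C_INS], 1),
                "remove": d[K.C_REM + 1] / max(d[K.C_REM], 1),
                "filament": d[K.C_FIL + 1] / max(d[K.C_FIL], 1),
            }

    def warmup(self, n_sweeps, target=(0.30, 0.50), blocks=10):
        """Equilibrate while tuning the displacement amplitude into
        ``target`` acceptance; the amplitude is frozen afterwards (tuning
        during production would violate detailed balance)."""
        per = max(int(n_sweeps) // blocks, 1)
        for _ in range(blocks):
            acc = self.run(per)["displace"]
            if acc > target[1]:
                self.schedule.amplitude *= 1.15
            elif acc < target[0]:
                self.schedule.amplitude /= 1.15
            self.schedule.amplitude = min(self.schedule.amplitude,
                                          0.45 * self.params.a_min)
        self._tuned = True
        return self.schedule.amplitude


# ----------------------------------------------------------------- spectrum

def _height_grid(mesh: TriMesh, G):
    ids = mesh.vertex_ids
    x, y, z = mesh.m.pos[ids, 0], mesh.m.pos[ids, 1], mesh.m.pos[ids, 2]
    ix = np.clip((x / mesh.Lx * G).astype(int), 0, G - 1)
    iy = np.clip((y / mesh.Ly * G).astype(int), 0, G - 1)
    s = np.zeros((G, G))
    c = np.zeros((G, G))
    np.add.at(s, (ix, iy), z)
    np.add.at(c, (ix, iy), 1.0)
    h = np.where(c > 0, s / np.maximum(c, 1), 0.0)
    empty = c == 0
    # fill gaps from periodic nearest neighbours (few % of cells at most)
    for _ in range(3):
        if not empty.any():
            break
        nsum = np.zeros((G, G))
        ncnt = np.zeros((G, G))
        for ax, sh in ((0, 1), (0, -1), (1, 1), (1, -1)):
            nsum += np.roll(np.where(empty, 0.0, h), sh, axis=ax)
            ncnt += np.roll((~empty).astype(float), sh, axis=ax)
        fill = empty & (ncnt > 0)
        h[fill] = nsum[fill] / ncnt[fill]
        empty = empty & ~fill
    return h


def measure_spectrum(mc: MembraneMC, n_samples, stride, grid=None,
                     n_max=4, n_blocks=10):
    """Height-fluctuation spectrum <|h_q|^2> of a (near-)flat patch.

    Vertex heights are interpolated onto a regular G x G grid, Fourier
    transformed with the convention h_q = (1/N) sum_j h_j exp(-i q r_j), and
    averaged over ``n_samples`` configurations ``stride`` sweeps apart.
    Returns a dict with mode indices, wavevectors, means, and jackknife
    standard errors.  For an equilibrated patch the continuum prediction is
    <|h_q|^2> = k_BT / [A (kappa q^4 + gamma q^2)].
    """
    mesh = mc.mesh
    G = grid or max(6, int(0.75 * np.sqrt(mesh.n_vertices)))
    modes = []
    for mx in range(n_max + 1):
        for my in range(n_max + 1):
            if mx == 0 and my == 0:
                continue
            if mx * mx + my * my <= n_max * n_max:
                modes.append((mx, my))
    amps = np.zeros((int(n_samples), len(modes)))
    for it in range(int(n_samples)):
        mc.run(stride)
        h = _height_grid(mesh, G)
        h = h - h.mean()
        hq = np.fft.fft2(h) / (G * G)
        p = np.abs(hq) ** 2
        for k, (mx, my) in enumerate(modes):
            amps[it, k] = 0.5 * (p[mx, my] + p[-mx if mx else 0,
                                               -my if my else 0])
    mean = amps.mean(axis=0)
    nb = min(n_blocks, len(amps))
    blocks = np.array_split(amps, nb)
    bm = np.array([b.mean(axis=0) for b in blocks])
    err = bm.std(axis=0, ddof=1) / np.sqrt(nb)
    qx = 2 * np.pi * np.array([m[0] for m in modes]) / mesh.Lx
    qy = 2 * np.pi * np.array([m[1] for m in modes]) / mesh.Ly
    return {
        "modes": modes,
        "q": np.hypot(qx, qy),
        "mean": mean,
        "err": err,
        "area": mesh.Lx * mesh.Ly,
        "n_samples": int(n_samples),
    }


def spectrum_theory(q, area, kappa, gamma):
    return 1.0 / (area * (kappa * q**4 + gamma * q**2))


def fit_tension_from_spectrum(spec, kappa):
    """Least-squares tension from 1/<|h_q|^2> = A(kappa q^4 + gamma q^2).

    Returns (gamma, gamma_err) using the low-q modes, kappa held fixed.
    """
    q = spec["q"]
    y = 1.0 / (spec["area"] * spec["mean"]) - kappa * q**4
    # propagate: sigma_y = err / (A * mean^2); weight 1/sigma^2
    sig = spec["err"] / (spec["area"] * spec["mean"] ** 2)
    wgt = 1.0 / np.maximum(sig, 1e-300) ** 2
    gamma = float(np.sum(wgt * q**2 * y) / np.sum(wgt * q**4))
    gerr = float(1.0 / np.sqrt(np.sum(wgt * q**4)))
    return gamma, gerr


# -------------------------------------------------------------- calibration

@dataclass
class CalibrationCurve:
    """Measured fugacity -> tension mapping and its two-constant fit.

    The fit is z = C exp(-gamma/(rho k_BT)); gamma decreases with ln z.
    """

    z: np.ndarray
    gamma: np.ndarray
    gamma_err: np.ndarray
    stable: np.ndarray
    C: float = np.nan
    rho: float = np.nan
    residual: float = np.nan
    method: str = "spectrum"

    def fit(self):
        ok = self.stable.astype(bool)
        if ok.sum() < 2:
            raise ValueError("need >= 2 stable calibration points")
        lnz = np.log(self.z[ok])
        # ln z = ln C - gamma / rho
        A = np.vstack([np.ones_like(lnz), -self.gamma[ok]]).T
        coef, res, *_ = np.linalg.lstsq(A, lnz, rcond=None)
        self.C = float(np.exp(coef[0]))
        self.rho = float(1.0 / coef[1])
        pred = A @ coef
        self.residual = float(np.sqrt(np.mean((pred - lnz) ** 2)))
        return self

    def z_for_gamma(self, gamma):
        return self.C * np.exp(-np.asarray(gamma) / self.rho)

    def gamma_for_z(self, z):
        return -self.rho * np.log(np.asarray(z) / self.C)


def calibrate_fugacity(z_values, base_params: MembraneParams, Lx=160.0,
                       target_edge=9.5, warm_sweeps=400, n_samples=150,
                       stride=6, seed=0, schedule=None):
    """Measure gamma(z) from the low-q spectrum of grand-canonical runs.

    For each z a fresh flat patch is equilibrated grand canonically (explicit
    gamma term off) and the effective frame tension is fitted from the
    fluctuation spectrum with kappa fixed; (C, rho) are then fitted to
    z = C exp(-gamma/rho).  Points with a non-positive fitted tension are
    flagged unstable (the membrane would not sustain a pulled tube) and are
    excluded from the fit.
    """
    from .mesh import build_flat_patch

    z_values = np.asarray(z_values, dtype=float)
    gammas, errs, stable = [], [], []
    for iz, z in enumerate(z_values):
        mesh = build_flat_patch(Lx, Lx, target_edge)
        p = MembraneParams(kappa=base_params.kappa, gamma=0.0, z=float(z),
                           a_min=base_params.a_min, a_max=base_params.a_max,
                           d_mem=base_params.d_mem, d_fil=base_params.d_fil)
        sch = schedule() if callable(schedule) else MoveSchedule()
        mc = MembraneMC(mesh, p, sch, seed=seed + 1000 * iz)
        mc.warmup(warm_sweeps)
        spec = measure_spectrum(mc, n_samples, stride)
        g, ge = fit_tension_from_spectrum(spec, p.kappa)
        gammas.append(g)
        errs.append(ge)
        stable.append(g > 0)
    curve = CalibrationCurve(
        z=z_values,
        gamma=np.array(gammas),
        gamma_err=np.array(errs),
        stable=np.array(stable),
    )
    return curve.fit()
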