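"""Fugacity -> surface-tension calibration.

The mapping z(gamma) = C exp(-gamma/(rho k_BT)) is measured in two steps:

1.  Relative tensions by thermodynamic integration.  At fixed projected
    area A_p the grand potential obeys d Omega / d ln z = -<V>, and the
    frame tension is gamma = Omega / A_p, so

        gamma(z) = gamma(z0) - (1/A_p) * int_{ln z0}^{ln z} <V> d ln z'.

    <V> is self-averaging and cheap to measure, so the *differences* of
    gamma across the z grid converge quickly.  Note d gamma / d ln z =
    -<V>/A_p: the relation z = C exp(-gamma/rho) with constant rho is
    equivalent to an (approximately) z-independent projected vertex
    density, and rho is that density.

2.  One absolute anchor.  gamma(z0) is fixed by pulling a membrane tube at
    z0 and inverting the equilibrium tube radius, gamma = kappa/(2 R^2)
    (the same closed form used to analyze the simulations).

The anchored curve is then fitted to ln z = ln C - gamma/rho.
"""

from __future__ import annotations

import numpy as np

from .energy import MembraneParams
from .mesh import build_flat_patch
from .montecarlo import CalibrationCurve, MembraneMC, MoveSchedule


def mean_vertex_count(z, kappa=20.0, Lx=160.0, target_edge=9.5, seed=0,
                      warm_sweeps=1500, sweeps=4000, stride=5,
                      exchange_fraction=0.3):
    """Stationary <V> (and its blocked standard error) of a flat GC patch."""
    mesh = build_flat_patch(Lx, Lx, target_edge)
    p = MembraneParams(kappa=kappa, gamma=0.0, z=float(z))
    mc = MembraneMC(mesh, p, MoveSchedule(exchange_fraction=exchange_fraction),
                    seed=seed)
    mc.warmup(warm_sweeps)
    vs = []
    for _ in range(int(sweeps) // stride):
        mc.run(stride)
        vs.append(mesh.n_vertices)
    vs = np.array(vs, dtype=float)
    nb = 10
    bm = np.array([b.mean() for b in np.array_split(vs, nb)])
    return float(vs.mean()), float(bm.std(ddof=1) / np.sqrt(nb))


def calibrate_ti(z_values, kappa=20.0, Lx=160.0, target_edge=9.5,
                 anchor_z=None, anchor_gamma=None, seed=0, sweeps=4000,
                 anchor_kw=None):
    """Tube-anchored thermodynamic-integration calibration curve.

    ``anchor_gamma`` (if given) bypasses the tube run — used to share one
    anchor between patch sizes when only the density/slope is of interest.
    """
    z_values = np.sort(np.asarray(z_values, dtype=float))
    if np.any(z_values <= 0):
        raise ValueError("fugacities must be positive")
    A_p = Lx * Lx
    Vm, Ve = [], []
    for i, z in enumerate(z_values):
        v, e = mean_vertex_count(z, kappa=kappa, Lx=Lx,
                                 target_edge=target_edge,
                                 seed=seed + 101 * i, sweeps=sweeps)
        Vm.append(v)
        Ve.append(e)
    Vm = np.array(Vm)
    Ve = np.array(Ve)
    lnz = np.log(z_values)
    # cumulative trapezoid of <V> d ln z
    integral = np.concatenate(
        ([0.0], np.cumsum(0.5 * (Vm[1:] + Vm[:-1]) * np.diff(lnz))))
    if anchor_z is None:
        anchor_z = z_values[len(z_values) // 2]
    i0 = int(np.argmin(np.abs(z_values - anchor_z)))
    if anchor_gamma is None:
        from .analysis import pull_tube

        # elevated exchange rate + long relaxation: the anchor radius is
        # only as good as the tube's area equilibration
        kw = dict(exchange_fraction=0.8, relax_sweeps=8000, n_samples=220)
        kw.update(anchor_kw or {})
        res = pull_tube(float(z_values[i0]), kappa=kappa,
                        seed=seed + 9999, **kw)
        anchor_gamma = kappa / (2.0 * res["R"] ** 2)
        anchor_err = anchor_gamma * 2.0 * res["R_err"] / res["R"]
    else:
        anchor_err = 0.0
    gamma = anchor_gamma - (integral - integral[i0]) / A_p
    gerr = np.sqrt((np.abs(lnz - lnz[i0]) * Ve / A_p) ** 2 + anchor_err**2)
    curve = CalibrationCurve(
        z=z_values, gamma=gamma, gamma_err=gerr,
        stable=gamma > 0,
        method="tube-anchored thermodynamic integration")
    curve.fit()
    return curve
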