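"""Reduced single-filament bundling kinetics.

A tagged filament grows from a base a vertical distance L0 below a (mean)
membrane plane, at relative angle theta between filament axis and membrane
normal.  It polymerizes freely at rate k_on,0 until its straight tip reaches
the plane; beyond that, each monomer addition requires a thermal fluctuation
(filament bending toward the membrane's downhill direction and/or a local
membrane height fluctuation) that opens a gap of one monomer length.  Once
the constrained ground-state tip tangent is parallel to the plane, growth is
unimpeded again: the filament has reached the "bent and growing" state.

The effective rate ladder k_on(n) = k_on,0 * P_bend(n -> n+1) feeds a
birth-death master equation

    dP(n,t)/dt = k_off [P(n+1,t) - P(n,t)]
                 + k_on(n-1) P(n-1,t) - k_on(n) P(n,t)

with a reflecting boundary at n = 1 (the base segment cannot depolymerize)
and an absorbing boundary at the bent state n*.  First-passage statistics of
this chain reproduce the waiting time for a filament to join a nascent
bundle; the mean first-passage time varies by orders of magnitude across
modest changes of (theta, L0).

P_bend here is a saddle-point estimate over the softest deformation modes:
the filament may bend (discrete WLC energy) and the membrane may lift
locally (a single Gaussian height mode whose variance sigma_m^2 is the
discrete Helfrich mode sum of the patch, i.e. stiffness k_BT/sigma_m^2).
P_bend(n -> n+1) = exp(-dE*) where dE* is the minimal excess energy, above
the constrained ground state of the n-monomer chain, of any configuration
in which one more monomer fits below the (lifted) plane.  Zero required
clearance gives dE* = 0 and probability one.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate, optimize

from .filament import DELTA_FIL


@dataclass(frozen=True)
class TiltScenario:
    """Geometry and elasticity of the tilted-membrane single-filament model."""

    theta: float = 45.0        # relative filament-membrane angle, degrees
    L0: float = 60.0           # vertical base-membrane distance, nm
    kappa: float = 20.0        # membrane bending rigidity, k_BT
    gamma: float = 0.01        # membrane tension, k_BT/nm^2
    L_p: float = 15000.0       # filament persistence length, nm
    delta: float = DELTA_FIL   # monomer length increment, nm
    patch: float = 180.0       # membrane patch size for the mode sum, nm
    cutoff: float = 9.5        # microscopic membrane cutoff (vertex spacing)

    def __post_init__(self):
        if not (0 <= self.theta < 90):
            raise ValueError("theta must be in [0, 90) degrees")
        if self.L0 <= 0:
            raise ValueError("L0 must be positive")
        nc = contact_index(self)
        if nc < 1:
            raise ValueError("filament starts in contact with the membrane")


def contact_index(s: TiltScenario):
    """Largest monomer count still growing unimpeded (straight geometry)."""
    c = np.cos(np.radians(s.theta))
    return int(np.floor(s.L0 / (s.delta * c) - 1.0))


def _minimize_chain(s: TiltScenario, n, gated, sigma_m2, psi0=None):
    """Constrained minimum of WLC bending + membrane-lift energy.

    Variables are the free segment angles psi_1..psi_{n-1} (psi_0 = theta is
    clamped; angles from the vertical, bending confined to the tilt plane)
    and the local membrane lift h >= 0 with energy h^2/(2 sigma_m^2).  All
    bead heights must stay below the lifted plane L0 + h; with ``gated`` the
    continuation bead z_tip + delta cos(psi_{n-1}) must fit below it too
    (growth locks in curvature, so the new segment continues the tip
    tangent).  Returns (energy, psi, h).
    """
    th = np.radians(s.theta)
    stiff = s.L_p / s.delta
    if n < 2:
        # only the membrane can yield
        need = s.delta * np.cos(th) * (2 if gated else 1) - s.L0
        h = max(0.0, need)
        return h * h / (2 * sigma_m2), np.full(max(n, 1), th), h

    def energy(x):
        psi = np.concatenate(([th], x[:-1]))
        h = x[-1]
        return (stiff * np.sum(1.0 - np.cos(np.diff(psi)))
                + 0.5 * h * h / sigma_m2)

    def grad(x):
        psi = np.concatenate(([th], x[:-1]))
        d = np.sin(np.diff(psi))     # d[i] = sin(psi_{i+1} - psi_i)
        g = d.copy()                 # dE/dpsi_{i+1} from joint i
        g[:-1] -= d[1:]              # dE/dpsi_{i+1} from joint i+1
        return np.concatenate([stiff * g, [x[-1] / sigma_m2]])

    def clearances(x):
        psi = np.concatenate(([th], x[:-1]))
        h = x[-1]
        z = s.delta * np.cumsum(np.cos(psi))
        out = s.L0 + h - z
        if gated:
            znew = z[-1] + s.delta * np.cos(psi[-1])
            out = np.append(out, s.L0 + h - znew)
        return out

    def clearances_jac(x):
        psi = np.concatenate(([th], x[:-1]))
        sn = s.delta * np.sin(psi)          # dz_k/dpsi_j = -delta sin(psi_j)
        nr = n + 1 if gated else n
        J = np.zeros((nr, n))
        for j in range(1, n):               # free angle psi_j
            J[j:n, j - 1] = sn[j]
        J[:, -1] = 1.0                      # d/dh
        if gated:
            J[n, : n - 1] = J[n - 1, : n - 1]
            J[n, n - 2] += sn[n - 1]        # extra tip-tangent term
        return J

    if psi0 is not None and len(psi0) >= n:
        x0 = np.append(psi0[1:n], 0.0)
    else:
        x0 = np.append(np.full(n - 1, th), 0.0)
    cons = [{"type": "ineq", "fun": clearances, "jac": clearances_jac}]
    bounds = [(None, None)] * (n - 1) + [(0.0, None)]
    res = optimize.minimize(
        energy, x0, jac=grad, constraints=cons, bounds=bounds,
        method="SLSQP", options={"maxiter": 300, "ftol": 1e-11})
    psi = np.concatenate(([th], res.x[:-1]))
    return float(res.fun), psi, float(res.x[-1])


def required_gap(n, s: TiltScenario):
    """Clearance (nm) the tip must gain to add monomer n+1, plus indices.

    Returns ``(gap, n_c, n_star)`` where n_c is the contact index and n_star
    the absorbing index (ground-state tip tangent parallel to the plane).
    The ground state is computed by constrained minimization of the discrete
    WLC bending energy below the plane, warm-started monomer by monomer; the
    new monomer continues the ground-state tip tangent (growth locks in
    curvature), and the gap is its penetration depth above the plane.
    """
    n = int(n)
    n_c = contact_index(s)
    if n <= n_c:
        return 0.0, n_c, _absorbing_index(s)
    gaps = _gap_profile(s)
    n_star = _absorbing_index(s)
    if n_star is not None and n >= n_star:
        return 0.0, n_c, n_star
    if n - n_c - 1 < len(gaps):
        return float(gaps[n - n_c - 1]), n_c, n_star
    return float(gaps[-1]) if len(gaps) else 0.0, n_c, n_star


@lru_cache(maxsize=64)
def _profile(s: TiltScenario, n_max_extra=400):
    """Blocked-regime profile for n = n_c+1 .. termination.

    Returns (gaps, tips, barriers, n_star): per-n geometric clearance of the
    continuation bead above the plane, ground-state tip angles, activation
    barriers dE*(n) of the gated states, and the absorbing index n* at which
    the ground-state tip tangent turns parallel to the plane.
    """
    n_c = contact_index(s)
    sig2 = membrane_height_variance(s)
    gaps, tips, barriers = [], [], []
    n_star = None
    psi_g = None   # pure-bending (geometric) ground state
    psi_f = None   # free-energy ground state incl. the membrane lift mode
    for n in range(n_c + 1, n_c + 1 + n_max_extra):
        # geometry (clearance, tip tangent, absorbing index): membrane at
        # its mean plane, no lift
        _eg, psi_g, _ = _minimize_chain(s, n, False, 1e-12, psi0=psi_g)
        tip = psi_g[-1]
        tips.append(float(tip))
        if tip >= np.pi / 2 - 1e-6:
            n_star = n
            break
        ztip = s.delta * np.sum(np.cos(psi_g))
        znew = ztip + s.delta * np.cos(tip)
        gaps.append(max(0.0, znew - s.L0))
        # activation barrier: both soft modes available to ground and gated
        # states alike
        e_gs, psi_f, _ = _minimize_chain(s, n, False, sig2, psi0=psi_f)
        e_gate, _, _ = _minimize_chain(s, n, True, sig2, psi0=psi_f)
        barriers.append(max(0.0, e_gate - e_gs))
        if barriers[-1] > 60.0:
            # p_bend < 1e-26: the chain never passes on any relevant
            # timescale; treat as having no reachable bent state
            break
    return tuple(gaps), tuple(tips), tuple(barriers), n_star


def _gap_profile(s: TiltScenario):
    return np.array(_profile(s)[0])


def _absorbing_index(s: TiltScenario):
    return _profile(s)[3]


def membrane_height_variance(s: TiltScenario):
    """Local height variance of the patch from the discrete Helfrich modes."""
    L = s.patch
    nmax = int(L / s.cutoff)
    n = np.arange(-nmax, nmax + 1)
    nx, ny = np.meshgrid(n, n)
    q2 = (2 * np.pi / L) ** 2 * (nx**2 + ny**2)
    q2 = q2[q2 > 0]
    return float(np.sum(1.0 / (L * L * (s.kappa * q2**2 + s.gamma * q2))))


def filament_tip_sigma(n, s: TiltScenario, tip_angle=None):
    """Vertical std-dev of the clamped filament's softest transverse mode."""
    ell = n * s.delta
    var_t = ell**3 / (3.0 * s.L_p)
    proj = np.sin(max(np.radians(s.theta), tip_angle or 0.0))
    return np.sqrt(var_t) * proj


def p_bend(n, s: TiltScenario):
    """Equilibrium probability that room for one more monomer opens at n.

    exp(-dE*) with dE* the gated-state activation barrier; 1 below contact
    and at/after the bent absorbing state.  Monotone decreasing in the
    required clearance and increasing in the fluctuation amplitudes (softer
    membrane or filament lowers the barrier).
    """
    n = int(n)
    n_c = contact_index(s)
    if n <= n_c:
        return 1.0
    gaps, tips, barriers, n_star = _profile(s)
    if n_star is not None and n >= n_star:
        return 1.0
    i = n - n_c - 1
    dE = barriers[i] if i < len(barriers) else barriers[-1]
    return float(np.exp(-dE))


# ------------------------------------------------------------- rate ladder

@dataclass
class RateLadder:
    """Effective polymerization rates k_on(n), n = 1..n_max, in units of
    k_on,0; absorbing at ``n_star`` (None for an open chain)."""

    k_on: np.ndarray
    k_off: float
    n_star: int | None = None

    def __post_init__(self):
        self.k_on = np.asarray(self.k_on, dtype=float)
        if np.any(self.k_on < 0) or self.k_off < 0:
            raise ValueError("rates must be non-negative")

    @property
    def n_max(self):
        return len(self.k_on)


def build_ladder(s: TiltScenario, k_off=0.01, k_on0=1.0):
    """Rate ladder of the tilted-membrane scenario (units of k_on,0)."""
    n_c = contact_index(s)
    gaps, tips, barriers, n_star = _profile(s)
    if n_star is None:
        n_star = n_c + 1 + len(gaps) + 1
        absorbing = None
    else:
        absorbing = n_star
    ks = np.empty(n_star)
    for n in range(1, n_star + 1):
        ks[n - 1] = k_on0 * p_bend(n, s)
    return RateLadder(ks, k_off, absorbing)


# ---------------------------------------------------------- master equation

def evolve_master_equation(r: RateLadder, P0, t_grid):
    """Numerical solution P(n, t) of the birth-death master equation.

    States are n = 1..N (N = r.n_max truncation or n*-1 with absorption);
    reflecting at n = 1 (no depolymerization of the base segment), absorbing
    flux into n* when ``r.n_star`` is set.  Returns (P, absorbed) with P of
    shape (len(t_grid), N); total probability is conserved to better than
    1e-8 at all times.
    """
    P0 = np.asarray(P0, dtype=float)
    if abs(P0.sum() - 1.0) > 1e-8:
        raise ValueError("P0 must be normalized")
    N = r.n_star - 1 if r.n_star is not None else r.n_max
    if len(P0) != N:
        raise ValueError(f"P0 must have length {N}")
    kon = r.k_on[:N].copy()
    if r.n_star is None:
        kon[-1] = 0.0                     # truncation: reflect at n_max
    koff = r.k_off
    t_grid = np.asarray(t_grid, dtype=float)

    def rhs(t, y):
        P = y[:N]
        dP = np.zeros(N + 1)
        up = kon * P                      # flux n -> n+1
        down = koff * P                   # flux n -> n-1 (suppressed at n=1)
        down = down.copy()
        down[0] = 0.0
        dP[:N] -= up + down
        dP[1:N] += up[:-1]
        dP[0:N - 1] += down[1:]
        if r.n_star is not None:
            dP[N] = up[-1]                # absorbed mass
        return dP

    y0 = np.concatenate([P0, [0.0]])
    sol = integrate.solve_ivp(
        rhs, (0.0, float(t_grid[-1])), y0, t_eval=t_grid,
        method="LSODA", rtol=1e-10, atol=1e-14)
    P = sol.y[:N].T
    absorbed = sol.y[N]
    return P, absorbed


def mfpt_closed_form(r: RateLadder, n0=1):
    """Mean first-passage time to n* via the standard birth-death recursion.

    T_k (expected time from k to k+1) obeys T_1 = 1/k_on(1) and
    T_k = (1 + k_off T_{k-1}) / k_on(k); the MFPT from n0 is sum_{k=n0}^{n*-1} T_k.
    Returns inf if some k_on vanishes below n* with k_off = 0.
    """
    if r.n_star is None:
        raise ValueError("ladder has no absorbing state")
    T = 0.0
    Tk = 0.0
    for k in range(1, r.n_star):
        kon = r.k_on[k - 1]
        if kon <= 0:
            return np.inf
        Tk = (1.0 + (r.k_off * Tk if k > 1 else 0.0)) / kon
        if k >= n0:
            T += Tk
    return float(T)


def first_passage_stats(r: RateLadder, n0=1, t_grid=None):
    """First-passage density p(tau_FP) and the MFPT.

    p(tau) is the time derivative of the absorbed mass from the master
    equation started at n0; the MFPT is computed independently by the
    closed-form recursion and, as a cross-check, by integrating the survival
    function.  Returns a dict with ``t``, ``p``, ``mfpt`` (closed form) and
    ``mfpt_integral``.
    """
    if r.n_star is None:
        raise ValueError("ladder has no absorbing state")
    mfpt = mfpt_closed_form(r, n0)
    if not np.isfinite(mfpt):
        return {"t": np.array([]), "p": np.array([]), "mfpt": np.inf,
                "mfpt_integral": np.inf}
    N = r.n_star - 1
    kon = r.k_on[:N]
    koff = r.k_off

    def rhs(t, y):
        P = y[:N]
        dP = np.zeros(N + 2)
        up = kon * P
        down = koff * P
        down = down.copy()
        down[0] = 0.0
        dP[:N] -= up + down
        dP[1:N] += up[:-1]
        dP[0:N - 1] += down[1:]
        dP[N] = up[-1]          # absorbed
        dP[N + 1] = P.sum()     # integral of survival -> MFPT
        return dP

    y0 = np.zeros(N + 2)
    y0[n0 - 1] = 1.0
    t_max = float(t_grid[-1]) if t_grid is not None else 30.0 * mfpt
    sol = integrate.solve_ivp(rhs, (0.0, t_max), y0,
                              t_eval=t_grid, method="LSODA",
                              rtol=1e-11, atol=1e-16,
                              dense_output=t_grid is None)
    if t_grid is None:
        t = np.linspace(0, t_max, 2000)
        y = sol.sol(t)
    else:
        t = np.asarray(t_grid, dtype=float)
        y = sol.y
    surv_int = sol.y[N + 1, -1] if t_grid is not None else sol.sol(t_max)[N + 1]
    p = r.k_on[N - 1] * y[N - 1]
    return {"t": t, "p": p, "mfpt": mfpt, "mfpt_integral": float(surv_int)}


def mfpt_map(theta_range, L0_range, base: TiltScenario | None = None,
             k_off=0.01):
    """MFPT(theta, L0) matrix of the filament bending transition.

    Rows follow ``L0_range``, columns ``theta_range``.  The map spans orders
    of magnitude over modest parameter changes; the theta -> 0 edge diverges
    (no bent escape state within reach).
    """
    base = base or TiltScenario()
    out = np.empty((len(L0_range), len(theta_range)))
    for i, L0 in enumerate(L0_range):
        for j, th in enumerate(theta_range):
            try:
                s = TiltScenario(theta=float(th), L0=float(L0),
                                 kappa=base.kappa, gamma=base.gamma,
                                 L_p=base.L_p, delta=base.delta,
                                 patch=base.patch, cutoff=base.cutoff)
            except ValueError:
                out[i, j] = np.nan
                continue
            ladder = build_ladder(s, k_off=k_off)
            if ladder.n_star is None:
                out[i, j] = np.inf
            else:
                out[i, j] = mfpt_closed_form(ladder, n0=1)
    return out
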