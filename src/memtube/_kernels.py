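"""Numba kernels for the triangulated-membrane and filament Monte Carlo.

All state lives in preallocated flat arrays bundled into namedtuples
(``MeshBuf``, ``FilBuf``) so the same topology-editing routines are shared
between the Python-level API (single moves with undo) and the hot sweep
kernels.  Lengths are in nm, energies in units of k_BT.

Mesh representation: vertex positions ``pos``; oriented triangles ``tri``;
per-vertex incident-triangle lists ``v2t`` (the vertex degree on a closed
surface equals its number of incident triangles).  Compact id lists
(``vlist``/``tlist``/``mlist``/``n3l``) enable O(1) uniform sampling of
vertices, triangles, mobile vertices and removable (mobile, 3-coordinated)
vertices.  ``meta`` holds the counts:
[nv, nf, n_mobile, n_removable, n_vfree, n_tfree].

Periodic wrap applies to x and y only; z is unbounded.  Minimum-image
conventions assume every edge is shorter than half the box, which the tether
upper bound enforces.
"""

from collections import namedtuple

import numpy as np
from numba import njit

MAXDEG = 16

MeshBuf = namedtuple(
    "MeshBuf",
    [
        "pos",      # f8 (capV, 3)
        "tri",      # i4 (capF, 3)
        "v2t",      # i4 (capV, MAXDEG)
        "v2tn",     # i4 (capV,)  vertex degree
        "frozen",   # u1 (capV,)
        "att",      # u1 (capV,)  pulling-spring attachment flag
        "valive",   # u1 (capV,)
        "talive",   # u1 (capF,)
        "vlist",    # i4 compact alive-vertex ids
        "vposl",    # i4 inverse of vlist
        "mlist",    # i4 compact mobile-vertex ids
        "mposl",
        "tlist",    # i4 compact alive-triangle ids
        "tposl",
        "n3l",      # i4 compact removable-vertex ids
        "n3posl",
        "vfree",    # i4 vertex free-slot stack
        "tfree",    # i4 triangle free-slot stack
        "meta",     # i8 (8,)
        "box",      # f8 (2,) Lx, Ly
        "spring",   # f8 (4,) stiffness, anchor height, sum z over att, n att
    ],
)

FilBuf = namedtuple(
    "FilBuf",
    [
        "pos",      # f8 (nfil, cap, 3)
        "n",        # i4 (nfil,) node counts
        "scratch",  # f8 (cap, 3) proposal workspace
    ],
)

# prm layout
P_KAPPA, P_GAMMA, P_Z, P_AMIN, P_AMAX, P_DMEM, P_DFIL, P_AMP, P_SIG, \
    P_AMPFIL, P_LP, P_DELTA = range(12)

# counters layout: attempted/accepted pairs
C_DISP, C_FLIP, C_INS, C_REM, C_FIL, C_NCOUNT = 0, 2, 4, 6, 8, 10


def empty_filbuf(nfil=1, cap=4):
    return FilBuf(
        pos=np.zeros((max(nfil, 1), cap, 3)),
        n=np.zeros(max(nfil, 1), dtype=np.int32),
        scratch=np.zeros((cap, 3)),
    )


# ----------------------------------------------------------------- geometry

@njit(cache=True, inline="always")
def _mi(d, L):
    if d > 0.5 * L:
        return d - L
    if d < -0.5 * L:
        return d + L
    return d


@njit(cache=True, inline="always")
def _rel(pos, j, i, Lx, Ly):
    """Minimum-image displacement pos[j] - pos[i]."""
    return (
        _mi(pos[j, 0] - pos[i, 0], Lx),
        _mi(pos[j, 1] - pos[i, 1], Ly),
        pos[j, 2] - pos[i, 2],
    )


@njit(cache=True, inline="always")
def _dist2(pos, j, i, Lx, Ly):
    dx, dy, dz = _rel(pos, j, i, Lx, Ly)
    return dx * dx + dy * dy + dz * dz


@njit(cache=True, inline="always")
def _dist2_xyz(x, y, z, pos, i, Lx, Ly):
    dx = _mi(x - pos[i, 0], Lx)
    dy = _mi(y - pos[i, 1], Ly)
    dz = z - pos[i, 2]
    return dx * dx + dy * dy + dz * dz


@njit(cache=True)
def vertex_bend_area(m, v):
    """Cotangent mean-curvature vector and barycentric area at vertex v.

    Returns (A, Kx, Ky, Kz, nx, ny, nz) with K the discrete mean-curvature
    normal (|K| = 2|H|) and n the area-weighted outward face normal
    (un-normalized).
    """
    Lx, Ly = m.box[0], m.box[1]
    pos = m.pos
    A = 0.0
    Kx = Ky = Kz = 0.0
    nx = ny = nz = 0.0
    deg = m.v2tn[v]
    for it in range(deg):
        t = m.v2t[v, it]
        t0, t1, t2 = m.tri[t, 0], m.tri[t, 1], m.tri[t, 2]
        if t0 == v:
            a, b = t1, t2
        elif t1 == v:
            a, b = t2, t0
        else:
            a, b = t0, t1
        rax, ray, raz = _rel(pos, a, v, Lx, Ly)
        rbx, rby, rbz = _rel(pos, b, v, Lx, Ly)
        cx = ray * rbz - raz * rby
        cy = raz * rbx - rax * rbz
        cz = rax * rby - ray * rbx
        cn = np.sqrt(cx * cx + cy * cy + cz * cz)
        if cn < 1e-12:
            cn = 1e-12
        A += cn / 6.0
        nx += 0.5 * cx
        ny += 0.5 * cy
        nz += 0.5 * cz
        # cot of angle at a between (v-a) and (b-a); contributes on edge (v,b)
        ax, ay, az = -rax, -ray, -raz
        bx, by, bz = rbx - rax, rby - ray, rbz - raz
        dot = ax * bx + ay * by + az * bz
        crx = ay * bz - az * by
        cry = az * bx - ax * bz
        crz = ax * by - ay * bx
        cr = np.sqrt(crx * crx + cry * cry + crz * crz)
        if cr < 1e-12:
            cr = 1e-12
        cot_a = dot / cr
        Kx -= cot_a * rbx
        Ky -= cot_a * rby
        Kz -= cot_a * rbz
        # cot of angle at b between (v-b) and (a-b); contributes on edge (v,a)
        ax, ay, az = -rbx, -rby, -rbz
        bx, by, bz = rax - rbx, ray - rby, raz - rbz
        dot = ax * bx + ay * by + az * bz
        crx = ay * bz - az * by
        cry = az * bx - ax * bz
        crz = ax * by - ay * bx
        cr = np.sqrt(crx * crx + cry * cry + crz * crz)
        if cr < 1e-12:
            cr = 1e-12
        cot_b = dot / cr
        Kx -= cot_b * rax
        Ky -= cot_b * ray
        Kz -= cot_b * raz
    Kx /= 2.0 * A
    Ky /= 2.0 * A
    Kz /= 2.0 * A
    return A, Kx, Ky, Kz, nx, ny, nz


@njit(cache=True, inline="always")
def vertex_energy(m, v, kappa, gamma):
    A, Kx, Ky, Kz, _, _, _ = vertex_bend_area(m, v)
    return (0.5 * kappa * (Kx * Kx + Ky * Ky + Kz * Kz) + gamma) * A


@njit(cache=True)
def local_energy(m, vs, nvs, kappa, gamma):
    e = 0.0
    for i in range(nvs):
        e += vertex_energy(m, vs[i], kappa, gamma)
    return e


@njit(cache=True)
def ring_of(m, v, out):
    """Ordered-free one-ring vertex ids of v into out; returns count."""
    deg = m.v2tn[v]
    cnt = 0
    for it in range(deg):
        t = m.v2t[v, it]
        for k in range(3):
            w = m.tri[t, k]
            if w == v:
                continue
            seen = False
            for q in range(cnt):
                if out[q] == w:
                    seen = True
                    break
            if not seen:
                out[cnt] = w
                cnt += 1
    return cnt


# ----------------------------------------------------- bookkeeping helpers

@njit(cache=True, inline="always")
def _list_add(lst, posl, count, x):
    lst[count] = x
    posl[x] = count
    return count + 1


@njit(cache=True, inline="always")
def _list_remove(lst, posl, count, x):
    p = posl[x]
    last = lst[count - 1]
    lst[p] = last
    posl[last] = p
    posl[x] = -1
    return count - 1


@njit(cache=True)
def n3_fix(m, v):
    """Keep the removable-vertex candidate list consistent for vertex v."""
    want = (
        m.valive[v] == 1
        and m.frozen[v] == 0
        and m.att[v] == 0
        and m.v2tn[v] == 3
    )
    inlist = m.n3posl[v] >= 0
    if want and not inlist:
        m.meta[3] = _list_add(m.n3l, m.n3posl, m.meta[3], v)
    elif inlist and not want:
        m.meta[3] = _list_remove(m.n3l, m.n3posl, m.meta[3], v)


@njit(cache=True)
def _v2t_add(m, v, t):
    n = m.v2tn[v]
    m.v2t[v, n] = t
    m.v2tn[v] = n + 1


@njit(cache=True)
def _v2t_remove(m, v, t):
    n = m.v2tn[v]
    for i in range(n):
        if m.v2t[v, i] == t:
            m.v2t[v, i] = m.v2t[v, n - 1]
            m.v2tn[v] = n - 1
            return
    # unreachable on a consistent mesh


@njit(cache=True)
def alloc_vertex(m):
    nfree = m.meta[4]
    slot = m.vfree[nfree - 1]
    m.meta[4] = nfree - 1
    m.valive[slot] = 1
    m.frozen[slot] = 0
    m.att[slot] = 0
    m.v2tn[slot] = 0
    m.meta[0] = _list_add(m.vlist, m.vposl, m.meta[0], slot)
    m.meta[2] = _list_add(m.mlist, m.mposl, m.meta[2], slot)
    return slot


@njit(cache=True)
def free_vertex(m, v):
    if m.n3posl[v] >= 0:
        m.meta[3] = _list_remove(m.n3l, m.n3posl, m.meta[3], v)
    m.meta[0] = _list_remove(m.vlist, m.vposl, m.meta[0], v)
    if m.mposl[v] >= 0:
        m.meta[2] = _list_remove(m.mlist, m.mposl, m.meta[2], v)
    m.valive[v] = 0
    m.vfree[m.meta[4]] = v
    m.meta[4] += 1


@njit(cache=True)
def alloc_tri(m):
    nfree = m.meta[5]
    slot = m.tfree[nfree - 1]
    m.meta[5] = nfree - 1
    m.talive[slot] = 1
    m.meta[1] = _list_add(m.tlist, m.tposl, m.meta[1], slot)
    return slot


@njit(cache=True)
def free_tri(m, t):
    m.meta[1] = _list_remove(m.tlist, m.tposl, m.meta[1], t)
    m.talive[t] = 0
    m.tfree[m.meta[5]] = t
    m.meta[5] += 1


@njit(cache=True)
def find_opposite(m, i, j, t_excl):
    """Triangle != t_excl containing directed edge (j, i); returns (t2, l)."""
    for it in range(m.v2tn[i]):
        t = m.v2t[i, it]
        if t == t_excl:
            continue
        t0, t1, t2 = m.tri[t, 0], m.tri[t, 1], m.tri[t, 2]
        if t0 == j or t1 == j or t2 == j:
            l = t0 + t1 + t2 - i - j
            return t, l
    return -1, -1


@njit(cache=True)
def edge_exists(m, k, l):
    for it in range(m.v2tn[k]):
        t = m.v2t[k, it]
        if m.tri[t, 0] == l or m.tri[t, 1] == l or m.tri[t, 2] == l:
            return True
    return False


# ---------------------------------------------------------- topology edits

@njit(cache=True)
def apply_flip(m, t, t2, i, j, k, l):
    """Re-diagonalize the pair (t=(i,j,k), t2=(j,i,l)) across edge (i,j).

    Afterwards t=(i,l,k), t2=(l,j,k).  The inverse operation is
    apply_flip(m, t, t2, l, k, i, j).
    """
    m.tri[t, 0] = i
    m.tri[t, 1] = l
    m.tri[t, 2] = k
    m.tri[t2, 0] = l
    m.tri[t2, 1] = j
    m.tri[t2, 2] = k
    _v2t_remove(m, j, t)
    _v2t_add(m, l, t)
    _v2t_remove(m, i, t2)
    _v2t_add(m, k, t2)
    n3_fix(m, i)
    n3_fix(m, j)
    n3_fix(m, k)
    n3_fix(m, l)


@njit(cache=True)
def apply_insert(m, t, x, y, z):
    """Split triangle t=(a,b,c) by a new vertex at (x, y, z); returns its id."""
    a, b, c = m.tri[t, 0], m.tri[t, 1], m.tri[t, 2]
    vn = alloc_vertex(m)
    m.pos[vn, 0] = x % m.box[0]
    m.pos[vn, 1] = y % m.box[1]
    m.pos[vn, 2] = z
    t1 = alloc_tri(m)
    t2 = alloc_tri(m)
    m.tri[t, 0] = a
    m.tri[t, 1] = b
    m.tri[t, 2] = vn
    m.tri[t1, 0] = b
    m.tri[t1, 1] = c
    m.tri[t1, 2] = vn
    m.tri[t2, 0] = c
    m.tri[t2, 1] = a
    m.tri[t2, 2] = vn
    _v2t_add(m, a, t2)
    _v2t_add(m, b, t1)
    _v2t_remove(m, c, t)
    _v2t_add(m, c, t1)
    _v2t_add(m, c, t2)
    _v2t_add(m, vn, t)
    _v2t_add(m, vn, t1)
    _v2t_add(m, vn, t2)
    n3_fix(m, a)
    n3_fix(m, b)
    n3_fix(m, c)
    n3_fix(m, vn)
    return vn


@njit(cache=True)
def ordered_ring3(m, v):
    """Oriented one-ring (a, b, c) of a 3-coordinated vertex."""
    ts = m.v2t[v]
    pa = np.empty(3, np.int32)
    pb = np.empty(3, np.int32)
    for it in range(3):
        t = ts[it]
        t0, t1, t2 = m.tri[t, 0], m.tri[t, 1], m.tri[t, 2]
        if t0 == v:
            pa[it], pb[it] = t1, t2
        elif t1 == v:
            pa[it], pb[it] = t2, t0
        else:
            pa[it], pb[it] = t0, t1
    a = np.int64(pa[0])
    b = np.int64(pb[0])
    c = np.int64(-1)
    for it in range(1, 3):
        if pa[it] == b:
            c = np.int64(pb[it])
    return a, b, c


@njit(cache=True)
def apply_remove(m, v):
    """Remove a 3-coordinated vertex; inverse of apply_insert.

    Returns the kept triangle slot (now the re-formed outer triangle).
    """
    a, b, c = ordered_ring3(m, v)
    ring = np.empty(3, np.int64)
    ring[0], ring[1], ring[2] = a, b, c
    ts = np.empty(3, np.int64)
    ts[0] = m.v2t[v, 0]
    ts[1] = m.v2t[v, 1]
    ts[2] = m.v2t[v, 2]
    t0, t1, t2 = ts[0], ts[1], ts[2]
    for iw in range(3):
        w = ring[iw]
        for jt in range(3):
            t = ts[jt]
            # remove every incidence of w on v's triangles
            for it in range(m.v2tn[w]):
                if m.v2t[w, it] == t:
                    m.v2t[w, it] = m.v2t[w, m.v2tn[w] - 1]
                    m.v2tn[w] -= 1
                    break
    free_tri(m, t2)
    free_tri(m, t1)
    m.tri[t0, 0] = a
    m.tri[t0, 1] = b
    m.tri[t0, 2] = c
    _v2t_add(m, a, t0)
    _v2t_add(m, b, t0)
    _v2t_add(m, c, t0)
    free_vertex(m, v)
    n3_fix(m, a)
    n3_fix(m, b)
    n3_fix(m, c)
    return t0


# ------------------------------------------------------------ hard checks

@njit(cache=True)
def point_clear_membrane(m, x, y, z, dmin, skip, nskip):
    """True if (x,y,z) is at least dmin from every membrane vertex not in skip.

    Only the vertices whose ids appear in ``cand`` would be a cheaper local
    test; this is the exhaustive variant used for proposals near the sheet.
    """
    d2 = dmin * dmin
    Lx, Ly = m.box[0], m.box[1]
    for p in range(m.meta[0]):
        w = m.vlist[p]
        sk = False
        for q in range(nskip):
            if skip[q] == w:
                sk = True
                break
        if sk:
            continue
        dz = z - m.pos[w, 2]
        if dz * dz >= d2:
            continue
        if _dist2_xyz(x, y, z, m.pos, w, Lx, Ly) < d2:
            return False
    return True


@njit(cache=True)
def point_clear_local(m, x, y, z, dmin, center_vs, ncen, skip, nskip):
    """Hard-core test of a point against the one-rings of ``center_vs``."""
    d2 = dmin * dmin
    Lx, Ly = m.box[0], m.box[1]
    for ic in range(ncen):
        v = center_vs[ic]
        for it in range(m.v2tn[v]):
            t = m.v2t[v, it]
            for kk in range(3):
                w = m.tri[t, kk]
                sk = False
                for q in range(nskip):
                    if skip[q] == w:
                        sk = True
                        break
                if sk:
                    continue
                if _dist2_xyz(x, y, z, m.pos, w, Lx, Ly) < d2:
                    return False
    return True


@njit(cache=True)
def point_clear_filaments(fb, nfil, x, y, z, dmin, self_fil, self_lo, Lx, Ly):
    """Clearance of a point against filament nodes.

    Nodes of filament ``self_fil`` with index >= self_lo are skipped (chain
    neighbors of a moved/added node).
    """
    d2 = dmin * dmin
    for f in range(nfil):
        nn = fb.n[f] + 1
        for q in range(nn):
            if f == self_fil and q >= self_lo:
                continue
            dz = z - fb.pos[f, q, 2]
            if dz * dz >= d2:
                continue
            dx = _mi(x - fb.pos[f, q, 0], Lx)
            dy = _mi(y - fb.pos[f, q, 1], Ly)
            if dx * dx + dy * dy + dz * dz < d2:
                return False
    return True


# ------------------------------------------------------------- MC moves

@njit(cache=True)
def try_displace(m, fb, nfil, prm, rng, beta=1.0):
    if m.meta[2] == 0:
        return 0
    Lx, Ly = m.box[0], m.box[1]
    v = m.mlist[int(rng.random() * m.meta[2])]
    amp = prm[P_AMP]
    dx = amp * (2.0 * rng.random() - 1.0)
    dy = amp * (2.0 * rng.random() - 1.0)
    dz = amp * (2.0 * rng.random() - 1.0)
    nx = (m.pos[v, 0] + dx) % Lx
    ny = (m.pos[v, 1] + dy) % Ly
    nz = m.pos[v, 2] + dz
    ring = np.empty(MAXDEG, np.int32)
    nr = ring_of(m, v, ring)
    amin2 = prm[P_AMIN] * prm[P_AMIN]
    amax2 = prm[P_AMAX] * prm[P_AMAX]
    for q in range(nr):
        d2 = _dist2_xyz(nx, ny, nz, m.pos, ring[q], Lx, Ly)
        if d2 < amin2 or d2 > amax2:
            return 0
    # hard core vs second ring (neighbors pass via the tether lower bound)
    skip = np.empty(MAXDEG + 1, np.int32)
    skip[0] = v
    for q in range(nr):
        skip[q + 1] = ring[q]
    if not point_clear_local(m, nx, ny, nz, prm[P_DMEM], ring, nr,
                             skip, nr + 1):
        return 0
    if nfil > 0:
        dmin = 0.5 * (prm[P_DMEM] + prm[P_DFIL])
        if not point_clear_filaments(fb, nfil, nx, ny, nz, dmin, -1, 0,
                                     Lx, Ly):
            return 0
    vs = np.empty(MAXDEG + 1, np.int32)
    vs[0] = v
    for q in range(nr):
        vs[q + 1] = ring[q]
    kappa, gamma = prm[P_KAPPA], prm[P_GAMMA]
    e0 = local_energy(m, vs, nr + 1, kappa, gamma)
    if m.att[v] == 1 and m.spring[3] > 0:
        K = m.spring[0]
        zb0 = m.spring[2] / m.spring[3]
        zb1 = (m.spring[2] + dz) / m.spring[3]
        e_spr = 0.5 * K * ((zb1 - m.spring[1]) ** 2 - (zb0 - m.spring[1]) ** 2)
    else:
        e_spr = 0.0
    ox, oy, oz = m.pos[v, 0], m.pos[v, 1], m.pos[v, 2]
    m.pos[v, 0] = nx
    m.pos[v, 1] = ny
    m.pos[v, 2] = nz
    de = local_energy(m, vs, nr + 1, kappa, gamma) - e0 + e_spr
    if de <= 0.0 or rng.random() < np.exp(-beta * de):
        if m.att[v] == 1:
            m.spring[2] += dz
        return 1
    m.pos[v, 0] = ox
    m.pos[v, 1] = oy
    m.pos[v, 2] = oz
    return 0


@njit(cache=True)
def try_flip(m, prm, rng, beta=1.0):
    if m.meta[1] == 0:
        return 0
    t = m.tlist[int(rng.random() * m.meta[1])]
    e = int(rng.random() * 3)
    i = m.tri[t, e]
    j = m.tri[t, (e + 1) % 3]
    k = m.tri[t, (e + 2) % 3]
    t2, l = find_opposite(m, i, j, t)
    if t2 < 0:
        return 0
    if m.v2tn[i] < 4 or m.v2tn[j] < 4:
        return 0
    if m.v2tn[k] >= MAXDEG or m.v2tn[l] >= MAXDEG:
        return 0
    if edge_exists(m, k, l):
        return 0
    d2 = _dist2(m.pos, k, l, m.box[0], m.box[1])
    if d2 < prm[P_AMIN] ** 2 or d2 > prm[P_AMAX] ** 2:
        return 0
    vs = np.empty(4, np.int32)
    vs[0], vs[1], vs[2], vs[3] = i, j, k, l
    kappa, gamma = prm[P_KAPPA], prm[P_GAMMA]
    e0 = local_energy(m, vs, 4, kappa, gamma)
    apply_flip(m, t, t2, i, j, k, l)
    de = local_energy(m, vs, 4, kappa, gamma) - e0
    if de <= 0.0 or rng.random() < np.exp(-beta * de):
        return 1
    apply_flip(m, t, t2, l, k, i, j)
    return 0


@njit(cache=True)
def _phi_ins(dx, dy, dz, sigma):
    """Insertion-offset proposal density times the reference volume 1 nm^3."""
    s2 = sigma * sigma
    r2 = dx * dx + dy * dy + dz * dz
    return (2.0 * np.pi * s2) ** (-1.5) * np.exp(-0.5 * r2 / s2)


@njit(cache=True)
def try_insert(m, fb, nfil, prm, rng, beta=1.0):
    if m.meta[1] == 0 or m.meta[4] < 2 or m.meta[5] < 3:
        return 0
    Lx, Ly = m.box[0], m.box[1]
    t = m.tlist[int(rng.random() * m.meta[1])]
    a, b, c = m.tri[t, 0], m.tri[t, 1], m.tri[t, 2]
    if m.v2tn[a] >= MAXDEG or m.v2tn[b] >= MAXDEG or m.v2tn[c] >= MAXDEG:
        return 0
    rbx, rby, rbz = _rel(m.pos, b, a, Lx, Ly)
    rcx, rcy, rcz = _rel(m.pos, c, a, Lx, Ly)
    cenx = m.pos[a, 0] + (rbx + rcx) / 3.0
    ceny = m.pos[a, 1] + (rby + rcy) / 3.0
    cenz = m.pos[a, 2] + (rbz + rcz) / 3.0
    sig = prm[P_SIG]
    ox = sig * rng.standard_normal()
    oy = sig * rng.standard_normal()
    oz = sig * rng.standard_normal()
    nx, ny, nz = cenx + ox, ceny + oy, cenz + oz
    amin2 = prm[P_AMIN] ** 2
    amax2 = prm[P_AMAX] ** 2
    for w in (a, b, c):
        d2 = _dist2_xyz(nx, ny, nz, m.pos, w, Lx, Ly)
        if d2 < amin2 or d2 > amax2:
            return 0
    abc = np.empty(3, np.int32)
    abc[0], abc[1], abc[2] = a, b, c
    if not point_clear_local(m, nx, ny, nz, prm[P_DMEM], abc, 3, abc, 3):
        return 0
    if nfil > 0:
        dmin = 0.5 * (prm[P_DMEM] + prm[P_DFIL])
        if not point_clear_filaments(fb, nfil, nx, ny, nz, dmin, -1, 0,
                                     Lx, Ly):
            return 0
    kappa, gamma = prm[P_KAPPA], prm[P_GAMMA]
    e0 = local_energy(m, abc, 3, kappa, gamma)
    F_before = m.meta[1]
    vn = apply_insert(m, t, nx, ny, nz)
    vs = np.empty(4, np.int32)
    vs[0], vs[1], vs[2] = a, b, c
    vs[3] = vn
    de = local_energy(m, vs, 4, kappa, gamma) - e0
    n3_after = m.meta[3]
    phi = _phi_ins(ox, oy, oz, sig)
    r = prm[P_Z] * np.exp(-beta * de) * F_before / (n3_after * phi)
    if rng.random() < r:
        return 1
    apply_remove(m, vn)
    return 0


@njit(cache=True)
def try_remove(m, fb, nfil, prm, rng, beta=1.0):
    if m.meta[3] == 0:
        return 0
    Lx, Ly = m.box[0], m.box[1]
    v = m.n3l[int(rng.random() * m.meta[3])]
    a, b, c = ordered_ring3(m, v)
    if m.v2tn[a] < 4 or m.v2tn[b] < 4 or m.v2tn[c] < 4:
        return 0
    # re-formed triangle must not duplicate an existing one
    for it in range(m.v2tn[a]):
        t = m.v2t[a, it]
        hasb = m.tri[t, 0] == b or m.tri[t, 1] == b or m.tri[t, 2] == b
        hasc = m.tri[t, 0] == c or m.tri[t, 1] == c or m.tri[t, 2] == c
        if hasb and hasc:
            return 0
    rbx, rby, rbz = _rel(m.pos, b, a, Lx, Ly)
    rcx, rcy, rcz = _rel(m.pos, c, a, Lx, Ly)
    cenx = m.pos[a, 0] + (rbx + rcx) / 3.0
    ceny = m.pos[a, 1] + (rby + rcy) / 3.0
    cenz = m.pos[a, 2] + (rbz + rcz) / 3.0
    ox = _mi(m.pos[v, 0] - cenx, Lx)
    oy = _mi(m.pos[v, 1] - ceny, Ly)
    oz = m.pos[v, 2] - cenz
    vs = np.empty(4, np.int32)
    vs[0], vs[1], vs[2] = a, b, c
    vs[3] = v
    kappa, gamma = prm[P_KAPPA], prm[P_GAMMA]
    e0 = local_energy(m, vs, 4, kappa, gamma)
    n3_before = m.meta[3]
    px, py, pz = m.pos[v, 0], m.pos[v, 1], m.pos[v, 2]
    t_kept = apply_remove(m, v)
    de = local_energy(m, vs, 3, kappa, gamma) - e0
    F_after = m.meta[1]
    phi = _phi_ins(ox, oy, oz, prm[P_SIG])
    r = np.exp(-beta * de) * n3_before * phi / (prm[P_Z] * F_after)
    if rng.random() < r:
        return 1
    apply_insert(m, t_kept, px, py, pz)
    return 0


# --------------------------------------------------------- filament moves

@njit(cache=True, inline="always")
def _rot_about(px, py, pz, ox, oy, oz, ux, uy, uz, ct, st):
    """Rodrigues rotation of point p about axis u through origin o."""
    vx, vy, vz = px - ox, py - oy, pz - oz
    cx = uy * vz - uz * vy
    cy = uz * vx - ux * vz
    cz = ux * vy - uy * vx
    d = ux * vx + uy * vy + uz * vz
    rx = vx * ct + cx * st + ux * d * (1.0 - ct)
    ry = vy * ct + cy * st + uy * d * (1.0 - ct)
    rz = vz * ct + cz * st + uz * d * (1.0 - ct)
    return ox + rx, oy + ry, oz + rz


@njit(cache=True, inline="always")
def _joint_energy(ax, ay, az, bx, by, bz, cx, cy, cz, lp_over_d):
    """WLC energy (Lp/δ)(1 - cosφ) of the joint at b on nodes a-b-c."""
    t1x, t1y, t1z = bx - ax, by - ay, bz - az
    t2x, t2y, t2z = cx - bx, cy - by, cz - bz
    n1 = np.sqrt(t1x * t1x + t1y * t1y + t1z * t1z)
    n2 = np.sqrt(t2x * t2x + t2y * t2y + t2z * t2z)
    cosphi = (t1x * t2x + t1y * t2y + t1z * t2z) / (n1 * n2)
    return lp_over_d * (1.0 - cosphi)


@njit(cache=True)
def fil_nodes_clear(m, fb, nfil, f, lo, hi, prm, use_membrane):
    """Steric test of (proposed) nodes lo..hi of filament f held in scratch."""
    Lx, Ly = m.box[0], m.box[1]
    dmix = 0.5 * (prm[P_DMEM] + prm[P_DFIL])
    dff = prm[P_DFIL]
    d2ff = dff * dff
    nn = fb.n[f] + 1
    for q in range(lo, hi + 1):
        x, y, z = fb.scratch[q, 0], fb.scratch[q, 1], fb.scratch[q, 2]
        if use_membrane:
            dummy = np.empty(1, np.int32)
            if not point_clear_membrane(m, x, y, z, dmix, dummy, 0):
                return False
        for g in range(nfil):
            ng = fb.n[g] + 1
            for p in range(ng):
                if g == f:
                    if p >= lo and p <= hi:
                        continue  # moved block is rigid; internal ok
                    if abs(p - q) <= 4:
                        continue  # bead overlap of chain neighbors
                dz = z - fb.pos[g, p, 2]
                if dz * dz >= d2ff:
                    continue
                dx = _mi(x - fb.pos[g, p, 0], Lx)
                dy = _mi(y - fb.pos[g, p, 1], Ly)
                if dx * dx + dy * dy + dz * dz < d2ff:
                    return False
    return True


@njit(cache=True)
def try_fil_move(m, fb, nfil, f, prm, rng, use_membrane, beta=1.0):
    """One pivot (terminal free-rotation) or crankshaft move on filament f."""
    nn = fb.n[f] + 1  # node count
    if nn < 3:
        return 0
    lp_over_d = prm[P_LP] / prm[P_DELTA]
    amp = prm[P_AMPFIL]
    th = amp * (2.0 * rng.random() - 1.0)
    ct, st = np.cos(th), np.sin(th)
    crank = rng.random() < 0.5 and nn >= 4
    if crank:
        arc = 2 + int(rng.random() * 5.0)  # 2..6 segments
        if arc > nn - 2:
            arc = nn - 2
        j = 1 + int(rng.random() * (nn - 1 - arc))
        k = j + arc
        # axis along the chord j -> k
        ax = fb.pos[f, k, 0] - fb.pos[f, j, 0]
        ay = fb.pos[f, k, 1] - fb.pos[f, j, 1]
        az = fb.pos[f, k, 2] - fb.pos[f, j, 2]
        an = np.sqrt(ax * ax + ay * ay + az * az)
        if an < 1e-12:
            return 0
        ax, ay, az = ax / an, ay / an, az / an
        lo, hi = j + 1, k - 1
    else:
        j = 1 + int(rng.random() * (nn - 2))
        k = -1
        ax = rng.standard_normal()
        ay = rng.standard_normal()
        az = rng.standard_normal()
        an = np.sqrt(ax * ax + ay * ay + az * az)
        if an < 1e-12:
            return 0
        ax, ay, az = ax / an, ay / an, az / an
        lo, hi = j + 1, nn - 1
    ox, oy, oz = fb.pos[f, j, 0], fb.pos[f, j, 1], fb.pos[f, j, 2]
    for q in range(lo, hi + 1):
        x, y, z = _rot_about(
            fb.pos[f, q, 0], fb.pos[f, q, 1], fb.pos[f, q, 2],
            ox, oy, oz, ax, ay, az, ct, st)
        fb.scratch[q, 0] = x
        fb.scratch[q, 1] = y
        fb.scratch[q, 2] = z
    # energy: only the hinge joints change (rotations are rigid)
    e0 = 0.0
    e1 = 0.0
    # joint at j (nodes j-1, j, j+1)
    e0 += _joint_energy(
        fb.pos[f, j - 1, 0], fb.pos[f, j - 1, 1], fb.pos[f, j - 1, 2],
        ox, oy, oz,
        fb.pos[f, j + 1, 0], fb.pos[f, j + 1, 1], fb.pos[f, j + 1, 2],
        lp_over_d)
    e1 += _joint_energy(
        fb.pos[f, j - 1, 0], fb.pos[f, j - 1, 1], fb.pos[f, j - 1, 2],
        ox, oy, oz,
        fb.scratch[j + 1, 0], fb.scratch[j + 1, 1], fb.scratch[j + 1, 2],
        lp_over_d)
    if crank and k < nn - 1:
        e0 += _joint_energy(
            fb.pos[f, k - 1, 0], fb.pos[f, k - 1, 1], fb.pos[f, k - 1, 2],
            fb.pos[f, k, 0], fb.pos[f, k, 1], fb.pos[f, k, 2],
            fb.pos[f, k + 1, 0], fb.pos[f, k + 1, 1], fb.pos[f, k + 1, 2],
            lp_over_d)
        e1 += _joint_energy(
            fb.scratch[k - 1, 0], fb.scratch[k - 1, 1], fb.scratch[k - 1, 2],
            fb.pos[f, k, 0], fb.pos[f, k, 1], fb.pos[f, k, 2],
            fb.pos[f, k + 1, 0], fb.pos[f, k + 1, 1], fb.pos[f, k + 1, 2],
            lp_over_d)
    # (if k is the barbed-end node there is no joint beyond the tip)
    de = e1 - e0
    if de > 0.0 and rng.random() >= np.exp(-beta * de):
        return 0
    if not fil_nodes_clear(m, fb, nfil, f, lo, hi, prm, use_membrane):
        return 0
    for q in range(lo, hi + 1):
        fb.pos[f, q, 0] = fb.scratch[q, 0]
        fb.pos[f, q, 1] = fb.scratch[q, 1]
        fb.pos[f, q, 2] = fb.scratch[q, 2]
    return 1


# --------------------------------------------------------------- sweeps

@njit(cache=True)
def run_moves(m, fb, nfil, prm, rng, counters,
              n_disp, n_flip, n_ins, n_rem, n_fil, use_membrane=True,
              beta=1.0):
    """Randomly interleaved block of MC moves with fixed mixing probabilities."""
    ntot = n_disp + n_flip + n_ins + n_rem + n_fil
    if ntot == 0:
        return
    p1 = n_disp / ntot
    p2 = p1 + n_flip / ntot
    p3 = p2 + n_ins / ntot
    p4 = p3 + n_rem / ntot
    for _ in range(ntot):
        u = rng.random()
        if u < p1:
            counters[C_DISP] += 1
            counters[C_DISP + 1] += try_displace(m, fb, nfil, prm, rng, beta)
        elif u < p2:
            counters[C_FLIP] += 1
            counters[C_FLIP + 1] += try_flip(m, prm, rng, beta)
        elif u < p3:
            counters[C_INS] += 1
            counters[C_INS + 1] += try_insert(m, fb, nfil, prm, rng, beta)
        elif u < p4:
            counters[C_REM] += 1
            counters[C_REM + 1] += try_remove(m, fb, nfil, prm, rng, beta)
        else:
            f = int(rng.random() * nfil)
            counters[C_FIL] += 1
            counters[C_FIL + 1] += try_fil_move(
                m, fb, nfil, f, prm, rng, use_membrane, beta)


@njit(cache=True)
def total_bend_tension(m, kappa, gamma):
    e = 0.0
    for p in range(m.meta[0]):
        e += vertex_energy(m, m.vlist[p], kappa, gamma)
    return e


@njit(cache=True)
def total_area(m):
    a = 0.0
    for p in range(m.meta[0]):
        A, _, _, _, _, _, _ = vertex_bend_area(m, m.vlist[p])
        a += A
    return a
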