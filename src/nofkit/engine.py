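"""McMurchie-Davidson evaluation of Gaussian integrals.

Internal engine behind :mod:`nofkit.integrals`.  Works in Cartesian
primitives via Hermite expansions, transforms shell blocks to real
spherical harmonics, and renormalizes every AO to unit self-overlap.
Supports s/p/d/f shells and the 2-/3-center Coulomb integrals needed for
the resolution-of-the-identity (density-fitting) path.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gamma, gammainc

from .basis import Shell, _prim_norm, cart_components, sph_transform

__all__ = ["overlap", "kinetic", "nuclear_attraction", "eri_full", "coulomb_2c", "coulomb_3c"]


# ---------------------------------------------------------------------------
# Boys function
# ---------------------------------------------------------------------------

def boys(nmax: int, x: np.ndarray) -> np.ndarray:
    """F_n(x) for n = 0..nmax; returns array (nmax+1, *x.shape)."""
    x = np.asarray(x, dtype=float)
    out = np.empty((nmax + 1,) + x.shape)
    small = x < 1e-13
    xs = np.where(small, 1.0, x)  # placeholder to avoid 0-division
    n = nmax
    fn = gammainc(n + 0.5, xs) * gamma(n + 0.5) / (2.0 * xs ** (n + 0.5))
    fn = np.where(small, 1.0 / (2 * n + 1), fn)
    out[nmax] = fn
    if nmax > 0:
        ex = np.exp(-x)
        for n in range(nmax - 1, -1, -1):
            out[n] = (2.0 * x * out[n + 1] + ex) / (2 * n + 1)
            out[n] = np.where(small, 1.0 / (2 * n + 1), out[n])
    return out


# ---------------------------------------------------------------------------
# Hermite expansion coefficients
# ---------------------------------------------------------------------------

def _hermite_1d(la: int, lb: int, a, b, ab: float):
    """E[i][j][t] arrays over the primitive-pair axis for one dimension.

    ``a``/``b`` are broadcastable primitive-exponent arrays, ``ab`` the
    scalar A-B component.  The Gaussian product prefactor exp(-mu*AB^2) is
    folded into E via the base case.
    """
    p = a + b
    mu = a * b / p
    xpa = -b / p * ab
    xpb = a / p * ab
    E = {}
    E[(0, 0, 0)] = np.exp(-mu * ab * ab)
    for i in range(la + 1):
        for j in range(lb + 1):
            if i == 0 and j == 0:
                continue
            for t in range(i + j + 1):
                if j == 0:
                    # decrement i
                    val = 0.0
                    if t - 1 >= 0:
                        val = E.get((i - 1, j, t - 1), 0.0) / (2 * p)
                    val = val + xpa * E.get((i - 1, j, t), 0.0)
                    val = val + (t + 1) * E.get((i - 1, j, t + 1), 0.0)
                else:
                    val = 0.0
                    if t - 1 >= 0:
                        val = E.get((i, j - 1, t - 1), 0.0) / (2 * p)
                    val = val + xpb * E.get((i, j - 1, t), 0.0)
                    val = val + (t + 1) * E.get((i, j - 1, t + 1), 0.0)
                E[(i, j, t)] = val
    return E


class _ShellPair:
    """Precomputed pair data: Hermite expansion of all Cartesian products."""

    def __init__(self, sha: Shell, shb: Shell, norm_a=True, norm_b=True):
        self.sha, self.shb = sha, shb
        la, lb = sha.l, shb.l
        aa = np.repeat(sha.exps, len(shb.exps))
        bb = np.tile(shb.exps, len(sha.exps))
        if norm_a:
            na = np.array([_prim_norm(x, la) for x in sha.exps])
            ca = np.repeat(sha.coefs * na, len(shb.exps))
        else:
            ca = np.repeat(sha.coefs, len(shb.exps))
        if norm_b:
            nb = np.array([_prim_norm(x, lb) for x in shb.exps])
            cb = np.tile(shb.coefs * nb, len(sha.exps))
        else:
            cb = np.tile(shb.coefs, len(sha.exps))
        self.a, self.b = aa, bb
        self.coef = ca * cb
        self.p = aa + bb
        AB = sha.center - shb.center
        self.AB = AB
        self.P = (aa[:, None] * sha.center + bb[:, None] * shb.center) / self.p[:, None]
        self.E = [_hermite_1d(la, lb, aa, bb, AB[d]) for d in range(3)]
        self.carts_a = cart_components(la)
        self.carts_b = cart_components(lb)
        self.L = la + lb

    def hermite_tensor(self):
        """A[k, ca, cb, t, u, v] combined expansion coefficients (coef folded)."""
        K = len(self.p)
        na, nb = len(self.carts_a), len(self.carts_b)
        T = self.L + 1
        A = np.zeros((K, na, nb, T, T, T))
        for ia, (ax, ay, az) in enumerate(self.carts_a):
            for ib, (bx, by, bz) in enumerate(self.carts_b):
                for t in range(ax + bx + 1):
                    Ex = self.E[0].get((ax, bx, t), None)
                    if Ex is None:
                        continue
                    for u in range(ay + by + 1):
                        Ey = self.E[1].get((ay, by, u), None)
                        if Ey is None:
                            continue
                        for v in range(az + bz + 1):
                            Ez = self.E[2].get((az, bz, v), None)
                            if Ez is None:
                                continue
                            A[:, ia, ib, t, u, v] = self.coef * Ex * Ey * Ez
        return A


# ---------------------------------------------------------------------------
# Hermite Coulomb integrals R_{tuv}
# ---------------------------------------------------------------------------

def _hermite_coulomb(tmax: int, umax: int, vmax: int, alpha, R):
    """R[t,u,v] arrays (over leading axes of alpha) for the Hermite Coulomb
    integral with exponent ``alpha`` and separation ``R`` (..., 3)."""
    N = tmax + umax + vmax
    r2 = np.einsum("...i,...i->...", R, R)
    F = boys(N, alpha * r2)
    base = {}  # (n, t, u, v) -> array
    for n in range(N + 1):
        base[(n, 0, 0, 0)] = (-2.0 * alpha) ** n * F[n]

    def get(n, t, u, v):
        key = (n, t, u, v)
        if key in base:
            return base[key]
        if t > 0:
            val = (t - 1) * get(n + 1, t - 2, u, v) if t > 1 else 0.0
            val = val + R[..., 0] * get(n + 1, t - 1, u, v)
        elif u > 0:
            val = (u - 1) * get(n + 1, t, u - 2, v) if u > 1 else 0.0
            val = val + R[..., 1] * get(n + 1, t, u - 1, v)
        else:
            val = (v - 1) * get(n + 1, t, u, v - 2) if v > 1 else 0.0
            val = val + R[..., 2] * get(n + 1, t, u, v - 1)
        base[key] = val
        return val

    shape = np.broadcast_shapes(np.shape(alpha), r2.shape)
    out = np.zeros(shape + (tmax + 1, umax + 1, vmax + 1))
    for t in range(tmax + 1):
        for u in range(umax + 1):
            for v in range(vmax + 1):
                out[..., t, u, v] = get(0, t, u, v)
    return out


# ---------------------------------------------------------------------------
# One-electron integrals
# ---------------------------------------------------------------------------

def _overlap_1d(E, i, j, p):
    return E.get((i, j, 0), 0.0) * np.sqrt(np.pi / p)


def _pair_overlap_cart(sp: _ShellPair):
    na, nb = len(sp.carts_a), len(sp.carts_b)
    S = np.zeros((na, nb))
    for ia, A in enumerate(sp.carts_a):
        for ib, B in enumerate(sp.carts_b):
            val = sp.coef.copy().astype(float)
            for d in range(3):
                val = val * _overlap_1d(sp.E[d], A[d], B[d], sp.p)
            S[ia, ib] = val.sum()
    return S


def _pair_kinetic_cart(sp: _ShellPair):
    """Kinetic energy via the standard 1D decomposition."""
    sha, shb = sp.sha, sp.shb
    la, lb = sha.l, shb.l
    # need E up to lb+2 in each dimension
    E = [_hermite_1d(la, lb + 2, sp.a, sp.b, sp.AB[d]) for d in range(3)]
    b = sp.b

    def s1d(d, i, j):
        return E[d].get((i, j, 0), 0.0) * np.sqrt(np.pi / sp.p)

    def t1d(d, i, j):
        val = -2.0 * b ** 2 * s1d(d, i, j + 2) + b * (2 * j + 1) * s1d(d, i, j)
        if j >= 2:
            val = val - 0.5 * j * (j - 1) * s1d(d, i, j - 2)
        return val

    na, nb_ = len(sp.carts_a), len(sp.carts_b)
    T = np.zeros((na, nb_))
    for ia, A in enumerate(sp.carts_a):
        for ib, B in enumerate(sp.carts_b):
            sx, sy, sz = s1d(0, A[0], B[0]), s1d(1, A[1], B[1]), s1d(2, A[2], B[2])
            tx, ty, tz = t1d(0, A[0], B[0]), t1d(1, A[1], B[1]), t1d(2, A[2], B[2])
            T[ia, ib] = (sp.coef * (tx * sy * sz + sx * ty * sz + sx * sy * tz)).sum()
    return T


def _pair_nuclear_cart(sp: _ShellPair, coords: np.ndarray, charges: np.ndarray):
    A = sp.hermite_tensor()  # (K, na, nb, T, T, T)
    K, na, nb = A.shape[:3]
    L = sp.L
    V = np.zeros((na, nb))
    for C, Z in zip(coords, charges):
        PC = sp.P - C  # (K, 3)
        R = _hermite_coulomb(L, L, L, sp.p, PC)  # (K, T, T, T)
        V += -Z * np.einsum("kabtuv,ktuv,k->ab", A, R, 2.0 * np.pi / sp.p)
    return V


# ---------------------------------------------------------------------------
# Public matrix builders
# ---------------------------------------------------------------------------

def _assemble(shells, pair_func, *args):
    offs = np.cumsum([0] + [sh.n_sph for sh in shells])
    n = offs[-1]
    M = np.zeros((n, n))
    for i, shi in enumerate(shells):
        Ti = sph_transform(shi.l)
        for j, shj in enumerate(shells[: i + 1]):
            Tj = sph_transform(shj.l)
            blk = pair_func(_ShellPair(shi, shj), *args)
            blk = Ti @ blk @ Tj.T
            M[offs[i]:offs[i + 1], offs[j]:offs[j + 1]] = blk
            M[offs[j]:offs[j + 1], offs[i]:offs[i + 1]] = blk.T
    return M


def overlap(shells) -> np.ndarray:
    return _assemble(shells, _pair_overlap_cart)


def kinetic(shells) -> np.ndarray:
    return _assemble(shells, _pair_kinetic_cart)


def nuclear_attraction(shells, coords, charges) -> np.ndarray:
    return _assemble(shells, _pair_nuclear_cart, coords, charges)


def _pair_list(shells):
    pairs = []
    for i in range(len(shells)):
        for j in range(i + 1):
            pairs.append((i, j))
    return pairs


def _eri_block(spa: _ShellPair, spb: _ShellPair):
    """(ab|cd) Cartesian block, shape (na, nb, nc, nd)."""
    Aa = spa.hermite_tensor()
    Ab = spb.hermite_tensor()
    Ka, La = Aa.shape[0], spa.L
    Kb, Lb = Ab.shape[0], spb.L
    # sign (-1)^(t'+u'+v') on the ket expansion
    Tb = Lb + 1
    sgn = np.zeros((Tb, Tb, Tb))
    for t in range(Tb):
        for u in range(Tb):
            for v in range(Tb):
                sgn[t, u, v] = (-1.0) ** (t + u + v)
    Ab = Ab * sgn
    p = spa.p[:, None]
    q = spb.p[None, :]
    alpha = p * q / (p + q)
    PQ = spa.P[:, None, :] - spb.P[None, :, :]
    R = _hermite_coulomb(La + Lb, La + Lb, La + Lb, alpha, PQ)  # (Ka,Kb,T,T,T)
    pref = 2.0 * np.pi ** 2.5 / (p * q * np.sqrt(p + q))
    # contract Hermite indices of bra and ket against the shifted R tensor
    na, nb = Aa.shape[1], Aa.shape[2]
    nc, nd = Ab.shape[1], Ab.shape[2]
    out = np.zeros((na, nb, nc, nd))
    Ta = La + 1
    for t in range(Ta):
        for u in range(Ta):
            for v in range(Ta):
                Abra = Aa[:, :, :, t, u, v]  # (Ka, na, nb)
                if not np.any(Abra):
                    continue
                Rsub = R[:, :, t:t + Tb, u:u + Tb, v:v + Tb] * pref[..., None, None, None]
                # contract ket Hermite indices and ket primitives
                ket = np.einsum("kmtuv,mcdtuv->kcd", Rsub, Ab, optimize=True)
                out += np.einsum("kab,kcd->abcd", Abra, ket, optimize=True)
    return out


def eri_full(shells) -> np.ndarray:
    """Full (munu|lambdasigma) tensor over spherical AOs, 8-fold symmetric."""
    offs = np.cumsum([0] + [sh.n_sph for sh in shells])
    n = offs[-1]
    G = np.zeros((n, n, n, n))
    pairs = _pair_list(shells)
    sps = {(i, j): _ShellPair(shells[i], shells[j]) for i, j in pairs}
    T = {i: sph_transform(sh.l) for i, sh in enumerate(shells)}
    for a, (i, j) in enumerate(pairs):
        for b in range(a + 1):
            k, l = pairs[b]
            blk = _eri_block(sps[(i, j)], sps[(k, l)])
            blk = np.einsum("ai,bj,ck,dl,ijkl->abcd", T[i], T[j], T[k], T[l], blk, optimize=True)
            si, sj = slice(offs[i], offs[i + 1]), slice(offs[j], offs[j + 1])
            sk, sl = slice(offs[k], offs[k + 1]), slice(offs[l], offs[l + 1])
            G[si, sj, sk, sl] = blk
            G[sj, si, sk, sl] = blk.transpose(1, 0, 2, 3)
            G[si, sj, sl, sk] = blk.transpose(0, 1, 3, 2)
            G[sj, si, sl, sk] = blk.transpose(1, 0, 3, 2)
            G[sk, sl, si, sj] = blk.transpose(2, 3, 0, 1)
            G[sl, sk, si, sj] = blk.transpose(3, 2, 0, 1)
            G[sk, sl, sj, si] = blk.transpose(2, 3, 1, 0)
            G[sl, sk, sj, si] = blk.transpose(3, 2, 1, 0)
    return G


def _dummy_shell(center: np.ndarray) -> Shell:
    """Unit s 'shell' with near-zero exponent: multiplying by it leaves a
    Gaussian pair unchanged, which turns 4-center code into 3-/2-center."""
    return Shell(l=0, exps=np.array([1e-30]), coefs=np.array([1.0]), center=center, atom=-1)


def _unit_pair(sh: Shell) -> _ShellPair:
    sp = _ShellPair(sh, _dummy_shell(sh.center), norm_a=True, norm_b=False)
    return sp


def coulomb_3c(shells, aux_shells) -> np.ndarray:
    """(munu|P) three-index Coulomb tensor, spherical AOs x spherical aux."""
    offs = np.cumsum([0] + [sh.n_sph for sh in shells])
    aoffs = np.cumsum([0] + [sh.n_sph for sh in aux_shells])
    n, na = offs[-1], aoffs[-1]
    out = np.zeros((n, n, na))
    T = {i: sph_transform(sh.l) for i, sh in enumerate(shells)}
    aux_pairs = [_unit_pair(sh) for sh in aux_shells]
    for i in range(len(shells)):
        for j in range(i + 1):
            sp = _ShellPair(shells[i], shells[j])
            si, sj = slice(offs[i], offs[i + 1]), slice(offs[j], offs[j + 1])
            for P, app in enumerate(aux_pairs):
                blk = _eri_block(sp, app)[:, :, :, 0]  # (na_c, nb_c, ncart_P)
                blk = np.einsum("ai,bj,ck,ijk->abc", T[i], T[j],
                                sph_transform(aux_shells[P].l), blk, optimize=True)
                sP = slice(aoffs[P], aoffs[P + 1])
                out[si, sj, sP] = blk
                out[sj, si, sP] = blk.transpose(1, 0, 2)
    return out


def coulomb_2c(aux_shells) -> np.ndarray:
    """(P|Q) two-index Coulomb metric over spherical aux functions."""
    aoffs = np.cumsum([0] + [sh.n_sph for sh in aux_shells])
    n = aoffs[-1]
    out = np.zeros((n, n))
    pairs = [_unit_pair(sh) for sh in aux_shells]
    for i in range(len(aux_shells)):
        for j in range(i + 1):
            blk = _eri_block(pairs[i], pairs[j])[:, 0, :, 0]
            blk = sph_transform(aux_shells[i].l) @ blk @ sph_transform(aux_shells[j].l).T
            si, sj = slice(aoffs[i], aoffs[i + 1]), slice(aoffs[j], aoffs[j + 1])
            out[si, sj] = blk
            out[sj, si] = blk.T
    return out
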