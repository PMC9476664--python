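"""Cartesian Gaussian integrals via the McMurchie–Davidson scheme.

Implements overlap, kinetic, nuclear-attraction, two-/three-/four-center
electron-repulsion integrals (Coulomb, erf- and erfc-attenuated kernels) and
basis-function evaluation on real-space points.  Hermite expansion
coefficients are vectorized over primitive pairs; the Hermite Coulomb tensor
R_tuv is built by the usual auxiliary-index recursion on top of a downward
Boys-function recursion.

Only the integral classes needed here are exercised (s/p orbital shells,
up to d auxiliary shells), but the recursions are general in ``l``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gamma, gammainc

from .basis import BasisSet, Shell, cartesian_components, primitive_norm, _double_factorial


# ---------------------------------------------------------------------------
# Boys function
# ---------------------------------------------------------------------------

def boys(n_max: int, T: np.ndarray) -> np.ndarray:
    """F_n(T) for n = 0..n_max; returns array of shape T.shape + (n_max+1,)."""
    T = np.asarray(T, float)
    out = np.empty(T.shape + (n_max + 1,))
    a = n_max + 0.5
    Tsafe = np.where(T < 1e-13, 1.0, T)
    Fmax = gammainc(a, Tsafe) * gamma(a) / (2.0 * Tsafe**a)
    # small-T series for the top order; downward recursion is then stable
    series = 1.0 / (2 * n_max + 1) - T / (2 * n_max + 3) + T**2 / (2 * (2 * n_max + 5))
    out[..., n_max] = np.where(T < 1e-13, series, Fmax)
    expT = np.exp(-T)
    for n in range(n_max - 1, -1, -1):
        out[..., n] = (2.0 * T * out[..., n + 1] + expT) / (2 * n + 1)
    return out


# ---------------------------------------------------------------------------
# Shell-pair data
# ---------------------------------------------------------------------------

class _ShellPair:
    """Precomputed Hermite expansion data for a pair of contracted shells."""

    __slots__ = ("sha", "shb", "p", "P", "cc", "E", "la", "lb")

    def __init__(self, sha: Shell, shb: Shell, extra_b: int = 0):
        self.sha, self.shb = sha, shb
        a = sha.exps[:, None]
        b = shb.exps[None, :]
        p = (a + b).ravel()
        A, B = sha.center, shb.center
        P = (a[..., None] * A + b[..., None] * B).reshape(-1, 3) / p[:, None]
        self.p, self.P = p, P
        self.cc = (sha.coefs[:, None] * shb.coefs[None, :]).ravel()
        self.la, self.lb = sha.l, shb.l + extra_b
        mu = (a * b / (a + b)).ravel()
        AB = A - B
        # E[axis][t, i, j, npp]
        self.E = [
            _hermite_E(self.la, self.lb, p, mu, A[ax] - B[ax], P[:, ax] - A[ax],
                       P[:, ax] - B[ax])
            for ax in range(3)
        ]


def _hermite_E(la: int, lb: int, p, mu, ABx, PAx, PBx):
    """1D Hermite coefficients E_t^{ij}, array (la+1, lb+1, la+lb+1, npp)."""
    npp = len(p)
    tmax = la + lb
    E = np.zeros((la + 1, lb + 1, tmax + 1, npp))
    E[0, 0, 0] = np.exp(-mu * ABx * ABx)
    inv2p = 0.5 / p
    for i in range(1, la + 1):
        for t in range(i + 1):
            val = PAx * E[i - 1, 0, t]
            if t > 0:
                val = val + inv2p * E[i - 1, 0, t - 1]
            if t + 1 <= i - 1:
                val = val + (t + 1) * E[i - 1, 0, t + 1]
            E[i, 0, t] = val
    for j in range(1, lb + 1):
        for i in range(la + 1):
            for t in range(i + j + 1):
                val = PBx * E[i, j - 1, t]
                if t > 0:
                    val = val + inv2p * E[i, j - 1, t - 1]
                if t + 1 <= i + j - 1:
                    val = val + (t + 1) * E[i, j - 1, t + 1]
                E[i, j, t] = val
    return E


_COMP_SCALE_CACHE: dict[tuple[int, int, int], float] = {}


def _comp_scale(comp: tuple[int, int, int]) -> float:
    """Norm ratio N(lx,ly,lz)/N(l,0,0); independent of the exponent."""
    if comp not in _COMP_SCALE_CACHE:
        lx, ly, lz = comp
        l = lx + ly + lz
        _COMP_SCALE_CACHE[comp] = np.sqrt(
            _double_factorial(2 * l - 1)
            / (_double_factorial(2 * lx - 1)
               * _double_factorial(2 * ly - 1)
               * _double_factorial(2 * lz - 1))
        )
    return _COMP_SCALE_CACHE[comp]


def _pair_E_tensor(sp: _ShellPair, la: int, lb: int, sign_ket: bool = False):
    """Stack E products for all Cartesian component pairs.

    Returns array (ncomp_a*ncomp_b, npp, tx+1, ty+1, tz+1) with contraction
    coefficients and component norm scales folded in; if ``sign_ket`` the
    (-1)^(t+u+v) Hermite ket phase is folded in as well.
    """
    comps_a = cartesian_components(la)
    comps_b = cartesian_components(lb)
    npp = len(sp.p)
    tx, ty, tz = la + lb, la + lb, la + lb
    out = np.zeros((len(comps_a) * len(comps_b), npp, tx + 1, ty + 1, tz + 1))
    for ia, ca in enumerate(comps_a):
        for ib, cb in enumerate(comps_b):
            scale = _comp_scale(ca) * _comp_scale(cb)
            ex = sp.E[0][ca[0], cb[0]]  # (tmax+1, npp)
            ey = sp.E[1][ca[1], cb[1]]
            ez = sp.E[2][ca[2], cb[2]]
            nx, nyv, nz = ca[0] + cb[0], ca[1] + cb[1], ca[2] + cb[2]
            block = np.einsum("tp,up,vp->ptuv", ex[: nx + 1], ey[: nyv + 1],
                              ez[: nz + 1], optimize=True)
            out[ia * len(comps_b) + ib, :, : nx + 1, : nyv + 1, : nz + 1] = scale * block
    out *= sp.cc[None, :, None, None, None]
    if sign_ket:
        t = np.arange(tx + 1)[:, None, None]
        u = np.arange(ty + 1)[None, :, None]
        v = np.arange(tz + 1)[None, None, :]
        out *= ((-1.0) ** (t + u + v))[None, None]
    return out


# ---------------------------------------------------------------------------
# Hermite Coulomb tensor
# ---------------------------------------------------------------------------

def _hermite_R(tmax: int, umax: int, vmax: int, rho, PQ, Fn):
    """R_tuv arrays of shape Fn.shape[:-1]; returns ndarray (t,u,v, ...)."""
    nmax = Fn.shape[-1] - 1
    memo: dict[tuple[int, int, int, int], np.ndarray] = {}

    def R(t, u, v, n):
        key = (t, u, v, n)
        if key in memo:
            return memo[key]
        if t == u == v == 0:
            val = ((-2.0 * rho) ** n) * Fn[..., n]
        elif t > 0:
            val = PQ[..., 0] * R(t - 1, u, v, n + 1)
            if t > 1:
                val = val + (t - 1) * R(t - 2, u, v, n + 1)
        elif u > 0:
            val = PQ[..., 1] * R(t, u - 1, v, n + 1)
            if u > 1:
                val = val + (u - 1) * R(t, u - 2, v, n + 1)
        else:
            val = PQ[..., 2] * R(t, u, v - 1, n + 1)
            if v > 1:
                val = val + (v - 1) * R(t, u, v - 2, n + 1)
        memo[key] = val
        return val

    out = np.empty((tmax + 1, umax + 1, vmax + 1) + Fn.shape[:-1])
    for t in range(tmax + 1):
        for u in range(umax + 1):
            for v in range(vmax + 1):
                if t + u + v <= nmax:
                    out[t, u, v] = R(t, u, v, 0)
                else:
                    out[t, u, v] = 0.0
    return out


def _kernel_boys(nmax, T, rho, kernel):
    """Boys table for the requested two-electron kernel."""
    if kernel == "coulomb":
        return boys(nmax, T)
    kind, omega = kernel
    theta = omega**2 / (rho + omega**2)
    lr = boys(nmax, theta * T)
    lr = lr * theta[..., None] ** (np.arange(nmax + 1) + 0.5)
    if kind == "erf":
        return lr
    if kind == "erfc":
        return boys(nmax, T) - lr
    raise ValueError(f"unknown kernel {kernel!r}")


# ---------------------------------------------------------------------------
# Public integral drivers
# ---------------------------------------------------------------------------

def contracted_overlap_self(shell: Shell) -> float:
    """Self-overlap of the (l,0,0) component of a contracted shell."""
    a = shell.exps[:, None]
    b = shell.exps[None, :]
    p = a + b
    l = shell.l
    s1d = _double_factorial(2 * l - 1) / (2.0 * p) ** l
    val = shell.coefs[:, None] * shell.coefs[None, :] * (np.pi / p) ** 1.5 * s1d
    return float(val.sum())


def _overlap_block(sp: _ShellPair):
    la, lb = sp.sha.l, sp.shb.l
    comps_a = cartesian_components(la)
    comps_b = cartesian_components(lb)
    out = np.empty((len(comps_a), len(comps_b)))
    pref = (np.pi / sp.p) ** 1.5 * sp.cc
    for ia, ca in enumerate(comps_a):
        for ib, cb in enumerate(comps_b):
            val = (sp.E[0][ca[0], cb[0], 0] * sp.E[1][ca[1], cb[1], 0]
                   * sp.E[2][ca[2], cb[2], 0] * pref)
            out[ia, ib] = val.sum() * _comp_scale(ca) * _comp_scale(cb)
    return out


def overlap(basis: BasisSet) -> np.ndarray:
    n = basis.nbf
    S = np.zeros((n, n))
    sl = basis.shell_slices()
    for i, shi in enumerate(basis.shells):
        for j in range(i + 1):
            sp = _ShellPair(shi, basis.shells[j])
            blk = _overlap_block(sp)
            S[sl[i][0]: sl[i][1], sl[j][0]: sl[j][1]] = blk
            S[sl[j][0]: sl[j][1], sl[i][0]: sl[i][1]] = blk.T
    return S


def kinetic(basis: BasisSet) -> np.ndarray:
    n = basis.nbf
    T = np.zeros((n, n))
    sl = basis.shell_slices()
    for i, shi in enumerate(basis.shells):
        for j in range(i + 1):
            shj = basis.shells[j]
            sp = _ShellPair(shi, shj, extra_b=2)
            b = np.repeat(shj.exps[None, :], len(shi.exps), 0).ravel()
            pref = (np.pi / sp.p) ** 0.5
            comps_a = cartesian_components(shi.l)
            comps_b = cartesian_components(shj.l)
            blk = np.empty((len(comps_a), len(comps_b)))

            def s1d(ax, ii, jj):
                if jj < 0:
                    return 0.0
                return sp.E[ax][ii, jj, 0] * pref

            for ia, ca in enumerate(comps_a):
                for ib, cb in enumerate(comps_b):
                    term = 0.0
                    for ax in range(3):
                        ii, jj = ca[ax], cb[ax]
                        k1d = (-2.0 * b**2 * s1d(ax, ii, jj + 2)
                               + b * (2 * jj + 1) * s1d(ax, ii, jj)
                               - 0.5 * jj * (jj - 1) * s1d(ax, ii, jj - 2))
                        o1, o2 = [a for a in range(3) if a != ax]
                        term = term + k1d * s1d(o1, ca[o1], cb[o1]) * s1d(o2, ca[o2], cb[o2])
                    blk[ia, ib] = (term * sp.cc).sum() * _comp_scale(ca) * _comp_scale(cb)
            T[sl[i][0]: sl[i][1], sl[j][0]: sl[j][1]] = blk
            T[sl[j][0]: sl[j][1], sl[i][0]: sl[i][1]] = blk.T
    return T


def nuclear_attraction(basis: BasisSet, charges, centers) -> np.ndarray:
    """Electron-nucleus attraction matrix (negative-definite-ish)."""
    n = basis.nbf
    V = np.zeros((n, n))
    sl = basis.shell_slices()
    centers = np.asarray(centers, float)
    charges = np.asarray(charges, float)
    for i, shi in enumerate(basis.shells):
        for j in range(i + 1):
            shj = basis.shells[j]
            sp = _ShellPair(shi, shj)
            la, lb = shi.l, shj.l
            tmax = la + lb
            Eb = _pair_E_tensor(sp, la, lb)  # (nAB, npp, t,u,v)
            blk = 0.0
            for Z, C in zip(charges, centers):
                PC = sp.P - C[None, :]
                Tval = sp.p * np.einsum("pi,pi->p", PC, PC)
                Fn = boys(tmax, Tval)
                Rt = _hermite_R(tmax, tmax, tmax, sp.p, PC, Fn)  # (t,u,v,npp)
                pref = -Z * 2.0 * np.pi / sp.p
                blk = blk + np.einsum("aptuv,tuvp,p->a", Eb, Rt, pref,
                                      optimize=True)
            blk = blk.reshape(shi.ncomp, shj.ncomp)
            V[sl[i][0]: sl[i][1], sl[j][0]: sl[j][1]] = blk
            V[sl[j][0]: sl[j][1], sl[i][0]: sl[i][1]] = blk.T
    return V


def _eri_shellquartet(spb: _ShellPair, spk: _ShellPair, kernel="coulomb"):
    """(ab|cd) block for one shell quartet; returns (nA, nB) component array."""
    la, lb = spb.sha.l, spb.shb.l
    lc, ld = spk.sha.l, spk.shb.l
    t1 = la + lb
    t2 = lc + ld
    tt = t1 + t2
    p = spb.p[:, None]
    q = spk.p[None, :]
    rho = p * q / (p + q)
    PQ = spb.P[:, None, :] - spk.P[None, :, :]
    T = rho * np.einsum("pqi,pqi->pq", PQ, PQ)
    Fn = _kernel_boys(tt, T, rho, kernel)
    pref = 2.0 * np.pi**2.5 / (p * q * np.sqrt(p + q))
    Fn = Fn * pref[..., None]
    Rt = _hermite_R(tt, tt, tt, rho, PQ, Fn)  # (T,U,V,npb,npk)
    Eb = _pair_E_tensor(spb, la, lb)                      # (nA, npb, t,u,v)
    Ek = _pair_E_tensor(spk, lc, ld, sign_ket=True)       # (nB, npk, τ,ν,φ)
    nA, npb = Eb.shape[0], Eb.shape[1]
    nB = Ek.shape[0]
    tmp = np.zeros((nB, npb, t1 + 1, t1 + 1, t1 + 1))
    for tau in range(t2 + 1):
        for nu in range(t2 + 1 - tau):
            for ph in range(t2 + 1 - tau - nu):
                Ekv = Ek[:, :, tau, nu, ph]
                if not Ekv.any():
                    continue
                Rslice = Rt[tau: tau + t1 + 1, nu: nu + t1 + 1,
                            ph: ph + t1 + 1]  # (t,u,v,npb,npk)
                tmp += np.einsum("bk,tuvpk->bptuv", Ekv, Rslice, optimize=True)
    return np.einsum("aptuv,bptuv->ab", Eb, tmp, optimize=True)


def eri_dense(basis: BasisSet, kernel="coulomb") -> np.ndarray:
    """Full (μν|λσ) tensor with 8-fold permutational symmetry."""
    n = basis.nbf
    I = np.zeros((n, n, n, n))
    sl = basis.shell_slices()
    shells = basis.shells
    pairs = [(i, j) for i in range(len(shells)) for j in range(i + 1)]
    sps = {ij: _ShellPair(shells[ij[0]], shells[ij[1]]) for ij in pairs}
    for a, ij in enumerate(pairs):
        i, j = ij
        for kl in pairs[: a + 1]:
            k, l = kl
            blk = _eri_shellquartet(sps[ij], sps[kl], kernel)
            ni, nj = shells[i].ncomp, shells[j].ncomp
            nk, nl = shells[k].ncomp, shells[l].ncomp
            blk = blk.reshape(ni, nj, nk, nl)
            si, sj = slice(*sl[i]), slice(*sl[j])
            sk, slc = slice(*sl[k]), slice(*sl[l])
            I[si, sj, sk, slc] = blk
            I[sj, si, sk, slc] = blk.transpose(1, 0, 2, 3)
            I[si, sj, slc, sk] = blk.transpose(0, 1, 3, 2)
            I[sj, si, slc, sk] = blk.transpose(1, 0, 3, 2)
            I[sk, slc, si, sj] = blk.transpose(2, 3, 0, 1)
            I[slc, sk, si, sj] = blk.transpose(3, 2, 0, 1)
            I[sk, slc, sj, si] = blk.transpose(2, 3, 1, 0)
            I[slc, sk, sj, si] = blk.transpose(3, 2, 1, 0)
    return I


def _dummy_shell(center) -> Shell:
    return Shell(center=np.asarray(center, float), l=0,
                 exps=np.array([0.0]), coefs=np.array([1.0]))


def eri_3c(basis: BasisSet, aux: BasisSet, kernel="coulomb") -> np.ndarray:
    """(α|μν) three-center integrals, shape (naux, n, n)."""
    n, na = basis.nbf, aux.nbf
    out = np.zeros((na, n, n))
    sl = basis.shell_slices()
    asl = aux.shell_slices()
    pair_list = [(i, j) for i in range(len(basis.shells)) for j in range(i + 1)]
    sps = {ij: _ShellPair(basis.shells[ij[0]], basis.shells[ij[1]])
           for ij in pair_list}
    for ia, sha in enumerate(aux.shells):
        spa = _ShellPair(sha, _dummy_shell(sha.center))
        for ij in pair_list:
            i, j = ij
            blk = _eri_shellquartet(spa, sps[ij], kernel)
            blk = blk.reshape(sha.ncomp, basis.shells[i].ncomp,
                              basis.shells[j].ncomp)
            out[asl[ia][0]: asl[ia][1], sl[i][0]: sl[i][1], sl[j][0]: sl[j][1]] = blk
            out[asl[ia][0]: asl[ia][1], sl[j][0]: sl[j][1], sl[i][0]: sl[i][1]] = (
                blk.transpose(0, 2, 1))
    return out


def eri_2c(aux: BasisSet, kernel="coulomb") -> np.ndarray:
    """(α|β) two-center integrals of the requested kernel."""
    na = aux.nbf
    out = np.zeros((na, na))
    asl = aux.shell_slices()
    sps = [_ShellPair(sh, _dummy_shell(sh.center)) for sh in aux.shells]
    for i in range(len(aux.shells)):
        for j in range(i + 1):
            blk = _eri_shellquartet(sps[i], sps[j], kernel)
            blk = blk.reshape(aux.shells[i].ncomp, aux.shells[j].ncomp)
            out[asl[i][0]: asl[i][1], asl[j][0]: asl[j][1]] = blk
            out[asl[j][0]: asl[j][1], asl[i][0]: asl[i][1]] = blk.T
    return out


def eval_basis(basis: BasisSet, points) -> np.ndarray:
    """Basis-function values χ_μ(r_p); shape (nbf, npoints)."""
    pts = np.atleast_2d(np.asarray(points, float))
    out = np.empty((basis.nbf, len(pts)))
    row = 0
    for sh in basis.shells:
        d = pts - sh.center[None, :]
        r2 = np.einsum("pi,pi->p", d, d)
        with np.errstate(under="ignore"):
            rad = (sh.coefs[:, None] * np.exp(-sh.exps[:, None] * r2[None, :]))
        for comp in cartesian_components(sh.l):
            ang = (d[:, 0] ** comp[0]) * (d[:, 1] ** comp[1]) * (d[:, 2] ** comp[2])
            out[row] = _comp_scale(comp) * (rad.sum(0) * ang)
            row += 1
    return out
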