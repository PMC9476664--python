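"""MP2 contraction engine: Laplace energies, dense R-matrix oracles, and the
tensor-hypercontracted Coulomb-/exchange-like R algorithms.

Conventions.  With weighted pseudodensities P̲, P̅ (quadrature weight split
ω^{1/4} per factor) the Laplace AO-MP2 energy per quadrature point is

    e_κ = -[J_αβ + ½ J_αα + ½ J_ββ] + ½ [K_α + K_β]

where J_{ηη'} contracts two ERIs with (P̲η, P̅η, P̲η', P̅η') in the "direct"
index pattern and K_η is the same-spin crossed (exchange) pattern.  The R
intermediates are the exact matrix derivatives of e_κ with respect to the
pseudodensities,

    R̲η = ∂e_κ/∂P̲η ,   R̅η = ∂e_κ/∂P̅η ,

which makes Σ_η [Tr(R̲η P̲η) + Tr(R̅η P̅η)] = 4 e_κ (each term is linear in
each of its four pseudodensity factors).  The Coulomb-like part collects the
J-derivatives, the exchange-like part the K-derivatives.

In THC form with grid pseudodensities A = X̲ᵀX̲, B = X̅ᵀX̅ the Coulomb part is
a Schur product against the precontraction D = Z (A∘B) Z, and the exchange
part is accumulated over the common occupied pseudo-MO index j with a single
Z-containing intermediate E_j = Z diag(X̲_j) B shared between R̲ˣ and R̅ˣ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blocking import NBConfig, SignificanceList, build_list, compose_lists
from .engine import SCFContext, ao_eri_dense
from .laplace import (LaplaceQuadrature, PseudoDensityPair, build_pseudodensities,
                      cholesky_pseudo_mos)

_SPINS = (0, 1)


# ---------------------------------------------------------------------------
# canonical MO-MP2 oracle (independent code path, no Laplace machinery)
# ---------------------------------------------------------------------------

def mp2_energy_canonical(scf: SCFContext, return_weight: bool = False):
    """Canonical unrestricted MO-MP2 correlation energy.

    With ``return_weight`` also returns Σ |numerator|/Δ, the quantity that
    bounds the Laplace quadrature error propagation.
    """
    I = ao_eri_dense(scf)
    e_corr, weight = 0.0, 0.0
    ovov = {}
    for s in _SPINS:
        Co, Cv = scf.C_occ(s), scf.C_virt(s)
        for sp in _SPINS:
            if (s, sp) in ovov or (sp, s) in ovov:
                continue
            Co2, Cv2 = scf.C_occ(sp), scf.C_virt(sp)
            ovov[(s, sp)] = np.einsum("mnls,mi,na,lj,sb->iajb", I, Co, Cv,
                                      Co2, Cv2, optimize=True)

    def get(s, sp):
        if (s, sp) in ovov:
            return ovov[(s, sp)]
        return ovov[(sp, s)].transpose(2, 3, 0, 1)

    for s in _SPINS:
        for sp in _SPINS:
            T = get(s, sp)
            no1, nv1, no2, nv2 = T.shape
            if 0 in T.shape:
                continue
            eo1 = scf.eps[s][: scf.n_occ[s]]
            ev1 = scf.eps[s][scf.n_occ[s]:]
            eo2 = scf.eps[sp][: scf.n_occ[sp]]
            ev2 = scf.eps[sp][scf.n_occ[sp]:]
            denom = (ev1[None, :, None, None] + ev2[None, None, None, :]
                     - eo1[:, None, None, None] - eo2[None, None, :, None])
            if s == sp:
                num = 0.5 * (T**2 - T * T.transpose(0, 3, 2, 1))
            else:
                num = 0.5 * T**2  # α,β and β,α each counted once in the loop
            e_corr -= float(np.sum(num / denom))
            weight += float(np.sum(np.abs(num) / denom))
    if return_weight:
        return e_corr, weight
    return e_corr


# ---------------------------------------------------------------------------
# dense Laplace machinery
# ---------------------------------------------------------------------------

def _channel_J(I, Pu1, Pv1, Pu2, Pv2):
    return float(np.einsum("mnls,MNLS,mM,nN,lL,sS->", I, I, Pu1, Pv1,
                           Pu2, Pv2, optimize=True))


def _channel_K(I, Pu, Pv):
    return float(np.einsum("mnls,MNLS,mM,lL,nS,sN->", I, I, Pu, Pu,
                           Pv, Pv, optimize=True))


def laplace_point_energy(I, pair: PseudoDensityPair) -> float:
    """e_κ from weighted pseudodensities and the dense ERI tensor."""
    Pu, Pv = pair.P_occ, pair.P_virt
    J_ab = _channel_J(I, Pu[0], Pv[0], Pu[1], Pv[1])
    J_aa = _channel_J(I, Pu[0], Pv[0], Pu[0], Pv[0])
    J_bb = _channel_J(I, Pu[1], Pv[1], Pu[1], Pv[1])
    K_a = _channel_K(I, Pu[0], Pv[0])
    K_b = _channel_K(I, Pu[1], Pv[1])
    return -(J_ab + 0.5 * J_aa + 0.5 * J_bb) + 0.5 * (K_a + K_b)


def mp2_energy_laplace_dense(scf: SCFContext, quad: LaplaceQuadrature,
                             shift: float | None = None) -> float:
    """Dense Laplace AO-MP2 correlation energy (Eq-1-style oracle)."""
    I = ao_eri_dense(scf)
    e = 0.0
    for k in range(quad.n_points):
        pair = build_pseudodensities(scf, quad, k, shift=shift)
        e += laplace_point_energy(I, pair)
    return e


@dataclass
class RMatrixPair:
    """Per-Laplace-point R intermediates, R = ∂e_κ/∂(pseudodensity)."""

    kappa: int
    R_occ: tuple[np.ndarray, np.ndarray]    # R̲ per spin
    R_virt: tuple[np.ndarray, np.ndarray]   # R̅ per spin
    provenance: dict = field(default_factory=dict)


def r_dense_oracle(scf: SCFContext, quad: LaplaceQuadrature, kappa: int,
                   shift: float | None = None, parts: str = "both",
                   pair: PseudoDensityPair | None = None) -> RMatrixPair:
    """Literal dense contraction of the R intermediates.

    ``parts`` selects "coulomb" (J-derivatives), "exchange" (K-derivatives)
    or "both"; the two parts sum exactly to the total by construction.
    """
    I = ao_eri_dense(scf)
    if pair is None:
        pair = build_pseudodensities(scf, quad, kappa, shift=shift)
    Pu, Pv = pair.P_occ, pair.P_virt
    n = scf.nbf
    Ro = [np.zeros((n, n)), np.zeros((n, n))]
    Rv = [np.zeros((n, n)), np.zeros((n, n))]
    want_c = parts in ("both", "coulomb")
    want_x = parts in ("both", "exchange")
    for s in _SPINS:
        o = 1 - s
        if want_c:
            # -J_{s,o} term (counted once) and -1/2 J_{ss} (two occurrences)
            Rv[s] -= np.einsum("mnls,MNLS,mM,lL,sS->nN", I, I, Pu[s],
                               Pu[o], Pv[o], optimize=True)
            Rv[s] -= np.einsum("mnls,MNLS,mM,lL,sS->nN", I, I, Pu[s],
                               Pu[s], Pv[s], optimize=True)
            Ro[s] -= np.einsum("mnls,MNLS,nN,lL,sS->mM", I, I, Pv[s],
                               Pu[o], Pv[o], optimize=True)
            Ro[s] -= np.einsum("mnls,MNLS,nN,lL,sS->mM", I, I, Pv[s],
                               Pu[s], Pv[s], optimize=True)
        if want_x:
            # +1/2 K_s; each pseudodensity appears twice -> symmetrized term
            tv = np.einsum("mnls,MNLS,mM,lL,sN->nS", I, I, Pu[s], Pu[s],
                           Pv[s], optimize=True)
            Rv[s] += 0.5 * (tv + tv.T)
            to = np.einsum("mnls,MNLS,nS,lL,sN->mM", I, I, Pv[s], Pu[s],
                           Pv[s], optimize=True)
            Ro[s] += 0.5 * (to + to.T)
    return RMatrixPair(kappa=kappa, R_occ=(Ro[0], Ro[1]), R_virt=(Rv[0], Rv[1]),
                       provenance={"path": "dense", "parts": parts})


def r_ri_oracle(scf: SCFContext, ri_B: np.ndarray, quad: LaplaceQuadrature,
                kappa: int, shift: float | None = None) -> RMatrixPair:
    """Second oracle: same contractions with RI-factorized ERIs."""
    I = np.einsum("tmn,tls->mnls", ri_B, ri_B, optimize=True)
    pair = build_pseudodensities(scf, quad, kappa, shift=shift)
    saved = scf._eri
    scf._eri = I
    try:
        out = r_dense_oracle(scf, quad, kappa, shift=shift, pair=pair)
    finally:
        scf._eri = saved
    out.provenance["path"] = "ri-cdd"
    return out


# ---------------------------------------------------------------------------
# grid-basis (THC) machinery
# ---------------------------------------------------------------------------

@dataclass
class GridPseudoDensities:
    kappa: int
    A: tuple[np.ndarray, np.ndarray]   # occupied, per spin (N_grid × N_grid)
    B: tuple[np.ndarray, np.ndarray]   # virtual


def grid_pseudodensities(X_occ, X_virt, kappa: int) -> GridPseudoDensities:
    """A = X̲ᵀX̲ and B = X̅ᵀX̅ per spin (pseudodensities in the grid basis)."""
    A = tuple(X_occ[s].T @ X_occ[s] for s in _SPINS)
    B = tuple(X_virt[s].T @ X_virt[s] for s in _SPINS)
    return GridPseudoDensities(kappa=kappa, A=A, B=B)


def coulomb_precontraction(A: np.ndarray, B: np.ndarray,
                           Lam: np.ndarray) -> np.ndarray:
    """D = Z (A∘B) Z evaluated through the Λ factor (Z = ΛΛᵀ)."""
    AB = A * B
    inner = Lam.T @ AB @ Lam
    return Lam @ inner @ Lam.T


def coulomb_R(D_same: np.ndarray, D_other: np.ndarray, X: np.ndarray,
              A: np.ndarray, B: np.ndarray):
    """Coulomb-like R parts: Schur product plus two dense multiplies.

    Returns (R̲ᶜ, R̅ᶜ) for the spin whose grid pseudodensities are (A, B);
    the roles of A and B interchange between the two outputs.
    """
    Dsum = D_same + D_other
    Rv = -(X @ (A * Dsum) @ X.T)
    Ro = -(X @ (B * Dsum) @ X.T)
    return Ro, Rv


def exchange_R(X_occ_s: np.ndarray, X_virt_s: np.ndarray, Z: np.ndarray,
               X: np.ndarray, nb: NBConfig | None = None,
               lists: dict | None = None):
    """Exchange-like R parts for one spin (joint accumulation over j).

    The Z-containing intermediate E_j = Z diag(X̲_j) B is computed once per
    occupied pseudo-MO j and shared between the R̲ˣ and R̅ˣ precursors

        G_A += E_j ∘ E_jᵀ            (→ R̲ˣ = ½ · 2 · X G_A Xᵀ)
        G_B += diag(X̲_j) Z (A ∘ E_jᵀ) (→ R̅ˣ)

    With ``nb`` given, the grid indices are restricted to the significance
    lists; ``nb=None`` runs the same loop with full index lists.
    """
    ng = Z.shape[0]
    r_occ = X_occ_s.shape[0]
    B = X_virt_s.T @ X_virt_s
    A = X_occ_s.T @ X_occ_s
    if lists is None:
        lists = exchange_lists(X_occ_s, X_virt_s, nb, ng)
    Pj_lists, Rj_lists = lists["Pj"], lists["Rj"]
    G_A = np.zeros((ng, ng))
    G_B = np.zeros((ng, ng))
    for j in range(r_occ):
        Pj = Pj_lists[j]       # occupied-collocation support of j
        Rj = Rj_lists[j]       # virtual-supported grid points (B-protected)
        if len(Pj) == 0 or len(Rj) == 0:
            continue
        v = X_occ_s[j, Pj]
        # E_j rows stay full: that index is an open output index with no
        # exponential protection; the B column index is restricted to Rj
        Ej = (Z[:, Pj] * v[None, :]) @ B[np.ix_(Pj, Rj)]    # ng × |Rj|
        EjV = Ej[Rj, :]                                      # |Rj| × |Rj|
        G_A[np.ix_(Rj, Rj)] += EjV * EjV.T
        Mj = A[Rj, :] * Ej.T                                 # |Rj| × ng
        Fj = Z[np.ix_(Pj, Rj)] @ Mj                          # |Pj| × ng
        G_B[Pj, :] += v[:, None] * Fj
    R_occ_x = X @ G_A @ X.T
    G_Bs = 0.5 * (G_B + G_B.T)
    R_virt_x = X @ G_Bs @ X.T
    return R_occ_x, R_virt_x


def exchange_lists(X_occ_s, X_virt_s, nb: NBConfig | None, ng: int) -> dict:
    """Significance lists driving the screened exchange contraction.

    {P_j} from the occupied collocation magnitudes; {R_j} composed from the
    grid–virtual list {b_R} and the virtual–occupied list {b_j}.
    """
    r_occ = X_occ_s.shape[0]
    if nb is None:
        full = [np.arange(ng)] * r_occ
        return {"Pj": full, "Rj": full, "n_pairs": {}}
    from .blocking import grid_orbital_screen, orbital_orbital_screen, transpose_list

    L_Pj = build_list(grid_orbital_screen(X_occ_s), nb.eps_Sj)     # j -> {P}
    L_bR = build_list(grid_orbital_screen(X_virt_s).T, nb.eps_bR)  # R -> {b}
    L_bj = build_list(orbital_orbital_screen(X_occ_s, X_virt_s),
                      nb.eps_bj)                                   # j -> {b}
    # {R_j}: R significant for j iff some virtual b is shared (indirect
    # exponential coupling through the virtual index)
    L_Rj = compose_lists(transpose_list(L_bR), L_bj)               # j -> {R}
    Pj = [np.asarray(L_Pj.members(j), int) for j in range(r_occ)]
    Rj = [np.asarray(L_Rj.members(j), int) for j in range(r_occ)]
    return {"Pj": Pj, "Rj": Rj,
            "n_pairs": {"Sj": L_Pj.n_pairs, "bR": L_bR.n_pairs,
                        "bj": L_bj.n_pairs, "Rj": L_Rj.n_pairs}}


def build_R(scf: SCFContext, thc, quad: LaplaceQuadrature,
            nb: NBConfig | None = None, shift: float | None = None,
            cdd_threshold: float = 1e-10) -> list[RMatrixPair]:
    """Per-Laplace-point R matrices from the THC factorization (Algorithm-4
    style driver: precontraction, Coulomb parts, exchange parts)."""
    out = []
    X = thc.X
    Z = thc.Z
    Lam = thc.Lam
    for k in range(quad.n_points):
        pair = build_pseudodensities(scf, quad, k, shift=shift)
        cdd = cholesky_pseudo_mos(pair, cdd_threshold)
        Xo = tuple((cdd.L_occ[s].T @ X) for s in _SPINS)
        Xv = tuple((cdd.L_virt[s].T @ X) for s in _SPINS)
        gp = grid_pseudodensities(Xo, Xv, k)
        D = [coulomb_precontraction(gp.A[s], gp.B[s], Lam) for s in _SPINS]
        Ro = [None, None]
        Rv = [None, None]
        diag = {}
        for s in _SPINS:
            o = 1 - s
            ro_c, rv_c = coulomb_R(D[s], D[o], X, gp.A[s], gp.B[s])
            lists = exchange_lists(Xo[s], Xv[s], nb, Z.shape[0])
            ro_x, rv_x = exchange_R(Xo[s], Xv[s], Z, X, nb, lists=lists)
            Ro[s] = ro_c + ro_x
            Rv[s] = rv_c + rv_x
            diag[f"n_pairs_spin{s}"] = lists["n_pairs"]
        out.append(RMatrixPair(kappa=k, R_occ=(Ro[0], Ro[1]),
                               R_virt=(Rv[0], Rv[1]),
                               provenance={"path": "thc", "nb": nb, **diag}))
    return out


# ---------------------------------------------------------------------------
# THC energies / exchange energy with natural blocking
# ---------------------------------------------------------------------------

def thc_point_energy(gp: GridPseudoDensities, Z: np.ndarray) -> float:
    """e_κ in THC form (Coulomb channels via traces, exchange via loop)."""
    A, B = gp.A, gp.B
    AB = [A[s] * B[s] for s in _SPINS]
    J_ab = float(np.sum(AB[0] * (Z @ AB[1] @ Z)))
    J_aa = float(np.sum(AB[0] * (Z @ AB[0] @ Z)))
    J_bb = float(np.sum(AB[1] * (Z @ AB[1] @ Z)))
    K = [exchange_energy_dense_grid(A[s], B[s], Z) for s in _SPINS]
    return -(J_ab + 0.5 * J_aa + 0.5 * J_bb) + 0.5 * (K[0] + K[1])


def exchange_energy_dense_grid(A, B, Z) -> float:
    """Brute-force exchange-like contraction Σ Z Z A B A B (grid indices)."""
    return float(np.einsum("PQ,pq,Pp,Pq,Qq,Qp->", Z, Z, A, B, A, B,
                           optimize=True))


def exchange_energy_nb(X_occ_s, X_virt_s, Z, nb: NBConfig | None = None) -> float:
    """Exchange-like energy term, batched over occupied pairs with NB lists.

    K = Σ_{ij} Tr[(diag(X̲_i) E_j)²],  E_j = Z diag(X̲_j) B.
    """
    r_occ, ng = X_occ_s.shape
    B = X_virt_s.T @ X_virt_s
    lists = exchange_lists(X_occ_s, X_virt_s, nb, ng)
    Pj, Rj = lists["Pj"], lists["Rj"]
    if nb is None:
        pair_ok = [np.arange(r_occ)] * r_occ
    else:
        from .blocking import orbital_orbital_screen, transpose_list
        L_aj = build_list(orbital_orbital_screen(X_occ_s, X_virt_s), nb.eps_bj)
        L_ij = compose_lists(transpose_list(L_aj), L_aj)
        pair_ok = [np.asarray(L_ij.members(j), int) for j in range(r_occ)]
    total = 0.0
    for j in range(r_occ):
        if len(Pj[j]) == 0 or len(Rj[j]) == 0:
            continue
        v = X_occ_s[j, Pj[j]]
        Ej = (Z[np.ix_(Rj[j], Pj[j])] * v[None, :]) @ B[np.ix_(Pj[j], Rj[j])]
        Xi = X_occ_s[np.asarray(pair_ok[j], int)][:, Rj[j]]
        # Σ_i Tr[(diag(X̲_i) E_j)²] = Σ_PQ (E_j ∘ E_jᵀ)_PQ (X_iᵀX_i)_PQ
        total += float(np.sum((Ej * Ej.T) * (Xi.T @ Xi)))
    return total


def mp2_energy_thc(scf: SCFContext, thc, quad: LaplaceQuadrature,
                   shift: float | None = None,
                   cdd_threshold: float = 1e-10) -> float:
    """THC-MP2 correlation energy summed over Laplace points."""
    e = 0.0
    for k in range(quad.n_points):
        pair = build_pseudodensities(scf, quad, k, shift=shift)
        cdd = cholesky_pseudo_mos(pair, cdd_threshold)
        Xo = tuple((cdd.L_occ[s].T @ thc.X) for s in _SPINS)
        Xv = tuple((cdd.L_virt[s].T @ thc.X) for s in _SPINS)
        e += thc_point_energy(grid_pseudodensities(Xo, Xv, k), thc.Z)
    return e
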