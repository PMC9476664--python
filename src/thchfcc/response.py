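"""Downstream of the R intermediates: density-derivative bookkeeping,
Y objects, Fock-like builds, Z-vector CPSCF, relaxed density and the final
hyperfine trace.

Derivation sketch.  For a perturbation ξ′ that leaves the basis functions
(and hence S) untouched, the Laplace AO-MP2 energy depends on ξ′ only
through the pseudodensities, which are matrix functions of (P_occ, F):

    P̲(κ) = ω^{1/4} e^{τ P_occ F̃} P_occ ,   P̅(κ) = ω^{1/4} e^{-τ P_virt F̃} P_virt

(F̃ = F - μS with the fixed mid-gap shift; P_virt = S⁻¹ - P_occ).  Writing
R = ∂e_κ/∂(pseudodensity) and using the Fréchet derivative of the matrix
exponential, every trace collapses onto two effective AO matrices per spin,

    E_F = Σ_κ ω^{1/4} τ (Y̲ P_occ - Y̅ P_virt)
    E_P = Σ_κ ω^{1/4} [ τ F̃ (Y̲ + Y̅) + R̲ e^{τ P_occ F̃} - R̅ e^{-τ P_virt F̃} ]

with Y̲ = Φ_{τ P_occ F̃}[P_occ R̲], Y̅ = Φ_{-τ P_virt F̃}[P_virt R̅] and
Φ_A[B] = ∫₀¹ e^{sA} B e^{(1-s)A} ds, so that

    dE₂/dξ′ = Σ_η Tr(E_F^η dF_η) + Tr(E_P^η dP_η).

dF = dh + G[dP] moves the two-electron part onto a Fock-like build of E_F;
the remaining Tr(Λ dP) term is closed with one Z-vector CPSCF solve.  The
relaxed density D_η = sym(E_F^η) + D_z^η then gives the MP2 part of the
derivative as Tr(h^ξ′_η D_η); the SCF part is the plain spin density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import FC_PREFACTOR_MHZ, nuclear_g_factor
from .contractions import RMatrixPair
from .engine import SCFContext, fermi_contact_integrals, fock_like_build
from .laplace import LaplaceQuadrature, level_shift

_SPINS = (0, 1)


# ---------------------------------------------------------------------------
# Y objects: Fréchet derivative of the matrix exponential
# ---------------------------------------------------------------------------

@dataclass
class YSolution:
    Y: np.ndarray
    expA: np.ndarray
    iterations: int
    residual: float


def solve_Y(A: np.ndarray, B: np.ndarray) -> YSolution:
    """Y = Φ_A[B] = ∫₀¹ e^{sA} B e^{(1-s)A} ds by recursion.

    Scaled Taylor series for the block pair (e^{A/2^s}, Φ_{A/2^s}[B])
    followed by s doubling steps Y ← e^A Y + Y e^A, E ← E².  The returned
    residual checks the defining relations  A Y - Y A = e^A B - B e^A  and
    Tr Y = Tr(B e^A)  of the substituted solution.
    """
    n = A.shape[0]
    if n == 0:
        return YSolution(Y=A.copy(), expA=A.copy(), iterations=0, residual=0.0)
    norm = np.linalg.norm(A, 1)
    s = max(0, int(np.ceil(np.log2(max(norm, 1e-300) / 0.25))))
    As = A / (2.0**s)
    Bs = B / (2.0**s)      # the doubling step scales A and B jointly
    E = np.eye(n) + As
    Y = Bs.copy()
    T = As.copy()          # As^k / k!
    U = Bs.copy()          # X_k / k!  (X_k = Σ As^i Bs As^{k-1-i})
    it = 1
    for k in range(2, 60):
        U = (U @ As + T @ Bs) / k
        T = T @ As / k
        E += T
        Y += U
        it += 1
        if np.abs(T).max() < 1e-18 and np.abs(U).max() < 1e-18:
            break
    for _ in range(s):
        Y = E @ Y + Y @ E
        E = E @ E
        it += 1
    res1 = np.abs(A @ Y - Y @ A - (E @ B - B @ E)).max()
    res2 = abs(np.trace(Y) - np.trace(B @ E))
    scale = max(1.0, np.abs(Y).max())
    return YSolution(Y=Y, expA=E, iterations=it,
                     residual=float(max(res1, res2) / scale))


# ---------------------------------------------------------------------------
# gradient intermediates
# ---------------------------------------------------------------------------

@dataclass
class ResponseIntermediates:
    E_F: tuple[np.ndarray, np.ndarray]   # coefficient of dF per spin
    E_P: tuple[np.ndarray, np.ndarray]   # coefficient of dP_occ per spin
    max_y_residual: float
    shift: float


def response_intermediates(scf: SCFContext, quad: LaplaceQuadrature,
                           rpairs: list[RMatrixPair],
                           shift: float | None = None) -> ResponseIntermediates:
    """Accumulate E_F and E_P over Laplace points from the R intermediates."""
    mu = level_shift(scf) if shift is None else shift
    n = scf.nbf
    E_F = [np.zeros((n, n)), np.zeros((n, n))]
    E_P = [np.zeros((n, n)), np.zeros((n, n))]
    max_res = 0.0
    for rp in rpairs:
        k = rp.kappa
        t = quad.exponents[k]
        w4 = quad.weights[k] ** 0.25
        for sp in _SPINS:
            Ft = scf.F[sp] - mu * scf.S
            Po = scf.P_occ(sp)
            Pv = scf.P_virt(sp)
            sol_o = solve_Y(t * (Po @ Ft), Po @ rp.R_occ[sp])
            sol_v = solve_Y(-t * (Pv @ Ft), Pv @ rp.R_virt[sp])
            max_res = max(max_res, sol_o.residual, sol_v.residual)
            Yo, Yv = sol_o.Y, sol_v.Y
            E_F[sp] += w4 * t * (Yo @ Po - Yv @ Pv)
            E_P[sp] += w4 * (t * Ft @ (Yo + Yv)
                             + rp.R_occ[sp] @ sol_o.expA
                             - rp.R_virt[sp] @ sol_v.expA)
    return ResponseIntermediates(E_F=(E_F[0], E_F[1]), E_P=(E_P[0], E_P[1]),
                                 max_y_residual=max_res, shift=mu)


def build_fock_like(scf: SCFContext, D_alpha: np.ndarray, D_beta: np.ndarray):
    """Coulomb+exchange build with density stand-ins (unrestricted)."""
    return fock_like_build(scf, D_alpha, D_beta)


def assemble_rhs(scf: SCFContext, interm: ResponseIntermediates):
    """Z-vector right-hand side Λ_η = sym(E_P^η) + 𝔉_η[sym(E_F)].

    Collects every ξ′-independent term multiplying the occupied density
    response; the h^ξ′ term itself never enters here.
    """
    Ef = [0.5 * (interm.E_F[s] + interm.E_F[s].T) for s in _SPINS]
    V = build_fock_like(scf, Ef[0], Ef[1])
    return tuple(0.5 * (interm.E_P[s] + interm.E_P[s].T) + V[s]
                 for s in _SPINS)


# ---------------------------------------------------------------------------
# CPSCF / Z-vector
# ---------------------------------------------------------------------------

class CPSCFError(RuntimeError):
    def __init__(self, msg, history):
        super().__init__(msg)
        self.history = history


def cpscf_apply(scf: SCFContext, z: tuple[np.ndarray, np.ndarray]):
    """Orbital-Hessian action on an occupied-virtual rotation pair."""
    D = []
    for sp in _SPINS:
        Co, Cv = scf.C_occ(sp), scf.C_virt(sp)
        D.append(Cv @ z[sp] @ Co.T + Co @ z[sp].T @ Cv.T)
    G = fock_like_build(scf, D[0], D[1])
    out = []
    for sp in _SPINS:
        Co, Cv = scf.C_occ(sp), scf.C_virt(sp)
        eo = scf.eps[sp][: scf.n_occ[sp]]
        ev = scf.eps[sp][scf.n_occ[sp]:]
        gap = ev[:, None] - eo[None, :]
        out.append(gap * z[sp] + Cv.T @ G[sp] @ Co)
    return tuple(out)


def solve_cpscf(scf: SCFContext, rhs: tuple[np.ndarray, np.ndarray],
                conv: float = 1e-4, max_iter: int = 400):
    """Preconditioned conjugate gradients on the coupled ov response.

    Stops when the residual max-norm falls below ``conv``; raises with the
    residual history otherwise.
    """
    gaps = []
    for sp in _SPINS:
        eo = scf.eps[sp][: scf.n_occ[sp]]
        ev = scf.eps[sp][scf.n_occ[sp]:]
        gaps.append(ev[:, None] - eo[None, :])

    def precond(r):
        return tuple(r[sp] / gaps[sp] if r[sp].size else r[sp]
                     for sp in _SPINS)

    def dot(a, b):
        return sum(float(np.sum(a[sp] * b[sp])) for sp in _SPINS)

    z = tuple(np.zeros_like(rhs[sp]) for sp in _SPINS)
    r = tuple(rhs[sp].copy() for sp in _SPINS)
    history = []
    resmax = max((np.abs(r[sp]).max() if r[sp].size else 0.0)
                 for sp in _SPINS)
    if resmax < conv:
        return z, history
    p = precond(r)
    rz = dot(r, p)
    for it in range(max_iter):
        Ap = cpscf_apply(scf, p)
        alpha = rz / dot(p, Ap)
        z = tuple(z[sp] + alpha * p[sp] for sp in _SPINS)
        r = tuple(r[sp] - alpha * Ap[sp] for sp in _SPINS)
        resmax = max((np.abs(r[sp]).max() if r[sp].size else 0.0)
                     for sp in _SPINS)
        history.append(resmax)
        if resmax < conv:
            return z, history
        rp = precond(r)
        rz_new = dot(r, rp)
        p = tuple(rp[sp] + (rz_new / rz) * p[sp] for sp in _SPINS)
        rz = rz_new
    raise CPSCFError(f"CPSCF not converged in {max_iter} iterations "
                     f"(residual {resmax:.2e})", history)


# ---------------------------------------------------------------------------
# relaxed density and hyperfine trace
# ---------------------------------------------------------------------------

@dataclass
class RelaxedDensity:
    D_mp2: tuple[np.ndarray, np.ndarray]       # explicit + response, per spin
    D_explicit: tuple[np.ndarray, np.ndarray]
    D_response: tuple[np.ndarray, np.ndarray]
    cpscf_iterations: int
    max_y_residual: float


def relaxed_density(scf: SCFContext, quad: LaplaceQuadrature,
                    rpairs: list[RMatrixPair], shift: float | None = None,
                    cpscf_conv: float = 1e-4) -> RelaxedDensity:
    """Effective one-particle MP2 density for basis-independent perturbations."""
    interm = response_intermediates(scf, quad, rpairs, shift=shift)
    Lam = assemble_rhs(scf, interm)
    rhs = []
    for sp in _SPINS:
        Co, Cv = scf.C_occ(sp), scf.C_virt(sp)
        rhs.append(2.0 * Cv.T @ Lam[sp] @ Co)
    z, history = solve_cpscf(scf, tuple(rhs), conv=cpscf_conv)
    D_expl, D_resp, D_tot = [], [], []
    for sp in _SPINS:
        Co, Cv = scf.C_occ(sp), scf.C_virt(sp)
        expl = 0.5 * (interm.E_F[sp] + interm.E_F[sp].T)
        resp = -0.5 * (Cv @ z[sp] @ Co.T + Co @ z[sp].T @ Cv.T)
        D_expl.append(expl)
        D_resp.append(resp)
        D_tot.append(expl + resp)
    return RelaxedDensity(D_mp2=(D_tot[0], D_tot[1]),
                          D_explicit=(D_expl[0], D_expl[1]),
                          D_response=(D_resp[0], D_resp[1]),
                          cpscf_iterations=len(history),
                          max_y_residual=interm.max_y_residual)


@dataclass
class HFCCResult:
    nucleus: int
    element: str
    isotope: str
    g_factor: float
    A_iso_scf: float
    A_iso_mp2: float

    @property
    def A_iso_total(self) -> float:
        return self.A_iso_scf + self.A_iso_mp2


def hfcc_prefactor_mhz(scf: SCFContext, g_factor: float) -> float:
    """MHz per unit of the spin-density trace, including 1/(2<S_z>)."""
    two_sz = scf.n_occ[0] - scf.n_occ[1]
    return FC_PREFACTOR_MHZ * g_factor / (two_sz if two_sz != 0 else 1)


def compute_hfcc(scf: SCFContext, relaxed: RelaxedDensity | None, k: int,
                 g_factor: float | None = None) -> HFCCResult:
    """Isotropic hyperfine coupling of nucleus ``k`` in MHz."""
    element = scf.molecule.symbols[k]
    isotope, g = nuclear_g_factor(element) if g_factor is None \
        else ("custom", g_factor)
    fc = fermi_contact_integrals(scf, k)
    pref = hfcc_prefactor_mhz(scf, g)
    rho_scf = float(np.sum(fc.H_FC * (scf.P_occ(0) - scf.P_occ(1))))
    A_scf = pref * rho_scf
    if relaxed is None:
        A_mp2 = 0.0
    else:
        rho_mp2 = float(np.sum(fc.H_FC * (relaxed.D_mp2[0] - relaxed.D_mp2[1])))
        A_mp2 = pref * rho_mp2
    return HFCCResult(nucleus=k, element=element, isotope=isotope, g_factor=g,
                      A_iso_scf=A_scf, A_iso_mp2=A_mp2)
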