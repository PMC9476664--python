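"""Unrestricted Hartree–Fock with DIIS acceleration.

Closed shells are treated in the same unrestricted framework so that
spin-symmetry properties remain expressible downstream.  The solver works
with a dense AO ERI tensor (desk-scale systems); the Fock build is exposed
separately because the response machinery reuses it for Fock-like
intermediates of arbitrary symmetric "densities".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla


class SCFConvergenceError(RuntimeError):
    def __init__(self, message, trace):
        super().__init__(message)
        self.trace = trace


def coulomb_exchange(I: np.ndarray, D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """J[D] and K[D] for a (not necessarily idempotent) symmetric matrix D."""
    J = np.einsum("mnls,ls->mn", I, D, optimize=True)
    K = np.einsum("mlns,ls->mn", I, D, optimize=True)
    return J, K


def fock_like(I: np.ndarray, D_alpha: np.ndarray, D_beta: np.ndarray):
    """Unrestricted Fock-like two-electron build for a density-like pair.

    Returns (G_alpha, G_beta) with G_eta = J[D_alpha + D_beta] - K[D_eta].
    """
    Jt = np.einsum("mnls,ls->mn", I, D_alpha + D_beta, optimize=True)
    Ka = np.einsum("mlns,ls->mn", I, D_alpha, optimize=True)
    Kb = np.einsum("mlns,ls->mn", I, D_beta, optimize=True)
    return Jt - Ka, Jt - Kb


@dataclass
class UHFResult:
    energy: float
    C: tuple[np.ndarray, np.ndarray]
    eps: tuple[np.ndarray, np.ndarray]
    n_occ: tuple[int, int]
    F: tuple[np.ndarray, np.ndarray]
    P: tuple[np.ndarray, np.ndarray]
    converged: bool = True
    iterations: int = 0
    trace: list = field(default_factory=list)


def run_uhf(S, h, I, n_alpha, n_beta, e_nuc=0.0, *, h_alpha=None, h_beta=None,
            conv_energy=1e-11, conv_commutator=1e-9, max_iter=300,
            guess=None) -> UHFResult:
    """Solve the UHF equations by diagonalization with DIIS.

    ``h_alpha``/``h_beta`` allow a spin-dependent one-electron perturbation
    (used by the finite-difference hyperfine oracle); they default to ``h``.
    """
    n = S.shape[0]
    ha = h if h_alpha is None else h_alpha
    hb = h if h_beta is None else h_beta
    X = _lowdin(S)

    if guess is not None:
        Pa, Pb = guess
    else:
        Pa = _core_density(X, ha, n_alpha)
        Pb = _core_density(X, hb, n_beta)

    diis_F, diis_err = [], []
    E_old, trace = 0.0, []
    for it in range(1, max_iter + 1):
        Ga, Gb = fock_like(I, Pa, Pb)
        Fa, Fb = ha + Ga, hb + Gb
        # DIIS on the orthonormalized commutators of both spins
        erra = X.T @ (Fa @ Pa @ S - S @ Pa @ Fa) @ X
        errb = X.T @ (Fb @ Pb @ S - S @ Pb @ Fb) @ X
        err = np.concatenate([erra.ravel(), errb.ravel()])
        comm = max(np.abs(erra).max() if erra.size else 0.0,
                   np.abs(errb).max() if errb.size else 0.0)
        E = 0.5 * (np.sum(Pa * (ha + Fa)) + np.sum(Pb * (hb + Fb))) + e_nuc
        trace.append((it, E, comm))
        if abs(E - E_old) < conv_energy and comm < conv_commutator and it > 2:
            ea, Ca = _diag(Fa, X)
            eb, Cb = _diag(Fb, X)
            return UHFResult(energy=E, C=(Ca, Cb), eps=(ea, eb),
                             n_occ=(n_alpha, n_beta), F=(Fa, Fb), P=(Pa, Pb),
                             iterations=it, trace=trace)
        E_old = E

        diis_F.append((Fa.copy(), Fb.copy()))
        diis_err.append(err)
        if len(diis_F) > 10:
            diis_F.pop(0)
            diis_err.pop(0)
        if len(diis_F) > 1:
            Fa, Fb = _diis_extrapolate(diis_F, diis_err)

        ea, Ca = _diag(Fa, X)
        eb, Cb = _diag(Fb, X)
        Pa = Ca[:, :n_alpha] @ Ca[:, :n_alpha].T
        Pb = Cb[:, :n_beta] @ Cb[:, :n_beta].T

    raise SCFConvergenceError(
        f"UHF not converged in {max_iter} iterations "
        f"(last |dE|={abs(E - E_old):.2e}, commutator={comm:.2e})", trace)


def _lowdin(S):
    e, U = np.linalg.eigh(S)
    keep = e > 1e-10 * e.max()
    return U[:, keep] / np.sqrt(e[keep])


def _diag(F, X):
    e, Ct = np.linalg.eigh(X.T @ F @ X)
    return e, X @ Ct


def _core_density(X, h, nocc):
    _, C = _diag(h, X)
    return C[:, :nocc] @ C[:, :nocc].T


def _diis_extrapolate(Fs, errs):
    m = len(Fs)
    B = np.empty((m + 1, m + 1))
    B[-1, :] = -1.0
    B[:, -1] = -1.0
    B[-1, -1] = 0.0
    for i in range(m):
        for j in range(m):
            B[i, j] = errs[i] @ errs[j]
    rhs = np.zeros(m + 1)
    rhs[-1] = -1.0
    try:
        c = np.linalg.solve(B, rhs)[:m]
    except np.linalg.LinAlgError:
        c = np.linalg.lstsq(B, rhs, rcond=None)[0][:m]
    Fa = sum(ci * F[0] for ci, F in zip(c, Fs))
    Fb = sum(ci * F[1] for ci, F in zip(c, Fs))
    return Fa, Fb
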