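"""Laplace quadrature of the MP2 energy denominator, pseudodensities and
their pivoted Cholesky decomposition.

The orbital-energy denominator 1/x on x ∈ [x_min, x_max] is approximated by
Σ_κ ω_κ exp(-x τ_κ).  The occupied/virtual pseudodensities absorb the
exponential factors into density-like AO matrices,

    P̲(κ) = ω_κ^{1/4} Σ_i e^{+(ε_i - μ) τ_κ} C_i C_iᵀ
    P̅(κ) = ω_κ^{1/4} Σ_a e^{-(ε_a - μ) τ_κ} C_a C_aᵀ

with a level shift μ placed mid-gap; the shift cancels exactly in every
energy term (each term carries two occupied and two virtual factors), and is
kept fixed in all derivative bookkeeping.  The quadrature weight is split
symmetrically over the four factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .engine import SCFContext


# ---------------------------------------------------------------------------
# quadrature
# ---------------------------------------------------------------------------

@dataclass
class LaplaceQuadrature:
    weights: np.ndarray     # ω_κ > 0
    exponents: np.ndarray   # τ_κ > 0, strictly increasing
    x_min: float
    x_max: float
    max_rel_error: float

    @property
    def n_points(self) -> int:
        return len(self.weights)

    def evaluate(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        return np.einsum("k,xk->x", self.weights,
                         np.exp(-np.outer(x, self.exponents)))

    def rel_error(self, x) -> np.ndarray:
        return (self.evaluate(x) - 1.0 / np.asarray(x)) * np.asarray(x)

    def dumps(self) -> str:
        lines = [f"x_min {float(self.x_min)!r}", f"x_max {float(self.x_max)!r}",
                 f"max_rel_error {float(self.max_rel_error)!r}"]
        for w, t in zip(self.weights, self.exponents):
            lines.append(f"point {float(w)!r} {float(t)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def loads(cls, text: str) -> "LaplaceQuadrature":
        kv, pts = {}, []
        for ln in text.splitlines():
            parts = ln.split()
            if not parts:
                continue
            if parts[0] == "point":
                pts.append((float(parts[1]), float(parts[2])))
            else:
                kv[parts[0]] = float(parts[1])
        w = np.array([p[0] for p in pts])
        t = np.array([p[1] for p in pts])
        return cls(weights=w, exponents=t, x_min=kv["x_min"],
                   x_max=kv["x_max"], max_rel_error=kv["max_rel_error"])


def fit_laplace_quadrature(x_min: float, x_max: float, K: int = 7,
                           n_sample: int = 20000) -> LaplaceQuadrature:
    """Least-squares exponential-sum fit of 1/x on [x_min, x_max].

    Geometric-progression initialization refined by Levenberg–Marquardt on
    log-parameters; the relative error is measured (not assumed) on a dense
    log-spaced sample and stored.
    """
    if not (0 < x_min <= x_max):
        raise ValueError("require 0 < x_min <= x_max")
    if K < 1:
        raise ValueError("K >= 1")
    if np.isclose(x_min, x_max):
        # one-point interpolation at a: ω e^{-aτ} = 1/a exactly
        tau = np.full(K, 1.0 / x_min) * (1.0 + 1e-3 * np.arange(K))
        w = np.zeros(K)
        w[0] = np.exp(tau[0] * x_min) / x_min
        quad = LaplaceQuadrature(w[:1], tau[:1], x_min, x_max, 0.0)
        quad.max_rel_error = float(np.abs(quad.rel_error([x_min])).max())
        return quad

    # fit on the scaled interval [1, R], then rescale
    R = x_max / x_min
    xs = np.geomspace(1.0, R, 1500)

    def unpack(params):
        return (np.exp(np.clip(params[:K], -700, 700)),
                np.exp(np.clip(params[K:], -700, 700)))

    def resid(params):
        w, tau = unpack(params)
        return (np.exp(-np.clip(np.outer(xs, tau), 0, 700)) @ w) * xs - 1.0

    def jac(params):
        w, tau = unpack(params)
        E = np.exp(-np.clip(np.outer(xs, tau), 0, 700))
        J = np.empty((len(xs), 2 * K))
        J[:, :K] = E * w[None, :] * xs[:, None]
        J[:, K:] = -E * (w * tau)[None, :] * (xs**2)[:, None]
        return J

    # sinc-quadrature initializations of 1/x = ∫ exp(-x e^u + u) du
    best = None
    for lo_c, hi_c in [(0.05, 4.0), (0.2, 6.0), (0.5, 3.0)]:
        if K > 1:
            u = np.linspace(np.log(lo_c / R), np.log(hi_c), K)
            h = u[1] - u[0]
        else:
            u = np.array([np.log(1.0 / np.sqrt(R))])
            h = 1.0
        p0 = np.concatenate([np.log(h) + u, u])
        sol = least_squares(resid, p0, jac=jac, method="lm", max_nfev=3000,
                            xtol=3e-16, ftol=3e-16, gtol=3e-16)
        err = np.abs(resid(sol.x)).max()
        if best is None or err < best[0]:
            best = (err, sol.x)
    w, tau = unpack(best[1])
    order = np.argsort(tau)
    w, tau = w[order], tau[order]
    tau = tau * (1.0 + 1e-14 * np.arange(K))  # keep τ strictly increasing
    # rescale to [x_min, x_max]
    w, tau = w / x_min, tau / x_min
    quad = LaplaceQuadrature(weights=w, exponents=tau, x_min=x_min,
                             x_max=x_max, max_rel_error=0.0)
    dense = np.geomspace(x_min, x_max, max(n_sample, 10000))
    quad.max_rel_error = float(np.abs(quad.rel_error(dense)).max())
    return quad


# ---------------------------------------------------------------------------
# pseudodensities
# ---------------------------------------------------------------------------

def denominator_range(scf: SCFContext) -> tuple[float, float]:
    """Range [x_min, x_max] covering all MP2 denominators ε_a+ε_b-ε_i-ε_j."""
    gaps_min, gaps_max = [], []
    for s in (0, 1):
        no = scf.n_occ[s]
        eps = scf.eps[s]
        if no == 0 or no == len(eps):
            continue
        gaps_min.append(eps[no:].min() - eps[:no].max())
        gaps_max.append(eps[no:].max() - eps[:no].min())
    if not gaps_min:
        return (1.0, 1.0)
    return (2.0 * min(gaps_min), 2.0 * max(gaps_max))


def level_shift(scf: SCFContext) -> float:
    """Mid-gap chemical-potential shift μ, merged over spins."""
    homo, lumo = [], []
    for s in (0, 1):
        no = scf.n_occ[s]
        eps = scf.eps[s]
        if no > 0:
            homo.append(eps[:no].max())
        if no < len(eps):
            lumo.append(eps[no:].min())
    if not homo or not lumo:
        return 0.0
    return 0.5 * (max(homo) + min(lumo))


@dataclass
class PseudoDensityPair:
    kappa: int
    P_occ: tuple[np.ndarray, np.ndarray]   # P̲ per spin (weighted)
    P_virt: tuple[np.ndarray, np.ndarray]  # P̅ per spin (weighted)
    shift: float
    tau: float
    weight: float


def build_pseudodensities(scf: SCFContext, quad: LaplaceQuadrature,
                          kappa: int, shift: float | None = None,
                          check_range: bool = True) -> PseudoDensityPair:
    """Eq-4-style pseudodensities at Laplace point ``kappa``."""
    x_lo, x_hi = denominator_range(scf)
    if check_range and (x_lo < quad.x_min * (1 - 1e-9)
                        or x_hi > quad.x_max * (1 + 1e-9)):
        raise ValueError(
            f"denominator range [{x_lo:.6f}, {x_hi:.6f}] outside quadrature "
            f"interval [{quad.x_min:.6f}, {quad.x_max:.6f}]")
    mu = level_shift(scf) if shift is None else shift
    t = quad.exponents[kappa]
    w4 = quad.weights[kappa] ** 0.25
    Po, Pv = [], []
    for s in (0, 1):
        no = scf.n_occ[s]
        C = scf.C[s]
        eps = scf.eps[s]
        occ = C[:, :no] * np.exp(+(eps[:no] - mu) * t * 0.5)
        vir = C[:, no:] * np.exp(-(eps[no:] - mu) * t * 0.5)
        Po.append(w4 * occ @ occ.T)
        Pv.append(w4 * vir @ vir.T)
    return PseudoDensityPair(kappa=kappa, P_occ=(Po[0], Po[1]),
                             P_virt=(Pv[0], Pv[1]), shift=mu, tau=t,
                             weight=quad.weights[kappa])


# ---------------------------------------------------------------------------
# pivoted Cholesky
# ---------------------------------------------------------------------------

def pivoted_cholesky(M: np.ndarray, threshold: float = 1e-8) -> np.ndarray:
    """Pivoted Cholesky factor L (columns in pivot order) with ‖LLᵀ-M‖_max
    below ``threshold``.  Pivots below -10·threshold raise (not PSD);
    slightly negative pivots are clamped.
    """
    n = M.shape[0]

    def col(j):
        return M[:, j].astype(float).copy()

    return _pcd_oracle(np.diag(M).astype(float).copy(), col, n, threshold)


def _pcd_oracle(diag: np.ndarray, column, n: int, threshold: float,
                max_rank: int | None = None,
                return_pivots: bool = False):
    """Partial pivoted Cholesky given a diagonal and a column oracle."""
    max_rank = n if max_rank is None else min(max_rank, n)
    L = np.zeros((n, max_rank))
    pivots: list[int] = []
    neg_tol = max(10.0 * threshold, 1e-12 * max(diag.max(), 0.0), 1e-15)
    for k in range(max_rank):
        jmin = int(np.argmin(diag))
        if diag[jmin] < -neg_tol:
            raise ValueError(f"matrix not PSD: pivot {diag[jmin]:.3e} at {jmin}")
        j = int(np.argmax(diag))
        piv = diag[j]
        if piv <= threshold:
            break
        c = column(j) - L[:, :k] @ L[j, :k]
        lk = c / np.sqrt(piv)
        lk[j] = np.sqrt(piv)
        L[:, k] = lk
        diag = diag - lk * lk
        diag[j] = 0.0
        diag = np.where(diag < 0, 0.0, diag)
        pivots.append(j)
    L = L[:, : len(pivots)]
    if return_pivots:
        return L, pivots
    return L


@dataclass
class CholeskyMOs:
    """Cholesky pseudo-MO coefficients of the (weighted) pseudodensities."""

    L_occ: tuple[np.ndarray, np.ndarray]
    L_virt: tuple[np.ndarray, np.ndarray]
    threshold: float
    kappa: int


def cholesky_pseudo_mos(pair: PseudoDensityPair,
                        threshold: float = 1e-8) -> CholeskyMOs:
    Lo, Lv = [], []
    for s in (0, 1):
        Lo.append(pivoted_cholesky(pair.P_occ[s], threshold))
        Lv.append(pivoted_cholesky(pair.P_virt[s], threshold))
    return CholeskyMOs(L_occ=(Lo[0], Lo[1]), L_virt=(Lv[0], Lv[1]),
                       threshold=threshold, kappa=pair.kappa)


def quadrature_for(scf: SCFContext, K: int = 7) -> LaplaceQuadrature:
    """Fit a quadrature covering the denominator spectrum of ``scf``."""
    x_lo, x_hi = denominator_range(scf)
    return fit_laplace_quadrature(x_lo, x_hi, K)
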