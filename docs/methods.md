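# Methods

This note documents the model, the numerical choices, and the limits of what
the test suite demonstrates. Everything quantitative stated here is computed
by the tests or by `scripts/acceptance.py`; nothing is quoted from external
sources.

## Scope of the model

The package computes the isotropic (Fermi-contact) hyperfine coupling
constant of each nucleus in an open-shell molecule at the unrestricted MP2
level, as the analytic first derivative of E_SCF + E_MP2 with respect to the
nuclear magnetic moment. The perturbation couples with opposite sign to the
α and β spin densities and does not touch the basis functions, so no
integral derivatives or overlap-derivative terms arise. Anisotropic
(dipolar) hyperfine components, spin–orbit corrections, finite-nucleus
models, vibrational averaging and solvation are all out of scope. The
Fermi-contact operator is the point evaluation H_FC,μν = χ_μ(R_k)χ_ν(R_k);
its trace with the relaxed spin density, times
(2/3)μ₀ g_e μ_B g_k μ_N / (2⟨S_z⟩) (CODATA 2018 constants, built-in
g-factors for ¹H, ¹¹B, ¹³C, ¹⁴N, ¹⁷O, ¹⁹F, ³¹P), gives A_iso in MHz. Which
constant set a given literature value used is rarely stated, so the g-factor
is overridable per call.

## Derivative formulation

The Laplace-quadrature energy depends on the perturbation only through the
pseudodensities, which are matrix functions of the occupied density and the
Fock matrix: P̲(κ) = ω^{1/4} e^{τ P_occ F̃} P_occ and
P̅(κ) = ω^{1/4} e^{−τ P_virt F̃} P_virt, with F̃ = F − μS and μ a fixed
mid-gap shift (the shift cancels exactly in every energy term because each
term carries two occupied and two virtual factors; it is therefore frozen in
the differentiation). Defining R = ∂e_κ/∂(pseudodensity) — the contraction
of all perturbation-independent integral content — the chain rule through
(P_occ, F) closes with the Fréchet derivative of the matrix exponential,

    Y = Φ_A[B] = ∫₀¹ e^{sA} B e^{(1−s)A} ds ,

evaluated at A = ±τ P F̃ with direction B = P R. Collecting coefficients of
dF and dP_occ (using dP_virt = −dP_occ, valid because S is
perturbation-independent), moving the dF two-electron response onto a
Fock-like build of the dF-coefficient, and closing the remaining
Tr(Λ dP_occ) with a single Z-vector CPSCF solve yields the relaxed density.
The multilinearity identity Σ_η [Tr(R̲P̲) + Tr(R̅P̅)] = 4e_κ and, above all,
agreement with a central finite difference of the total energy are the
arbiters of every sign and weight in this assembly; the test suite checks
the finite-difference property on four radicals at tolerance 10⁻³ MHz and
observes agreement at the 10⁻⁵ MHz level.

Y is computed by a scaling-and-squaring recursion on the block pair
(e^{A/2^s}, Φ): Taylor series at the scaled argument, then s doubling steps
Y ← e^A Y + Y e^A. Both A and B must be scaled by 2^{−s}. The residual check
substitutes the solution into A Y − Y A = e^A B − B e^A and
Tr Y = Tr(B e^A); the independent oracle in the tests is SciPy's
`expm_frechet`. Weights are split symmetrically (ω^{1/4} on each of the four
pseudodensity factors), so doubling one quadrature weight scales that
point's R pair by exactly 2^{3/4} — a property test.

## Laplace quadrature

1/x is fitted on [x_min, x_max] = [2·min gap, 2·max gap] (merged over spin
channels) by Levenberg–Marquardt on log-parameters with an analytic
Jacobian, initialized from several sinc-quadrature discretizations of
1/x = ∫ e^{−x e^u + u} du; the best local solution is kept. This is not a
minimax (Remez) construction: the maximum relative error is *measured* on a
dense log-spaced sample (10⁴ points at fit time, re-checked on 10⁵ in the
tests) and stored, and every downstream energy tolerance is expressed
through that stored error times the Σ|amplitude|/Δ weight of the canonical
oracle, so a mediocre fit weakens bounds but never invalidates them. K = 7
points are the default; the measured error is monotone non-increasing in K
over 3..10 on the tested intervals. For a one-electron system there are no
denominators and the quadrature degenerates to a single exact point.

## Integral engine, bases

No quantum-chemistry backend is assumed: the package carries a
McMurchie–Davidson engine (Hermite expansion coefficients vectorized over
primitive pairs, Boys function by downward recursion from a regularized
incomplete gamma, Hermite Coulomb tensor by the auxiliary-index recursion)
for overlap, kinetic, nuclear attraction, 2-/3-/4-center ERIs under
Coulomb, erf- and erfc-attenuated kernels, and basis evaluation on points.
Cartesian shells throughout; s/p orbital bases (STO-3G for H/B/C/N/O/F,
6-31G for H/C/N/O, embedded as plain data) and up to d auxiliary shells.
Closed-form s-Gaussian repulsion, kernel partition erf+erfc = 1/r, and
standard total energies (H/STO-3G −0.466582 Eh, H₂O/STO-3G −74.963 Eh at
the experimental geometry) pin the engine in the tests.

The auxiliary basis is generated per element as even-tempered s/p/d
expansions covering the orbital-product exponent range (≈ 15–20 functions
per basis function — deliberately oversized, trading integral time for
fitting accuracy, max ERI reconstruction error ~5·10⁻⁵ for STO-3G systems
and ~1.4·10⁻⁴ for 6-31G water under the Coulomb metric). For attenuated
metrics the fit is contracted robustly against the Coulomb two-center
matrix, B = V_C^{1/2} m⁻¹ (m|μν).

## THC factorization

Grid points are selected from an atom-centered parent quadrature
(Gauss–Chebyshev radial × Gauss–Legendre/uniform spherical product,
Bragg-radius scaling) by pivoted Cholesky of the grid Gram metric
S_PQ = (XᵀX)∘², keeping N_grid = 3·N_aux points with the reference
N_aux ≈ 3·N_bf of the usual optimized fitting sets (the generated auxiliary
basis is intentionally larger and would distort the sizing convention).
When the Gram rank is exhausted first, the remaining points are appended in
descending-diagonal order: this redundancy matters, because with a strictly
rank-minimal grid every point is load-bearing and magnitude-based screening
of grid points becomes disproportionately harmful.

The kernel solves the least-squares normal equations Z = S⁺WS⁺, evaluated
through the SVD pseudo-inverse of the collocation-product matrix
(Z = Y⁺(μν|λσ)Y⁺ᵀ, Y_{μν,P} = X_μP X_νP; algebraically identical, but the
conditioning of S is not squared). Relative singular-value cutoff 10⁻¹⁰;
W comes from the RI factors in production and from dense ERIs for the
"exact projection" oracle kernel, which reproduces every ERI to machine
precision once the grid spans the product space. Λ with ΛΛᵀ = Z_PSD comes
from the symmetric eigendecomposition with eigenvalues below 10⁻¹² λ_max
clamped and reported.

## Screened exchange contraction

The exchange-like R parts are accumulated over the occupied pseudo-MO index
j with one Z-containing intermediate E_j = Z diag(X̲_j) B shared between
both parts: G_A += E_j∘E_jᵀ (→ R̲ˣ) and G_B += diag(X̲_j) Z (A∘E_jᵀ)
(→ R̅ˣ). Index restriction follows the decay structure, not symmetry
convenience: the {P_j} list (|X̲_jP| > ε_Sj) restricts every index carrying
an occupied collocation factor; the composed list {R_j} (grid points
supported by some virtual orbital shared with j, through the {b_R} and
{b_j} lists) restricts only indices protected by a B = X̅ᵀX̅ factor. The
output-side index of G_B carries no decay factor and is never restricted —
restricting it looks symmetric but silently discards O(1) contributions
(observed as ~1 MHz hyperfine shifts on the hydroxyl radical before this
distinction was enforced). With all thresholds zero the screened code path
runs with full index lists and is bit-identical to the unscreened one. At
the default thresholds (ε_Sj = 10⁻³, ε_bR = ε_bj = 10⁻²) the measured
hyperfine shift against ε = 0 stays below 0.1 MHz on every fixture radical
(acceptance-script value ≈ 0.05 MHz, dominated by the hydroxyl radical,
whose single α virtual orbital in the minimal basis makes the {b_R}
composition maximally aggressive).

## CPSCF / Z-vector

The coupled-perturbed equations are solved once (Z-vector side) by
preconditioned conjugate gradients on the spin-coupled occupied–virtual
rotation space, with the orbital-energy gap as preconditioner and the
Fock-like build supplying the coupling; convergence is a residual max-norm,
default 10⁻⁴ (the value that keeps desk-scale hyperfine errors well below
1 MHz). Validation runs in the tests tighten this to 10⁻⁹–10⁻¹⁰ so that the
finite-difference comparison probes the derivative assembly rather than
solver truncation; the re-application residual is the solver's contract.

## Finite-difference oracle

The oracle adds ±λ H_FC (spin-antisymmetric) to the core Hamiltonian,
re-converges UHF to 10⁻¹³ Eh starting from the unperturbed density,
re-evaluates the dense Laplace MP2 energy with the *frozen* λ = 0
quadrature (matching the analytic treatment of the quadrature as fixed
parameters), and forms (E₊ − E₋)/2λ. λ = 10⁻⁵ sits on the measured plateau
(scan 10⁻⁴..10⁻⁶); central-difference symmetry and the one-electron null
are separate checks.

## Synthetic fixtures and what the tests do not show

The fixture set (H, OH, CH₃, NH₂, H₂O as closed-shell control, n-C₃H₇ as a
small member of the linear-alkyl series) uses idealized experimental
geometries in minimal/split-valence bases. These are desk-scale surrogates:
they exercise every code path (degenerate π radical, planar σ/π radical,
empty β channel, closed shell, multi-carbon chain) but say nothing about
basis-set convergence of HFCCs (minimal-basis spin densities are strongly
overestimated and spin-contaminated at UHF-MP2), about the asymptotic
scaling claims that motivate natural blocking, or about rotational
invariance errors of grid-based THC beyond the ~10⁻² MHz level observed
between symmetry-equivalent methyl protons. Accuracy statements are
self-referenced against the dense/canonical/finite-difference oracles, not
against published benchmark tables, whose geometries and hand-optimized
grids are not reproducible here.

## Numerical defaults

| quantity | default | notes |
|---|---|---|
| Laplace points K | 7 | error measured and stored |
| SCF convergence | 10⁻⁸ Eh / 10⁻⁷ commutator | 10⁻¹³/10⁻¹⁰ in validation runs |
| attenuation ω | 0.1 bohr⁻¹ | erfc metric in the RI fit |
| grid ratio | 3.0 × N_aux (N_aux ≈ 3 N_bf) | pivoted-Cholesky selection |
| fit cutoff | 10⁻¹⁰ (relative, singular values of Y) | |
| Λ clamp | 10⁻¹² λ_max | clamped count reported |
| ε_Sj, ε_bR, ε_bj | 10⁻³, 10⁻², 10⁻² | strict >, ties excluded |
| CDD threshold | 10⁻⁸ absolute | pivots in (−10⁻⁷, 0] clamped |
| CPSCF residual | 10⁻⁴ max-norm | |
| FD step λ | 10⁻⁵ | plateau-scanned |
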