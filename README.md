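# thchfcc

Isotropic hyperfine coupling constants (HFCCs) from first derivatives of the
Laplace-transformed AO-MP2 energy, with all electron-repulsion-integral (ERI)
contractions performed in tensor-hypercontracted (THC) form and the
exchange-like contractions screened by natural-blocking significance lists.

## Who this is for

Computational chemists studying open-shell molecules (organic radicals,
spin labels) who want electron-spin-resonance observables — the isotropic,
Fermi-contact part of the hyperfine tensor — at the MP2 level of theory,
and method developers who want a compact, oracle-validated reference
implementation of the THC/Cholesky-pseudodensity machinery behind it.

## The method in brief

The unrestricted MP2 correlation energy is written without canonical-orbital
denominators by a Laplace quadrature, 1/x ≈ Σ_κ ω_κ e^(−x τ_κ), which turns
the energy into traces of AO matrices built from occupied/virtual
*pseudodensities*

    P̲^η(κ) = ω_κ^{1/4} Σ_i e^{+(ε_i−μ)τ_κ} C_i C_iᵀ,
    P̅^η(κ) = ω_κ^{1/4} Σ_a e^{−(ε_a−μ)τ_κ} C_a C_aᵀ.

For a perturbation ξ′ that leaves the basis functions untouched — here the
nuclear magnetic moment, whose one-electron operator is the Fermi-contact
matrix H_FC,μν = χ_μ(R_k)χ_ν(R_k) with opposite sign for α and β spin — the
derivative needs only (i) the **R intermediates**, R = ∂e_κ/∂(pseudodensity),
which contain every ERI contraction, and (ii) cheap density-derivative
bookkeeping (Fréchet derivatives of the matrix exponentials above, a
Fock-like build, and one Z-vector CPSCF solve), giving a relaxed density D
with

    A_iso(k) = (2/3) μ₀ g_e μ_B g_k μ_N ρ_s(R_k) / (2⟨S_z⟩),
    ρ_s(R_k) = Tr[H_FC (D^α − D^β)].

The expensive step, forming R, uses the least-squares THC factorization
(μν|λσ) ≈ Σ_PQ X_μP X_νP Z_PQ X_λQ X_σQ fitted through an erfc-attenuated
Coulomb metric (ω = 0.1): Coulomb-like parts reduce to a Schur product
against the precontraction D = Z(A∘B)Z, and exchange-like parts are batched
over the common occupied Cholesky-pseudo-MO index with significance lists
(thresholds ε_Sj = 10⁻³, ε_bR = ε_bj = 10⁻²) pruning the grid/orbital index
pairs.

Correctness is anchored by independent oracles: dense (unfactorized) R
contractions, canonical MO-MP2, and a central finite-difference derivative
of the total energy with the Fermi-contact operator added to the core
Hamiltonian.

## Worked example

```sh
$ hfcc validate CH3
 nucleus  isotope      A_scf/MHz      A_mp2/MHz    A_total/MHz
      C0      13C     278.821956     -37.948813     240.873143
      H1       1H    -152.134489      25.817652    -126.316837
      H2       1H    -152.134489      25.817652    -126.316837
      H3       1H    -152.134489      25.817652    -126.316837

nucleus 0: analytic +240.873143 MHz, finite-difference +240.873137 MHz, |Δ| = 6.24e-06 MHz [ok]
nucleus 1: analytic -126.316837 MHz, finite-difference -126.316835 MHz, |Δ| = 1.73e-06 MHz [ok]
```

For the planar methyl radical in the minimal basis the unrestricted SCF spin
density puts +278.8 MHz on ¹³C; the MP2 relaxed-density correction removes
−37.9 MHz of that (spin polarization is overestimated at the UHF level), for
a total of +240.9 MHz, and the analytic derivative agrees with the
finite-difference oracle to a few 10⁻⁶ MHz. The proton coupling is negative
(−126 MHz), with the sign expected from π-spin polarization, and the MP2
correction (+25.8 MHz) damps the UHF overestimate.

A production-style run over an XYZ file uses the THC backend:

```sh
hfcc run mol.xyz --multiplicity 2 --basis sto-3g --laplace 7 --omega 0.1 \
    --grid-ratio 3.0 --eps-sj 1e-3 --eps-br 1e-2 --eps-bj 1e-2 \
    --out results.csv --diagnostics diag.json
```

From Python:

```python
from thchfcc import RunConfig, run_hfcc, get_fixture
res = run_hfcc(RunConfig(), get_fixture("CH3").molecule)
print(res.table())
```

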