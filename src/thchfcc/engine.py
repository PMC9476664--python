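"""Contract layer between the correlation/gradient machinery and the
integral engine.

Every downstream module consumes only the types defined here
(:class:`Molecule`, :class:`SCFContext`, :class:`FermiContactOperator`,
:class:`RIFactors`) plus collocation matrices, so the integral backend is
fully encapsulated.  The unrestricted formalism is used throughout, also for
closed shells, which keeps spin-symmetry checks expressible.

Conventions: Cartesian Gaussians; shells ordered by atom then angular
momentum as listed in the basis data; all matrices in the AO basis; energies
in Hartree; coordinates in bohr internally (XYZ input in Å).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import integrals as ig
from .basis import BasisSet, angstrom_to_bohr, build_aux_basis, build_basis, nuclear_charge
from .scf import UHFResult, fock_like, run_uhf

DENSE_ERI_MAX_NBF = 120


@dataclass
class Molecule:
    symbols: list[str]
    coords: np.ndarray          # (natom, 3) Å
    charge: int = 0
    multiplicity: int = 1
    name: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        n_el = self.n_electrons
        if n_el < 0:
            raise ValueError("negative electron count")
        if (n_el - (self.multiplicity - 1)) % 2 != 0:
            raise ValueError(
                f"multiplicity {self.multiplicity} inconsistent with "
                f"{n_el} electrons")

    @property
    def n_electrons(self) -> int:
        return sum(nuclear_charge(s) for s in self.symbols) - self.charge

    @property
    def n_alpha(self) -> int:
        return (self.n_electrons + self.multiplicity - 1) // 2

    @property
    def n_beta(self) -> int:
        return self.n_electrons - self.n_alpha

    @property
    def coords_bohr(self) -> np.ndarray:
        return angstrom_to_bohr(self.coords)

    @property
    def charges(self) -> np.ndarray:
        return np.array([nuclear_charge(s) for s in self.symbols], float)

    def nuclear_repulsion(self) -> float:
        xyz = self.coords_bohr
        z = self.charges
        e = 0.0
        for i in range(len(z)):
            for j in range(i):
                e += z[i] * z[j] / np.linalg.norm(xyz[i] - xyz[j])
        return e

    @classmethod
    def from_xyz(cls, path, charge=0, multiplicity=1) -> "Molecule":
        with open(path) as fh:
            lines = fh.read().splitlines()
        nat = int(lines[0].split()[0])
        symbols, coords = [], []
        for ln in lines[2: 2 + nat]:
            parts = ln.split()
            symbols.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        return cls(symbols=symbols, coords=np.array(coords), charge=charge,
                   multiplicity=multiplicity)


@dataclass
class SCFContext:
    """Converged per-spin UHF quantities in a fixed AO basis."""

    molecule: Molecule
    basis: BasisSet
    aux_basis: BasisSet
    S: np.ndarray
    h: np.ndarray
    F: tuple[np.ndarray, np.ndarray]
    C: tuple[np.ndarray, np.ndarray]
    eps: tuple[np.ndarray, np.ndarray]
    n_occ: tuple[int, int]
    E_scf: float
    e_nuc: float
    h_spin: tuple[np.ndarray, np.ndarray] | None = None  # perturbed h, if any
    metadata: dict = field(default_factory=dict)
    _eri: np.ndarray | None = None

    @property
    def nbf(self) -> int:
        return self.S.shape[0]

    def C_occ(self, spin: int) -> np.ndarray:
        return self.C[spin][:, : self.n_occ[spin]]

    def C_virt(self, spin: int) -> np.ndarray:
        return self.C[spin][:, self.n_occ[spin]:]

    def P_occ(self, spin: int) -> np.ndarray:
        Co = self.C_occ(spin)
        return Co @ Co.T

    def P_virt(self, spin: int) -> np.ndarray:
        Cv = self.C_virt(spin)
        return Cv @ Cv.T

    def h_eff(self, spin: int) -> np.ndarray:
        return self.h if self.h_spin is None else self.h_spin[spin]


def build_scf_context(molecule: Molecule, basis: str = "sto-3g",
                      aux_basis: str | None = None, *,
                      conv_energy: float = 1e-11,
                      conv_commutator: float = 1e-9,
                      h_perturbation: tuple[np.ndarray, np.ndarray] | None = None,
                      guess=None, max_iter: int = 300) -> SCFContext:
    """Run UHF and package the converged context.

    ``h_perturbation`` adds per-spin one-electron terms to the core
    Hamiltonian (the finite-difference oracle's hook).  Non-convergence
    raises with the iteration trace attached.
    """
    xyz = molecule.coords_bohr
    bas = build_basis(molecule.symbols, xyz, basis)
    aux = build_aux_basis(molecule.symbols, xyz, bas)
    S = ig.overlap(bas)
    T = ig.kinetic(bas)
    V = ig.nuclear_attraction(bas, molecule.charges, xyz)
    h = T + V
    I = ig.eri_dense(bas)
    ha = hb = None
    if h_perturbation is not None:
        ha = h + h_perturbation[0]
        hb = h + h_perturbation[1]
    res: UHFResult = run_uhf(
        S, h, I, molecule.n_alpha, molecule.n_beta, molecule.nuclear_repulsion(),
        h_alpha=ha, h_beta=hb, conv_energy=conv_energy,
        conv_commutator=conv_commutator, guess=guess, max_iter=max_iter)
    ctx = SCFContext(
        molecule=molecule, basis=bas, aux_basis=aux, S=S, h=h, F=res.F,
        C=res.C, eps=res.eps, n_occ=res.n_occ, E_scf=res.energy,
        e_nuc=molecule.nuclear_repulsion(),
        h_spin=None if h_perturbation is None else (ha, hb),
        metadata={
            "basis": basis, "aux_basis": aux_basis or "auto-aux",
            "scf_iterations": res.iterations,
            "cartesian": True,
        },
        _eri=I)
    return ctx


def ao_eri_dense(scf: SCFContext) -> np.ndarray:
    """Dense AO ERI tensor (oracle input; guarded by an explicit size cap)."""
    if scf.nbf > DENSE_ERI_MAX_NBF:
        raise ValueError(
            f"dense ERI guard: {scf.nbf} basis functions > {DENSE_ERI_MAX_NBF}")
    if scf._eri is None:
        scf._eri = ig.eri_dense(scf.basis)
    return scf._eri


def fock_like_build(scf: SCFContext, D_alpha: np.ndarray, D_beta: np.ndarray):
    """Fock-like intermediate: two-electron build with density stand-ins."""
    return fock_like(ao_eri_dense(scf), D_alpha, D_beta)


@dataclass
class FermiContactOperator:
    nucleus: int
    H_FC: np.ndarray            # outer product of AO values at the nucleus
    ao_values: np.ndarray       # χ_μ(R_k)


def fermi_contact_integrals(scf: SCFContext, k: int) -> FermiContactOperator:
    """AO matrix of the Fermi-contact (point spin-density) operator at nucleus k."""
    if not 0 <= k < len(scf.molecule.symbols):
        raise IndexError(f"nucleus index {k} out of range")
    r = scf.molecule.coords_bohr[k]
    vals = ig.eval_basis(scf.basis, r[None, :])[:, 0]
    return FermiContactOperator(nucleus=k, H_FC=np.outer(vals, vals), ao_values=vals)


@dataclass
class RIFactors:
    """Three-index factors B with (μν|λσ) ≈ Σ_t B_t,μν B_t,λσ.

    Built robustly for attenuated metrics: fit coefficients in the requested
    metric, contracted against the Coulomb two-center matrix
    (B = V_C^{1/2} m^{-1} (m|μν)).
    """

    B: np.ndarray               # (naux, n, n)
    metric: str
    omega: float | None
    condition_number: float

    def reconstruct(self) -> np.ndarray:
        return np.einsum("tmn,tls->mnls", self.B, self.B, optimize=True)


def ri_factors(scf: SCFContext, metric: str = "coulomb",
               omega: float | None = None) -> RIFactors:
    """Density-fitting factors under the Coulomb or attenuated metric."""
    aux = scf.aux_basis
    V_c = ig.eri_2c(aux, "coulomb")
    if metric == "coulomb":
        m2, m3 = V_c, ig.eri_3c(scf.basis, aux, "coulomb")
    elif metric == "attenuated":
        if omega is None:
            raise ValueError("attenuated metric requires omega")
        kern = ("erfc", omega)
        m2 = ig.eri_2c(aux, kern)
        m3 = ig.eri_3c(scf.basis, aux, kern)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    n = scf.nbf
    e, U = np.linalg.eigh(m2)
    cond = abs(e).max() / max(abs(e).min(), 1e-300)
    keep = e > 1e-12 * abs(e).max()
    m2_inv = (U[:, keep] / e[keep]) @ U[:, keep].T
    C = m2_inv @ m3.reshape(len(e), -1)        # fit coefficients
    # robust half-factor: B = V_C^{1/2} C
    ev, Uv = np.linalg.eigh(V_c)
    ev = np.clip(ev, 0.0, None)
    V_half = (Uv * np.sqrt(ev)) @ Uv.T
    B = (V_half @ C).reshape(-1, n, n)
    B = 0.5 * (B + B.transpose(0, 2, 1))
    return RIFactors(B=B, metric=metric, omega=omega, condition_number=cond)


def collocate(scf: SCFContext, points) -> np.ndarray:
    """Basis values on arbitrary Cartesian points (bohr); (nbf, npoints)."""
    return ig.eval_basis(scf.basis, points)
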