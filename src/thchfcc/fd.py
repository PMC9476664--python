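"""Independent finite-difference oracle for the hyperfine derivative.

The spin-dependent Fermi-contact operator (+Q for α, -Q for β) is added to
the core Hamiltonian with strength ±λ; SCF and the dense Laplace MP2 energy
are re-converged at both displacements and the central difference
(E₊ - E₋)/2λ is converted to MHz with the same constants as the analytic
route.  The Laplace quadrature is fitted once at λ = 0 and frozen, matching
the analytic gradient which treats the quadrature as a fixed parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contractions import mp2_energy_laplace_dense
from .engine import Molecule, SCFContext, build_scf_context, fermi_contact_integrals
from .laplace import LaplaceQuadrature, quadrature_for
from .response import hfcc_prefactor_mhz


@dataclass
class FDResult:
    nucleus: int
    lam: float
    A_iso_scf: float
    A_iso_mp2: float

    @property
    def A_iso_total(self) -> float:
        return self.A_iso_scf + self.A_iso_mp2


def _perturbed_energies(molecule: Molecule, basis: str, Q: np.ndarray,
                        lam: float, quad: LaplaceQuadrature,
                        guess=None) -> tuple[float, float]:
    ctx = build_scf_context(
        molecule, basis, h_perturbation=(lam * Q, -lam * Q), guess=guess,
        conv_energy=1e-13, conv_commutator=1e-10)
    e2 = mp2_energy_laplace_dense(ctx, quad)
    return ctx.E_scf, e2


def fd_hfcc_oracle(molecule: Molecule, k: int, lam: float = 1e-5,
                   basis: str = "sto-3g", n_laplace: int = 7,
                   scf: SCFContext | None = None,
                   quad: LaplaceQuadrature | None = None) -> FDResult:
    """Central-difference A_iso for nucleus ``k`` (SCF and MP2 parts)."""
    if scf is None:
        scf = build_scf_context(molecule, basis, conv_energy=1e-13,
                                conv_commutator=1e-10)
    if quad is None:
        quad = quadrature_for(scf, K=n_laplace)
    # widen the fit interval bookkeeping: perturbed spectra move slightly
    quad = LaplaceQuadrature(quad.weights, quad.exponents,
                             quad.x_min * 0.5, quad.x_max * 2.0,
                             quad.max_rel_error)
    Q = fermi_contact_integrals(scf, k).H_FC
    guess = (scf.P_occ(0), scf.P_occ(1))
    ep_scf, ep_2 = _perturbed_energies(molecule, basis, Q, +lam, quad, guess)
    em_scf, em_2 = _perturbed_energies(molecule, basis, Q, -lam, quad, guess)
    _, g = _gfac(scf, k)
    pref = hfcc_prefactor_mhz(scf, g)
    return FDResult(nucleus=k, lam=lam,
                    A_iso_scf=pref * (ep_scf - em_scf) / (2 * lam),
                    A_iso_mp2=pref * (ep_2 - em_2) / (2 * lam))


def _gfac(scf, k):
    from .constants import nuclear_g_factor
    return nuclear_g_factor(scf.molecule.symbols[k])


def fd_plateau_scan(molecule: Molecule, k: int, lams=(1e-4, 1e-5, 1e-6),
                    basis: str = "sto-3g", n_laplace: int = 7):
    """A_iso(λ) over a λ-scan; plateau agreement validates the step size."""
    scf = build_scf_context(molecule, basis, conv_energy=1e-13,
                            conv_commutator=1e-10)
    quad = quadrature_for(scf, K=n_laplace)
    return [fd_hfcc_oracle(molecule, k, lam, basis, scf=scf, quad=quad)
            for lam in lams]
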