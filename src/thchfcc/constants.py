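"""Physical constants (CODATA 2018) and nuclear g-factors for hyperfine couplings.

The isotropic (Fermi-contact) hyperfine coupling constant of nucleus ``k`` is

    A_iso(k) [MHz] = (2/3) * mu0 * g_e * mu_B * g_k * mu_N
                     / (h * a0^3) * rho_s(R_k) / (2 <S_z>)

with ``rho_s(R_k)`` the spin density at the nucleus in atomic units (a0^-3)
and ``2<S_z> = N_alpha - N_beta``.  The numerical prefactor is assembled here
once so that the analytic-derivative route and the finite-difference oracle
use identical unit conversion.
"""

from __future__ import annotations

import math

# CODATA 2018
MU0 = 1.25663706212e-6        # N A^-2
G_E = 2.00231930436256        # electron g-factor (magnitude)
MU_B = 9.2740100783e-24       # J T^-1
MU_N = 5.0507837461e-27       # J T^-1
PLANCK_H = 6.62607015e-34     # J s
BOHR_M = 5.29177210903e-11    # m
HARTREE_J = 4.3597447222071e-18

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903

#: MHz per (g_N * spin density in a0^-3), for 2<S_z> = 1
FC_PREFACTOR_MHZ = (
    (2.0 / 3.0) * MU0 * G_E * MU_B * MU_N / (PLANCK_H * BOHR_M**3) / 1.0e6
)

# Nuclear g-factors of the most abundant magnetic isotope per element
# (g_k = mu_k / (mu_N * I), signed).
ISOTOPE_G_FACTORS: dict[str, tuple[str, float]] = {
    "H": ("1H", 5.58569468),
    "B": ("11B", 1.7924326),
    "C": ("13C", 1.40482),
    "N": ("14N", 0.40376100),
    "O": ("17O", -0.757516),
    "F": ("19F", 5.257736),
    "P": ("31P", 2.26320),
}

ELEMENT_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7,
    "O": 8, "F": 9, "Ne": 10, "P": 15, "S": 16,
}


def nuclear_g_factor(element: str) -> tuple[str, float]:
    """Return (isotope label, g-factor) for ``element``.

    Raises ``KeyError`` listing the available isotopes for unknown elements.
    """
    try:
        return ISOTOPE_G_FACTORS[element]
    except KeyError:
        raise KeyError(
            f"no g-factor tabulated for element {element!r}; "
            f"available: {sorted(ISOTOPE_G_FACTORS)}"
        ) from None


def _selftest() -> float:  # pragma: no cover - sanity helper
    # hydrogen atom, exact spin density 1/pi -> ~1422.7 MHz
    return FC_PREFACTOR_MHZ * 5.58569468 / math.pi
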