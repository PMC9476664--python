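"""Gaussian basis sets: embedded orbital bases and generated auxiliary bases.

Two orbital bases are shipped as plain data: the minimal STO-3G set and the
split-valence 6-31G set (s/p elements only).  Density-fitting auxiliary bases
are generated per element as even-tempered s/p/d expansions spanning the
exponent range of the orbital-product space; named RI sets are not bundled.

All shells are Cartesian.  Contraction coefficients refer to normalized
primitives of the shell's angular momentum; the contracted function is
re-normalized to unit self-overlap for the (l,0,0) component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import BOHR_PER_ANGSTROM, ELEMENT_NUMBERS

# exponents / coefficients: tuples of (l, [(exp, coef), ...])
_STO3G = {
    "H": [(0, [(3.42525091, 0.15432897), (0.62391373, 0.53532814), (0.16885540, 0.44463454)])],
    "B": [
        (0, [(48.7911130, 0.15432897), (8.8873622, 0.53532814), (2.4052670, 0.44463454)]),
        (0, [(2.2369561, -0.09996723), (0.5198205, 0.39951283), (0.1690618, 0.70011547)]),
        (1, [(2.2369561, 0.15591627), (0.5198205, 0.60768372), (0.1690618, 0.39195739)]),
    ],
    "C": [
        (0, [(71.6168370, 0.15432897), (13.0450960, 0.53532814), (3.5305122, 0.44463454)]),
        (0, [(2.9412494, -0.09996723), (0.6834831, 0.39951283), (0.2222899, 0.70011547)]),
        (1, [(2.9412494, 0.15591627), (0.6834831, 0.60768372), (0.2222899, 0.39195739)]),
    ],
    "N": [
        (0, [(99.1061690, 0.15432897), (18.0523120, 0.53532814), (4.8856602, 0.44463454)]),
        (0, [(3.7804559, -0.09996723), (0.8784966, 0.39951283), (0.2857144, 0.70011547)]),
        (1, [(3.7804559, 0.15591627), (0.8784966, 0.60768372), (0.2857144, 0.39195739)]),
    ],
    "O": [
        (0, [(130.7093200, 0.15432897), (23.8088610, 0.53532814), (6.4436083, 0.44463454)]),
        (0, [(5.0331513, -0.09996723), (1.1695961, 0.39951283), (0.3803890, 0.70011547)]),
        (1, [(5.0331513, 0.15591627), (1.1695961, 0.60768372), (0.3803890, 0.39195739)]),
    ],
    "F": [
        (0, [(166.6791300, 0.15432897), (30.3608120, 0.53532814), (8.2168207, 0.44463454)]),
        (0, [(6.4648032, -0.09996723), (1.5022812, 0.39951283), (0.4885885, 0.70011547)]),
        (1, [(6.4648032, 0.15591627), (1.5022812, 0.60768372), (0.4885885, 0.39195739)]),
    ],
}

_631G = {
    "H": [
        (0, [(18.7311370, 0.03349460), (2.8253937, 0.23472695), (0.6401217, 0.81375733)]),
        (0, [(0.1612778, 1.0)]),
    ],
    "C": [
        (0, [(3047.5249, 0.0018347), (457.36951, 0.0140373), (103.94869, 0.0688426),
             (29.210155, 0.2321844), (9.2866630, 0.4679413), (3.1639270, 0.3623120)]),
        (0, [(7.8682724, -0.1193324), (1.8812885, -0.1608542), (0.5442493, 1.1434564)]),
        (1, [(7.8682724, 0.0689991), (1.8812885, 0.3164240), (0.5442493, 0.7443083)]),
        (0, [(0.1687144, 1.0)]),
        (1, [(0.1687144, 1.0)]),
    ],
    "N": [
        (0, [(4173.5110, 0.0018348), (627.45790, 0.0139950), (142.90210, 0.0685870),
             (40.234330, 0.2322410), (12.820210, 0.4690700), (4.3904370, 0.3604550)]),
        (0, [(11.626358, -0.1149610), (2.7162800, -0.1691180), (0.7722180, 1.1458520)]),
        (1, [(11.626358, 0.0675800), (2.7162800, 0.3239070), (0.7722180, 0.7408950)]),
        (0, [(0.2120313, 1.0)]),
        (1, [(0.2120313, 1.0)]),
    ],
    "O": [
        (0, [(5484.6717, 0.0018311), (825.23495, 0.0139501), (188.04696, 0.0684451),
             (52.964500, 0.2327143), (16.897570, 0.4701930), (5.7996353, 0.3585209)]),
        (0, [(15.539616, -0.1107775), (3.5999336, -0.1480263), (1.0137618, 1.1307670)]),
        (1, [(15.539616, 0.0708743), (3.5999336, 0.3397528), (1.0137618, 0.7271586)]),
        (0, [(0.2700058, 1.0)]),
        (1, [(0.2700058, 1.0)]),
    ],
}

_BASIS_LIBRARY = {"sto-3g": _STO3G, "6-31g": _631G}


def cartesian_components(l: int) -> list[tuple[int, int, int]]:
    """Cartesian (lx, ly, lz) tuples for angular momentum ``l`` in fixed order."""
    return [
        (lx, ly, l - lx - ly)
        for lx in range(l, -1, -1)
        for ly in range(l - lx, -1, -1)
    ]


def _double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def primitive_norm(alpha: float, lx: int, ly: int, lz: int) -> float:
    """Normalization constant of a Cartesian primitive Gaussian."""
    l = lx + ly + lz
    num = (2.0 * alpha / np.pi) ** 0.75 * (4.0 * alpha) ** (l / 2.0)
    den = np.sqrt(
        _double_factorial(2 * lx - 1)
        * _double_factorial(2 * ly - 1)
        * _double_factorial(2 * lz - 1)
    )
    return num / den


@dataclass
class Shell:
    """One contracted Cartesian Gaussian shell."""

    center: np.ndarray          # (3,) bohr
    l: int
    exps: np.ndarray            # (nprim,)
    coefs: np.ndarray           # (nprim,) includes primitive norms for (l,0,0)
    atom: int = -1

    @property
    def ncomp(self) -> int:
        return (self.l + 1) * (self.l + 2) // 2

    def component_coefs(self, comp: tuple[int, int, int]) -> np.ndarray:
        """Contraction coefficients re-scaled for Cartesian component ``comp``."""
        lx, ly, lz = comp
        scale = np.array(
            [primitive_norm(a, lx, ly, lz) / primitive_norm(a, self.l, 0, 0)
             for a in self.exps]
        )
        return self.coefs * scale


def _normalize_shell(shell: Shell) -> None:
    # unit self-overlap of the (l,0,0) component
    from .integrals import contracted_overlap_self

    s = contracted_overlap_self(shell)
    shell.coefs = shell.coefs / np.sqrt(s)


@dataclass
class BasisSet:
    shells: list[Shell]
    name: str = ""
    labels: list[str] = field(default_factory=list)  # per basis function

    @property
    def nbf(self) -> int:
        return sum(sh.ncomp for sh in self.shells)

    def shell_slices(self) -> list[tuple[int, int]]:
        out, off = [], 0
        for sh in self.shells:
            out.append((off, off + sh.ncomp))
            off += sh.ncomp
        return out

    def function_atoms(self) -> np.ndarray:
        return np.concatenate([[sh.atom] * sh.ncomp for sh in self.shells])


def build_basis(symbols, coords_bohr, name: str) -> BasisSet:
    """Construct a :class:`BasisSet` for atoms at ``coords_bohr`` (a.u.)."""
    key = name.lower()
    if key not in _BASIS_LIBRARY:
        raise ValueError(f"unknown basis {name!r}; available: {sorted(_BASIS_LIBRARY)}")
    lib = _BASIS_LIBRARY[key]
    shells: list[Shell] = []
    labels: list[str] = []
    for iatom, (sym, xyz) in enumerate(zip(symbols, coords_bohr)):
        if sym not in lib:
            raise ValueError(f"basis {name!r} has no data for element {sym!r}")
        for l, prims in lib[sym]:
            exps = np.array([p[0] for p in prims])
            coefs = np.array(
                [c * primitive_norm(a, l, 0, 0) for a, c in prims]
            )
            sh = Shell(center=np.asarray(xyz, float), l=l, exps=exps,
                       coefs=coefs, atom=iatom)
            _normalize_shell(sh)
            shells.append(sh)
            for comp in cartesian_components(l):
                labels.append(f"{sym}{iatom}:{'spdfg'[l]}{''.join(map(str, comp))}")
    return BasisSet(shells=shells, name=key, labels=labels)


def build_aux_basis(symbols, coords_bohr, orbital_basis: BasisSet,
                    beta: float = 2.5, name: str = "auto-aux") -> BasisSet:
    """Even-tempered auxiliary basis spanning the orbital product space.

    For each element the primitive exponent range [a_min, a_max] of the
    orbital basis is collected; the auxiliary expansion covers
    [a_min, 2 a_max] geometrically with ratio ``beta`` for l = 0, 1 and a
    sparser d set.  This is the usual automatic even-tempered construction
    used when no optimized fitting set is available.
    """
    # exponent ranges per element
    ranges: dict[str, tuple[float, float]] = {}
    for sh in orbital_basis.shells:
        sym = symbols[sh.atom]
        lo, hi = ranges.get(sym, (np.inf, 0.0))
        ranges[sym] = (min(lo, sh.exps.min()), max(hi, sh.exps.max()))

    shells: list[Shell] = []
    labels: list[str] = []
    for iatom, (sym, xyz) in enumerate(zip(symbols, coords_bohr)):
        a_min, a_max = ranges[sym]
        for l, (lo, hi, ratio) in enumerate(
            [(0.5 * a_min, 2.2 * a_max, beta * 0.80),
             (0.6 * a_min, 1.6 * a_max, beta * 0.92),
             (0.8 * a_min, 1.0 * a_max, beta * 1.12)]
        ):
            n = max(1, int(np.ceil(np.log(hi / lo) / np.log(ratio))) + 1)
            exps = lo * ratio ** np.arange(n)
            for a in exps:
                sh = Shell(center=np.asarray(xyz, float), l=l,
                           exps=np.array([a]),
                           coefs=np.array([primitive_norm(a, l, 0, 0)]),
                           atom=iatom)
                _normalize_shell(sh)
                shells.append(sh)
                for comp in cartesian_components(l):
                    labels.append(f"{sym}{iatom}:aux-{'spdfg'[l]}{''.join(map(str, comp))}")
    return BasisSet(shells=shells, name=name, labels=labels)


def angstrom_to_bohr(coords) -> np.ndarray:
    return np.asarray(coords, float) * BOHR_PER_ANGSTROM


def nuclear_charge(symbol: str) -> int:
    return ELEMENT_NUMBERS[symbol]
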