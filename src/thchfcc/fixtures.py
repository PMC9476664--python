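"""Small open-shell (and closed-shell control) fixture molecules.

Geometries use standard experimental/idealized structural parameters; the
n-propyl radical is the n = 3 member of the linear alkyl series at desk
scale.  All fixtures converge with default SCF settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import Molecule


@dataclass
class Fixture:
    name: str
    molecule: Molecule
    tags: tuple[str, ...] = field(default_factory=tuple)


def _ch3() -> Molecule:
    # planar D3h, C-H 1.079 Å
    r = 1.079
    ang = np.deg2rad([90.0, 210.0, 330.0])
    coords = [[0.0, 0.0, 0.0]] + [
        [r * np.cos(a), r * np.sin(a), 0.0] for a in ang]
    return Molecule(symbols=["C", "H", "H", "H"], coords=coords,
                    multiplicity=2, name="CH3")


def _nh2() -> Molecule:
    # N-H 1.024 Å, H-N-H 103.4 deg
    r, half = 1.024, np.deg2rad(103.4 / 2)
    return Molecule(
        symbols=["N", "H", "H"],
        coords=[[0.0, 0.0, 0.0],
                [r * np.sin(half), 0.0, -r * np.cos(half)],
                [-r * np.sin(half), 0.0, -r * np.cos(half)]],
        multiplicity=2, name="NH2")


def _h2o() -> Molecule:
    r, half = 0.9572, np.deg2rad(104.52 / 2)
    return Molecule(
        symbols=["O", "H", "H"],
        coords=[[0.0, 0.0, 0.0],
                [r * np.sin(half), 0.0, -r * np.cos(half)],
                [-r * np.sin(half), 0.0, -r * np.cos(half)]],
        multiplicity=1, name="H2O")


def _propyl() -> Molecule:
    # n-propyl radical CH2-CH2-CH3 (idealized bond lengths/angles)
    coords = [
        [0.000, 0.000, 0.000],     # C1 (radical center)
        [1.495, 0.000, 0.000],     # C2
        [2.068, 1.419, 0.000],     # C3
        [-0.540, 0.935, 0.000],    # H on C1
        [-0.540, -0.935, 0.000],   # H on C1
        [1.890, -0.580, 0.840],    # H on C2
        [1.890, -0.580, -0.840],   # H on C2
        [1.252, 2.141, 0.000],     # H on C3
        [2.681, 1.563, 0.890],     # H on C3
        [2.681, 1.563, -0.890],    # H on C3
    ]
    return Molecule(symbols=["C", "C", "C", "H", "H", "H", "H", "H", "H", "H"],
                    coords=coords, multiplicity=2, name="C3H7")


def fixtures() -> list[Fixture]:
    return [
        Fixture("H", Molecule(["H"], [[0.0, 0.0, 0.0]], multiplicity=2,
                              name="H"), tags=("tiny", "radical")),
        Fixture("OH", Molecule(["O", "H"], [[0.0, 0.0, 0.0],
                                            [0.0, 0.0, 0.970]],
                               multiplicity=2, name="OH"),
                tags=("tiny", "radical")),
        Fixture("CH3", _ch3(), tags=("small", "radical")),
        Fixture("NH2", _nh2(), tags=("small", "radical")),
        Fixture("H2O", _h2o(), tags=("small", "closed-shell")),
        Fixture("C3H7", _propyl(), tags=("medium", "radical", "alkyl")),
    ]


def get_fixture(name: str) -> Fixture:
    for f in fixtures():
        if f.name.lower() == name.lower():
            return f
    raise KeyError(f"no fixture {name!r}; available: "
                   f"{[f.name for f in fixtures()]}")
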