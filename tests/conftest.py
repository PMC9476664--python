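"""Shared, lazily built and session-cached quantum-chemistry objects.

Building an SCF context dominates test runtime, so contexts, quadratures,
dense R oracles and THC factorizations are cached per (fixture, basis) key
and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from thchfcc import contractions as ct
from thchfcc.engine import build_scf_context, ri_factors
from thchfcc.fixtures import get_fixture
from thchfcc.laplace import quadrature_for
from thchfcc.thc import build_thc


class Cache:
    def __init__(self):
        self._store = {}

    def scf(self, name: str, basis: str = "sto-3g"):
        key = ("scf", name, basis)
        if key not in self._store:
            self._store[key] = build_scf_context(
                get_fixture(name).molecule, basis,
                conv_energy=1e-13, conv_commutator=1e-10)
        return self._store[key]

    def quad(self, name: str, basis: str = "sto-3g", K: int = 7):
        key = ("quad", name, basis, K)
        if key not in self._store:
            self._store[key] = quadrature_for(self.scf(name, basis), K=K)
        return self._store[key]

    def rdense(self, name: str, basis: str = "sto-3g", K: int = 7):
        key = ("rdense", name, basis, K)
        if key not in self._store:
            scf = self.scf(name, basis)
            quad = self.quad(name, basis, K)
            self._store[key] = [ct.r_dense_oracle(scf, quad, k)
                                for k in range(quad.n_points)]
        return self._store[key]

    def ri(self, name: str, basis: str = "sto-3g", metric="attenuated",
           omega=0.1):
        key = ("ri", name, basis, metric, omega)
        if key not in self._store:
            self._store[key] = ri_factors(self.scf(name, basis), metric,
                                          omega=omega)
        return self._store[key]

    def thc(self, name: str, basis: str = "sto-3g", ratio: float = 3.0):
        key = ("thc", name, basis, ratio)
        if key not in self._store:
            self._store[key] = build_thc(self.scf(name, basis),
                                         ri=self.ri(name, basis),
                                         target_ratio=ratio)
        return self._store[key]


@pytest.fixture(scope="session")
def cache():
    return Cache()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
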