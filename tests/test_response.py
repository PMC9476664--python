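"""Response machinery: Y objects, Fock-like builds, CPSCF, relaxed density
and the assembled hyperfine derivative."""

import numpy as np
import pytest
import scipy.linalg as sla
from hypothesis import given, settings, strategies as st

from thchfcc import contractions as ct
from thchfcc.engine import ao_eri_dense, fermi_contact_integrals
from thchfcc.response import (build_fock_like, compute_hfcc, cpscf_apply,
                              relaxed_density, solve_cpscf, solve_Y)


class TestSolveY:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.05, 8.0))
    def test_matches_scipy_frechet_derivative(self, seed, scale):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        A = rng.normal(size=(n, n)) * scale
        B = rng.normal(size=(n, n))
        sol = solve_Y(A, B)
        E_ref, Y_ref = sla.expm_frechet(A, B)
        ref = max(1.0, np.abs(Y_ref).max())
        assert np.abs(sol.Y - Y_ref).max() < 1e-10 * ref
        assert np.abs(sol.expA - E_ref).max() < 1e-11 * max(1.0, np.abs(E_ref).max())
        assert sol.residual < 1e-10

    def test_zero_direction(self, rng):
        A = rng.normal(size=(5, 5))
        sol = solve_Y(A, np.zeros((5, 5)))
        assert np.abs(sol.Y).max() == 0.0

    def test_linearity_in_B(self, rng):
        A = rng.normal(size=(6, 6))
        B = rng.normal(size=(6, 6))
        assert np.allclose(solve_Y(A, 3.0 * B).Y, 3.0 * solve_Y(A, B).Y,
                           rtol=1e-12)

    def test_two_by_two_against_quadrature_oracle(self):
        """Hand system vs direct numerical evaluation of ∫e^{sA}Be^{(1-s)A}ds."""
        from scipy.integrate import quad as spquad

        A = np.array([[0.3, 1.1], [0.0, -0.4]])
        B = np.array([[1.0, 2.0], [3.0, 4.0]])
        ref = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                ref[i, j] = spquad(
                    lambda s: (sla.expm(s * A) @ B @ sla.expm((1 - s) * A))[i, j],
                    0.0, 1.0, epsabs=1e-13, epsrel=1e-13)[0]
        assert np.abs(solve_Y(A, B).Y - ref).max() < 1e-10

    def test_empty_matrix(self):
        sol = solve_Y(np.zeros((0, 0)), np.zeros((0, 0)))
        assert sol.Y.shape == (0, 0)


class TestFockLike:
    def test_zero_density(self, cache):
        scf = cache.scf("OH")
        Ga, Gb = build_fock_like(scf, np.zeros((scf.nbf,) * 2),
                                 np.zeros((scf.nbf,) * 2))
        assert np.abs(Ga).max() == 0.0 and np.abs(Gb).max() == 0.0

    def test_scf_density_reproduces_two_electron_fock(self, cache):
        scf = cache.scf("NH2")
        Ga, Gb = build_fock_like(scf, scf.P_occ(0), scf.P_occ(1))
        assert np.abs(scf.h + Ga - scf.F[0]).max() < 1e-9
        assert np.abs(scf.h + Gb - scf.F[1]).max() < 1e-9

    def test_linearity(self, cache, rng):
        scf = cache.scf("OH")
        n = scf.nbf
        D1 = rng.normal(size=(n, n)); D1 = D1 + D1.T
        D2 = rng.normal(size=(n, n)); D2 = D2 + D2.T
        G1 = build_fock_like(scf, D1, D1)
        G2 = build_fock_like(scf, D2, D2)
        G12 = build_fock_like(scf, D1 + D2, D1 + D2)
        for a, b, c in zip(G1, G2, G12):
            assert np.abs(a + b - c).max() < 1e-10


class TestCPSCF:
    def test_zero_rhs_gives_zero(self, cache):
        scf = cache.scf("CH3")
        rhs = tuple(np.zeros((scf.nbf - scf.n_occ[s], scf.n_occ[s]))
                    for s in (0, 1))
        z, hist = solve_cpscf(scf, rhs, conv=1e-8)
        assert all(np.abs(z[s]).max() == 0.0 for s in (0, 1))

    def test_solution_satisfies_stationarity(self, cache, rng):
        scf = cache.scf("NH2")
        rhs = tuple(rng.normal(size=(scf.nbf - scf.n_occ[s], scf.n_occ[s]))
                    for s in (0, 1))
        conv = 1e-9
        z, hist = solve_cpscf(scf, rhs, conv=conv)
        Az = cpscf_apply(scf, z)
        for s in (0, 1):
            assert np.abs(Az[s] - rhs[s]).max() < conv

    def test_default_convergence_threshold(self):
        import inspect

        sig = inspect.signature(solve_cpscf)
        assert sig.parameters["conv"].default == 1e-4


class TestRelaxedDensity:
    def test_one_electron_mp2_density_vanishes(self, cache):
        scf = cache.scf("H")
        quad = cache.quad("H")
        rel = relaxed_density(scf, quad, cache.rdense("H"), cpscf_conv=1e-9)
        for s in (0, 1):
            assert np.abs(rel.D_mp2[s]).max() < 1e-12

    def test_density_is_symmetric(self, cache):
        scf = cache.scf("OH")
        rel = relaxed_density(scf, cache.quad("OH"), cache.rdense("OH"),
                              cpscf_conv=1e-9)
        for s in (0, 1):
            assert np.abs(rel.D_mp2[s] - rel.D_mp2[s].T).max() < 1e-12

    def test_spin_trace_antisymmetry_under_spin_flip(self, cache):
        """Swapping the α and β SCF solutions negates the spin-density trace."""
        import copy

        scf = cache.scf("NH2")
        quad = cache.quad("NH2")
        rel = relaxed_density(scf, quad, cache.rdense("NH2"), cpscf_conv=1e-10)
        flipped = copy.copy(scf)
        flipped.C = (scf.C[1], scf.C[0])
        flipped.eps = (scf.eps[1], scf.eps[0])
        flipped.n_occ = (scf.n_occ[1], scf.n_occ[0])
        flipped.F = (scf.F[1], scf.F[0])
        rp_f = [ct.r_dense_oracle(flipped, quad, k)
                for k in range(quad.n_points)]
        rel_f = relaxed_density(flipped, quad, rp_f, cpscf_conv=1e-10)
        fc = fermi_contact_integrals(scf, 0)
        tr = np.sum(fc.H_FC * ((scf.P_occ(0) + rel.D_mp2[0])
                               - (scf.P_occ(1) + rel.D_mp2[1])))
        tr_f = np.sum(fc.H_FC * ((flipped.P_occ(0) + rel_f.D_mp2[0])
                                 - (flipped.P_occ(1) + rel_f.D_mp2[1])))
        assert tr_f == pytest.approx(-tr, rel=1e-8)


class TestComputeHFCC:
    def test_closed_shell_couplings_vanish(self, cache):
        scf = cache.scf("H2O")
        rel = relaxed_density(scf, cache.quad("H2O"), cache.rdense("H2O"),
                              cpscf_conv=1e-8)
        for k in range(3):
            res = compute_hfcc(scf, rel, k)
            assert abs(res.A_iso_total) < 1e-6

    def test_hydrogen_atom_pointwise_density(self, cache):
        from thchfcc.engine import collocate
        from thchfcc.response import hfcc_prefactor_mhz

        scf = cache.scf("H")
        res = compute_hfcc(scf, None, 0)
        assert res.A_iso_mp2 == 0.0
        v = collocate(scf, scf.molecule.coords_bohr[0][None, :])[:, 0]
        rho = float(v @ (scf.P_occ(0) - scf.P_occ(1)) @ v)
        assert res.A_iso_scf == pytest.approx(
            hfcc_prefactor_mhz(scf, res.g_factor) * rho, rel=1e-12)

    def test_unknown_isotope_lists_alternatives(self, cache):
        import copy

        scf = copy.copy(cache.scf("H"))
        from thchfcc.engine import Molecule
        scf.molecule = Molecule(["He"], [[0.0, 0.0, 0.0]], multiplicity=1)
        with pytest.raises(KeyError, match="available"):
            compute_hfcc(scf, None, 0)

    def test_total_is_sum_of_parts(self, cache):
        scf = cache.scf("OH")
        rel = relaxed_density(scf, cache.quad("OH"), cache.rdense("OH"),
                              cpscf_conv=1e-8)
        res = compute_hfcc(scf, rel, 1)
        assert res.A_iso_total == res.A_iso_scf + res.A_iso_mp2
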