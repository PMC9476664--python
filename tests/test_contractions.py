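"""Contraction engine: Laplace energies, R oracles, THC Coulomb/exchange
algorithms and the screened exchange energy."""

import numpy as np
import pytest

from thchfcc import contractions as ct
from thchfcc.blocking import NBConfig
from thchfcc.engine import ao_eri_dense
from thchfcc.laplace import (LaplaceQuadrature, build_pseudodensities,
                             cholesky_pseudo_mos, quadrature_for)


class TestLaplaceEnergy:
    def test_one_electron_system_is_zero(self, cache):
        scf = cache.scf("H")
        quad = cache.quad("H")
        assert ct.mp2_energy_laplace_dense(scf, quad) == pytest.approx(0.0,
                                                                       abs=1e-14)
        assert ct.mp2_energy_canonical(scf) == pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize("name", ["OH", "CH3", "NH2", "H2O"])
    def test_matches_canonical_within_quadrature_error(self, name, cache):
        scf = cache.scf(name)
        quad = cache.quad(name)
        e_can, bound = ct.mp2_energy_canonical(scf, return_weight=True)
        e_lap = ct.mp2_energy_laplace_dense(scf, quad)
        assert abs(e_lap - e_can) <= quad.max_rel_error * bound

    def test_weight_linearity(self, cache):
        scf = cache.scf("OH")
        quad = cache.quad("OH")
        doubled = LaplaceQuadrature(2.0 * quad.weights, quad.exponents,
                                    quad.x_min, quad.x_max,
                                    quad.max_rel_error)
        e1 = ct.mp2_energy_laplace_dense(scf, quad)
        e2 = ct.mp2_energy_laplace_dense(scf, doubled)
        assert e2 == pytest.approx(2.0 * e1, rel=1e-12)


class TestDenseROracle:
    def test_gradient_property_euler_identity(self, cache):
        """Σ_η Tr(R̲P̲)+Tr(R̅P̅) = 4 e_κ (multilinearity of the energy)."""
        scf = cache.scf("NH2")
        quad = cache.quad("NH2")
        I = ao_eri_dense(scf)
        for k in (0, 4):
            pair = build_pseudodensities(scf, quad, k)
            ek = ct.laplace_point_energy(I, pair)
            R = ct.r_dense_oracle(scf, quad, k, pair=pair)
            tot = sum(np.sum(R.R_occ[s] * pair.P_occ[s])
                      + np.sum(R.R_virt[s] * pair.P_virt[s]) for s in (0, 1))
            assert tot == pytest.approx(4.0 * ek, rel=1e-10)

    def test_r_is_derivative_of_point_energy(self, cache):
        scf = cache.scf("CH3")
        quad = cache.quad("CH3")
        I = ao_eri_dense(scf)
        pair = build_pseudodensities(scf, quad, 3)
        R = ct.r_dense_oracle(scf, quad, 3, pair=pair)
        h = 1e-6
        base = pair.P_occ[0].copy()
        for idx in [(0, 0), (2, 5)]:
            Pp = base.copy(); Pp[idx] += h
            Pm = base.copy(); Pm[idx] -= h
            pair.P_occ = (Pp, pair.P_occ[1])
            ep = ct.laplace_point_energy(I, pair)
            pair.P_occ = (Pm, pair.P_occ[1])
            em = ct.laplace_point_energy(I, pair)
            pair.P_occ = (base, pair.P_occ[1])
            assert (ep - em) / (2 * h) == pytest.approx(R.R_occ[0][idx],
                                                        abs=5e-9)

    def test_zero_pseudodensities_give_zero(self, cache):
        scf = cache.scf("OH")
        quad = cache.quad("OH")
        pair = build_pseudodensities(scf, quad, 0)
        n = scf.nbf
        pair.P_occ = (np.zeros((n, n)), np.zeros((n, n)))
        pair.P_virt = (np.zeros((n, n)), np.zeros((n, n)))
        R = ct.r_dense_oracle(scf, quad, 0, pair=pair)
        for s in (0, 1):
            assert np.abs(R.R_occ[s]).max() == 0.0
            assert np.abs(R.R_virt[s]).max() == 0.0

    def test_closed_shell_spin_symmetry(self, cache):
        scf = cache.scf("H2O")
        quad = cache.quad("H2O")
        R = ct.r_dense_oracle(scf, quad, 2)
        assert np.abs(R.R_occ[0] - R.R_occ[1]).max() < 1e-10
        assert np.abs(R.R_virt[0] - R.R_virt[1]).max() < 1e-10

    def test_ri_cdd_second_oracle_agrees(self, cache):
        scf = cache.scf("CH3")
        quad = cache.quad("CH3")
        Rd = ct.r_dense_oracle(scf, quad, 2)
        Rri = ct.r_ri_oracle(scf, cache.ri("CH3").B, quad, 2)
        for s in (0, 1):
            assert np.abs(Rd.R_occ[s] - Rri.R_occ[s]).max() < 1e-4
            assert np.abs(Rd.R_virt[s] - Rri.R_virt[s]).max() < 1e-4

    def test_coulomb_exchange_partition_sums_to_total(self, cache):
        scf = cache.scf("NH2")
        quad = cache.quad("NH2")
        Rall = ct.r_dense_oracle(scf, quad, 1, parts="both")
        Rc = ct.r_dense_oracle(scf, quad, 1, parts="coulomb")
        Rx = ct.r_dense_oracle(scf, quad, 1, parts="exchange")
        for s in (0, 1):
            assert np.abs(Rc.R_occ[s] + Rx.R_occ[s]
                          - Rall.R_occ[s]).max() < 1e-12
            assert np.abs(Rc.R_virt[s] + Rx.R_virt[s]
                          - Rall.R_virt[s]).max() < 1e-12


class TestGridPseudoDensities:
    def test_gram_structure(self, cache, rng):
        Xo = (rng.normal(size=(3, 10)), rng.normal(size=(2, 10)))
        Xv = (rng.normal(size=(5, 10)), rng.normal(size=(6, 10)))
        gp = ct.grid_pseudodensities(Xo, Xv, 0)
        for s in (0, 1):
            assert np.linalg.eigvalsh(gp.A[s]).min() > -1e-12
            assert np.trace(gp.A[s]) == pytest.approx(np.sum(Xo[s]**2),
                                                      rel=1e-12)
        single = ct.grid_pseudodensities((Xo[0][:1], Xo[1]), Xv, 0)
        assert np.linalg.matrix_rank(single.A[0], tol=1e-10) == 1


class TestCoulombTHC:
    def test_precontraction_matches_unfactorized_kernel(self, cache, rng):
        from thchfcc.thc import factorize_Z

        n = 30
        G = rng.normal(size=(n, n))
        Z = G @ G.T  # strictly PSD kernel so Λ is exact
        Lam, _ = factorize_Z(Z)
        A = rng.normal(size=(n, n)); A = A @ A.T
        B = rng.normal(size=(n, n)); B = B @ B.T
        D = ct.coulomb_precontraction(A, B, Lam)
        D_ref = Z @ (A * B) @ Z
        assert np.abs(D - D_ref).max() < 1e-10 * np.abs(D_ref).max()

    def test_zero_and_linearity(self, cache, rng):
        n = 8
        X = rng.normal(size=(5, n))
        A = rng.normal(size=(n, n)); A = A @ A.T
        B = rng.normal(size=(n, n)); B = B @ B.T
        zero = np.zeros((n, n))
        ro, rv = ct.coulomb_R(zero, zero, X, A, B)
        assert np.abs(ro).max() == 0.0 and np.abs(rv).max() == 0.0
        ro1, rv1 = ct.coulomb_R(A, B, X, A, B)
        ro2, rv2 = ct.coulomb_R(3 * A, 3 * B, X, A, B)
        assert np.allclose(ro2, 3 * ro1) and np.allclose(rv2, 3 * rv1)


class TestExchangeTHC:
    def test_matches_grid_einsum_oracle(self, rng):
        """j-batched E/F accumulation equals the literal contraction."""
        ng, ro, rv, nbf = 14, 4, 6, 5
        Xo = rng.normal(size=(ro, ng))
        Xv = rng.normal(size=(rv, ng))
        Z = rng.normal(size=(ng, ng)); Z = 0.5 * (Z + Z.T)
        X = rng.normal(size=(nbf, ng))
        A = Xo.T @ Xo
        B = Xv.T @ Xv
        # ∂K/∂A and ∂K/∂B by explicit index sums
        dKdA = 2 * np.einsum("PQ,pq,Pq,Qq,Qp->Pp", Z, Z, B, A, B,
                             optimize=True)
        dKdB = 2 * np.einsum("xQ,Qy,QR,xR,Ry->xy", Z, A, B, A, Z,
                             optimize=True)
        Ro_ref = X @ dKdA @ X.T
        Rv_ref = X @ (0.5 * (dKdB + dKdB.T)) @ X.T
        ro_x, rv_x = ct.exchange_R(Xo, Xv, Z, X, nb=None)
        assert np.abs(2 * ro_x - Ro_ref).max() < 1e-9 * np.abs(Ro_ref).max()
        assert np.abs(2 * rv_x - Rv_ref).max() < 1e-9 * np.abs(Rv_ref).max()

    def test_zero_virtual_space(self, rng):
        Xo = rng.normal(size=(3, 9))
        Xv = np.zeros((4, 9))
        Z = np.eye(9)
        X = rng.normal(size=(4, 9))
        ro_x, rv_x = ct.exchange_R(Xo, Xv, Z, X, nb=None)
        assert np.abs(ro_x).max() == 0.0 and np.abs(rv_x).max() == 0.0

    def test_screened_with_zero_thresholds_bitwise_equals_unscreened(self, cache):
        scf = cache.scf("CH3")
        quad = cache.quad("CH3")
        thc = cache.thc("CH3")
        pair = build_pseudodensities(scf, quad, 0)
        cdd = cholesky_pseudo_mos(pair, 1e-10)
        Xo = cdd.L_occ[0].T @ thc.X
        Xv = cdd.L_virt[0].T @ thc.X
        a = ct.exchange_R(Xo, Xv, thc.Z, thc.X, nb=None)
        b = ct.exchange_R(Xo, Xv, thc.Z, thc.X, nb=NBConfig(0.0, 0.0, 0.0))
        assert np.array_equal(a[0], b[0])
        assert np.array_equal(a[1], b[1])


class TestBuildR:
    def test_unscreened_thc_matches_dense_oracle(self, cache):
        scf = cache.scf("CH3")
        quad = cache.quad("CH3")
        thc = cache.thc("CH3")
        rpairs = ct.build_R(scf, thc, quad, nb=None)
        for k in (0, 5):
            Rd = ct.r_dense_oracle(scf, quad, k)
            for s in (0, 1):
                assert np.abs(rpairs[k].R_occ[s] - Rd.R_occ[s]).max() < 1e-4
                assert np.abs(rpairs[k].R_virt[s] - Rd.R_virt[s]).max() < 1e-4

    def test_weight_scaling_is_local_to_the_point(self, cache):
        scf = cache.scf("OH")
        quad = cache.quad("OH")
        thc = cache.thc("OH")
        k0 = 2
        w2 = quad.weights.copy()
        w2[k0] *= 2.0
        quad2 = LaplaceQuadrature(w2, quad.exponents, quad.x_min, quad.x_max,
                                  quad.max_rel_error)
        r1 = ct.build_R(scf, thc, quad, nb=None)
        r2 = ct.build_R(scf, thc, quad2, nb=None)
        for k in range(quad.n_points):
            # R carries the three remaining ω^{1/4}-weighted factors, so a
            # doubled weight scales only that point's pair by 2^{3/4}
            scale = 2.0**0.75 if k == k0 else 1.0
            for s in (0, 1):
                assert np.allclose(r2[k].R_occ[s], scale * r1[k].R_occ[s],
                                   rtol=1e-10, atol=1e-14)

    def test_one_electron_system_r_vanishes(self, cache):
        scf = cache.scf("H")
        quad = cache.quad("H")
        R = ct.r_dense_oracle(scf, quad, 0)
        for s in (0, 1):
            assert np.abs(R.R_occ[s]).max() < 1e-14
            assert np.abs(R.R_virt[s]).max() < 1e-14


class TestExchangeEnergyNB:
    def test_unscreened_matches_brute_force(self, cache):
        scf = cache.scf("H2O")
        quad = cache.quad("H2O")
        thc = cache.thc("H2O")
        pair = build_pseudodensities(scf, quad, 3)
        cdd = cholesky_pseudo_mos(pair, 1e-10)
        Xo = cdd.L_occ[0].T @ thc.X
        Xv = cdd.L_virt[0].T @ thc.X
        A, B = Xo.T @ Xo, Xv.T @ Xv
        ref = ct.exchange_energy_dense_grid(A, B, thc.Z)
        val = ct.exchange_energy_nb(Xo, Xv, thc.Z, nb=None)
        assert val == pytest.approx(ref, rel=1e-10, abs=1e-12)

    def test_zero_kernel(self, cache, rng):
        Xo = rng.normal(size=(3, 12))
        Xv = rng.normal(size=(4, 12))
        assert ct.exchange_energy_nb(Xo, Xv, np.zeros((12, 12)),
                                     nb=None) == 0.0

    def test_error_shrinks_with_tighter_thresholds(self, cache):
        scf = cache.scf("CH3")
        quad = cache.quad("CH3")
        thc = cache.thc("CH3")
        pair = build_pseudodensities(scf, quad, 2)
        cdd = cholesky_pseudo_mos(pair, 1e-10)
        Xo = cdd.L_occ[0].T @ thc.X
        Xv = cdd.L_virt[0].T @ thc.X
        exact = ct.exchange_energy_nb(Xo, Xv, thc.Z, nb=None)
        errs = [abs(ct.exchange_energy_nb(Xo, Xv, thc.Z,
                                          nb=NBConfig(s, 10 * s, 10 * s))
                    - exact)
                for s in (1e-2, 1e-4, 1e-6)]
        assert errs[2] <= errs[0] + 1e-14
        assert errs[2] <= errs[1] + 1e-14


def test_thc_point_energy_spin_symmetry(cache):
    scf = cache.scf("H2O")
    quad = cache.quad("H2O")
    thc = cache.thc("H2O")
    e = ct.mp2_energy_thc(scf, thc, quad)
    e_dense = ct.mp2_energy_laplace_dense(scf, quad)
    assert e == pytest.approx(e_dense, abs=5e-4)
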