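"""Laplace quadrature, pseudodensities and pivoted Cholesky."""

import numpy as np
import pytest

from thchfcc.laplace import (LaplaceQuadrature, build_pseudodensities,
                             cholesky_pseudo_mos, denominator_range,
                             fit_laplace_quadrature, level_shift,
                             pivoted_cholesky, quadrature_for)


class TestQuadratureFit:
    def test_degenerate_interval_is_exact(self):
        quad = fit_laplace_quadrature(2.5, 2.5, K=1)
        assert quad.n_points == 1
        assert quad.max_rel_error < 1e-14
        w, t = quad.weights[0], quad.exponents[0]
        assert w * np.exp(-2.5 * t) == pytest.approx(1.0 / 2.5, rel=1e-14)

    def test_stored_error_matches_fresh_resampling(self):
        quad = fit_laplace_quadrature(1.0, 1000.0, K=7)
        xs = np.geomspace(1.0, 1000.0, 100000)
        fresh = np.abs(quad.rel_error(xs)).max()
        assert fresh <= 2.0 * quad.max_rel_error
        assert quad.max_rel_error <= 2.0 * fresh

    def test_monotone_convergence_in_K(self):
        errs = [fit_laplace_quadrature(1.0, 30.0, K=k).max_rel_error
                for k in range(3, 11)]
        for lo, hi in zip(errs[1:], errs[:-1]):
            assert lo <= hi * (1 + 1e-9)

    def test_positivity_and_ordering(self):
        quad = fit_laplace_quadrature(0.5, 80.0, K=6)
        assert np.all(quad.weights > 0)
        assert np.all(quad.exponents > 0)
        assert np.all(np.diff(quad.exponents) > 0)

    def test_dump_load_roundtrip(self):
        quad = fit_laplace_quadrature(1.0, 50.0, K=5)
        clone = LaplaceQuadrature.loads(quad.dumps())
        assert np.array_equal(clone.weights, quad.weights)
        assert np.array_equal(clone.exponents, quad.exponents)
        assert clone.max_rel_error == quad.max_rel_error

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            fit_laplace_quadrature(-1.0, 2.0, K=4)


class TestPseudoDensities:
    def test_closed_shell_spin_symmetry(self, cache):
        scf = cache.scf("H2O")
        quad = cache.quad("H2O")
        for k in (0, 3):
            pair = build_pseudodensities(scf, quad, k)
            assert np.abs(pair.P_occ[0] - pair.P_occ[1]).max() < 1e-10
            assert np.abs(pair.P_virt[0] - pair.P_virt[1]).max() < 1e-10

    def test_subspace_projections(self, cache):
        scf = cache.scf("CH3")
        quad = cache.quad("CH3")
        pair = build_pseudodensities(scf, quad, 2)
        for s in (0, 1):
            assert np.abs(pair.P_occ[s] @ scf.S @ scf.P_virt(s)).max() < 1e-8
            assert np.abs(pair.P_virt[s] @ scf.S @ scf.P_occ(s)).max() < 1e-8

    def test_denominator_reconstruction(self, cache, rng):
        """κ-summed exponential factors reproduce 1/(ε_a+ε_b-ε_i-ε_j)."""
        scf = cache.scf("CH3")
        quad = cache.quad("CH3")
        mu = level_shift(scf)
        no_a, no_b = scf.n_occ
        eps_a, eps_b = scf.eps
        for _ in range(20):
            i = rng.integers(no_a)
            a = rng.integers(no_a, len(eps_a))
            j = rng.integers(no_b)
            b = rng.integers(no_b, len(eps_b))
            delta = eps_a[a] + eps_b[b] - eps_a[i] - eps_b[j]
            acc = sum(
                quad.weights[k]
                * np.exp((eps_a[i] - mu) * quad.exponents[k])
                * np.exp((eps_b[j] - mu) * quad.exponents[k])
                * np.exp(-(eps_a[a] - mu) * quad.exponents[k])
                * np.exp(-(eps_b[b] - mu) * quad.exponents[k])
                for k in range(quad.n_points))
            assert abs(acc - 1.0 / delta) * delta <= 2 * quad.max_rel_error

    def test_spectrum_outside_interval_raises(self, cache):
        scf = cache.scf("CH3")
        bad = fit_laplace_quadrature(100.0, 200.0, K=4)
        with pytest.raises(ValueError, match="outside"):
            build_pseudodensities(scf, bad, 0)

    def test_range_covers_all_channels(self, cache):
        scf = cache.scf("NH2")
        lo, hi = denominator_range(scf)
        for s in (0, 1):
            no = scf.n_occ[s]
            gaps = scf.eps[s][no:, None] - scf.eps[s][None, :no]
            assert 2 * gaps.min() >= lo - 1e-12
            assert 2 * gaps.max() <= hi + 1e-12


class TestPivotedCholesky:
    def test_identity(self):
        L = pivoted_cholesky(np.eye(4), threshold=1e-12)
        assert L.shape == (4, 4)
        assert np.abs(L @ L.T - np.eye(4)).max() < 1e-14
        # columns are signed unit vectors
        assert np.allclose(np.abs(L).max(axis=0), 1.0)

    def test_known_rank_reconstruction(self, rng):
        G = rng.normal(size=(10, 3))
        M = G @ G.T
        L = pivoted_cholesky(M, threshold=1e-10)
        assert L.shape[1] == 3
        assert np.abs(L @ L.T - M).max() < 1e-10

    def test_not_psd_rejected(self):
        M = np.diag([1.0, -1.0])
        with pytest.raises(ValueError, match="not PSD"):
            pivoted_cholesky(M, threshold=1e-10)

    def test_pseudodensity_rank_bound(self, cache):
        scf = cache.scf("CH3")
        quad = cache.quad("CH3")
        pair = build_pseudodensities(scf, quad, 1)
        cdd = cholesky_pseudo_mos(pair, threshold=1e-8)
        for s in (0, 1):
            assert cdd.L_occ[s].shape[1] <= scf.n_occ[s]
            assert cdd.L_virt[s].shape[1] <= scf.nbf - scf.n_occ[s]
            # CDD reconstruction within the decomposition threshold
            assert np.abs(cdd.L_occ[s] @ cdd.L_occ[s].T
                          - pair.P_occ[s]).max() < 1e-8
            assert np.abs(cdd.L_virt[s] @ cdd.L_virt[s].T
                          - pair.P_virt[s]).max() < 1e-8


def test_laplace_energy_converges_with_K(cache):
    """Laplace AO-MP2 approaches canonical MO-MP2 as K grows."""
    from thchfcc import contractions as ct

    for name in ("OH", "NH2"):
        scf = cache.scf(name)
        e_ref = ct.mp2_energy_canonical(scf)
        d4 = abs(ct.mp2_energy_laplace_dense(scf, quadrature_for(scf, K=4))
                 - e_ref)
        d8 = abs(ct.mp2_energy_laplace_dense(scf, quadrature_for(scf, K=8))
                 - e_ref)
        assert d8 < d4
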