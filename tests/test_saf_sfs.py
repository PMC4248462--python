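"""SAF recursion against exhaustive enumeration, and the 1D/2D SFS EMs."""

import numpy as np
import pytest

from conftest import brute_force_saf, certain_gl3
from glpop.gl_models import gl3_batch_from_counts
from glpop.saf_sfs import (align_sites, loglik_sfs_1d, loglik_sfs_2d,
                           saf_batch, saf_site, sfs_em_1d, sfs_em_2d)
from glpop.simulate import (SimConfig, correlated_joint_sfs, neutral_sfs,
                            sim_onepop, sim_twopop)


class TestSafSite:
    def test_single_individual_is_its_gl(self, rng):
        gl3 = np.log(rng.random((1, 3)))
        logp = saf_site(gl3)
        np.testing.assert_allclose(logp, gl3[0] - gl3[0].max(), atol=1e-12)

    def test_flat_gls_give_constant_saf(self):
        logp = saf_site(np.zeros((5, 3)))
        np.testing.assert_allclose(logp, 0.0, atol=1e-12)

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_matches_enumeration_oracle(self, n, rng):
        for _ in range(25):
            gl3 = np.log(rng.random((n, 3)))
            got = np.exp(saf_site(gl3))
            want = np.exp(brute_force_saf(gl3))
            np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_no_underflow_at_100_individuals(self, rng):
        gl3 = np.log(rng.random((100, 3)) * 1e-4 + 1e-300)
        logp = saf_site(gl3)
        assert np.all(np.isfinite(logp[np.exp(logp) > 0])) and logp.max() == 0.0

    def test_zero_individuals_is_error(self):
        with pytest.raises(ValueError):
            saf_batch(np.zeros((3, 0, 3)))


class TestSfs1d:
    def test_certain_data_returns_histogram(self, rng):
        n, S = 4, 300
        counts = rng.integers(0, 2 * n + 1, size=S)
        safs = np.full((S, 2 * n + 1), -80.0)
        safs[np.arange(S), counts] = 0.0
        gamma = sfs_em_1d(safs)
        hist = np.bincount(counts, minlength=2 * n + 1) / S
        np.testing.assert_allclose(gamma, hist, atol=1e-9)

    def test_single_site_concentrates_on_argmax(self, rng):
        safs = np.log(rng.random((1, 7)))
        gamma = sfs_em_1d(safs, max_iter=5000, tol=1e-14)
        assert gamma.argmax() == safs[0].argmax()
        assert gamma.max() > 0.999

    def test_one_step_from_uniform_is_normalised_saf(self, rng):
        safs = np.log(rng.random((1, 7)))
        gamma = sfs_em_1d(safs, max_iter=1)
        p = np.exp(safs[0])
        np.testing.assert_allclose(gamma, p / p.sum(), atol=1e-12)

    def test_recovery_at_2x_depth(self):
        """The benchmark regime: 10 diploids, 5e4 sites, 2X, 0.2% error."""
        cfg = SimConfig(n_individuals=10, n_sites=50_000, mean_depth=2.0,
                        error_rate=0.002, seed=7)
        truth = sim_onepop(cfg)
        gl3 = gl3_batch_from_counts(truth.counts, 10 ** (-cfg.phred / 10),
                                    truth.alleles)
        gamma, trace = sfs_em_1d(saf_batch(gl3), return_trace=True)
        tv = 0.5 * np.abs(gamma - cfg.resolved_sfs()).sum()
        assert tv < 0.05
        assert np.all(np.diff(trace) >= -1e-9)

    def test_site_order_irrelevant(self, rng):
        safs = np.log(rng.random((40, 5)))
        perm = rng.permutation(40)
        np.testing.assert_allclose(sfs_em_1d(safs), sfs_em_1d(safs[perm]),
                                   atol=1e-12)


class TestLoglik2d:
    def test_concentrated_gamma_is_single_term(self, rng):
        safs1 = np.log(rng.random((5, 3)))
        safs2 = np.log(rng.random((5, 5)))
        gamma = np.zeros((3, 5))
        gamma[1, 2] = 1.0
        got = loglik_sfs_2d(safs1, safs2, gamma)
        assert got == pytest.approx(float((safs1[:, 1] + safs2[:, 2]).sum()))

    def test_uniform_gamma_is_log_mean_outer(self, rng):
        safs1 = np.log(rng.random((4, 3)))
        safs2 = np.log(rng.random((4, 3)))
        gamma = np.full((3, 3), 1 / 9)
        want = sum(np.log(np.outer(np.exp(s1), np.exp(s2)).mean())
                   for s1, s2 in zip(safs1, safs2))
        assert loglik_sfs_2d(safs1, safs2, gamma) == pytest.approx(want)

    def test_matches_double_loop(self, rng):
        safs1 = np.log(rng.random((3, 3)))
        safs2 = np.log(rng.random((3, 3)))
        gamma = rng.dirichlet(np.ones(9)).reshape(3, 3)
        brute = 0.0
        for s in range(3):
            tot = sum(gamma[i, j] * np.exp(safs1[s, i]) * np.exp(safs2[s, j])
                      for i in range(3) for j in range(3))
            brute += np.log(tot)
        assert loglik_sfs_2d(safs1, safs2, gamma) == pytest.approx(brute,
                                                                   rel=1e-12)


class TestSfs2d:
    def test_certain_data_returns_2d_histogram(self, rng):
        n1, n2, S = 2, 3, 400
        i_cnt = rng.integers(0, 2 * n1 + 1, size=S)
        j_cnt = rng.integers(0, 2 * n2 + 1, size=S)
        safs1 = np.full((S, 2 * n1 + 1), -80.0)
        safs2 = np.full((S, 2 * n2 + 1), -80.0)
        safs1[np.arange(S), i_cnt] = 0.0
        safs2[np.arange(S), j_cnt] = 0.0
        gamma = sfs_em_2d(safs1, safs2)
        hist = np.zeros((2 * n1 + 1, 2 * n2 + 1))
        np.add.at(hist, (i_cnt, j_cnt), 1.0 / S)
        np.testing.assert_allclose(gamma, hist, atol=1e-9)

    def test_zero_sites_is_error(self):
        with pytest.raises(ValueError):
            sfs_em_2d(np.zeros((0, 3)), np.zeros((0, 3)))

    def test_duplicated_population_concentrates_on_diagonal(self, rng):
        S, K = 500, 7
        counts = rng.integers(0, K, size=S)
        safs = np.full((S, K), -80.0)
        safs[np.arange(S), counts] = 0.0
        gamma = sfs_em_2d(safs, safs)
        assert np.trace(gamma) > 0.99

    def test_independent_pops_marginals_recovered(self):
        g1 = neutral_sfs(12, invariant_mass=0.5)
        g2 = neutral_sfs(12, invariant_mass=0.4)
        cfg1 = SimConfig(n_individuals=6, n_sites=50_000, seed=11)
        cfg2 = SimConfig(n_individuals=6, n_sites=50_000, seed=11)
        t1, t2 = sim_twopop(cfg1, cfg2, np.outer(g1, g2))
        s1 = saf_batch(gl3_batch_from_counts(t1.counts, 0.002, t1.alleles))
        s2 = saf_batch(gl3_batch_from_counts(t2.counts, 0.002, t2.alleles))
        gamma, trace = sfs_em_2d(s1, s2, return_trace=True)
        assert np.all(np.diff(trace) >= -1e-9)
        assert 0.5 * np.abs(gamma.sum(axis=1) - g1).sum() < 0.05
        assert 0.5 * np.abs(gamma.sum(axis=0) - g2).sum() < 0.05

    def test_correlated_spectrum_recovered(self):
        joint = correlated_joint_sfs(6, 6)
        cfg1 = SimConfig(n_individuals=6, n_sites=50_000, seed=23)
        cfg2 = SimConfig(n_individuals=6, n_sites=50_000, seed=23)
        t1, t2 = sim_twopop(cfg1, cfg2, joint)
        s1 = saf_batch(gl3_batch_from_counts(t1.counts, 0.002, t1.alleles))
        s2 = saf_batch(gl3_batch_from_counts(t2.counts, 0.002, t2.alleles))
        gamma = sfs_em_2d(s1, s2, max_iter=2000)
        assert 0.5 * np.abs(gamma - joint).sum() < 0.08


class TestAlignSites:
    def test_intersection_and_order(self):
        sites1 = [("chr1", 1), ("chr1", 2), ("chr2", 5)]
        sites2 = [("chr2", 5), ("chr1", 2), ("chr1", 9)]
        s1 = np.arange(9).reshape(3, 3)
        s2 = np.arange(9).reshape(3, 3) + 100
        a1, a2, keys = align_sites(sites1, s1, sites2, s2)
        assert keys == [("chr1", 2), ("chr2", 5)]
        np.testing.assert_array_equal(a1, s1[[1, 2]])
        np.testing.assert_array_equal(a2, s2[[1, 0]])

    def test_disjoint_sites_is_error(self):
        with pytest.raises(ValueError, match="share no"):
            align_sites([("chr1", 1)], np.zeros((1, 3)),
                        [("chr1", 2)], np.zeros((1, 3)))
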