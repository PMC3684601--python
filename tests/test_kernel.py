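import numpy as np
import pytest
from scipy import stats

import famkernel as fk
from famkernel.kernel_test import (W1, W2, W3, WeightScheme, _liu_pvalue,
                                   beta_weights, kernel_test,
                                   mixed_score_statistic, null_eigenvalues,
                                   pvalue_mixture, pvalue_resampling,
                                   q_statistic)
from famkernel.polygenic import PolygenicModel
from famkernel.transform import grammar_plus, simple_score

from conftest import random_region


def ids(n):
    return np.array([f"s{i}" for i in range(n)], dtype=object)


class TestBetaWeights:
    def test_closed_forms(self):
        pdf = WeightScheme(1, 25, convention="pdf")
        assert beta_weights(np.array([0.1]), pdf)[0] == pytest.approx(
            25 * 0.9 ** 24, rel=1e-6)
        arcsine = WeightScheme(0.5, 0.5, convention="pdf")
        assert beta_weights(np.array([0.5]), arcsine)[0] == pytest.approx(
            2 / np.pi, rel=1e-9)
        np.testing.assert_allclose(
            beta_weights(np.array([0.05, 0.3]), WeightScheme(1, 1)), 1.0,
            rtol=1e-12)

    def test_squared_convention(self):
        m = np.array([0.08, 0.4])
        np.testing.assert_allclose(beta_weights(m, W3),
                                   beta_weights(m, WeightScheme(1, 25, convention="pdf")) ** 2)

    def test_domain(self):
        with pytest.raises(ValueError, match="MAF"):
            beta_weights(np.array([0.0]), W2)
        with pytest.raises(ValueError, match="positive"):
            WeightScheme(0, 1)


class TestMixedScoreStatistic:
    def test_identity_R_is_ols_score(self):
        rng = np.random.default_rng(0)
        n = 40
        y = rng.standard_normal(n)
        fit = PolygenicModel.from_components(np.eye(n), 0.0, 1.0, y=y)
        region = random_region(rng, n, 8)
        t = mixed_score_statistic(fit, region)
        gc = region.genotypes - region.genotypes.mean(0)
        ytil = y - y.mean()
        expect = (gc.T @ ytil) ** 2 / (gc ** 2).sum(0)  # sigma2 = 1
        np.testing.assert_allclose(t, expect, atol=1e-10)

    def test_toy_hand_algebra(self, two_block_R):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(4)
        fit = PolygenicModel.from_components(two_block_R, 0.5, 1.0, y=y)
        g = np.array([0.0, 0.5, 0.5, 1.0])
        region = fk.GenotypeRegion(g[:, None], "1", [1], ids(4))
        V = 0.5 * two_block_R + 0.5 * np.eye(4)
        gt = g - g.mean()
        ytil = fit.centered_trait()
        expect = (gt @ np.linalg.solve(V, ytil)) ** 2 / (gt @ np.linalg.solve(V, gt))
        assert mixed_score_statistic(fit, region)[0] == pytest.approx(expect, abs=1e-10)

    def test_null_mean_is_one(self, family_pedigree, family_R):
        """T_m is asymptotically chi2_1 under the null: unit mean over
        markers and trait replicates (the shared trait realization makes the
        per-replicate marker average fluctuate, so both are averaged)."""
        rng = np.random.default_rng(2)
        n = family_R.n
        from famkernel.simulate import relationship_factor
        chol = relationship_factor(family_R.values)
        mafs = rng.uniform(0.05, 0.5, 1000)
        G = fk.gene_drop(family_pedigree, mafs, seed=3)
        region = fk.GenotypeRegion(G, "1", np.arange(1000) + 1,
                                   family_pedigree.ids)
        means = []
        for _ in range(20):
            y = (np.sqrt(0.5) * (chol @ rng.standard_normal(n))
                 + np.sqrt(0.5) * rng.standard_normal(n))
            fit = PolygenicModel.from_components(family_R, 0.5, 1.0, y=y)
            means.append(mixed_score_statistic(fit, region).mean())
        assert 0.95 <= np.mean(means) <= 1.05


class TestQStatistic:
    def test_single_marker_reduces_to_score(self, two_block_R):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(4)
        fit = PolygenicModel.from_components(two_block_R, 0.5, 1.0, y=y)
        g = np.array([0.0, 0.5, 0.5, 1.0])
        region = fk.GenotypeRegion(g[:, None], "1", [1], ids(4))
        yp = grammar_plus(fit)
        q = q_statistic(yp, region, W2)
        t = simple_score(yp, region).t_stat[0]
        # the intercept projection re-centers y+, matching the centered score
        assert q == pytest.approx(t, rel=1e-8)

    def test_matches_loop_sum(self):
        rng = np.random.default_rng(4)
        n = 60
        y = rng.standard_normal(n)
        fit = PolygenicModel.from_components(np.eye(n), 0.2, 1.0, y=y)
        region = random_region(rng, n, 3)
        yp = grammar_plus(fit)
        for scheme in (W1, W2, W3):
            sc = simple_score(yp, region)
            w = scheme.weights(region.mafs[sc.used])
            q_loop = float((w * sc.t_stat).sum())
            assert q_statistic(yp, region, scheme) == pytest.approx(q_loop, abs=1e-8)

    def test_zero_weights_zero_q(self):
        rng = np.random.default_rng(5)
        n = 30
        y = rng.standard_normal(n)
        fit = PolygenicModel.from_components(np.eye(n), 0.0, 1.0, y=y)
        region = random_region(rng, n, 4)

        class Zero(WeightScheme):
            def weights(self, mafs):
                return np.zeros(len(mafs))

        res = kernel_test(grammar_plus(fit), region, Zero(1, 1, "zero"))
        assert res.q == 0.0 and res.p_mixture == 1.0


class TestNullEigenvalues:
    def test_single_marker_unit_lambda(self):
        g = np.array([0.0, 0.0, 0.5, 1.0])
        region = fk.GenotypeRegion(g[:, None], "1", [1], ids(4))
        lams = null_eigenvalues(region, W2)
        np.testing.assert_allclose(lams, [1.0], atol=1e-12)

    def test_two_orthogonal_markers(self):
        g = np.column_stack([[0.0, 0.0, 1.0, 1.0], [0.0, 1.0, 0.0, 1.0]])
        region = fk.GenotypeRegion(g, "1", [1, 2], ids(4))
        lams = null_eigenvalues(region, W2)
        np.testing.assert_allclose(lams, [1.0, 1.0], atol=1e-12)

    def test_trace_identity(self):
        rng = np.random.default_rng(6)
        region = random_region(rng, 50, 12)
        gc = region.genotypes - region.genotypes.mean(0)
        used = (gc ** 2).sum(0) > 0
        gn = gc[:, used] / np.sqrt((gc[:, used] ** 2).sum(0))
        w = W3.weights(region.mafs[used])
        qc = np.ones((50, 1)) / np.sqrt(50)
        gp = gn - qc @ (qc.T @ gn)
        lams = null_eigenvalues(region, W3)
        assert lams.sum() == pytest.approx((w * (gp ** 2).sum(0)).sum(), abs=1e-8)


class TestPvalueMixture:
    @pytest.mark.parametrize("lams,q,expect", [
        ([1.0], 3.841458820694124, 0.05),
        ([1.0, 1.0], 5.991464547107979, 0.05),
    ])
    def test_chi_square_quantiles(self, lams, q, expect):
        p, method = pvalue_mixture(q, np.array(lams))
        assert method == "imhof"
        assert p == pytest.approx(expect, abs=1e-6)

    def test_monte_carlo_agreement(self):
        rng = np.random.default_rng(7)
        n_draw = 200_000
        for _ in range(3):
            lams = rng.uniform(0.1, 2.0, 5)
            q = float(rng.uniform(0.5, 2.0) * lams.sum())
            draws = rng.chisquare(1, (n_draw, 5)) @ lams
            p_mc = (draws >= q).mean()
            se = np.sqrt(p_mc * (1 - p_mc) / n_draw)
            p, _ = pvalue_mixture(q, lams)
            assert abs(p - p_mc) < 3 * se + 1e-12

    def test_liu_fallback_close_to_imhof(self):
        lams = np.array([1.2, 0.8, 0.4])
        q = 6.0
        p_imhof, _ = pvalue_mixture(q, lams)
        assert _liu_pvalue(q, lams) == pytest.approx(p_imhof, abs=5e-3)

    def test_clipping_and_edge_cases(self):
        p, _ = pvalue_mixture(1e6, np.array([1.0]))
        assert 1e-16 <= p < 1e-10
        assert pvalue_mixture(0.0, np.array([1.0]))[0] == 1.0
        with pytest.raises(ValueError):
            pvalue_mixture(1.0, np.array([]))


class TestPvalueResampling:
    def _trait(self, n, seed, signal=None):
        rng = np.random.default_rng(seed)
        y = rng.standard_normal(n)
        if signal is not None:
            y = y + signal
        fit = PolygenicModel.from_components(np.eye(n), 0.0, 1.0, y=y)
        return fit.center_phenotype()

    def test_add_one_estimator_floor(self):
        rng = np.random.default_rng(8)
        n = 100
        region = random_region(rng, n, 5)
        signal = 10.0 * (region.genotypes[:, 0] - region.genotypes[:, 0].mean())
        yt = self._trait(n, 9, signal)
        p = pvalue_resampling(yt, region, W2, n_resamples=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_reproducible_and_min_resamples(self):
        rng = np.random.default_rng(10)
        region = random_region(rng, 50, 4)
        yt = self._trait(50, 11)
        a = pvalue_resampling(yt, region, W2, 199, seed=7)
        b = pvalue_resampling(yt, region, W2, 199, seed=7)
        assert a == b
        with pytest.raises(ValueError, match="100"):
            pvalue_resampling(yt, region, W2, 50, seed=7)

    def test_null_uniformity(self):
        """Permutation P values are uniform under the null (KS at 0.01)."""
        rng = np.random.default_rng(12)
        n = 100
        ps = []
        for i in range(400):
            region = random_region(rng, n, 8)
            yt = self._trait(n, 1000 + i)
            ps.append(pvalue_resampling(yt, region, W2, 499,
                                        seed=int(rng.integers(2 ** 31))))
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestKernelTest:
    def test_requires_two_polymorphic_markers(self):
        g = np.column_stack([[0.5] * 4, [0.0, 0.5, 0.5, 1.0]])
        region = fk.GenotypeRegion(g, "1", [1, 2], ids(4))
        rng = np.random.default_rng(13)
        fit = PolygenicModel.from_components(np.eye(4), 0.0, 1.0,
                                             y=rng.standard_normal(4))
        with pytest.raises(ValueError, match="polymorphic"):
            kernel_test(fit.center_phenotype(), region, W2)

    def test_result_fields_and_trace_conservation(self):
        rng = np.random.default_rng(14)
        n = 80
        region = random_region(rng, n, 10)
        fit = PolygenicModel.from_components(np.eye(n), 0.0, 1.0,
                                             y=rng.standard_normal(n))
        res = kernel_test(grammar_plus(fit), region, W1, n_resamples=199, seed=3)
        assert res.q >= 0 and 0 < res.p_mixture <= 1
        assert res.n_markers == 10 and res.transform == "grammar_plus"
        assert res.p_resampling is not None
        gc = region.genotypes - region.genotypes.mean(0)
        gn = gc / np.sqrt((gc ** 2).sum(0))
        w = W1.weights(region.mafs)
        qc = np.ones((n, 1)) / np.sqrt(n)
        gp = gn - qc @ (qc.T @ gn)
        assert res.lambdas.sum() == pytest.approx((w * (gp ** 2).sum(0)).sum(),
                                                  abs=1e-8)
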