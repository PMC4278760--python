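"""GLM estimators: OLS/AR baselines, the sandwich, and cross-voxel covariance."""

import numpy as np
import pytest
from scipy import stats

from inlimbo.design import build_design, make_blocks
from inlimbo.glm import (ARWhitenedGLM, OLSGLM, SandwichGLM, contrast_zmap,
                         fit_ols, fit_sandwich, sandwich_covariance, t_to_z,
                         _yule_walker)
from inlimbo.simulate import _ar1_noise

C = np.array([1.0, 0.0])


def block_design(T, tr=2.0, cycle=40.0):
    onsets = [k * cycle for k in range(int(T * tr / cycle))]
    return build_design({"task": onsets}, cycle / 2, T, tr,
                        nuisance=np.ones((T, 1)))


@pytest.fixture(scope="module")
def X200():
    return block_design(200).values


class TestOLS:
    def test_intercept_only_recovers_mean(self, rng):
        y = rng.normal(2.0, 1.0, 50)
        fit = fit_ols(y, np.ones((50, 1)), [1.0])
        assert fit.beta[0, 0] == pytest.approx(y.mean())
        assert fit.dof == 49

    def test_exact_fit_has_zero_variance(self, X200):
        y = X200 @ np.array([1.5, 3.0])
        fit = fit_ols(y, X200, C)
        assert fit.variance[0] == pytest.approx(0.0, abs=1e-20)
        assert fit.contrast[0] == pytest.approx(1.5)

    def test_unbiased_under_white_noise(self, X200, rng):
        # Monte-Carlo oracle: mean estimate within 3 MC SE of the truth
        n = 2000
        Y = (X200 @ np.array([1.0, 0.0]))[:, None] + rng.normal(0, 1, (200, n))
        est, _ = OLSGLM().fit(X200, Y).contrast_estimate(C)
        assert abs(est.mean() - 1.0) < 3 * est.std() / np.sqrt(n)

    def test_singular_design_raises(self):
        X = np.ones((20, 2))
        with pytest.raises(ValueError, match="singular|rank"):
            OLSGLM().fit(X, np.arange(20.0))


class TestARWhitened:
    def test_white_noise_matches_ols(self, X200, rng):
        Y = rng.normal(0, 1, (200, 50))
        ar = ARWhitenedGLM(order=1).fit(X200, Y)
        ols = OLSGLM().fit(X200, Y)
        np.testing.assert_allclose(ar.coef_, ols.coef_, atol=0.15)

    def test_order_zero_rejected(self, X200):
        with pytest.raises(ValueError, match="order"):
            ARWhitenedGLM(order=0).fit(X200, np.zeros(200))

    def test_nonstationary_fit_advises_sandwich(self, X200, rng, monkeypatch):
        import inlimbo.glm as glm_mod
        monkeypatch.setattr(glm_mod, "_yule_walker",
                            lambda resid, order: np.full((order, resid.shape[1]), 1.05))
        with pytest.raises(ValueError, match="sandwich"):
            ARWhitenedGLM(order=1).fit(X200, rng.normal(0, 1, (200, 3)))

    def test_yule_walker_matches_statsmodels(self, rng):
        from statsmodels.regression.linear_model import yule_walker
        series = _ar1_noise(rng, 400, (3,), 1.0, 0.5)
        phi = _yule_walker(series, 2)
        for v in range(3):
            ref, _ = yule_walker(series[:, v], order=2, method="mle")
            np.testing.assert_allclose(phi[:, v], ref, atol=0.02)

    def test_ar1_coverage_beats_ols(self, rng):
        # AR(1) coefficient 0.5: prewhitened CI coverage lands near nominal
        # while naive OLS under-covers — the motivation for robust variances
        T, n = 200, 5000
        X = block_design(T).values
        noise = _ar1_noise(rng, T, (n,), 1.0, 0.5)
        Y = (X @ np.array([1.0, 0.0]))[:, None] + noise
        ar = ARWhitenedGLM(order=1).fit(X, Y)
        est, var = ar.contrast_estimate(C)
        crit = stats.t.ppf(0.975, ar.dof_)
        cover_ar = np.mean(np.abs(est - 1.0) <= crit * np.sqrt(var))
        ols = OLSGLM().fit(X, Y)
        oest, ovar = ols.contrast_estimate(C)
        crit_o = stats.t.ppf(0.975, ols.dof_)
        cover_ols = np.mean(np.abs(oest - 1.0) <= crit_o * np.sqrt(ovar))
        assert 0.93 <= cover_ar <= 0.97
        assert cover_ols < 0.93


class TestSandwich:
    def test_exact_fit_zero_variance(self, X200):
        y = X200 @ np.array([2.0, 1.0])
        fit = fit_sandwich(make_blocks(y, X200), C)
        assert fit.contrast[0] == pytest.approx(2.0)
        assert fit.variance[0] == pytest.approx(0.0, abs=1e-18)
        assert fit.estimator == "sandwich"
        assert fit.residual_blocks is not None

    def test_matches_matrix_form_oracle(self, X200, rng):
        # independent oracle: assemble the bread-meat-bread product from
        # explicit matrices and compare with the score-based implementation
        y = (X200 @ np.array([1.0, 0.5])) + rng.normal(0, 1, 200)
        q = 4
        blocks = make_blocks(y, X200, q=q)
        fit = fit_sandwich(blocks, C)
        Xi = blocks.block_design
        yi = blocks.block_data
        bread = sum(Xi[i].T @ Xi[i] for i in range(q))
        beta = np.linalg.solve(bread, sum(Xi[i].T @ yi[i] for i in range(q)))
        resid = [yi[i] - Xi[i] @ beta for i in range(q)]
        sigma = sum(np.outer(r, r) for r in resid) / (q - 1)
        meat = sum(Xi[i].T @ sigma @ Xi[i] for i in range(q))
        binv = np.linalg.inv(bread)
        var = C @ binv @ meat @ binv @ C
        assert fit.contrast[0] == pytest.approx(C @ beta)
        assert fit.variance[0] == pytest.approx(var, rel=1e-10)
        assert fit.dof == q - 1

    def test_invariant_to_block_permutation(self, X200, rng):
        from inlimbo.design import ReplicationBlocks
        y = rng.normal(0, 1, 200)
        blocks = make_blocks(y, X200, q=5)
        perm = np.array([3, 0, 4, 1, 2])
        shuffled = ReplicationBlocks(block_design=blocks.block_design[perm],
                                     block_data=blocks.block_data[perm])
        f1 = fit_sandwich(blocks, C)
        f2 = fit_sandwich(shuffled, C)
        assert f1.contrast[0] == pytest.approx(f2.contrast[0])
        assert f1.variance[0] == pytest.approx(f2.variance[0])

    def test_rank_deficient_block_raises(self):
        X = np.column_stack([np.r_[np.zeros(10), np.sin(np.arange(10))],
                             np.ones(20)])
        # first block's task column is identically zero -> rank deficient
        with pytest.raises(ValueError, match="rank deficient"):
            fit_sandwich(make_blocks(np.arange(20.0), X, q=2), C)


@pytest.fixture(scope="module")
def pair_fit(X200):
    rng = np.random.default_rng(11)
    shared = rng.normal(0, 1, 200)
    Y = np.column_stack([shared, shared, rng.normal(0, 1, 200)])
    Y += (X200 @ np.array([1.0, 0.0]))[:, None]
    model = SandwichGLM().fit(X200, Y)
    return model.to_fit(C)


class TestCrossVoxelCovariance:
    def test_self_covariance_is_variance(self, pair_fit):
        for j in range(3):
            assert sandwich_covariance(pair_fit, j, j) == \
                pytest.approx(pair_fit.variance[j])

    def test_symmetry_and_psd(self, pair_fit):
        c01 = sandwich_covariance(pair_fit, 0, 1)
        c10 = sandwich_covariance(pair_fit, 1, 0)
        assert c01 == pytest.approx(c10)
        det = pair_fit.variance[0] * pair_fit.variance[2] \
            - sandwich_covariance(pair_fit, 0, 2) ** 2
        assert det >= -1e-15

    def test_identical_noise_gives_cov_equal_var(self, pair_fit):
        # voxels 0 and 1 share the identical noise realization
        assert sandwich_covariance(pair_fit, 0, 1) == \
            pytest.approx(pair_fit.variance[0], rel=1e-10)

    def test_independent_voxels_have_zero_mean_covariance(self, X200):
        rng = np.random.default_rng(12)
        n = 500
        covs = np.empty(n)
        Y = (X200 @ np.array([1.0, 0.0]))[:, None] + rng.normal(0, 1, (200, 2 * n))
        model = SandwichGLM().fit(X200, Y)
        s = model.block_scores(C)
        covs = (s[:, :n] * s[:, n:]).sum(axis=0)
        assert abs(covs.mean()) < 3 * covs.std() / np.sqrt(n)

    def test_requires_sandwich_fit(self, X200, rng):
        fit = fit_ols(rng.normal(0, 1, 200), X200, C)
        with pytest.raises(ValueError, match="sandwich"):
            sandwich_covariance(fit, 0, 0)


class TestEstimatorAgreement:
    def test_white_noise_estimates_agree_in_expectation(self, X200):
        rng = np.random.default_rng(13)
        n = 1000
        Y = (X200 @ np.array([1.0, 0.0]))[:, None] + rng.normal(0, 1, (200, n))
        e_ols, _ = OLSGLM().fit(X200, Y).contrast_estimate(C)
        e_ar, _ = ARWhitenedGLM(order=1).fit(X200, Y).contrast_estimate(C)
        e_sw, _ = SandwichGLM().fit(X200, Y).contrast_estimate(C)
        se = e_ols.std() / np.sqrt(n)
        assert abs(e_ols.mean() - e_sw.mean()) < 3 * se
        assert abs(e_ols.mean() - e_ar.mean()) < 3 * se


class TestZConversion:
    def test_zero_t_maps_to_zero_z(self):
        assert t_to_z(np.array([0.0]), 10)[0] == pytest.approx(0.0)

    def test_matches_composed_cdfs(self):
        z = t_to_z(np.array([2.0]), 24)[0]
        assert z == pytest.approx(stats.norm.ppf(stats.t.cdf(2.0, 24)), rel=1e-10)

    def test_strictly_monotone_and_odd(self):
        t = np.linspace(-30, 30, 301)
        z = t_to_z(t, 13)
        assert np.all(np.diff(z) > 0)
        np.testing.assert_allclose(z, -t_to_z(-t, 13), atol=1e-10)
        assert np.all(np.isfinite(z))

    def test_zmap_excludes_zero_variance_voxels(self, X200, rng):
        Y = np.column_stack([rng.normal(0, 1, 200), np.zeros(200)])
        Y += (X200 @ np.array([1.0, 100.0]))[:, None]
        fit = SandwichGLM().fit(X200, Y).to_fit(C)
        zmap = contrast_zmap(fit)
        assert zmap.mask[0] and not zmap.mask[1]

    def test_all_zero_variance_raises(self, X200):
        y = X200 @ np.array([1.0, 0.0])
        fit = fit_sandwich(make_blocks(y, X200), C)
        with pytest.raises(ValueError, match="zero variance"):
            contrast_zmap(fit)
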