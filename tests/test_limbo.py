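"""Comparison-voxel selection and in-limbo labeling."""

import numpy as np
import pytest
from scipy import stats

from inlimbo.glm import GLMFit
from inlimbo.limbo import (LABEL_ACTIVATED, LABEL_BACKGROUND, LABEL_IN_LIMBO,
                           LABEL_LESS, ComparisonVoxel,
                           EmptySignificantSetError, SubjectDifference,
                           classify_brain, limbo_test_group,
                           limbo_test_single, select_comparison_voxel)
from inlimbo.threshold import ClusterResult, ZMap


def toy_zmap_and_clusters(zvals, sig_mask):
    z = np.asarray(zvals, dtype=float)
    mask = np.ones(z.shape, bool)
    zmap = ZMap(z=z, mask=mask, dof=13)
    labels, _ = __import__("scipy.ndimage", fromlist=["label"]).label(sig_mask)
    res = ClusterResult(significant=np.asarray(sig_mask, bool), clusters=[],
                        z_threshold=2.3, alpha_cluster=0.05, method="none",
                        cluster_labels=labels)
    return zmap, res


def crafted_fit(contrasts, score_columns, dof=24):
    """A sandwich GLMFit with hand-set variances/covariances.

    ``score_columns`` is a (rows, V) array of normalized block scores, so
    Var_v = sum of squared column v and Cov_jk = column cross-product.
    """
    s = np.asarray(score_columns, dtype=float)
    contrasts = np.asarray(contrasts, dtype=float)
    return GLMFit(beta=np.zeros((len(contrasts), 1)), contrast=contrasts,
                  variance=(s**2).sum(axis=0), dof=dof, estimator="sandwich",
                  contrast_weights=np.array([1.0]),
                  residual_blocks=np.zeros((2, 1, len(contrasts))),
                  block_scores=s)


class TestComparisonVoxelSelection:
    def test_selects_minimum_statistic(self):
        zmap, res = toy_zmap_and_clusters([[4.1, 3.2, 5.0]],
                                          [[True, True, True]])
        comp = select_comparison_voxel(zmap, res)
        assert comp.index == (0, 1)
        assert comp.z_value == pytest.approx(3.2)

    def test_tie_broken_lexicographically_with_warning(self):
        zmap, res = toy_zmap_and_clusters([[3.0, 4.0], [3.0, 5.0]],
                                          [[True, True], [True, True]])
        with pytest.warns(UserWarning, match="tie"):
            comp = select_comparison_voxel(zmap, res)
        assert comp.index == (0, 0)

    def test_empty_significant_set_is_an_error(self):
        zmap, res = toy_zmap_and_clusters([[1.0, 1.5]], [[False, False]])
        with pytest.raises(EmptySignificantSetError, match="in limbo"):
            select_comparison_voxel(zmap, res)


class TestSingleSubjectTest:
    def make_comp(self, fit, flat_index):
        return ComparisonVoxel(
            index=(0, flat_index), flat_index=flat_index,
            contrast=float(fit.contrast[flat_index]),
            variance=float(fit.variance[flat_index]),
            t_value=0.0, z_value=0.0,
            block_scores=fit.block_scores[:, flat_index])

    def test_frozen_arithmetic_zero_covariance(self):
        # comparison contrast 2.0 (var 0.25), voxel 1.0 (var 0.25), cov 0:
        # t = (2 - 1) / sqrt(0.5) = 1.4142
        fit = crafted_fit([2.0, 1.0], [[0.5, 0.0], [0.0, 0.5]])
        t, p, label = limbo_test_single(fit, self.make_comp(fit, 0), 1)
        assert t == pytest.approx(np.sqrt(2.0), rel=1e-12)
        assert p == pytest.approx(stats.t.sf(np.sqrt(2.0), 24), rel=1e-12)

    def test_frozen_arithmetic_positive_covariance_sharpens(self):
        # same variances but cov 0.20: t = 1 / sqrt(0.1) = 3.1623
        fit = crafted_fit([2.0, 1.0], [[0.5, 0.4], [0.0, 0.3]])
        assert fit.variance[1] == pytest.approx(0.25)
        t, _, _ = limbo_test_single(fit, self.make_comp(fit, 0), 1)
        assert t == pytest.approx(np.sqrt(10.0), rel=1e-12)

    def test_degenerate_pair_raises_and_numerator_is_zero(self):
        fit = crafted_fit([2.0, 2.0], [[0.5, 0.5], [0.1, 0.1]])
        comp = self.make_comp(fit, 0)
        # self-consistency: the numerator against itself is exactly zero
        assert comp.contrast - fit.contrast[1] == 0.0
        with pytest.raises(ValueError, match="degenerate"):
            limbo_test_single(fit, comp, 1)

    def test_alpha_decides_label(self):
        fit = crafted_fit([2.0, 1.0], [[0.5, 0.0], [0.0, 0.5]])
        comp = self.make_comp(fit, 0)
        _, p, label_strict = limbo_test_single(fit, comp, 1, alpha=0.01)
        assert label_strict == "in_limbo"
        _, _, label_loose = limbo_test_single(fit, comp, 1, alpha=0.2)
        assert label_loose == "less"


class TestGroupTest:
    def test_equal_weights_reduce_to_unweighted_mean(self, rng):
        d = rng.normal(1.0, 1.0, 12)
        diffs = SubjectDifference(d=d, sd=np.full(12, 0.7))
        t, p, _ = limbo_test_group(diffs)
        se = d.std(ddof=1) / np.sqrt(12)
        assert t == pytest.approx(d.mean() / se, rel=1e-10)

    def test_matches_statsmodels_wls(self, rng):
        import statsmodels.api as sm
        d = rng.normal(0.5, 1.0, 15)
        sd = rng.uniform(0.5, 2.0, 15)
        t, p, _ = limbo_test_group(SubjectDifference(d=d, sd=sd))
        res = sm.WLS(d, np.ones(15), weights=1.0 / sd**2).fit()
        assert t == pytest.approx(float(res.tvalues[0]), rel=1e-10)
        assert p == pytest.approx(float(stats.t.sf(res.tvalues[0], 14)), rel=1e-10)

    def test_all_zero_differences_give_t_zero(self):
        t, p, label = limbo_test_group(
            SubjectDifference(d=np.zeros(8), sd=np.ones(8)))
        assert t == 0.0 and p == pytest.approx(0.5)
        assert label == "in_limbo"

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError, match="standard deviations"):
            SubjectDifference(d=np.ones(5), sd=np.array([1, 1, 0, 1, 1.0]))
        with pytest.raises(ValueError, match="2 subjects"):
            SubjectDifference(d=np.ones(1), sd=np.ones(1))


class TestClassifyBrain:
    def test_partition_of_the_mask(self, canonical_result):
        _, _, res = canonical_result
        labels = res.limbo.labels
        mask = res.mask
        assert np.all(labels[~mask] == LABEL_BACKGROUND)
        inside = labels[mask]
        assert np.all(np.isin(inside, [LABEL_LESS, LABEL_IN_LIMBO,
                                       LABEL_ACTIVATED]))
        np.testing.assert_array_equal(labels == LABEL_ACTIVATED,
                                      res.clusters.significant & mask)

    def test_limbo_maps_defined_exactly_on_tested_voxels(self, canonical_result):
        _, _, res = canonical_result
        tested = np.isin(res.limbo.labels, [LABEL_LESS, LABEL_IN_LIMBO])
        assert np.all(np.isfinite(res.limbo.t_limbo[tested]))
        assert np.all(np.isnan(res.limbo.t_limbo[~tested]))

    def test_in_limbo_volume_monotone_in_alpha(self, canonical_result):
        _, _, res = canonical_result
        sizes = []
        for alpha in (0.01, 0.05, 0.2):
            out = classify_brain(res.zmap, res.clusters, fit=res.fit,
                                 alpha=alpha)
            sizes.append((out.labels == LABEL_IN_LIMBO).sum())
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_fdr_in_limbo_set_contains_uncorrected(self, canonical_result):
        _, _, res = canonical_result
        none = classify_brain(res.zmap, res.clusters, fit=res.fit,
                              correction="none")
        fdr = classify_brain(res.zmap, res.clusters, fit=res.fit,
                             correction="fdr")
        n_set = none.labels == LABEL_IN_LIMBO
        f_set = fdr.labels == LABEL_IN_LIMBO
        assert np.all(n_set <= f_set)

    def test_changing_comparison_voxel_changes_t_values(self, canonical_result):
        _, _, res = canonical_result
        default = res.limbo
        # benchmark against the least-significant cluster mean instead
        alt = classify_brain(res.zmap, res.clusters, fit=res.fit,
                             selection_rule="cluster_mean")
        tested = np.isin(default.labels, [LABEL_LESS, LABEL_IN_LIMBO])
        assert not np.allclose(default.t_limbo[tested], alt.t_limbo[tested])

    def test_far_background_with_large_comparison_is_less(self):
        # limiting case: tiny-variance voxels near zero against a clearly
        # larger comparison contrast are all "less", in-limbo volume 0
        n = 6
        cols = np.zeros((2, n))
        cols[0] = 0.01
        cols[0, 0] = 0.5
        fit = crafted_fit(np.r_[3.0, np.zeros(n - 1)], cols, dof=20)
        z = np.r_[5.0, np.zeros(n - 1)][None, :]
        sig = np.zeros((1, n), bool)
        sig[0, 0] = True
        zmap, res = toy_zmap_and_clusters(z, sig)
        out = classify_brain(zmap, res, fit=fit)
        assert (out.labels == LABEL_IN_LIMBO).sum() == 0
        assert (out.labels == LABEL_LESS).sum() == n - 1
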