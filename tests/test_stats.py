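"""Group statistics: ANCOVA oracle, smoothness, GRF clusters, ROI stats."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.ndimage import gaussian_filter

from alffband.stats import (DesignInfo, bonferroni_gate, estimate_smoothness,
                            fit_voxelwise_ancova, grf_cluster_threshold,
                            partial_correlation, posthoc_pairwise)
from alffband.synthetic import VoxelGrid, compartment_masks


def _toy_design(rng, n_per=8):
    groups = np.repeat(["NC", "SCD", "aMCI", "dAD"], n_per)
    cov = rng.standard_normal((len(groups), 5))
    return DesignInfo(groups=groups, covariates=cov)


def oracle_f(y, groups, cov):
    """Explicit per-voxel regression F for the group factor."""
    levels = list(dict.fromkeys(groups.tolist()))
    n = len(y)
    dummies = np.column_stack([(groups == g).astype(float)
                               for g in levels[1:]])
    Xf = np.column_stack([np.ones(n), dummies, cov])
    Xr = np.column_stack([np.ones(n), cov])
    def sse(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return r @ r
    df1 = len(levels) - 1
    df2 = n - Xf.shape[1]
    return ((sse(Xr) - sse(Xf)) / df1) / (sse(Xf) / df2)


class TestVoxelwiseAncova:
    def test_matches_per_voxel_oracle(self, rng):
        design = _toy_design(rng)
        maps = rng.standard_normal((32, 6, 6, 4))
        mask = np.ones((6, 6, 4), bool)
        statmap, _ = fit_voxelwise_ancova(maps, design, mask)
        for idx in np.ndindex(6, 6, 4):
            expected = oracle_f(maps[(slice(None),) + idx], design.groups,
                                design.covariates)
            assert statmap.f_values[idx] == pytest.approx(expected, rel=1e-8)

    def test_degrees_of_freedom_arithmetic(self, rng):
        statmap, _ = fit_voxelwise_ancova(
            np.random.default_rng(0).standard_normal((32, 4, 4, 2)),
            _toy_design(rng), np.ones((4, 4, 2), bool))
        assert statmap.df1 == 3
        assert statmap.df2 == 32 - 4 - 5

    def test_null_f_values_follow_f_distribution(self):
        """Identical group distributions: KS vs F(3, 23), median p > 0.01."""
        pvals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            design = _toy_design(rng)
            maps = rng.standard_normal((32, 8, 8, 6))
            statmap, _ = fit_voxelwise_ancova(maps, design,
                                              np.ones((8, 8, 6), bool))
            f = statmap.f_values.ravel()
            pvals.append(sps.kstest(f, "f", args=(3, 23)).pvalue)
        assert np.median(pvals) > 0.01

    def test_f_invariant_to_group_reference_choice(self, rng):
        maps = rng.standard_normal((32, 4, 4, 2))
        cov = rng.standard_normal((32, 5))
        g1 = np.repeat(["NC", "SCD", "aMCI", "dAD"], 8)
        order = rng.permutation(32)
        a, _ = fit_voxelwise_ancova(maps, DesignInfo(g1, cov),
                                    np.ones((4, 4, 2), bool))
        b, _ = fit_voxelwise_ancova(maps[order],
                                    DesignInfo(g1[order], cov[order]),
                                    np.ones((4, 4, 2), bool))
        assert np.allclose(a.f_values, b.f_values, rtol=1e-8)

    def test_standardized_residuals_unit_variance(self, rng):
        design = _toy_design(rng)
        maps = rng.standard_normal((32, 4, 4, 2))
        mask = np.ones((4, 4, 2), bool)
        statmap, resid = fit_voxelwise_ancova(maps, design, mask)
        ss = (resid**2).sum(axis=0)
        assert np.allclose(ss[mask], statmap.df2, rtol=1e-8)


class TestSmoothness:
    def test_recovers_known_6mm_kernel_within_20pct(self):
        dims = (24, 24, 18)
        mask = compartment_masks(dims)["gm"]
        sigma = 6.0 / 2.3548 / 3.0
        ests = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            fields = gaussian_filter(rng.standard_normal((16,) + dims),
                                     (0,) + (sigma,) * 3)
            sm = estimate_smoothness(fields, mask, (3.0, 3.0, 3.0))
            ests.append(np.mean(sm.fwhm_mm))
        assert abs(np.mean(ests) - 6.0) / 6.0 < 0.2

    def test_white_noise_hits_lattice_floor_below_two_voxels(self, rng):
        dims = (16, 16, 12)
        mask = np.zeros(dims, bool)
        mask[2:-2, 2:-2, 2:-2] = True
        sm = estimate_smoothness(rng.standard_normal((16,) + dims), mask,
                                 (3.0, 3.0, 3.0))
        floor = 3.0 * np.sqrt(2 * np.log(2))  # voxel * sqrt(4 ln2 / 2)
        for f in sm.fwhm_mm:
            assert f == pytest.approx(floor, rel=1e-6)
            assert f < 2 * 3.0

    def test_fwhm_scales_linearly_with_voxel_size(self, rng):
        dims = (16, 16, 12)
        mask = np.ones(dims, bool)
        fields = gaussian_filter(rng.standard_normal((8,) + dims),
                                 (0, 1.2, 1.2, 1.2))
        a = estimate_smoothness(fields, mask, (3.0, 3.0, 3.0))
        b = estimate_smoothness(fields, mask, (6.0, 6.0, 6.0))
        assert np.allclose(np.array(b.fwhm_mm), 2 * np.array(a.fwhm_mm))


class TestGrfClusters:
    def _stat_and_smooth(self, rng, effect_region=None, parc=None,
                         effect=0.0):
        """ANCOVA stat map from smoothed-noise subject maps, optionally with
        a planted group effect added in one parcel."""
        dims = (24, 24, 18)
        mask = compartment_masks(dims)["gm"]
        sigma = 6.0 / 2.3548 / 3.0
        maps = gaussian_filter(rng.standard_normal((32,) + dims),
                               (0,) + (sigma,) * 3)
        groups = np.repeat(["NC", "SCD", "aMCI", "dAD"], 8)
        if effect_region is not None:
            bump = (parc.labels == effect_region).astype(float)
            maps[groups == "dAD"] += effect * bump
        design = DesignInfo(groups=groups,
                            covariates=rng.standard_normal((32, 5)))
        statmap, resid = fit_voxelwise_ancova(maps, design, mask)
        smooth = estimate_smoothness(resid, mask, (3.0, 3.0, 3.0),
                                     error_df=statmap.df2)
        return statmap, smooth, mask

    def test_subthreshold_map_gives_empty_report(self, rng):
        statmap, smooth, _ = self._stat_and_smooth(rng)
        capped = statmap.f_values.copy()
        capped[:] = np.minimum(capped, 1.0)
        from alffband.stats import StatMap
        weak = StatMap(f_values=capped, df1=statmap.df1, df2=statmap.df2,
                       mask=statmap.mask)
        assert grf_cluster_threshold(weak, smooth, VoxelGrid()) == []

    def test_planted_effect_hosts_largest_cluster(self, default_parc):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            statmap, smooth, _ = self._stat_and_smooth(
                rng, effect_region=67, parc=default_parc, effect=1.5)
            clusters = grf_cluster_threshold(statmap, smooth, VoxelGrid())
            if not clusters:
                continue
            top = clusters[0]
            labels = default_parc.labels[tuple(top.voxels.T)]
            if np.any(labels == 67):
                hits += 1
        assert hits >= 18

    def test_cluster_report_fields_are_consistent(self, default_parc):
        rng = np.random.default_rng(7)
        statmap, smooth, mask = self._stat_and_smooth(
            rng, effect_region=67, parc=default_parc, effect=2.0)
        clusters = grf_cluster_threshold(statmap, smooth, VoxelGrid())
        assert clusters, "strong planted effect should survive"
        for c in clusters:
            assert c.size == len(c.voxels)
            assert 0 < c.corrected_p < 0.05
            assert any(np.array_equal(np.array(c.peak_ijk), v)
                       for v in c.voxels)
            assert c.peak_stat == statmap.f_values[c.peak_ijk]


class TestPosthoc:
    def test_identical_groups_all_adjusted_p_one(self, rng):
        # literally identical samples per group: zero contrasts, p = 1
        pattern = rng.standard_normal(10)
        y = np.tile(pattern, 4)
        groups = np.repeat(["NC", "SCD", "aMCI", "dAD"], 10)
        design = DesignInfo(groups=groups, covariates=np.empty((40, 0)))
        out = posthoc_pairwise(y, design)
        assert len(out) == 6
        assert np.allclose(out["t"], 0.0, atol=1e-10)
        assert np.all(out["p_bonferroni"] == 1.0)

    def test_two_groups_no_covariates_matches_pooled_t(self, rng):
        ya = rng.standard_normal(12) + 1.0
        yb = rng.standard_normal(10)
        y = np.concatenate([ya, yb])
        groups = np.array(["A"] * 12 + ["B"] * 10)
        design = DesignInfo(groups=groups, covariates=np.empty((22, 0)))
        out = posthoc_pairwise(y, design)
        t_ref, p_ref = sps.ttest_ind(ya, yb)
        assert out.loc[0, "t"] == pytest.approx(t_ref, rel=1e-10)
        assert out.loc[0, "p_uncorrected"] == pytest.approx(p_ref, rel=1e-10)

    def test_four_groups_give_six_comparisons(self, rng):
        design = _toy_design(rng, n_per=4)
        out = posthoc_pairwise(rng.standard_normal(16), design)
        assert len(out) == 6

    def test_small_group_rejected(self, rng):
        groups = np.array(["A"] * 5 + ["B"])
        design = DesignInfo(groups=groups, covariates=np.empty((6, 0)))
        with pytest.raises(ValueError, match="B"):
            posthoc_pairwise(rng.standard_normal(6), design)


class TestPartialCorrelation:
    def test_without_covariates_reduces_to_pearson(self, rng):
        x, y = rng.standard_normal((2, 30))
        r, p = partial_correlation(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert r == pytest.approx(r_ref, rel=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_score_fully_explained_by_covariates_gives_zero(self, rng):
        C = rng.standard_normal((40, 3))
        x = rng.standard_normal(40)
        y = C @ np.array([1.0, -2.0, 0.5]) + 3.0
        r, _ = partial_correlation(x, y + 1e-3 * rng.standard_normal(40), C)
        assert abs(r) < 0.3  # residual y is pure jitter, uncorrelated with x

    def test_matches_inverse_correlation_matrix_oracle(self, rng):
        data = rng.standard_normal((60, 5))
        x, y, C = data[:, 0], data[:, 1], data[:, 2:]
        r, _ = partial_correlation(x, y, C)
        prec = np.linalg.inv(np.corrcoef(data.T))
        r_oracle = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        assert r == pytest.approx(r_oracle, abs=1e-10)


class TestBonferroniGate:
    @pytest.mark.parametrize("p, m, expect_sig", [
        (0.009, 5, True),   # 0.009 < 0.05/5
        (0.02, 5, False),
        (0.04, 1, True),    # plain 0.05 gate
    ])
    def test_threshold_rule(self, p, m, expect_sig):
        sig, p_adj = bonferroni_gate(p, m)
        assert sig is expect_sig
        assert p_adj == pytest.approx(min(1.0, m * p))

    def test_adjusted_p_never_decreases_and_caps_at_one(self):
        for p in (0.0, 0.001, 0.2, 0.5, 1.0):
            _, p_adj = bonferroni_gate(p, 5)
            assert p_adj >= p
            assert p_adj <= 1.0
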