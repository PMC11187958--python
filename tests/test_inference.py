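"""Permutation inference, TFCE, and the scalar clinical/demographic statistics."""

from collections import deque

import numpy as np
import pytest

from seedfc import (TFCEParams, chi_square_2x2, classify_remitters,
                    fwer_pvalues, paired_change_map, paired_ttest,
                    partial_correlation, percent_change, permutation_corr_map,
                    permutation_ttest_map, remove_outliers, tfce_enhance,
                    two_sample_t)


class TestPercentChange:
    @pytest.mark.parametrize("pre,post,expect", [
        (20, 10, -50.0), (15, 15, 0.0), (32, 40, 25.0),
    ])
    def test_values(self, pre, post, expect):
        assert percent_change(pre, post) == pytest.approx(expect)

    def test_zero_baseline_errors(self):
        with pytest.raises(ValueError):
            percent_change(0, 5)


class TestRemoveOutliers:
    def test_single_pass_keeps_borderline_point(self):
        # mean 20, sample SD 44.72 -> |100-20| = 80 < 3*44.72: retained
        keep = remove_outliers([0, 0, 0, 0, 100])
        assert keep.tolist() == [0, 1, 2, 3, 4]

    def test_planted_extreme_value_removed(self, rng):
        v = np.concatenate([rng.standard_normal(50), [10.0]])
        keep = remove_outliers(v)
        assert 50 not in keep
        assert len(keep) >= 49

    def test_zero_sd_retains_all(self):
        assert remove_outliers([5, 5, 5, 5]).tolist() == [0, 1, 2, 3]


def brute_tfce(stat, params):
    """Independent oracle: explicit threshold loop with BFS flood fill."""
    shape = stat.shape
    offsets = [(dx, dy, dz)
               for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
               if (dx, dy, dz) != (0, 0, 0)]

    def component_sizes(mask):
        sizes = np.zeros(shape)
        seen = np.zeros(shape, dtype=bool)
        for start in zip(*np.nonzero(mask)):
            if seen[start]:
                continue
            comp, queue = [], deque([start])
            seen[start] = True
            while queue:
                v = queue.popleft()
                comp.append(v)
                for off in offsets:
                    u = tuple(v[i] + off[i] for i in range(3))
                    if all(0 <= u[i] < shape[i] for i in range(3)) \
                            and mask[u] and not seen[u]:
                        seen[u] = True
                        queue.append(u)
            for v in comp:
                sizes[v] = len(comp)
        return sizes

    out = np.zeros(shape)
    for sign in (1.0, -1.0):
        v = np.maximum(sign * stat, 0.0)
        if v.max() <= 0:
            continue
        dh = v.max() / params.n_height_steps
        for i in range(1, params.n_height_steps + 1):
            h = i * dh
            mask = v >= h
            sizes = component_sizes(mask)
            out += sign * np.where(
                mask, sizes**params.extent_power * h**params.height_power * dh, 0.0)
    return out


class TestTfce:
    def test_matches_brute_force_oracle_on_random_maps(self, rng):
        params = TFCEParams(n_height_steps=40)
        for _ in range(3):
            stat = rng.standard_normal((6, 6, 6))
            mine = tfce_enhance(stat, params)
            oracle = brute_tfce(stat, params)
            scale = np.abs(oracle).max()
            assert np.abs(mine - oracle).max() <= 1e-6 * scale

    def test_single_voxel_closed_form(self):
        # isolated voxel of height s: integral of h^2 dh = s^3/3
        stat = np.zeros((6, 6, 6))
        stat[3, 3, 3] = 3.0
        val = tfce_enhance(stat, TFCEParams(n_height_steps=1000))[3, 3, 3]
        assert val == pytest.approx(9.0, rel=0.02)

    def test_monotone_in_voxel_height(self, rng):
        params = TFCEParams(n_height_steps=50)
        stat = np.abs(rng.standard_normal((5, 5, 5)))
        raised = stat.copy()
        raised[2, 2, 2] += 1.0
        assert (tfce_enhance(raised, params) >= tfce_enhance(stat, params) - 1e-12).all()

    def test_disjoint_identical_blobs_equal(self):
        stat = np.zeros((8, 8, 8))
        stat[1:3, 1:3, 1:3] = 2.0
        stat[5:7, 5:7, 5:7] = 2.0
        out = tfce_enhance(stat, TFCEParams())
        assert np.allclose(out[1:3, 1:3, 1:3], out[5:7, 5:7, 5:7])

    def test_zero_map_passthrough(self):
        assert not tfce_enhance(np.zeros((4, 4, 4)), TFCEParams()).any()

    def test_negative_tail_antisymmetric(self, rng):
        params = TFCEParams(n_height_steps=50)
        stat = rng.standard_normal((5, 5, 5))
        assert np.allclose(tfce_enhance(-stat, params), -tfce_enhance(stat, params))


class TestFwerPvalues:
    def test_observed_above_all_null(self):
        null = np.arange(499, dtype=float)
        p = fwer_pvalues(np.array([1e9]), null)
        assert p[0] == pytest.approx(1 / 500)

    def test_zero_observation_has_p_one(self):
        null = np.abs(np.random.default_rng(0).standard_normal(99)) + 0.1
        assert fwer_pvalues(np.array([0.0]), null)[0] == 1.0

    def test_monotone_nonincreasing_in_observed(self, rng):
        null = rng.random(200)
        obs = np.sort(rng.random(50))
        p = fwer_pvalues(obs, null)
        assert (np.diff(p) <= 1e-15).all()

    def test_empty_null_errors(self):
        with pytest.raises(ValueError):
            fwer_pvalues(np.array([1.0]), np.array([]))


class TestPairedChangeMap:
    def test_post_equals_pre_gives_zero(self, rng):
        maps = [rng.standard_normal((4, 4, 4)) for _ in range(5)]
        delta = paired_change_map(maps, maps)
        assert not delta.any()

    def test_single_subject_single_voxel(self):
        pre = np.zeros((2, 2, 2))
        post = np.zeros((2, 2, 2))
        pre[0, 0, 0], post[0, 0, 0] = 0.2, 0.5
        delta = paired_change_map([pre], [post])
        assert delta[0, 0, 0, 0] == pytest.approx(0.3)

    def test_linearity_in_inputs(self, rng):
        pre = [rng.standard_normal((3, 3, 3)) for _ in range(4)]
        post = [rng.standard_normal((3, 3, 3)) for _ in range(4)]
        d1 = paired_change_map(pre, post)
        d2 = paired_change_map([2 * m for m in pre], [2 * m for m in post])
        assert np.allclose(d2, 2 * d1)

    def test_unmatched_subjects_error(self):
        from seedfc import ConnectivityMap
        a = ConnectivityMap(np.zeros((2, 2, 2)), "sfc_z", subject_id="sub-000")
        b = ConnectivityMap(np.zeros((2, 2, 2)), "sfc_z", subject_id="sub-001")
        with pytest.raises(ValueError, match="unmatched"):
            paired_change_map([a], [b])


def random_delta(rng, n=12, shape=(8, 8, 6)):
    return rng.standard_normal((n,) + shape)


class TestPermutationTtestMap:
    def test_sign_flip_swaps_tails_exactly(self, rng):
        delta = random_delta(rng)
        covs = rng.standard_normal((12, 2))
        kw = dict(covariates=covs, params=TFCEParams(n_height_steps=30),
                  n_perm=120, seed=3)
        res_pos = permutation_ttest_map(delta, **kw)
        res_neg = permutation_ttest_map(-delta, **kw)
        assert np.allclose(res_neg.stat_map, -res_pos.stat_map)
        assert np.allclose(res_neg.tfce_map, -res_pos.tfce_map)
        assert np.allclose(res_neg.p_map, res_pos.p_map)

    def test_planted_block_detected(self, rng):
        hits = 0
        n_rep = 12
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            delta = r.standard_normal((20, 8, 8, 6))
            delta[:, 2:5, 2:5, 2:5] += 0.9  # ~1 SD planted change, 27 voxels
            res = permutation_ttest_map(delta, covariates=r.standard_normal((20, 2)),
                                        params=TFCEParams(n_height_steps=30),
                                        n_perm=250, seed=rep)
            if res.p_map[2:5, 2:5, 2:5].min() < 0.05:
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_reproducible_given_seed(self, rng):
        delta = random_delta(rng)
        a = permutation_ttest_map(delta, n_perm=100, seed=9,
                                  params=TFCEParams(n_height_steps=20))
        b = permutation_ttest_map(delta, n_perm=100, seed=9,
                                  params=TFCEParams(n_height_steps=20))
        assert np.array_equal(a.p_map, b.p_map)

    def test_too_few_subjects_error(self, rng):
        with pytest.raises(ValueError, match="8 subjects"):
            permutation_ttest_map(random_delta(rng, n=5), n_perm=100)

    def test_min_attainable_p(self, rng):
        res = permutation_ttest_map(random_delta(rng), n_perm=199, seed=0,
                                    params=TFCEParams(n_height_steps=20))
        assert res.min_attainable_p == pytest.approx(1 / 200)
        assert res.p_map.min() >= res.min_attainable_p


class TestPermutationCorrMap:
    def test_relabeling_invariance_of_observed_stat(self, rng):
        delta = random_delta(rng, n=15)
        pc = rng.standard_normal(15)
        covs = rng.standard_normal((15, 2))
        kw = dict(params=TFCEParams(n_height_steps=20), n_perm=100, seed=4)
        res = permutation_corr_map(delta, pc, covs, **kw)
        perm = rng.permutation(15)
        res_p = permutation_corr_map(delta[perm], pc[perm], covs[perm], **kw)
        assert np.allclose(res.stat_map, res_p.stat_map)

    def test_planted_slope_sign_recovered(self, rng):
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            r = np.random.default_rng(1000 + rep)
            pc = r.standard_normal(20)
            delta = r.standard_normal((20, 8, 8, 6))
            delta[:, 2:4, 2:4, 2:4] += 0.8 * pc[:, None, None, None]
            res = permutation_corr_map(delta, pc, r.standard_normal((20, 2)),
                                       params=TFCEParams(n_height_steps=30),
                                       n_perm=200, seed=rep)
            if res.stat_map[2:4, 2:4, 2:4].mean() > 0:
                hits += 1
        assert hits >= 0.95 * n_rep

    def test_constant_clinical_vector_errors(self, rng):
        with pytest.raises(ValueError, match="constant"):
            permutation_corr_map(random_delta(rng), np.ones(12), n_perm=100)


class TestPartialCorrelation:
    def test_reduces_to_pearson_without_covariates(self, rng):
        x, y = rng.standard_normal((2, 40))
        r, _ = partial_correlation(x, y)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_covariate_explained_y_gives_zero(self, rng):
        # projection argument: if y lies in the covariate span its residual
        # vanishes and nothing is left to correlate
        C = rng.standard_normal((50, 2))
        y = 2.0 * C[:, 0] - C[:, 1] + 3.0
        x = rng.standard_normal(50)
        r, p = partial_correlation(x, y, C)
        assert abs(r) < 1e-6

    def test_identical_vectors(self, rng):
        x = rng.standard_normal(30)
        r, p = partial_correlation(x, x)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)


class TestScalarTests:
    def test_paired_ttest_hand_value(self):
        t, df, p = paired_ttest([0, 0, 0], [1, 2, 3])
        assert t == pytest.approx(3.4641016, abs=1e-6)
        assert df == 2

    def test_paired_ttest_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            paired_ttest([1, 2, 3], [2, 3, 4])

    def test_paired_ttest_antisymmetric(self, rng):
        pre, post = rng.standard_normal((2, 15))
        t1, _, _ = paired_ttest(pre, post)
        t2, _, _ = paired_ttest(post, pre)
        assert t1 == pytest.approx(-t2)

    def test_two_sample_summary_equals_raw(self, rng):
        a = rng.standard_normal(20) * 3 + 1
        b = rng.standard_normal(25) * 2
        t_raw, df_raw, _ = two_sample_t(a, b)
        t_sum, df_sum, _ = two_sample_t(
            (20, a.mean(), a.std(ddof=1)), (25, b.mean(), b.std(ddof=1)))
        assert t_sum == pytest.approx(t_raw, abs=1e-10)
        assert df_sum == df_raw

    def test_identical_groups_give_zero(self, rng):
        a = rng.standard_normal(10)
        t, _, p = two_sample_t(a, a)
        assert t == pytest.approx(0.0)

    def test_chi2_proportional_table_is_zero(self):
        chi2, df, p = chi_square_2x2([[10, 20], [30, 60]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1

    def test_chi2_transpose_invariant(self):
        a, *_ = chi_square_2x2([[11, 44], [7, 51]])
        b, *_ = chi_square_2x2([[11, 7], [44, 51]])
        assert a == pytest.approx(b)

    def test_chi2_zero_margin_errors(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 9]])

    @pytest.mark.parametrize("score,expect", [(6, True), (7, True), (8, False)])
    def test_remission_boundary(self, score, expect):
        assert classify_remitters([score]) == [expect]

    def test_remitter_list(self):
        assert classify_remitters([6, 7, 8, 20]) == [True, True, False, False]

    def test_negative_score_errors(self):
        with pytest.raises(ValueError):
            classify_remitters([-1])
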