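"""GLM contrasts, TFCE, block-restricted permutation and GPD tail."""

import math

import numpy as np
import pytest
from scipy import stats

from framesync.inference import (
    TFCEParams,
    audit_exchangeability,
    build_condition_design,
    contrast_vector,
    glm_contrast_stat,
    gpd_tail_pvalue,
    permute_and_correct,
    permute_and_correct_segments,
    tfce,
)


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------

def paired_fixture(n_pairs=6, n_vox=5, d=0.7, noise=1.0, seed=0):
    """Two-condition repeated-measures samples with a known mean difference."""
    rng = np.random.default_rng(seed)
    block_ids = np.repeat(np.arange(n_pairs), 2)
    cond_idx = np.tile([0, 1], n_pairs)
    base = rng.standard_normal((n_pairs, n_vox))
    Y = np.empty((2 * n_pairs, n_vox))
    for p in range(n_pairs):
        Y[2 * p] = base[p] + d + noise * rng.standard_normal(n_vox)
        Y[2 * p + 1] = base[p] + noise * rng.standard_normal(n_vox)
    return Y, block_ids, cond_idx


class TestGlmContrastStat:
    def test_equals_paired_t_oracle(self):
        """GLM with pair mean regressors is algebraically the paired t-test."""
        Y, block_ids, cond_idx = paired_fixture()
        X = build_condition_design(block_ids, cond_idx, 2)
        t = glm_contrast_stat(Y, X, contrast_vector(X.shape[1], 0, 1))
        diffs = Y[cond_idx == 0] - Y[cond_idx == 1]
        oracle = stats.ttest_1samp(diffs, 0.0, axis=0).statistic
        np.testing.assert_allclose(t, oracle, atol=1e-10)

    def test_zero_residual_limit_capped_with_sign(self):
        block_ids = np.repeat(np.arange(4), 2)
        cond_idx = np.tile([0, 1], 4)
        base = np.arange(8, dtype=float)[:, None] * 0  # zeros
        Y = base.copy()
        Y[cond_idx == 0] += 2.0  # condition A exceeds B by exactly 2, no noise
        X = build_condition_design(block_ids, cond_idx, 2)
        t = glm_contrast_stat(Y, X, contrast_vector(X.shape[1], 0, 1))
        assert np.all(t == 1e6)
        t_neg = glm_contrast_stat(Y, X, contrast_vector(X.shape[1], 1, 0))
        assert np.all(t_neg == -1e6)

    def test_equal_group_means_give_small_t(self):
        Y, block_ids, cond_idx = paired_fixture(n_pairs=40, d=0.0, seed=2)
        X = build_condition_design(block_ids, cond_idx, 2)
        t = glm_contrast_stat(Y, X, contrast_vector(X.shape[1], 0, 1))
        assert np.all(np.abs(t) < 4.0)

    def test_rank_deficient_design_rejected(self):
        Y = np.zeros((6, 2))
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError, match="rank"):
            glm_contrast_stat(Y, X, np.array([1.0, 0.0]))


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------

def tfce_brute_force(stat_map, mask, E, H, dh):
    """Independent oracle: explicit threshold loop with BFS flood fill."""
    shape = stat_map.shape
    out = np.zeros(shape)
    for sign in (1.0, -1.0):
        vals = np.where(mask & (sign * stat_map > 0), sign * stat_map, 0.0)
        vmax = vals.max()
        h = dh
        while h <= vmax + 1e-12:
            above = vals >= h
            seen = np.zeros(shape, bool)
            for start in np.argwhere(above):
                start = tuple(start)
                if seen[start]:
                    continue
                queue, comp = [start], []
                seen[start] = True
                while queue:
                    v = queue.pop()
                    comp.append(v)
                    for ax in range(3):
                        for step in (-1, 1):
                            w = list(v)
                            w[ax] += step
                            w = tuple(w)
                            if (
                                0 <= w[ax] < shape[ax]
                                and above[w]
                                and not seen[w]
                            ):
                                seen[w] = True
                                queue.append(w)
                contrib = (len(comp) ** E) * (h**H) * dh
                for v in comp:
                    out[v] += sign * contrib
            h += dh
    return out


class TestTfce:
    def test_zero_map_stays_zero(self):
        m = np.zeros((4, 4, 4))
        np.testing.assert_array_equal(tfce(m, np.ones((4, 4, 4))), m)

    def test_isolated_voxel_closed_form(self):
        """Single voxel of height v integrates to v^3/3 for E=.5, H=2."""
        v = 3.7
        m = np.zeros((5, 5, 5))
        m[2, 2, 2] = v
        out = tfce(m, np.ones((5, 5, 5), bool), TFCEParams(dh=v / 1000))
        assert out[2, 2, 2] == pytest.approx(v**3 / 3, rel=0.01)

    def test_plateau_exceeds_single_voxel_by_sqrt2(self):
        v = 2.0
        single = np.zeros((5, 5, 5))
        single[2, 2, 2] = v
        plateau = single.copy()
        plateau[2, 2, 3] = v
        params = TFCEParams(dh=v / 1000)
        mask = np.ones((5, 5, 5), bool)
        ratio = tfce(plateau, mask, params)[2, 2, 2] / tfce(single, mask, params)[2, 2, 2]
        assert ratio == pytest.approx(math.sqrt(2), rel=0.01)

    def test_matches_brute_force_on_random_maps(self):
        rng = np.random.default_rng(3)
        mask = np.ones((6, 6, 6), bool)
        for seed in range(2):
            m = rng.standard_normal((6, 6, 6))
            dh = np.abs(m).max() / 25
            ours = tfce(m, mask, TFCEParams(dh=dh))
            oracle = tfce_brute_force(m, mask, 0.5, 2.0, dh)
            np.testing.assert_allclose(ours, oracle, atol=1e-8)

    def test_negative_values_resigned(self):
        m = np.zeros((4, 4, 4))
        m[1, 1, 1] = -2.0
        out = tfce(m, np.ones((4, 4, 4), bool), TFCEParams(dh=0.002))
        assert out[1, 1, 1] == pytest.approx(-(2.0**3) / 3, rel=0.01)

    def test_invalid_dh_rejected(self):
        with pytest.raises(ValueError, match="dh"):
            TFCEParams(dh=-1.0)


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def grid_ids(n_vox=27):
    return np.arange(n_vox)


class TestPermuteAndCorrect:
    mask = np.ones((3, 3, 3), bool)

    def test_exhaustive_enumeration_for_small_blocks(self):
        """2 conditions x 3 blocks -> 2^3 = 8 distinct relabelings."""
        Y, block_ids, cond_idx = paired_fixture(n_pairs=3, n_vox=27, seed=4)
        with pytest.warns(UserWarning, match="8 distinct"):
            res = permute_and_correct(
                Y, block_ids, cond_idx, [("a>b", 0, 1)], self.mask, grid_ids(),
                n_perm=100, seed=0,
            )
        assert res[0].exhaustive and res[0].n_permutations == 8
        assert res[0].p_fwe.min() >= 1 / 8

    def test_minimal_p_is_permutation_floor(self):
        """Observed labeling counts, so p can never drop below 1/(n+1)."""
        Y, block_ids, cond_idx = paired_fixture(n_pairs=10, n_vox=27, d=50.0,
                                                noise=0.01, seed=5)
        res = permute_and_correct(
            Y, block_ids, cond_idx, [("a>b", 0, 1)], self.mask, grid_ids(),
            n_perm=99, seed=1,
        )
        assert res[0].p_fwe.min() == pytest.approx(1 / 100)

    def test_p_monotone_in_observed_tfce(self):
        Y, block_ids, cond_idx = paired_fixture(n_pairs=8, n_vox=27, d=0.5, seed=6)
        res = permute_and_correct(
            Y, block_ids, cond_idx, [("a>b", 0, 1)], self.mask, grid_ids(),
            n_perm=150, seed=2,
        )[0]
        tf = res.observed_tfce[self.mask]
        p = res.p_fwe[self.mask]
        order = np.argsort(tf)
        assert np.all(np.diff(p[order]) <= 1e-12)

    def test_across_contrast_fwe_not_smaller_than_within(self):
        Y, block_ids, cond_idx = paired_fixture(n_pairs=8, n_vox=27, d=0.5, seed=7)
        kwargs = dict(n_perm=150, seed=3)
        contrasts = [("a>b", 0, 1), ("b>a", 1, 0)]
        within = permute_and_correct(
            Y, block_ids, cond_idx, contrasts, self.mask, grid_ids(), fwe="within", **kwargs
        )
        across = permute_and_correct(
            Y, block_ids, cond_idx, contrasts, self.mask, grid_ids(), fwe="across", **kwargs
        )
        for w, a in zip(within, across):
            assert np.all(a.p_fwe[self.mask] >= w.p_fwe[self.mask] - 1e-12)

    def test_deterministic_given_seed(self):
        Y, block_ids, cond_idx = paired_fixture(n_pairs=8, n_vox=27, seed=8)
        args = (Y, block_ids, cond_idx, [("a>b", 0, 1)], self.mask, grid_ids())
        r1 = permute_and_correct(*args, n_perm=120, seed=11)[0]
        r2 = permute_and_correct(*args, n_perm=120, seed=11)[0]
        np.testing.assert_array_equal(r1.max_null, r2.max_null)
        np.testing.assert_array_equal(r1.p_fwe, r2.p_fwe)

    def test_permutation_log_respects_blocks(self):
        Y, block_ids, cond_idx = paired_fixture(n_pairs=6, n_vox=27, seed=9)
        res = permute_and_correct(
            Y, block_ids, cond_idx, [("a>b", 0, 1)], self.mask, grid_ids(),
            n_perm=50, seed=4, log_permutations=True,
        )[0]
        assert len(res.permutation_log) == res.n_permutations
        assert audit_exchangeability(res.permutation_log, block_ids) == 0


class TestPermuteSegments:
    mask = np.ones((3, 3, 3), bool)

    def make_y4(self, d=0.0, n_pairs=6, n_stim=4, n_frames=3, seed=0):
        rng = np.random.default_rng(seed)
        Y4 = rng.standard_normal((n_pairs, n_stim, n_frames, 27))
        Y4[:, :, 0, :5] += d  # first condition, first 5 voxels
        cond_of = np.tile(np.arange(n_frames), (n_stim, 1))
        return Y4, cond_of

    def test_detects_planted_condition_difference(self):
        Y4, cond_of = self.make_y4(d=1.2, n_pairs=10, n_stim=10, seed=10)
        res = permute_and_correct_segments(
            Y4, cond_of, [("c0>c1", 0, 1)], self.mask, grid_ids(), n_perm=200, seed=5
        )[0]
        sig = res.p_fwe.ravel(order="F") <= 0.05
        assert sig[:5].all() and not sig[5:].any()

    def test_coherent_relabeling_logged_within_blocks(self):
        Y4, cond_of = self.make_y4(seed=11)
        res = permute_and_correct_segments(
            Y4, cond_of, [("c0>c1", 0, 1)], self.mask, grid_ids(),
            n_perm=40, seed=6, log_permutations=True,
        )[0]
        n_pairs, n_stim, n_frames, _ = Y4.shape
        rows_block = np.repeat(np.arange(n_pairs), n_stim * n_frames)
        assert audit_exchangeability(res.permutation_log, rows_block) == 0

    def test_deterministic_and_exhaustive_small_space(self):
        Y4, cond_of = self.make_y4(n_stim=1, n_frames=3, seed=12)
        with pytest.warns(UserWarning, match="6 distinct"):
            res = permute_and_correct_segments(
                Y4, cond_of, [("c0>c1", 0, 1)], self.mask, grid_ids(),
                n_perm=100, seed=7,
            )[0]
        assert res.exhaustive and res.n_permutations == 6


# ---------------------------------------------------------------------------
# GPD tail approximation
# ---------------------------------------------------------------------------

class TestGpdTail:
    def test_large_p_returned_unchanged(self):
        rng = np.random.default_rng(0)
        null = rng.exponential(size=500)
        obs = np.quantile(null, 0.5)
        emp = (1 + (null >= obs).sum()) / (len(null) + 1)
        assert gpd_tail_pvalue(obs, null) == pytest.approx(emp)

    def test_exponential_tail_recovered(self):
        """Null ~ Exp(1): the 0.001 quantile's refined p is near 0.001."""
        rng = np.random.default_rng(1)
        hits = 0
        for rep in range(10):
            null = rng.exponential(size=1000)
            obs = -math.log(0.001)  # true sf = 0.001
            p = gpd_tail_pvalue(obs, null)
            if 0.0005 <= p <= 0.002:
                hits += 1
        assert hits >= 7

    def test_far_observation_beats_empirical_floor(self):
        rng = np.random.default_rng(2)
        null = rng.exponential(size=1000)
        p = gpd_tail_pvalue(null.max() * 5, null)
        assert p < 1 / 1001

    def test_degenerate_null_falls_back(self):
        null = np.ones(200)
        with pytest.warns(UserWarning, match="degenerate|empirical"):
            p = gpd_tail_pvalue(2.0, null)
        assert p == pytest.approx(1 / 201)
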