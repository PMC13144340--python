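"""Pair maps, Fisher transform, condition averaging and baseline correction."""

import itertools
import math

import numpy as np
import pytest

from framesync.isc import (
    PairMap,
    all_pair_maps,
    average_by_condition,
    baseline_map,
    fisher_z,
    ordered_pairs,
    pearson_map,
    stack_condition_maps,
    stack_segment_maps,
    subtract_baseline,
)
from framesync.preprocess import MaskedSeries

from conftest import analyze_cohort, small_config


def series_of(matrix):
    matrix = np.atleast_2d(np.asarray(matrix, float))
    return MaskedSeries(np.arange(matrix.shape[0]), matrix)


class TestPearsonMap:
    def test_identical_series_correlate_perfectly(self):
        a = series_of(np.random.default_rng(0).standard_normal((5, 10)))
        np.testing.assert_allclose(pearson_map(a, a), 1.0)

    def test_negated_series(self):
        a = series_of(np.random.default_rng(1).standard_normal((5, 10)))
        b = series_of(-a.matrix)
        np.testing.assert_allclose(pearson_map(a, b), -1.0)

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal((4, 5)), rng.standard_normal((4, 5))
        r = pearson_map(series_of(x), series_of(y))
        oracle = [np.corrcoef(x[v], y[v])[0, 1] for v in range(4)]
        np.testing.assert_allclose(r, oracle, atol=1e-12)

    def test_zero_variance_voxel_yields_zero(self):
        x = np.random.default_rng(3).standard_normal((2, 8))
        x[0] = 5.0  # constant voxel
        r = pearson_map(series_of(x), series_of(np.random.default_rng(4).standard_normal((2, 8))))
        assert r[0] == 0.0 and np.isfinite(r[1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            pearson_map(series_of(np.zeros((1, 5))), series_of(np.zeros((1, 6))))


class TestFisherZ:
    def test_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.9) == pytest.approx(1.4722, abs=1e-4)

    def test_clamped_at_unity(self):
        z = fisher_z(1.0)
        assert np.isfinite(z)
        assert z == pytest.approx(math.atanh(1 - 1e-7), rel=1e-12)
        assert z == pytest.approx(8.41, abs=0.1)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.5)


class TestAllPairMaps:
    def test_pair_count(self, tiny_cohort):
        n = len(tiny_cohort["series"])
        n_seg = len(tiny_cohort["seg_table"])
        assert len(tiny_cohort["maps"]) == n * (n - 1) // 2 * n_seg
        assert len(ordered_pairs([f"sub-{i:02d}" for i in range(1, 28)])) == 351

    def test_symmetry_under_participant_order(self, tiny_cohort):
        """r(i, j) = r(j, i): map values do not depend on who comes first."""
        series = tiny_cohort["series"]
        pids = sorted(series)[:2]
        seg = sorted(series[pids[0]])[0]
        forward = pearson_map(series[pids[0]][seg], series[pids[1]][seg])
        backward = pearson_map(series[pids[1]][seg], series[pids[0]][seg])
        np.testing.assert_allclose(forward, backward, atol=1e-14)

    def test_missing_segment_named(self, tiny_cohort):
        series = {k: dict(v) for k, v in tiny_cohort["series"].items()}
        victim = sorted(series)[1]
        dropped = sorted(series[victim])[0]
        del series[victim][dropped]
        with pytest.raises(ValueError, match=victim):
            all_pair_maps(series)


class TestAverageByCondition:
    def make_maps(self, values_list, frame="neutral", topic="climate"):
        return [
            PairMap(("a", "b"), f"stim{k:02d}_{frame}", v, frame=frame, topic=topic)
            for k, v in enumerate(values_list)
        ]

    def test_identical_maps_average_to_member(self):
        v = np.random.default_rng(0).standard_normal(10)
        out = average_by_condition(self.make_maps([v] * 12))
        assert len(out) == 1
        np.testing.assert_allclose(out[0].values, v, rtol=1e-12)

    def test_opposite_maps_cancel(self):
        v = np.random.default_rng(1).standard_normal(10)
        out = average_by_condition(self.make_maps([v, -v]))
        np.testing.assert_allclose(out[0].values, 0.0, atol=1e-15)

    def test_matches_elementwise_mean_oracle(self):
        rng = np.random.default_rng(2)
        vals = [rng.standard_normal(6) for _ in range(3)]
        out = average_by_condition(self.make_maps(vals))
        np.testing.assert_allclose(out[0].values, np.mean(vals, axis=0), atol=1e-12)

    def test_unlabeled_maps_rejected(self):
        m = PairMap(("a", "b"), "stim01_neutral", np.zeros(3))
        with pytest.raises(ValueError, match="labels"):
            average_by_condition([m])

    def test_frame_topic_grouping(self, tiny_cohort):
        out = average_by_condition(tiny_cohort["maps"], grouping="frame_topic")
        scopes = {m.scope for m in out}
        n_pairs = 6
        assert len(out) == len(scopes) * n_pairs


class TestBaseline:
    def test_two_segments_give_two_ordered_combinations(self):
        rng = np.random.default_rng(0)
        si = {f"s{k}": series_of(rng.standard_normal((3, 12))) for k in range(2)}
        sj = {f"s{k}": series_of(rng.standard_normal((3, 12))) for k in range(2)}
        bm = baseline_map(("a", "b"), si, sj)
        oracle = np.mean(
            [
                fisher_z(pearson_map(si["s0"], sj["s1"])),
                fisher_z(pearson_map(si["s1"], sj["s0"])),
            ],
            axis=0,
        )
        np.testing.assert_allclose(bm.values, oracle, atol=1e-12)

    def test_unequal_lengths_truncated_to_shorter(self):
        rng = np.random.default_rng(1)
        si = {"s0": series_of(rng.standard_normal((2, 20))),
              "s1": series_of(rng.standard_normal((2, 14)))}
        sj = {"s0": series_of(rng.standard_normal((2, 20))),
              "s1": series_of(rng.standard_normal((2, 14)))}
        bm = baseline_map(("a", "b"), si, sj)
        a = fisher_z(pearson_map(series_of(si["s0"].matrix[:, :14]), sj["s1"]))
        b = fisher_z(pearson_map(si["s1"], series_of(sj["s0"].matrix[:, :14])))
        np.testing.assert_allclose(bm.values, (a + b) / 2, atol=1e-12)

    def test_single_segment_rejected(self):
        s = {"s0": series_of(np.random.default_rng(0).standard_normal((2, 12)))}
        with pytest.raises(ValueError, match="at least 2"):
            baseline_map(("a", "b"), s, s)

    def test_shared_drift_makes_baseline_positive(self):
        """Stimulus-nonspecific shared structure is exactly what it captures."""
        rng = np.random.default_rng(2)
        drift = np.linspace(-2, 2, 30)
        si = {f"s{k}": series_of(drift + 0.3 * rng.standard_normal(30)) for k in range(3)}
        sj = {f"s{k}": series_of(drift + 0.3 * rng.standard_normal(30)) for k in range(3)}
        bm = baseline_map(("a", "b"), si, sj)
        assert bm.values.mean() > 1.0

    def test_null_baseline_centered_on_zero(self):
        rng = np.random.default_rng(3)
        si = {f"s{k}": series_of(rng.standard_normal((20, 40))) for k in range(4)}
        sj = {f"s{k}": series_of(rng.standard_normal((20, 40))) for k in range(4)}
        bm = baseline_map(("a", "b"), si, sj)
        se = bm.values.std(ddof=1) / math.sqrt(bm.values.size)
        assert abs(bm.values.mean()) < 3 * se

    def test_subsampling_is_seeded(self):
        rng = np.random.default_rng(4)
        si = {f"s{k}": series_of(rng.standard_normal((2, 12))) for k in range(4)}
        sj = {f"s{k}": series_of(rng.standard_normal((2, 12))) for k in range(4)}
        a = baseline_map(("a", "b"), si, sj, max_combinations=5, seed=9)
        b = baseline_map(("a", "b"), si, sj, max_combinations=5, seed=9)
        np.testing.assert_array_equal(a.values, b.values)


class TestSubtractBaseline:
    def test_subtracting_self_zeroes(self):
        v = np.random.default_rng(0).standard_normal(8)
        m = PairMap(("a", "b"), "stim01_neutral", v, frame="neutral")
        base = PairMap(("a", "b"), "baseline", v)
        out = subtract_baseline(m, base)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-15)
        assert out.baseline_subtracted

    def test_zero_baseline_is_identity(self):
        v = np.random.default_rng(1).standard_normal(8)
        m = PairMap(("a", "b"), "stim01_neutral", v, frame="neutral")
        out = subtract_baseline(m, PairMap(("a", "b"), "baseline", np.zeros(8)))
        np.testing.assert_array_equal(out.values, v)

    def test_elementwise_oracle_and_double_subtraction_guard(self):
        rng = np.random.default_rng(2)
        v, w = rng.standard_normal(8), rng.standard_normal(8)
        m = PairMap(("a", "b"), "stim01_neutral", v, frame="neutral")
        out = subtract_baseline(m, PairMap(("a", "b"), "baseline", w))
        np.testing.assert_allclose(out.values, v - w, atol=1e-15)
        with pytest.raises(ValueError, match="already"):
            subtract_baseline(out, PairMap(("a", "b"), "baseline", w))

    def test_pair_mismatch_rejected(self):
        m = PairMap(("a", "b"), "stim01_neutral", np.zeros(3), frame="neutral")
        base = PairMap(("a", "c"), "baseline", np.zeros(3))
        with pytest.raises(ValueError, match="pair"):
            subtract_baseline(m, base)


class TestPipelineOracleEquivalence:
    def test_z_maps_match_brute_force_corrcoef(self):
        """Full pipeline z-maps equal atanh(corrcoef) per voxel to 1e-10."""
        cfg = small_config(n_participants=4, seed=13)
        out = analyze_cohort(cfg)
        maps = all_pair_maps(out["series"], out["seg_table"])
        series = out["series"]
        for m in maps[:12]:
            i, j = m.pair
            a, b = series[i][m.scope].matrix, series[j][m.scope].matrix
            oracle = np.array(
                [np.arctanh(np.clip(np.corrcoef(a[v], b[v])[0, 1], -(1 - 1e-7), 1 - 1e-7))
                 for v in range(a.shape[0])]
            )
            np.testing.assert_allclose(m.values, oracle, atol=1e-10)


class TestStacking:
    def test_condition_stack_row_order(self, tiny_cohort):
        cond = average_by_condition(tiny_cohort["maps"], "frame")
        Y, pairs, conditions, block_ids, cond_idx = stack_condition_maps(cond)
        assert Y.shape == (len(pairs) * len(conditions), 64)
        lookup = {(m.pair, m.scope): m.values for m in cond}
        k = 0
        for bi, pair in enumerate(pairs):
            for ci, c in enumerate(conditions):
                np.testing.assert_array_equal(Y[k], lookup[(pair, c)])
                assert block_ids[k] == bi and cond_idx[k] == ci
                k += 1

    def test_segment_stack_matches_condition_means(self, tiny_cohort):
        Y4, pairs, stimuli, conditions, cond_of = stack_segment_maps(
            tiny_cohort["maps"], "frame"
        )
        cond = average_by_condition(tiny_cohort["maps"], "frame")
        lookup = {(m.pair, m.scope): m.values for m in cond}
        for pi, pair in enumerate(pairs):
            for ci, c in enumerate(conditions):
                sel = np.flatnonzero(cond_of.ravel() == ci)
                mean = Y4[pi].reshape(-1, Y4.shape[-1])[sel].mean(axis=0)
                np.testing.assert_allclose(mean, lookup[(pair, c)], atol=1e-12)

    def test_incomplete_grid_rejected(self, tiny_cohort):
        with pytest.raises(ValueError, match="complete"):
            stack_segment_maps(tiny_cohort["maps"][:-1], "frame")
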