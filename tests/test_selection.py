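import numpy as np
import pytest

import twofilter as tf
from twofilter.evaluation import CvSpec
from twofilter.selection import _best_cell
from twofilter.stats import UP_IN_CLASS0, UP_IN_CLASS1


def random_stats(rng, n=60):
    return [
        tf.FeatureStats(f"g{i}", float(rng.normal(scale=1.5)),
                        float(rng.uniform(1e-6, 1.0)))
        for i in range(n)
    ]


class TestTwoWayFilter:
    def test_vacuous_thresholds_return_all(self, rng):
        stats = random_stats(rng)
        fs = tf.two_way_filter(stats, tf.FilterThresholds(0.0, 1.0))
        assert set(fs.feature_ids) == {s.feature_id for s in stats}

    def test_each_threshold_excludes(self):
        stats = [tf.FeatureStats("a", 2.0, 0.001),
                 tf.FeatureStats("b", 0.5, 0.001),
                 tf.FeatureStats("c", -2.0, 0.5)]
        fs = tf.two_way_filter(stats, tf.FilterThresholds(1.0, 0.01))
        assert fs.feature_ids == ["a"]

    def test_matches_predicate_oracle(self, rng):
        stats = random_stats(rng, 200)
        for _ in range(20):
            t = tf.FilterThresholds(float(rng.uniform(0, 3)),
                                    float(rng.uniform(0.001, 1)))
            fs = tf.two_way_filter(stats, t)
            expect = {s.feature_id for s in stats
                      if abs(s.mean_diff) >= t.t1 and s.mw_p <= t.t2}
            assert set(fs.feature_ids) == expect

    def test_ordering(self):
        stats = [tf.FeatureStats("b", 1.0, 0.05),
                 tf.FeatureStats("a", 1.0, 0.05),
                 tf.FeatureStats("c", -3.0, 0.2),
                 tf.FeatureStats("d", 2.0, 0.01)]
        fs = tf.two_way_filter(stats, tf.FilterThresholds(0.0, 1.0))
        assert fs.feature_ids == ["c", "d", "a", "b"]

    def test_monotone_in_thresholds(self, rng):
        stats = random_stats(rng, 150)
        for _ in range(20):
            t1s = np.sort(rng.uniform(0, 2.5, size=4))
            t2s = np.sort(rng.uniform(0.001, 1, size=4))[::-1]
            prev = None
            for t1, t2 in zip(t1s, t2s):
                cur = set(tf.two_way_filter(
                    stats, tf.FilterThresholds(float(t1), float(t2))).feature_ids)
                if prev is not None:
                    assert cur <= prev
                prev = cur


class TestBuildGrid:
    def test_default_is_200_cells(self, rng):
        grid = tf.build_grid(random_stats(rng))
        assert grid.n_cells == 200
        assert len(grid.cells) == 200

    def test_degenerate_stats_still_well_formed(self):
        stats = [tf.FeatureStats(f"g{i}", 1.0, 0.5) for i in range(10)]
        grid = tf.build_grid(stats)
        assert grid.n_cells == 200
        assert all(v == 1.0 for v in grid.t1_values)

    def test_t1_axis_within_observed_range(self, rng):
        stats = random_stats(rng, 300)
        amd = [s.abs_mean_diff for s in stats]
        grid = tf.build_grid(stats)
        assert min(grid.t1_values) >= min(amd)
        assert max(grid.t1_values) <= max(amd)

    def test_t2_axis_bounds(self, rng):
        stats = random_stats(rng, 300)
        grid = tf.build_grid(stats)
        assert max(grid.t2_values) == pytest.approx(0.1)
        assert min(grid.t2_values) >= 1e-6


class TestBestCell:
    def test_tie_breaking_order(self):
        # equal AUROC: prefer fewer features, then stricter p, then larger t1
        mean_auc = np.array([0.8, 0.8, 0.8, 0.7])
        n_feat = np.array([10.0, 5.0, 5.0, 1.0])
        t1s = np.array([0.5, 0.5, 0.5, 2.0])
        t2s = np.array([0.1, 0.05, 0.01, 0.1])
        assert _best_cell(mean_auc, n_feat, t1s, t2s) == 2


class TestGridSearch:
    def test_singleton_grid(self, signal_cohort):
        cohort, m = signal_cohort
        grid = tf.ThresholdGrid((1.0,), (0.01,))
        best, surface = tf.grid_search(m, cohort.labels, grid, CvSpec(seed=2))
        assert best == tf.FilterThresholds(1.0, 0.01)
        assert len(surface) == 1

    def test_rejects_noise_admitting_cells(self):
        # spiked features have |mean diff| >= 2; all noise well below 1:
        # the winner must not open the filter to the noise floor
        c = tf.generate(tf.GeneratorConfig(seed=31, effect_size=3.0,
                                           n_features=500, n_samples=120))
        m = tf.floor_and_log(c.expression)
        stats = tf.compute_feature_stats(m, c.labels)
        grid = tf.build_grid(stats, n_t1=10, n_t2=5)
        best, _ = tf.grid_search(m, c.labels, grid, CvSpec(repeats=2, seed=3))
        noise_amd = [s.abs_mean_diff for s in stats
                     if s.feature_id not in c.truth_ids]
        assert best.t1 > np.max(noise_amd)

    def test_surface_reproducible(self, null_cohort):
        cohort, m = null_cohort
        stats = tf.compute_feature_stats(m, cohort.labels)
        grid = tf.build_grid(stats, n_t1=6, n_t2=4)
        _, s1 = tf.grid_search(m, cohort.labels, grid, CvSpec(seed=21))
        _, s2 = tf.grid_search(m, cohort.labels, grid, CvSpec(seed=21))
        assert s1.equals(s2)


class TestSelectFeatures:
    def test_recovers_planted_features(self, signal_cohort):
        cohort, m = signal_cohort
        fs = tf.select_features(m, cohort.labels, spec=CvSpec(seed=17))
        recall, precision = tf.truth_recovery_report(cohort, fs)
        assert recall >= 0.8
        assert precision >= 0.7
        assert fs.cv_performance.mean_auroc > 0.9

    def test_both_directions_populated(self, signal_cohort):
        cohort, m = signal_cohort
        fs = tf.select_features(m, cohort.labels, spec=CvSpec(seed=17))
        dirs = fs.by_direction()
        assert dirs[UP_IN_CLASS1] and dirs[UP_IN_CLASS0]

    def test_members_satisfy_thresholds(self, signal_cohort):
        cohort, m = signal_cohort
        fs = tf.select_features(m, cohort.labels, spec=CvSpec(seed=17))
        for s in fs.members:
            assert s.abs_mean_diff >= fs.thresholds.t1
            assert s.mw_p <= fs.thresholds.t2

    def test_label_swap_flips_directions_only(self, signal_cohort):
        cohort, m = signal_cohort
        y = cohort.labels
        a = tf.select_features(m, y, spec=CvSpec(seed=23))
        b = tf.select_features(m, 1 - y, spec=CvSpec(seed=23))
        assert set(a.feature_ids) == set(b.feature_ids)
        da, db = a.by_direction(), b.by_direction()
        assert set(da[UP_IN_CLASS1]) == set(db[UP_IN_CLASS0])
        assert set(da[UP_IN_CLASS0]) == set(db[UP_IN_CLASS1])

    def test_null_data_yields_empty_or_weak_set(self, null_cohort):
        cohort, m = null_cohort
        fs = tf.select_features(m, cohort.labels, spec=CvSpec(seed=29))
        if fs.members:
            assert fs.cv_performance.mean_auroc >= 0.65
        else:
            assert fs.cv_performance.mean_auroc < 0.65

    def test_deterministic(self, signal_cohort):
        cohort, m = signal_cohort
        a = tf.select_features(m, cohort.labels, spec=CvSpec(seed=17))
        b = tf.select_features(m, cohort.labels, spec=CvSpec(seed=17))
        assert a == b


class TestIterativeDiscovery:
    def test_rounds_disjoint_and_recover_spikes(self):
        c = tf.generate(tf.GeneratorConfig(
            seed=41, n_informative_up=10, n_informative_down=10))
        m = tf.floor_and_log(c.expression)
        res = tf.iterative_discovery(m, c.labels, spec=CvSpec(seed=43),
                                     max_rounds=3)
        ids = res.all_feature_ids
        assert len(ids) == len(set(ids))  # pairwise disjoint rounds
        recall, _ = tf.truth_recovery_report(c, ids)
        assert recall >= 0.8

    def test_pure_noise_stops_immediately(self, null_cohort):
        cohort, m = null_cohort
        res = tf.iterative_discovery(m, cohort.labels, spec=CvSpec(seed=47))
        assert len(res.rounds) <= 1
        assert res.stop_reason in ("performance_floor", "empty_set",
                                   "max_rounds")


class TestEstimators:
    def test_two_way_filter_cv_transform(self, signal_cohort):
        cohort, m = signal_cohort
        X = m.values.T  # DataFrame: samples x features, named columns
        sel = tf.TwoWayFilterCV(random_state=17).fit(X, cohort.labels)
        assert set(sel.feature_set_.feature_ids) <= set(X.columns)
        reduced = sel.transform(X.to_numpy())
        assert reduced.shape == (X.shape[0], len(sel.feature_set_.members))
        assert sel.surface_.shape[0] == 200

    def test_iterative_estimator_matches_function(self, signal_cohort):
        cohort, m = signal_cohort
        est = tf.IterativeDiscovery(random_state=19, max_rounds=2)
        est.fit(m.values.T, cohort.labels)
        res = tf.iterative_discovery(m, cohort.labels,
                                     spec=CvSpec(seed=19), max_rounds=2)
        assert [fs.feature_ids for fs in est.rounds_] \
            == [fs.feature_ids for fs in res.rounds]
        assert est.stop_reason_ == res.stop_reason


def test_threshold_validation():
    with pytest.raises(ValueError):
        tf.FilterThresholds(-0.1, 0.5)
    with pytest.raises(ValueError):
        tf.FilterThresholds(0.0, 0.0)
    with pytest.raises(ValueError):
        tf.FilterThresholds(0.0, 1.5)
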