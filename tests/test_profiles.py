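"""Tests for cluster profiling: tests, fold changes, severity summary."""

import math

import numpy as np
import pytest
from scipy import stats

from adsubpop.cohort import FeatureSpec, infer_feature_spec
from adsubpop.profiles import (FoldChangeTable,
                               cluster_feature_chisq, cluster_feature_ttest,
                               TestResult as FeatureTestResult,
                               familywise_adjust, fold_change, rank_clusters,
                               select_top_features, severity_summary)
from adsubpop.synthetic import REFERENCE_PROFILE, SyntheticSpec, generate_cohort


def _specs():
    return [infer_feature_spec(f) for f in REFERENCE_PROFILE]


class TestWelch:
    def test_identical_groups(self):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        r = cluster_feature_ttest(vals, labels, 0)
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_closed_form_example(self):
        vals = np.array([10.0, 12.0, 14.0, 1.0, 2.0, 3.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        r = cluster_feature_ttest(vals, labels, 0)
        assert r.statistic == pytest.approx(10 / math.sqrt(5 / 3), abs=1e-9)
        assert r.df == pytest.approx(50 / 17, abs=1e-6)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        r1 = cluster_feature_ttest(vals, labels, 0)
        r2 = cluster_feature_ttest(vals + 17.3, labels, 0)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-9)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_agreement_with_reference_implementation(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = rng.integers(6, 60)
            vals = rng.normal(size=n) * rng.uniform(0.5, 4)
            labels = rng.integers(0, 2, size=n)
            if min((labels == 0).sum(), (labels == 1).sum()) < 2:
                continue
            r = cluster_feature_ttest(vals, labels, 0)
            ref = stats.ttest_ind(vals[labels == 0], vals[labels == 1],
                                  equal_var=False)
            assert r.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert r.p_value == pytest.approx(ref.pvalue, abs=1e-9)


class TestChiSquared:
    def test_gender_split_example(self):
        # 19 F / 43 M against an approximately balanced cohort expectation
        r = cluster_feature_chisq({"F": 19, "M": 43}, {"F": 50, "M": 50})
        assert r.statistic == pytest.approx(288 / 31, abs=1e-9)
        assert r.df == 1

    def test_exact_match_gives_zero(self):
        r = cluster_feature_chisq({"a": 10, "b": 30}, {"a": 100, "b": 300})
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_doubling_counts_doubles_statistic(self):
        r1 = cluster_feature_chisq({"a": 5, "b": 20}, {"a": 40, "b": 60})
        r2 = cluster_feature_chisq({"a": 10, "b": 40}, {"a": 80, "b": 120})
        assert r2.statistic == pytest.approx(2 * r1.statistic, abs=1e-9)
        assert r2.df == r1.df

    def test_agreement_with_reference_implementation(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            L = rng.integers(2, 6)
            overall = rng.integers(10, 100, size=L)
            obs = rng.integers(1, 30, size=L)
            r = cluster_feature_chisq(
                {f"c{i}": int(o) for i, o in enumerate(obs)},
                {f"c{i}": int(o) for i, o in enumerate(overall)})
            exp = overall / overall.sum() * obs.sum()
            ref = stats.chisquare(obs, exp)
            assert r.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert r.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            cluster_feature_chisq({}, {"a": 10})


class TestFamilywise:
    @staticmethod
    def _result(feature, cluster, p):
        # embed the p-value in a consistent welch-t result
        t = stats.t.isf(p / 2, 30)
        return FeatureTestResult(feature, cluster, t, p, "welch_t", 30.0)

    def test_single_test_uses_raw_alpha(self):
        res = familywise_adjust([self._result("f", 0, 0.04)], alpha=0.05)
        assert res[0].threshold == 0.05
        assert res[0].significant

    def test_all_p_one_never_flags(self):
        results = [FeatureTestResult(f"f{i}", 0, 0.0, 1.0, "welch_t", 10.0)
                   for i in range(5)]
        assert not any(r.significant for r in familywise_adjust(results))

    def test_familywise_error_rate_controlled_under_null(self):
        # 10 independent null tests per family, many replicates
        rng = np.random.default_rng(3)
        reps = 10_000
        p = rng.uniform(size=(reps, 10))
        false_positives = 0
        for i in range(reps):
            results = [self._result(f"f{j}", 0, p[i, j]) for j in range(10)]
            familywise_adjust(results, alpha=0.05)
            false_positives += any(r.significant for r in results)
        # the bound is on the true rate: allow 3 se of Monte-Carlo noise
        margin = 3 * np.sqrt(0.05 * 0.95 / reps)
        assert false_positives / reps <= 0.05 + margin

    def test_tukey_adjustment_across_cluster_comparisons(self):
        results = [self._result("f", c, 0.02) for c in range(4)]
        familywise_adjust(results, alpha=0.05)
        # studentized-range adjustment across 4 comparisons inflates p
        assert all(r.p_adjusted > 0.02 for r in results)


class TestFoldChange:
    def test_definitional_arithmetic(self):
        vals = np.array([105.0, 105.0, 100.0, 95.0])
        labels = np.array([0, 0, 1, 1])
        # cluster mean 105, overall mean 101.25
        assert fold_change(vals, labels, 0) == pytest.approx(
            100 * (105 - 101.25) / 101.25)

    def test_equal_means_give_exact_zero(self):
        vals = np.array([1.0, 3.0, 2.0, 2.0])
        labels = np.array([0, 0, 1, 1])
        assert fold_change(vals, labels, 0) == 0.0

    def test_zero_overall_mean_flagged(self):
        vals = np.array([-1.0, 1.0, -1.0, 1.0])
        assert math.isnan(fold_change(vals, np.array([0, 0, 1, 1]), 0))

    def test_reference_profile_direction_standardization(self):
        table = FoldChangeTable.from_profile(REFERENCE_PROFILE, _specs())
        row = table.entries.query("cluster == 1 and feature == 'ADAS11'")
        assert row["percent_fold_change"].iloc[0] == -25.079
        assert row["direction_standardized"].iloc[0] == 25.079  # deficit flip


class TestTopFeatures:
    def _table(self, folds):
        profile = {f: (v,) for f, v in folds.items()}
        specs = [FeatureSpec(f, "continuous", "other", "neutral")
                 for f in folds]
        return FoldChangeTable.from_profile(profile, specs)

    def test_rank_by_min_p(self):
        table = self._table({"a": 1.0, "b": 2.0, "c": 3.0})
        results = [FeatureTestResult("a", 0, 0, 0.001, "welch_t", 10),
                   FeatureTestResult("b", 0, 0, 0.5, "welch_t", 10),
                   FeatureTestResult("c", 0, 0, 0.0001, "welch_t", 10)]
        per_cluster, union = select_top_features(table, results, n=2)
        assert per_cluster[0] == ["c", "a"]
        assert union == ["c", "a"]

    def test_ties_break_by_fold_magnitude(self):
        table = self._table({"a": 1.0, "b": 9.0})
        results = [FeatureTestResult("a", 0, 0, 0.01, "welch_t", 10),
                   FeatureTestResult("b", 0, 0, 0.01, "welch_t", 10)]
        _, union = select_top_features(table, results, n=1)
        assert union == ["b"]

    def test_n_larger_than_feature_count(self):
        table = self._table({"a": 1.0, "b": 2.0})
        _, union = select_top_features(table, [], n=10)
        assert sorted(union) == ["a", "b"]


class TestSeveritySummary:
    def _summary(self, profile=None):
        table = FoldChangeTable.from_profile(profile or REFERENCE_PROFILE,
                                             _specs())
        return severity_summary(table, _specs())

    def test_reference_profile_aggregates(self):
        s = self._summary()
        assert s.cognition_mean[1] == pytest.approx(17.3, abs=0.05)
        assert s.volume_mean[1] == pytest.approx(13.3, abs=0.05)
        assert s.cognition_mean[0] == pytest.approx(-4.6, abs=0.05)
        assert s.volume_mean[0] == pytest.approx(3.8, abs=0.05)

    def test_zero_profile_gives_zero_axes(self):
        zero = {f: (0.0,) * 4 for f in REFERENCE_PROFILE}
        s = self._summary(zero)
        for c in s.clusters:
            assert s.cognition_mean[c] == 0.0 and s.cognition_sd[c] == 0.0
            assert s.volume_mean[c] == 0.0 and s.volume_sd[c] == 0.0

    def test_linearity_under_scaling(self):
        scaled = {f: tuple(3.0 * v for v in vals)
                  for f, vals in REFERENCE_PROFILE.items()}
        s1, s3 = self._summary(), self._summary(scaled)
        for c in s1.clusters:
            assert s3.cognition_mean[c] == pytest.approx(
                3 * s1.cognition_mean[c], abs=1e-9)
            assert s3.volume_mean[c] == pytest.approx(
                3 * s1.volume_mean[c], abs=1e-9)

    def test_unknown_feature_rejected_by_name(self):
        table = FoldChangeTable.from_profile(
            {"NOT_A_FEATURE": (1.0,)},
            [FeatureSpec("NOT_A_FEATURE", "continuous", "other", "neutral")])
        with pytest.raises(KeyError, match="NOT_A_FEATURE"):
            severity_summary(table, _specs())

    def test_planted_axis_signs_recovered_on_true_labels(self):
        # generated cohorts must reproduce the planted severity pattern
        spec = SyntheticSpec()
        expected_cog = np.sign([-4.6, 17.3, -16.3, 10.8])
        expected_vol = np.sign([3.8, 13.3, -8.4, -4.9])
        for seed in range(20):
            cohort, truth = generate_cohort(spec, seed=seed)
            table = FoldChangeTable.compute(
                cohort.frame, truth.subpop, cohort.feature_specs,
                features=list(REFERENCE_PROFILE))
            s = severity_summary(table, cohort.feature_specs)
            got_cog = [np.sign(s.cognition_mean[c]) for c in range(4)]
            got_vol = [np.sign(s.volume_mean[c]) for c in range(4)]
            assert np.array_equal(got_cog, expected_cog), f"seed {seed}"
            assert np.array_equal(got_vol, expected_vol), f"seed {seed}"


class TestRankClusters:
    def test_reference_profile_orderings(self):
        table = FoldChangeTable.from_profile(REFERENCE_PROFILE, _specs())
        orders = rank_clusters(severity_summary(table, _specs()))
        assert orders["combined_mean"] == [1, 3, 0, 2]
        assert orders["volume_weighted"] == [1, 0, 3, 2]

    def test_symmetric_two_cluster_case(self):
        from adsubpop.profiles import SeveritySummary
        s = SeveritySummary([0, 1], {0: 5.0, 1: -5.0}, {0: 0, 1: 0},
                            {0: 5.0, 1: -5.0}, {0: 0, 1: 0}, ["a"], ["b"])
        orders = rank_clusters(s)
        assert orders["combined_mean"] == [0, 1]
        assert orders["volume_weighted"] == [0, 1]

    def test_singleton(self):
        from adsubpop.profiles import SeveritySummary
        s = SeveritySummary([2], {2: 1.0}, {2: 0.0}, {2: 2.0}, {2: 0.0},
                            ["a"], ["b"])
        assert rank_clusters(s)["combined_mean"] == [2]
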