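"""Tests for medication normalization, Apriori mining and rule metrics."""

import math

import numpy as np
import pandas as pd
import pytest

from adsubpop.lexicon import DrugLexicon, annotate_class, normalize_drug_name
from adsubpop.rules import (TransactionStats, apriori, build_transactions,
                            cohort_fraction, demographic_split, generate_rules,
                            mine, overlay_clusters, rule_coverage,
                            rule_metrics)
from conftest import brute_force_itemsets, make_transactions, random_transaction_db

# the worked 4-transaction database used across several tests
TOY_DB = make_transactions([{"a", "b"}, {"a", "b"}, {"a"}, {"b", "c"}])


class TestNormalization:
    @pytest.mark.parametrize("raw, expected", [
        ("vit. c", "vitamin_c"),
        ("Vitamin C", "vitamin_c"),
        ("vitamin_c", "vitamin_c"),
        ("ARICEPT", "aricept"),
        ("Donepezil HCL", "donepezil"),
    ])
    def test_dialects_collapse(self, raw, expected):
        assert normalize_drug_name(raw) == expected

    def test_brand_kept_distinct_from_generic(self):
        assert normalize_drug_name("Aricept") == "aricept" != "donepezil"

    def test_empty_name_rejected(self):
        with pytest.raises(ValueError):
            normalize_drug_name("   ")

    def test_unknown_name_passes_through_normalized(self):
        assert normalize_drug_name("Zzz-Unknown Drug") == "zzz_unknown_drug"

    @pytest.mark.parametrize("token, cls", [
        ("aricept", "cholinesterase_inhibitor"),
        ("namenda", "nmda_receptor_antagonist"),
        ("zoloft", "serotonin_reuptake_inhibitor"),
        ("simvastatin", "hmg_coa_reductase_inhibitor"),
        ("lipitor", "hmg_coa_reductase_inhibitor"),
        ("zzz_unknown_drug", "unclassified"),
    ])
    def test_class_annotation(self, token, cls):
        assert annotate_class(token) == cls


class TestBuildTransactions:
    def _inputs(self):
        med = pd.DataFrame({"PTID": ["P1", "P1"], "VISCODE": ["bl", "bl"],
                            "raw_drug_name": ["vit. c", "Aricept"]})
        labels = pd.DataFrame({"PTID": ["P1"], "VISCODE": ["bl"],
                               "DX": ["AD"], "cluster": [3]})
        return med, labels

    def test_assembles_all_token_kinds(self):
        med, labels = self._inputs()
        (t,) = build_transactions(med, labels)
        assert {"vitamin_c", "aricept", "antioxidant_vitamin",
                "cholinesterase_inhibitor", "dx_ad", "cluster_3"} == t.items

    def test_one_transaction_per_visit(self):
        med = pd.DataFrame({"PTID": ["P1"], "VISCODE": ["bl"],
                            "raw_drug_name": ["Zoloft"]})
        labels = pd.DataFrame({"PTID": ["P1", "P1"], "VISCODE": ["bl", "m06"],
                               "DX": ["AD", "AD"], "cluster": [1, 1]})
        assert len(build_transactions(med, labels)) == 2

    def test_visit_without_medication_keeps_label_tokens(self):
        labels = pd.DataFrame({"PTID": ["P9"], "VISCODE": ["bl"],
                               "DX": ["CN"], "cluster": [-1]})
        (t,) = build_transactions(pd.DataFrame(
            columns=["PTID", "VISCODE", "raw_drug_name"]), labels)
        assert t.items == {"dx_cn"}

    def test_orphan_medication_row_rejected(self):
        med, labels = self._inputs()
        med.loc[len(med)] = ["P404", "bl", "Zoloft"]
        with pytest.raises(ValueError, match="P404"):
            build_transactions(med, labels)


class TestApriori:
    def test_worked_example(self):
        found = {tuple(sorted(s.itemset)): s.support
                 for s in apriori(TOY_DB, min_support=0.5)}
        assert found == {("a",): 0.75, ("b",): 0.75, ("a", "b"): 0.5}

    def test_min_support_one_on_toy_db(self):
        assert apriori(TOY_DB, min_support=1.0) == []

    def test_tiny_support_is_exhaustive(self):
        got = {frozenset(s.itemset) for s in apriori(TOY_DB, min_support=1e-9)}
        oracle = set(brute_force_itemsets(TOY_DB, 1e-9))
        assert got == oracle

    def test_empty_transaction_list(self):
        assert apriori([], min_support=0.1) == []

    def test_matches_brute_force_on_random_dbs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            db = random_transaction_db(rng)
            min_support = rng.choice([0.01, 0.05, 0.2, 0.5])
            got = {s.itemset: s.count for s in apriori(db, min_support)}
            assert got == brute_force_itemsets(db, min_support)

    def test_downward_closure_structural(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            db = random_transaction_db(rng)
            out = apriori(db, 0.05)
            singles = {next(iter(s.itemset)) for s in out if len(s.itemset) == 1}
            for s in out:
                if len(s.itemset) == 2:
                    assert s.itemset <= singles


class TestRuleMetrics:
    def test_worked_example(self):
        r = rule_metrics(["a"], ["b"], TransactionStats(TOY_DB))
        assert r.support == 0.5
        assert r.confidence == pytest.approx(2 / 3)
        assert r.lift == pytest.approx(8 / 9)
        assert r.leverage == pytest.approx(-0.0625)
        assert r.conviction == pytest.approx(0.75)

    def test_independent_items(self):
        db = make_transactions([{"a", "b"}, {"a"}, {"b"}, set()])
        r = rule_metrics(["a"], ["b"], TransactionStats(db))
        assert r.lift == pytest.approx(1.0)
        assert r.leverage == pytest.approx(0.0)

    def test_certain_consequent_gives_infinite_conviction(self):
        db = make_transactions([{"x", "y"}, {"x", "y"}, {"z"}])
        r = rule_metrics(["x"], ["y"], TransactionStats(db))
        assert r.confidence == 1.0
        assert math.isinf(r.conviction)

    def test_zero_support_antecedent_rejected(self):
        with pytest.raises(ValueError):
            rule_metrics(["nope"], ["a"], TransactionStats(TOY_DB))

    def test_overlapping_itemsets_rejected(self):
        with pytest.raises(ValueError):
            rule_metrics(["a"], ["a", "b"], TransactionStats(TOY_DB))

    def test_identities_on_random_rules(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            db = random_transaction_db(rng)
            stats = TransactionStats(db)
            itemsets = apriori(db, 0.02)
            pairs = [s.itemset for s in itemsets if len(s.itemset) == 2]
            for pair in pairs[:20]:
                x, y = sorted(pair)
                r = rule_metrics([x], [y], stats)
                rev = rule_metrics([y], [x], stats)
                # conf(X->Y) * supp(X) = supp(X u Y) exactly on counts
                assert r.confidence * stats.count([x]) == pytest.approx(
                    stats.count([x, y]), abs=1e-9)
                assert r.lift == pytest.approx(rev.lift, abs=1e-12)
                assert r.leverage == pytest.approx(rev.leverage, abs=1e-15)
                assert (abs(r.lift - 1.0) < 1e-12) == (abs(r.leverage) < 1e-12)


class TestGenerateRules:
    def test_thresholds_on_worked_example(self):
        itemsets = apriori(TOY_DB, 0.5)
        loose = generate_rules(itemsets, TOY_DB, min_confidence=0.6,
                               min_lift=0.0)
        assert {tuple(sorted(r.antecedent)) + tuple(sorted(r.consequent))
                for r in loose} == {("a", "b"), ("b", "a")}
        strict = generate_rules(itemsets, TOY_DB, min_confidence=0.6,
                                min_lift=1.0)
        assert strict == []  # lift 8/9 fails the strict > 1 threshold

    def test_empty_itemsets(self):
        assert generate_rules([], TOY_DB) == []

    def test_sorted_by_lift_then_confidence(self):
        rng = np.random.default_rng(3)
        db = random_transaction_db(rng)
        rules = generate_rules(apriori(db, 0.02), db, min_confidence=0.0,
                               min_lift=0.0)
        keys = [(-r.lift, -r.confidence, -r.support) for r in rules]
        assert keys == sorted(keys)


class TestCoverage:
    def test_patient_deduplication(self):
        db = make_transactions(
            [{"simvastatin", "dx_ad"}] * 3 + [{"dx_ad"}],
            patients=["P1", "P1", "P1", "P2"])
        r = rule_metrics(["simvastatin"], ["dx_ad"], TransactionStats(db))
        n, _ = rule_coverage(r, db)
        assert n == 1

    def test_demographic_percent_splits(self):
        assert demographic_split({"F": 19, "M": 43}) == {"F": 30.65, "M": 69.35}
        assert demographic_split({"F": 22, "M": 31}) == {"F": 41.51, "M": 58.49}

    def test_coverage_with_demographics(self):
        db = make_transactions([{"x", "dx_ad"}] * 4,
                               patients=["P1", "P2", "P3", "P4"])
        demo = {p: {"PTGENDER": "F" if p in ("P1",) else "M"}
                for p in ("P1", "P2", "P3", "P4")}
        r = rule_metrics(["x"], ["dx_ad"], TransactionStats(db))
        n, splits = rule_coverage(r, db, demo)
        assert n == 4
        assert splits["PTGENDER"] == {"F": 25.0, "M": 75.0}

    def test_cohort_fraction_rounding(self):
        assert cohort_fraction(68, 424) == 16.0
        assert cohort_fraction(79, 424) == 18.6
        assert cohort_fraction(0, 424) == 0.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_fraction(1, 0)


class TestOverlay:
    def test_missing_cluster_tokens_advises_rebuild(self):
        with pytest.raises(ValueError, match="include_cluster"):
            overlay_clusters([], TOY_DB)

    def test_impossible_threshold_reports_all_clusters_empty(self):
        db = make_transactions([{"zoloft", "cluster_2"}] * 5
                               + [{"cluster_0"}] * 5)
        itemsets, _ = mine(db)[0], None
        rules = generate_rules(apriori(db, 0.001), db, min_confidence=1.01)
        overlay = overlay_clusters(rules, db)
        assert set(overlay.per_cluster) == {0, 2}
        assert all(v == [] for v in overlay.per_cluster.values())

    def test_passing_rule_lands_on_its_cluster(self):
        db = make_transactions([{"zoloft", "cluster_2"}] * 8
                               + [{"cluster_0"}] * 8)
        _, rules = mine(db)
        overlay = overlay_clusters(rules, db)
        assert "zoloft" in overlay.antecedent_tokens(2)
        assert overlay.antecedent_tokens(0) == set()


class TestMiningProperties:
    from hypothesis import given, settings, strategies as st

    @st.composite
    def _dbs(draw, st=st):
        n_items = draw(st.integers(2, 6))
        alphabet = [f"i{j}" for j in range(n_items)]
        baskets = draw(st.lists(
            st.sets(st.sampled_from(alphabet), max_size=n_items),
            min_size=1, max_size=30))
        return make_transactions(baskets)

    @settings(max_examples=60, derandomize=True)
    @given(db=_dbs(), min_support=st.sampled_from([0.05, 0.2, 0.5]))
    def test_support_counts_exact_and_downward_closed(self, db, min_support):
        out = apriori(db, min_support)
        singles = {next(iter(s.itemset)) for s in out if len(s.itemset) == 1}
        for s in out:
            assert s.support == s.count / len(db)
            assert s.count == sum(1 for t in db if s.itemset <= t.items)
            if len(s.itemset) == 2:
                assert s.itemset <= singles

    @settings(max_examples=60, derandomize=True)
    @given(db=_dbs())
    def test_rule_metric_identities_hold_universally(self, db):
        stats = TransactionStats(db)
        for s in apriori(db, 0.01):
            if len(s.itemset) != 2:
                continue
            x, y = sorted(s.itemset)
            r, rev = rule_metrics([x], [y], stats), rule_metrics([y], [x], stats)
            assert r.confidence * stats.count([x]) == pytest.approx(
                stats.count([x, y]), abs=1e-9)
            assert r.lift == pytest.approx(rev.lift, abs=1e-12)
            assert r.leverage == pytest.approx(rev.leverage, abs=1e-15)
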