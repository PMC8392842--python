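"""Apriori frequent-itemset mining and association-rule metrics.

Each patient clinic visit is one transaction; its items are the normalized
medication tokens, optionally their pharmacologic class tokens, a diagnosis
token (``dx_ad``) and a cluster token (``cluster_2``).  Itemset generation
is capped at two joined singletons, matching a cohort-scale sample size:
singletons are support-filtered, surviving singletons are joined and
filtered again (downward closure holds by construction).  The five rule
metrics — support, confidence, lift, leverage, conviction — are computed
from exact integer transaction counts.

Coverage statistics deduplicate visits to distinct patients: a rule
"applies to" the set of patients with at least one qualifying visit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .lexicon import DrugLexicon, annotate_class, normalize_drug_name


@dataclass(frozen=True)
class Transaction:
    transaction_id: str
    patient_id: str
    items: frozenset[str]


@dataclass(frozen=True)
class ItemsetStats:
    itemset: frozenset[str]
    count: int
    support: float


@dataclass
class AssociationRule:
    antecedent: frozenset[str]
    consequent: frozenset[str]
    support: float
    confidence: float
    lift: float
    leverage: float
    conviction: float          # math.inf when confidence == 1
    n_patients_applied: int = 0

    def key(self) -> tuple:
        return (tuple(sorted(self.antecedent)), tuple(sorted(self.consequent)))

    def to_record(self) -> dict:
        return {
            "antecedent": "&".join(sorted(self.antecedent)),
            "consequent": "&".join(sorted(self.consequent)),
            "support": self.support,
            "confidence": self.confidence,
            "lift": self.lift,
            "leverage": self.leverage,
            "conviction": "inf" if math.isinf(self.conviction) else self.conviction,
            "n_patients": self.n_patients_applied,
        }


def build_transactions(medication_log: pd.DataFrame,
                       cohort_labels: pd.DataFrame,
                       lexicon: DrugLexicon | None = None,
                       include_diagnosis: bool = True,
                       include_cluster: bool = True,
                       include_classes: bool = True) -> list[Transaction]:
    """Assemble one transaction per patient visit.

    ``medication_log`` has columns (PTID, VISCODE, raw_drug_name);
    ``cohort_labels`` has one row per visit with PTID, VISCODE, DX and
    (optionally) a ``cluster`` column.  Every medication row must join to a
    cohort visit; orphans raise with the offending patient ids.
    """
    lex = lexicon or DrugLexicon()
    key = ["PTID", "VISCODE"]
    known = set(map(tuple, cohort_labels[key].itertuples(index=False)))
    log_keys = set(map(tuple, medication_log[key].itertuples(index=False)))
    orphans = sorted({p for p, v in log_keys - known})
    if orphans:
        raise ValueError(f"medication rows for unknown patient visits: {orphans}")

    drugs: dict[tuple, set[str]] = {k: set() for k in known}
    for row in medication_log.itertuples(index=False):
        drugs[(row.PTID, row.VISCODE)].add(
            normalize_drug_name(row.raw_drug_name, lex))

    transactions = []
    for row in cohort_labels.itertuples(index=False):
        k = (row.PTID, row.VISCODE)
        items = set(drugs.get(k, ()))
        if include_classes:
            items |= {annotate_class(d, lex) for d in items} - {"unclassified"}
        if include_diagnosis:
            items.add(f"dx_{row.DX.lower()}")
        if include_cluster and hasattr(row, "cluster") and row.cluster >= 0:
            items.add(f"cluster_{int(row.cluster)}")
        transactions.append(Transaction(f"{row.PTID}:{row.VISCODE}",
                                        row.PTID, frozenset(items)))
    return transactions


class TransactionStats:
    """Exact itemset counting over a fixed transaction list."""

    def __init__(self, transactions: Sequence[Transaction]):
        self.transactions = list(transactions)
        self.n = len(self.transactions)

    def count(self, itemset: Iterable[str]) -> int:
        items = frozenset(itemset)
        return sum(1 for t in self.transactions if items <= t.items)

    def support(self, itemset: Iterable[str]) -> float:
        if self.n == 0:
            return 0.0
        return self.count(itemset) / self.n


def apriori(transactions: Sequence[Transaction], min_support: float = 0.001,
            max_size: int = 2) -> list[ItemsetStats]:
    """Frequent itemsets of size ≤ ``max_size`` (capped at 2) by Apriori.

    Phase 1 filters candidate singletons by support; phase 2 joins the
    surviving singletons pairwise and filters again.  Counts are exact, and
    every stored 2-itemset has both singletons stored too (downward
    closure).
    """
    if not 0 < min_support <= 1:
        raise ValueError("min_support must be in (0, 1]")
    if max_size not in (1, 2):
        raise ValueError("itemset generation is limited to two joined singletons")
    n = len(transactions)
    if n == 0:
        return []

    counts: dict[str, int] = {}
    for t in transactions:
        for item in t.items:
            counts[item] = counts.get(item, 0) + 1
    frequent1 = {i for i, c in counts.items() if c / n >= min_support}
    out = [ItemsetStats(frozenset([i]), counts[i], counts[i] / n)
           for i in sorted(frequent1)]
    if max_size == 1:
        return out

    pair_counts: dict[frozenset[str], int] = {}
    for t in transactions:
        present = sorted(frequent1 & t.items)
        for a, b in combinations(present, 2):
            key = frozenset((a, b))
            pair_counts[key] = pair_counts.get(key, 0) + 1
    for key in sorted(pair_counts, key=lambda s: tuple(sorted(s))):
        c = pair_counts[key]
        if c / n >= min_support:
            out.append(ItemsetStats(key, c, c / n))
    return out


def rule_metrics(antecedent: Iterable[str], consequent: Iterable[str],
                 stats: TransactionStats) -> AssociationRule:
    """Compute support, confidence, lift, leverage and conviction exactly.

    All five derive from integer transaction counts; conviction is the
    ``inf`` sentinel when confidence is 1.
    """
    X, Y = frozenset(antecedent), frozenset(consequent)
    if X & Y:
        raise ValueError("antecedent and consequent must be disjoint")
    n = stats.n
    c_x, c_y, c_xy = stats.count(X), stats.count(Y), stats.count(X | Y)
    if c_x == 0:
        raise ValueError(f"antecedent {sorted(X)} has zero support")
    supp = c_xy / n
    supp_x, supp_y = c_x / n, c_y / n
    conf = c_xy / c_x
    lift = supp / (supp_x * supp_y) if c_y else math.inf
    leverage = supp - supp_x * supp_y
    conviction = math.inf if conf == 1.0 else (1.0 - supp_y) / (1.0 - conf)
    return AssociationRule(X, Y, supp, conf, lift, leverage, conviction)


def generate_rules(itemsets: Sequence[ItemsetStats],
                   transactions: Sequence[Transaction],
                   min_confidence: float = 0.7, min_lift: float = 1.0,
                   strict_lift: bool = True) -> list[AssociationRule]:
    """Evaluate both directions of every frequent 2-itemset.

    Rules failing the confidence threshold or the lift threshold (strict
    ``> min_lift`` by default: lift exactly 1 is no positive association)
    are dropped.  Survivors are sorted by (lift, confidence, support)
    descending, ties by rule key for determinism.
    """
    stats = TransactionStats(transactions)
    rules = []
    for s in itemsets:
        if len(s.itemset) != 2:
            continue
        a, b = sorted(s.itemset)
        for x, y in ((a, b), (b, a)):
            r = rule_metrics([x], [y], stats)
            ok_lift = r.lift > min_lift if strict_lift else r.lift >= min_lift
            if r.confidence >= min_confidence and ok_lift:
                r.n_patients_applied = len({
                    t.patient_id for t in transactions
                    if (r.antecedent | r.consequent) <= t.items})
                rules.append(r)
    rules.sort(key=lambda r: (-r.lift, -r.confidence, -r.support, r.key()))
    return rules


def rule_coverage(rule: AssociationRule, transactions: Sequence[Transaction],
                  demographics: Mapping[str, Mapping[str, str]] | None = None
                  ) -> tuple[int, dict[str, dict[str, float]]]:
    """Distinct patients covered by a rule, with demographic percent splits.

    A patient is covered if any of their visits contains antecedent ∪
    consequent.  ``demographics`` maps patient_id → {variable: category};
    per-category percentages are rounded to 2 decimals.
    """
    needed = rule.antecedent | rule.consequent
    patients = {t.patient_id for t in transactions if needed <= t.items}
    splits: dict[str, dict[str, float]] = {}
    if demographics and patients:
        by_var: dict[str, dict[str, int]] = {}
        for p in patients:
            for var, cat in demographics.get(p, {}).items():
                by_var.setdefault(var, {}).setdefault(cat, 0)
                by_var[var][cat] += 1
        for var, cats in by_var.items():
            total = sum(cats.values())
            splits[var] = {c: round(100.0 * k / total, 2)
                           for c, k in sorted(cats.items())}
    return len(patients), splits


def demographic_split(counts: Mapping[str, int]) -> dict[str, float]:
    """Percent split of covered patients by category, 2-decimal rounding."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no covered patients")
    return {c: round(100.0 * k / total, 2) for c, k in counts.items()}


def cohort_fraction(n_covered: int, cohort_size: int) -> float:
    """Percent of a diagnosis cohort covered by a rule, 1-decimal rounding."""
    if cohort_size <= 0:
        raise ValueError("cohort is empty")
    return round(100.0 * n_covered / cohort_size, 1)


@dataclass
class ClusterOverlay:
    """Per-cluster association report: passing rules with a cluster consequent."""

    per_cluster: dict[int, list[AssociationRule]] = field(default_factory=dict)

    def antecedent_tokens(self, cluster: int) -> set[str]:
        return {tok for r in self.per_cluster.get(cluster, ())
                for tok in r.antecedent}

    def to_dict(self) -> dict:
        return {
            str(c): ([r.to_record() for r in rules] if rules
                     else "no associated substances")
            for c, rules in sorted(self.per_cluster.items())
        }


def overlay_clusters(rules: Sequence[AssociationRule],
                     transactions: Sequence[Transaction],
                     clusters: Iterable[int] | None = None) -> ClusterOverlay:
    """Group passing rules by their cluster-token consequent.

    Clusters with no passing rule are reported explicitly (an empty list)
    rather than omitted.  Raises if the transactions carry no cluster
    tokens at all, which means they were built without cluster labels.
    """
    tokens = {i for t in transactions for i in t.items}
    cluster_tokens = {t for t in tokens if t.startswith("cluster_")}
    if not cluster_tokens:
        raise ValueError(
            "transactions carry no cluster tokens; rebuild them with "
            "include_cluster=True")
    if clusters is None:
        clusters = sorted(int(t.split("_", 1)[1]) for t in cluster_tokens)
    overlay = ClusterOverlay({int(c): [] for c in clusters})
    for r in rules:
        if len(r.consequent) != 1:
            continue
        (cons,) = r.consequent
        if cons.startswith("cluster_"):
            c = int(cons.split("_", 1)[1])
            if c in overlay.per_cluster:
                overlay.per_cluster[c].append(r)
    return overlay


def mine(transactions: Sequence[Transaction], min_support: float = 0.001,
         min_confidence: float = 0.7, min_lift: float = 1.0,
         max_size: int = 2) -> tuple[list[ItemsetStats], list[AssociationRule]]:
    """Convenience wrapper: Apriori then rule generation."""
    itemsets = apriori(transactions, min_support=min_support, max_size=max_size)
    rules = generate_rules(itemsets, transactions,
                           min_confidence=min_confidence, min_lift=min_lift)
    return itemsets, rules


def itemsets_frame(itemsets: Sequence[ItemsetStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"itemset": "&".join(sorted(s.itemset)), "count": s.count,
          "support": s.support} for s in itemsets])


def rules_frame(rules: Sequence[AssociationRule]) -> pd.DataFrame:
    return pd.DataFrame([r.to_record() for r in rules])
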