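"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from adsubpop.rules import Transaction


@pytest.fixture
def tiny_cohort_csv(tmp_path):
    """3-visit cohort (AD/CN/AD) with a censored biomarker value."""
    path = tmp_path / "cohort.csv"
    pd.DataFrame({
        "PTID": ["P1", "P2", "P3"],
        "VISCODE": ["bl", "bl", "bl"],
        "DX": ["AD", "CN", "AD"],
        "MMSE": ["24", "29", "21"],
        "ABETA": ["<200", "950", "1100"],
        "PTGENDER": ["Female", "Male", "Male"],
    }).to_csv(path, index=False)
    return path


def make_transactions(itemsets: list[set], patients: list[str] | None = None
                      ) -> list[Transaction]:
    patients = patients or [f"P{i}" for i in range(len(itemsets))]
    return [Transaction(f"T{i}", p, frozenset(s))
            for i, (s, p) in enumerate(zip(itemsets, patients))]


def brute_force_itemsets(transactions, min_support, max_size=2):
    """Oracle: enumerate every 1- and 2-itemset and count supports directly."""
    n = len(transactions)
    items = sorted({i for t in transactions for i in t.items})
    out = {}
    for size in range(1, max_size + 1):
        for combo in combinations(items, size):
            c = sum(1 for t in transactions if set(combo) <= t.items)
            if n and c / n >= min_support:
                out[frozenset(combo)] = c
    return out


def random_transaction_db(rng: np.random.Generator,
                          max_items: int = 12, max_tx: int = 200
                          ) -> list[Transaction]:
    n_items = rng.integers(2, max_items + 1)
    n_tx = rng.integers(1, max_tx + 1)
    alphabet = [f"i{j}" for j in range(n_items)]
    p = rng.uniform(0.05, 0.6, size=n_items)
    txs = []
    for i in range(n_tx):
        basket = {a for a, q in zip(alphabet, p) if rng.random() < q}
        txs.append(Transaction(f"T{i}", f"P{i % max(1, n_tx // 2)}",
                               frozenset(basket)))
    return txs
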