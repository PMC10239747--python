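"""Apriori engine tests: discretization, oracle equivalence, properties.

The independent oracle enumerates the full powerset of the vocabulary with
bitmask counting, so it shares no code path with the level-wise miner.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sarcomir.config import MiningConfig
from sarcomir.containers import ClinicalTable, ExpressionMatrix
from sarcomir.exceptions import ConfigurationError
from sarcomir.rules import (
    AssociationRule,
    TransactionDB,
    apriori_frequent_itemsets,
    build_transactions,
    extract_hub_genes,
    filter_outcome_rules,
    generate_rules,
)

# ---------------------------------------------------------------------------
# Independent brute-force oracle (bitmask powerset enumeration)
# ---------------------------------------------------------------------------


def bruteforce_frequent(db: TransactionDB, min_support: float, max_size: int):
    items = list(db.item_vocabulary)
    masks = [sum(1 << i for i, item in enumerate(items) if item in tx)
             for tx in db.transactions]
    n = len(masks)
    out = {}
    for size in range(1, min(max_size, len(items)) + 1):
        for combo in combinations(range(len(items)), size):
            mask = sum(1 << i for i in combo)
            count = sum(1 for m in masks if m & mask == mask)
            support = count / n
            if support >= min_support:
                out[frozenset(items[i] for i in combo)] = support
    return out


def bruteforce_rules(db: TransactionDB, cfg: MiningConfig):
    """Rules recomputed directly from raw transactions, no frequent map."""
    n = len(db.transactions)

    def sup(itemset):
        return sum(1 for tx in db.transactions if itemset <= tx) / n

    freq = bruteforce_frequent(db, cfg.min_support, cfg.max_itemset_size)
    rules = []
    for itemset in freq:
        if len(itemset) < 2:
            continue
        items = sorted(itemset)
        for r in range(1, len(items)):
            for ante in combinations(items, r):
                a = frozenset(ante)
                c = itemset - a
                sa, sc, s = sup(a), sup(c), freq[itemset]
                if sa == 0 or sc == 0:
                    continue
                conf = s / sa
                lift = conf / sc
                if conf >= cfg.min_confidence and lift >= cfg.min_lift:
                    rules.append((tuple(sorted(a)), tuple(sorted(c)), s, conf, lift))
    return rules


def random_db(rng: np.random.Generator, max_items=12, max_tx=40) -> TransactionDB:
    n_items = int(rng.integers(3, max_items + 1))
    n_tx = int(rng.integers(4, max_tx + 1))
    items = tuple(f"i{k:02d}" for k in range(n_items))
    dens = rng.uniform(0.15, 0.6)
    transactions = [
        frozenset(item for item in items if rng.random() < dens) for _ in range(n_tx)
    ]
    return TransactionDB(items, transactions, [f"s{j}" for j in range(n_tx)])


def assert_matches_oracle(db: TransactionDB, cfg: MiningConfig):
    freq = apriori_frequent_itemsets(db, cfg.min_support, cfg.max_itemset_size)
    expected = bruteforce_frequent(db, cfg.min_support, cfg.max_itemset_size)
    assert set(freq) == set(expected)
    for itemset, support in expected.items():
        assert freq[itemset] == pytest.approx(support, abs=1e-12)
    mined = [(tuple(sorted(r.antecedent)), tuple(sorted(r.consequent)),
              r.support, r.confidence, r.lift)
             for r in generate_rules(freq, db, cfg)]
    oracle = bruteforce_rules(db, cfg)
    assert {m[:2] for m in mined} == {o[:2] for o in oracle}
    oracle_map = {o[:2]: o[2:] for o in oracle}
    for m in mined:
        for got, want in zip(m[2:], oracle_map[m[:2]]):
            assert got == pytest.approx(want, abs=1e-12)


# ---------------------------------------------------------------------------
# build_transactions
# ---------------------------------------------------------------------------


def _clinical(times, events, mets):
    return ClinicalTable(pd.DataFrame(
        {"time_months": times, "event": events, "metastasis": mets},
        index=[f"s{i}" for i in range(len(times))]))


def _gene_matrix(values, genes):
    samples = [f"s{i}" for i in range(len(values[0]))]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestBuildTransactions:
    def test_hand_derived_fixture(self):
        # 4 samples; gA upper quartile cut = 3.25 -> only s3 high;
        # gB constant -> never high.
        mat = _gene_matrix([[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0]], ["gA", "gB"])
        clin = _clinical([10.0, 70.0, 30.0, 50.0], [1, 1, 0, 1], [1, 0, 0, 1])
        db = build_transactions(mat, clin, {"gA", "gB"}, MiningConfig())
        expected = [
            {"MET", "SURV_LT5"},          # s0: event at 10 < 60, met
            set(),                        # s1: event at 70 -> no SURV item
            set(),                        # s2: censored at 30 -> no SURV item
            {"gA:high", "MET", "SURV_LT5"},  # s3: 4.0 > 3.25
        ]
        assert [set(tx) for tx in db.transactions] == expected

    def test_constant_gene_yields_no_items(self):
        mat = _gene_matrix([[2.0, 2.0, 2.0, 2.0]], ["g"])
        clin = _clinical([1.0] * 4, [0] * 4, [0] * 4)
        db = build_transactions(mat, clin, {"g"}, MiningConfig())
        assert all(tx == frozenset() for tx in db.transactions)

    def test_median_discretization(self):
        mat = _gene_matrix([[1.0, 2.0, 3.0, 4.0]], ["g"])
        clin = _clinical([1.0] * 4, [0] * 4, [0] * 4)
        cfg = dataclasses.replace(MiningConfig(), discretization="median")
        db = build_transactions(mat, clin, {"g"}, cfg)
        assert sum("g:high" in tx for tx in db.transactions) == 2

    def test_empty_gene_set_raises(self):
        mat = _gene_matrix([[1.0, 2.0]], ["g"])
        clin = _clinical([1.0] * 2, [0] * 2, [0] * 2)
        with pytest.raises(ConfigurationError):
            build_transactions(mat, clin, set(), MiningConfig())


# ---------------------------------------------------------------------------
# Apriori + rules
# ---------------------------------------------------------------------------


class TestApriori:
    def test_full_support_means_every_transaction(self):
        db = TransactionDB(
            ("a", "b", "c"),
            [frozenset("ab"), frozenset("abc"), frozenset("ab")],
            ["s0", "s1", "s2"])
        freq = apriori_frequent_itemsets(db, 1.0, 3)
        assert set(freq) == {frozenset("a"), frozenset("b"), frozenset("ab")}

    def test_five_transaction_toy_matches_enumeration(self):
        db = TransactionDB(
            ("a", "b", "c", "d"),
            [frozenset("abc"), frozenset("ab"), frozenset("ac"),
             frozenset("bd"), frozenset("acd")],
            [f"s{i}" for i in range(5)])
        assert_matches_oracle(db, dataclasses.replace(
            MiningConfig(), min_support=0.4, min_confidence=0.1, min_lift=1e-9,
            max_itemset_size=4))

    def test_empty_db(self):
        db = TransactionDB(("a",), [], [])
        assert apriori_frequent_itemsets(db, 0.5, 3) == {}

    @pytest.mark.parametrize("seed", range(10))
    def test_random_dbs_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        db = random_db(rng)
        cfg = dataclasses.replace(
            MiningConfig(),
            min_support=float(rng.uniform(0.1, 0.5)),
            min_confidence=float(rng.uniform(0.2, 0.8)),
            min_lift=float(rng.uniform(0.5, 1.3)),
            max_itemset_size=int(rng.integers(2, 6)))
        assert_matches_oracle(db, cfg)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_antimonotonicity_property(self, seed):
        """support(S) >= support(T) for all mined S subseteq T."""
        rng = np.random.default_rng(seed)
        db = random_db(rng, max_items=8, max_tx=25)
        freq = apriori_frequent_itemsets(db, 0.1, 5)
        for s in freq:
            for t in freq:
                if s < t:
                    assert freq[s] >= freq[t] - 1e-15

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_threshold_monotonicity(self, seed):
        """Raising min_support never adds itemsets; raising min_confidence
        never adds rules."""
        rng = np.random.default_rng(seed)
        db = random_db(rng, max_items=8, max_tx=25)
        loose = apriori_frequent_itemsets(db, 0.1, 4)
        tight = apriori_frequent_itemsets(db, 0.3, 4)
        assert set(tight) <= set(loose)
        cfg_loose = dataclasses.replace(MiningConfig(), min_confidence=0.3, min_lift=1e-9)
        cfg_tight = dataclasses.replace(MiningConfig(), min_confidence=0.7, min_lift=1e-9)
        rules_loose = {(r.antecedent, r.consequent) for r in generate_rules(loose, db, cfg_loose)}
        rules_tight = {(r.antecedent, r.consequent) for r in generate_rules(loose, db, cfg_tight)}
        assert rules_tight <= rules_loose

    def test_rule_metric_identity_and_determinism(self):
        rng = np.random.default_rng(42)
        db = random_db(rng)
        cfg = dataclasses.replace(MiningConfig(), min_confidence=0.2, min_lift=1e-9)
        freq = apriori_frequent_itemsets(db, 0.15, 4)
        rules = generate_rules(freq, db, cfg)
        n = len(db.transactions)
        for r in rules:
            sup_a = sum(1 for tx in db.transactions if r.antecedent <= tx) / n
            sup_both = sum(1 for tx in db.transactions if r.antecedent | r.consequent <= tx) / n
            assert r.confidence == pytest.approx(sup_both / sup_a, abs=1e-12)
        assert rules == generate_rules(freq, db, cfg)

    def test_universal_consequent_has_unit_lift(self):
        db = TransactionDB(
            ("a", "b"),
            [frozenset("ab"), frozenset("ab"), frozenset("b")],
            ["s0", "s1", "s2"])
        cfg = dataclasses.replace(MiningConfig(), min_support=0.5,
                                  min_confidence=0.1, min_lift=1e-9)
        freq = apriori_frequent_itemsets(db, 0.5, 2)
        rules = generate_rules(freq, db, cfg)
        lift = {(r.antecedent, r.consequent): r.lift for r in rules}
        assert lift[(frozenset("a"), frozenset("b"))] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Outcome filtering and hub extraction
# ---------------------------------------------------------------------------


def _rule(ante, cons, s=0.5, c=0.9, l=2.0):
    return AssociationRule(frozenset(ante), frozenset(cons), s, c, l)


class TestOutcomeRules:
    def test_filter_keeps_gene_to_outcome(self):
        keep = _rule({"A:high"}, {"MET", "SURV_LT5"})
        drop_dir = _rule({"MET"}, {"A:high", "SURV_LT5"})
        drop_partial = _rule({"A:high"}, {"MET"})
        kept = filter_outcome_rules([keep, drop_dir, drop_partial])
        assert kept == [keep]

    def test_filter_allows_extra_consequent_genes(self):
        rule = _rule({"A:high"}, {"B:high", "MET", "SURV_LT5"})
        assert filter_outcome_rules([rule]) == [rule]

    def test_single_rule_hub_extraction(self):
        cfg = dataclasses.replace(MiningConfig(), hub_fraction=1.0)
        rule = _rule({"A:high", "B:high"}, {"MET", "SURV_LT5"})
        hubs, counts = extract_hub_genes([rule], cfg)
        assert hubs == ["A", "B"]
        assert set(counts["gene_id"]) == {"A", "B"}

    def test_no_rules_is_empty_result_not_error(self):
        hubs, counts = extract_hub_genes([], MiningConfig())
        assert hubs == [] and len(counts) == 0

    def test_ranking_by_count_then_name(self):
        rules = [
            _rule({"B:high"}, {"MET", "SURV_LT5"}, s=0.5),
            _rule({"B:high", "C:high"}, {"MET", "SURV_LT5"}, s=0.4),
            _rule({"A:high"}, {"MET", "SURV_LT5"}, s=0.3),
        ]
        cfg = dataclasses.replace(MiningConfig(), hub_fraction=0.1)
        hubs, _ = extract_hub_genes(rules, cfg)
        assert hubs == ["B", "A", "C"]
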