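"""Association-rule mining over discretized expression and clinical items.

This module is the analytical core of the package.  Each patient sample
becomes a transaction of binary items: ``<gene>:high`` when the gene's
expression strictly exceeds a per-gene discretization cut (upper quartile by
default), ``MET`` when metastasis was recorded, and ``SURV_LT5`` when death
was observed earlier than the survival cutoff (censoring before the cutoff
is not evidence of short survival, so censored samples carry no survival
item).  Frequent itemsets are mined with a hand-written level-wise Apriori
(prefix join + subset pruning, support counted by transaction scan), rules
are enumerated over all antecedent/consequent bipartitions, filtered to
"gene-high implies bad outcome" form, and hub biomarker genes are the genes
recurring in the antecedents of the top rules.

All orderings are made fully deterministic: rules sort by support,
confidence and lift (descending) with lexicographic tie-breaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .config import MiningConfig
from .containers import ClinicalTable, ExpressionMatrix
from .exceptions import ConfigurationError

MET_ITEM = "MET"
SURV_ITEM = "SURV_LT5"
OUTCOME_ITEMS = frozenset({MET_ITEM, SURV_ITEM})
HIGH_SUFFIX = ":high"

_DISCRETIZATION_QUANTILE = {"upper_quartile": 0.75, "median": 0.5, "tertile": 2.0 / 3.0}


def gene_item(gene_id: str) -> str:
    return f"{gene_id}{HIGH_SUFFIX}"


def item_gene(item: str) -> str | None:
    """Gene id of a ``<gene>:high`` item, or None for clinical items."""
    if item.endswith(HIGH_SUFFIX) and item not in OUTCOME_ITEMS:
        return item[: -len(HIGH_SUFFIX)]
    return None


@dataclass
class TransactionDB:
    """Per-sample item sets over a fixed, ordered vocabulary."""

    item_vocabulary: tuple[str, ...]
    transactions: list[frozenset[str]]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if len(set(self.item_vocabulary)) != len(self.item_vocabulary):
            raise ConfigurationError("item_vocabulary: duplicate items")
        vocab = set(self.item_vocabulary)
        for sid, tx in zip(self.sample_ids, self.transactions):
            if not tx <= vocab:
                raise ConfigurationError(
                    f"transaction {sid} contains items outside the vocabulary")

    def __len__(self) -> int:
        return len(self.transactions)


@dataclass(frozen=True)
class AssociationRule:
    """Antecedent => consequent with support, confidence and lift."""

    antecedent: frozenset[str]
    consequent: frozenset[str]
    support: float
    confidence: float
    lift: float

    def __post_init__(self) -> None:
        if self.antecedent & self.consequent:
            raise ConfigurationError("rule antecedent and consequent overlap")

    def sort_key(self):
        return (
            -self.support,
            -self.confidence,
            -self.lift,
            tuple(sorted(self.antecedent)),
            tuple(sorted(self.consequent)),
        )


def build_transactions(
    gene_mat: ExpressionMatrix,
    clin: ClinicalTable,
    genes,
    cfg: MiningConfig,
) -> TransactionDB:
    """Discretize expression and clinical outcomes into transactions.

    The per-gene cut is the configured quantile of that gene's expression
    across the clinical samples; a sample carries ``<gene>:high`` only when
    its value is STRICTLY above the cut (a constant gene therefore yields no
    items).  Samples are the clinical-table samples present in the matrix.
    """
    cfg.validate()
    genes = sorted(set(genes))
    if not genes:
        raise ConfigurationError("genes: transaction gene set is empty")
    missing = [g for g in genes if g not in gene_mat.values.index]
    if missing:
        raise ConfigurationError(f"genes: absent from expression matrix: {missing[:5]}")
    samples = [s for s in clin.sample_ids if s in set(gene_mat.sample_ids)]
    if not samples:
        raise ConfigurationError("no samples shared between expression matrix and clinical table")

    expr = gene_mat.values.loc[genes, samples]
    quantile = _DISCRETIZATION_QUANTILE[cfg.discretization]
    cuts = expr.quantile(quantile, axis=1)
    high = expr.gt(cuts, axis=0)

    table = clin.table.loc[samples]
    met = table["metastasis"].to_numpy() == 1
    surv = (table["event"].to_numpy() == 1) & (
        table["time_months"].to_numpy() < cfg.survival_cutoff_months)

    transactions = []
    for j, sample in enumerate(samples):
        items = {gene_item(g) for g in high.index[high.iloc[:, j].to_numpy()]}
        if met[j]:
            items.add(MET_ITEM)
        if surv[j]:
            items.add(SURV_ITEM)
        transactions.append(frozenset(items))
    vocabulary = tuple([gene_item(g) for g in genes] + [MET_ITEM, SURV_ITEM])
    return TransactionDB(vocabulary, transactions, samples)


def apriori_frequent_itemsets(
    db: TransactionDB, min_support: float, max_size: int
) -> dict[frozenset[str], float]:
    """Level-wise Apriori enumeration of frequent itemsets.

    Returns every itemset of size 1..max_size with support >= min_support,
    mapped to its support (fraction of transactions containing it).
    Candidates of size k are generated by joining frequent (k-1)-itemsets
    sharing a (k-2)-prefix, pruned when any (k-1)-subset is infrequent, and
    counted by a scan over the transactions.
    """
    if not (0.0 < min_support <= 1.0):
        raise ConfigurationError("min_support: must lie in (0, 1]")
    n = len(db.transactions)
    if n == 0:
        return {}

    frequent: dict[frozenset[str], float] = {}

    # Level 1: count single items.
    counts: dict[str, int] = {item: 0 for item in db.item_vocabulary}
    for tx in db.transactions:
        for item in tx:
            counts[item] += 1
    level = []
    for item in sorted(counts):
        support = counts[item] / n
        if support >= min_support:
            frequent[frozenset((item,))] = support
            level.append((item,))

    k = 2
    while level and k <= max_size:
        prev = set(level)
        candidates = []
        for i, a in enumerate(level):
            for b in level[i + 1:]:
                if a[:-1] != b[:-1]:
                    break  # level is sorted; prefixes diverge from here on
                cand = a + (b[-1],)
                if all(cand[:j] + cand[j + 1:] in prev for j in range(len(cand))):
                    candidates.append(cand)
        next_level = []
        for cand in candidates:
            cset = frozenset(cand)
            count = sum(1 for tx in db.transactions if cset <= tx)
            support = count / n
            if support >= min_support:
                frequent[cset] = support
                next_level.append(cand)
        next_level.sort()
        level = next_level
        k += 1
    return frequent


def _support_of(itemset: frozenset, freq: dict, db: TransactionDB) -> float:
    """Support from the frequent map, falling back to a transaction scan."""
    if itemset in freq:
        return freq[itemset]
    n = len(db.transactions)
    if n == 0:
        return 0.0
    return sum(1 for tx in db.transactions if itemset <= tx) / n


def generate_rules(
    freq: dict[frozenset[str], float],
    db: TransactionDB,
    cfg: MiningConfig,
) -> list[AssociationRule]:
    """All confident, lifted bipartitions of the frequent itemsets.

    For every frequent itemset of size >= 2 and every nonempty proper subset
    taken as antecedent, the rule antecedent => (itemset - antecedent) is
    emitted when confidence >= min_confidence and lift >= min_lift.  The
    returned list is deterministically sorted by (support desc, confidence
    desc, lift desc, lexicographic antecedent, lexicographic consequent).
    """
    cfg.validate()
    rules = []
    for itemset, support in freq.items():
        if len(itemset) < 2:
            continue
        items = sorted(itemset)
        for r in range(1, len(items)):
            for ante in combinations(items, r):
                antecedent = frozenset(ante)
                consequent = itemset - antecedent
                sup_a = _support_of(antecedent, freq, db)
                if sup_a == 0:
                    continue
                confidence = support / sup_a
                if confidence < cfg.min_confidence:
                    continue
                sup_c = _support_of(consequent, freq, db)
                if sup_c == 0:
                    continue
                lift = confidence / sup_c
                if lift < cfg.min_lift:
                    continue
                rules.append(AssociationRule(antecedent, consequent, support, confidence, lift))
    rules.sort(key=AssociationRule.sort_key)
    return rules


def filter_outcome_rules(
    rules, outcome_items: frozenset[str] = OUTCOME_ITEMS
) -> list[AssociationRule]:
    """Keep rules of the form {gene-high items} => {both outcomes, ...}.

    A rule survives iff its consequent contains every outcome item and its
    antecedent consists only of gene-high items.
    """
    kept = []
    for rule in rules:
        if not outcome_items <= rule.consequent:
            continue
        if any(item_gene(item) is None for item in rule.antecedent):
            continue
        kept.append(rule)
    return kept


def extract_hub_genes(
    filtered_rules, cfg: MiningConfig
) -> tuple[list[str], pd.DataFrame]:
    """Genes recurring in the antecedents of the top outcome rules.

    Among the top ``top_n_rules`` rules (by the deterministic sort), a gene
    is a hub iff it appears in the antecedent of at least ``hub_fraction`` of
    them.  Returns ``(hubs, counts)`` with hubs ranked by appearance count
    then name; both are empty when no rules were supplied (an empty-result
    signal, not an error).
    """
    cfg.validate()
    top = sorted(filtered_rules, key=AssociationRule.sort_key)[: cfg.top_n_rules]
    counts: dict[str, int] = {}
    for rule in top:
        for item in rule.antecedent:
            gene = item_gene(item)
            if gene is not None:
                counts[gene] = counts.get(gene, 0) + 1
    table = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene_id", "rule_count"],
    )
    table["n_top_rules"] = len(top)
    threshold = cfg.hub_fraction * len(top)
    hubs = [g for g, c in zip(table["gene_id"], table["rule_count"]) if c >= threshold]
    return hubs, table


def mine_outcome_rules(
    gene_mat: ExpressionMatrix,
    clin: ClinicalTable,
    genes,
    cfg: MiningConfig,
) -> tuple[TransactionDB, list[AssociationRule], list[str], pd.DataFrame]:
    """Convenience wrapper: transactions -> Apriori -> outcome rules -> hubs."""
    db = build_transactions(gene_mat, clin, genes, cfg)
    freq = apriori_frequent_itemsets(db, cfg.min_support, cfg.max_itemset_size)
    rules = generate_rules(freq, db, cfg)
    outcome_rules = filter_outcome_rules(rules)
    hubs, counts = extract_hub_genes(outcome_rules, cfg)
    return db, outcome_rules, hubs, counts


def rules_to_frame(rules) -> pd.DataFrame:
    """Tabular view of a rule list (items ';'-joined), for TSV export."""
    rows = [
        (
            ";".join(sorted(r.antecedent)),
            ";".join(sorted(r.consequent)),
            r.support,
            r.confidence,
            r.lift,
        )
        for r in rules
    ]
    return pd.DataFrame(
        rows, columns=["antecedent", "consequent", "support", "confidence", "lift"])
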