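"""Translate hub biomarker genes into ranked treatment proposals.

Primary drugs come straight from a gene-drug association table (one or more
drugs per hub; hubs without an entry are flagged).  Combination candidates
are all unordered pairs of distinct primary drugs.  Secondary drugs are
chosen by a second round of rule mining: for each hub, rules whose
antecedent contains the hub-high item and the metastasis item and whose
consequent consists only of high-expression items of OTHER drug-annotated
genes; a drug is ranked by the number of distinct (hub, rule) pairs whose
consequent genes map to it, mirroring "more association rules than others".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .config import MiningConfig
from .containers import ClinicalTable, ExpressionMatrix, GeneDrugTable, normalize_drug_name
from .rules import (
    MET_ITEM,
    AssociationRule,
    apriori_frequent_itemsets,
    build_transactions,
    gene_item,
    generate_rules,
    item_gene,
)


def primary_drugs(hubs, table: GeneDrugTable) -> tuple[dict[str, list[str]], list[str]]:
    """All drugs associated with each hub gene.

    Returns ``(mapping, missing)``: hub -> sorted drug list, plus the hubs
    with no association (flagged, not an error).
    """
    mapping: dict[str, list[str]] = {}
    missing = []
    for hub in hubs:
        drugs = table.drugs_of(hub)
        if drugs:
            mapping[hub] = drugs
        else:
            missing.append(hub)
    return mapping, missing


def primary_combinations(mapping: dict[str, list[str]]) -> list[tuple[str, str]]:
    """All unordered pairs of distinct primary drugs (dedup by identity key)."""
    seen: dict[str, str] = {}
    for drugs in mapping.values():
        for drug in drugs:
            seen.setdefault(normalize_drug_name(drug), drug)
    distinct = [seen[k] for k in sorted(seen)]
    if len(distinct) < 2:
        return []
    return [tuple(sorted(pair, key=normalize_drug_name)) for pair in combinations(distinct, 2)]


def secondary_drug_ranking(
    hubs,
    gene_mat: ExpressionMatrix,
    clin: ClinicalTable,
    table: GeneDrugTable,
    cfg: MiningConfig,
) -> tuple[list[tuple[str, int]], pd.DataFrame]:
    """Rank candidate secondary drugs by association-rule count.

    Transactions cover the hub genes plus every drug-annotated non-hub gene
    present in the matrix.  For each hub, qualifying rules have antecedent
    containing {hub:high, MET} with any further items being gene-high items,
    and a consequent consisting only of high items of drug-annotated
    non-hub genes.  Each qualifying (hub, rule) pair credits one count to
    every drug mapped to a consequent gene.  The ranking is invariant to the
    gene-drug table's row order.  Returns ``(ranking, provenance)``.
    """
    hubs = sorted(set(hubs))
    annotated = sorted(
        (table.annotated_genes() - set(hubs)) & set(gene_mat.feature_ids))
    if not annotated:
        return [], pd.DataFrame(
            columns=["drug_name", "hub_gene", "antecedent", "consequent", "support",
                     "confidence", "lift"])
    mine_genes = sorted(set(hubs) | set(annotated))
    db = build_transactions(gene_mat, clin, mine_genes, cfg)
    freq = apriori_frequent_itemsets(db, cfg.min_support, cfg.max_itemset_size)
    rules = generate_rules(freq, db, cfg)

    annotated_items = {gene_item(g) for g in annotated}
    hub_items = {hub: gene_item(hub) for hub in hubs}
    counts: dict[str, set[tuple[str, frozenset, frozenset]]] = {}
    display: dict[str, str] = {}
    prov_rows = []
    for rule in rules:
        if not rule.consequent <= annotated_items:
            continue
        extra = rule.antecedent - {MET_ITEM}
        if MET_ITEM not in rule.antecedent or any(item_gene(i) is None for i in extra):
            continue
        consequent_genes = [item_gene(i) for i in sorted(rule.consequent)]
        for hub in hubs:
            if hub_items[hub] not in rule.antecedent:
                continue
            key = (hub, rule.antecedent, rule.consequent)
            for gene in consequent_genes:
                for drug in table.drugs_of(gene):
                    norm = normalize_drug_name(drug)
                    display.setdefault(norm, drug)
                    counts.setdefault(norm, set()).add(key)
                    prov_rows.append((
                        display[norm], hub,
                        ";".join(sorted(rule.antecedent)),
                        ";".join(sorted(rule.consequent)),
                        rule.support, rule.confidence, rule.lift,
                    ))
    ranking = sorted(
        ((display[norm], len(keys)) for norm, keys in counts.items()),
        key=lambda kv: (-kv[1], normalize_drug_name(kv[0])),
    )
    provenance = pd.DataFrame(
        prov_rows,
        columns=["drug_name", "hub_gene", "antecedent", "consequent", "support",
                 "confidence", "lift"],
    ).drop_duplicates().reset_index(drop=True)
    return ranking, provenance


@dataclass
class TreatmentPlan:
    """Serializable treatment report: primaries, combinations, secondaries.

    ``provenance`` records, per secondary drug, the supporting rules; every
    listed drug is traceable either to a gene-drug record (primaries) or to
    at least one mined rule (secondaries).
    """

    hub_genes: list[str]
    primary: dict[str, list[str]]            # hub gene -> drugs
    unmapped_hubs: list[str]
    primary_pairs: list[tuple[str, str]]
    secondary: list[tuple[str, int]]         # (drug, rule count), ranked
    provenance: list[dict] = field(default_factory=list)
    status: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "hub_genes": self.hub_genes,
            "primary": self.primary,
            "unmapped_hubs": self.unmapped_hubs,
            "primary_pairs": [list(p) for p in self.primary_pairs],
            "secondary": [[d, c] for d, c in self.secondary],
            "provenance": self.provenance,
            "status": self.status,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TreatmentPlan":
        raw = json.loads(text)
        return cls(
            hub_genes=list(raw["hub_genes"]),
            primary={k: list(v) for k, v in raw["primary"].items()},
            unmapped_hubs=list(raw["unmapped_hubs"]),
            primary_pairs=[tuple(p) for p in raw["primary_pairs"]],
            secondary=[(d, int(c)) for d, c in raw["secondary"]],
            provenance=list(raw["provenance"]),
            status=list(raw["status"]),
        )

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for hub in self.hub_genes:
            for drug in self.primary.get(hub, []):
                rows.append(("primary", hub, drug, ""))
        for hub in self.unmapped_hubs:
            rows.append(("primary", hub, "", "no gene-drug association"))
        for a, b in self.primary_pairs:
            rows.append(("combination", "", f"{a} + {b}", ""))
        for drug, count in self.secondary:
            rows.append(("secondary", "", drug, f"{count} supporting rules"))
        return pd.DataFrame(rows, columns=["category", "hub_gene", "drug", "note"])


def build_treatment_plan(
    hubs,
    gene_mat: ExpressionMatrix,
    clin: ClinicalTable,
    table: GeneDrugTable,
    cfg: MiningConfig,
) -> TreatmentPlan:
    """Assemble the full treatment report from upstream artifacts.

    Empty upstream results (no hubs, no mapped drugs, no secondary rules)
    become status warnings; a report is always produced.
    """
    hubs = list(hubs)
    status = []
    if not hubs:
        status.append("no hub genes supplied; plan is empty")
        return TreatmentPlan([], {}, [], [], [], [], status)
    mapping, missing = primary_drugs(hubs, table)
    if missing:
        status.append(f"hubs without gene-drug association: {missing}")
    pairs = primary_combinations(mapping)
    if not pairs:
        status.append("fewer than two distinct primary drugs; no combinations proposed")
    ranking, prov = secondary_drug_ranking(hubs, gene_mat, clin, table, cfg)
    if not ranking:
        status.append("no secondary-drug rules found")
    return TreatmentPlan(
        hub_genes=sorted(hubs),
        primary=mapping,
        unmapped_hubs=missing,
        primary_pairs=pairs,
        secondary=ranking,
        provenance=prov.to_dict(orient="records"),
        status=status,
    )
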