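"""Synthetic cohorts, annotation tables and implanted ground truth.

The generator emulates the study design the pipeline was built for: two
miRNA cohorts (sarcoma cell lines vs a nontumor line; tumor vs nontumor
tissue) sharing a conserved set of down-regulated miRNAs and one conserved
up-regulated miRNA; a clinical mRNA cohort in which the signature miRNAs'
target genes are up-regulated and anti-correlated with their regulators; a
latent "hub-high" patient subgroup in which a few hub biomarker genes (and a
set of bystander genes) are strongly over-expressed, metastasis is more
likely and survival is shorter; and annotation tables (miRNA->target map,
gene->drug table, gene sets) wiring hubs to distinct primary drugs and
bystanders to one shared secondary drug.

Everything is driven by a single integer seed through named, independently
reproducible RNG sub-streams, so any artifact can be regenerated on its own
and identical configurations yield byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SynthConfig
from .containers import (
    CASE,
    CONTROL,
    ClinicalTable,
    DESignature,
    ExpressionMatrix,
    GeneDrugTable,
    GeneSetCollection,
    TargetMapTable,
)
from .exceptions import ConsistencyError

# Named RNG sub-streams: each artifact draws from its own deterministic
# stream derived from (seed, stream id), so regenerating one table never
# perturbs another.
_STREAMS = {
    "assign": 0,
    "baseline_mirna": 1,
    "baseline_gene": 2,
    "cell_noise": 3,
    "tumor_noise": 4,
    "clinical_mirna": 5,
    "gene_noise": 6,
    "latent": 7,
    "latent_tumor": 8,
    "met": 9,
    "surv": 10,
    "censor": 11,
    "tmap_extra": 12,
    "genesets": 13,
}

_MIRNA_BASE_MEAN, _MIRNA_BASE_SD = 7.0, 1.5
_GENE_BASE_MEAN, _GENE_BASE_SD = 8.0, 1.5


def _rng(cfg: SynthConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), _STREAMS[stream]])


def _mirna_ids(cfg: SynthConfig) -> list[str]:
    return [f"miR-{i:04d}" for i in range(1, cfg.n_mirnas + 1)]


def _gene_ids(cfg: SynthConfig) -> list[str]:
    return [f"GENE{i:04d}" for i in range(1, cfg.n_genes + 1)]


@dataclass
class GroundTruth:
    """Implanted truth, for recovery tests and synthetic annotation tables."""

    conserved_down_mirnas: set[str]
    cellline_only_down_mirnas: set[str]
    up_mirnas: set[str]
    hub_genes: set[str]
    implanted_target_map: dict[str, tuple[str, ...]]  # conserved-down miRNA -> targets
    primary_drug_per_hub: dict[str, str]
    secondary_drug: str
    bystander_genes: tuple[str, ...]
    decoy_drug_genes: tuple[str, ...]
    config_digest: str = ""

    def __post_init__(self) -> None:
        if self.conserved_down_mirnas & self.up_mirnas:
            raise ConsistencyError("conserved-down and up miRNA sets overlap")
        all_targets = {g for tg in self.implanted_target_map.values() for g in tg}
        if not self.hub_genes <= all_targets:
            raise ConsistencyError("hub genes are not all implanted as miRNA targets")

    @property
    def target_genes(self) -> set[str]:
        return {g for tg in self.implanted_target_map.values() for g in tg}

    def to_json(self) -> str:
        payload = {
            "conserved_down_mirnas": sorted(self.conserved_down_mirnas),
            "cellline_only_down_mirnas": sorted(self.cellline_only_down_mirnas),
            "up_mirnas": sorted(self.up_mirnas),
            "hub_genes": sorted(self.hub_genes),
            "implanted_target_map": {m: list(g) for m, g in sorted(self.implanted_target_map.items())},
            "primary_drug_per_hub": dict(sorted(self.primary_drug_per_hub.items())),
            "secondary_drug": self.secondary_drug,
            "bystander_genes": list(self.bystander_genes),
            "decoy_drug_genes": list(self.decoy_drug_genes),
            "config_digest": self.config_digest,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        return cls(
            conserved_down_mirnas=set(raw["conserved_down_mirnas"]),
            cellline_only_down_mirnas=set(raw["cellline_only_down_mirnas"]),
            up_mirnas=set(raw["up_mirnas"]),
            hub_genes=set(raw["hub_genes"]),
            implanted_target_map={m: tuple(g) for m, g in raw["implanted_target_map"].items()},
            primary_drug_per_hub=raw["primary_drug_per_hub"],
            secondary_drug=raw["secondary_drug"],
            bystander_genes=tuple(raw["bystander_genes"]),
            decoy_drug_genes=tuple(raw["decoy_drug_genes"]),
            config_digest=raw.get("config_digest", ""),
        )


@dataclass
class ClinicalCohort:
    """Clinical-cohort bundle: mRNA matrix, follow-up table, and extras.

    ``gene_expr`` contains the clinical tumor samples (case) plus the
    tumor-cohort samples (case tumors and nontumor controls) so downstream
    stages have both a tumor-vs-normal contrast and samples shared with the
    miRNA tumor cohort for anti-correlation.  ``mirna_expr`` holds miRNA
    expression for the clinical samples (used for signature-score survival
    stratification).  ``hub_high`` is the latent subgroup indicator over the
    clinical samples, exposed for recovery tests only.
    """

    gene_expr: ExpressionMatrix
    clinical: ClinicalTable
    mirna_expr: ExpressionMatrix
    hub_high: pd.Series


def _assign_roles(cfg: SynthConfig) -> GroundTruth:
    rng = _rng(cfg, "assign")
    mirnas = np.array(_mirna_ids(cfg))
    genes = np.array(_gene_ids(cfg))
    mperm = rng.permutation(len(mirnas))
    gperm = rng.permutation(len(genes))

    i = 0
    conserved = [mirnas[j] for j in mperm[i:i + cfg.n_conserved_down]]
    i += cfg.n_conserved_down
    cell_only = [mirnas[j] for j in mperm[i:i + cfg.n_cellline_only_down]]
    i += cfg.n_cellline_only_down
    up = [mirnas[j] for j in mperm[i:i + cfg.n_up]]

    k = 0
    hubs = [genes[j] for j in gperm[k:k + cfg.n_hub_genes]]
    k += cfg.n_hub_genes
    per_pool = cfg.targets_per_mirna - 1 if cfg.n_hub_genes > 0 else cfg.targets_per_mirna
    per_pool = max(per_pool, 0)
    pool = [genes[j] for j in gperm[k:k + cfg.n_conserved_down * per_pool]]
    k += cfg.n_conserved_down * per_pool
    bystanders = [genes[j] for j in gperm[k:k + cfg.n_bystanders]]
    k += cfg.n_bystanders
    decoys = [genes[j] for j in gperm[k:k + cfg.n_decoy_drug_genes]]

    tmap: dict[str, tuple[str, ...]] = {}
    for idx, m in enumerate(conserved):
        targets: list[str] = []
        if cfg.n_hub_genes > 0 and cfg.targets_per_mirna >= 1:
            targets.append(hubs[idx % cfg.n_hub_genes])
        targets.extend(pool[idx * per_pool:(idx + 1) * per_pool])
        tmap[m] = tuple(targets)

    primaries = {hub: f"PRIMARY_DRUG_{j + 1}" for j, hub in enumerate(sorted(hubs))}
    return GroundTruth(
        conserved_down_mirnas=set(conserved),
        cellline_only_down_mirnas=set(cell_only),
        up_mirnas=set(up),
        hub_genes=set(hubs),
        implanted_target_map=tmap,
        primary_drug_per_hub=primaries,
        secondary_drug="SECONDARY_DRUG",
        bystander_genes=tuple(bystanders),
        decoy_drug_genes=tuple(decoys),
        config_digest=cfg.digest(),
    )


def _mirna_baselines(cfg: SynthConfig) -> pd.Series:
    rng = _rng(cfg, "baseline_mirna")
    vals = _MIRNA_BASE_MEAN + _MIRNA_BASE_SD * rng.standard_normal(cfg.n_mirnas)
    return pd.Series(vals, index=_mirna_ids(cfg))


def _gene_baselines(cfg: SynthConfig) -> pd.Series:
    rng = _rng(cfg, "baseline_gene")
    vals = _GENE_BASE_MEAN + _GENE_BASE_SD * rng.standard_normal(cfg.n_genes)
    return pd.Series(vals, index=_gene_ids(cfg))


def _mirna_shift(cfg: SynthConfig, truth: GroundTruth, include_cell_only: bool) -> pd.Series:
    shift = pd.Series(0.0, index=_mirna_ids(cfg))
    down = set(truth.conserved_down_mirnas)
    if include_cell_only:
        down |= truth.cellline_only_down_mirnas
    shift[shift.index.isin(down)] = -cfg.effect_log2fc
    shift[shift.index.isin(truth.up_mirnas)] = cfg.effect_log2fc
    return shift


def _mirna_cohort(cfg, truth, prefix: str, n_per_group: int, stream: str,
                  include_cell_only: bool) -> ExpressionMatrix:
    base = _mirna_baselines(cfg)
    shift = _mirna_shift(cfg, truth, include_cell_only)
    samples = [f"{prefix}_T{i + 1:03d}" for i in range(n_per_group)] + \
              [f"{prefix}_N{i + 1:03d}" for i in range(n_per_group)]
    group = pd.Series([CASE] * n_per_group + [CONTROL] * n_per_group, index=samples)
    noise = _rng(cfg, stream).standard_normal((cfg.n_mirnas, len(samples))) * cfg.noise_sd
    values = base.to_numpy()[:, None] + noise
    values[:, :n_per_group] += shift.to_numpy()[:, None]
    return ExpressionMatrix(pd.DataFrame(values, index=base.index, columns=samples), group)


def simulate_mirna_cohorts(cfg: SynthConfig) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Simulate the cell-line and tumor-tissue miRNA cohorts.

    Conserved-down miRNAs are shifted by ``-effect_log2fc`` in the case group
    of BOTH cohorts, cell-line-only down miRNAs only in the cell-line cohort,
    up miRNAs by ``+effect_log2fc`` in both; everything else differs only by
    Gaussian log2 noise.
    """
    cfg.validate()
    truth = _assign_roles(cfg)
    cell = _mirna_cohort(cfg, truth, "CL", cfg.n_cell_samples, "cell_noise",
                         include_cell_only=True)
    tumor = _mirna_cohort(cfg, truth, "TU", cfg.n_tumor_samples, "tumor_noise",
                          include_cell_only=False)
    return cell, tumor, truth


def _check_truth(cfg: SynthConfig, truth: GroundTruth) -> None:
    if truth.config_digest and truth.config_digest != cfg.digest():
        raise ConsistencyError(
            "ground truth was generated from a different configuration "
            f"(digest {truth.config_digest} != {cfg.digest()})")


def simulate_clinical_cohort(cfg: SynthConfig, truth: GroundTruth) -> ClinicalCohort:
    """Simulate the clinical mRNA cohort with survival and metastasis.

    A latent hub-high subgroup (fraction ``hub_high_frac`` of clinical
    tumors) carries strongly elevated hub and bystander genes, an extra
    down-shift of the conserved signature miRNAs, higher metastasis
    probability and an exponential survival hazard multiplied by
    ``hazard_ratio_hub``.  Target genes respond negatively to their
    regulating miRNAs' deviations, making them up-regulated in tumors and
    anti-correlated with the signature.
    """
    cfg.validate()
    _check_truth(cfg, truth)

    n = cfg.n_clinical_samples
    pt_samples = [f"PT{i + 1:04d}" for i in range(n)]

    # Latent hub-high subgroup: exact count among clinical samples.
    n_high = int(round(cfg.hub_high_frac * n))
    order = _rng(cfg, "latent").permutation(n)
    latent_pt = np.zeros(n, dtype=bool)
    latent_pt[order[:n_high]] = True

    # Clinical-sample miRNA expression (all samples are tumors).
    mir_base = _mirna_baselines(cfg)
    shift = _mirna_shift(cfg, truth, include_cell_only=False)
    noise = _rng(cfg, "clinical_mirna").standard_normal((cfg.n_mirnas, n)) * cfg.noise_sd
    mir_vals = mir_base.to_numpy()[:, None] + shift.to_numpy()[:, None] + noise
    conserved_mask = mir_base.index.isin(truth.conserved_down_mirnas)
    mir_vals[np.ix_(conserved_mask, latent_pt)] -= cfg.mirna_hub_coupling * cfg.effect_log2fc
    mirna_expr = ExpressionMatrix(
        pd.DataFrame(mir_vals, index=mir_base.index, columns=pt_samples),
        pd.Series(CASE, index=pt_samples),
    )

    # Tumor-cohort miRNA matrix regenerated deterministically so its samples
    # can be embedded in the gene matrix with coupled values.
    tumor = _mirna_cohort(cfg, truth, "TU", cfg.n_tumor_samples, "tumor_noise",
                          include_cell_only=False)
    latent_tu = np.concatenate([
        _rng(cfg, "latent_tumor").random(cfg.n_tumor_samples) < cfg.hub_high_frac,
        np.zeros(cfg.n_tumor_samples, dtype=bool),  # controls never hub-high
    ])

    all_samples = tumor.sample_ids + pt_samples
    latent_all = np.concatenate([latent_tu, latent_pt])
    mir_all = np.concatenate([tumor.values.to_numpy(), mir_vals], axis=1)
    mir_dev = mir_all - mir_base.to_numpy()[:, None]
    mir_index = {m: i for i, m in enumerate(mir_base.index)}

    gene_base = _gene_baselines(cfg)
    gnoise = _rng(cfg, "gene_noise").standard_normal((cfg.n_genes, len(all_samples))) * cfg.noise_sd
    gene_vals = gene_base.to_numpy()[:, None] + gnoise

    regulators: dict[str, list[str]] = {}
    for m, targets in truth.implanted_target_map.items():
        for g in targets:
            regulators.setdefault(g, []).append(m)
    gene_index = {g: i for i, g in enumerate(gene_base.index)}
    for g, regs in regulators.items():
        rows = [mir_index[m] for m in sorted(regs)]
        gene_vals[gene_index[g]] -= cfg.target_coupling * mir_dev[rows].mean(axis=0)
    for g in sorted(truth.hub_genes | set(truth.bystander_genes)):
        gene_vals[gene_index[g]] += cfg.effect_log2fc * latent_all

    group = pd.Series(
        [CASE] * cfg.n_tumor_samples + [CONTROL] * cfg.n_tumor_samples + [CASE] * n,
        index=all_samples,
    )
    gene_expr = ExpressionMatrix(
        pd.DataFrame(gene_vals, index=gene_base.index, columns=all_samples), group)

    # Clinical outcomes for the PT samples only.
    met_p = np.where(latent_pt, cfg.met_prob_hub_high, cfg.met_prob_base)
    metastasis = (_rng(cfg, "met").random(n) < met_p).astype(int)
    base_rate = np.log(2.0) / cfg.baseline_median_months
    rate = base_rate * np.where(latent_pt, cfg.hazard_ratio_hub, 1.0)
    t_event = _rng(cfg, "surv").standard_exponential(n) / rate
    cens_rng = _rng(cfg, "censor")
    censored = cens_rng.random(n) < cfg.censor_rate
    frac = cens_rng.random(n)
    time = np.where(censored, t_event * frac, t_event)
    event = (~censored).astype(int)
    clinical = ClinicalTable(pd.DataFrame(
        {"time_months": time, "event": event, "metastasis": metastasis},
        index=pd.Index(pt_samples, name="sample_id"),
    ))

    return ClinicalCohort(
        gene_expr=gene_expr,
        clinical=clinical,
        mirna_expr=mirna_expr,
        hub_high=pd.Series(latent_pt, index=pt_samples, name="hub_high"),
    )


def simulate_annotation_tables(
    cfg: SynthConfig, truth: GroundTruth
) -> tuple[TargetMapTable, GeneDrugTable, GeneSetCollection]:
    """Materialize the miRNA->target map, gene->drug table and gene sets.

    The target map carries the implanted regulator->target pairs (plus decoy
    targets for the up miRNAs); the drug table links each hub to its distinct
    primary drug, every bystander to the shared secondary drug, and each
    decoy gene to its own decoy drug; the gene-set collection contains one
    set enriched for implanted targets plus random decoy sets.
    """
    cfg.validate()
    _check_truth(cfg, truth)

    rows = [(m, g) for m in sorted(truth.implanted_target_map)
            for g in truth.implanted_target_map[m]]
    all_genes = _gene_ids(cfg)
    occupied = truth.target_genes | set(truth.bystander_genes) | set(truth.decoy_drug_genes)
    noise_genes = [g for g in all_genes if g not in occupied]
    extra_rng = _rng(cfg, "tmap_extra")
    for m in sorted(truth.up_mirnas):
        k = min(cfg.targets_per_mirna, len(noise_genes))
        if k:
            picks = extra_rng.choice(len(noise_genes), size=k, replace=False)
            rows.extend((m, noise_genes[j]) for j in sorted(picks))
    tmap = TargetMapTable(pd.DataFrame(rows, columns=["mirna_id", "gene_id"]))

    drug_rows = [(hub, drug) for hub, drug in sorted(truth.primary_drug_per_hub.items())]
    drug_rows += [(g, truth.secondary_drug) for g in truth.bystander_genes]
    drug_rows += [(g, f"DECOY_DRUG_{j + 1:02d}") for j, g in enumerate(truth.decoy_drug_genes)]
    gdt = GeneDrugTable(pd.DataFrame(drug_rows, columns=["gene_id", "drug_name"]))

    gs_rng = _rng(cfg, "genesets")
    targets = sorted(truth.target_genes)
    n_members = max(1, int(0.6 * len(targets))) if targets else 0
    enriched: set[str] = set()
    if n_members:
        picks = gs_rng.choice(len(targets), size=n_members, replace=False)
        enriched = {targets[j] for j in picks} | truth.hub_genes
        if noise_genes:
            extras = gs_rng.choice(len(noise_genes), size=min(3, len(noise_genes)), replace=False)
            enriched |= {noise_genes[j] for j in extras}
    sets = {"IMPLANTED_TARGET_PROGRAM": enriched}
    descriptions = {"IMPLANTED_TARGET_PROGRAM": "synthetic set enriched for implanted miRNA targets"}
    for j in range(4):
        size = min(20, len(all_genes))
        picks = gs_rng.choice(len(all_genes), size=size, replace=False)
        name = f"RANDOM_SET_{j + 1}"
        sets[name] = {all_genes[i] for i in picks}
        descriptions[name] = "synthetic random decoy set"
    return tmap, gdt, GeneSetCollection(sets=sets, descriptions=descriptions)


# ---------------------------------------------------------------------------
# Stand-in supplementary differential-expression lists
# ---------------------------------------------------------------------------

def synthetic_supplementary_signatures() -> tuple[DESignature, DESignature]:
    """Synthetic stand-in for the two published supplementary miRNA DE lists.

    The real supplementary tables are not redistributable, so this builds two
    signature tables with the published list structure: 81 cell-line entries
    (23 down, 49 up, 9 with no direction call) and 51 tumor entries (49 down,
    2 up), sharing exactly 16 down-regulated miRNAs and one up-regulated
    miRNA, hsa-miR-138-5p.  Only hsa-miR-138-5p is a real identifier; all
    other names are synthetic placeholders.
    """

    shared_down = [f"hsa-miR-syn-dn{i:02d}" for i in range(1, 17)]
    cell_only_down = [f"hsa-miR-syn-cdn{i:02d}" for i in range(1, 8)]           # 23 down total
    shared_up = ["hsa-miR-138-5p"]
    cell_only_up = [f"hsa-miR-syn-cup{i:02d}" for i in range(1, 49)]            # 49 up total
    cell_uncalled = [f"hsa-miR-syn-cna{i:02d}" for i in range(1, 10)]           # 81 entries total
    tumor_only_down = [f"hsa-miR-syn-tdn{i:02d}" for i in range(1, 34)]         # 49 down total
    tumor_only_up = ["hsa-miR-syn-tup01"]                                       # 2 up total

    def build(down, up, uncalled):
        names = down + up + uncalled
        direction = ["down"] * len(down) + ["up"] * len(up) + ["unchanged"] * len(uncalled)
        lfc = [-2.0] * len(down) + [2.0] * len(up) + [0.0] * len(uncalled)
        p = [1e-4] * (len(down) + len(up)) + [0.5] * len(uncalled)
        q = [1e-3] * (len(down) + len(up)) + [0.8] * len(uncalled)
        table = pd.DataFrame(
            {"log2fc": lfc, "p": p, "q": q, "direction": direction},
            index=pd.Index(names, name="feature_id"),
        )
        return DESignature(table)

    cell = build(shared_down + cell_only_down, shared_up + cell_only_up, cell_uncalled)
    tumor = build(shared_down + tumor_only_down, shared_up + tumor_only_up, [])
    return cell, tumor
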