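"""Stage orchestration: simulate -> de -> intersect -> targets -> mine -> treat.

Each stage reads its predecessors' files from the output directory, writes
its own artifacts plus a run manifest, and fails with an actionable
:class:`~sarcomir.exceptions.DependencyError` naming any missing input.
Artifacts contain no timestamps and floats are serialized at fixed
precision, so two runs of the same configuration are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, io
from .config import PipelineConfig
from .containers import GeneSetCollection
from .diffexpr import compute_de, intersect_signatures, logrank_by_median_score, signature_score
from .exceptions import DependencyError, SarcomirError
from .rules import mine_outcome_rules, rules_to_frame
from .synth import (
    GroundTruth,
    simulate_annotation_tables,
    simulate_clinical_cohort,
    simulate_mirna_cohorts,
)
from .targets import candidate_targets, filter_upregulated_anticorrelated, hypergeom_enrichment
from .therapy import build_treatment_plan

logger = logging.getLogger(__name__)

STAGES = ("simulate", "de", "intersect", "targets", "mine", "treat")

_FILES = {
    "cell_mirna": "cell_mirna.tsv",
    "cell_groups": "cell_mirna.groups.tsv",
    "tumor_mirna": "tumor_mirna.tsv",
    "tumor_groups": "tumor_mirna.groups.tsv",
    "clinical_mirna": "clinical_mirna.tsv",
    "gene_expr": "gene_expr.tsv",
    "gene_groups": "gene_expr.groups.tsv",
    "clinical": "clinical.tsv",
    "target_map": "target_map.tsv",
    "gene_drug": "gene_drug.tsv",
    "gene_sets": "gene_sets.gmt",
    "ground_truth": "ground_truth.json",
    "de_cell": "de_cell.tsv",
    "de_tumor": "de_tumor.tsv",
    "sig_down": "signature_down.tsv",
    "sig_up": "signature_up.tsv",
    "sig_discordant": "signature_discordant.tsv",
    "survival": "survival_logrank.json",
    "candidates": "candidate_targets.tsv",
    "filtered": "filtered_targets.tsv",
    "enrichment": "enrichment.tsv",
    "transactions": "transactions.tsv",
    "rules": "rules.tsv",
    "hubs": "hub_genes.tsv",
    "plan": "treatment_plan.json",
    "plan_summary": "treatment_summary.tsv",
}


def artifact(cfg: PipelineConfig, key: str) -> Path:
    return Path(cfg.outdir) / _FILES[key]


def _need(cfg: PipelineConfig, *keys) -> None:
    missing = [str(artifact(cfg, k)) for k in keys if not artifact(cfg, k).exists()]
    if missing:
        raise DependencyError(
            "missing input artifact(s): " + ", ".join(missing)
            + " (run the producing stage first)")


def _write_manifest(cfg: PipelineConfig, stage: str) -> None:
    import numpy
    import scipy

    manifest = {
        "stage": stage,
        "config_digest": cfg.digest(),
        "seed": cfg.effective_synth().seed,
        "versions": {
            "sarcomir": __version__,
            "numpy": numpy.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
    }
    path = Path(cfg.outdir) / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def stage_simulate(cfg: PipelineConfig) -> None:
    synth_cfg = cfg.effective_synth()
    cell, tumor, truth = simulate_mirna_cohorts(synth_cfg)
    cohort = simulate_clinical_cohort(synth_cfg, truth)
    tmap, gdt, gene_sets = simulate_annotation_tables(synth_cfg, truth)

    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_expression(cell, artifact(cfg, "cell_mirna"), artifact(cfg, "cell_groups"))
    io.write_expression(tumor, artifact(cfg, "tumor_mirna"), artifact(cfg, "tumor_groups"))
    io.write_expression(cohort.mirna_expr, artifact(cfg, "clinical_mirna"))
    io.write_expression(cohort.gene_expr, artifact(cfg, "gene_expr"), artifact(cfg, "gene_groups"))
    io.write_clinical(cohort.clinical, artifact(cfg, "clinical"))
    io.write_target_map(tmap, artifact(cfg, "target_map"))
    io.write_gene_drug(gdt, artifact(cfg, "gene_drug"))
    io.write_gmt(gene_sets, artifact(cfg, "gene_sets"))
    artifact(cfg, "ground_truth").write_text(truth.to_json() + "\n")


def stage_de(cfg: PipelineConfig) -> None:
    _need(cfg, "cell_mirna", "cell_groups", "tumor_mirna", "tumor_groups")
    for key, out_key in (("cell", "de_cell"), ("tumor", "de_tumor")):
        mat = io.read_expression(artifact(cfg, f"{key}_mirna"), artifact(cfg, f"{key}_groups"))
        sig = compute_de(mat, cfg.de.fc_threshold, cfg.de.q_threshold)
        io.write_de(sig, artifact(cfg, out_key))


def stage_intersect(cfg: PipelineConfig) -> None:
    _need(cfg, "de_cell", "de_tumor")
    sig_cell = io.read_de(artifact(cfg, "de_cell"))
    sig_tumor = io.read_de(artifact(cfg, "de_tumor"))
    down, up, discordant = intersect_signatures(sig_cell, sig_tumor)
    io.write_gene_list(down, artifact(cfg, "sig_down"), header="mirna_id")
    io.write_gene_list(up, artifact(cfg, "sig_up"), header="mirna_id")
    io.write_gene_list(discordant, artifact(cfg, "sig_discordant"), header="mirna_id")

    # Fig-1b-style survival stratification when clinical miRNA data exist.
    if artifact(cfg, "clinical_mirna").exists() and artifact(cfg, "clinical").exists() and down:
        mat = io.read_expression(artifact(cfg, "clinical_mirna"))
        clin = io.read_clinical(artifact(cfg, "clinical"))
        scores = signature_score(mat, down)
        chi_square, p, sizes = logrank_by_median_score(scores, clin)
        payload = {"chi_square": chi_square, "p": p, "group_sizes": sizes,
                   "n_signature_mirnas": len(down)}
        artifact(cfg, "survival").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def stage_targets(cfg: PipelineConfig) -> None:
    _need(cfg, "sig_down", "target_map", "tumor_mirna", "gene_expr", "gene_groups")
    down = set(io.read_gene_list(artifact(cfg, "sig_down")))
    tmap = io.read_target_map(artifact(cfg, "target_map"))
    genes, degree = candidate_targets(down, tmap)
    frame = degree.to_frame().reset_index()
    io.write_frame(frame, artifact(cfg, "candidates"))

    mirna_mat = io.read_expression(artifact(cfg, "tumor_mirna"), artifact(cfg, "tumor_groups"))
    gene_mat = io.read_expression(artifact(cfg, "gene_expr"), artifact(cfg, "gene_groups"))
    kept, _detail = filter_upregulated_anticorrelated(
        genes, mirna_mat, gene_mat, tmap, down,
        rho_threshold=cfg.targets.rho_threshold,
        q_threshold=cfg.targets.q_threshold,
        de_config=cfg.de,
    )
    io.write_gene_list(kept, artifact(cfg, "filtered"))

    if artifact(cfg, "gene_sets").exists():
        collection = io.read_gmt(artifact(cfg, "gene_sets"))
        universe = set(gene_mat.feature_ids)
        enrichment = hypergeom_enrichment(kept & universe, universe, collection)
        io.write_frame(enrichment, artifact(cfg, "enrichment"))


def stage_mine(cfg: PipelineConfig) -> None:
    _need(cfg, "filtered", "gene_expr", "clinical")
    genes = set(io.read_gene_list(artifact(cfg, "filtered")))
    if not genes:
        raise DependencyError(
            f"{artifact(cfg, 'filtered')}: filtered gene list is empty; nothing to mine")
    gene_mat = io.read_expression(artifact(cfg, "gene_expr"))
    clin = io.read_clinical(artifact(cfg, "clinical"))
    db, outcome_rules, hubs, counts = mine_outcome_rules(gene_mat, clin, genes, cfg.mining)
    with open(artifact(cfg, "transactions"), "w") as fh:
        fh.write("sample_id\titems\n")
        for sid, tx in zip(db.sample_ids, db.transactions):
            fh.write(f"{sid}\t{';'.join(sorted(tx))}\n")
    io.write_frame(rules_to_frame(outcome_rules), artifact(cfg, "rules"))
    io.write_frame(counts, artifact(cfg, "hubs"))


def stage_treat(cfg: PipelineConfig) -> None:
    _need(cfg, "hubs", "gene_expr", "clinical", "gene_drug")
    hub_frame = pd.read_csv(artifact(cfg, "hubs"), sep="\t")
    threshold_col = hub_frame["n_top_rules"] * cfg.mining.hub_fraction if len(hub_frame) else []
    hubs = [g for g, c, t in zip(hub_frame.get("gene_id", []),
                                 hub_frame.get("rule_count", []),
                                 threshold_col) if c >= t]
    gene_mat = io.read_expression(artifact(cfg, "gene_expr"))
    clin = io.read_clinical(artifact(cfg, "clinical"))
    table = io.read_gene_drug(artifact(cfg, "gene_drug"))
    plan = build_treatment_plan(hubs, gene_mat, clin, table, cfg.mining)
    artifact(cfg, "plan").write_text(plan.to_json() + "\n")
    io.write_frame(plan.summary_frame(), artifact(cfg, "plan_summary"))


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "de": stage_de,
    "intersect": stage_intersect,
    "targets": stage_targets,
    "mine": stage_mine,
    "treat": stage_treat,
}


def run_stage(stage: str, cfg: PipelineConfig) -> None:
    """Run one named stage (or ``"all"``) and write its manifest."""
    cfg.validate()
    if stage == "all":
        for name in STAGES:
            logger.info("running stage %s", name)
            _STAGE_FUNCS[name](cfg)
            _write_manifest(cfg, name)
        return
    if stage not in _STAGE_FUNCS:
        raise SarcomirError(f"unknown stage '{stage}'; expected one of {STAGES + ('all',)}")
    logger.info("running stage %s", stage)
    _STAGE_FUNCS[stage](cfg)
    _write_manifest(cfg, stage)


@dataclass
class ValidationReport:
    """Input-schema problems split into fatal errors and warnings."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def is_clean(self) -> bool:
        return not self.errors and not self.warnings


def validate_inputs(cfg: PipelineConfig) -> ValidationReport:
    """Check artifact files for schema problems without running any stage.

    Duplicate feature ids and malformed tables are fatal; sample-id
    mismatches between expression and clinical tables are warnings.
    """
    report = ValidationReport()

    def check_expression(key):
        path = artifact(cfg, key)
        if not path.exists():
            return None
        try:
            frame = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:
            report.errors.append(f"{path}: unreadable ({exc})")
            return None
        if frame.index.duplicated().any():
            dups = sorted(frame.index[frame.index.duplicated()].unique())
            report.errors.append(f"{path}: duplicate feature ids {dups[:5]}")
        if frame.columns.duplicated().any():
            report.errors.append(f"{path}: duplicate sample ids")
        return frame

    gene = check_expression("gene_expr")
    check_expression("cell_mirna")
    check_expression("tumor_mirna")
    check_expression("clinical_mirna")

    clin_path = artifact(cfg, "clinical")
    if clin_path.exists():
        try:
            clin = pd.read_csv(clin_path, sep="\t", index_col=0)
        except Exception as exc:
            report.errors.append(f"{clin_path}: unreadable ({exc})")
            clin = None
        if clin is not None:
            missing_cols = {"time_months", "event", "metastasis"} - set(clin.columns)
            if missing_cols:
                report.errors.append(f"{clin_path}: missing columns {sorted(missing_cols)}")
            elif gene is not None:
                in_expr = set(gene.columns)
                orphan = sorted(set(clin.index) - in_expr)
                if orphan:
                    report.warnings.append(
                        f"{clin_path}: {len(orphan)} clinical samples absent from "
                        f"expression matrix: {orphan[:5]}")
                unannotated = sorted(in_expr - set(clin.index))
                if unannotated:
                    report.warnings.append(
                        f"{clin_path}: {len(unannotated)} expression samples lack "
                        f"clinical rows: {unannotated[:5]}")

    gmt_path = artifact(cfg, "gene_sets")
    if gmt_path.exists():
        try:
            io.read_gmt(gmt_path)
        except SarcomirError as exc:
            report.errors.append(str(exc))
    return report
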