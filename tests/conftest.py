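"""Shared fixtures: a small synthetic world reused across module tests."""

from __future__ import annotations

import dataclasses

import pytest

from sarcomir.config import SynthConfig
from sarcomir.synth import (
    simulate_annotation_tables,
    simulate_clinical_cohort,
    simulate_mirna_cohorts,
)


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """A scaled-down configuration for fast unit tests."""
    return SynthConfig(
        n_mirnas=60,
        n_genes=80,
        n_cell_samples=10,
        n_tumor_samples=10,
        n_clinical_samples=160,
        n_conserved_down=8,
        n_cellline_only_down=3,
        n_up=1,
        targets_per_mirna=3,
        n_bystanders=5,
        n_decoy_drug_genes=8,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """Simulated cohorts + annotation tables + truth for the small config."""
    cell, tumor, truth = simulate_mirna_cohorts(small_cfg)
    cohort = simulate_clinical_cohort(small_cfg, truth)
    tmap, gdt, gene_sets = simulate_annotation_tables(small_cfg, truth)
    return {
        "cfg": small_cfg,
        "cell": cell,
        "tumor": tumor,
        "truth": truth,
        "cohort": cohort,
        "tmap": tmap,
        "gene_drug": gdt,
        "gene_sets": gene_sets,
    }


@pytest.fixture()
def zero_noise_cfg(small_cfg) -> SynthConfig:
    return dataclasses.replace(small_cfg, noise_sd=0.0)
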