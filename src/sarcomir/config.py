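"""Configuration dataclasses for simulation, mining and the pipeline.

All knobs that govern a run live here, so a single YAML file can reproduce
every artifact bit-for-bit.  Validation raises
:class:`~sarcomir.exceptions.ConfigurationError` naming the offending field.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .exceptions import ConfigurationError


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ConfigurationError(message)


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    Counts describe the two miRNA cohorts (sarcoma cell lines vs a nontumor
    line; tumor vs nontumor tissue), the clinical mRNA cohort, and the
    implanted ground truth: a conserved set of down-regulated miRNAs, a
    cell-line-only down set, a conserved up set, hub biomarker genes targeted
    by several signature miRNAs, bystander genes co-expressed with the hubs,
    and decoy drug-annotated genes.  Effects are log2 fold changes; survival
    is exponential with a hazard multiplier for the hub-high subgroup.
    """

    n_mirnas: int = 200
    n_genes: int = 300
    n_cell_samples: int = 20          # per group, cell-line cohort
    n_tumor_samples: int = 20         # per group, tumor-tissue cohort
    n_clinical_samples: int = 500
    n_conserved_down: int = 16
    n_cellline_only_down: int = 7
    n_up: int = 1
    n_hub_genes: int = 3
    targets_per_mirna: int = 5
    n_bystanders: int = 10            # co-high with hubs; share the secondary drug
    n_decoy_drug_genes: int = 20      # drug-annotated noise genes
    effect_log2fc: float = 2.0
    noise_sd: float = 0.5
    hub_high_frac: float = 0.25       # latent fraction of clinical tumors with hubs high
    met_prob_hub_high: float = 0.9
    met_prob_base: float = 0.15
    hazard_ratio_hub: float = 6.0
    baseline_median_months: float = 120.0
    censor_rate: float = 0.2
    mirna_hub_coupling: float = 0.25  # extra down-shift of signature miRNAs in hub-high samples
    target_coupling: float = 0.8      # gene response per unit of regulating-miRNA deviation
    seed: int = 0

    def validate(self) -> None:
        counts = [
            "n_mirnas", "n_genes", "n_cell_samples", "n_tumor_samples",
            "n_clinical_samples", "n_conserved_down", "n_cellline_only_down",
            "n_up", "n_hub_genes", "targets_per_mirna", "n_bystanders",
            "n_decoy_drug_genes",
        ]
        for name in counts:
            _require(int(getattr(self, name)) >= 0, f"{name}: must be >= 0")
        _require(
            self.n_conserved_down + self.n_cellline_only_down + self.n_up <= self.n_mirnas,
            "n_conserved_down: implanted miRNA roles exceed n_mirnas",
        )
        _require(self.n_hub_genes <= self.n_genes, "n_hub_genes: exceeds n_genes")
        per_mirna_pool = self.targets_per_mirna - 1 if self.n_hub_genes > 0 else self.targets_per_mirna
        n_nonhub_targets = self.n_conserved_down * max(per_mirna_pool, 0)
        _require(
            self.n_hub_genes + n_nonhub_targets + self.n_bystanders + self.n_decoy_drug_genes
            <= self.n_genes,
            "n_genes: too small for implanted hubs, targets, bystanders and decoys",
        )
        if self.n_hub_genes > 0 and self.n_conserved_down > 0:
            _require(self.targets_per_mirna >= 1,
                     "targets_per_mirna: must be >= 1 to place hub genes")
        for name in ("met_prob_hub_high", "met_prob_base", "censor_rate", "hub_high_frac"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, f"{name}: must lie in [0, 1]")
        _require(self.effect_log2fc > 0, "effect_log2fc: must be > 0")
        _require(self.noise_sd >= 0, "noise_sd: must be >= 0")
        _require(self.hazard_ratio_hub > 0, "hazard_ratio_hub: must be > 0")
        _require(self.baseline_median_months > 0, "baseline_median_months: must be > 0")
        _require(self.target_coupling >= 0, "target_coupling: must be >= 0")
        _require(self.mirna_hub_coupling >= 0, "mirna_hub_coupling: must be >= 0")

    def digest(self) -> str:
        """Stable hash of the configuration, used for consistency checks."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


DISCRETIZATIONS = ("upper_quartile", "median", "tertile")


@dataclass
class MiningConfig:
    """Association-rule mining parameters.

    ``discretization`` sets the per-gene "highly expressed" cut: strictly
    above the upper quartile (default), the median, or the upper tertile.
    ``survival_cutoff_months`` defines the short-survival item (an observed
    event earlier than the cutoff; 60 months = 5 years).
    """

    min_support: float = 0.10
    min_confidence: float = 0.50
    min_lift: float = 1.2
    max_itemset_size: int = 4
    discretization: str = "upper_quartile"
    survival_cutoff_months: float = 60.0
    top_n_rules: int = 50
    hub_fraction: float = 0.30

    def validate(self) -> None:
        for name in ("min_support", "min_confidence", "hub_fraction"):
            v = getattr(self, name)
            _require(0.0 < v <= 1.0, f"{name}: must lie in (0, 1]")
        _require(self.min_lift > 0, "min_lift: must be > 0")
        _require(self.max_itemset_size >= 2, "max_itemset_size: must be >= 2")
        _require(self.discretization in DISCRETIZATIONS,
                 f"discretization: must be one of {DISCRETIZATIONS}")
        _require(self.survival_cutoff_months > 0, "survival_cutoff_months: must be > 0")
        _require(self.top_n_rules >= 1, "top_n_rules: must be >= 1")


@dataclass
class DEConfig:
    """Differential-expression call thresholds (log2 fold change and FDR)."""

    fc_threshold: float = 1.0
    q_threshold: float = 0.05

    def validate(self) -> None:
        _require(self.fc_threshold >= 0, "fc_threshold: must be >= 0")
        _require(0.0 < self.q_threshold <= 1.0, "q_threshold: must lie in (0, 1]")


@dataclass
class TargetFilterConfig:
    """Thresholds for the up-regulated / anti-correlated target filter."""

    rho_threshold: float = -0.3
    q_threshold: float = 0.05

    def validate(self) -> None:
        _require(-1.0 <= self.rho_threshold <= 0.0,
                 "rho_threshold: must lie in [-1, 0]")
        _require(0.0 < self.q_threshold <= 1.0, "q_threshold: must lie in (0, 1]")


@dataclass
class PipelineConfig:
    """Everything a full run needs: sub-configs, seed and output directory."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    de: DEConfig = field(default_factory=DEConfig)
    targets: TargetFilterConfig = field(default_factory=TargetFilterConfig)
    mining: MiningConfig = field(default_factory=MiningConfig)
    outdir: str = "sarcomir_run"
    seed: int | None = None  # overrides synth.seed when set

    def validate(self) -> None:
        self.effective_synth().validate()
        self.de.validate()
        self.targets.validate()
        self.mining.validate()

    def effective_synth(self) -> SynthConfig:
        if self.seed is None:
            return self.synth
        return dataclasses.replace(self.synth, seed=int(self.seed))

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "synth": dataclasses.asdict(self.synth),
            "de": dataclasses.asdict(self.de),
            "targets": dataclasses.asdict(self.targets),
            "mining": dataclasses.asdict(self.mining),
            "outdir": self.outdir,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(klass, block):
            block = dict(block or {})
            valid = {f.name for f in dataclasses.fields(klass)}
            unknown = set(block) - valid
            if unknown:
                raise ConfigurationError(
                    f"{klass.__name__}: unknown fields {sorted(unknown)}")
            return klass(**block)

        return cls(
            synth=build(SynthConfig, raw.get("synth")),
            de=build(DEConfig, raw.get("de")),
            targets=build(TargetFilterConfig, raw.get("targets")),
            mining=build(MiningConfig, raw.get("mining")),
            outdir=raw.get("outdir", "sarcomir_run"),
            seed=raw.get("seed"),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        # outdir is a location, not content: runs of one configuration into
        # different directories must stay byte-identical
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]
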