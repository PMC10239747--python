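"""Core in-memory containers shared by all pipeline stages.

Expression data lives in a features x samples :class:`pandas.DataFrame` of
log2 values, wrapped together with an optional per-sample group label
(``"case"`` / ``"control"``).  Clinical follow-up is a per-sample table of
survival time in months, an event flag and a metastasis flag.  Differential
expression results are a per-feature table with a categorical direction call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

CASE = "case"
CONTROL = "control"

DIRECTION_DOWN = "down"
DIRECTION_UP = "up"
DIRECTION_UNCHANGED = "unchanged"


@dataclass
class ExpressionMatrix:
    """Log2 expression values (features x samples) with optional group labels.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample id.
    group
        Optional per-sample label aligned with ``values.columns``; the
        conventional labels are ``"case"`` and ``"control"``.
    """

    values: pd.DataFrame
    group: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ConfigurationError(f"duplicate feature ids: {list(dups)[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ConfigurationError(f"duplicate sample ids: {list(dups)[:5]}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ConfigurationError("values: expression matrix contains non-finite entries")
        if self.group is not None:
            self.group = self.group.reindex(self.values.columns)
            if self.group.isna().any():
                missing = self.group.index[self.group.isna()]
                raise ConfigurationError(f"group: labels missing for samples {list(missing)[:5]}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, label: str) -> list[str]:
        if self.group is None:
            raise ConfigurationError("group: matrix carries no group labels")
        return list(self.group.index[self.group == label])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        cols = [s for s in sample_ids if s in self.values.columns]
        grp = self.group.loc[cols] if self.group is not None else None
        return ExpressionMatrix(self.values.loc[:, cols], grp)


@dataclass
class ClinicalTable:
    """Per-sample follow-up: time (months), event flag, metastasis flag."""

    table: pd.DataFrame  # index: sample_id; columns: time_months, event, metastasis

    def __post_init__(self) -> None:
        required = {"time_months", "event", "metastasis"}
        missing = required - set(self.table.columns)
        if missing:
            raise ConfigurationError(f"clinical table missing columns: {sorted(missing)}")
        if (self.table["time_months"] < 0).any():
            raise ConfigurationError("time_months: negative survival time")
        for col in ("event", "metastasis"):
            if not self.table[col].isin([0, 1]).all():
                raise ConfigurationError(f"{col}: flags must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def subset(self, sample_ids) -> "ClinicalTable":
        keep = [s for s in sample_ids if s in self.table.index]
        return ClinicalTable(self.table.loc[keep])


@dataclass
class DESignature:
    """Per-feature differential expression result.

    ``table`` has columns ``log2fc`` (case mean minus control mean), ``p``
    (two-sided Welch p-value), ``q`` (Benjamini–Hochberg adjusted) and
    ``direction`` in {down, up, unchanged}.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"log2fc", "p", "q", "direction"}
        missing = required - set(self.table.columns)
        if missing:
            raise ConfigurationError(f"DE table missing columns: {sorted(missing)}")

    @property
    def down(self) -> set[str]:
        return set(self.table.index[self.table["direction"] == DIRECTION_DOWN])

    @property
    def up(self) -> set[str]:
        return set(self.table.index[self.table["direction"] == DIRECTION_UP])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class TargetMapTable:
    """miRNA -> target gene pairs; duplicates are collapsed on load."""

    pairs: pd.DataFrame  # columns: mirna_id, gene_id

    def __post_init__(self) -> None:
        required = {"mirna_id", "gene_id"}
        missing = required - set(self.pairs.columns)
        if missing:
            raise ConfigurationError(f"target map missing columns: {sorted(missing)}")
        self.pairs = (
            self.pairs.drop_duplicates(subset=["mirna_id", "gene_id"])
            .reset_index(drop=True)
        )

    def targets_of(self, mirna_id: str) -> set[str]:
        sub = self.pairs[self.pairs["mirna_id"] == mirna_id]
        return set(sub["gene_id"])

    def regulators_of(self, gene_id: str) -> set[str]:
        sub = self.pairs[self.pairs["gene_id"] == gene_id]
        return set(sub["mirna_id"])


@dataclass
class GeneDrugTable:
    """Gene -> drug association records; pairs unique after load.

    Drug identity is case-insensitive after whitespace normalization; the
    first-seen spelling is kept for display.
    """

    pairs: pd.DataFrame  # columns: gene_id, drug_name

    def __post_init__(self) -> None:
        required = {"gene_id", "drug_name"}
        missing = required - set(self.pairs.columns)
        if missing:
            raise ConfigurationError(f"gene-drug table missing columns: {sorted(missing)}")
        norm = self.pairs["drug_name"].map(normalize_drug_name)
        self.pairs = (
            self.pairs.assign(_norm=norm)
            .drop_duplicates(subset=["gene_id", "_norm"])
            .drop(columns="_norm")
            .reset_index(drop=True)
        )

    def drugs_of(self, gene_id: str) -> list[str]:
        sub = self.pairs[self.pairs["gene_id"] == gene_id]
        return sorted(set(sub["drug_name"]), key=normalize_drug_name)

    def annotated_genes(self) -> set[str]:
        return set(self.pairs["gene_id"])


def normalize_drug_name(name: str) -> str:
    """Whitespace-normalized, case-folded drug identity key."""
    return " ".join(str(name).split()).casefold()


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with optional descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)
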