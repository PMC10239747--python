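"""Plain-text readers and writers for every pipeline artifact.

Expression matrices are TSV with the feature id in the first column and one
column per sample; group labels travel in a companion two-column TSV.
Clinical tables, target maps, gene-drug tables and DE results are simple
headered TSVs; gene sets use the GMT convention (name, description, then
tab-separated gene ids).  Floats are serialized at fixed precision so
identical runs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import (
    ClinicalTable,
    DESignature,
    ExpressionMatrix,
    GeneDrugTable,
    GeneSetCollection,
    TargetMapTable,
)
from .exceptions import ParseError

FLOAT_FORMAT = "%.10g"


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except pd.errors.ParserError as exc:  # carries the offending line number
        raise ParseError(f"{path}: {exc}") from exc


def write_expression(mat: ExpressionMatrix, path, groups_path=None) -> None:
    out = mat.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)
    if groups_path is not None and mat.group is not None:
        grp = mat.group.rename("group").to_frame()
        grp.index.name = "sample_id"
        grp.to_csv(groups_path, sep="\t")


def read_expression(path, groups_path=None) -> ExpressionMatrix:
    values = _read_tsv(path, index_col=0)
    group = None
    if groups_path is not None and Path(groups_path).exists():
        grp = _read_tsv(groups_path, index_col=0)
        if "group" not in grp.columns:
            raise ParseError(f"{groups_path}: missing 'group' column")
        group = grp["group"]
    return ExpressionMatrix(values, group)


def write_clinical(clin: ClinicalTable, path) -> None:
    out = clin.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_clinical(path) -> ClinicalTable:
    return ClinicalTable(_read_tsv(path, index_col=0))


def write_de(sig: DESignature, path) -> None:
    out = sig.table.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_de(path) -> DESignature:
    return DESignature(_read_tsv(path, index_col=0))


def write_gene_list(genes, path, header: str = "gene_id") -> None:
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for g in sorted(genes):
            fh.write(str(g) + "\n")


def read_gene_list(path) -> list[str]:
    frame = _read_tsv(path)
    return list(frame.iloc[:, 0])


def write_target_map(tmap: TargetMapTable, path) -> None:
    tmap.pairs.to_csv(path, sep="\t", index=False)


def read_target_map(path) -> TargetMapTable:
    return TargetMapTable(_read_tsv(path))


def write_gene_drug(table: GeneDrugTable, path) -> None:
    table.pairs.to_csv(path, sep="\t", index=False)


def read_gene_drug(path) -> GeneDrugTable:
    return GeneDrugTable(_read_tsv(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description, genes")
            name, desc, genes = parts[0], parts[1], parts[2:]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene set '{name}'")
            sets[name] = {g for g in genes if g}
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_frame(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
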