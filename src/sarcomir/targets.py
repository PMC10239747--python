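"""Map the conserved down-miRNA signature to candidate target genes.

Candidates are the union of annotated targets of the signature miRNAs; they
are then filtered to genes that are (a) up-regulated in tumors vs nontumor
samples and (b) anti-correlated (Spearman) with at least one of their
regulating down-miRNAs across shared samples.  Hypergeometric
over-representation against a gene-set collection summarizes the biology of
the surviving candidates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import DEConfig, TargetFilterConfig
from .containers import (
    DESignature,
    ExpressionMatrix,
    GeneSetCollection,
    TargetMapTable,
)
from .diffexpr import compute_de
from .exceptions import InsufficientOverlapError, MembershipError


def candidate_targets(
    down_mirnas, tmap: TargetMapTable
) -> tuple[set[str], pd.Series]:
    """Union of annotated targets of the listed miRNAs, with node degree.

    Returns ``(genes, degree)`` where ``degree`` counts the distinct listed
    miRNAs regulating each gene (the gene's in-degree in the miRNA-target
    network restricted to the signature).
    """
    down_mirnas = set(down_mirnas)
    sub = tmap.pairs[tmap.pairs["mirna_id"].isin(down_mirnas)]
    degree = sub.groupby("gene_id")["mirna_id"].nunique().sort_index()
    degree.name = "n_regulating_mirnas"
    return set(degree.index), degree


def filter_upregulated_anticorrelated(
    genes,
    mirna_mat: ExpressionMatrix,
    gene_mat: ExpressionMatrix,
    tmap: TargetMapTable,
    down_mirnas,
    rho_threshold: float = -0.3,
    q_threshold: float = 0.05,
    de_config: DEConfig | None = None,
    gene_signature: DESignature | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Keep genes up-regulated in tumors and anti-correlated with a regulator.

    A gene survives iff it is called ``up`` by :func:`compute_de` on
    ``gene_mat`` (case = tumor) AND its Spearman correlation with at least
    one of its regulating down-miRNAs is ``<= rho_threshold`` with BH
    ``q <= q_threshold`` across the samples shared by both matrices.  The
    kept set is non-decreasing as ``rho_threshold`` rises toward 0.

    ``gene_signature`` may carry a precomputed DE result for ``gene_mat``.
    Returns ``(kept_genes, detail)`` where ``detail`` has one row per tested
    (gene, miRNA) pair with rho, p and q.
    """
    de_config = de_config or DEConfig()
    shared = [s for s in mirna_mat.sample_ids if s in set(gene_mat.sample_ids)]
    if len(shared) < 3:
        raise InsufficientOverlapError(
            f"only {len(shared)} samples shared between miRNA and gene matrices")

    if gene_signature is None:
        gene_signature = compute_de(gene_mat, de_config.fc_threshold, de_config.q_threshold)
    up_genes = gene_signature.up & set(genes)

    down_mirnas = set(down_mirnas) & set(mirna_mat.feature_ids)
    records = []
    gshared = gene_mat.values[shared]
    mshared = mirna_mat.values[shared]
    for gene in sorted(up_genes):
        if gene not in gene_mat.values.index:
            continue
        regs = sorted(tmap.regulators_of(gene) & down_mirnas)
        gvals = gshared.loc[gene].to_numpy(dtype=float)
        for mirna in regs:
            rho, p = stats.spearmanr(gvals, mshared.loc[mirna].to_numpy(dtype=float))
            if np.isnan(rho):
                rho, p = 0.0, 1.0
            records.append((gene, mirna, float(rho), float(p)))
    detail = pd.DataFrame(records, columns=["gene_id", "mirna_id", "rho", "p"])
    if len(detail):
        detail["q"] = multipletests(detail["p"].to_numpy(), method="fdr_bh")[1]
        hits = detail[(detail["rho"] <= rho_threshold) & (detail["q"] <= q_threshold)]
        kept = set(hits["gene_id"])
    else:
        detail["q"] = pd.Series(dtype=float)
        kept = set()
    return kept, detail


def hypergeom_enrichment(
    query, universe, collection: GeneSetCollection
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` per set.

    For each gene set S (intersected with the universe), the p-value is the
    probability of drawing at least ``|query & S|`` members of S in
    ``|query|`` draws without replacement from the universe; BH adjustment
    is applied across sets.  An empty overlap gives p = 1.
    """
    query = set(query)
    universe = set(universe)
    if not query <= universe:
        extra = sorted(query - universe)
        raise MembershipError(f"query genes outside universe: {extra[:5]}")
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & universe
        overlap = len(query & members)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(query)))
        rows.append((name, overlap, len(members), len(universe), len(query), p))
    result = pd.DataFrame(
        rows, columns=["set_name", "overlap", "set_size", "universe_size", "draw_size", "p"])
    if len(result):
        result["q"] = multipletests(result["p"].to_numpy(), method="fdr_bh")[1]
    else:
        result["q"] = pd.Series(dtype=float)
    return result
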