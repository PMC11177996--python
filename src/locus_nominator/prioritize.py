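"""Weighted evidence matrix and gene nomination at GWAS loci.

For every genomic feature within the sentinel's 1-Mb flanks a row of
boolean evidence categories is assembled (colocalization, shared QTL
locus, sentinel-is-QTL, gene-based significance, nearest gene, protein-
altering variant), weighted by a 50-point table, and summed.  Features
scoring at least the minimum (default 4) survive, and within a locus any
feature whose score falls 20% or more below the top score is pruned; the
survivors are the nominated genes.  A separate rule labels a gene
cell-type specific when its top expression fraction is at least 1.5x the
second highest.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .config import EvidenceWeights, GENOME_WIDE_P, GeneModel
from .datatypes import Locus

logger = logging.getLogger(__name__)

#: consequence strings counted as protein-altering (non-synonymous exonic)
PROTEIN_ALTERING = {
    "missense", "missense_variant", "nonsynonymous", "nonsynonymous_snv",
    "stop_gained", "stop_lost", "start_lost", "stopgain", "stoploss",
    "frameshift", "frameshift_variant", "inframe_insertion", "inframe_deletion",
}


def _pos_from_id(variant_id: str) -> int:
    m = re.match(r"chr[^:]*:(\d+):", variant_id)
    if not m:
        raise ValueError(f"cannot parse position from variant id {variant_id!r}")
    return int(m.group(1))


def nearest_gene(chrom, pos, gene_models: list[GeneModel]) -> str | None:
    """Gene with minimum distance to its body (0 if inside); ties broken by
    distance to TSS, then identifier order."""
    cands = [g for g in gene_models if str(g.chrom) == str(chrom)]
    if not cands:
        logger.warning("no genes on chromosome %s for nearest-gene lookup", chrom)
        return None

    def key(g: GeneModel):
        body = 0 if g.start <= pos <= g.end else min(abs(pos - g.start), abs(pos - g.end))
        return (body, abs(pos - g.tss), g.id)

    return min(cands, key=key).id


def build_evidence_matrix(
    locus: Locus,
    coloc_results: pd.DataFrame,
    qtl_evidence: pd.DataFrame,
    gene_results: pd.DataFrame,
    annotations: pd.DataFrame,
    gene_models: list[GeneModel],
) -> pd.DataFrame:
    """One boolean row per genomic feature overlapping the locus window.

    Inputs are the per-locus colocalization table (locus, gene, kind,
    pp_h4), the QTL evidence table (shared_locus / lead_is_qtl flags), the
    gene-based results (gene, significant), and a variant consequence table
    (chrom, pos, ref, alt, gene, consequence).
    """
    features = [
        g for g in gene_models
        if str(g.chrom) == locus.chrom and g.end >= locus.start and g.start <= locus.end
    ]
    if not features:
        logger.warning("locus %s: no genomic features in window", locus.lead_id)

    member_pos = [(_pos_from_id(v)) for v in locus.member_ids] or [locus.lead_pos]
    nearest = {
        nearest_gene(locus.chrom, p, gene_models) for p in member_pos
    }

    gws_keys = set()
    for vid in locus.member_ids or [locus.lead_id]:
        parts = vid.split(":")
        gws_keys.add((parts[0].removeprefix("chr"), int(parts[1]), parts[2], parts[3]))
    ann = annotations.copy()
    if not ann.empty:
        ann["_key"] = list(
            zip(ann["chrom"].astype(str).str.removeprefix("chr"), ann["pos"].astype(int),
                ann["ref"], ann["alt"])
        )
        ann = ann.loc[ann["_key"].isin(gws_keys)]
        ann = ann.loc[ann["consequence"].str.lower().isin(PROTEIN_ALTERING)]

    cl = coloc_results.loc[coloc_results["locus"] == locus.lead_id] if not coloc_results.empty else coloc_results
    qe = qtl_evidence.loc[qtl_evidence["locus"] == locus.lead_id] if not qtl_evidence.empty else qtl_evidence
    sig_genes = (
        set(gene_results.loc[gene_results["significant"], "gene"])
        if "significant" in gene_results else set()
    )

    def any_flag(df, gene, kind, col):
        if df is None or df.empty:
            return False
        sel = (df["gene"] == gene) & (df["kind"] == kind)
        return bool(df.loc[sel, col].any())

    rows = []
    for g in features:
        row = {
            "locus": locus.lead_id,
            "gene": g.id,
            "biotype": g.biotype,
            "coloc_pqtl": any_flag(cl, g.id, "pQTL", "colocalizes"),
            "coloc_eqtl": any_flag(cl, g.id, "eQTL", "colocalizes"),
            "lead_is_pqtl": any_flag(qe, g.id, "pQTL", "lead_is_qtl"),
            "lead_is_eqtl": any_flag(qe, g.id, "eQTL", "lead_is_qtl"),
            "shared_locus_pqtl": any_flag(qe, g.id, "pQTL", "shared_locus"),
            "shared_locus_eqtl": any_flag(qe, g.id, "eQTL", "shared_locus"),
            "genebased_significant": g.id in sig_genes,
            "nearest_gene": g.id in nearest,
            "protein_altering": bool((ann["gene"] == g.id).any()) if not ann.empty else False,
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=["locus", "gene", "biotype", *EvidenceWeights.CATEGORIES])


def score_genes(matrix: pd.DataFrame, weights: EvidenceWeights | None = None) -> pd.DataFrame:
    """Weighted row sums of the boolean matrix."""
    weights = weights or EvidenceWeights()
    out = matrix.copy()
    score = np.zeros(len(out))
    for cat in EvidenceWeights.CATEGORIES:
        score += out[cat].to_numpy(bool) * getattr(weights, cat)
    out["score"] = score
    out["n_categories"] = out[list(EvidenceWeights.CATEGORIES)].sum(axis=1).astype(int)
    return out


def nominate(scored: pd.DataFrame, weights: EvidenceWeights | None = None) -> pd.DataFrame:
    """Apply the minimum-score floor and the relative-difference pruning.

    Rows with score >= min_score survive the floor; among survivors, a row
    is pruned when (top - score)/top >= rel_diff (a gene exactly 20% below
    the top is excluded).  Survivors sort by score descending, ties broken
    by more evidence categories, then by identifier.
    """
    weights = weights or EvidenceWeights()
    if scored.empty:
        return scored.copy()
    passing = scored.loc[scored["score"] >= weights.min_score].copy()
    if passing.empty:
        return passing
    top = passing["score"].max()
    keep = (top - passing["score"]) / top < weights.rel_diff
    passing = passing.loc[keep]
    return passing.sort_values(
        ["score", "n_categories", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)


def celltype_specificity(fractions: dict[str, float], ratio: float = 1.5) -> str | None:
    """Top cell type iff its expression fraction is >= ratio x the second.

    ``fractions`` maps cell type to its share of the gene's summed
    expression; shares must be nonnegative and sum to 1.
    """
    if len(fractions) < 2:
        raise ValueError("cell-type specificity needs at least two cell types")
    vals = np.array(list(fractions.values()), dtype=float)
    if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-6:
        raise ValueError("fractions must be nonnegative and sum to 1")
    order = sorted(fractions.items(), key=lambda kv: -kv[1])
    (top_name, top), (_, second) = order[0], order[1]
    if second == 0:
        return top_name if top > 0 else None
    return top_name if top >= ratio * second else None
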