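"""Non-colocalization molecular-QTL evidence.

Two boolean queries per (locus, analyte): does the analyte have any
genome-wide significant QTL inside the locus window (a "shared locus"),
and is the sentinel variant itself a genome-wide significant QTL for the
analyte.  The cis window for an analyte is 1 Mb either side of the mapped
gene's strand-aware transcription start site.
"""

from __future__ import annotations

import logging

import pandas as pd

from .config import GENOME_WIDE_P, GeneModel
from .datatypes import Locus

logger = logging.getLogger(__name__)

CIS_WINDOW_BP = 1_000_000


def cis_window(gene: GeneModel) -> tuple[int, int]:
    """[TSS - 1 Mb, TSS + 1 Mb], clipped at position 1. TSS is gene start on
    the + strand and gene end on the - strand."""
    tss = gene.tss  # raises on missing/invalid strand
    return max(1, tss - CIS_WINDOW_BP), tss + CIS_WINDOW_BP


def shared_locus(locus: Locus, qtl: pd.DataFrame, qtl_gws: float = GENOME_WIDE_P) -> bool:
    """True iff any association of the analyte with P < qtl_gws lies within
    the sentinel's flanks (threshold is strict)."""
    hits = qtl.loc[
        (qtl["chrom"].astype(str) == locus.chrom)
        & qtl["pos"].between(locus.start, locus.end)
        & (qtl["p"] < qtl_gws)
    ]
    return not hits.empty


def lead_variant_is_qtl(
    locus: Locus, qtl: pd.DataFrame, qtl_gws: float = GENOME_WIDE_P
) -> tuple[bool, str]:
    """Whether the sentinel variant itself is a genome-wide significant QTL.

    Matching is by chrom:pos with allele harmonization (a ref/alt swap still
    matches).  Returns ``(flag, reason)`` where reason distinguishes an
    untested lead (absent from the QTL panel) from a true negative.
    """
    lead_chrom, lead_pos = locus.chrom, locus.lead_pos
    lead_ref, lead_alt = locus.lead_id.split(":")[-2:]
    cand = qtl.loc[(qtl["chrom"].astype(str) == lead_chrom) & (qtl["pos"] == lead_pos)]
    if cand.empty:
        logger.debug("lead %s untested in QTL panel", locus.lead_id)
        return False, "untested"
    same = (cand["ref"] == lead_ref) & (cand["alt"] == lead_alt)
    swap = (cand["ref"] == lead_alt) & (cand["alt"] == lead_ref)
    cand = cand.loc[same | swap]
    if cand.empty:
        return False, "allele_mismatch"
    if (cand["p"] < qtl_gws).any():
        return True, "significant"
    return False, "tested_not_significant"


def qtl_evidence_table(
    loci: list[Locus],
    qtl_datasets: list[pd.DataFrame],
    qtl_gws: float = GENOME_WIDE_P,
) -> pd.DataFrame:
    """Evidence rows {locus, gene, kind, tissue, shared_locus, lead_is_qtl}.

    Asserts the implication lead_is_qtl => shared_locus on every row (a
    significant lead inside its own window is itself a shared-locus hit).
    """
    rows = []
    for locus in loci:
        for qtl in qtl_datasets:
            if qtl.empty:
                continue
            first = qtl.iloc[0]
            shared = shared_locus(locus, qtl, qtl_gws)
            lead_flag, reason = lead_variant_is_qtl(locus, qtl, qtl_gws)
            assert not (lead_flag and not shared), "lead_is_qtl must imply shared_locus"
            rows.append(
                {
                    "locus": locus.lead_id,
                    "gene": first.get("gene_id", first["analyte_id"]),
                    "analyte_id": first["analyte_id"],
                    "kind": first.get("kind", "eQTL"),
                    "tissue": first["tissue"],
                    "shared_locus": shared,
                    "lead_is_qtl": lead_flag,
                    "lead_qtl_reason": reason,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "locus", "gene", "analyte_id", "kind", "tissue",
            "shared_locus", "lead_is_qtl", "lead_qtl_reason",
        ],
    )
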