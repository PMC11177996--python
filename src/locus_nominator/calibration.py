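"""Seeded simulation studies that exercise the pipeline end-to-end.

These are the package's own operating-characteristic checks: colocalization
posterior calibration under shared vs distinct causal variants, null GWAS
inflation, stepwise-conditional signal recovery, and evidence-matrix gene
nomination.  Effect sizes are fixed a priori to give essentially complete
single-variant power at the chosen sample sizes (e.g. a log-odds of 0.7 at
MAF 0.3 with 750 cases / 750 controls puts the expected Wald z near 8.8,
>99.9% power at the genome-wide threshold), so the replicate rates measure
the method, not the sample size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coloc import ColocPriors, coloc_abf, coloc_gwas_locus
from .config import (
    AncestrySpec,
    CausalVariant,
    GeneModel,
    LDBlock,
    QTLSpec,
    SimConfig,
)
from .datatypes import GenotypeMatrix
from .genebased import run_gene_based
from .gwas import define_loci, genomic_inflation, run_single_variant_gwas, stepwise_conditional
from .prioritize import build_evidence_matrix, nominate, score_genes
from .qtl import qtl_evidence_table
from .simulate import _ols_scan, simulate_genotypes, simulate_phenotypes


def coloc_replicate(seed: int, shared: bool, n: int = 2000, n_snps: int = 60):
    """One colocalization replicate: two quantitative traits, each driven by
    a strong single causal variant (0.35 trait-SD per allele) in an LD block,
    with the causal variant shared or distinct."""
    cfg = SimConfig(
        seed=seed,
        ancestries=[AncestrySpec("panel", n, 0)],
        n_variants=n_snps,
        ld_blocks=[LDBlock(n_snps, 0.7)],
        prevalence_target=0.5,
    )
    g = simulate_genotypes(cfg, "panel")
    d = g.dosage_float()
    rng = np.random.default_rng(seed + 1)
    causal_a = n_snps // 2
    causal_b = causal_a if shared else min(n_snps - 1, causal_a + n_snps // 3)
    trait_a = 0.35 * d[:, causal_a] + rng.standard_normal(n)
    trait_b = 0.35 * d[:, causal_b] + rng.standard_normal(n)
    beta_a, se_a, _ = _ols_scan(d, trait_a)
    beta_b, se_b, _ = _ols_scan(d, trait_b)
    return coloc_abf(
        g.variants.assign(beta=beta_a, se=se_a),
        g.variants.assign(beta=beta_b, se=se_b),
        ColocPriors(),
    )


def coloc_calibration(seed: int, n_reps: int = 200, n: int = 2000) -> dict:
    """Fractions of replicates reaching the decision criteria under shared
    and distinct causal variants."""
    shared_hits = sum(
        coloc_replicate(seed * 100_003 + i, shared=True, n=n).pp_h4 >= 0.8
        for i in range(n_reps)
    )
    distinct = [
        coloc_replicate(seed * 100_003 + 50_000 + i, shared=False, n=n)
        for i in range(n_reps)
    ]
    h3_wins = sum(r.pp_h3 > r.pp_h4 for r in distinct)
    return {
        "shared_pp_h4_rate": shared_hits / n_reps,
        "distinct_h3_rate": h3_wins / n_reps,
        "n_reps": n_reps,
    }


def null_gwas_study(seed: int, n: int = 5000, n_variants: int = 5000) -> dict:
    """Fully null case-control cohort: returns lambda-GC and the rejection
    count at alpha = 1e-3 over all converged variants."""
    cfg = SimConfig(
        seed=seed,
        ancestries=[AncestrySpec("null", n // 2, n - n // 2)],
        n_variants=n_variants,
        ld_blocks=[LDBlock(n_variants, 0.0)],
        prevalence_target=0.5,
    )
    g = simulate_genotypes(cfg, "null")
    ph = simulate_phenotypes(g, cfg, "null")
    ss = run_single_variant_gwas(g, ph)
    p = ss["p"].dropna()
    return {
        "lambda": genomic_inflation(p),
        "n_tests": int(len(p)),
        "n_rejected_1e3": int((p < 1e-3).sum()),
    }


def conditional_replicate(seed: int, causal: list[tuple[int, float]],
                          n_per_arm: int = 1500, n_snps: int = 40) -> int | None:
    """Number of independent signals recovered at one simulated locus, or
    None when no genome-wide locus emerged."""
    cfg = SimConfig(
        seed=seed,
        ancestries=[AncestrySpec("A", n_per_arm, n_per_arm)],
        n_variants=n_snps,
        ld_blocks=[LDBlock(n_snps, 0.0)],
        maf_range=(0.3, 0.4),
        causal_variants=[CausalVariant(i, {"A": b}) for i, b in causal],
        prevalence_target=0.5,
    )
    g = simulate_genotypes(cfg, "A")
    ph = simulate_phenotypes(g, cfg, "A")
    ss = run_single_variant_gwas(g, ph, covariate_names=[])
    loci = define_loci(ss)
    if not loci:
        return None
    return len(stepwise_conditional(loci[0], g, ph, covariate_names=[]))


def conditional_recovery(seed: int, n_reps: int = 100) -> dict:
    """Signal-count recovery rates for one strong causal variant (log-odds
    0.5) and for two unlinked strong causal variants in one window."""
    base = seed * 55_001
    one = [conditional_replicate(base + i, [(20, 0.5)]) for i in range(n_reps)]
    two = [conditional_replicate(base + 10_000 + i, [(5, 0.5), (30, 0.5)]) for i in range(n_reps)]
    return {
        "one_causal_rate": sum(r == 1 for r in one) / n_reps,
        "two_causal_rate": sum(r == 2 for r in two) / n_reps,
        "n_reps": n_reps,
    }


def nomination_replicate(seed: int, n_per_arm: int = 750, n_snps: int = 60):
    """One end-to-end prioritization replicate.

    A case-control cohort with one strong causal variant (log-odds 0.7, MAF
    0.25-0.35); the causal gene's eQTL shares that causal variant
    (0.8 SD/allele), while a decoy gene in the same window has no evidence
    of any kind.  Returns the set of nominated gene ids (empty when the
    locus itself failed to reach genome-wide significance).
    """
    causal_idx = n_snps // 2
    genes = [
        GeneModel("CAUSAL_GENE", "1", 1_000_000 + 10_000 * causal_idx - 30_000,
                  1_000_000 + 10_000 * causal_idx + 30_000, "+"),
        GeneModel("DECOY_GENE", "1", 1_050_000, 1_090_000, "-"),
    ]
    cfg = SimConfig(
        seed=seed,
        ancestries=[AncestrySpec("A", n_per_arm, n_per_arm)],
        n_variants=n_snps,
        ld_blocks=[LDBlock(n_snps, 0.4)],
        maf_range=(0.25, 0.35),
        causal_variants=[CausalVariant(causal_idx, {"A": 0.7})],
        prevalence_target=0.5,
        genes=genes,
        qtl_specs=[
            QTLSpec("CAUSAL_GENE", "cortex", "eQTL", causal_idx, 0.8,
                    shared_with_gwas=True, n_samples=n_per_arm),
        ],
    )
    from .simulate import simulate_qtl_dataset

    g = simulate_genotypes(cfg, "A")
    ph = simulate_phenotypes(g, cfg, "A")
    ss = run_single_variant_gwas(g, ph, covariate_names=[])
    loci = define_loci(ss)
    if not loci:
        return set(), genes
    locus = loci[0]
    qtl = simulate_qtl_dataset(g, cfg.qtl_specs[0], cfg, gene=genes[0])
    res = coloc_gwas_locus(locus, ss, qtl)
    coloc_df = pd.DataFrame(
        [{"locus": locus.lead_id, "gene": "CAUSAL_GENE", "kind": "eQTL",
          "pp_h4": res.pp_h4, "colocalizes": res.colocalizes}]
    )
    ev = qtl_evidence_table([locus], [qtl])
    gene_tab = run_gene_based(ss, genes, g, seed=seed)
    ann = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "gene", "consequence"])
    matrix = build_evidence_matrix(locus, coloc_df, ev, gene_tab, ann, genes)
    nom = nominate(score_genes(matrix))
    return set(nom["gene"]), genes


def nomination_recovery(seed: int, n_reps: int = 100) -> dict:
    base = seed * 77_003
    causal_hits, decoy_hits = 0, 0
    for i in range(n_reps):
        nominated, _ = nomination_replicate(base + i)
        causal_hits += "CAUSAL_GENE" in nominated
        decoy_hits += "DECOY_GENE" in nominated
    return {
        "causal_nomination_rate": causal_hits / n_reps,
        "decoy_nomination_rate": decoy_hits / n_reps,
        "n_reps": n_reps,
    }
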