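"""End-to-end orchestration: simulate -> qc -> gwas -> condition -> meta ->
coloc -> overlap -> gene test -> prioritize -> prs -> report.

Every stage reads the previous stage's tables, the global seed propagates
to every stochastic step, and a JSON manifest records per-stage counts so
a run is fully reproducible from its config.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as lio
from .coloc import coloc_gwas_locus
from .config import (
    ColocPriors,
    EvidenceWeights,
    GENOME_WIDE_P,
    PRSConfig,
    QCThresholds,
    SimConfig,
)
from .datatypes import Locus
from .genebased import run_gene_based
from .gwas import (
    apply_variant_qc,
    define_loci,
    genomic_inflation,
    run_single_variant_gwas,
    stepwise_conditional,
)
from .meta import run_trans_ancestry_meta
from .prioritize import build_evidence_matrix, nearest_gene, nominate, score_genes
from .prs import run_prs
from .qtl import qtl_evidence_table

logger = logging.getLogger(__name__)

STAGES = [
    "simulate", "qc", "gwas", "condition", "meta",
    "coloc", "overlap", "genetest", "prioritize", "prs", "report",
]


class DependencyError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    sim: SimConfig
    out_dir: str
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    qc: QCThresholds = field(default_factory=QCThresholds)
    coloc_priors: ColocPriors = field(default_factory=ColocPriors)
    weights: EvidenceWeights = field(default_factory=EvidenceWeights)
    prs: PRSConfig = field(default_factory=PRSConfig)
    p_threshold: float = GENOME_WIDE_P
    annotations: pd.DataFrame | None = None
    prs_base_stats: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        # downstream stages cannot run without their producers
        deps = {
            "qc": "simulate", "gwas": "qc", "condition": "gwas", "meta": "gwas",
            "coloc": "gwas", "overlap": "gwas", "genetest": "gwas",
            "prioritize": "gwas", "prs": "qc",
        }
        for stage, needs in deps.items():
            if stage in self.stages and needs not in self.stages:
                raise DependencyError(f"stage '{stage}' requires stage '{needs}'")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order and return the manifest."""
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {"seed": config.sim.seed, "stages": {}, "out_dir": config.out_dir}
    ctx: dict = {}

    for stage in STAGES:
        if stage not in config.stages:
            continue
        try:
            counts = _run_stage(stage, config, ctx)
        except Exception as err:
            manifest["stages"][stage] = {"status": "failed", "error": str(err)}
            _write_manifest(manifest, config.out_dir)
            raise RuntimeError(f"stage '{stage}' failed: {err}") from err
        manifest["stages"][stage] = {"status": "ok", **counts}
    _write_manifest(manifest, config.out_dir)
    return manifest


def _write_manifest(manifest: dict, out_dir: str) -> None:
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _run_stage(stage: str, config: PipelineConfig, ctx: dict) -> dict:
    sim = config.sim
    out = config.out_dir

    if stage == "simulate":
        from .simulate import simulate_study

        genotypes, phenotypes, qtls = simulate_study(sim)
        ctx.update(genotypes=genotypes, phenotypes=phenotypes, qtls=qtls)
        for label, g in genotypes.items():
            lio.write_vcf(g, os.path.join(out, f"genotypes_{label}.vcf"))
            lio.write_tsv(phenotypes[label], os.path.join(out, f"phenotypes_{label}.tsv"))
        for i, q in enumerate(qtls):
            lio.write_qtl_tsv(q, os.path.join(out, f"qtl_{i}.tsv"))
        lio.write_bed(sim.genes, os.path.join(out, "genes.bed"))
        lio.write_gff3(sim.genes, os.path.join(out, "genes.gff3"))
        return {
            "ancestries": list(genotypes),
            "n_variants": sim.n_variants,
            "n_qtl_datasets": len(qtls),
        }

    if stage == "qc":
        filtered, reports = {}, {}
        for label, g in ctx["genotypes"].items():
            fg, rep = apply_variant_qc(g, config.qc)
            filtered[label] = fg
            reports[label] = rep
        ctx["genotypes_qc"] = filtered
        with open(os.path.join(out, "qc_report.json"), "w") as fh:
            json.dump(reports, fh, indent=2)
        return {label: rep["n_removed_total"] for label, rep in reports.items()}

    if stage == "gwas":
        sumstats, lambdas = {}, {}
        for label, g in ctx["genotypes_qc"].items():
            ss = run_single_variant_gwas(g, ctx["phenotypes"][label], ancestry=label)
            sumstats[label] = ss
            ok = ss["p"].dropna()
            lambdas[label] = genomic_inflation(ok) if len(ok) else np.nan
            lio.write_tsv(ss, os.path.join(out, f"sumstats_{label}.tsv"))
        ctx["sumstats"] = sumstats
        ctx["lambdas"] = lambdas
        return {"lambda": lambdas}

    if stage == "meta":
        meta = run_trans_ancestry_meta(list(ctx["sumstats"].values()))
        ctx["meta"] = meta
        lio.write_tsv(meta, os.path.join(out, "meta.tsv"))
        loci = define_loci(meta, config.p_threshold)
        ctx["loci"] = loci
        _write_locus_table(loci, os.path.join(out, "loci.tsv"))
        return {"n_variants": len(meta), "n_loci": len(loci)}

    if stage == "condition":
        # per-ancestry conditional chains at that ancestry's own loci
        chains = {}
        for label, ss in ctx["sumstats"].items():
            for locus in define_loci(ss, config.p_threshold):
                chain = stepwise_conditional(
                    locus, ctx["genotypes_qc"][label], ctx["phenotypes"][label]
                )
                locus.independent_signals = chain
                chains[f"{label}:{locus.lead_id}"] = chain
        ctx["conditional"] = chains
        with open(os.path.join(out, "conditional.json"), "w") as fh:
            json.dump(chains, fh, indent=2)
        return {"n_loci_conditioned": len(chains)}

    if stage == "coloc":
        loci = ctx.get("loci") or _fallback_loci(ctx, config)
        anchor = next(iter(ctx["sumstats"].values()))
        rows = []
        for locus in loci:
            for q in ctx["qtls"]:
                res = coloc_gwas_locus(locus, anchor, q, config.coloc_priors)
                first = q.iloc[0]
                rows.append(
                    {
                        "locus": locus.lead_id,
                        "gene": first.get("gene_id", first["analyte_id"]),
                        "analyte_id": first["analyte_id"],
                        "kind": first.get("kind", "eQTL"),
                        "tissue": first["tissue"],
                        "n_snps": res.n_snps,
                        "pp_h0": res.pp_h0, "pp_h1": res.pp_h1, "pp_h2": res.pp_h2,
                        "pp_h3": res.pp_h3, "pp_h4": res.pp_h4,
                        "colocalizes": res.colocalizes,
                        "tested": res.tested,
                    }
                )
        coloc_df = pd.DataFrame(rows)
        ctx["coloc"] = coloc_df
        lio.write_tsv(coloc_df, os.path.join(out, "coloc.tsv"))
        return {"n_tests": len(coloc_df), "n_colocalized": int(coloc_df["colocalizes"].sum()) if len(coloc_df) else 0}

    if stage == "overlap":
        loci = ctx.get("loci") or _fallback_loci(ctx, config)
        ev = qtl_evidence_table(loci, ctx["qtls"], config.p_threshold)
        ctx["qtl_evidence"] = ev
        lio.write_tsv(ev, os.path.join(out, "qtl_evidence.tsv"))
        return {"n_rows": len(ev)}

    if stage == "genetest":
        anchor_label = next(iter(ctx["sumstats"]))
        genes = run_gene_based(
            ctx["sumstats"][anchor_label],
            sim.genes,
            ctx["genotypes_qc"][anchor_label],
            seed=sim.seed,
        )
        ctx["gene_results"] = genes
        lio.write_tsv(genes, os.path.join(out, "gene_based.tsv"))
        return {"n_genes_tested": len(genes)}

    if stage == "prioritize":
        loci = ctx.get("loci") or _fallback_loci(ctx, config)
        ann = config.annotations if config.annotations is not None else pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "gene", "consequence"]
        )
        matrices, nominations = [], []
        for locus in loci:
            matrix = build_evidence_matrix(
                locus,
                ctx.get("coloc", pd.DataFrame()),
                ctx.get("qtl_evidence", pd.DataFrame()),
                ctx.get("gene_results", pd.DataFrame()),
                ann,
                sim.genes,
            )
            scored = score_genes(matrix, config.weights)
            matrices.append(scored)
            nom = nominate(scored, config.weights)
            locus.nearest_gene = nearest_gene(locus.chrom, locus.lead_pos, sim.genes)
            nominations.append(nom)
        scored_all = pd.concat(matrices, ignore_index=True) if matrices else pd.DataFrame()
        nom_all = pd.concat(nominations, ignore_index=True) if nominations else pd.DataFrame()
        ctx["scored"] = scored_all
        ctx["nominated"] = nom_all
        lio.write_tsv(scored_all, os.path.join(out, "evidence_matrix.tsv"))
        lio.write_tsv(nom_all, os.path.join(out, "nominated_genes.tsv"))
        return {
            "n_loci": len(loci),
            "n_nominated": int(nom_all["gene"].nunique()) if len(nom_all) else 0,
        }

    if stage == "prs":
        label = next(iter(ctx["genotypes_qc"]))
        base = config.prs_base_stats
        if base is None and "sumstats" in ctx and len(ctx["sumstats"]) > 1:
            # no external base GWAS: use the last ancestry as base, first as target
            base_label = list(ctx["sumstats"])[-1]
            base = ctx["sumstats"][base_label].dropna(subset=["p"])
        if base is None:
            return {"skipped": "no base summary statistics available"}
        table = run_prs(
            ctx["genotypes_qc"][label], ctx["phenotypes"][label], base, config=config.prs
        )
        ctx["prs"] = table
        lio.write_tsv(table, os.path.join(out, "prs.tsv"))
        return {"n_thresholds": len(table)}

    if stage == "report":
        path = os.path.join(out, "report.md")
        write_report(ctx, config, path)
        return {"report": path}

    raise ValueError(f"unknown stage {stage!r}")


def _fallback_loci(ctx: dict, config: PipelineConfig) -> list[Locus]:
    anchor = next(iter(ctx["sumstats"].values()))
    loci = define_loci(anchor, config.p_threshold)
    ctx["loci"] = loci
    return loci


def _write_locus_table(loci: list[Locus], path: str) -> None:
    pd.DataFrame(
        [
            {
                "lead_id": l.lead_id, "chrom": l.chrom, "pos": l.lead_pos,
                "p": l.lead_p, "start": l.start, "end": l.end,
                "n_members": len(l.member_ids),
                "independent_signals": ",".join(l.independent_signals),
                "nearest_gene": l.nearest_gene or "",
            }
            for l in loci
        ]
    ).to_csv(path, sep="\t", index=False)


def write_report(ctx: dict, config: PipelineConfig, path: str) -> str:
    """Human-readable run summary: loci, nominations, PRS, QC and inflation."""
    lines = ["# Locus nomination run report", ""]
    lambdas = ctx.get("lambdas", {})
    if lambdas:
        lines.append("## Genomic inflation")
        for label, lam in lambdas.items():
            lines.append(f"- lambda({label}) = {lam:.3f}")
        lines.append("")
    loci = ctx.get("loci", [])
    lines.append(f"## Loci ({len(loci)})")
    if not loci:
        lines.append("No genome-wide significant loci.")
    for l in loci:
        lines.append(
            f"- {l.lead_id} (chr{l.chrom}:{l.start}-{l.end}), lead P = {l.lead_p:.3g}, "
            f"{len(l.member_ids)} member variants, "
            f"{len(l.independent_signals)} independent signal(s)"
        )
    lines.append("")
    nom = ctx.get("nominated")
    if nom is not None and len(nom):
        lines.append("## Nominated genes")
        for locus_id, grp in nom.groupby("locus"):
            lines.append(f"- Locus {locus_id}:")
            for _, r in grp.iterrows():
                cats = [c for c in EvidenceWeights.CATEGORIES if r[c]]
                lines.append(f"    - {r['gene']} (score {r['score']:.1f}; {', '.join(cats)})")
        lines.append("")
    elif "scored" in ctx:
        lines.append("## Nominated genes\nNone passed the score and pruning rules.\n")
    prs_tab = ctx.get("prs")
    if prs_tab is not None and len(prs_tab):
        lines.append("## PRS")
        for _, r in prs_tab.iterrows():
            lines.append(
                f"- P <= {r['threshold']:g}: {int(r['n_snps'])} SNPs, "
                f"Nagelkerke R^2 = {r['r2_nagelkerke']:.3f}, P = {r['p']:.3g}"
            )
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
    return path
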