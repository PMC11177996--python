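"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF with a GT field (read back through cyvcf2);
phenotypes/covariates, summary statistics, QTL datasets and evidence
tables are TSV; gene models are BED (0-based half-open) or GFF3 (1-based
closed).  All internal coordinates are 1-based closed - conversion
happens only at the parser boundary.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .config import GeneModel
from .datatypes import MISSING, QTL_COLUMNS, GenotypeMatrix

_GT_CODES = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(genotypes: GenotypeMatrix, path: str) -> None:
    chroms = genotypes.variants["chrom"].astype(str).unique()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        for j, rec in enumerate(genotypes.variants.itertuples(index=False)):
            gts = "\t".join(_GT_CODES[int(d)] for d in genotypes.dosages[:, j])
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.id}\t{rec.ref}\t{rec.alt}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, cols = [], []
    for var in vcf:
        alt = var.ALT[0] if var.ALT else "."
        vid = var.ID or f"chr{var.CHROM}:{var.POS}:{var.REF}:{alt}"
        rows.append(
            {"chrom": str(var.CHROM), "pos": var.POS, "ref": var.REF, "alt": alt, "id": vid}
        )
        # gt_types: 0=hom_ref, 1=het, 2=unknown, 3=hom_alt
        g = var.gt_types.copy()
        dos = np.where(g == 0, 0, np.where(g == 1, 1, np.where(g == 3, 2, MISSING)))
        cols.append(dos.astype(np.int8))
    variants = pd.DataFrame(rows)
    dosages = (
        np.column_stack(cols) if cols else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, variants, dosages)


def write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_qtl_tsv(qtl: pd.DataFrame, path: str) -> None:
    cols = QTL_COLUMNS + [c for c in ("id", "kind", "gene_id", "cis") if c in qtl.columns]
    qtl[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


def write_bed(genes: list[GeneModel], path: str) -> None:
    """BED6: 0-based half-open intervals."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.id}\t0\t{g.strand}\n")


def read_bed(path: str) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            genes.append(
                GeneModel(
                    id=f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}",
                    chrom=f[0],
                    start=int(f[1]) + 1,
                    end=int(f[2]),
                    strand=f[5] if len(f) > 5 else "+",
                )
            )
    return genes


def write_gff3(genes: list[GeneModel], path: str) -> None:
    """GFF3 gene features: 1-based closed intervals."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.id};biotype={g.biotype}"
            fh.write(
                f"{g.chrom}\tlocus_nominator\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            genes.append(
                GeneModel(
                    id=attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}"),
                    chrom=f[0],
                    start=int(f[3]),
                    end=int(f[4]),
                    strand=f[6] if f[6] in "+-" else "+",
                    biotype=attrs.get("biotype", "protein_coding"),
                )
            )
    return genes


def read_gene_models(path: str) -> list[GeneModel]:
    """Dispatch on extension: .bed or .gff/.gff3."""
    ext = os.path.splitext(path)[1].lower()
    if ext == ".bed":
        return read_bed(path)
    if ext in (".gff", ".gff3"):
        return read_gff3(path)
    raise ValueError(f"unrecognized gene-model format: {path}")
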