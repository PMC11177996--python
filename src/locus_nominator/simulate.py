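"""Synthetic multi-ancestry case-control study generator.

The generator produces every input the downstream pipeline consumes:
genotypes with block LD, case-control phenotypes obeying the early-onset
age partition (cases with onset <= 70 years, controls > 70 at last visit),
cohort/array structure, covariates, gene models and molecular-QTL summary
statistics whose causal variant is either shared with or distinct from the
GWAS causal variant.

Haplotype model
---------------
Each haplotype is drawn by thresholding a latent standard-normal vector:
within an LD block the latent field is AR(1) with parameter rho, and a
variant carries the alternate allele when its latent value falls below the
normal quantile of its target allele frequency.  This gives marginally
correct allele frequencies and monotonically decaying LD within blocks,
with independence across blocks — no recombination map is modeled.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import ConfigError, GeneModel, QTLSpec, SimConfig
from .datatypes import MISSING, QTL_COLUMNS, GenotypeMatrix, variant_id


class SimulationError(RuntimeError):
    """Raised when a requested simulation is degenerate (e.g. monomorphic causal)."""


# Alternate the ref/alt pair down the variant list so allele-harmonization
# code paths see a mix of non-ambiguous pairs.
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


def _ancestry_rng(config: SimConfig, ancestry_label: str, salt: str) -> np.random.Generator:
    """Independent, reproducible stream per (config seed, ancestry, purpose)."""
    ss = np.random.SeedSequence(
        [config.seed, zlib.crc32(ancestry_label.encode()), zlib.crc32(salt.encode())]
    )
    return np.random.default_rng(ss)


def variant_table(config: SimConfig) -> pd.DataFrame:
    """Variant records shared by every ancestry (positions strictly increasing)."""
    pos = config.pos_start + config.pos_step * np.arange(config.n_variants)
    ref, alt = zip(*(_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(config.n_variants)))
    df = pd.DataFrame(
        {"chrom": config.chrom, "pos": pos, "ref": ref, "alt": alt}
    )
    df["id"] = [variant_id(c, p, r, a) for c, p, r, a in zip(df.chrom, df.pos, df.ref, df.alt)]
    return df


def _variant_mafs(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.maf_range
    return rng.uniform(lo, hi, size=config.n_variants)


def _draw_haplotypes(
    n_hap: int, mafs: np.ndarray, blocks, rng: np.random.Generator
) -> np.ndarray:
    """Threshold a blockwise-AR(1) latent Gaussian field at the MAF quantile."""
    n_var = len(mafs)
    latent = np.empty((n_hap, n_var))
    start = 0
    for block in blocks:
        m = block.n_snps
        rho = block.rho
        e = rng.standard_normal((n_hap, m))
        z = np.empty_like(e)
        z[:, 0] = e[:, 0]
        scale = np.sqrt(1.0 - rho**2)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + scale * e[:, j]
        latent[:, start : start + m] = z
        start += m
    thresholds = stats.norm.ppf(mafs)
    return (latent < thresholds).astype(np.int8)


def simulate_genotypes(config: SimConfig, ancestry_label: str) -> GenotypeMatrix:
    """Two thresholded-Gaussian haplotypes per individual; dosage is their sum.

    Deterministic given (seed, ancestry); each ancestry draws its own MAFs
    and haplotypes from an independent stream, so allele frequencies differ
    across ancestries as they do in real cohorts.
    """
    spec = config.ancestry(ancestry_label)
    rng = _ancestry_rng(config, ancestry_label, "genotypes")
    mafs = _variant_mafs(config, rng)
    n = spec.n
    hap1 = _draw_haplotypes(n, mafs, config.ld_blocks, rng)
    hap2 = _draw_haplotypes(n, mafs, config.ld_blocks, rng)
    dosages = (hap1 + hap2).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(dosages.shape) < config.missing_rate
        dosages[miss] = MISSING
    samples = [f"{ancestry_label}_S{i:05d}" for i in range(n)]
    return GenotypeMatrix(samples, variant_table(config), dosages)


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept such that mean logistic(intercept + eta) == target."""

    def gap(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + eta)))) - target)

    lo, hi = -40.0, 40.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ConfigError(f"prevalence_target {target} unattainable for the given effects")
    return optimize.brentq(gap, lo, hi, xtol=1e-10)


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimConfig, ancestry_label: str
) -> pd.DataFrame:
    """Case-control status from a logistic model plus covariates and ages.

    Case probability is logistic(intercept + sum(beta * dosage) + covariate
    effects); the intercept is solved numerically so the expected case
    fraction matches ``prevalence_target``.  Ages obey the study's defining
    partition: cases are assigned an onset age uniform on [40, 70] years,
    controls an age at last visit uniform on (70, 95].
    """
    spec = config.ancestry(ancestry_label)
    n = genotypes.n_samples
    rng = _ancestry_rng(config, ancestry_label, "phenotypes")

    sex = rng.integers(1, 3, size=n)  # 1 or 2
    pcs = rng.standard_normal((n, 10))

    fractions = np.array([c.fraction for c in config.cohorts])
    cohort_idx = rng.choice(len(config.cohorts), size=n, p=fractions)
    cohort = np.array([config.cohorts[i].label for i in cohort_idx])
    array = np.array([config.cohorts[i].array_label for i in cohort_idx])

    dos = genotypes.dosage_float()
    eta = np.zeros(n)
    for cv in config.causal_variants:
        beta = cv.beta_per_ancestry.get(ancestry_label, 0.0)
        eta += beta * dos[:, cv.variant_index]
    eff = config.covariate_effects
    eta += eff.get("sex", 0.0) * (sex - 1)
    eta += eff.get("array", 0.0) * cohort_idx
    eta += eff.get("pc", 0.0) * pcs[:, 0]

    intercept = _solve_intercept(eta, config.prevalence_target)
    p_case = 1.0 / (1.0 + np.exp(-(intercept + eta)))
    status = (rng.random(n) < p_case).astype(int)

    age = np.where(
        status == 1,
        rng.uniform(40.0, 70.0, size=n),
        rng.uniform(70.0, 95.0, size=n) + 1e-9,  # strictly > 70
    )

    df = pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "status": status,
            "age": np.round(age, 1).clip(min=None, max=95.0),
            "sex": sex,
            "cohort": cohort,
            "array": array,
        }
    )
    # rounding must not break the partition
    df.loc[df.status == 1, "age"] = df.loc[df.status == 1, "age"].clip(upper=70.0)
    df.loc[df.status == 0, "age"] = df.loc[df.status == 0, "age"].clip(lower=70.1)
    for k in range(10):
        df[f"pc{k + 1}"] = pcs[:, k]
    return df


def simulate_qtl_dataset(
    genotypes: GenotypeMatrix, spec: QTLSpec, config: SimConfig, gene: GeneModel | None = None
) -> pd.DataFrame:
    """Molecular-trait summary statistics from a single-causal-variant model.

    The analyte level is ``effect * dosage(causal) + N(0,1)`` noise in a
    subsample of ``spec.n_samples`` individuals; per-variant marginal
    statistics come from ordinary least squares of trait on dosage.
    """
    rng = _ancestry_rng(config, spec.analyte_id, "qtl")
    n_avail = genotypes.n_samples
    n = min(spec.n_samples, n_avail)
    take = rng.choice(n_avail, size=n, replace=False) if n < n_avail else np.arange(n_avail)
    dos = genotypes.dosage_float()[take]

    causal = dos[:, spec.causal_variant_index]
    if np.std(causal) == 0:
        raise SimulationError(
            f"causal variant index {spec.causal_variant_index} is monomorphic in this panel"
        )
    trait = spec.effect_sd_units * causal + rng.standard_normal(n)

    beta, se, p = _ols_scan(dos, trait)
    out = genotypes.variants.copy()
    out.insert(0, "tissue", spec.tissue)
    out.insert(0, "analyte_id", spec.analyte_id)
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["n"] = n
    out["kind"] = spec.analyte_kind
    out["gene_id"] = spec.gene_id
    if gene is not None:
        out["cis"] = (out["chrom"].astype(str) == str(gene.chrom)) & (
            (out["pos"] - gene.tss).abs() <= 1_000_000
        )
    return out[QTL_COLUMNS + ["id", "kind", "gene_id"] + (["cis"] if gene is not None else [])]


def _ols_scan(dosages: np.ndarray, trait: np.ndarray):
    """Vectorized simple-regression (with intercept) scan of trait on each variant."""
    n = len(trait)
    x = dosages - dosages.mean(axis=0)
    y = trait - trait.mean()
    sxx = (x**2).sum(axis=0)
    sxy = (x * y[:, None]).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = (y**2).sum() - beta * sxy
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    mono = sxx == 0
    beta[mono], se[mono], p[mono] = 0.0, np.inf, 1.0
    return beta, se, np.clip(p, np.nextafter(0, 1), 1.0)


def simulate_study(config: SimConfig):
    """Generate the whole study: per-ancestry genotypes/phenotypes plus QTL tables.

    Returns ``(genotypes, phenotypes, qtl_datasets)`` where the first two are
    dicts keyed by ancestry label and the third is a list of QTL DataFrames
    (simulated in the first ancestry's genotype panel).
    """
    genotypes = {a.label: simulate_genotypes(config, a.label) for a in config.ancestries}
    phenotypes = {
        a.label: simulate_phenotypes(genotypes[a.label], config, a.label)
        for a in config.ancestries
    }
    panel = genotypes[config.ancestries[0].label]
    genes = {g.id: g for g in config.genes}
    qtls = [
        simulate_qtl_dataset(panel, q, config, gene=genes.get(q.gene_id))
        for q in config.qtl_specs
    ]
    return genotypes, phenotypes, qtls
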