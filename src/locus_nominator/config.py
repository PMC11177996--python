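"""Configuration objects for every pipeline stage.

All thresholds that drive scientific decisions (genome-wide significance,
locus flank size, colocalization posterior cutoff, nomination score floor,
relative-difference pruning, cell-type ratio, minor-allele-count floor)
live here as named defaults so a run is fully described by one config file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

GENOME_WIDE_P = 5e-8
LOCUS_FLANK_BP = 1_000_000


class ConfigError(ValueError):
    """Raised when a configuration value violates its documented domain."""


# ---------------------------------------------------------------------------
# Synthetic-study description
# ---------------------------------------------------------------------------


@dataclass
class AncestrySpec:
    label: str
    n_cases: int
    n_controls: int

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls


@dataclass
class LDBlock:
    """A run of adjacent variants whose latent haplotype field is AR(1)."""

    n_snps: int
    rho: float


@dataclass
class CausalVariant:
    variant_index: int
    beta_per_ancestry: dict[str, float]


@dataclass
class CohortSpec:
    label: str
    array_label: str
    fraction: float


@dataclass
class GeneModel:
    """A genomic feature (gene, lncRNA, pseudogene) with a strand-aware TSS."""

    id: str
    chrom: str
    start: int  # 1-based closed
    end: int
    strand: str = "+"
    biotype: str = "protein_coding"

    @property
    def tss(self) -> int:
        if self.strand == "+":
            return self.start
        if self.strand == "-":
            return self.end
        raise ConfigError(f"gene {self.id}: strand must be '+' or '-', got {self.strand!r}")


@dataclass
class QTLSpec:
    gene_id: str
    tissue: str
    analyte_kind: str  # eQTL | pQTL | metabQTL
    causal_variant_index: int
    effect_sd_units: float
    shared_with_gwas: bool = False
    analyte_id: Optional[str] = None
    n_samples: int = 1000

    def __post_init__(self) -> None:
        if self.analyte_kind not in ("eQTL", "pQTL", "metabQTL"):
            raise ConfigError(f"analyte_kind must be eQTL/pQTL/metabQTL, got {self.analyte_kind!r}")
        if self.analyte_id is None:
            self.analyte_id = f"{self.gene_id}_{self.analyte_kind}"


@dataclass
class SimConfig:
    """Full generative description of a synthetic multi-ancestry study."""

    seed: int
    ancestries: list[AncestrySpec]
    n_variants: int
    ld_blocks: list[LDBlock]
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_variants: list[CausalVariant] = field(default_factory=list)
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"sex": 0.0, "array": 0.0, "pc": 0.0}
    )
    prevalence_target: float = 0.5
    cohorts: list[CohortSpec] = field(
        default_factory=lambda: [CohortSpec("cohort1", "array1", 1.0)]
    )
    genes: list[GeneModel] = field(default_factory=list)
    qtl_specs: list[QTLSpec] = field(default_factory=list)
    chrom: str = "1"
    pos_start: int = 1_000_000
    pos_step: int = 10_000
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if sum(b.n_snps for b in self.ld_blocks) != self.n_variants:
            raise ConfigError(
                "ld_blocks: block sizes sum to "
                f"{sum(b.n_snps for b in self.ld_blocks)}, expected n_variants={self.n_variants}"
            )
        for b in self.ld_blocks:
            if not (0.0 <= b.rho < 1.0):
                raise ConfigError(f"ld_blocks: rho must be in [0,1), got {b.rho}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must satisfy 0 < min <= max <= 0.5, got {self.maf_range}")
        for cv in self.causal_variants:
            if not (0 <= cv.variant_index < self.n_variants):
                raise ConfigError(f"causal variant_index {cv.variant_index} out of range")
        for q in self.qtl_specs:
            if not (0 <= q.causal_variant_index < self.n_variants):
                raise ConfigError(f"qtl causal_variant_index {q.causal_variant_index} out of range")
        if not (0.0 < self.prevalence_target < 1.0):
            raise ConfigError(f"prevalence_target must be in (0,1), got {self.prevalence_target}")
        total = sum(c.fraction for c in self.cohorts)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"cohort fractions must sum to 1, got {total}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError(f"missing_rate must be in [0,1), got {self.missing_rate}")

    def ancestry(self, label: str) -> AncestrySpec:
        for a in self.ancestries:
            if a.label == label:
                return a
        raise ConfigError(f"unknown ancestry label {label!r}")


# ---------------------------------------------------------------------------
# Analysis-stage parameters
# ---------------------------------------------------------------------------


@dataclass
class QCThresholds:
    """Variant/sample QC filters.

    ``hwe_p_min`` is the QC-stage Hardy-Weinberg floor; ``hwe_p_strict`` is
    the much looser floor re-applied at analysis time to merged multi-cohort
    data, where mild stratification inflates the exact test.
    The MAF floor is never set directly: it is derived from the
    minor-allele-count floor as mac_min / (2 * n_samples).
    """

    variant_call_rate_min: float = 0.90
    sample_call_rate_min: float = 0.98
    hwe_p_min: float = 1e-6
    hwe_p_strict: float = 1e-30
    mac_min: int = 5

    def __post_init__(self) -> None:
        for name in ("variant_call_rate_min", "sample_call_rate_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.mac_min < 0:
            raise ConfigError(f"mac_min must be >= 0, got {self.mac_min}")

    def maf_min(self, n_samples: int) -> float:
        return self.mac_min / (2 * n_samples)


@dataclass
class ColocPriors:
    """Per-SNP causal priors and effect-size prior SDs for ABF colocalization."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    prior_sd_quant: float = 0.15
    prior_sd_cc: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.p12 <= min(self.p1, self.p2) < 1.0):
            raise ConfigError(
                f"priors must satisfy 0 < p12 <= min(p1, p2) < 1; got "
                f"p1={self.p1}, p2={self.p2}, p12={self.p12}"
            )
        if self.prior_sd_quant <= 0 or self.prior_sd_cc <= 0:
            raise ConfigError("prior SDs must be positive")


@dataclass
class EvidenceWeights:
    """Weight table for the 50-point presence/absence evidence matrix.

    The default weights are a reconstruction: they honor the published
    constraints (total of 50 points; a single colocalization suffices to
    clear the minimum score of 4) but the exact published table is not
    available, so every weight is overridable in config.
    """

    coloc_pqtl: float = 10.0
    coloc_eqtl: float = 10.0
    lead_is_pqtl: float = 6.0
    lead_is_eqtl: float = 6.0
    shared_locus_pqtl: float = 4.0
    shared_locus_eqtl: float = 4.0
    genebased_significant: float = 4.0
    nearest_gene: float = 4.0
    protein_altering: float = 2.0
    max_total: float = 50.0
    min_score: float = 4.0
    rel_diff: float = 0.20

    CATEGORIES = (
        "coloc_pqtl",
        "coloc_eqtl",
        "lead_is_pqtl",
        "lead_is_eqtl",
        "shared_locus_pqtl",
        "shared_locus_eqtl",
        "genebased_significant",
        "nearest_gene",
        "protein_altering",
    )

    def __post_init__(self) -> None:
        for c in self.CATEGORIES:
            if getattr(self, c) < 0:
                raise ConfigError(f"weight {c} must be >= 0")
        if self.total() > self.max_total + 1e-9:
            raise ConfigError(f"weights sum to {self.total()}, exceeding max_total={self.max_total}")
        if self.min_score <= 0:
            raise ConfigError("min_score must be > 0")
        if not (0.0 < self.rel_diff < 1.0):
            raise ConfigError(f"rel_diff must be in (0,1), got {self.rel_diff}")

    def total(self) -> float:
        return sum(getattr(self, c) for c in self.CATEGORIES)

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in self.CATEGORIES}


@dataclass
class PRSConfig:
    """Clumping + thresholding PRS parameters, including the APOE region."""

    p_thresholds: tuple[float, ...] = (5e-8, 5e-5, 5e-2, 5e-1)
    clump_p: float = 1.0
    clump_r2: float = 0.1
    clump_kb: float = 250.0
    apoe_chrom: str = "19"
    apoe_start: int = 44_000_009
    apoe_end: int = 47_999_435
    include_apoe: bool = False

    def __post_init__(self) -> None:
        self.p_thresholds = tuple(sorted(self.p_thresholds))
        if not (0.0 < self.clump_r2 <= 1.0):
            raise ConfigError(f"clump_r2 must be in (0,1], got {self.clump_r2}")
        if self.clump_kb <= 0:
            raise ConfigError(f"clump_kb must be > 0, got {self.clump_kb}")


# ---------------------------------------------------------------------------
# YAML round-trip for SimConfig (the `simulate --config` file format)
# ---------------------------------------------------------------------------


def sim_config_to_yaml(config: SimConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def sim_config_from_yaml(path: str) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return sim_config_from_dict(raw)


def sim_config_from_dict(raw: dict) -> SimConfig:
    raw = dict(raw)
    raw["ancestries"] = [AncestrySpec(**a) for a in raw["ancestries"]]
    raw["ld_blocks"] = [LDBlock(**b) for b in raw["ld_blocks"]]
    raw["maf_range"] = tuple(raw.get("maf_range", (0.05, 0.5)))
    raw["causal_variants"] = [CausalVariant(**c) for c in raw.get("causal_variants", [])]
    raw["cohorts"] = [CohortSpec(**c) for c in raw.get("cohorts", [{"label": "cohort1", "array_label": "array1", "fraction": 1.0}])]
    raw["genes"] = [GeneModel(**g) for g in raw.get("genes", [])]
    raw["qtl_specs"] = [QTLSpec(**q) for q in raw.get("qtl_specs", [])]
    return SimConfig(**raw)
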