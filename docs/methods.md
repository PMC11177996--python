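# Methods

## Study design being modeled

The pipeline targets the downstream half of a multi-ancestry case-control
GWAS of early-onset Alzheimer disease. Case status is age-anchored: cases
have an age at onset of 70 years or younger, controls are cognitively
healthy and older than 70 at last visit. Because the phenotype definition
is itself an age partition, age is never used as a covariate anywhere in
the pipeline. Each ancestry is analyzed separately with its own QC and
association scan, then combined by meta-analysis; all locus-level
evidence (colocalization, QTL overlap, gene-based tests, annotation) is
folded into one weighted matrix per locus that nominates likely
functional genes.

## Synthetic data generator

**What it emulates.** Multi-ancestry case-control cohorts with block LD,
cohort/array substructure, the case ≤ 70 / control > 70 age rule, and
molecular QTL datasets (eQTL/pQTL/metabQTL) whose causal variant either
coincides with a GWAS causal variant or not.

**Haplotype model.** Each haplotype is a thresholded latent Gaussian:
within an LD block the latent field is AR(1) with parameter ρ ∈ [0,1),
and variant *j* carries the alternate allele when its latent value falls
below Φ⁻¹(MAF_j). Marginal allele frequencies are exact by construction
and LD decays monotonically with distance inside a block. Note that the
genotype-scale r² is substantially attenuated relative to the latent ρ
(ρ = 0.95 at MAF 0.3 gives genotype r² ≈ 0.58), so tests that need a
target genotype correlation should measure it rather than assume ρ². No
recombination map, phasing realism, admixture or sex chromosomes are
modeled; each ancestry draws its own MAFs and haplotypes from an
independent, seed-derived stream.

**Phenotypes.** Case probability is logistic(β₀ + Σβ·dosage + covariate
effects); β₀ is solved by root-finding so the expected case fraction
matches the configured prevalence target. Ages are uniform on [40, 70]
for cases and (70, 95] for controls — the paper-level constraint is only
the ≤ 70 / > 70 partition, so these distributions are conventions, chosen
once and documented, with no downstream effect beyond the partition.

**QTL datasets.** Analyte level = effect·dosage(causal) + N(0, 1) noise
in a subsample of the genotype panel; per-variant summary statistics are
marginal OLS fits. A dataset is labeled cis when the causal variant lies
within 1 Mb of the mapped gene's TSS.

**What passing tests do not show.** The generator has a single causal
variant per signal, Gaussian trait noise, no genotyping batch effects,
no population stratification beyond the configured covariate effects,
and exact logistic phenotypes. Calibration and recovery rates measured on
it demonstrate correctness of the statistical machinery under its own
assumptions, not robustness to real-data pathologies (imputation error,
cryptic relatedness, phenotype misclassification).

## Variant QC

Genotyping-rate filter (default ≥ 0.90 per variant, ≥ 0.98 per sample),
exact conditional Hardy–Weinberg test, and a minor-allele-count floor
(default MAC ≥ 5). The MAF floor is always derived as `mac_min / (2n)`
from the actual sample count rather than configured directly, which keeps
per-dataset cutoffs self-consistent. The HWE test is the exact
conditional test (enumeration over heterozygote counts given allele
counts, summing all outcomes no more probable than the observed one),
chosen over the χ² approximation for small-count robustness; a much
looser strict floor (1×10⁻³⁰) is available for re-filtering merged
multi-cohort data where mild stratification inflates the statistic.

## Association scan

Per-variant logistic regression (status ~ dosage + sex + array + 10 PCs)
by damped Newton/IRLS, warm-started at the covariate-only optimum so a
scan typically needs 3–5 iterations per variant. The array covariate is
dropped automatically when single-valued; collinear covariate columns are
dropped with a logged warning. Missing dosages are mean-imputed within
variant. Monomorphic or non-converging (quasi-separated) variants are
retained in the output with NA statistics and a reason code so downstream
joins stay aligned. The engine is checked against `statsmodels.Logit` to
|Δβ| < 10⁻⁵ in the test suite. λ-GC is `median(χ²₁)/0.4549`.

## Loci and conditional analysis

Greedy sentinel picking: the most significant remaining genome-wide
variant (P < 5×10⁻⁸) seeds a locus with 1-Mb flanks and absorbs every
genome-wide variant in its window. Overlapping flanks of distinct leads
are allowed; leads themselves are always > 1 Mb apart or on different
chromosomes. Stepwise conditioning adds the current lead's dosage as a
covariate and refits every variant in the window, stopping when the
minimum conditional P rises to ≥ 5×10⁻⁸ or a new lead is collinear with
the existing conditioning set (covariate PCs are held fixed across
steps). Cohort heterogeneity per variant is Cochran's Q with the flag
raised strictly below het P = 0.05.

## Meta-analysis

Inverse-variance fixed effects and DerSimonian–Laird random effects
(τ² = max(0, (Q − df)/C), C = Σw − Σw²/Σw) with I² reported; when
Q ≤ df the two coincide. Both P values are emitted; the headline column
is random-effects. Variants are harmonized across ancestries by
chrom:pos with sign flips for ref/alt swaps; strand-ambiguous (A/T, C/G)
mismatches are dropped with a logged count. Variants present in only
some ancestries meta-analyze over those (k < 3). `se_from_beta_p`
recovers a standard error from a published (β, P) pair through the
normal quantile, enabling re-combination of printed tables; recovering
an SE from rounded inputs carries the rounding into the combined P, so
worked-example agreement is checked on the log₁₀ scale with a 0.2 band.

## Colocalization

Wakefield's approximate Bayes factor per variant,
`log ABF = ½ log(1−r) + (z²/2) r` with `r = W/(V+W)`, V the squared SE
and W the squared prior effect SD (0.2 for case-control log-odds, 0.15
for quantitative traits). Hypothesis weights follow the standard
single-causal-variant configuration sums with per-SNP priors p₁ = p₂ =
10⁻⁴ and p₁₂ = 10⁻⁵ (the upstream method's defaults — the source study
names the method without parameter overrides; all are configurable).
Everything is accumulated in log space with log-sum-exp, so |z| in the
hundreds cannot overflow; the H3 term is the log-difference of the full
product and the diagonal. A region colocalizes when PP.H4 ≥ 0.8. Zero
overlapping variants yields an explicit "not tested" result distinct
from H0; fewer than 25 overlapping variants flags the result
low-confidence (posteriors on tiny windows are unstable) without
suppressing it.

## Gene-based test

SNP z-scores within a gene (window 0 bp by default) are collapsed to the
mean χ². Under the null z ~ MVN(0, R) with R the in-sample dosage
correlation (10⁻⁶ diagonal jitter), the statistic is a weighted sum of
1-df χ² variables with weights the eigenvalues of R. With identity R the
closed-form χ²_m tail is used; otherwise Satterthwaite moment-matching
(g·χ²_h matched on mean and variance) by default, or seeded Monte-Carlo
on request; the method used is recorded per gene. The family-wise cutoff
is 0.05 divided by the number of genes actually tested.

## Prioritization

Per locus, every genomic feature (genes, lncRNA, pseudogenes — no
biotype filtering) whose body overlaps the sentinel ± 1 Mb gets a row of
nine boolean categories: eQTL and pQTL colocalization (PP.H4 ≥ 0.8),
shared locus, sentinel-is-QTL, gene-based significance, nearest gene to
at least one genome-wide significant locus member, and a protein-altering
(non-synonymous exonic) genome-wide significant variant in the feature.
Consequence calls are consumed from an input table; prediction itself is
out of scope. Default weights (reconstructed, config-overridable):
colocalization 10 each, sentinel-is-QTL 6 each, shared locus 4 each,
gene-based 4, nearest gene 4, protein-altering 2 — total 50, and any
single colocalization clears the minimum score of 4, matching the design
constraint that colocalization evidence alone suffices. Nomination keeps
scores ≥ 4 and prunes rows whose relative deficit to the locus top score
is ≥ 20% (a gene exactly 20% below the top is excluded); ties break by
more evidence categories, then identifier. Nearest-gene assignment is
distance to the gene body (0 inside), ties by TSS distance, then
identifier — a single gene per variant. Cell-type specificity assigns
the top expression fraction's cell type iff it is ≥ 1.5× the second.

## PRS

Greedy clumping by ascending base P: a variant is kept iff no
already-kept variant within 250 kb (distance from the index variant) has
r² > 0.1 with it in the LD panel; base variants absent from the panel
pass through with a logged count. The APOE region
(chr19:44,000,009–47,999,435, boundary-inclusive) is excluded unless
requested. Scores are Σβ·dosage over clumped variants at each base-P
threshold (5×10⁻⁸, 5×10⁻⁵, 5×10⁻², 5×10⁻¹); missing dosages contribute
2·AF·β. Fit quality is Nagelkerke R² (reported with Cox–Snell) from a
covariate-free logistic regression, matching the external tooling
convention for binary targets; complete separation is detected exactly
(the score orders all cases above all controls) and reported as R² = 1
with a flag. The published absolute R² values require the restricted
cohorts and external base summary statistics and are out of scope; the
tests check invariants (clump r² cap, nesting across thresholds,
monotonicity in base-target overlap) instead.

## Numerical choices

- Logistic IRLS: step-halving line search, convergence at max |Δβ| <
  10⁻⁸, quasi-separation flagged at |β| > 30 or SE > 10³.
- HWE: probabilities compared with a 10⁻¹² relative tolerance when
  summing "as or more extreme" outcomes, guarding against ties lost to
  rounding.
- LD matrices get 10⁻⁶ diagonal jitter before eigendecomposition;
  matrices still indefinite after jitter are an error, not silently
  repaired.
- Intercept root-finding for the phenotype model brackets [−40, 40] on
  the logit scale and fails loudly if the target prevalence is
  unattainable.
- Determinism: every stochastic routine draws from
  `numpy.random.default_rng` seeded by (config seed, ancestry/analyte
  label CRC, purpose string CRC), so identical configs give byte-identical
  outputs and streams are independent across purposes.

## Operating characteristics and problem sizes

`calibration.py` fixes the replicate designs: colocalization calibration
uses two quantitative traits with a 0.35 SD/allele causal effect at
n = 2,000 per side over 60 SNPs (ρ = 0.7 block); null-GWAS calibration
uses 5,000 samples × 5,000 unlinked variants; conditional recovery uses
1,500 cases/1,500 controls with log-odds 0.5 causal variants at MAF
0.3–0.4; nomination recovery uses 750/750 with log-odds 0.7 and an eQTL
sharing the causal variant at 0.8 SD/allele. Effects were chosen a
priori for essentially complete single-variant power (expected Wald z of
8–9 at the genome-wide threshold), so replicate rates measure the
decision rules rather than power. At 5,000 variants the λ-GC estimate
itself has Monte-Carlo spread of about ±0.03 (one SD); occasional
single-seed excursions just outside a ±0.05 band are sampling noise, not
miscalibration — the average over independent replicates sits at 1.00.

## Known limitations

- Single-causal-variant colocalization only (no SuSiE-style multi-signal
  decomposition, no conditional coloc).
- No mixed models or relatedness correction in the association scan; the
  generator produces unrelated individuals.
- The gene statistic is one member of the standard gene-test family
  (mean χ²); sum-of-χ² and top-k variants are not implemented.
- Allele harmonization is position-based and drops ambiguous mismatches
  rather than attempting strand inference from frequency.
- The evidence weight table is a documented reconstruction; analyses that
  depend on exact published weights should override it in config.
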