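"""Single-ancestry GWAS stage: variant QC, logistic association, inflation,
locus definition, stepwise conditional analysis and cohort heterogeneity.

Conventions fixed across the pipeline: dosages are additive counts of the
alternate allele; the genome-wide significance threshold is P < 5e-8; a
locus is the sentinel (most significant) variant plus 1-Mb flanks; age is
never a covariate because case/control status is defined by an age cutoff.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats

from .config import GENOME_WIDE_P, LOCUS_FLANK_BP, QCThresholds
from .datatypes import MISSING, SUMSTATS_COLUMNS, GenotypeMatrix, Locus
from .logistic import FitError, drop_collinear, fit_logistic

logger = logging.getLogger(__name__)

#: expected median of a 1-df chi-square statistic under the null
_CHI2_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


@lru_cache(maxsize=100_000)
def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test P value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed count.  Monomorphic variants return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("total genotype count must be positive")
    n_a = 2 * n_aa + n_Aa  # one allele's count; symmetry makes the choice irrelevant
    n_A = 2 * n - n_a
    if n_a == 0 or n_A == 0:
        return 1.0

    rare = min(n_a, n_A)
    # feasible heterozygote counts share the parity of the rare-allele count
    het_values = np.arange(rare % 2, rare + 1, 2)

    def log_prob(het: np.ndarray) -> np.ndarray:
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        lg = np.vectorize(lgamma)
        return (
            het * np.log(2.0)
            + lg(n + 1)
            - lg(het + 1)
            - lg(hom_rare + 1)
            - lg(hom_common + 1)
            + lg(n_a + 1)
            + lg(n_A + 1)
            - lg(2 * n + 1)
        )

    lp = log_prob(het_values)
    lp -= _logsumexp(lp)  # normalize in log space
    p_obs = lp[het_values == n_Aa]
    if p_obs.size == 0:  # observed het count infeasible for these allele counts
        raise ValueError("inconsistent genotype counts")
    keep = lp <= p_obs[0] + 1e-12
    return float(min(1.0, np.exp(_logsumexp(lp[keep]))))


def _logsumexp(x: np.ndarray) -> float:
    m = np.max(x)
    return float(m + np.log(np.sum(np.exp(x - m))))


# ---------------------------------------------------------------------------
# Variant / sample QC
# ---------------------------------------------------------------------------


def apply_sample_qc(genotypes: GenotypeMatrix, thresholds: QCThresholds):
    """Drop samples whose genotype call rate falls below the threshold."""
    call = 1.0 - np.mean(genotypes.dosages == MISSING, axis=1)
    keep = call >= thresholds.sample_call_rate_min
    report = {"n_samples_in": genotypes.n_samples, "n_samples_removed": int((~keep).sum())}
    out = GenotypeMatrix(
        [s for s, k in zip(genotypes.sample_ids, keep) if k],
        genotypes.variants,
        genotypes.dosages[keep],
    )
    return out, report


def apply_variant_qc(
    genotypes: GenotypeMatrix, thresholds: QCThresholds, hwe_p_min: float | None = None
):
    """Drop variants failing call-rate, Hardy-Weinberg or minor-allele-count filters.

    The MAF floor is implied by the MAC floor: maf_min = mac_min / (2 n).
    Returns the filtered matrix and a report with per-filter removal counts;
    a matrix left empty is reported explicitly via ``report["empty"]``.
    """
    hwe_floor = thresholds.hwe_p_min if hwe_p_min is None else hwe_p_min
    d = genotypes.dosages
    n_samples = genotypes.n_samples

    call = 1.0 - np.mean(d == MISSING, axis=0)
    fail_call = call < thresholds.variant_call_rate_min

    n_aa = (d == 2).sum(axis=0)
    n_Aa = (d == 1).sum(axis=0)
    n_AA = (d == 0).sum(axis=0)
    hwe_p = np.array(
        [hwe_exact_test(int(a), int(b), int(c)) for a, b, c in zip(n_AA, n_Aa, n_aa)]
    )
    fail_hwe = hwe_p < hwe_floor

    alt_count = 2 * n_aa + n_Aa
    called = 2 * (n_AA + n_Aa + n_aa)
    mac = np.minimum(alt_count, called - alt_count)
    fail_mac = mac < thresholds.mac_min

    keep = ~(fail_call | fail_hwe | fail_mac)
    report = {
        "n_variants_in": genotypes.n_variants,
        "n_removed_call_rate": int(fail_call.sum()),
        "n_removed_hwe": int(fail_hwe.sum()),
        "n_removed_mac": int(fail_mac.sum()),
        "n_removed_total": int((~keep).sum()),
        "n_variants_out": int(keep.sum()),
        "maf_min_implied": thresholds.maf_min(n_samples),
        "empty": bool(keep.sum() == 0),
    }
    if report["empty"]:
        logger.warning("variant QC removed every variant")
    return genotypes.subset_variants(keep), report


# ---------------------------------------------------------------------------
# Single-variant association
# ---------------------------------------------------------------------------


def default_covariates(phenotypes: pd.DataFrame) -> list[str]:
    """Sex, genotyping array and the first ten principal components.

    The array covariate is omitted when every sample shares one array (it
    would be constant); age is deliberately never included because the
    case/control definition is itself an age partition.
    """
    covs = ["sex"]
    if phenotypes["array"].nunique() > 1:
        covs.append("array")
    covs += [f"pc{k}" for k in range(1, 11) if f"pc{k}" in phenotypes.columns]
    return covs


def _covariate_design(phenotypes: pd.DataFrame, covariate_names: list[str]):
    cols, names = [], []
    for c in covariate_names:
        v = phenotypes[c]
        if v.dtype == object or str(v.dtype) == "category":
            dummies = pd.get_dummies(v, prefix=c, drop_first=True)
            for dc in dummies.columns:
                cols.append(dummies[dc].to_numpy(float))
                names.append(dc)
        else:
            cols.append(v.to_numpy(float))
            names.append(c)
    if not cols:
        return np.empty((len(phenotypes), 0)), []
    Z = np.column_stack(cols)
    Z0, kept, dropped = drop_collinear(Z, names)
    if dropped:
        logger.warning("dropped collinear covariates: %s", dropped)
    return Z0, kept


def run_single_variant_gwas(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    covariate_names: list[str] | None = None,
    extra_dosage_covariates: np.ndarray | None = None,
    ancestry: str = "",
) -> pd.DataFrame:
    """Per-variant logistic regression of status on dosage plus covariates.

    Missing dosages are mean-imputed within variant.  Variants whose fit
    does not converge (separation, monomorphism) are retained in the output
    with NA statistics and a reason code, and a count is logged.
    """
    if covariate_names is None:
        covariate_names = default_covariates(phenotypes)
    phen = phenotypes.set_index("sample_id").loc[genotypes.sample_ids].reset_index()
    y = phen["status"].to_numpy(float)
    Z, _ = _covariate_design(phen, covariate_names)
    if extra_dosage_covariates is not None:
        Z = np.column_stack([Z, extra_dosage_covariates]) if Z.size else extra_dosage_covariates

    n = len(y)
    intercept = np.ones((n, 1))
    base = np.hstack([intercept, Z])
    null_fit = fit_logistic(base, y)
    # warm start for each variant fit: variant beta 0, covariates at null optimum
    start = np.insert(null_fit.beta, 1, 0.0)

    dos = genotypes.dosage_float()
    freq = genotypes.allele_freq()
    called = (genotypes.dosages != MISSING).sum(axis=0)

    rows = []
    n_failed = 0
    for j in range(genotypes.n_variants):
        x = dos[:, j]
        rec = genotypes.variants.iloc[j]
        alt_freq = freq[j]
        maf = min(alt_freq, 1 - alt_freq) if np.isfinite(alt_freq) else np.nan
        mac = int(round(2 * called[j] * maf)) if np.isfinite(maf) else 0
        row = {
            "chrom": rec["chrom"], "pos": int(rec["pos"]), "ref": rec["ref"],
            "alt": rec["alt"], "id": rec["id"],
            "maf": maf, "mac": mac, "n": n,
            "n_cases": int(y.sum()), "n_controls": int(n - y.sum()),
            "reason": "",
        }
        if np.std(x) == 0:
            row.update(beta=np.nan, se=np.nan, z=np.nan, p=np.nan, reason="monomorphic")
            n_failed += 1
        else:
            X = np.hstack([intercept, x[:, None], Z])
            try:
                fit = fit_logistic(X, y, start=start)
            except FitError:
                fit = None
            if fit is None or not fit.converged or not np.isfinite(fit.se[1]) or fit.se[1] <= 0:
                row.update(beta=np.nan, se=np.nan, z=np.nan, p=np.nan, reason="non_converged")
                n_failed += 1
            else:
                b, s = fit.beta[1], fit.se[1]
                z = b / s
                row.update(beta=b, se=s, z=z, p=2 * stats.norm.sf(abs(z)))
        rows.append(row)
    if n_failed:
        logger.info("%d/%d variants flagged (monomorphic or non-converged)", n_failed, len(rows))
    out = pd.DataFrame(rows)
    out["ancestry"] = ancestry
    return out[SUMSTATS_COLUMNS + ["ancestry", "reason"]]


# ---------------------------------------------------------------------------
# Genomic inflation
# ---------------------------------------------------------------------------


def genomic_inflation(p_values) -> float:
    """Lambda-GC: median association chi-square over its null expectation."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no P values supplied")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("P values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / _CHI2_MEDIAN)


# ---------------------------------------------------------------------------
# Locus definition and conditional analysis
# ---------------------------------------------------------------------------


def define_loci(
    sumstats: pd.DataFrame,
    p_threshold: float = GENOME_WIDE_P,
    flank: int = LOCUS_FLANK_BP,
) -> list[Locus]:
    """Greedy sentinel picking: the most significant remaining genome-wide
    variant seeds a locus and absorbs all genome-wide variants within its
    flanks; repeat until none remain."""
    gws = sumstats.loc[sumstats["p"] < p_threshold].copy()
    loci: list[Locus] = []
    while not gws.empty:
        lead = gws.loc[gws["p"].idxmin()]
        member_mask = (gws["chrom"].astype(str) == str(lead["chrom"])) & (
            (gws["pos"] - lead["pos"]).abs() <= flank
        )
        members = gws.loc[member_mask]
        loci.append(
            Locus(
                lead_id=lead["id"],
                chrom=str(lead["chrom"]),
                lead_pos=int(lead["pos"]),
                lead_p=float(lead["p"]),
                flank=flank,
                member_ids=list(members["id"]),
            )
        )
        gws = gws.loc[~member_mask]
    return loci


def stepwise_conditional(
    locus: Locus,
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    covariate_names: list[str] | None = None,
    p_threshold: float = GENOME_WIDE_P,
) -> list[str]:
    """Iteratively condition on each new lead until no variant in the locus
    stays genome-wide significant; returns the ordered conditioning chain."""
    in_window = (genotypes.variants["chrom"].astype(str) == locus.chrom) & (
        genotypes.variants["pos"].between(locus.start, locus.end)
    )
    sub = genotypes.subset_variants(in_window.to_numpy())
    dos = sub.dosage_float()

    chain: list[str] = []
    cond: np.ndarray | None = None
    while True:
        scan = run_single_variant_gwas(
            sub, phenotypes, covariate_names, extra_dosage_covariates=cond
        )
        scan = scan.loc[~scan["id"].isin(chain) & scan["p"].notna()]
        if scan.empty or scan["p"].min() >= p_threshold:
            break
        new_id = scan.loc[scan["p"].idxmin(), "id"]
        j = int(np.where(sub.variants["id"] == new_id)[0][0])
        new_col = dos[:, [j]]
        if cond is not None:
            stacked = np.hstack([cond, new_col])
            if np.linalg.matrix_rank(stacked - stacked.mean(axis=0)) <= cond.shape[1]:
                logger.info("stopping conditional chain: %s collinear with prior leads", new_id)
                break
            cond = stacked
        else:
            cond = new_col
        chain.append(new_id)
    return chain


# ---------------------------------------------------------------------------
# Cohort heterogeneity
# ---------------------------------------------------------------------------


def cohort_heterogeneity(betas, ses) -> dict:
    """Cochran's Q across per-cohort estimates of one variant's effect.

    Heterogeneity is flagged when log10(het P) < -1.30103, i.e. strictly
    below P = 0.05 (the boundary itself is not flagged).
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if len(b) < 2:
        raise ValueError("heterogeneity needs at least two cohorts")
    if np.any(s <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / s**2
    pooled = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - pooled) ** 2))
    df = len(b) - 1
    het_p = float(stats.chi2.sf(q, df=df))
    log10p = float(np.log10(het_p)) if het_p > 0 else -np.inf
    return {
        "Q": q,
        "df": df,
        "het_p": het_p,
        "log10_het_p": log10p,
        "heterogeneous": log10p < -1.30103,
    }
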