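"""Approximate-Bayes-factor colocalization under a single-causal-variant model.

For each variant the association evidence is summarized by Wakefield's
approximate Bayes factor from (beta, se) and a normal effect-size prior.
Five hypotheses are compared over a region: H0 no causal variant for
either trait; H1/H2 a causal variant for one trait only; H3 distinct
causal variants; H4 one shared causal variant.  A region is declared
colocalized when PP.H4 >= 0.8.

All accumulation is in log space, so |z| up to the hundreds is safe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .config import ColocPriors
from .datatypes import Locus, harmonize_to

PP_H4_DECISION = 0.8
LOW_OVERLAP_N = 25


@dataclass
class ColocResult:
    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    n_snps: int
    lead_a: Optional[str] = None
    lead_b: Optional[str] = None
    tested: bool = True
    low_confidence: bool = False

    @property
    def colocalizes(self) -> bool:
        return self.tested and self.pp_h4 >= PP_H4_DECISION

    def posteriors(self) -> np.ndarray:
        return np.array([self.pp_h0, self.pp_h1, self.pp_h2, self.pp_h3, self.pp_h4])


def no_test_result() -> ColocResult:
    """Explicit 'could not test' outcome (zero overlapping variants) - not H0."""
    return ColocResult(np.nan, np.nan, np.nan, np.nan, np.nan, n_snps=0, tested=False)


def wakefield_labf(beta, se, prior_sd) -> np.ndarray:
    """Log approximate Bayes factor for a single-variant association.

    With V = se^2, W = prior_sd^2, r = W/(V+W) and z = beta/se:
    log ABF = 0.5 log(1 - r) + (z^2 / 2) r.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    v = se**2
    w = prior_sd**2
    r = w / (v + w)
    z = beta / se
    return 0.5 * np.log1p(-r) + 0.5 * z**2 * r


def coloc_from_labf(labf_a: np.ndarray, labf_b: np.ndarray, priors: ColocPriors) -> ColocResult:
    """Posteriors over H0..H4 from per-SNP log ABFs of the two traits."""
    labf_a = np.asarray(labf_a, dtype=float)
    labf_b = np.asarray(labf_b, dtype=float)
    if labf_a.shape != labf_b.shape or labf_a.size == 0:
        raise ValueError("log-ABF vectors must be nonempty and aligned")
    m = labf_a.size

    lsum_a = logsumexp(labf_a)
    lsum_b = logsumexp(labf_b)
    lsum_ab = logsumexp(labf_a + labf_b)

    lh0 = 0.0
    lh1 = np.log(priors.p1) + lsum_a
    lh2 = np.log(priors.p2) + lsum_b
    # H3: ordered pairs of distinct SNPs = full product minus the diagonal
    cross = lsum_a + lsum_b
    if m > 1 and cross > lsum_ab:
        lh3 = np.log(priors.p1) + np.log(priors.p2) + cross + np.log1p(-np.exp(lsum_ab - cross))
    else:
        lh3 = -np.inf
    lh4 = np.log(priors.p12) + lsum_ab

    lw = np.array([lh0, lh1, lh2, lh3, lh4])
    pp = np.exp(lw - logsumexp(lw))
    pp /= pp.sum()
    return ColocResult(*pp, n_snps=m)


def coloc_abf(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    priors: ColocPriors | None = None,
    prior_sd_a: float | None = None,
    prior_sd_b: float | None = None,
) -> ColocResult:
    """Colocalize two per-variant summary-statistic tables.

    Tables need chrom/pos/ref/alt/beta/se columns; variants are intersected
    with allele harmonization (sign flips do not change ABFs, but mismatched
    alleles are excluded).  Effect priors default to the quantitative-trait
    SD on both sides.
    """
    priors = priors or ColocPriors()
    sd_a = prior_sd_a if prior_sd_a is not None else priors.prior_sd_quant
    sd_b = prior_sd_b if prior_sd_b is not None else priors.prior_sd_quant

    a = stats_a.loc[stats_a["se"].notna() & (stats_a["se"] > 0)]
    b = stats_b.loc[stats_b["se"].notna() & (stats_b["se"] > 0)]
    merged, _log = harmonize_to(a, b)
    if merged.empty:
        return no_test_result()

    labf_a = wakefield_labf(merged["beta_a"].to_numpy(), merged["se_a"].to_numpy(), sd_a)
    labf_b = wakefield_labf(merged["beta_b"].to_numpy(), merged["se_b"].to_numpy(), sd_b)
    res = coloc_from_labf(labf_a, labf_b, priors)
    merged = merged.reset_index(drop=True)
    res.lead_a = str(merged.loc[int(np.argmax(labf_a)), "id_a"]) if "id_a" in merged else None
    res.lead_b = str(merged.loc[int(np.argmax(labf_b)), "id_a"]) if "id_a" in merged else None
    res.low_confidence = res.n_snps < LOW_OVERLAP_N
    return res


def coloc_gwas_locus(
    locus: Locus,
    gwas_stats: pd.DataFrame,
    qtl: pd.DataFrame,
    priors: ColocPriors | None = None,
    second_trait_cc: bool = False,
) -> ColocResult:
    """Colocalize a GWAS locus against one molecular QTL dataset.

    Both tables are restricted to the sentinel's 1-Mb flanks before
    intersection.  The GWAS (case-control, log-odds scale) side uses the
    binary-trait prior SD; the QTL side uses the quantitative prior unless
    ``second_trait_cc`` is set (the GWAS-vs-GWAS mode).
    """
    priors = priors or ColocPriors()
    win_a = gwas_stats.loc[
        (gwas_stats["chrom"].astype(str) == locus.chrom)
        & gwas_stats["pos"].between(locus.start, locus.end)
    ]
    win_b = qtl.loc[
        (qtl["chrom"].astype(str) == locus.chrom) & qtl["pos"].between(locus.start, locus.end)
    ]
    if win_a.empty or win_b.empty:
        return no_test_result()
    sd_b = priors.prior_sd_cc if second_trait_cc else priors.prior_sd_quant
    return coloc_abf(
        win_a, win_b, priors, prior_sd_a=priors.prior_sd_cc, prior_sd_b=sd_b
    )
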