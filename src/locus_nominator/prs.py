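"""Polygenic risk scoring by LD clumping and P-value thresholding.

A base GWAS (e.g. late-onset Alzheimer summary statistics) is clumped
against an LD panel, optionally stripped of the APOE region
(chr19:44,000,009-47,999,435), and per-sample scores (sum of beta x
dosage over variants passing each base-P threshold) are regressed against
target case-control status; fit quality is reported as Nagelkerke (and
Cox-Snell) pseudo-R^2 plus the score coefficient's Wald P.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PRSConfig
from .datatypes import MISSING, GenotypeMatrix, harmonize_to
from .logistic import fit_logistic

logger = logging.getLogger(__name__)


@dataclass
class PRSResult:
    threshold: float
    n_snps_used: int
    r2_nagelkerke: float
    r2_coxsnell: float
    p_association: float
    separation: bool = False
    empty: bool = False


def clump(
    base_stats: pd.DataFrame, ld_panel: GenotypeMatrix, config: PRSConfig | None = None
) -> list[str]:
    """Greedy LD clumping: iterate base variants by ascending P (those with
    P <= clump_p); keep a variant iff no already-kept variant within
    clump_kb has r^2 > clump_r2 with it.  Variants absent from the LD panel
    pass through with a logged count."""
    config = config or PRSConfig()
    cand = base_stats.loc[base_stats["p"] <= config.clump_p].sort_values("p")
    if cand.empty:
        return []
    panel_ids = {v: i for i, v in enumerate(ld_panel.variants["id"])}
    dos = ld_panel.dosage_float()
    window = config.clump_kb * 1000.0

    kept: list[dict] = []
    n_missing = 0
    for _, row in cand.iterrows():
        vid = row["id"]
        j = panel_ids.get(vid)
        if j is None:
            n_missing += 1
            kept.append({"id": vid, "chrom": str(row["chrom"]), "pos": row["pos"], "x": None})
            continue
        x = dos[:, j]
        pruned = False
        for k in kept:
            if k["x"] is None or k["chrom"] != str(row["chrom"]):
                continue
            if abs(k["pos"] - row["pos"]) > window:
                continue
            r = np.corrcoef(x, k["x"])[0, 1]
            if np.isfinite(r) and r**2 > config.clump_r2:
                pruned = True
                break
        if not pruned:
            kept.append({"id": vid, "chrom": str(row["chrom"]), "pos": row["pos"], "x": x})
    if n_missing:
        logger.info("%d base variants absent from LD panel passed through clumping", n_missing)
    return [k["id"] for k in kept]


def exclude_apoe(base_stats: pd.DataFrame, config: PRSConfig | None = None) -> pd.DataFrame:
    """Drop APOE-region variants unless the config includes them."""
    config = config or PRSConfig()
    if config.include_apoe:
        return base_stats.copy()
    chrom = base_stats["chrom"].astype(str).str.removeprefix("chr")
    in_region = (chrom == str(config.apoe_chrom).removeprefix("chr")) & base_stats[
        "pos"
    ].between(config.apoe_start, config.apoe_end)
    return base_stats.loc[~in_region].copy()


def score_samples(
    genotypes: GenotypeMatrix, base_stats: pd.DataFrame, threshold: float
) -> tuple[np.ndarray, int, bool]:
    """Per-sample score = sum over base variants with P <= threshold of
    beta x dosage.  Alleles are harmonized against the target panel;
    missing dosages contribute 2 x base allele frequency x beta.
    Returns (scores, n_snps_used, empty_flag)."""
    use = base_stats.loc[base_stats["p"] <= threshold]
    n = genotypes.n_samples
    if use.empty:
        logger.warning("no base variants at threshold %g; scores are all zero", threshold)
        return np.zeros(n), 0, True

    aligned, _log = harmonize_to(genotypes.variants.assign(beta=0.0), use)
    if aligned.empty:
        return np.zeros(n), 0, True
    panel_ids = {v: i for i, v in enumerate(genotypes.variants["id"])}
    scores = np.zeros(n)
    n_used = 0
    for _, row in aligned.iterrows():
        j = panel_ids.get(row["id_a"])
        if j is None:
            continue
        beta = row["beta_b"]
        d = genotypes.dosages[:, j].astype(float)
        miss = genotypes.dosages[:, j] == MISSING
        if miss.any():
            af = row.get("maf_b", row.get("maf", np.nan))
            if not np.isfinite(af):
                called = d[~miss]
                af = called.mean() / 2.0 if called.size else 0.0
            d[miss] = 2.0 * af
        scores += beta * d
        n_used += 1
    return scores, n_used, n_used == 0


def nagelkerke_r2(ll_null: float, ll_full: float, n: int) -> tuple[float, float]:
    """(Nagelkerke, Cox-Snell) pseudo-R^2 from the two log-likelihoods."""
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll_full) / n)
    max_cs = 1.0 - np.exp(2.0 * ll_null / n)
    return float(cox_snell / max_cs) if max_cs > 0 else 0.0, float(cox_snell)


def prs_association(scores: np.ndarray, status: np.ndarray, threshold: float = np.nan) -> PRSResult:
    """Logistic regression of case-control status on the risk score."""
    y = np.asarray(status, dtype=float)
    s = np.asarray(scores, dtype=float)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need at least two cases and two controls")
    if np.std(s) == 0:
        return PRSResult(threshold, 0, 0.0, 0.0, 1.0, empty=True)

    X0 = np.ones((len(y), 1))
    null_fit = fit_logistic(X0, y)

    # complete separation: the score perfectly orders cases above controls
    # (or vice versa); the likelihood supremum is 0 and R^2 (Nagelkerke) is 1
    if s[y == 1].min() > s[y == 0].max() or s[y == 1].max() < s[y == 0].min():
        nag, cs = nagelkerke_r2(null_fit.loglik, 0.0, len(y))
        return PRSResult(threshold, 1, nag, cs, 0.0, separation=True)

    X1 = np.column_stack([np.ones(len(y)), s])
    fit = fit_logistic(X1, y)
    nag, cs = nagelkerke_r2(null_fit.loglik, fit.loglik, len(y))
    p = float(fit.wald_p()[1])
    return PRSResult(threshold, 1, nag, cs, p)


def run_prs(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    base_stats: pd.DataFrame,
    ld_panel: GenotypeMatrix | None = None,
    config: PRSConfig | None = None,
) -> pd.DataFrame:
    """Full clump + threshold + score + fit sweep over the configured
    base-P thresholds; returns one row per threshold."""
    config = config or PRSConfig()
    ld_panel = ld_panel if ld_panel is not None else genotypes
    base = exclude_apoe(base_stats, config)
    kept = set(clump(base, ld_panel, config))
    clumped = base.loc[base["id"].isin(kept)]
    phen = phenotypes.set_index("sample_id").loc[genotypes.sample_ids]
    status = phen["status"].to_numpy(float)

    rows = []
    for thr in config.p_thresholds:
        scores, n_used, empty = score_samples(genotypes, clumped, thr)
        if empty:
            rows.append(
                {"threshold": thr, "n_snps": 0, "r2_nagelkerke": 0.0,
                 "r2_coxsnell": 0.0, "p": np.nan, "empty": True}
            )
            continue
        res = prs_association(scores, status, thr)
        rows.append(
            {"threshold": thr, "n_snps": n_used, "r2_nagelkerke": res.r2_nagelkerke,
             "r2_coxsnell": res.r2_coxsnell, "p": res.p_association, "empty": False}
        )
    return pd.DataFrame(rows)
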