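"""Trans-ancestry meta-analysis: inverse-variance fixed effects,
DerSimonian-Laird random effects, and Cochran heterogeneity statistics.

``se_from_beta_p`` recovers a standard error from a printed (beta, P)
pair via the normal quantile, which lets published per-ancestry tables be
re-combined without access to the underlying standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import harmonize_to


@dataclass
class MetaResult:
    beta_fixed: float
    se_fixed: float
    z_fixed: float
    p_fixed: float
    tau2: float
    beta_random: float
    se_random: float
    p_random: float
    Q: float
    df: int
    I2: float  # percent
    k: int
    studies: list = field(default_factory=list)
    single_study: bool = False


def se_from_beta_p(beta: float, p: float) -> float:
    """|beta| / z, with z the two-sided normal quantile of P."""
    if not (0.0 < p < 1.0):
        raise ValueError(f"P must be in (0,1) to recover an SE, got {p}")
    if beta == 0:
        raise ValueError("SE is undefined for beta = 0")
    z = stats.norm.isf(p / 2.0)
    if z <= 0:
        raise ValueError(f"P={p} gives a non-positive quantile")
    return abs(beta) / z


def _fixed(b: np.ndarray, se: np.ndarray):
    w = 1.0 / se**2
    beta = float(np.sum(w * b) / np.sum(w))
    se_f = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se_f
    return beta, se_f, z, 2 * float(stats.norm.sf(abs(z))), w


def fixed_effect_meta(studies: list[tuple[float, float]]) -> MetaResult:
    """Inverse-variance-weighted combination of (beta, se) pairs."""
    if len(studies) == 0:
        raise ValueError("meta-analysis needs at least one study")
    b = np.array([s[0] for s in studies], dtype=float)
    se = np.array([s[1] for s in studies], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    beta, se_f, z, p, w = _fixed(b, se)
    pooled_q = float(np.sum(w * (b - beta) ** 2))
    df = max(len(b) - 1, 0)
    i2 = max(0.0, (pooled_q - df) / pooled_q) * 100.0 if pooled_q > 0 else 0.0
    return MetaResult(
        beta_fixed=beta, se_fixed=se_f, z_fixed=z, p_fixed=p,
        tau2=0.0, beta_random=beta, se_random=se_f, p_random=p,
        Q=pooled_q, df=df, I2=i2, k=len(b), studies=list(studies),
    )


def random_effects_meta(studies: list[tuple[float, float]]) -> MetaResult:
    """DerSimonian-Laird random effects.

    tau^2 = max(0, (Q - df) / C) with C = sum(w) - sum(w^2)/sum(w); when
    Q <= df the estimate truncates to zero and the result coincides with
    fixed effects.  A single study passes through with a flag.
    """
    if len(studies) < 2:
        res = fixed_effect_meta(studies)
        res.single_study = True
        return res
    res = fixed_effect_meta(studies)
    b = np.array([s[0] for s in studies], dtype=float)
    se = np.array([s[1] for s in studies], dtype=float)
    w = 1.0 / se**2
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (res.Q - res.df) / c) if c > 0 else 0.0
    wr = 1.0 / (se**2 + tau2)
    beta_r = float(np.sum(wr * b) / np.sum(wr))
    se_r = float(1.0 / np.sqrt(np.sum(wr)))
    z = beta_r / se_r
    res.tau2 = tau2
    res.beta_random = beta_r
    res.se_random = se_r
    res.p_random = 2 * float(stats.norm.sf(abs(z)))
    return res


def run_trans_ancestry_meta(per_ancestry: list[pd.DataFrame]) -> pd.DataFrame:
    """Variant-wise meta over the ancestries in which a variant was tested.

    The first table's alleles anchor harmonization: swapped ref/alt flips
    the sign of beta, and strand-ambiguous mismatches are dropped with a
    logged count.  k may be smaller than the number of inputs for variants
    absent (or failed) in some ancestries.
    """
    if not per_ancestry:
        raise ValueError("no input summary statistics")
    frames = []
    for i, df in enumerate(per_ancestry):
        usable = df.loc[df["p"].notna() & df["se"].notna() & (df["se"] > 0)].copy()
        if i == 0:
            usable["_beta"] = usable["beta"]
            frames.append(usable)
        else:
            aligned, _log = harmonize_to(per_ancestry[0], usable)
            aligned = aligned.rename(
                columns={
                    "chrom_a": "chrom", "pos_a": "pos", "ref_a": "ref",
                    "alt_a": "alt", "id_a": "id", "beta_b": "_beta", "se_b": "se",
                }
            )
            frames.append(aligned[["chrom", "pos", "ref", "alt", "id", "_beta", "se"]])
            # variants private to a non-anchor ancestry still meta-analyze (k=1)
            anchor_keys = set(
                per_ancestry[0]["chrom"].astype(str) + ":" + per_ancestry[0]["pos"].astype(str)
            )
            priv = usable.loc[
                ~(usable["chrom"].astype(str) + ":" + usable["pos"].astype(str)).isin(anchor_keys)
            ].copy()
            priv["_beta"] = priv["beta"]
            frames.append(priv[["chrom", "pos", "ref", "alt", "id", "_beta", "se"]])

    stacked = pd.concat(frames, ignore_index=True)
    if stacked.empty:
        return pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "id", "k",
                     "beta_fixed", "se_fixed", "p_fixed",
                     "beta_random", "se_random", "p_random", "tau2", "Q", "I2"]
        )

    rows = []
    for vid, grp in stacked.groupby("id", sort=False):
        studies = list(zip(grp["_beta"], grp["se"]))
        res = random_effects_meta(studies)
        first = grp.iloc[0]
        rows.append(
            {
                "chrom": first["chrom"], "pos": int(first["pos"]),
                "ref": first["ref"], "alt": first["alt"], "id": vid,
                "k": res.k,
                "beta_fixed": res.beta_fixed, "se_fixed": res.se_fixed,
                "p_fixed": res.p_fixed,
                "beta_random": res.beta_random, "se_random": res.se_random,
                "p_random": res.p_random,
                "tau2": res.tau2, "Q": res.Q, "I2": res.I2,
            }
        )
    out = pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    # headline significance column follows the random-effects model
    out["p"] = out["p_random"]
    out["beta"] = out["beta_random"]
    out["se"] = out["se_random"]
    return out
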