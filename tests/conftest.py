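"""Shared builders for small synthetic studies used across the suite."""

import numpy as np
import pandas as pd
import pytest

from locus_nominator.config import (
    AncestrySpec,
    CausalVariant,
    CohortSpec,
    GeneModel,
    LDBlock,
    QTLSpec,
    SimConfig,
)


def small_config(seed=0, n_cases=500, n_controls=500, n_variants=100, rho=0.5, **kw):
    defaults = dict(
        seed=seed,
        ancestries=[AncestrySpec("NHW", n_cases, n_controls)],
        n_variants=n_variants,
        ld_blocks=[LDBlock(n_variants, rho)],
        prevalence_target=0.5,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture
def base_config():
    return small_config()


@pytest.fixture
def gene_models():
    return [
        GeneModel("GENE_A", "1", 1_400_000, 1_450_000, "+"),
        GeneModel("GENE_B", "1", 1_900_000, 1_950_000, "-"),
        GeneModel("LNC_C", "1", 1_100_000, 1_120_000, "+", biotype="lncRNA"),
    ]


def sumstats_frame(records):
    """Build a minimal summary-statistics frame from (chrom,pos,ref,alt,beta,se,p) tuples."""
    rows = []
    for chrom, pos, ref, alt, beta, se, p in records:
        rows.append(
            {
                "chrom": str(chrom), "pos": pos, "ref": ref, "alt": alt,
                "id": f"chr{chrom}:{pos}:{ref}:{alt}",
                "beta": beta, "se": se, "z": beta / se if se else np.nan, "p": p,
                "maf": 0.3, "mac": 100, "n": 1000, "n_cases": 500, "n_controls": 500,
            }
        )
    return pd.DataFrame(rows)
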