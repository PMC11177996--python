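"""GWAS core: exact HWE test against an enumeration oracle, QC filters,
logistic association against closed forms and statsmodels, inflation,
locus definition, conditional analysis and heterogeneity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import gammaln

from locus_nominator.config import CausalVariant, LDBlock, QCThresholds
from locus_nominator.datatypes import GenotypeMatrix
from locus_nominator.gwas import (
    apply_sample_qc,
    apply_variant_qc,
    cohort_heterogeneity,
    define_loci,
    genomic_inflation,
    hwe_exact_test,
    run_single_variant_gwas,
    stepwise_conditional,
)
from locus_nominator.simulate import simulate_genotypes, simulate_phenotypes

from conftest import small_config, sumstats_frame


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Brute-force: enumerate every heterozygote count compatible with the
    allele counts and sum probabilities <= that of the observed count."""
    n = n_AA + n_Aa + n_aa
    na = 2 * n_aa + n_Aa
    nA = 2 * n - na
    if na == 0 or nA == 0:
        return 1.0
    rare = min(na, nA)
    probs = {}
    for het in range(rare % 2, rare + 1, 2):
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        lp = (
            het * np.log(2)
            + gammaln(n + 1) - gammaln(het + 1) - gammaln(hom_r + 1) - gammaln(hom_c + 1)
            + gammaln(na + 1) + gammaln(nA + 1) - gammaln(2 * n + 1)
        )
        probs[het] = np.exp(lp)
    total = sum(probs.values())
    p_obs = probs[n_Aa] / total
    return min(1.0, sum(v / total for v in probs.values() if v / total <= p_obs * (1 + 1e-12)))


@pytest.mark.parametrize(
    "counts,expected",
    [((1, 0, 1), 1 / 3), ((25, 50, 25), 1.0), ((50, 0, 0), 1.0)],
)
def test_hwe_known_values(counts, expected):
    assert hwe_exact_test(*counts) == pytest.approx(expected, rel=1e-9)


def test_hwe_all_het_excess_is_extreme():
    assert hwe_exact_test(0, 100, 0) < 1e-10


@given(
    st.integers(0, 60), st.integers(0, 60), st.integers(0, 60)
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_hwe_matches_enumeration_oracle(a, b, c):
    if a + b + c == 0:
        return
    assert hwe_exact_test(a, b, c) == pytest.approx(hwe_enumeration_oracle(a, b, c), rel=1e-9)


def test_hwe_rejects_negative_counts():
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 2, 3)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def _matrix(dosages, positions=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    positions = positions or [1000 * (j + 1) for j in range(m)]
    variants = pd.DataFrame(
        {
            "chrom": "1", "pos": positions, "ref": "A", "alt": "G",
            "id": [f"chr1:{p}:A:G" for p in positions],
        }
    )
    return GenotypeMatrix([f"S{i}" for i in range(n)], variants, dosages)


class TestVariantQC:
    def test_clean_matrix_passes_through(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.3, size=(200, 10))  # HWE-consistent by construction
        g = _matrix(d)
        out, rep = apply_variant_qc(g, QCThresholds())
        assert rep["n_removed_total"] == 0 and out.n_variants == 10

    def test_low_call_rate_removed(self):
        d = np.ones((100, 2), dtype=np.int8)
        d[:, 0] = np.where(np.arange(100) < 15, -1, 1)  # 85% call rate
        g = _matrix(d)
        out, rep = apply_variant_qc(g, QCThresholds())
        assert rep["n_removed_call_rate"] == 1

    def test_low_mac_removed(self):
        d = np.zeros((100, 2), dtype=np.int8)
        d[:2, 0] = 1  # MAC 2 < 5
        d[:30, 1] = 1
        g = _matrix(d)
        out, rep = apply_variant_qc(g, QCThresholds())
        assert rep["n_removed_mac"] >= 1
        assert "chr1:2000:A:G" in list(out.variants["id"])

    def test_hwe_failure_removed(self):
        d = np.ones((200, 1), dtype=np.int8)  # everyone heterozygous
        g = _matrix(d)
        out, rep = apply_variant_qc(g, QCThresholds())
        assert rep["n_removed_hwe"] == 1 and rep["empty"]

    def test_implied_maf_cutoff(self):
        """MAC 5 in 1,213 samples implies a MAF floor of 5/(2*1213) ~ 0.206%."""
        assert QCThresholds().maf_min(1213) == pytest.approx(0.00206, abs=1e-5)

    def test_sample_qc(self):
        d = np.ones((10, 50), dtype=np.int8)
        d[0, :10] = -1  # 80% call rate sample
        g = _matrix(d)
        out, rep = apply_sample_qc(g, QCThresholds())
        assert rep["n_samples_removed"] == 1 and out.n_samples == 9


# ---------------------------------------------------------------------------
# Single-variant association
# ---------------------------------------------------------------------------


class TestAssociation:
    def test_matches_2x2_log_odds_ratio(self):
        """Binary carrier dosage with counts a=10,b=90 (cases), c=30,d=70
        (controls): logistic beta equals ln(ad/bc) = -1.3499."""
        dos = np.array([1] * 10 + [0] * 90 + [1] * 30 + [0] * 70, dtype=np.int8)[:, None]
        status = np.array([1] * 100 + [0] * 100)
        g = _matrix(dos)
        phen = pd.DataFrame({"sample_id": g.sample_ids, "status": status})
        ss = run_single_variant_gwas(g, phen, covariate_names=[])
        expected = np.log(10 * 70 / (90 * 30))
        assert ss.iloc[0]["beta"] == pytest.approx(expected, abs=1e-6)

    def test_matches_statsmodels_with_covariates(self):
        import statsmodels.api as sm

        cfg = small_config(seed=1, n_cases=300, n_controls=300, n_variants=5)
        g = simulate_genotypes(cfg, "NHW")
        ph = simulate_phenotypes(g, cfg, "NHW")
        ss = run_single_variant_gwas(g, ph, covariate_names=["sex", "pc1", "pc2"])
        x = g.dosage_float()
        for j in range(5):
            X = sm.add_constant(
                np.column_stack([x[:, j], ph["sex"], ph["pc1"], ph["pc2"]])
            )
            fit = sm.Logit(ph["status"].to_numpy(), X).fit(disp=0)
            assert ss.iloc[j]["beta"] == pytest.approx(np.asarray(fit.params)[1], abs=1e-5)
            assert ss.iloc[j]["se"] == pytest.approx(np.asarray(fit.bse)[1], rel=1e-4)

    def test_monomorphic_flagged_not_dropped(self):
        d = np.zeros((100, 2), dtype=np.int8)
        d[:50, 1] = 1
        g = _matrix(d)
        phen = pd.DataFrame(
            {"sample_id": g.sample_ids, "status": [1] * 50 + [0] * 50}
        )
        ss = run_single_variant_gwas(g, phen, covariate_names=[])
        assert len(ss) == 2
        assert ss.iloc[0]["reason"] == "monomorphic" and np.isnan(ss.iloc[0]["p"])

    def test_wald_ci_coverage(self):
        """95% Wald CI covers the simulated log-odds in ~95% of replicates."""
        true_beta = np.log(1.5)
        covered = 0
        reps = 60
        for seed in range(reps):
            cfg = small_config(
                seed=seed + 100, n_cases=400, n_controls=400, n_variants=1,
                rho=0.0, maf_range=(0.3, 0.3),
                causal_variants=[CausalVariant(0, {"NHW": true_beta})],
            )
            g = simulate_genotypes(cfg, "NHW")
            ph = simulate_phenotypes(g, cfg, "NHW")
            ss = run_single_variant_gwas(g, ph, covariate_names=[])
            lo = ss.iloc[0]["beta"] - 1.96 * ss.iloc[0]["se"]
            hi = ss.iloc[0]["beta"] + 1.96 * ss.iloc[0]["se"]
            covered += lo <= true_beta <= hi
        # 95% binomial interval for 60 reps: >= 52 successes
        assert covered >= 52


# ---------------------------------------------------------------------------
# Genomic inflation
# ---------------------------------------------------------------------------


class TestInflation:
    def test_all_half(self):
        assert genomic_inflation([0.5] * 100) == pytest.approx(1.0, rel=1e-9)

    def test_doubled_median_chi2(self):
        p = stats.chi2.sf(0.90988, df=1)
        assert genomic_inflation([p] * 10) == pytest.approx(2.0, rel=1e-4)

    def test_uniform_null(self):
        rng = np.random.default_rng(0)
        lam = genomic_inflation(rng.uniform(size=100_000))
        assert lam == pytest.approx(1.0, abs=0.02)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            genomic_inflation([0.5, 0.0])

    def test_invariant_to_order(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=999)
        assert genomic_inflation(p) == genomic_inflation(p[::-1])


# ---------------------------------------------------------------------------
# Loci
# ---------------------------------------------------------------------------


class TestDefineLoci:
    def test_two_close_hits_one_locus(self):
        ss = sumstats_frame(
            [("1", 1_000_000, "A", "G", 0.5, 0.08, 1e-9),
             ("1", 1_500_000, "A", "G", 0.5, 0.09, 1e-8)]
        )
        loci = define_loci(ss)
        assert len(loci) == 1 and loci[0].lead_pos == 1_000_000
        assert len(loci[0].member_ids) == 2

    def test_no_hit_empty(self):
        ss = sumstats_frame([("1", 1000, "A", "G", 0.1, 0.1, 1e-4)])
        assert define_loci(ss) == []

    def test_chromosome_separation(self):
        ss = sumstats_frame(
            [("1", 1_000_000, "A", "G", 0.5, 0.08, 1e-9),
             ("2", 1_000_000, "A", "G", 0.5, 0.08, 1e-9)]
        )
        assert len(define_loci(ss)) == 2

    def test_every_gws_variant_in_exactly_one_locus(self):
        rng = np.random.default_rng(7)
        recs = [
            ("1", int(p), "A", "G", 0.5, 0.07, 10.0 ** -rng.uniform(8, 12))
            for p in sorted(rng.integers(1, 20_000_000, size=40))
        ]
        ss = sumstats_frame(recs)
        loci = define_loci(ss)
        members = [m for l in loci for m in l.member_ids]
        assert sorted(members) == sorted(ss["id"])
        leads = [(l.chrom, l.lead_pos) for l in loci]
        for i, (c1, p1) in enumerate(leads):
            for c2, p2 in leads[i + 1:]:
                assert c1 != c2 or abs(p1 - p2) > 1_000_000


# ---------------------------------------------------------------------------
# Stepwise conditional
# ---------------------------------------------------------------------------


class TestConditional:
    def _study(self, seed, betas):
        cfg = small_config(
            seed=seed, n_cases=1500, n_controls=1500, n_variants=40,
            ld_blocks=[LDBlock(20, 0.0), LDBlock(20, 0.0)],
            maf_range=(0.3, 0.4),
            causal_variants=[CausalVariant(i, {"NHW": b}) for i, b in betas],
        )
        g = simulate_genotypes(cfg, "NHW")
        ph = simulate_phenotypes(g, cfg, "NHW")
        ss = run_single_variant_gwas(g, ph, covariate_names=[])
        loci = define_loci(ss)
        return g, ph, loci

    def test_single_causal_single_signal(self):
        g, ph, loci = self._study(1, [(10, 0.45)])
        assert len(loci) == 1
        chain = stepwise_conditional(loci[0], g, ph, covariate_names=[])
        assert len(chain) == 1

    def test_two_unlinked_causals_two_signals(self):
        g, ph, loci = self._study(2, [(5, 0.5), (30, 0.5)])
        assert len(loci) == 1  # within one 1-Mb window
        chain = stepwise_conditional(loci[0], g, ph, covariate_names=[])
        assert len(chain) == 2

    def test_chain_entries_significant_at_inclusion(self):
        g, ph, loci = self._study(3, [(5, 0.5), (30, 0.5)])
        chain = stepwise_conditional(loci[0], g, ph, covariate_names=[])
        # the first entry is the locus lead by construction
        assert chain[0] == loci[0].lead_id


# ---------------------------------------------------------------------------
# Heterogeneity
# ---------------------------------------------------------------------------


class TestHeterogeneity:
    def test_identical_cohorts_q_zero(self):
        res = cohort_heterogeneity([0.3, 0.3, 0.3], [0.1, 0.1, 0.1])
        assert res["Q"] == pytest.approx(0.0, abs=1e-12)
        assert res["het_p"] == pytest.approx(1.0)
        assert not res["heterogeneous"]

    def test_hand_computed_q(self):
        res = cohort_heterogeneity([0.0, 1.0], [0.1, 0.1])
        assert res["Q"] == pytest.approx(50.0, rel=1e-9)
        assert res["het_p"] == pytest.approx(stats.chi2.sf(50, 1), rel=1e-9)
        assert res["heterogeneous"]

    def test_boundary_not_flagged(self):
        """het P exactly 0.05 sits on log10 = -1.30103 and is not flagged."""
        q = stats.chi2.isf(0.05, df=1)
        se = 0.1
        delta = np.sqrt(q * 2 * se**2 / 2) * 2 / np.sqrt(2)  # construct Q == q
        b = np.array([0.0, 1.0]) * np.sqrt(q / 50.0)
        res = cohort_heterogeneity(b, [se, se])
        assert res["het_p"] == pytest.approx(0.05, rel=1e-9)
        assert not res["heterogeneous"]

    def test_bad_se_rejected(self):
        with pytest.raises(ValueError):
            cohort_heterogeneity([0.1, 0.2], [0.1, 0.0])
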