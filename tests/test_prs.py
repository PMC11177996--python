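"""PRS: clumping invariants against a brute-force checker, APOE exclusion
boundaries, scoring, and pseudo-R^2 behaviour."""

import numpy as np
import pandas as pd
import pytest

from locus_nominator.config import CausalVariant, LDBlock, PRSConfig
from locus_nominator.datatypes import GenotypeMatrix
from locus_nominator.prs import (
    clump,
    exclude_apoe,
    prs_association,
    run_prs,
    score_samples,
)
from locus_nominator.simulate import simulate_genotypes, simulate_phenotypes

from conftest import small_config, sumstats_frame


def panel_from_config(seed=0, n=800, m=60, rho=0.6):
    cfg = small_config(seed=seed, n_cases=n, n_controls=0, n_variants=m, rho=rho)
    return simulate_genotypes(cfg, "NHW"), cfg


def stats_for_panel(panel, p_values):
    recs = []
    for (_, v), p in zip(panel.variants.iterrows(), p_values):
        recs.append((v["chrom"], v["pos"], v["ref"], v["alt"], 0.2, 0.05, p))
    return sumstats_frame(recs)


class TestClump:
    def test_single_variant_kept(self):
        panel, _ = panel_from_config(m=1, rho=0.0)
        base = stats_for_panel(panel, [1e-9])
        assert clump(base, panel) == list(panel.variants["id"])

    def test_correlated_neighbor_pruned(self):
        """The weaker of two nearby correlated variants is clumped away."""
        cfg = small_config(
            seed=3, n_cases=800, n_controls=0, n_variants=10, rho=0.95,
            maf_range=(0.3, 0.3),
        )
        panel = simulate_genotypes(cfg, "NHW")
        d = panel.dosage_float()
        r2 = np.corrcoef(d[:, 0], d[:, 1])[0, 1] ** 2
        assert r2 > 0.1  # construction sanity
        ps = [1.0] * 10
        ps[0], ps[1] = 1e-9, 1e-5
        base = stats_for_panel(panel, ps)
        kept = clump(base, panel)
        ids = list(panel.variants["id"])
        assert ids[0] in kept and ids[1] not in kept

    def test_distant_pair_both_kept(self):
        """Same correlation but separated beyond clump_kb: both survive."""
        panel, _ = panel_from_config(seed=3, rho=0.95, m=10)
        ps = [1.0] * 10
        ps[0], ps[1] = 1e-9, 1e-5
        base = stats_for_panel(panel, ps)
        cfg = PRSConfig(clump_kb=5e-3)  # 5 bp window, pair is 10 kb apart
        kept = clump(base, panel, cfg)
        ids = list(panel.variants["id"])
        assert ids[0] in kept and ids[1] in kept

    def test_pairwise_r2_invariant_brute_force(self):
        """Every kept pair within the window has r^2 <= clump_r2, and every
        dropped variant has an explaining kept variant (brute-force check)."""
        panel, _ = panel_from_config(seed=7, rho=0.8, m=60)
        rng = np.random.default_rng(1)
        base = stats_for_panel(panel, rng.uniform(1e-10, 1, 60))
        cfg = PRSConfig()
        kept = clump(base, panel, cfg)
        d = panel.dosage_float()
        ids = list(panel.variants["id"])
        pos = dict(zip(ids, panel.variants["pos"]))
        col = {v: d[:, i] for i, v in enumerate(ids)}
        window = cfg.clump_kb * 1000
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                if abs(pos[a] - pos[b]) <= window:
                    r2 = np.corrcoef(col[a], col[b])[0, 1] ** 2
                    assert r2 <= cfg.clump_r2 + 1e-12
        pvals = dict(zip(base["id"], base["p"]))
        for v in set(ids) - set(kept):
            explainers = [
                k for k in kept
                if abs(pos[k] - pos[v]) <= window
                and np.corrcoef(col[k], col[v])[0, 1] ** 2 > cfg.clump_r2
                and pvals[k] <= pvals[v]
            ]
            assert explainers, f"dropped variant {v} has no explaining kept variant"


class TestApoeExclusion:
    BASE = sumstats_frame(
        [
            ("19", 45_000_000, "A", "G", 0.3, 0.05, 1e-10),
            ("19", 44_000_008, "C", "T", 0.3, 0.05, 1e-10),
            ("19", 44_000_009, "C", "T", 0.3, 0.05, 1e-10),
            ("1", 45_000_000, "A", "G", 0.3, 0.05, 1e-10),
        ]
    )

    def test_region_removed(self):
        out = exclude_apoe(self.BASE)
        kept = set(zip(out["chrom"], out["pos"]))
        assert ("19", 45_000_000) not in kept
        assert ("19", 44_000_009) not in kept

    def test_boundary_exclusive_below(self):
        out = exclude_apoe(self.BASE)
        assert ("19", 44_000_008) in set(zip(out["chrom"], out["pos"]))

    def test_other_chromosomes_kept(self):
        out = exclude_apoe(self.BASE)
        assert ("1", 45_000_000) in set(zip(out["chrom"], out["pos"]))

    def test_include_flag_keeps_all(self):
        out = exclude_apoe(self.BASE, PRSConfig(include_apoe=True))
        assert len(out) == len(self.BASE)


class TestScoring:
    def _tiny_panel(self, dosages):
        d = np.asarray(dosages, dtype=np.int8)
        variants = pd.DataFrame(
            {"chrom": "1", "pos": [1000], "ref": ["A"], "alt": ["G"],
             "id": ["chr1:1000:A:G"]}
        )
        return GenotypeMatrix([f"S{i}" for i in range(len(d))], variants, d.reshape(-1, 1))

    def test_beta_times_dosage(self):
        panel = self._tiny_panel([0, 1, 2])
        base = sumstats_frame([("1", 1000, "A", "G", 0.5, 0.05, 1e-9)])
        scores, n_used, empty = score_samples(panel, base, 1.0)
        assert np.allclose(scores, [0.0, 0.5, 1.0]) and n_used == 1 and not empty

    def test_allele_flip_invariance(self):
        panel = self._tiny_panel([0, 1, 2])
        flipped = sumstats_frame([("1", 1000, "G", "A", -0.5, 0.05, 1e-9)])
        scores, _, _ = score_samples(panel, flipped, 1.0)
        assert np.allclose(scores, [0.0, 0.5, 1.0])

    def test_no_variants_at_threshold_flagged(self):
        panel = self._tiny_panel([0, 1, 2])
        base = sumstats_frame([("1", 1000, "A", "G", 0.5, 0.05, 1e-4)])
        scores, n_used, empty = score_samples(panel, base, 5e-8)
        assert empty and np.allclose(scores, 0.0)

    def test_missing_dosage_mean_imputed(self):
        panel = self._tiny_panel([0, 2, -1])
        base = sumstats_frame([("1", 1000, "A", "G", 0.5, 0.05, 1e-9)])
        base["maf"] = 0.25
        scores, _, _ = score_samples(panel, base, 1.0)
        assert scores[2] == pytest.approx(2 * 0.25 * 0.5)


class TestAssociationFit:
    def test_perfect_separation_closed_form(self):
        """Balanced n=100 with a perfectly separating score: Cox-Snell hits
        its maximum 0.75 and Nagelkerke is exactly 1."""
        scores = np.concatenate([np.full(50, 2.0), np.full(50, -2.0)])
        status = np.array([1] * 50 + [0] * 50)
        res = prs_association(scores, status)
        assert res.separation
        assert res.r2_coxsnell == pytest.approx(0.75, abs=1e-9)
        assert res.r2_nagelkerke == pytest.approx(1.0, abs=1e-9)

    def test_null_score(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=5000)
        status = rng.integers(0, 2, size=5000)
        res = prs_association(scores, status)
        assert res.r2_nagelkerke < 0.01

    def test_constant_score_r2_zero(self):
        res = prs_association(np.zeros(100), np.array([1, 0] * 50))
        assert res.r2_nagelkerke == 0.0 and res.empty

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            prs_association(np.arange(10.0), np.array([1] + [0] * 9))


class TestEndToEnd:
    def test_r2_monotone_in_genetic_overlap(self):
        """Bigger shared causal effects between base and target give larger
        PRS R^2 (three effect tiers)."""
        r2s = []
        for tier, beta in enumerate([0.0, 0.25, 0.6]):
            cfg = small_config(
                seed=77, n_cases=1200, n_controls=1200, n_variants=40,
                ld_blocks=[LDBlock(40, 0.0)], maf_range=(0.2, 0.4),
                causal_variants=[CausalVariant(j, {"NHW": beta}) for j in (5, 15, 25)],
            )
            g = simulate_genotypes(cfg, "NHW")
            ph = simulate_phenotypes(g, cfg, "NHW")
            # base effects equal the generating model: a perfectly informative base GWAS
            base = stats_for_panel(g, [1e-9 if j in (5, 15, 25) else 0.9 for j in range(40)])
            base["beta"] = [beta if j in (5, 15, 25) else 0.0 for j in range(40)]
            tab = run_prs(g, ph, base)
            r2s.append(tab["r2_nagelkerke"].max())
        assert r2s[0] < r2s[1] < r2s[2]

    def test_nested_thresholds(self):
        panel, _ = panel_from_config(seed=5, n=500, m=30, rho=0.0)
        rng = np.random.default_rng(2)
        base = stats_for_panel(panel, 10 ** -rng.uniform(0, 10, 30))
        cfg = PRSConfig()
        kept = clump(base, panel, cfg)
        used = {
            thr: set(base.loc[base["id"].isin(kept) & (base["p"] <= thr), "id"])
            for thr in cfg.p_thresholds
        }
        thresholds = sorted(cfg.p_thresholds)
        for lo, hi in zip(thresholds, thresholds[1:]):
            assert used[lo] <= used[hi]
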