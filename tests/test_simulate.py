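import filecmp

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ernarch.discovery import filter_masked, ttre_window_counts, TTRE
from ernarch.simulate import (
    SimConfig,
    aggregate_signals,
    simulate_expression,
    simulate_genotypes,
    simulate_mask,
    simulate_procap,
    simulate_truth,
    write_fixture_set,
)


class TestGenotypes:
    def test_hardy_weinberg_mean_dosage(self):
        cfg = SimConfig(n_individuals=100, n_variants=100, maf_low=0.5, maf_high=0.5,
                        seed=3)
        gt = simulate_genotypes(cfg)
        # 10,000 Binomial(2, 0.5) draws: mean 1 within 3 SE
        se = np.sqrt(2 * 0.25 / gt.dosages.size)
        assert abs(gt.dosages.mean() - 1.0) < 3 * se

    def test_zero_frequency_gives_all_zero_dosages(self):
        cfg = SimConfig(n_individuals=20, n_variants=50, maf_low=0.0, maf_high=0.0,
                        seed=3)
        gt = simulate_genotypes(cfg)
        assert (gt.dosages == 0).all()

    def test_fixed_seed_reproducible(self):
        cfg = SimConfig(n_individuals=10, n_variants=30, seed=11)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        assert [v.position for v in a.variants] == [v.position for v in b.variants]

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_individuals=1)


class TestProcap:
    def test_null_strand_totals_exchangeable(self):
        """No planted effects: plus vs minus totals pass a sign test."""
        cfg = SimConfig(n_individuals=8, n_ttres=400, n_variants=400,
                        genome_length=400_000, n_ti_qtls=0, n_di_qtls=0,
                        n_e_qtls=0, n_replicate_pairs=0, baseline_mean=30,
                        seed=5)
        rng = cfg.rng()
        gt = simulate_genotypes(cfg, rng)
        truth = simulate_truth(cfg, gt, rng)
        signals = simulate_procap(cfg, gt, truth, rng)
        agg = aggregate_signals(signals)
        wins = 0
        informative = 0
        for _, row in truth.ttres.iterrows():
            mid = int(row["midpoint"])
            p = agg.window_count(mid + 1, mid + 251, "+")
            m = agg.window_count(mid - 250, mid + 1, "-")
            if p != m:
                informative += 1
                wins += p > m
        assert stats.binomtest(wins, informative).pvalue > 0.01

    def test_ti_fold_reproduced_between_homozygotes(self):
        """Planted 2-fold effects: dosage-2 vs dosage-0 mean counts ratio ~2."""
        cfg = SimConfig(n_individuals=40, n_ttres=300, n_variants=3_000,
                        genome_length=600_000, n_ti_qtls=300, n_di_qtls=0,
                        n_e_qtls=0, n_replicate_pairs=0, maf_low=0.3,
                        maf_high=0.5, seed=9)
        rng = cfg.rng()
        gt = simulate_genotypes(cfg, rng)
        truth = simulate_truth(cfg, gt, rng)
        signals = simulate_procap(cfg, gt, truth, rng)
        totals_by_dosage = {0: [], 2: []}
        for _, q in truth.qtls_of_type("ti").iterrows():
            row = truth.ttres.loc[q["target"]]
            mid = int(row["midpoint"])
            d = gt.dosages[int(q["variant_index"])]
            for j, s in enumerate(gt.samples):
                if d[j] in totals_by_dosage:
                    sig = signals[s]
                    t = (sig.window_count(mid + 1, mid + 251, "+")
                         + sig.window_count(mid - 250, mid + 1, "-"))
                    totals_by_dosage[int(d[j])].append(t)
        ratio = np.mean(totals_by_dosage[2]) / np.mean(totals_by_dosage[0])
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_poisson_limit_at_zero_dispersion(self):
        """dispersion -> 0: per-tTRE variance/mean of totals -> 1."""
        cfg = SimConfig(n_individuals=30, n_ttres=200, n_variants=200,
                        genome_length=200_000, n_ti_qtls=0, n_di_qtls=0,
                        n_e_qtls=0, n_replicate_pairs=0, dispersion=0.0,
                        baseline_mean=50, seed=13)
        rng = cfg.rng()
        gt = simulate_genotypes(cfg, rng)
        truth = simulate_truth(cfg, gt, rng)
        signals = simulate_procap(cfg, gt, truth, rng)
        fanos = []
        for _, row in truth.ttres.iterrows():
            mid = int(row["midpoint"])
            totals = [signals[s].window_count(mid + 1, mid + 251, "+")
                      + signals[s].window_count(mid - 250, mid + 1, "-")
                      for s in gt.samples]
            totals = np.array(totals, dtype=float)
            fanos.append(totals.var(ddof=1) / totals.mean())
        assert np.mean(fanos) == pytest.approx(1.0, abs=0.1)

    def test_divergent_orientation_preserved(self, small_cohort):
        cfg, _, truth, signals = small_cohort
        agg = aggregate_signals(signals)
        for _, row in truth.ttres.iterrows():
            mid = int(row["midpoint"])
            # bulk of minus signal left of midpoint, plus signal right
            minus_left = agg.window_count(mid - 250, mid, "-")
            minus_right = agg.window_count(mid, mid + 250, "-")
            plus_right = agg.window_count(mid, mid + 250, "+")
            plus_left = agg.window_count(mid - 250, mid, "+")
            assert minus_left > minus_right
            assert plus_right > plus_left


class TestExpression:
    def make(self, beta, noise, seed=21):
        cfg = SimConfig(n_individuals=60, n_ttres=10, n_variants=300,
                        genome_length=300_000, n_ti_qtls=0, n_di_qtls=0,
                        n_e_qtls=50, e_beta=beta, e_noise_sd=noise, seed=seed)
        rng = cfg.rng()
        gt = simulate_genotypes(cfg, rng)
        truth = simulate_truth(cfg, gt, rng)
        expr, tss = simulate_expression(cfg, gt, truth, rng)
        return cfg, gt, truth, expr, tss

    def test_zero_beta_uncorrelated_with_dosage(self):
        _, gt, truth, expr, _ = self.make(beta=0.0, noise=1.0)
        rs = []
        for _, q in truth.qtls_of_type("e").iterrows():
            d = gt.dosages[int(q["variant_index"])]
            rs.append(np.corrcoef(d, expr.loc[q["target"]])[0, 1])
        assert abs(np.mean(rs)) < 0.06

    def test_zero_noise_exact_linear_recovery(self):
        _, gt, truth, expr, _ = self.make(beta=1.0, noise=0.0)
        for _, q in truth.qtls_of_type("e").iterrows():
            d = gt.dosages[int(q["variant_index"])]
            np.testing.assert_allclose(expr.loc[q["target"]], 10.0 + d)

    def test_ols_recovers_planted_beta_within_2se(self):
        _, gt, truth, expr, _ = self.make(beta=1.0, noise=1.0)
        covered = 0
        n = 0
        for _, q in truth.qtls_of_type("e").iterrows():
            d = gt.dosages[int(q["variant_index"])]
            res = stats.linregress(d, expr.loc[q["target"]])
            covered += abs(res.slope - 1.0) <= 2 * res.stderr
            n += 1
        # nominal 2-SE coverage is ~95%; allow 3-sigma binomial slack
        assert covered / n >= 0.95 - 3 * np.sqrt(0.95 * 0.05 / n)

    def test_gene_tss_within_cis_window_of_driver(self):
        cfg, gt, truth, _, tss = self.make(beta=1.0, noise=1.0)
        for _, q in truth.qtls_of_type("e").iterrows():
            vpos = gt.variants[int(q["variant_index"])].position
            gpos = int(tss.loc[q["target"], "position"])
            assert abs(gpos - vpos) <= cfg.e_cis_window


class TestMask:
    def test_fraction_zero_empty(self):
        cfg = SimConfig(n_individuals=5, n_variants=50, seed=2)
        gt = simulate_genotypes(cfg)
        assert simulate_mask(cfg, gt, fraction=0.0).empty

    def test_fraction_one_masks_every_variant(self):
        cfg = SimConfig(n_individuals=5, n_variants=50, seed=2)
        gt = simulate_genotypes(cfg)
        mask = simulate_mask(cfg, gt, fraction=1.0)
        assert len(mask) == gt.n_variants

    def test_masked_ttre_absent_from_phenotype_matrix(self, small_cohort):
        cfg, _, truth, signals = small_cohort
        row = truth.ttres.iloc[0]
        mask = pd.DataFrame({"contig": [row["contig"]],
                             "start": [row["midpoint"] - 5],
                             "end": [row["midpoint"] + 5]})
        ttres = [TTRE(r["contig"], int(r["minus_position"]), int(r["plus_position"]),
                      id=r["id"]) for _, r in truth.ttres.iterrows()]
        kept = filter_masked(ttres, mask)
        plus, _ = ttre_window_counts(kept, signals)
        expected = set(truth.ttres["id"]) - {row["id"]}
        assert set(plus.index) == expected


class TestFixtureSet:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimConfig(n_individuals=4, n_ttres=5, n_variants=60,
                        genome_length=50_000, n_replicate_pairs=1,
                        n_ti_qtls=2, n_di_qtls=2, n_e_qtls=2, seed=17)
        write_fixture_set(cfg, tmp_path / "a")
        write_fixture_set(cfg, tmp_path / "b")
        files_a = sorted(p.name for p in (tmp_path / "a").iterdir())
        files_b = sorted(p.name for p in (tmp_path / "b").iterdir())
        assert files_a == files_b
        for name in files_a:
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False), name

    def test_vcf_round_trips_through_reader(self, tmp_path):
        from ernarch.io import read_vcf_dosages

        cfg = SimConfig(n_individuals=6, n_ttres=5, n_variants=40,
                        genome_length=50_000, n_replicate_pairs=0, seed=19)
        out = write_fixture_set(cfg, tmp_path / "fix")
        gt = out["genotypes"]
        back = read_vcf_dosages(str(tmp_path / "fix" / "genotypes.vcf"), maf_min=0.0)
        # reader drops maf-0 (monomorphic-by-chance) sites; compare the rest
        kept = {v.id: i for i, v in enumerate(back.variants)}
        for i, v in enumerate(gt.variants):
            if v.id in kept:
                np.testing.assert_array_equal(back.dosages[kept[v.id]],
                                              gt.dosages[i])


class TestPowerMonotonicity:
    @staticmethod
    def power(fold, n_individuals, seed=23):
        from ernarch.normalize import level_phenotype
        from ernarch.qtl import map_cis_qtls

        cfg = SimConfig(n_individuals=n_individuals, n_ttres=60, n_variants=800,
                        genome_length=300_000, n_ti_qtls=30, n_di_qtls=0,
                        n_e_qtls=0, n_replicate_pairs=0, ti_fold_hom=fold,
                        maf_low=0.2, maf_high=0.5, seed=seed)
        rng = cfg.rng()
        gt = simulate_genotypes(cfg, rng)
        truth = simulate_truth(cfg, gt, rng)
        signals = simulate_procap(cfg, gt, truth, rng)
        ttres = [TTRE(r["contig"], int(r["minus_position"]), int(r["plus_position"]),
                      id=r["id"]) for _, r in truth.ttres.iterrows()]
        plus, minus = ttre_window_counts(ttres, signals)
        phen = level_phenotype(plus, minus)
        pos = pd.DataFrame({"contig": truth.ttres["contig"].to_numpy(),
                            "position": truth.ttres["midpoint"].to_numpy()},
                           index=truth.ttres["id"])
        recs = map_cis_qtls(gt, phen, pos, "ti")
        ti = truth.qtls_of_type("ti")
        hits = 0
        for _, q in ti.iterrows():
            sub = recs[(recs["variant_id"] == q["variant_id"])
                       & (recs["element_id"] == q["target"])]
            hits += bool(len(sub)) and bool(sub["significant"].any())
        return hits / len(ti)

    def test_power_nondecreasing_in_fold_and_n(self):
        p_fold = [self.power(f, 40) for f in (1.2, 2.0, 4.0)]
        assert p_fold[0] <= p_fold[1] + 0.05
        assert p_fold[1] <= p_fold[2] + 0.05
        p_n = [self.power(2.0, n) for n in (20, 40, 80)]
        assert p_n[0] <= p_n[1] + 0.05
        assert p_n[1] <= p_n[2] + 0.05
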