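import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ernarch.architecture import (
    REGIONS,
    classify_region,
    overlap_enrichment,
    positional_enrichment,
    qq_compare,
    regional_frequency_test,
    ttre_gene_correlation,
)
from ernarch.discovery import TTRE


def enhancer(mid=10_000, core=70, contig="chr1", tid="t0"):
    return TTRE(contig, mid - core, mid + core, id=tid)


class TestClassifyRegion:
    def test_midpoint_is_center(self):
        assert classify_region(0, enhancer()) == "center"

    def test_core_offset_is_core(self):
        t = enhancer(core=70)
        assert classify_region(70, t) == "core"
        assert classify_region(-70, t) == "core"

    def test_between_center_and_core_is_ncnc(self):
        assert classify_region(40, enhancer(core=70)) == "NCNC"

    def test_out_and_far_out_margins(self):
        t = enhancer(core=70)  # element bounds +/-70, out margin 200
        assert classify_region(200, t) == "out"
        assert classify_region(271, t) == "far_out"
        assert classify_region(1_500, t) == "far_out"

    def test_center_precedence_on_narrow_elements(self):
        # cores overlap the center when the element is very narrow
        t = TTRE("chr1", 9_990, 10_010, id="narrow")  # core offsets +/-10
        assert classify_region(0, t) == "center"
        assert classify_region(-10, t) == "center"

    def test_offset_outside_window_rejected(self):
        with pytest.raises(ValueError):
            classify_region(2_001, enhancer())

    @settings(max_examples=200, deadline=None)
    @given(st.integers(-2_000, 2_000), st.integers(30, 150))
    def test_every_offset_gets_exactly_one_label(self, offset, core):
        label = classify_region(offset, enhancer(core=core))
        assert label in REGIONS


class TestPositionalEnrichment:
    def test_uniform_qtls_mostly_inside_band(self, rng):
        ttres = [enhancer(mid=m, tid=f"t{m}") for m in range(10_000, 110_000, 10_000)]
        snps = [("chr1", int(p)) for t in ttres
                for p in rng.integers(t.midpoint - 2_000, t.midpoint + 2_000, 300)]
        qtl_idx = rng.choice(len(snps), size=200, replace=False)
        qtls = [snps[i] for i in qtl_idx]
        prof = positional_enrichment(qtls, ttres, snps, n_resample=500, bin=100, rng=rng)
        inside = ((prof.observed >= prof.band_low) & (prof.observed <= prof.band_high))
        assert inside.mean() > 0.9

    def test_point_mass_at_zero_exceeds_band(self, rng):
        ttres = [enhancer(mid=m, tid=f"t{m}") for m in range(10_000, 60_000, 10_000)]
        snps = [("chr1", int(p)) for t in ttres
                for p in rng.integers(t.midpoint - 2_000, t.midpoint + 2_000, 200)]
        qtls = [("chr1", t.midpoint) for t in ttres for _ in range(20)]
        prof = positional_enrichment(qtls, ttres, snps + qtls, n_resample=500,
                                     bin=10, rng=rng)
        zero_bin = np.searchsorted(prof.bin_edges, 0, side="right") - 1
        assert prof.observed[zero_bin] > prof.band_high[zero_bin]
        assert abs(prof.peak_offset()) <= 10

    def test_small_background_samples_with_replacement(self, rng, caplog):
        ttres = [enhancer()]
        qtls = [("chr1", 10_000 + i) for i in range(-20, 20)]
        snps = [("chr1", 10_005)]
        with caplog.at_level("WARNING"):
            prof = positional_enrichment(qtls, ttres, snps, n_resample=10, rng=rng)
        assert prof.n_qtls == 40


class TestRegionalFrequency:
    def test_balanced_table_gives_or_one_p_one(self):
        t = enhancer()
        # 10 SNPs in far_out and 10 in center (via offsets), equal QTL rates
        snps = ([("chr1", 10_000 + off) for off in range(-5, 5)]
                + [("chr1", 10_000 + 1_500 + i) for i in range(10)])
        qtls = snps[:5] + snps[10:15]  # 5 of 10 QTLs in each region
        out = regional_frequency_test(snps, qtls, [t]).set_index("region")
        assert out.loc["center", "odds_ratio"] == pytest.approx(1.0)
        assert out.loc["center", "fisher_p"] == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_tail_oracle(self):
        # 2x2 table (8,2; 1,9): two-sided p by exhaustive tail enumeration
        table = np.array([[8, 2], [1, 9]])
        _, p_fisher = stats.fisher_exact(table, alternative="two-sided")
        n_row1, n_row2 = 10, 10
        k_total = 9  # total QTLs
        probs = [stats.hypergeom.pmf(k, n_row1 + n_row2, k_total, n_row1)
                 for k in range(k_total + 1)]
        p_obs = stats.hypergeom.pmf(8, n_row1 + n_row2, k_total, n_row1)
        p_oracle = sum(pr for pr in probs if pr <= p_obs + 1e-12)
        assert p_fisher == pytest.approx(p_oracle, rel=1e-9)

    def test_enriched_center_detected(self, rng):
        t = enhancer()
        center_snps = [("chr1", 10_000 + off) for off in range(-20, 20)]
        far_snps = [("chr1", 10_000 + 1_000 + i) for i in range(400)]
        snps = center_snps + far_snps
        qtls = center_snps[:30] + far_snps[:20]  # 75% vs 5%
        out = regional_frequency_test(snps, qtls, [t]).set_index("region")
        assert out.loc["center", "frequency"] > out.loc["far_out", "frequency"]
        assert out.loc["center", "fisher_p"] < 1e-6

    def test_zero_qtls_everywhere_skips_tests(self):
        t = enhancer()
        snps = [("chr1", 10_000)] + [("chr1", 11_500 + i) for i in range(5)]
        out = regional_frequency_test(snps, [], [t])
        assert (out["n_qtls"] == 0).all()
        assert out["fisher_p"].isna().all()

    def test_empty_far_out_rejected(self):
        t = enhancer()
        with pytest.raises(ValueError, match="far_out"):
            regional_frequency_test([("chr1", 10_000)], [], [t])


class TestOverlapEnrichment:
    def test_identical_sets_fold_one(self):
        s = {"a", "b", "c", "d"}
        ann = {"a", "b"}
        fold, _ = overlap_enrichment(s, ann, s)
        assert fold == pytest.approx(1.0)

    def test_disjoint_annotation_fold_zero(self):
        fold, _ = overlap_enrichment({"a", "b"}, {"x"}, {"a", "b", "c", "d"})
        assert fold == 0.0

    def test_fisher_p_matches_hypergeometric(self):
        qtl = {f"q{i}" for i in range(10)}
        bg = {f"b{i}" for i in range(10)}
        ann = {f"q{i}" for i in range(8)} | {"b0"}
        _, p = overlap_enrichment(qtl, ann, bg)
        _, p_direct = stats.fisher_exact([[8, 2], [1, 9]])
        assert p == pytest.approx(p_direct, rel=1e-12)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            overlap_enrichment({"a"}, {"a"}, set())


class TestQqCompare:
    def test_identical_samples_ks_p_one(self, rng):
        p = rng.uniform(size=50)
        _, d, ks_p = qq_compare(p, p)
        assert d == 0.0
        assert ks_p == 1.0

    def test_enriched_subset_sits_above_diagonal(self, rng):
        p_all = rng.uniform(size=5_000)
        p_sub = rng.uniform(size=1_000) ** 3  # stochastically smaller
        qq, _, ks_p = qq_compare(p_sub, p_all)
        assert ks_p < 1e-6
        assert (qq["observed_neglog10"] >= qq["expected_neglog10"] - 0.2).mean() > 0.9

    def test_matches_exact_ks_oracle_n5(self):
        p_sub = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        p_all = np.array([0.15, 0.35, 0.55, 0.75, 0.95])
        _, d, _ = qq_compare(p_sub, p_all)
        # direct D-statistic: max |ECDF1 - ECDF2| over all sample points
        grid = np.concatenate([p_sub, p_all])
        ecdf1 = np.array([(p_sub <= x).mean() for x in grid])
        ecdf2 = np.array([(p_all <= x).mean() for x in grid])
        assert d == pytest.approx(np.abs(ecdf1 - ecdf2).max())


class TestCoexpression:
    def test_identical_vectors_r_one(self, rng):
        v = rng.normal(size=10)
        phen = pd.DataFrame([v], index=["t0"], columns=[f"s{i}" for i in range(10)])
        expr = pd.DataFrame([v], index=["g0"], columns=phen.columns)
        tpos = pd.DataFrame({"contig": ["chr1"], "position": [5_000]}, index=["t0"])
        gtss = pd.DataFrame({"contig": ["chr1"], "position": [6_000], "strand": ["+"]},
                            index=["g0"])
        out = ttre_gene_correlation(phen, expr, tpos, gtss)
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "distance"] == -1_000  # tTRE upstream of a + gene

    def test_distance_sign_respects_gene_strand(self, rng):
        v = rng.normal(size=5)
        phen = pd.DataFrame([v], index=["t0"], columns=list("abcde"))
        expr = pd.DataFrame([v], index=["g0"], columns=list("abcde"))
        tpos = pd.DataFrame({"contig": ["chr1"], "position": [7_000]}, index=["t0"])
        gtss = pd.DataFrame({"contig": ["chr1"], "position": [6_000], "strand": ["-"]},
                            index=["g0"])
        out = ttre_gene_correlation(phen, expr, tpos, gtss)
        assert out.loc[0, "distance"] == -1_000  # downstream of a - strand gene

    def test_matches_covariance_formula_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 5.0, 4.0])
        phen = pd.DataFrame([x], index=["t0"], columns=list("abcde"))
        expr = pd.DataFrame([y], index=["g0"], columns=list("abcde"))
        tpos = pd.DataFrame({"contig": ["chr1"], "position": [1_000]}, index=["t0"])
        gtss = pd.DataFrame({"contig": ["chr1"], "position": [2_000], "strand": ["+"]},
                            index=["g0"])
        out = ttre_gene_correlation(phen, expr, tpos, gtss)
        r_oracle = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert out.loc[0, "r"] == pytest.approx(r_oracle, abs=1e-12)

    def test_independent_vectors_mean_r_near_zero(self, rng):
        n = 67
        cols = [f"s{i}" for i in range(n)]
        phen = pd.DataFrame(rng.normal(size=(100, n)),
                            index=[f"t{i}" for i in range(100)], columns=cols)
        expr = pd.DataFrame(rng.normal(size=(10, n)),
                            index=[f"g{i}" for i in range(10)], columns=cols)
        tpos = pd.DataFrame({"contig": "chr1",
                             "position": np.arange(100) * 1_000}, index=phen.index)
        gtss = pd.DataFrame({"contig": "chr1", "position": np.arange(10) * 10_000,
                             "strand": "+"}, index=expr.index)
        out = ttre_gene_correlation(phen, expr, tpos, gtss)
        assert len(out) == 1_000
        assert abs(out["r"].mean()) < 0.02

    def test_too_few_individuals_rejected(self):
        phen = pd.DataFrame([[1.0, 2.0]], index=["t0"], columns=["a", "b"])
        expr = pd.DataFrame([[1.0, 2.0]], index=["g0"], columns=["a", "b"])
        tpos = pd.DataFrame({"contig": ["chr1"], "position": [0]}, index=["t0"])
        gtss = pd.DataFrame({"contig": ["chr1"], "position": [0], "strand": ["+"]},
                            index=["g0"])
        with pytest.raises(ValueError):
            ttre_gene_correlation(phen, expr, tpos, gtss)


def test_region_enrichment_symmetric_in_table_orientation():
    """Swapping which margin is 'region' vs 'QTL' leaves the Fisher p fixed."""
    qtl = {f"q{i}" for i in range(6)}
    bg = {f"b{i}" for i in range(12)}
    ann = {"q0", "q1", "q2", "b0"}
    _, p = overlap_enrichment(qtl, ann, bg)
    # transposed framing: membership in the annotation defines the sets,
    # overlap with the QTL set defines the outcome
    universe = qtl | bg
    in_ann = ann & universe
    out_ann = universe - ann
    _, p_t = overlap_enrichment(in_ann, qtl, out_ann)
    assert p == pytest.approx(p_t, rel=1e-9)
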