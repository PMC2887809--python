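"""Generator contracts: closed-form truth, determinism, distribution shape."""

import numpy as np
import pandas as pd
import pytest

import asearray as aa
from asearray.simulate import ALLELE_A_DOSE

from conftest import clean_config


class TestExpectedFractions:
    @pytest.mark.parametrize("pair,p,expected", [
        (("AA", "BB"), 0.5, 0.5),
        (("AB", "AB"), 0.1, 0.5),   # same-genotype pairs ignore the mixing proportion
        (("AB", "AB"), 0.9, 0.5),
        (("AA", "AB"), 1.0, 1.0),
        (("BB", "AB"), 0.0, 0.5),
    ])
    def test_examples(self, pair, p, expected):
        assert aa.expected_allele_a_fraction(pair, p) == pytest.approx(expected)

    def test_conservation_and_symmetry(self):
        calls = list(ALLELE_A_DOSE)
        for g1 in calls:
            for g2 in calls:
                for p in (0.0, 0.17, 0.5, 0.83, 1.0):
                    fa = aa.expected_allele_a_fraction((g1, g2), p)
                    # allele-B fraction is the complement
                    fb = aa.expected_allele_a_fraction(
                        ({"AA": "BB", "AB": "AB", "BB": "AA"}[g1],
                         {"AA": "BB", "AB": "AB", "BB": "AA"}[g2]), p)
                    assert fa + fb == pytest.approx(1.0)
                    # swapping individuals mirrors the proportion
                    assert fa == pytest.approx(
                        aa.expected_allele_a_fraction((g2, g1), 1.0 - p))

    def test_nn_raises(self):
        with pytest.raises(ValueError):
            aa.expected_allele_a_fraction(("AA", "NN"), 0.5)


class TestFoldChange:
    def test_subtle_mixture_is_about_1_3_fold(self):
        assert round(aa.expected_fold_change(0.56), 1) == 1.3

    def test_60_40_is_1_5_fold(self):
        assert aa.expected_fold_change(0.60) == pytest.approx(1.5)

    def test_balanced_is_1(self):
        assert aa.expected_fold_change(0.5) == pytest.approx(1.0)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_pure_mixtures_raise(self, p):
        with pytest.raises(ValueError):
            aa.expected_fold_change(p)


class TestGenotypeSampling:
    def test_monomorphic_boundary(self):
        g = aa.sample_genotype_pair(50, allele_freq=0.0, nn_rate=0.0, seed=1)
        assert (g.to_numpy() == "BB").all()

    def test_all_missing_boundary(self):
        g = aa.sample_genotype_pair(50, allele_freq=0.5, nn_rate=1.0, seed=1)
        assert (g.to_numpy() == "NN").all()

    def test_het_fraction_within_binomial_error(self):
        n = 2000
        g = aa.sample_genotype_pair(n, allele_freq=0.5, nn_rate=0.0, seed=7)
        het = (g.to_numpy() == "AB").mean()
        # Hardy-Weinberg at f=0.5: P(AB)=0.5; 3 binomial SDs over 2n calls
        assert abs(het - 0.5) < 3 * np.sqrt(0.25 / (2 * n))

    def test_maximize_discordance(self):
        g = aa.sample_genotype_pair(500, allele_freq=0.5, seed=3, maximize_discordance=True)
        assert (g["ind1"] != g["ind2"]).all()

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            aa.sample_genotype_pair(10, allele_freq=1.5)


class TestMixtureExperiment:
    def test_deterministic(self, ab_pair):
        cfg = aa.SimConfig(n_snps=8, n_beads_per_snp=4, mixture_proportions=(0.5, 0.6),
                           n_replicates=2, seed=5)
        a = aa.simulate_mixture_experiment(cfg, ab_pair)
        b = aa.simulate_mixture_experiment(cfg, ab_pair)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_noise_free_m_equals_log_odds_of_theta(self, ab_pair):
        cfg = clean_config()
        beads, sheet, _ = aa.simulate_mixture_experiment(cfg, ab_pair)
        summary = aa.summarize_array(beads)
        for p in (0.36, 0.64):
            aid = sheet.loc[sheet["mix_p"] == p, "array_id"].iloc[0]
            m = summary.loc[summary["array_id"] == aid, "mean_M"]
            assert np.allclose(m, np.log2(p / (1 - p)), atol=1e-12)

    def test_noise_free_dye_bias_at_balanced_mixture(self, ab_pair):
        cfg = clean_config(mixture_proportions=(0.5,), dye_bias_intercept=0.4,
                           dye_bias_slope=0.0)
        beads, sheet, _ = aa.simulate_mixture_experiment(cfg, ab_pair)
        summary = aa.summarize_array(beads)
        assert np.allclose(summary["mean_M"], 0.4, atol=1e-12)

    def test_noise_free_m_monotone_in_mix_p(self, ab_pair):
        props = (0.2, 0.4, 0.5, 0.6, 0.8)
        cfg = clean_config(mixture_proportions=props)
        beads, sheet, _ = aa.simulate_mixture_experiment(cfg, ab_pair)
        summary = aa.summarize_array(beads).merge(sheet, on="array_id")
        by_p = summary.groupby("mix_p")["mean_M"].mean()
        assert (np.diff(by_p.loc[list(props)]) > 0).all()

    def test_requires_two_individuals(self, ab_pair):
        cfg = clean_config()
        with pytest.raises(ValueError):
            aa.simulate_mixture_experiment(cfg, ab_pair.assign(ind3="AB"))


class TestDyeSwap:
    def test_swapped_arrays_have_opposite_m(self):
        cfg = clean_config(n_snps=10, nonspecific_scale=1.0, seed=9)
        beads, sheet, _ = aa.simulate_dye_swap_experiment(cfg)
        summary = aa.summarize_array(beads).merge(sheet, on="array_id")
        piv = summary.pivot(index="snp_id", columns="dye", values="mean_M")
        assert np.allclose(piv["standard"], -piv["swapped"], atol=1e-9)

    def test_deterministic(self):
        cfg = aa.SimConfig(n_snps=10, n_beads_per_snp=4, n_replicates=2, seed=13)
        a = aa.simulate_dye_swap_experiment(cfg)[0]
        b = aa.simulate_dye_swap_experiment(cfg)[0]
        pd.testing.assert_frame_equal(a, b)

    def test_injected_bias_increases_with_intensity(self):
        cfg = aa.SimConfig(n_snps=400, n_replicates=2, seed=17,
                           dye_bias_slope=0.25, dye_bias_intercept=-2.5)
        beads, _, manifest = aa.simulate_dye_swap_experiment(cfg)
        mean_a = (aa.summarize_array(beads, use_background=True)
                  .groupby("snp_id")["mean_A"].mean())
        r = np.corrcoef(manifest.set_index("snp_id").loc[mean_a.index, "injected_bias"],
                        mean_a)[0, 1]
        assert r > 0.8


class TestCohort:
    def test_deterministic(self):
        cfg = aa.SimConfig(n_snps=20, seed=19, nonresponder_rate=0.2)
        g = aa.sample_genotype_cohort(20, 6, 0.5, seed=19)
        a = aa.simulate_cohort(cfg, g)[0]
        b = aa.simulate_cohort(cfg, g)[0]
        pd.testing.assert_frame_equal(a, b)

    def test_all_nonresponders_decorrelate_cdna_from_genotype(self):
        cfg = aa.SimConfig(n_snps=300, seed=23, nonresponder_rate=1.0)
        g = aa.sample_genotype_cohort(300, 8, 0.5, seed=23)
        summaries, sheet, _ = aa.simulate_cohort(cfg, g)
        merged = summaries.merge(sheet, on="array_id")
        piv = merged.pivot_table(index="snp_id", columns=["material", "sample_id"],
                                 values="mean_M")
        r = np.corrcoef(piv["cDNA"].to_numpy().ravel(), piv["gDNA"].to_numpy().ravel())[0, 1]
        assert abs(r) < 0.1

    def test_silenced_het_matches_homozygote_level(self):
        cfg = clean_config(n_snps=40, seed=29, silenced_rate=1.0,
                           signal_scale_cdna=2000.0, nonspecific_scale=50.0,
                           expression_log2_sd=0.0)
        g = aa.sample_genotype_cohort(40, 6, 0.5, seed=29)
        summaries, sheet, manifest = aa.simulate_cohort(cfg, g)
        merged = summaries.merge(sheet, on="array_id")
        cdna = merged[merged["material"] == "cDNA"].pivot(
            index="snp_id", columns="sample_id", values="mean_M")
        man = manifest.set_index("snp_id")
        for snp in cdna.index:
            calls = g.loc[snp]
            hets = calls[calls == "AB"].index
            if not len(hets) or not man.loc[snp, "silenced"]:
                continue
            # the silenced het expresses one allele: log-ratio sits at the
            # corresponding homozygote level, not at 0
            hom_call = "AA" if man.loc[snp, "silenced_allele"] == "A" else "BB"
            homs = calls[calls == hom_call].index
            if not len(homs):
                continue
            assert cdna.loc[snp, hets].to_numpy() == pytest.approx(
                cdna.loc[snp, homs].to_numpy().mean(), abs=1e-9)

    def test_gdna_shows_three_genotype_clusters_and_cdna_is_dimmer(self):
        cfg = aa.SimConfig(n_snps=400, seed=31, noise_sd=0.1,
                           probe_affinity_log2_sd=0.0)
        g = aa.sample_genotype_cohort(400, 4, 0.5, seed=31)
        summaries, sheet, _ = aa.simulate_cohort(cfg, g)
        merged = summaries.merge(sheet, on="array_id")
        gd = merged[merged["material"] == "gDNA"]
        one = gd[gd["sample_id"] == "ind1"].set_index("snp_id")
        calls = g["ind1"]
        centers = {c: one.loc[calls == c, "mean_M"].median() for c in ("AA", "AB", "BB")}
        assert centers["AA"] > centers["AB"] + 2 > centers["AB"] - 2 > centers["BB"]
        cd = merged[merged["material"] == "cDNA"]
        assert cd["mean_A"].median() < gd["mean_A"].median() - 1
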