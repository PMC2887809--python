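"""SNP-wise OLS, contrasts, empirical-Bayes moderation, dye effects."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import asearray as aa
from asearray.linear_models import (
    DesignMatrix, build_design_matrix, fit_snp_models, make_baseline_contrasts,
    apply_contrasts, empirical_bayes_moderate, fit_f_dist, squeeze_variances,
    estimate_dye_effects, pivot_m_matrix,
)

from conftest import clean_config


def _sheet(mixes=None, dyes=None, material="gDNA"):
    if mixes is not None:
        rows = [{"array_id": f"a{i}", "sample_id": f"m{p}", "material": material,
                 "dye": "standard", "mix_p": p, "replicate": i, "series": "A"}
                for i, p in enumerate(mixes)]
    else:
        rows = [{"array_id": f"a{i}", "sample_id": "s", "material": material,
                 "dye": d, "mix_p": np.nan, "replicate": i, "series": "ds"}
                for i, d in enumerate(dyes)]
    return pd.DataFrame(rows)


def _fit(Y, X, labels=None):
    N = X.shape[0]
    arrays = [f"a{i}" for i in range(N)]
    M = pd.DataFrame(Y, index=[f"s{i}" for i in range(len(Y))], columns=arrays)
    labels = labels or [f"b{k}" for k in range(X.shape[1])]
    return fit_snp_models(M, DesignMatrix(X, labels, arrays))


class TestDesignMatrix:
    def test_per_mixture_indicator(self):
        sheet = _sheet(mixes=[0.33, 0.33, 0.33, 0.5, 0.5, 0.5, 0.67, 0.67, 0.67])
        d = build_design_matrix(sheet, "per_mixture")
        assert d.X.shape == (9, 3)
        assert d.columns == ["mix_033", "mix_050", "mix_067"]
        assert (d.X.sum(axis=1) == 1).all()

    def test_dye_swap_coding(self):
        sheet = _sheet(dyes=["standard", "standard", "swapped", "swapped"])
        d = build_design_matrix(sheet, "dye_swap")
        assert d.X.tolist() == [[1, 1], [1, 1], [1, -1], [1, -1]]

    def test_rank_deficiency_rejected(self):
        X = np.ones((4, 2))
        with pytest.raises(ValueError, match="rank deficient"):
            DesignMatrix(X, ["c1", "c2"], [f"a{i}" for i in range(4)])

    def test_mixed_materials_rejected(self):
        sheet = _sheet(mixes=[0.5, 0.5])
        sheet.loc[1, "material"] = "cDNA"
        with pytest.raises(ValueError, match="materials"):
            build_design_matrix(sheet, "per_mixture")


class TestOLSFit:
    def test_exact_linear_data_has_zero_residuals(self, rng):
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        beta = rng.normal(0, 1, (10, 2))
        fit = _fit(beta @ X.T, X)
        assert np.allclose(fit.coefficients, beta, atol=1e-10)
        assert np.allclose(fit.sigma, 0.0, atol=1e-10)

    def test_intercept_model_closed_form(self, rng):
        Y = rng.normal(2, 1, (20, 7))
        fit = _fit(Y, np.ones((7, 1)))
        assert np.allclose(fit.coefficients[:, 0], Y.mean(axis=1))
        assert np.allclose(fit.sigma ** 2, Y.var(axis=1, ddof=1))

    def test_agrees_with_normal_equations(self, rng):
        for _ in range(5):
            X = rng.normal(0, 1, (8, 3))
            Y = rng.normal(0, 1, (15, 8))
            fit = _fit(Y, X)
            beta = np.linalg.solve(X.T @ X, X.T @ Y.T).T
            assert np.abs(fit.coefficients - beta).max() < 1e-10

    def test_missing_arrays_row_dropped(self, rng):
        X = np.ones((5, 1))
        Y = rng.normal(0, 1, (4, 5))
        Y[0, 2] = np.nan
        fit = _fit(Y, X)
        assert fit.df_residual[0] == 3
        assert fit.coefficients[0, 0] == pytest.approx(np.nanmean(Y[0]))

    def test_zero_residual_df_keeps_fit_without_sigma(self, rng):
        fit = _fit(rng.normal(0, 1, (4, 2)), np.column_stack([np.ones(2), [0.0, 1.0]]))
        assert np.isnan(fit.sigma).all()
        assert np.isfinite(fit.coefficients).all()


class TestContrasts:
    def test_identity_contrast_is_noop(self, rng):
        fit = _fit(rng.normal(0, 1, (6, 6)), np.column_stack([np.ones(6), np.arange(6.0)]))
        out = apply_contrasts(fit, np.eye(2), ["b0", "b1"])
        assert np.allclose(out.coefficients, fit.coefficients)
        assert np.allclose(out.unscaled_cov, fit.unscaled_cov)

    def test_zero_column_rejected(self, rng):
        fit = _fit(rng.normal(0, 1, (6, 6)), np.column_stack([np.ones(6), np.arange(6.0)]))
        with pytest.raises(ValueError, match="zero"):
            apply_contrasts(fit, np.array([[0.0], [0.0]]), ["null"])

    def test_baseline_contrast_recovers_noise_free_imbalance(self, ab_pair):
        props = (0.36, 0.5, 0.64)
        cfg = clean_config(mixture_proportions=props, n_replicates=2)
        beads, sheet, _ = aa.simulate_mixture_experiment(cfg, ab_pair)
        summary = aa.summarize_array(beads)
        design = build_design_matrix(sheet, "per_mixture")
        fit = fit_snp_models(pivot_m_matrix(summary), design)
        C, labels = make_baseline_contrasts(design.columns, "mix_050")
        out = apply_contrasts(fit, C, labels)
        for li, p in zip((0, 1), (0.36, 0.64)):
            assert np.allclose(out.coefficients[:, li], np.log2(p / (1 - p)), atol=1e-10)


class TestModeration:
    def test_matches_limma_reference(self, rng, tmp_path):
        """Moderated t, log-odds and hyperparameters agree with the R
        reference implementation of the shrinkage procedure (limma)."""
        G, N = 80, 6
        sigma = np.sqrt(3 * 0.04 / rng.chisquare(3, G))
        Y = rng.normal(0, 0.4, G)[:, None] + rng.normal(0, 1, (G, N)) * sigma[:, None]
        m_path = tmp_path / "m.tsv"
        pd.DataFrame(Y).to_csv(m_path, sep="\t", index=False)
        r_out = tmp_path / "r.tsv"
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            Y <- as.matrix(read.delim('{m_path}'))
            fit <- eBayes(lmFit(Y, design=matrix(1, ncol(Y), 1)), proportion=0.01)
            write.table(data.frame(t=fit$t[,1], lods=fit$lods[,1],
                                   d0=fit$df.prior, s20=fit$s2.prior),
                        '{r_out}', sep='\\t', row.names=FALSE)
        """)
        res = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        assert res.returncode == 0, res.stderr
        ref = pd.read_csv(r_out, sep="\t")

        fit = _fit(Y, np.ones((N, 1)))
        mod = empirical_bayes_moderate(fit, proportion=0.01)
        assert mod.df_prior == pytest.approx(ref["d0"].iloc[0], rel=1e-8)
        assert mod.s2_prior == pytest.approx(ref["s20"].iloc[0], rel=1e-8)
        assert np.abs(mod.t[:, 0] - ref["t"]).max() < 1e-8
        assert np.abs(mod.log_odds[:, 0] - ref["lods"]).max() < 1e-8

    def test_no_shrinkage_limit_recovers_ordinary_t(self, rng):
        fit = _fit(rng.normal(0, 1, (50, 6)), np.ones((6, 1)))
        mod = empirical_bayes_moderate(fit, prior_df=0.0, prior_var=1.0)
        ordinary = fit.coefficients[:, 0] / (fit.unscaled_se[:, 0] * fit.sigma)
        assert np.allclose(mod.t[:, 0], ordinary)

    def test_full_pooling_limit_uses_prior_variance_only(self, rng):
        fit = _fit(rng.normal(0, 1, (50, 6)), np.ones((6, 1)))
        mod = empirical_bayes_moderate(fit, prior_df=np.inf, prior_var=0.25)
        pooled = fit.coefficients[:, 0] / (fit.unscaled_se[:, 0] * 0.5)
        assert np.allclose(mod.t[:, 0], pooled)

    def test_shrinkage_bound_and_monotonicity(self, rng):
        fit = _fit(rng.normal(0, 1, (300, 5)) * rng.lognormal(0, 1, 300)[:, None],
                   np.ones((5, 1)))
        mod = empirical_bayes_moderate(fit)
        s2 = fit.sigma ** 2
        lo = np.minimum(s2, mod.s2_prior)
        hi = np.maximum(s2, mod.s2_prior)
        assert ((mod.s2_post >= lo - 1e-12) & (mod.s2_post <= hi + 1e-12)).all()
        order = np.argsort(s2)
        assert (np.diff(mod.s2_post[order]) >= -1e-12).all()

    def test_degenerate_zero_variance_prior_rejected(self):
        Y = np.tile([1.0, 1.0, 1.0, 1.0], (20, 1))
        fit = _fit(Y, np.ones((4, 1)))
        with pytest.raises(ValueError, match="degenerate"):
            empirical_bayes_moderate(fit)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(deadline=None, max_examples=10)
    def test_squeeze_stays_between_prior_and_sample(self, seed):
        r = np.random.default_rng(seed)
        s2 = r.lognormal(0, 1, 50)
        df = r.integers(1, 10, 50).astype(float)
        d0, s20 = fit_f_dist(s2, df)
        post = squeeze_variances(s2, df, d0, s20)
        assert ((post >= np.minimum(s2, s20) - 1e-9) &
                (post <= np.maximum(s2, s20) + 1e-9)).all()


class TestDyeEffects:
    def test_zero_bias_noise_free_intercepts_are_zero(self):
        cfg = clean_config(n_snps=12, n_replicates=2, nonspecific_scale=1.0, seed=51)
        beads, sheet, _ = aa.simulate_dye_swap_experiment(cfg)
        per_snp, trend = estimate_dye_effects(aa.summarize_array(beads), sheet)
        assert np.allclose(per_snp["dye_effect"], 0.0, atol=1e-9)

    def test_recovers_injected_intensity_dependent_bias(self):
        cfg = aa.SimConfig(n_snps=2000, n_replicates=4, seed=53,
                           dye_bias_slope=0.2, dye_bias_intercept=-0.5)
        beads, sheet, manifest = aa.simulate_dye_swap_experiment(cfg)
        summary = aa.summarize_array(beads, use_background=True)
        per_snp, trend = estimate_dye_effects(summary, sheet)
        merged = per_snp.merge(manifest, on="snp_id")
        r = np.corrcoef(merged["dye_effect"], merged["injected_bias"])[0, 1]
        assert r > 0.9
        assert trend["trend_slope"] == pytest.approx(0.2, abs=0.05)

    def test_normalization_shrinks_dye_effects(self):
        cfg = aa.SimConfig(n_snps=600, n_replicates=2, seed=57,
                           dye_bias_slope=0.2, dye_bias_intercept=-0.5)
        res = aa.run_dye_swap_analysis(cfg, materials=("gDNA",))
        eff = res["effects"]
        before = eff.loc[~eff["normalized"], "dye_effect"].abs().mean()
        after = eff.loc[eff["normalized"], "dye_effect"].abs().mean()
        assert after < before
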