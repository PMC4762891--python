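import numpy as np
import pandas as pd
import pytest

from sexde.de import (
    DesignSpec,
    build_design,
    call_sex_de,
    ebayes_moderate,
    estimate_consensus_correlation,
    estimate_variance_prior,
    fit_gene_models,
    impute_missing_covariates,
    run_de,
)
from sexde.exceptions import ParameterError
from sexde.io import ExpressionMatrix, SampleTable
from sexde.simulate import SimConfig, generate_cohort

from conftest import toy_matrix, toy_samples
from oracles import gls_oracle


class TestImputation:
    def make(self, pmi):
        return toy_samples({
            "sample": ["a1", "a2", "a3", "b1"],
            "sex": ["male", "male", "male", "female"],
            "subject": ["A", "A", "A", "B"],
            "PMI": pmi,
            "pH": [6.5, 6.5, 6.5, 6.5],
        })

    def test_subject_mean_substitution(self):
        out, report = impute_missing_covariates(self.make([10.0, np.nan, 14.0, 9.0]))
        assert out.data.loc["a2", "PMI"] == pytest.approx(12.0)
        assert report == []

    def test_no_missing_is_identity(self):
        s = self.make([10.0, 11.0, 14.0, 9.0])
        out, report = impute_missing_covariates(s)
        pd.testing.assert_frame_equal(out.data, s.data)
        assert report == []

    def test_all_missing_subject_gets_cohort_mean_with_report(self):
        out, report = impute_missing_covariates(self.make([10.0, 12.0, 14.0, np.nan]))
        assert out.data.loc["b1", "PMI"] == pytest.approx(12.0)  # cohort mean
        assert report == [{"covariate": "PMI", "subject": "B", "value": 12.0}]

    def test_covariate_missing_for_whole_cohort_rejected(self):
        with pytest.raises(ParameterError, match="PMI"):
            impute_missing_covariates(self.make([np.nan] * 4))


def cohort_samples(n_subj_per_sex, n_per_subj):
    rows = {"sample": [], "sex": [], "subject": []}
    for sex, tag in (("male", "M"), ("female", "F")):
        for s in range(n_subj_per_sex):
            for r in range(n_per_subj):
                rows["sample"].append(f"{tag}{s}_{r}")
                rows["sex"].append(sex)
                rows["subject"].append(f"{tag}{s}")
    return toy_samples(rows)


class TestConsensusCorrelation:
    def test_recovers_zero_rho(self):
        cfg = SimConfig(n_subjects_per_sex=5, n_regions_per_subject=4, n_genes=2000,
                        rho_subject=0.0, covariate_effect_scale=0.0,
                        n_sexchrom_female_marker=0, n_sexchrom_male_marker=0, seed=31)
        cohort = generate_cohort(cfg)
        rho = estimate_consensus_correlation(cohort.expression, DesignSpec(), cohort.samples)
        assert abs(rho) < 0.05

    def test_recovers_rho_half(self):
        cfg = SimConfig(n_subjects_per_sex=5, n_regions_per_subject=4, n_genes=2000,
                        rho_subject=0.5, covariate_effect_scale=0.0,
                        n_sexchrom_female_marker=0, n_sexchrom_male_marker=0, seed=37)
        cohort = generate_cohort(cfg)
        rho = estimate_consensus_correlation(cohort.expression, DesignSpec(), cohort.samples)
        assert abs(rho - 0.5) < 0.1

    def test_no_repeated_samples_returns_zero(self):
        samples = cohort_samples(4, 1)
        m = toy_matrix(np.random.default_rng(0).normal(size=(20, 8)),
                       samples=samples.sample_ids)
        assert estimate_consensus_correlation(m, DesignSpec(), samples) == 0.0

    def test_matches_statsmodels_mixedlm_on_single_gene(self):
        # independent mixed-model oracle: REML intraclass correlation
        import statsmodels.api as sm

        rng = np.random.default_rng(41)
        samples = cohort_samples(6, 4)
        n = len(samples.sample_ids)
        subj_codes = pd.factorize(samples.subject.to_numpy())[0]
        y = (rng.normal(0, np.sqrt(0.6), size=subj_codes.max() + 1)[subj_codes]
             + rng.normal(0, np.sqrt(0.4), size=n))
        m = toy_matrix(y[None, :], samples=samples.sample_ids)
        X, _ = build_design(samples, DesignSpec())
        fit = sm.MixedLM(y, X, groups=subj_codes).fit(reml=True)
        tau2 = float(np.asarray(fit.cov_re)[0, 0])
        rho_sm = tau2 / (tau2 + fit.scale)
        rho = estimate_consensus_correlation(m, DesignSpec(), samples)
        assert rho == pytest.approx(rho_sm, abs=0.01)


class TestGeneModels:
    def test_rho_zero_equals_ols(self):
        rng = np.random.default_rng(2)
        samples = cohort_samples(4, 3)
        Y = rng.normal(size=(30, len(samples.sample_ids)))
        m = toy_matrix(Y, samples=samples.sample_ids)
        fits = fit_gene_models(m, DesignSpec(), samples, rho=0.0)
        X, names = build_design(samples, DesignSpec())
        beta_ols, _, _, _ = np.linalg.lstsq(X, Y.T, rcond=None)
        np.testing.assert_allclose(fits["log2FD"], beta_ols[names.index("sex_male")],
                                   atol=1e-8)

    def test_gene_equal_to_sex_indicator_fits_perfectly(self):
        samples = cohort_samples(3, 2)
        male = (samples.sex == "male").to_numpy(float)
        m = toy_matrix(male[None, :], samples=samples.sample_ids)
        fits = fit_gene_models(m, DesignSpec(), samples, rho=0.0)
        assert fits["log2FD"].iloc[0] == pytest.approx(1.0, abs=1e-10)
        assert fits["s2"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_explicit_whitening_oracle_at_rho_half(self):
        rng = np.random.default_rng(3)
        samples = cohort_samples(3, 3)
        n = len(samples.sample_ids)
        y = rng.normal(size=n)
        m = toy_matrix(y[None, :], samples=samples.sample_ids)
        rho = 0.5
        subj = samples.subject.to_numpy()
        V = np.where(subj[:, None] == subj[None, :], rho, 0.0)
        np.fill_diagonal(V, 1.0)
        X, names = build_design(samples, DesignSpec())
        beta, cov_unit, s2 = gls_oracle(y, X, V)
        fits = fit_gene_models(m, DesignSpec(), samples, rho=rho)
        six = names.index("sex_male")
        assert fits["log2FD"].iloc[0] == pytest.approx(beta[six], abs=1e-10)
        assert fits["s2"].iloc[0] == pytest.approx(s2, abs=1e-10)
        assert fits["unit_se"].iloc[0] == pytest.approx(np.sqrt(cov_unit[six, six]), abs=1e-10)

    def test_collinear_design_names_columns(self):
        samples = cohort_samples(3, 2)
        df = samples.data.copy()
        df["age"] = 20.0  # constant: collinear with intercept
        samples = SampleTable(df)
        m = toy_matrix(np.zeros((2, len(df))), samples=list(df.index))
        with pytest.raises(ParameterError, match="age|intercept"):
            fit_gene_models(m, DesignSpec(covariates=["age"]), samples, rho=0.0)


class TestEBayes:
    def simulate_fits(self, n_genes=20000, d0=4.0, s0=0.05, dg=20, seed=13):
        rng = np.random.default_rng(seed)
        true_var = d0 * s0 / rng.chisquare(d0, n_genes)
        s2 = true_var * rng.chisquare(dg, n_genes) / dg
        return s2, np.full(n_genes, float(dg))

    def test_hyperparameter_recovery(self):
        s2, df = self.simulate_fits()
        d0_hat, s0_hat = estimate_variance_prior(s2, df)
        assert 3.0 <= d0_hat <= 5.5
        assert 0.045 <= s0_hat <= 0.055

    def test_equal_variances_give_infinite_d0(self):
        s2 = np.full(100, 0.05)
        d0_hat, s0_hat = estimate_variance_prior(s2, np.full(100, 20.0))
        assert np.isinf(d0_hat)
        # the log-scale bias correction keeps a small digamma offset here
        assert s0_hat == pytest.approx(0.05, rel=0.1)

    def test_moderated_variance_between_gene_and_prior(self):
        rng = np.random.default_rng(7)
        s2, df = self.simulate_fits(n_genes=500, seed=7)
        fits = pd.DataFrame({
            "log2FD": rng.normal(size=500), "unit_se": 0.2, "stderr": 0.2 * np.sqrt(s2),
            "s2": s2, "df_resid": df, "mean_expr": 5.0,
        }, index=[f"g{i}" for i in range(500)])
        table, params = ebayes_moderate(fits)
        lo = np.minimum(s2, params.s0_sq)
        hi = np.maximum(s2, params.s0_sq)
        inner = s2 != params.s0_sq
        assert (table["s2_post"].to_numpy()[inner] > lo[inner]).all()
        assert (table["s2_post"].to_numpy()[inner] < hi[inner]).all()

    def test_infinite_d0_moderation_uses_prior_variance(self):
        fits = pd.DataFrame({
            "log2FD": np.linspace(-1, 1, 50), "unit_se": 0.3,
            "stderr": 0.3 * np.sqrt(0.05), "s2": np.full(50, 0.05),
            "df_resid": np.full(50, 10.0), "mean_expr": 5.0,
        }, index=[f"g{i}" for i in range(50)])
        table, params = ebayes_moderate(fits)
        assert np.isinf(params.d0)
        np.testing.assert_allclose(table["s2_post"], params.s0_sq, rtol=1e-9)
        # with d0 = inf the t reference is effectively normal
        from scipy.stats import norm
        expected = 2 * norm.sf(np.abs(table["t"]))
        np.testing.assert_allclose(table["p"], expected, atol=1e-9)

    def test_bh_is_monotone_step_up(self):
        rng = np.random.default_rng(11)
        s2, df = self.simulate_fits(n_genes=200, seed=11)
        fits = pd.DataFrame({
            "log2FD": rng.normal(scale=0.3, size=200), "unit_se": 0.2,
            "stderr": 0.2 * np.sqrt(s2), "s2": s2, "df_resid": df, "mean_expr": 5.0,
        }, index=[f"g{i}" for i in range(200)])
        table, _ = ebayes_moderate(fits)
        from oracles import bh_stepup_oracle
        np.testing.assert_allclose(table["p_bh"], bh_stepup_oracle(table["p"].to_numpy()),
                                   atol=1e-12)
        assert (table["p_bh"] >= table["p"] - 1e-15).all()


class TestSexDECalls:
    def make_table(self, log2fd, p):
        return pd.DataFrame({
            "log2FD": log2fd, "FD": np.exp2(log2fd), "t": 0.0, "p": p,
            "p_bh": p, "mean_expr": 5.0,
        }, index=[f"g{i}" for i in range(len(p))])

    def test_tier_thresholds(self):
        fd = np.log2([1.25, 1.19, 1.0, 1 / 1.3])
        p = np.array([0.03, 1e-10, 0.001, 0.004])
        out = call_sex_de(self.make_table(fd, p))
        # FD=1.25, p=0.03: male-DE at 0.05 only
        assert out.loc["g0", "de_0.05"] == "male-DE"
        assert out.loc["g0", "de_0.01"] == ""
        # FD=1.19 never passes the fold threshold, however small p is
        assert (out.loc["g1", ["de_0.005", "de_0.01", "de_0.05"]] == "").all()
        # log2FD = 0: no direction at all
        assert out.loc["g2", "direction"] == ""
        # female-higher below the reciprocal threshold at all tiers
        assert (out.loc["g3", ["de_0.005", "de_0.01", "de_0.05"]] == "female-DE").all()

    def test_tiers_are_nested(self):
        rng = np.random.default_rng(19)
        fd = rng.normal(scale=0.5, size=300)
        p = rng.uniform(size=300)
        out = call_sex_de(self.make_table(fd, p))
        strict = out["de_0.005"] != ""
        mid = out["de_0.01"] != ""
        loose = out["de_0.05"] != ""
        assert (~strict | mid).all() and (~mid | loose).all()

    def test_fd_threshold_must_exceed_one(self):
        with pytest.raises(ParameterError):
            call_sex_de(self.make_table(np.zeros(2), np.ones(2)), fd_threshold=0.9)


class TestRunDE:
    def test_planted_fd_sign_and_recovery(self, planted_cohort):
        table, params = run_de(planted_cohort.expression, planted_cohort.samples,
                               covariates=["RIN", "age", "PMI", "lobe", "pH"])
        planted = planted_cohort.gene_sets.genes_of("planted")
        med = table.loc[planted, "log2FD"].median()
        assert med > 0
        assert abs(med - np.log2(1.3)) < 0.05
        assert 0.0 < params.rho < 0.6
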