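"""Joint haplotype-score fits, orthogonal polynomials, observational models."""

import numpy as np
import pandas as pd
import pytest

from duomr import (
    ModelSpec,
    SimulationConfig,
    fit_haplotype_model,
    fit_phenotype_association,
    orthogonal_polynomials,
    simulate_study,
)


class TestOrthogonalPolynomials:
    def test_orthogonality_means_and_norms(self):
        B = orthogonal_polynomials(np.arange(1.0, 11.0), degree=3)
        assert B.shape == (10, 3)
        gram = B.T @ B
        assert np.all(np.abs(gram - np.eye(3)) < 1e-10)
        assert np.all(np.abs(B.mean(axis=0)) < 1e-12)

    def test_degree_one_column_proportional_to_centered_input(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        B = orthogonal_polynomials(x, degree=2)
        c = x - x.mean()
        ratio = B[:, 0] / c
        assert np.all(np.abs(ratio - ratio[0]) < 1e-12)
        assert ratio[0] > 0  # sign convention: follows x

    def test_exact_cubic_recovered_with_zero_residual(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(250, 300, 200)
        y = 2.0 - 0.3 * x + 0.01 * x**2 - 1e-4 * x**3
        B = orthogonal_polynomials(x, degree=3)
        X = np.column_stack([np.ones_like(x), B])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        assert float(resid @ resid) < 1e-16 * float(y @ y)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            orthogonal_polynomials(np.full(10, 7.0), degree=3)


def _study(**kw):
    defaults = dict(n_pregnancies=8000, n_snps=40, fetal_drive_effect=0.0,
                    confounding_gest=0.0, seed=31)
    defaults.update(kw)
    return simulate_study(SimulationConfig(**defaults))


class TestHaplotypeModel:
    def test_maternal_only_simulation(self):
        s = _study(fetal_effect_per_score=0.0, maternal_effect=-0.8,
                   instrument_r2=0.1)
        fit = fit_haplotype_model(
            s.scores, s.phenotypes, ModelSpec(outcome="gestational_days")
        )
        truth_h2 = s.truth["beta_MY_gest"]
        assert abs(fit.beta[1] - truth_h2) < 3 * fit.se[1]
        assert abs(fit.beta[2]) < 3 * fit.se[2]  # no fetal path

    def test_fetal_only_simulation(self):
        s = _study(maternal_effect=0.0, fetal_effect_per_score=-0.6, seed=32)
        fit = fit_haplotype_model(
            s.scores, s.phenotypes, ModelSpec(outcome="gestational_days")
        )
        assert abs(fit.beta[2] - (-0.6)) < 3 * fit.se[2]
        assert abs(fit.beta[1]) < 3 * fit.se[1]  # no maternal path

    def test_matches_normal_equations(self, base_study):
        spec = ModelSpec(outcome="birth_weight")
        fit = fit_haplotype_model(base_study.scores, base_study.phenotypes, spec)
        df = base_study.scores.merge(base_study.phenotypes, on="pregnancy_id")
        B = orthogonal_polynomials(df["gestational_days"].to_numpy(), 3)
        X = np.column_stack(
            [
                np.ones(len(df)),
                df[["S_h1", "S_h2", "S_h3", "maternal_age", "fetal_sex"]],
                B,
            ]
        )
        y = df["birth_weight"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.beta, beta[1:4], atol=1e-8)

    def test_invariance_to_row_order_and_covariate_scaling(self, base_study):
        spec = ModelSpec(outcome="gestational_days")
        fit = fit_haplotype_model(base_study.scores, base_study.phenotypes, spec)
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(base_study.scores))
        fit_p = fit_haplotype_model(
            base_study.scores.iloc[perm].reset_index(drop=True),
            base_study.phenotypes,
            spec,
        )
        np.testing.assert_allclose(fit.beta, fit_p.beta, atol=1e-8)
        ph = base_study.phenotypes.copy()
        ph["maternal_age"] = ph["maternal_age"] * 12.0 + 7.0  # affine rescale
        fit_s = fit_haplotype_model(base_study.scores, ph, spec)
        np.testing.assert_allclose(fit.beta, fit_s.beta, atol=1e-8)
        np.testing.assert_allclose(fit.cov, fit_s.cov, atol=1e-8)

    def test_logistic_preterm_fit(self, base_study):
        spec = ModelSpec(outcome="preterm")
        fit = fit_haplotype_model(base_study.scores, base_study.phenotypes, spec)
        assert fit.family == "logistic"
        assert fit.cov.shape == (3, 3)
        assert np.all(fit.se > 0)

    def test_perfect_separation_raises(self, base_study):
        ph = base_study.phenotypes.copy()
        sep = base_study.scores["S_h1"] > base_study.scores["S_h1"].median()
        ph["preterm"] = sep.astype(int).to_numpy()
        ph["gestational_days"] = np.where(ph["preterm"], 250.0, 280.0)
        with pytest.raises(ValueError, match="logistic"):
            fit_haplotype_model(
                base_study.scores, ph, ModelSpec(outcome="preterm", covariates=())
            )

    def test_collinear_scores_raise(self, base_study):
        sc = base_study.scores.copy()
        sc["S_h3"] = sc["S_h1"]
        with pytest.raises(ValueError, match="ollinear|constant"):
            fit_haplotype_model(
                sc, base_study.phenotypes, ModelSpec(outcome="gestational_days")
            )

    def test_small_sample_raises(self, base_study):
        with pytest.raises(ValueError, match="100"):
            fit_haplotype_model(
                base_study.scores.head(50),
                base_study.phenotypes,
                ModelSpec(outcome="gestational_days"),
            )

    def test_per_dataset_fitting(self):
        s = _study(n_datasets=3)
        fits = fit_haplotype_model(
            s.scores, s.phenotypes, ModelSpec(outcome="gestational_days"),
            per_dataset=True,
        )
        assert sorted(fits) == ["D1", "D2", "D3"]
        assert sum(f.n_used for f in fits.values()) == 8000

    def test_permuted_outcome_type_i_error_calibrated(self):
        s = _study(n_pregnancies=600, n_snps=30, seed=33)
        spec = ModelSpec(outcome="gestational_days", covariates=())
        rng = np.random.default_rng(99)
        ph = s.phenotypes
        n_rep = 1000
        rejections = np.zeros(3)
        for _ in range(n_rep):
            shuffled = ph.copy()
            shuffled["gestational_days"] = rng.permutation(
                ph["gestational_days"].to_numpy()
            )
            fit = fit_haplotype_model(s.scores, shuffled, spec)
            rejections += fit.p < 0.05
        rates = rejections / n_rep
        assert np.all((rates > 0.035) & (rates < 0.065))


class TestPhenotypeAssociation:
    def test_recovers_total_observational_slope(self):
        s = _study(confounding_gest=0.36, instrument_r2=0.02, seed=34)
        res = fit_phenotype_association(
            s.phenotypes, "sbp", ModelSpec(outcome="gestational_days")
        )
        # total slope = causal + confounding * Var(e_env)/Var(X)
        cfg = s.config
        expect = cfg.maternal_effect + cfg.confounding_gest * (
            1 - cfg.instrument_r2
        )
        assert abs(res.beta - expect) < 3.5 * res.se

    def test_null_exposure_has_null_slope(self, base_study):
        res = fit_phenotype_association(
            base_study.phenotypes, "maternal_bmi",
            ModelSpec(outcome="gestational_days"),
        )
        assert abs(res.beta) < 3 * res.se

    def test_gestation_adjustment_moves_birthweight_slope_as_planted(self):
        # X lowers gestation (maternal_effect < 0) and gestation raises
        # birth weight, so adjusting for gestation must *raise* the slope
        s = _study(maternal_effect=-0.8, instrument_r2=0.1, seed=35)
        adj = fit_phenotype_association(
            s.phenotypes, "sbp",
            ModelSpec(outcome="birth_weight", gestation_adjust=True),
        )
        raw = fit_phenotype_association(
            s.phenotypes, "sbp",
            ModelSpec(outcome="birth_weight", gestation_adjust=False),
        )
        assert adj.beta > raw.beta
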