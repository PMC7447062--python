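"""Contrast estimators, Wald ratio and TSLS causal estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_fit
from duomr import (
    ModelSpec,
    SimulationConfig,
    TraitMeta,
    contrast,
    fit_haplotype_model,
    ratio_causal,
    score_trait_regression,
    simulate_study,
    tsls,
)
from duomr.effects import EffectEstimate
from duomr.simulate import simulate_transmission


class TestContrast:
    def test_fetal_contrast_matches_published_bp_birthweight_row(self):
        fit = make_fit([-6.8, -3.1, -5.9])
        assert contrast(fit, "fetal").estimate == pytest.approx(-4.8, abs=1e-12)

    def test_maternal_contrast_matches_published_bp_gestation_row(self):
        fit = make_fit([-0.22, -0.035, -0.016])
        assert contrast(fit, "maternal").estimate == pytest.approx(
            -0.1195, abs=1e-12
        )

    @given(
        st.tuples(*[st.floats(-100, 100) for _ in range(3)]),
    )
    def test_contrasts_sum_to_transmitted_effect(self, betas):
        fit = make_fit(betas)
        my = contrast(fit, "maternal").estimate
        fy = contrast(fit, "fetal").estimate
        assert my + fy == pytest.approx(fit.beta[0], abs=1e-10)

    def test_variance_uses_full_covariance(self):
        cov = np.array([[1.0, 0.5, 0.2], [0.5, 2.0, 0.1], [0.2, 0.1, 3.0]])
        fit = make_fit([1.0, 2.0, 3.0], cov)
        c = np.array([0.5, 0.5, -0.5])
        assert contrast(fit, "maternal").se == pytest.approx(
            np.sqrt(c @ cov @ c), abs=1e-12
        )

    def test_missing_covariance_rejected(self):
        fit = make_fit([1, 2, 3])
        fit.cov = None
        with pytest.raises(ValueError):
            contrast(fit, "maternal")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            contrast(make_fit([0, 0, 0]), "paternal")


class TestRatio:
    def test_fetal_growth_on_gestation_published_values(self):
        est = ratio_causal(
            (-0.0099, 0.0026),
            (1.3, 0.087),
            TraitMeta(name="fetal_growth", sd=426.0),
        )
        assert est.per_sd == pytest.approx(-3.244, abs=5e-3)

    def test_fetal_growth_on_sbp_published_values(self):
        est = ratio_causal(
            (0.0043, 0.0019),
            (1.3, 0.087),
            TraitMeta(name="fetal_growth", sd=426.0),
        )
        assert est.per_sd == pytest.approx(1.409, abs=5e-3)

    def test_zero_numerator(self):
        est = ratio_causal((0.0, 0.2), (2.0, 0.1))
        assert est.estimate == 0.0
        assert est.se == pytest.approx(0.2 / 2.0, abs=1e-12)

    def test_per_sd_scaling_and_ci(self):
        est = ratio_causal((1.0, 0.1), (2.0, 0.01), TraitMeta(name="x", sd=5.0))
        assert est.per_sd == pytest.approx(est.estimate * 5.0, abs=1e-12)
        assert est.ci95[0] < est.estimate < est.ci95[1]

    def test_weak_instrument_flag_and_strict_mode(self):
        est = ratio_causal((1.0, 0.1), (0.2, 0.1))
        assert est.weak_instrument
        with pytest.raises(ValueError, match="weak"):
            ratio_causal((1.0, 0.1), (0.2, 0.1), strict=True)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            ratio_causal((1.0, 0.1), (0.0, 0.1))


def _confounded_frame(n=5000, causal=2.0, seed=0):
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    u = rng.normal(size=n)  # unobserved confounder
    x = 0.8 * z + u + rng.normal(size=n)
    y = causal * x + 3.0 * u + rng.normal(size=n)
    return pd.DataFrame({"y": y, "x": x, "z": z})


class TestTsls:
    def test_recovers_causal_effect_under_confounding(self):
        df = _confounded_frame()
        est = tsls(df, "y", "x", "z")
        assert abs(est.estimate - 2.0) < 3 * est.se
        ols = np.polyfit(df.x, df.y, 1)[0]
        assert abs(ols - 2.0) > 10 * est.se  # OLS is visibly biased

    def test_null_causal_effect(self):
        df = _confounded_frame(causal=0.0, seed=1)
        est = tsls(df, "y", "x", "z")
        assert abs(est.estimate) < 3 * est.se

    def test_agrees_with_ratio_on_same_data(self):
        cfg = SimulationConfig(n_pregnancies=8000, n_snps=40, seed=41,
                               fetal_drive_effect=0.0, instrument_r2=0.1)
        s = simulate_study(cfg)
        merged = s.scores.merge(s.phenotypes, on="pregnancy_id")
        t = tsls(merged, "gestational_days", "sbp", "S_h2")
        num = score_trait_regression(
            s.scores, s.phenotypes, "gestational_days", score="S_h2"
        )
        den = score_trait_regression(s.scores, s.phenotypes, "sbp", score="S_h2")
        r = ratio_causal((num.beta, num.se), den)
        assert abs(t.estimate - r.estimate) < max(t.se, r.se)

    def test_weak_instrument_flagged_via_stage1_f(self):
        rng = np.random.default_rng(2)
        n = 500
        df = pd.DataFrame(
            {
                "z": rng.normal(size=n),
                "x": rng.normal(size=n),
            }
        )
        df["y"] = df.x + rng.normal(size=n)
        est = tsls(df, "y", "x", "z")
        assert est.weak_instrument and est.stage1_f < 10


class TestSimulationLevelProperties:
    def test_contrast_se_matches_bootstrap(self):
        cfg = SimulationConfig(n_pregnancies=5000, n_snps=40, seed=43,
                               fetal_drive_effect=0.0)
        s = simulate_study(cfg)
        fit = fit_haplotype_model(
            s.scores, s.phenotypes, ModelSpec(outcome="gestational_days")
        )
        my = contrast(fit, "maternal")
        df = s.scores.merge(s.phenotypes, on="pregnancy_id")
        X = np.column_stack(
            [
                np.ones(len(df)),
                df[["S_h1", "S_h2", "S_h3", "maternal_age", "fetal_sex"]],
            ]
        )
        y = df["gestational_days"].to_numpy()
        rng = np.random.default_rng(7)
        c = np.array([0.0, 0.5, 0.5, -0.5, 0.0, 0.0])
        boots = np.empty(500)
        for b in range(500):
            idx = rng.integers(0, len(y), len(y))
            beta = np.linalg.solve(X[idx].T @ X[idx], X[idx].T @ y[idx])
            boots[b] = c @ beta
        assert abs(boots.std(ddof=1) - my.se) / my.se < 0.15

    def test_maternal_effect_invariant_to_transmission_relabelling(self):
        # with no fetal path, phenotypes do not depend on which maternal
        # haplotype was transmitted; re-drawing the transmission must leave
        # the maternal-effect estimate unchanged up to sampling noise
        cfg = SimulationConfig(
            n_pregnancies=6000, n_snps=40, seed=44,
            fetal_effect_per_score=0.0, fetal_effect_bw_per_score=0.0,
            fetal_drive_effect=0.0,
        )
        s = simulate_study(cfg)
        spec = ModelSpec(outcome="gestational_days")
        fit1 = fit_haplotype_model(s.scores, s.phenotypes, spec)
        hap2, _ = simulate_transmission(s.parents, 4242)
        from duomr import compute_scores

        sc2 = compute_scores(hap2, s.parents.weights)
        fit2 = fit_haplotype_model(sc2, s.phenotypes, spec)
        my1, my2 = contrast(fit1, "maternal"), contrast(fit2, "maternal")
        assert abs(my1.estimate - my2.estimate) < 2 * np.hypot(my1.se, my2.se)


def test_effect_estimate_requires_positive_se():
    with pytest.raises(ValueError):
        EffectEstimate(kind="maternal", estimate=1.0, se=0.0, p=0.5)
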