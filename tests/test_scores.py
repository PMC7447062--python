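"""Haplotype resolution policies and score construction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from duomr import SimulationConfig, simulate_study
from duomr.io import PhasedDuos, VariantWeight
from duomr.scores import (
    DuoHaplotypes,
    compute_scores,
    resolve_haplotypes,
    score_trait_regression,
)


def duos_from(mother_pairs, child_pairs):
    mother = np.array(mother_pairs, dtype=np.int8)[None, :, :]
    child = np.array(child_pairs, dtype=np.int8)[None, :, :]
    vids = [f"v{i}" for i in range(mother.shape[1])]
    return PhasedDuos(["P1"], vids, mother, child)


class TestResolve:
    @pytest.mark.parametrize("policy", ["trust-phase", "mendelian-resolve"])
    def test_forced_cases(self, policy):
        # mother hom effect, child het (maternal allele 1): h=(1,1,0)
        # mother het, child hom other: h=(0,1,0)
        duos = duos_from([(1, 1), (1, 0)], [(1, 0), (0, 0)])
        hap = resolve_haplotypes(duos, policy=policy)
        assert (hap.h1[0, 0], hap.h2[0, 0], hap.h3[0, 0]) == (1, 1, 0)
        assert (hap.h1[0, 1], hap.h2[0, 1], hap.h3[0, 1]) == (0, 1, 0)

    def test_double_heterozygote_ambiguity_policy(self):
        duos = duos_from([(0, 1)], [(1, 0)])
        hap = resolve_haplotypes(duos, policy="mendelian-resolve")
        assert (hap.h1[0, 0], hap.h2[0, 0], hap.h3[0, 0]) == (0.5, 0.5, 0.5)
        assert hap.ambiguous[0, 0]
        # trust-phase uses the declared phase instead: (1, 0, 0)
        hap2 = resolve_haplotypes(duos, policy="trust-phase")
        assert (hap2.h1[0, 0], hap2.h2[0, 0], hap2.h3[0, 0]) == (1, 0, 0)
        assert not hap2.ambiguous.any()

    def test_mendelian_inconsistency_nulled_and_duo_rejected(self):
        # child claims maternal effect allele but mother carries none
        bad = ([(0, 0)], [(1, 0)])
        hap = resolve_haplotypes(duos_from(*bad), policy="trust-phase")
        assert hap.rejected == ["P1"]  # 1/1 variants inconsistent > 5%
        # same variant among 39 clean ones: kept, variant nulled
        mother = np.zeros((1, 40, 2), dtype=np.int8)
        child = np.zeros((1, 40, 2), dtype=np.int8)
        child[0, 0, 0] = 1
        duos = PhasedDuos(["P1"], [f"v{i}" for i in range(40)], mother, child)
        hap = resolve_haplotypes(duos, policy="trust-phase")
        assert hap.rejected == []
        assert np.isnan(hap.h1[0, 0]) and np.isnan(hap.h2[0, 0])
        assert hap.h1[0, 1] == 0

    def test_unknown_policy(self):
        with pytest.raises(ValueError, match="policy"):
            resolve_haplotypes(duos_from([(0, 0)], [(0, 0)]), policy="wat")


def _hap(h1, h2, h3, vids=None):
    h1, h2, h3 = (np.array(h, dtype=float)[None, :] for h in (h1, h2, h3))
    vids = vids or [f"v{i}" for i in range(h1.shape[1])]
    return DuoHaplotypes(["P1"], vids, h1, h2, h3)


def _weights(vals, vids=None):
    return [
        VariantWeight(vids[i] if vids else f"v{i}", "1", 100 + i, "A", "G", v)
        for i, v in enumerate(vals)
    ]


class TestComputeScores:
    def test_weighted_sum_example(self):
        hap = _hap([1, 0, 1], [0, 0, 0], [1, 1, 1])
        sc = compute_scores(hap, _weights([0.5, -0.2, 0.1]))
        assert sc.S_h1[0] == pytest.approx(0.6, abs=1e-15)
        assert sc.S_h2[0] == 0.0
        assert sc.S_h3[0] == pytest.approx(0.4, abs=1e-15)
        assert sc.S_mat[0] == sc.S_h1[0] + sc.S_h2[0]
        assert sc.S_fet[0] == sc.S_h1[0] + sc.S_h3[0]

    def test_all_zero_weights(self):
        hap = _hap([1, 1], [1, 0], [0, 1])
        sc = compute_scores(hap, _weights([0.0, 0.0]))
        assert (sc[["S_h1", "S_h2", "S_h3", "S_mat", "S_fet"]] == 0).all().all()

    def test_missing_variants_contribute_zero_and_counted(self):
        hap = _hap([1, np.nan], [0, np.nan], [1, np.nan])
        sc = compute_scores(hap, _weights([0.5, 100.0]))
        assert sc.S_h1[0] == 0.5
        assert sc.n_variants_used[0] == 1

    def test_empty_panel_intersection_raises(self):
        hap = _hap([1], [0], [1])
        with pytest.raises(ValueError, match="overlap"):
            compute_scores(hap, _weights([0.5], vids=["other"]))

    def test_resolved_scores_equal_truth_scores(self, base_study):
        # trust-phase resolution of the truth haplotypes is the identity
        sc = compute_scores(base_study.haplotypes, base_study.parents.weights)
        np.testing.assert_array_equal(
            sc[["S_h1", "S_h2", "S_h3"]].to_numpy(),
            base_study.scores[["S_h1", "S_h2", "S_h3"]].to_numpy(),
        )

    @given(st.integers(0, 2**31 - 1))
    def test_additive_identities_property(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(1, 8)
        h1, h2, h3 = rng.integers(0, 2, size=(3, m)).astype(float)
        sc = compute_scores(
            _hap(h1, h2, h3), _weights(rng.normal(0, 1, m).tolist())
        )
        assert sc.S_mat[0] == pytest.approx(sc.S_h1[0] + sc.S_h2[0], abs=1e-12)
        assert sc.S_fet[0] == pytest.approx(sc.S_h1[0] + sc.S_h3[0], abs=1e-12)


class TestInstrumentStrength:
    def test_beta_recovered_within_three_se(self, base_study):
        inst = score_trait_regression(
            base_study.scores, base_study.phenotypes, "sbp"
        )
        assert abs(inst.beta - base_study.truth["beta_MX"]) < 3 * inst.se

    def test_score_independent_trait_has_null_r2(self, base_study):
        inst = score_trait_regression(
            base_study.scores, base_study.phenotypes, "maternal_age"
        )
        assert inst.r2 < 0.002
        assert inst.p > 0.001

    def test_rank_deficient_design_raises(self, base_study):
        ph = base_study.phenotypes.copy()
        ph["dup"] = ph["maternal_age"]
        with pytest.raises(ValueError, match="rank-deficient"):
            score_trait_regression(
                base_study.scores, ph, "sbp", covariates=("maternal_age", "dup")
            )

    def test_too_few_observations_raises(self, base_study):
        with pytest.raises(ValueError, match="50"):
            score_trait_regression(
                base_study.scores.head(10), base_study.phenotypes, "sbp"
            )


class TestAssortativeMatingFootprint:
    def test_transmitted_and_nontransmitted_variances_match(self, base_study):
        s = base_study.scores
        v1, v2 = s.S_h1.var(), s.S_h2.var()
        assert abs(v1 - v2) / v1 < 0.15

    def test_score_correlations_increase_with_rho(self):
        r12, rm3 = [], []
        for rho in (0.0, 0.15, 0.3):
            cfg = SimulationConfig(
                n_pregnancies=8000, n_snps=40, seed=21, assortative_mating_rho=rho
            )
            sc = simulate_study(cfg).scores
            r12.append(np.corrcoef(sc.S_h1, sc.S_h2)[0, 1])
            rm3.append(np.corrcoef(sc.S_mat, sc.S_h3)[0, 1])
        assert r12[0] < r12[1] < r12[2]
        assert rm3[0] < rm3[1] < rm3[2]
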