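"""Synthetic mother-father-child duo study generator.

Emulates the statistical structure the haplotype-score analysis assumes:
independent (linkage-equilibrium) SNP panels, optional assortative mating
between parental scores, Mendelian transmission, a maternal trait
instrumented by the maternal genotype score at a configurable R², pregnancy
outcomes carrying planted maternal and fetal genetic effects, a smooth
(cubic) gestation-to-birth-weight link, shared-environment confounding, a
fetal-drive effect of fetal growth on a maternal pregnancy trait, and an
offspring adult trait sharing genetics with the fetal score.

Default parameter values mirror a blood-pressure-like exposure in a cohort
of ~10⁴ duos (trait SD 5.8 mmHg, instrument R² 2%, gestation 280 ± 11.4
days, gestational-age-adjusted birth-weight SD 426 g, preterm threshold
259 days).  Everything is deterministic under (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import VariantWeight
from .scores import DuoHaplotypes, compute_scores

__all__ = [
    "SimulationConfig",
    "Parents",
    "SimulatedStudy",
    "simulate_parents",
    "simulate_transmission",
    "simulate_phenotypes",
    "simulate_study",
    "write_vcf",
]

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("C", "T"), ("G", "T")]


@dataclass
class SimulationConfig:
    """Generative truth for one simulated duo study.

    Effects are in natural units: ``maternal_effect`` in outcome units per
    trait unit (the causal effect of the maternal trait), fetal effects in
    outcome units per score unit, ``fetal_drive_effect`` in trait units per
    SD of gestational-age-adjusted fetal growth.
    """

    n_pregnancies: int = 10_000
    n_snps: int = 86
    allele_freq_range: tuple[float, float] = (0.1, 0.9)
    weight_scale: float = 0.17
    assortative_mating_rho: float = 0.0
    instrument_r2: float = 0.02
    # maternal trait (exposure X); defaults are SBP-like
    trait_name: str = "sbp"
    trait_mean: float = 112.0
    trait_sd: float = 5.8
    # causal structure
    maternal_effect: float = -0.40          # days of gestation per trait unit
    maternal_effect_bw: float = -0.35       # g birth weight per trait unit
    fetal_effect_per_score: float = -0.10   # days per score unit (direct fetal)
    fetal_effect_bw_per_score: float = -4.8  # g per score unit (direct fetal)
    fetal_drive_effect: float = 1.41        # trait units per SD fetal growth
    confounding_gest: float = 0.36          # days per trait unit of shared env
    confounding_bw: float = 0.0             # g per trait unit of shared env
    # outcome scales
    gestation_mean: float = 280.0
    gestation_sd: float = 11.4
    birthweight_mean: float = 3540.0
    birthweight_sd_adjusted: float = 426.0
    gest_bw_coefs: tuple[float, float, float] = (25.0, -0.15, -0.005)
    sex_effect_bw: float = 130.0
    preterm_threshold: float = 259.0
    # offspring adult phenotype sharing genetics with S_fet
    adult_h2: float = 0.4
    adult_sd: float = 5.8
    n_datasets: int = 1
    seed: int = 2020

    def validate(self) -> None:
        lo, hi = self.allele_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("allele frequencies must lie strictly inside (0,1)")
        if not (0.0 < self.instrument_r2 < 1.0):
            raise ValueError("instrument_r2 must be in (0,1)")
        if not (0.0 <= self.assortative_mating_rho < 1.0):
            raise ValueError("assortative_mating_rho must be in [0,1)")
        for name in ("trait_sd", "gestation_sd", "birthweight_sd_adjusted",
                     "adult_sd", "weight_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.adult_h2 <= 1.0):
            raise ValueError("adult_h2 must be in [0,1]")
        if self.n_pregnancies < 1 or self.n_snps < 1:
            raise ValueError("n_pregnancies and n_snps must be positive")


@dataclass
class Parents:
    """Parental diplotypes plus total (genotype) scores per family."""

    mother: np.ndarray  # (n, 2, m) int8, storage order is arbitrary
    father: np.ndarray  # (n, 2, m)
    weights: list[VariantWeight]
    allele_freqs: np.ndarray
    effect_is_alt: np.ndarray  # per-variant: effect allele is VCF ALT
    maternal_score: np.ndarray
    paternal_score: np.ndarray


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    parents: Parents
    haplotypes: DuoHaplotypes
    transmitted_maternal: np.ndarray  # which maternal haplotype became h1
    phenotypes: pd.DataFrame
    scores: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _rank(x: np.ndarray) -> np.ndarray:
    return np.argsort(np.argsort(x, kind="stable"), kind="stable")


def _normal_scores(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Van der Waerden normal scores of x (rank-based, ties by draw order)."""
    from scipy import stats as _stats

    n = x.size
    return _stats.norm.ppf((_rank(x) + 1) / (n + 1))


def simulate_parents(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> Parents:
    """Draw parental haplotypes under linkage equilibrium.

    Each of the four parental haplotypes is Bernoulli(p_j) per SNP.
    Assortative mating is induced by a Gaussian-copula rank coupling of
    the total maternal and paternal scores: couples are formed so that the
    score ranks follow a bivariate normal with correlation
    ``assortative_mating_rho``, which preserves the marginal score
    distributions while hitting the target correlation.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, m = config.n_pregnancies, config.n_snps
    lo, hi = config.allele_freq_range
    freqs = rng.uniform(lo, hi, size=m)
    wvals = rng.normal(0.0, config.weight_scale, size=m)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    effect_is_alt = rng.integers(0, 2, size=m).astype(bool)
    weights = []
    for j in range(m):
        eff, oth = _ALLELE_PAIRS[pair_idx[j]]
        weights.append(
            VariantWeight(
                variant_id=f"snp{j + 1:05d}",
                chrom="1",
                pos=10_000 * (j + 1),
                effect_allele=eff,
                other_allele=oth,
                weight=float(wvals[j]),
                trait=config.trait_name,
            )
        )

    mother = (rng.random((n, 2, m)) < freqs).astype(np.int8)
    father = (rng.random((n, 2, m)) < freqs).astype(np.int8)

    rho = config.assortative_mating_rho
    if rho > 0.0:
        # equilibrium footprint within each parent: couple the two own
        # haplotype scores (the parent's parents were themselves assorted),
        # then couple the parental totals across the pairing
        for arr in (mother, father):
            sa = arr[:, 0, :] @ wvals
            sb = arr[:, 1, :] @ wvals
            z = rho * _normal_scores(sa, rng) + np.sqrt(1 - rho**2) * rng.normal(
                size=n
            )
            arr[:, 1, :] = arr[np.argsort(sb, kind="stable"), 1, :][_rank(z)]
        s_mat = mother.sum(axis=1) @ wvals
        s_pat = father.sum(axis=1) @ wvals
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        mother = mother[np.argsort(s_mat, kind="stable")][_rank(z[:, 0])]
        father = father[np.argsort(s_pat, kind="stable")][_rank(z[:, 1])]
    s_mat = mother.sum(axis=1) @ wvals
    s_pat = father.sum(axis=1) @ wvals

    return Parents(
        mother=mother,
        father=father,
        weights=weights,
        allele_freqs=freqs,
        effect_is_alt=effect_is_alt,
        maternal_score=s_mat,
        paternal_score=s_pat,
    )


def simulate_transmission(
    parents: Parents, rng: np.random.Generator | int | None = None
) -> tuple[DuoHaplotypes, np.ndarray]:
    """Transmit one uniformly chosen haplotype from each parent.

    Returns the truth haplotypes (h1 = transmitted maternal, h2 = the
    other maternal, h3 = transmitted paternal; child genotype = h1 + h3 by
    construction) and the index of the transmitted maternal haplotype.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = parents.mother.shape[0]
    rows = np.arange(n)
    tm = rng.integers(0, 2, size=n)
    tp = rng.integers(0, 2, size=n)
    h1 = parents.mother[rows, tm, :].astype(float)
    h2 = parents.mother[rows, 1 - tm, :].astype(float)
    h3 = parents.father[rows, tp, :].astype(float)
    hap = DuoHaplotypes(
        pregnancy_ids=[f"P{i + 1:06d}" for i in range(n)],
        variant_ids=[w.variant_id for w in parents.weights],
        h1=h1,
        h2=h2,
        h3=h3,
    )
    return hap, tm


def _noise_sd(target_sd: float, systematic: np.ndarray, what: str) -> float:
    var_sys = float(np.var(systematic))
    resid = target_sd**2 - var_sys
    if resid <= 0:
        raise ValueError(
            f"planted effects explain more variance than {what} allows: "
            f"systematic SD {np.sqrt(var_sys):.3f} >= target {target_sd}; "
            f"attainable SD bound is {np.sqrt(var_sys):.3f}"
        )
    return float(np.sqrt(resid))


def simulate_phenotypes(
    haplotypes: DuoHaplotypes,
    weights: list[VariantWeight],
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate the per-pregnancy phenotype table from truth haplotypes.

    The maternal trait X is ``a * S_mat`` plus environmental noise, with
    ``a`` scaled so the score explains ``instrument_r2`` of Var(X) and
    SD(X) matches ``trait_sd``.  Gestational duration adds the maternal
    causal path, a direct fetal effect of S_fet and a shared-environment
    confounding path; birth weight adds its own maternal/fetal components,
    a cubic function of centred gestational days and a fetal-sex shift,
    with residual noise scaled to the stated adjusted SD.  The fetal-drive
    path feeds the growth deviation (in SD) back into the maternal trait
    column.  Returns the table and a dict of generative truth values.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cfg = config
    n = haplotypes.n_duos
    sc = compute_scores(haplotypes, weights)
    s_mat = sc["S_mat"].to_numpy()
    s_fet = sc["S_fet"].to_numpy()

    sd_smat = float(np.std(s_mat))
    if sd_smat == 0:
        raise ValueError("degenerate panel: maternal score has zero variance")
    a = cfg.trait_sd * np.sqrt(cfg.instrument_r2) / sd_smat
    e_env = rng.normal(0.0, cfg.trait_sd * np.sqrt(1 - cfg.instrument_r2), n)
    x_pre = cfg.trait_mean + a * (s_mat - s_mat.mean()) + e_env

    gest_sys = (
        cfg.maternal_effect * (x_pre - cfg.trait_mean)
        + cfg.fetal_effect_per_score * (s_fet - s_fet.mean())
        + cfg.confounding_gest * e_env
    )
    gest = (
        cfg.gestation_mean
        + gest_sys
        - gest_sys.mean()
        + rng.normal(0.0, _noise_sd(cfg.gestation_sd, gest_sys, "gestation_sd"), n)
    )
    preterm = (gest < cfg.preterm_threshold).astype(int)

    sex = rng.integers(0, 2, size=n)
    bw_sys = (
        cfg.maternal_effect_bw * (x_pre - cfg.trait_mean)
        + cfg.fetal_effect_bw_per_score * (s_fet - s_fet.mean())
        + cfg.confounding_bw * e_env
        + cfg.sex_effect_bw * (sex - 0.5)
    )
    bw_dev = (
        bw_sys
        - bw_sys.mean()
        + rng.normal(
            0.0,
            _noise_sd(cfg.birthweight_sd_adjusted, bw_sys, "birthweight_sd_adjusted"),
            n,
        )
    )
    gc = gest - cfg.gestation_mean
    c1, c2, c3 = cfg.gest_bw_coefs
    cubic = c1 * gc + c2 * gc**2 + c3 * gc**3
    bw = cfg.birthweight_mean + (cubic - cubic.mean()) + bw_dev

    growth_sd = bw_dev / cfg.birthweight_sd_adjusted
    trait = x_pre + cfg.fetal_drive_effect * growth_sd

    length = (
        50.4
        + 0.0025 * bw_dev
        + 0.12 * gc
        + rng.normal(0.0, 1.5, n)
    )
    sd_sfet = float(np.std(s_fet))
    b_adult = cfg.adult_sd * np.sqrt(cfg.adult_h2) / sd_sfet if sd_sfet > 0 else 0.0
    adult = b_adult * (s_fet - s_fet.mean()) + rng.normal(
        0.0, cfg.adult_sd * np.sqrt(1 - cfg.adult_h2), n
    )

    datasets = [f"D{(i % cfg.n_datasets) + 1}" for i in range(n)]
    pheno = pd.DataFrame(
        {
            "pregnancy_id": haplotypes.pregnancy_ids,
            "maternal_age": np.round(rng.normal(28.0, 4.5, n), 1),
            "maternal_height": np.round(rng.normal(165.7, 6.4, n), 1),
            "maternal_bmi": np.round(rng.normal(23.3, 4.0, n), 1),
            "sbp": np.nan,
            "dbp": np.nan,
            "fpg": rng.normal(4.7, 0.36, n),
            "gestational_days": gest,
            "preterm": preterm,
            "birth_weight": bw,
            "birth_length": length,
            "adult_trait": adult,
            "fetal_sex": sex,
            "dataset": datasets,
        }
    )
    pheno[cfg.trait_name] = trait
    if cfg.trait_name != "dbp":
        pheno["dbp"] = 67.6 + 0.55 * (trait - trait.mean()) + rng.normal(0, 3.0, n)

    truth = {
        "beta_MX": a,
        "beta_MY_gest": cfg.maternal_effect * a,
        "beta_FY_gest": cfg.fetal_effect_per_score,
        "beta_MY_bw": cfg.maternal_effect_bw * a,
        "beta_FY_bw": cfg.fetal_effect_bw_per_score,
        "maternal_causal_gest": cfg.maternal_effect,
        "maternal_causal_bw": cfg.maternal_effect_bw,
        "fetal_drive_trait": cfg.fetal_drive_effect,
        "adult_beta_per_score": b_adult,
        "var_smat": float(np.var(s_mat)),
        "var_sfet": float(np.var(s_fet)),
        "cov_smat_sfet": float(np.cov(s_mat, s_fet, ddof=0)[0, 1]),
        "var_trait": float(np.var(trait)),
        "var_adult": float(np.var(adult)),
        "h2_trait": a**2 * float(np.var(s_mat)) / float(np.var(trait)),
        "h2_adult": (
            b_adult**2 * float(np.var(s_fet)) / float(np.var(adult))
            if np.var(adult) > 0
            else 0.0
        ),
    }
    return pheno, truth


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """End-to-end simulation: parents -> transmission -> phenotypes.

    A single seeded generator drives every draw, so results are
    byte-identical under a fixed (config, seed).
    """
    rng = np.random.default_rng(config.seed)
    parents = simulate_parents(config, rng)
    hap, tm = simulate_transmission(parents, rng)
    pheno, truth = simulate_phenotypes(hap, parents.weights, config, rng)
    sc = compute_scores(hap, parents.weights)
    return SimulatedStudy(
        config=config,
        parents=parents,
        haplotypes=hap,
        transmitted_maternal=tm,
        phenotypes=pheno,
        scores=sc,
        truth=truth,
    )


def write_vcf(study: SimulatedStudy, vcf_path, pedigree_path) -> None:
    """Write the simulated duos as a phased VCF 4.2 plus pedigree TSV.

    Mother samples carry their diplotype in storage order (which is
    independent of transmission); child genotypes are phased
    maternal-origin first.  REF/ALT orientation of the effect allele is
    randomized per variant at generation time, so readers must recode.
    """
    parents = study.parents
    hap = study.haplotypes
    n = hap.n_duos
    mother_ids = [f"M{i + 1:06d}" for i in range(n)]
    child_ids = [f"C{i + 1:06d}" for i in range(n)]

    with open(vcf_path, "wt", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=duomr-simulate\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(mother_ids + child_ids)
            + "\n"
        )
        for j, w in enumerate(parents.weights):
            eff_alt = bool(parents.effect_is_alt[j])
            ref, alt = (
                (w.other_allele, w.effect_allele)
                if eff_alt
                else (w.effect_allele, w.other_allele)
            )

            def code(ind: np.ndarray) -> np.ndarray:
                ind = ind.astype(int)
                return ind if eff_alt else 1 - ind

            ma = code(parents.mother[:, 0, j])
            mb = code(parents.mother[:, 1, j])
            ca = code(hap.h1[:, j])
            cb = code(hap.h3[:, j])
            cells = [f"{a}|{b}" for a, b in zip(ma, mb)]
            cells += [f"{a}|{b}" for a, b in zip(ca, cb)]
            fh.write(
                f"1\t{w.pos}\t{w.variant_id}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(cells)
                + "\n"
            )

    ped = pd.DataFrame(
        {
            "child_id": child_ids,
            "mother_id": mother_ids,
            "pregnancy_id": hap.pregnancy_ids,
        }
    )
    ped.to_csv(pedigree_path, sep="\t", index=False)
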