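"""End-to-end orchestration: simulate → score → fit → contrast → causal →
confounding → meta → pleiotropy, from a single config.

Every stage reads and writes plain TSVs in the output directory, so any
stage can be re-run independently through the library API.  A manifest
records the seed, package versions and record counts at every stage;
results are byte-identical under a fixed (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .assoc import ModelSpec, fit_haplotype_model
from .confounding import confounded_mat_to_outcome, confounded_outcome_to_adult
from .effects import TraitMeta, contrast, ratio_causal, tsls
from .meta import fixed_effect_meta, random_effects_meta
from .presso import global_outlier_distortion, per_snp_allele_effects
from .scores import compute_scores, resolve_haplotypes, score_trait_regression
from .simulate import SimulationConfig, simulate_study, write_vcf

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "report_summary"]

logger = logging.getLogger("duomr")

DEFAULT_OUTCOMES = ("gestational_days", "preterm", "birth_weight", "birth_length")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    outcomes: tuple[str, ...] = DEFAULT_OUTCOMES
    presso_outcome: str = "birth_weight"
    presso_n_sim: int = 1000
    strict: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is not None:
            self.simulation.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)


@dataclass
class PipelineResult:
    outdir: Path
    results: pd.DataFrame
    causal: pd.DataFrame
    confounded: pd.DataFrame
    meta: pd.DataFrame
    presso: pd.DataFrame
    manifest: dict


def _causal_row(name, est):
    return {
        "analysis": name,
        "method": est.method,
        "estimate": est.estimate,
        "se": est.se,
        "p": est.p,
        "per_sd": est.per_sd,
        "per_sd_se": est.per_sd_se,
        "ci_lo": est.ci95[0],
        "ci_hi": est.ci95[1],
        "weak_instrument": est.weak_instrument,
    }


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis on a simulated duo study.

    Writes weights/VCF/pedigree/phenotypes, re-reads them through the
    format layer (so the exercised path is the same one real data would
    take), fits the joint haplotype models per outcome, derives contrasts
    and causal estimates, closed-form confounded associations,
    fixed/random-effects meta-analyses across dataset labels, and the
    pleiotropy tests on per-SNP allele effects.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.simulation
    manifest: dict = {
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "versions": _versions(),
        "counts": {},
    }

    logger.info("simulating %d duos x %d SNPs", cfg.n_pregnancies, cfg.n_snps)
    study = simulate_study(cfg)
    vcf_path = outdir / "duos.vcf"
    ped_path = outdir / "pedigree.tsv"
    wts_path = outdir / "weights.tsv"
    phe_path = outdir / "phenotypes.tsv"
    write_vcf(study, vcf_path, ped_path)
    io.write_weights(study.parents.weights, wts_path)
    io.write_phenotypes(study.phenotypes, phe_path)

    weights = io.read_weights(wts_path)
    duos = io.read_phased_duos(vcf_path, ped_path, weights)
    hap = resolve_haplotypes(duos)
    scores = compute_scores(hap, weights)
    pheno = io.read_phenotypes(phe_path)
    manifest["counts"].update(
        duos_in=duos.n_duos,
        duos_used=hap.n_duos,
        duos_excluded=len(hap.rejected),
        variants_matched=duos.n_variants,
        variants_excluded=len(duos.exclusions),
    )
    logger.info(
        "read %d duos, %d variants (%d excluded)",
        duos.n_duos,
        duos.n_variants,
        len(duos.exclusions),
    )

    instrument = score_trait_regression(scores, pheno, cfg.trait_name)
    manifest["instrument"] = dataclasses.asdict(instrument)

    per_dataset = cfg.n_datasets > 1
    result_rows: list[dict] = []
    meta_rows: list[dict] = []
    fits_all: dict[str, object] = {}
    for outcome in (*config.outcomes, cfg.trait_name):
        spec = ModelSpec(outcome=outcome)
        fits = fit_haplotype_model(
            scores, pheno, spec, per_dataset=per_dataset, trait=cfg.trait_name
        )
        fits = fits if isinstance(fits, dict) else {"all": fits}
        for ds, fit in fits.items():
            terms = dict(zip(("h1", "h2", "h3"), zip(fit.beta, fit.se, fit.p)))
            for kind in ("maternal", "fetal"):
                eff = contrast(fit, kind)
                terms[kind] = (eff.estimate, eff.se, eff.p)
            for term, (b, s, p) in terms.items():
                result_rows.append(
                    {
                        "trait": cfg.trait_name,
                        "outcome": outcome,
                        "dataset": ds,
                        "term": term,
                        "beta": b,
                        "se": s,
                        "p": p,
                        "n": fit.n_used,
                    }
                )
        if per_dataset:
            pooled = {}
            for term in ("h1", "h2", "h3", "maternal", "fetal"):
                sub = [r for r in result_rows if r["outcome"] == outcome
                       and r["term"] == term and r["dataset"] != "pooled"]
                betas = [r["beta"] for r in sub]
                ses = [r["se"] for r in sub]
                for res in (fixed_effect_meta(betas, ses),
                            random_effects_meta(betas, ses)):
                    meta_rows.append(
                        {
                            "outcome": outcome,
                            "term": term,
                            "model": res.model,
                            "beta": res.beta,
                            "se": res.se,
                            "p": res.p,
                            "q": res.q,
                            "p_q": res.p_q,
                            "i2": res.i2,
                            "tau2": res.tau2,
                            "k": res.k,
                        }
                    )
                    if res.model == "fixed":
                        pooled[term] = res
            # pooled fit for downstream contrasts: re-fit on all data
            fits_all[outcome] = fit_haplotype_model(
                scores, pheno, spec, per_dataset=False, trait=cfg.trait_name
            )
        else:
            fits_all[outcome] = fits["all"]

    trait_meta = TraitMeta(
        name=cfg.trait_name, sd=cfg.trait_sd, h2=study.truth["h2_trait"]
    )
    growth_meta = TraitMeta(name="fetal_growth", sd=cfg.birthweight_sd_adjusted)

    causal_rows = []
    gest_fit = fits_all["gestational_days"]
    my_gest = contrast(gest_fit, "maternal")
    causal_rows.append(
        _causal_row(
            f"{cfg.trait_name}->gestational_days",
            ratio_causal(my_gest, instrument, trait_meta, strict=config.strict),
        )
    )
    merged = scores.merge(pheno, on="pregnancy_id")
    causal_rows.append(
        _causal_row(
            f"{cfg.trait_name}->gestational_days",
            tsls(
                merged,
                "gestational_days",
                cfg.trait_name,
                "S_h2",
                covariates=("maternal_age", "fetal_sex"),
                trait_meta=trait_meta,
            ),
        )
    )
    # fetal drive: paternal transmitted score instrument, growth proxy = bw
    bw_fit = fits_all["birth_weight"]
    drive_fit = fits_all[cfg.trait_name]
    causal_rows.append(
        _causal_row(
            f"fetal_growth->{cfg.trait_name}",
            ratio_causal(
                (drive_fit.beta[2], drive_fit.se[2]),
                (bw_fit.beta[2], bw_fit.se[2]),
                growth_meta,
                instrument="S_h3",
            ),
        )
    )

    conf_rows = []
    fy_gest = contrast(gest_fit, "fetal")
    c1 = confounded_mat_to_outcome(
        fy_gest, (instrument.beta, instrument.se), study.truth["h2_trait"]
    )
    conf_rows.append(
        {
            "analysis": f"{cfg.trait_name}->gestational_days",
            "direction": c1.direction,
            "method": 0,
            "estimate": c1.estimate,
            "se": c1.se,
            "p": c1.p,
            "maternal_component": np.nan,
            "fetal_component": np.nan,
        }
    )
    var_bw_adj = float(
        np.var(
            merged["birth_weight"]
            - np.poly1d(np.polyfit(merged["gestational_days"],
                                   merged["birth_weight"], 3))(
                merged["gestational_days"]
            )
        )
    )
    # put the fit on the adult-trait genetic-value scale: one rescaled score
    # unit predicts one unit of the offspring adult trait
    b_adult = score_trait_regression(scores, pheno, "adult_trait", score="S_fet")
    bw_fit_adult = dataclasses.replace(
        bw_fit, beta=bw_fit.beta / b_adult.beta, cov=bw_fit.cov / b_adult.beta**2
    )
    for method in (1, 2):
        c = confounded_outcome_to_adult(
            bw_fit_adult,
            study.truth["h2_adult"],
            study.truth["var_adult"],
            var_bw_adj,
            method=method,
        )
        conf_rows.append(
            {
                "analysis": "birth_weight->adult_trait",
                "direction": c.direction,
                "method": method,
                "estimate": c.estimate,
                "se": c.se,
                "p": c.p,
                "maternal_component": c.maternal_component,
                "fetal_component": c.fetal_component,
            }
        )

    presso_rows = []
    spec_p = ModelSpec(outcome=config.presso_outcome)
    pairs = per_snp_allele_effects(hap, pheno, spec_p, weights=weights)
    rng = np.random.default_rng(cfg.seed + 1)
    for cls in ("h1", "h2", "h3"):
        sub = pairs[pairs["allele_class"] == cls]
        res = global_outlier_distortion(
            sub["beta_exp"].to_numpy(),
            sub["beta_out"].to_numpy(),
            sub["se_out"].to_numpy(),
            n_sim=config.presso_n_sim,
            seed=rng,
            variant_ids=list(sub["variant_id"]),
        )
        presso_rows.append(
            {
                "outcome": config.presso_outcome,
                "allele_class": cls,
                "slope_raw": res.slope_raw,
                "se_raw": res.se_raw,
                "slope_corrected": res.slope_corrected,
                "se_corrected": res.se_corrected,
                "rss_obs": res.rss_obs,
                "global_p": res.global_p,
                "n_outliers": len(res.outliers),
                "distortion_p": res.distortion_p,
            }
        )

    results_df = pd.DataFrame(result_rows)
    causal_df = pd.DataFrame(causal_rows)
    conf_df = pd.DataFrame(conf_rows)
    meta_df = pd.DataFrame(
        meta_rows,
        columns=["outcome", "term", "model", "beta", "se", "p", "q", "p_q",
                 "i2", "tau2", "k"],
    )
    presso_df = pd.DataFrame(presso_rows)

    io.write_results(result_rows, outdir / "results.tsv")
    for name, df in (
        ("causal", causal_df),
        ("confounded", conf_df),
        ("meta", meta_df),
        ("presso", presso_df),
    ):
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False, na_rep="NA")
    with open(outdir / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    logger.info("pipeline complete: %s", outdir)

    return PipelineResult(
        outdir=outdir,
        results=results_df,
        causal=causal_df,
        confounded=conf_df,
        meta=meta_df,
        presso=presso_df,
        manifest=manifest,
    )


def _versions() -> dict:
    import scipy
    import statsmodels

    from . import __version__

    return {
        "duomr": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


def report_summary(bundle: PipelineResult, sig: int = 4) -> str:
    """Human-readable per-trait, per-outcome summary of a result bundle."""
    if bundle.results.empty:
        return "no results\n"

    def fmt(v) -> str:
        if pd.isna(v):
            return "NA"
        return f"{float(v):.{sig}g}"

    lines = []
    for (trait, outcome, ds), grp in bundle.results.groupby(
        ["trait", "outcome", "dataset"], sort=True
    ):
        lines.append(f"== {trait} -> {outcome} [{ds}] (n={int(grp['n'].iloc[0])})")
        for term in ("h1", "h2", "h3", "maternal", "fetal"):
            row = grp[grp["term"] == term].iloc[0]
            lines.append(
                f"  {term:<9} beta={fmt(row.beta):>10}  se={fmt(row.se):>10}"
                f"  p={fmt(row.p)}"
            )
    if not bundle.causal.empty:
        lines.append("== causal estimates")
        for _, r in bundle.causal.iterrows():
            extra = f"  per_sd={fmt(r.per_sd)}" if not pd.isna(r.per_sd) else ""
            lines.append(
                f"  {r.analysis} [{r.method}] beta={fmt(r.estimate)} "
                f"se={fmt(r.se)} p={fmt(r.p)}{extra}"
            )
    if not bundle.meta.empty:
        lines.append("== meta-analysis (fixed)")
        for _, r in bundle.meta[bundle.meta.model == "fixed"].iterrows():
            lines.append(
                f"  {r.outcome}/{r.term}: beta={fmt(r.beta)} se={fmt(r.se)} "
                f"Q={fmt(r.q)} p_Q={fmt(r.p_q)} k={int(r.k)}"
            )
    return "\n".join(lines) + "\n"
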