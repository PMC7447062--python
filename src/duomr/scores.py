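"""Haplotype resolution and weighted genetic scores for mother-child duos.

A duo carries three allele classes at every SNP: the maternal transmitted
allele (h1), the maternal nontransmitted allele (h2) and the paternal
transmitted allele (h3).  Weighted sums of effect alleles over a SNP panel
give the three haplotype scores S_h1, S_h2, S_h3, from which the maternal
and fetal genotype scores follow by the additive identities
``S_mat = S_h1 + S_h2`` and ``S_fet = S_h1 + S_h3``.

Scores are kept in trait units (trait units of the weight file per effect
allele, summed); conversion to per-SD units is an explicit downstream step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import PhasedDuos, VariantWeight

__all__ = [
    "DuoHaplotypes",
    "InstrumentStrength",
    "resolve_haplotypes",
    "compute_scores",
    "score_trait_regression",
]

SCORE_COLUMNS = ["S_h1", "S_h2", "S_h3", "S_mat", "S_fet"]


@dataclass
class DuoHaplotypes:
    """Per-duo h1/h2/h3 effect-allele indicators over a SNP panel.

    Entries are 0, 1, 0.5 (ambiguous double-heterozygote under the
    ``mendelian-resolve`` policy) or NaN (Mendelian-inconsistent or missing;
    such variants contribute 0 to every score, symmetrically).
    """

    pregnancy_ids: list[str]
    variant_ids: list[str]
    h1: np.ndarray
    h2: np.ndarray
    h3: np.ndarray
    ambiguous: np.ndarray = None
    rejected: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ambiguous is None:
            self.ambiguous = np.zeros(self.h1.shape, dtype=bool)

    @property
    def n_duos(self) -> int:
        return len(self.pregnancy_ids)


def resolve_haplotypes(
    duos: PhasedDuos,
    policy: str = "trust-phase",
    max_inconsistent_frac: float = 0.05,
) -> DuoHaplotypes:
    """Resolve h1/h2/h3 from phased duo records.

    ``trust-phase`` takes the child's declared maternal-origin allele as h1
    and the remaining maternal allele as h2.  ``mendelian-resolve`` ignores
    the within-sample phase order and resolves from dosages alone; the
    mother-heterozygous/child-heterozygous case is genuinely ambiguous and
    is assigned the expected value 0.5 for h1, h2 and h3 with a flag
    (unbiased for score sums, and it avoids differential missingness
    between haplotypes).

    Mendelian-inconsistent variants (the child's maternal allele is not
    carried by the mother) are set to NaN per duo; duos with more than
    ``max_inconsistent_frac`` inconsistent variants are rejected outright.
    """
    n, m = duos.mother.shape[0], duos.mother.shape[1]
    mdose = duos.mother.sum(axis=2).astype(float)
    cdose = duos.child.sum(axis=2).astype(float)
    ambiguous = np.zeros((n, m), dtype=bool)

    if policy == "trust-phase":
        h1 = duos.child[:, :, 0].astype(float)
        h3 = duos.child[:, :, 1].astype(float)
        h2 = mdose - h1
        inconsistent = (h2 < 0) | (h2 > 1)
    elif policy == "mendelian-resolve":
        h1 = np.full((n, m), np.nan)
        h2 = np.full((n, m), np.nan)
        h3 = np.full((n, m), np.nan)
        hom = (mdose == 0) | (mdose == 2)
        h1[hom] = (mdose[hom] / 2)
        h2[hom] = (mdose[hom] / 2)
        h3[hom] = cdose[hom] - h1[hom]
        het = mdose == 1
        for dc, (a, b, c) in {0: (0, 1, 0), 2: (1, 0, 1)}.items():
            sel = het & (cdose == dc)
            h1[sel], h2[sel], h3[sel] = a, b, c
        amb = het & (cdose == 1)
        h1[amb] = h2[amb] = h3[amb] = 0.5
        ambiguous = amb
        inconsistent = (h3 < 0) | (h3 > 1)
    else:
        raise ValueError(f"unknown policy {policy!r}")

    for arr in (h1, h2, h3):
        arr[inconsistent] = np.nan

    frac_bad = inconsistent.mean(axis=1)
    keep = frac_bad <= max_inconsistent_frac
    rejected = [p for p, k in zip(duos.pregnancy_ids, keep) if not k]
    return DuoHaplotypes(
        pregnancy_ids=[p for p, k in zip(duos.pregnancy_ids, keep) if k],
        variant_ids=list(duos.variant_ids),
        h1=h1[keep],
        h2=h2[keep],
        h3=h3[keep],
        ambiguous=ambiguous[keep],
        rejected=rejected,
    )


def compute_scores(
    haplotypes: DuoHaplotypes, weights: list[VariantWeight]
) -> pd.DataFrame:
    """Build the five weighted genetic scores per pregnancy.

    S_hk = sum_j w_j * h_k,j over the intersection of the haplotype panel
    and the weight set; NaN entries (missing or inconsistent variants)
    contribute 0 to all three haplotype scores and are excluded from
    ``n_variants_used``.  The additive identities S_mat = S_h1 + S_h2 and
    S_fet = S_h1 + S_h3 hold exactly on the output.
    """
    wmap = {w.variant_id: w.weight for w in weights}
    cols = [j for j, v in enumerate(haplotypes.variant_ids) if v in wmap]
    if not cols:
        raise ValueError("no overlap between haplotype panel and weight set")
    wvec = np.array([wmap[haplotypes.variant_ids[j]] for j in cols])
    h1 = haplotypes.h1[:, cols]
    h2 = haplotypes.h2[:, cols]
    h3 = haplotypes.h3[:, cols]
    used = (~np.isnan(h1) & ~np.isnan(h2) & ~np.isnan(h3)).sum(axis=1)

    def _score(h: np.ndarray) -> np.ndarray:
        return np.nansum(h * wvec, axis=1)

    s1, s2, s3 = _score(h1), _score(h2), _score(h3)
    df = pd.DataFrame(
        {
            "pregnancy_id": haplotypes.pregnancy_ids,
            "S_h1": s1,
            "S_h2": s2,
            "S_h3": s3,
            "S_mat": s1 + s2,
            "S_fet": s1 + s3,
            "n_variants_used": used,
        }
    )
    if not np.all(np.isfinite(df[SCORE_COLUMNS].to_numpy())):
        raise ValueError("non-finite scores")
    return df


@dataclass(frozen=True)
class InstrumentStrength:
    """Instrument-strength summary of a score-on-trait regression.

    ``beta`` (with ``se``) is the per-score-unit association with the
    maternal trait — the denominator of the causal ratio estimate — and
    ``r2`` is the incremental variance in the trait explained by the score
    over the covariates alone.
    """

    score: str
    trait: str
    beta: float
    se: float
    p: float
    r2: float
    n: int


def score_trait_regression(
    scores: pd.DataFrame,
    phenotypes: pd.DataFrame,
    trait: str,
    score: str = "S_mat",
    covariates: tuple[str, ...] = (),
) -> InstrumentStrength:
    """Regress a maternal trait on one genetic score (plus covariates).

    Listwise deletion per model; requires >= 50 complete observations.
    Raises on a rank-deficient design.
    """
    df = scores.merge(phenotypes, on="pregnancy_id")
    cols = [trait, score, *covariates]
    df = df.dropna(subset=cols)
    if len(df) < 50:
        raise ValueError(f"only {len(df)} complete observations (need >= 50)")
    X = sm.add_constant(df[[score, *covariates]].to_numpy(dtype=float))
    if np.linalg.cond(X) > 1e8:
        raise ValueError("rank-deficient design")
    y = df[trait].to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit()
    if covariates:
        base = sm.OLS(
            y, sm.add_constant(df[list(covariates)].to_numpy(dtype=float))
        ).fit()
        r2 = fit.rsquared - base.rsquared
    else:
        r2 = fit.rsquared
    return InstrumentStrength(
        score=score,
        trait=trait,
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        p=float(fit.pvalues[1]),
        r2=float(r2),
        n=int(len(df)),
    )
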