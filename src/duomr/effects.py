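"""Maternal/fetal effect contrasts and instrumental-variable causal estimates.

Under additivity of maternal and fetal effects and a zero parent-of-origin
effect, the total effect of the maternal transmitted haplotype decomposes
as β_h1 = maternal + fetal.  The average maternal effect over the two
maternal haplotypes is the contrast

    β_MY = (β_h1 − β_h3 + β_h2) / 2,

and the average fetal genetic effect over the two transmitted haplotypes is

    β_FY = (β_h1 − β_h2 + β_h3) / 2,

so β_MY + β_FY = β_h1 identically.  Causal effects of the maternal trait
follow from the Wald ratio β_MY / β_MX or from two-stage least squares
with the nontransmitted score S_h2 as instrument; the fetal-drive effect
of fetal growth on a maternal pregnancy trait uses the paternal
transmitted score S_h3 as instrument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .assoc import HaplotypeFit
from .scores import InstrumentStrength

__all__ = [
    "TraitMeta",
    "EffectEstimate",
    "CausalEstimate",
    "CONTRAST_VECTORS",
    "contrast",
    "ratio_causal",
    "tsls",
]

#: Contrast weights on (β_h1, β_h2, β_h3).
CONTRAST_VECTORS = {
    "maternal": np.array([0.5, 0.5, -0.5]),
    "fetal": np.array([0.5, -0.5, 0.5]),
}


@dataclass(frozen=True)
class TraitMeta:
    """Per-trait constants used for per-SD scaling and confounding formulas.

    ``sd`` is in trait units (e.g. 6.4 cm for adult height); ``h2`` the
    additive heritability fraction; ``var_adult`` / ``var_outcome`` the
    variances entering the outcome-to-adult confounding formulas.
    """

    name: str
    sd: float
    h2: float | None = None
    var_adult: float | None = None
    var_outcome: float | None = None

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.h2 is not None and not (0.0 <= self.h2 <= 1.0):
            raise ValueError("h2 must be in [0,1]")


@dataclass(frozen=True)
class EffectEstimate:
    """A maternal (β_MY) or fetal (β_FY) contrast with its Wald inference."""

    kind: str
    estimate: float
    se: float
    p: float
    outcome: str = ""
    trait: str = ""

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("SE must be positive")


def contrast(fit: HaplotypeFit, kind: str) -> EffectEstimate:
    """Maternal or fetal effect contrast from a joint haplotype fit.

    estimate = c·β with c = (½, ½, −½) for the maternal effect and
    (½, −½, ½) for the fetal effect; Var = cᵀ Σ c from the fit's full
    coefficient covariance.
    """
    if kind not in CONTRAST_VECTORS:
        raise ValueError(f"kind must be 'maternal' or 'fetal', got {kind!r}")
    if fit.cov is None:
        raise ValueError("fit carries no coefficient covariance")
    fit.validate()
    c = CONTRAST_VECTORS[kind]
    est = float(c @ fit.beta)
    var = float(c @ fit.cov @ c)
    se = float(np.sqrt(var))
    p = float(2 * stats.norm.sf(abs(est) / se)) if se > 0 else float("nan")
    return EffectEstimate(
        kind=kind, estimate=est, se=se, p=p, outcome=fit.outcome, trait=fit.trait
    )


@dataclass(frozen=True)
class CausalEstimate:
    """An instrumental-variable causal estimate.

    ``estimate`` is per exposure unit; ``per_sd`` rescales by the exposure
    SD when trait metadata is supplied.  CI95 is the symmetric normal
    approximation.  ``weak_instrument`` marks a denominator smaller than
    three of its SEs.
    """

    method: str
    estimate: float
    se: float
    p: float
    ci95: tuple[float, float]
    per_sd: float | None = None
    per_sd_se: float | None = None
    instrument: str = ""
    exposure: str = ""
    outcome: str = ""
    weak_instrument: bool = False
    stage1_f: float | None = None


def _wrap(method, est, se, sd, **kw) -> CausalEstimate:
    p = float(2 * stats.norm.sf(abs(est) / se)) if se > 0 else float("nan")
    ci = (est - 1.96 * se, est + 1.96 * se)
    per_sd = est * sd if sd is not None else None
    per_sd_se = se * sd if sd is not None else None
    return CausalEstimate(
        method=method,
        estimate=float(est),
        se=float(se),
        p=p,
        ci95=ci,
        per_sd=per_sd,
        per_sd_se=per_sd_se,
        **kw,
    )


def ratio_causal(
    numerator: EffectEstimate | tuple[float, float],
    denominator: InstrumentStrength | tuple[float, float],
    trait_meta: TraitMeta | None = None,
    strict: bool = False,
    instrument: str = "",
) -> CausalEstimate:
    """Wald ratio causal estimate, numerator / denominator.

    For the maternal causal effect the numerator is β_MY (outcome per
    score unit) and the denominator β_MX (trait per score unit); for the
    fetal-drive analysis both are per-SNP-score coefficients of the
    paternal transmitted haplotype (outcome vs fetal-growth proxy), and
    ``trait_meta.sd`` converts to per-SD-of-fetal-growth units.

    The SE is first-order delta method with zero numerator/denominator
    cross-covariance (the two usually come from different regressions).
    A denominator with |β| <= 3 SE is flagged as a weak instrument (or
    raises in ``strict`` mode).
    """
    b_num, se_num = (
        (numerator.estimate, numerator.se)
        if isinstance(numerator, EffectEstimate)
        else (float(numerator[0]), float(numerator[1]))
    )
    b_den, se_den = (
        (denominator.beta, denominator.se)
        if isinstance(denominator, InstrumentStrength)
        else (float(denominator[0]), float(denominator[1]))
    )
    if b_den == 0:
        raise ZeroDivisionError("zero instrument-exposure association")
    weak = abs(b_den) <= 3 * se_den
    if weak and strict:
        raise ValueError(
            f"weak instrument: |beta|={abs(b_den):.4g} <= 3*SE={3 * se_den:.4g}"
        )
    est = b_num / b_den
    se = np.sqrt(se_num**2 / b_den**2 + b_num**2 * se_den**2 / b_den**4)
    sd = trait_meta.sd if trait_meta is not None else None
    return _wrap(
        "ratio",
        est,
        se,
        sd,
        instrument=instrument,
        weak_instrument=bool(weak),
    )


def tsls(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    instrument: str,
    covariates: tuple[str, ...] = (),
    trait_meta: TraitMeta | None = None,
) -> CausalEstimate:
    """Two-stage least squares with a genetic-score instrument.

    Stage 1 regresses the exposure on the instrument and covariates;
    stage 2 regresses the outcome on the fitted exposure and the same
    covariates.  Coefficient SEs use the proper TSLS residuals — stage-2
    coefficients with residuals computed from the *observed* exposure.
    Stage-1 partial F below 10 flags a weak instrument.
    """
    cols = [outcome, exposure, instrument, *covariates]
    df = data.dropna(subset=list(dict.fromkeys(cols)))
    n = len(df)
    if n < 100:
        raise ValueError(f"only {n} complete observations (need >= 100)")
    y = df[outcome].to_numpy(dtype=float)
    x = df[exposure].to_numpy(dtype=float)
    z = df[instrument].to_numpy(dtype=float)
    C = df[list(covariates)].to_numpy(dtype=float) if covariates else np.empty((n, 0))

    Z1 = sm.add_constant(np.column_stack([z, C]), has_constant="add")
    stage1 = sm.OLS(x, Z1).fit()
    f1 = float((stage1.params[1] / stage1.bse[1]) ** 2)
    x_hat = stage1.fittedvalues

    X2 = sm.add_constant(np.column_stack([x_hat, C]), has_constant="add")
    beta = np.linalg.solve(X2.T @ X2, X2.T @ y)
    resid = y - sm.add_constant(np.column_stack([x, C]), has_constant="add") @ beta
    dof = n - X2.shape[1]
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X2.T @ X2)
    est, se = float(beta[1]), float(np.sqrt(cov[1, 1]))
    sd = trait_meta.sd if trait_meta is not None else None
    return _wrap(
        "tsls",
        est,
        se,
        sd,
        instrument=instrument,
        exposure=exposure,
        outcome=outcome,
        weak_instrument=f1 < 10,
        stage1_f=f1,
    )
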