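"""Joint haplotype-score regression models and phenotype associations.

The central model regresses a pregnancy outcome Y on the three haplotype
scores simultaneously, ``Y ~ S_h1 + S_h2 + S_h3 + Cov``, so the three
coefficients share one sample and their full covariance is available for
the maternal/fetal contrasts.  Birth weight and length are adjusted for
gestational duration with the first three orthogonal polynomials, because
the gestation-size relationship is nonlinear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "HaplotypeFit",
    "AssociationResult",
    "orthogonal_polynomials",
    "fit_haplotype_model",
    "fit_phenotype_association",
]

#: Outcomes whose analysis adjusts for the gestation polynomial block.
GESTATION_ADJUSTED = frozenset({"birth_weight", "birth_length"})
#: Binary outcomes (logistic family).
BINARY_OUTCOMES = frozenset({"preterm"})

_SCORES = ["S_h1", "S_h2", "S_h3"]


def orthogonal_polynomials(x: np.ndarray, degree: int = 3) -> np.ndarray:
    """Orthogonal-polynomial covariate block for a quantitative covariate.

    Returns ``degree`` columns that are mutually orthogonal, orthogonal to
    the intercept (zero column means) and unit-norm — the classic
    orthogonal-polynomial contrast basis.  Column k correlates positively
    with x**k, making the sign convention deterministic.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be 1-D")
    if np.unique(x).size <= degree:
        raise ValueError(f"need more than {degree} distinct values")
    powers = np.column_stack([x**k for k in range(degree + 1)])
    q, r = np.linalg.qr(powers)
    # fix signs so diag(R) > 0, i.e. column k follows x**k
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    q = q * signs
    return q[:, 1:]


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, GLM family, covariates, dataset column.

    ``family`` and the gestation block are inferred from the outcome when
    left at their defaults (``preterm`` is logistic; birth weight/length
    include the degree-3 gestation polynomial block).  Maternal height and
    BMI are deliberately *not* default covariates of score models — they
    are downstream of the scores being instrumented.
    """

    outcome: str
    family: str = ""
    covariates: tuple[str, ...] = ("maternal_age", "fetal_sex")
    gestation_adjust: bool | None = None
    gestation_degree: int = 3
    dataset_column: str = "dataset"

    def resolved_family(self) -> str:
        if self.family:
            return self.family
        return "logistic" if self.outcome in BINARY_OUTCOMES else "linear"

    def resolved_gestation_adjust(self) -> bool:
        if self.gestation_adjust is not None:
            return self.gestation_adjust
        return self.outcome in GESTATION_ADJUSTED


@dataclass
class HaplotypeFit:
    """Coefficients of the joint three-haplotype-score regression.

    ``beta`` holds (β_h1, β_h2, β_h3) in outcome units (or log-OR) per
    score unit; ``cov`` is their full 3x3 covariance, required by the
    contrast estimators.
    """

    outcome: str
    dataset: str
    beta: np.ndarray
    cov: np.ndarray
    n_used: int
    family: str
    converged: bool = True
    trait: str = ""

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def p(self) -> np.ndarray:
        from scipy import stats

        z = self.beta / self.se
        return 2 * stats.norm.sf(np.abs(z))

    def validate(self) -> None:
        if self.beta.shape != (3,) or self.cov.shape != (3, 3):
            raise ValueError("haplotype fit must carry 3 coefficients + 3x3 cov")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance not symmetric")
        if np.any(np.linalg.eigvalsh(self.cov) < -1e-10):
            raise ValueError("covariance not positive semi-definite")


def _design(
    df: pd.DataFrame, spec: ModelSpec, main_cols: list[str]
) -> tuple[np.ndarray, np.ndarray, int]:
    cols = [spec.outcome, *main_cols, *spec.covariates]
    if spec.resolved_gestation_adjust():
        cols.append("gestational_days")
    sub = df.dropna(subset=[c for c in dict.fromkeys(cols)])
    y = sub[spec.outcome].to_numpy(dtype=float)
    blocks = [sub[main_cols].to_numpy(dtype=float)]
    if spec.covariates:
        blocks.append(sub[list(spec.covariates)].to_numpy(dtype=float))
    if spec.resolved_gestation_adjust():
        blocks.append(
            orthogonal_polynomials(
                sub["gestational_days"].to_numpy(dtype=float),
                spec.gestation_degree,
            )
        )
    X = sm.add_constant(np.column_stack(blocks), has_constant="add")
    return y, X, len(sub)


def _fit_glm(y, X, family: str):
    if family == "linear":
        return sm.OLS(y, X).fit()
    if family == "logistic":
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-8)
        except Exception as exc:  # includes perfect separation
            raise ValueError(f"logistic fit failed: {exc}") from exc
        if not res.mle_retvals.get("converged", False):
            raise ValueError("logistic fit did not converge")
        return res
    raise ValueError(f"unknown family {family!r}")


def fit_haplotype_model(
    scores: pd.DataFrame,
    phenotypes: pd.DataFrame,
    spec: ModelSpec,
    per_dataset: bool = False,
    trait: str = "",
) -> HaplotypeFit | dict[str, HaplotypeFit]:
    """Fit ``outcome ~ S_h1 + S_h2 + S_h3 + Cov``.

    Listwise deletion per model; requires >= 100 complete observations and
    a well-conditioned design (condition number <= 1e8).  With
    ``per_dataset`` a separate fit is returned per dataset label, ready
    for meta-analysis.
    """
    df = scores.merge(phenotypes, on="pregnancy_id")
    if per_dataset:
        out: dict[str, HaplotypeFit] = {}
        for name, grp in df.groupby(spec.dataset_column, sort=True):
            out[str(name)] = _fit_single(grp, spec, str(name), trait)
        return out
    return _fit_single(df, spec, "all", trait)


def _fit_single(
    df: pd.DataFrame, spec: ModelSpec, dataset: str, trait: str
) -> HaplotypeFit:
    y, X, n = _design(df, spec, _SCORES)
    if n < 100:
        raise ValueError(f"only {n} complete observations (need >= 100)")
    if np.ptp(X[:, 1:4], axis=0).min() == 0:
        raise ValueError("constant haplotype score in design")
    if np.linalg.cond(X) > 1e8:
        raise ValueError("collinear design (condition number > 1e8)")
    family = spec.resolved_family()
    res = _fit_glm(y, X, family)
    fit = HaplotypeFit(
        outcome=spec.outcome,
        dataset=dataset,
        beta=np.asarray(res.params[1:4], dtype=float),
        cov=np.asarray(res.cov_params())[1:4, 1:4].astype(float),
        n_used=n,
        family=family,
        trait=trait,
    )
    fit.validate()
    return fit


@dataclass(frozen=True)
class AssociationResult:
    """Observational (potentially confounded) trait-outcome association."""

    exposure: str
    outcome: str
    beta: float
    se: float
    p: float
    n: int
    family: str


def fit_phenotype_association(
    phenotypes: pd.DataFrame,
    exposure: str,
    spec: ModelSpec,
    covariates: tuple[str, ...] | None = None,
) -> AssociationResult:
    """Observational regression of an outcome on a maternal trait.

    Default covariates follow the phenotype-association scheme: maternal
    age, fetal sex, maternal height and prepregnancy BMI (the latter two
    dropped automatically when the exposure is itself one of them), plus
    the gestation polynomial block for birth weight/length.
    """
    if covariates is None:
        covariates = tuple(
            c
            for c in ("maternal_age", "fetal_sex", "maternal_height", "maternal_bmi")
            if c != exposure and c in phenotypes.columns
        )
    spec = ModelSpec(
        outcome=spec.outcome,
        family=spec.family,
        covariates=covariates,
        gestation_adjust=spec.gestation_adjust,
        gestation_degree=spec.gestation_degree,
        dataset_column=spec.dataset_column,
    )
    y, X, n = _design(phenotypes, spec, [exposure])
    if n < 100:
        raise ValueError(f"only {n} complete observations (need >= 100)")
    if np.linalg.cond(X) > 1e8:
        raise ValueError("collinear design (condition number > 1e8)")
    family = spec.resolved_family()
    res = _fit_glm(y, X, family)
    return AssociationResult(
        exposure=exposure,
        outcome=spec.outcome,
        beta=float(res.params[1]),
        se=float(res.bse[1]),
        p=float(res.pvalues[1]),
        n=n,
        family=family,
    )
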