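"""Closed-form genetically confounded associations.

Mother and child share half their alleles, and the SNPs of an adult-trait
score can act directly on a pregnancy outcome in the fetus.  Both routes
generate observational associations with no causal path.  Two directions
are estimated:

* maternal phenotype X → pregnancy outcome Y:
  ``β_XYc = (h²_X / 2) · β_FY / β_MX`` — the fetal genetic effect of the
  X-associated alleles, scaled by the transmitted half of X's additive
  genetic variance (outcome units per X unit);

* pregnancy outcome Y → adult offspring phenotype X′, in SD(X′) per SD(Y):
  Method 1: ``h² · √(Var(X′)/Var(Y)) · (β_MY/2 + β_FY)`` — partitionable
  into a maternal (β_MY/2) and a fetal (β_FY) component;
  Method 2: ``h² · √(Var(X′)/Var(Y)) · (β_h1 + β_h3)/2``.
  The two coincide exactly when the additivity identity
  β_h1 = β_h2 + β_h3 holds in the fitted coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .assoc import HaplotypeFit
from .effects import EffectEstimate

__all__ = [
    "ConfoundedEstimate",
    "confounded_mat_to_outcome",
    "confounded_outcome_to_adult",
]


@dataclass(frozen=True)
class ConfoundedEstimate:
    """A genetically confounded association estimate.

    For Method 1 of the outcome→adult direction the maternal and fetal
    components sum exactly to the total.
    """

    direction: str
    estimate: float
    se: float
    p: float
    method: int | None = None
    maternal_component: float | None = None
    fetal_component: float | None = None

    def ci95(self) -> tuple[float, float]:
        return (self.estimate - 1.96 * self.se, self.estimate + 1.96 * self.se)


def _p(est: float, se: float) -> float:
    return float(2 * stats.norm.sf(abs(est) / se)) if se > 0 else float("nan")


def confounded_mat_to_outcome(
    beta_FY: EffectEstimate | tuple[float, float],
    beta_MX: tuple[float, float],
    h2_x: float,
) -> ConfoundedEstimate:
    """Genetically confounded X→Y association from the fetal effect.

    ``beta_FY`` is the fetal genetic effect of the X score on Y (outcome
    units per score unit), ``beta_MX`` the score-trait association (X
    units per score unit) with its SE, ``h2_x`` the additive heritability
    of X.  Result is in outcome units per X unit.  SE by the first-order
    delta method with zero cross-covariance.
    """
    if not (0.0 <= h2_x <= 1.0):
        raise ValueError("h2_x must be in [0,1]")
    b_fy, se_fy = (
        (beta_FY.estimate, beta_FY.se)
        if isinstance(beta_FY, EffectEstimate)
        else (float(beta_FY[0]), float(beta_FY[1]))
    )
    b_mx, se_mx = float(beta_MX[0]), float(beta_MX[1])
    if b_mx == 0:
        raise ZeroDivisionError("beta_MX is zero")
    scale = h2_x / 2.0
    est = scale * b_fy / b_mx
    se = scale * np.sqrt(se_fy**2 / b_mx**2 + b_fy**2 * se_mx**2 / b_mx**4)
    return ConfoundedEstimate(
        direction="X->Y", estimate=float(est), se=float(se), p=_p(est, se)
    )


def confounded_outcome_to_adult(
    fit: HaplotypeFit,
    h2: float,
    var_adult: float,
    var_outcome: float,
    method: int = 1,
) -> ConfoundedEstimate:
    """Genetically confounded Y→X′ association, in SD(X′) per SD(Y).

    ``fit`` is the joint haplotype fit of the X′ score on the pregnancy
    outcome Y.  ``var_outcome`` should be the gestation-adjusted outcome
    variance when the fit adjusted for gestation.  The SE propagates the
    fit's full coefficient covariance through the linear combination
    (Method 1: ¾β_h1 − ¼β_h2 + ¼β_h3; Method 2: ½β_h1 + ½β_h3).
    """
    if not (0.0 <= h2 <= 1.0):
        raise ValueError("h2 must be in [0,1]")
    if var_adult <= 0 or var_outcome <= 0:
        raise ValueError("variances must be positive")
    fit.validate()
    scale = h2 * np.sqrt(var_adult / var_outcome)
    if method == 1:
        # beta_MY/2 + beta_FY expressed on (b1, b2, b3)
        c = np.array([0.75, -0.25, 0.25])
        mat = 0.5 * float(np.array([0.5, 0.5, -0.5]) @ fit.beta)
        fet = float(np.array([0.5, -0.5, 0.5]) @ fit.beta)
        components = {
            "maternal_component": scale * mat,
            "fetal_component": scale * fet,
        }
    elif method == 2:
        c = np.array([0.5, 0.0, 0.5])
        components = {}
    else:
        raise ValueError("method must be 1 or 2")
    est = scale * float(c @ fit.beta)
    se = scale * float(np.sqrt(c @ fit.cov @ c))
    return ConfoundedEstimate(
        direction="Y->X'",
        estimate=est,
        se=se,
        p=_p(est, se),
        method=method,
        **components,
    )
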