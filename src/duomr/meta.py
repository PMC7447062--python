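"""Inverse-variance meta-analysis with heterogeneity statistics.

Fixed-effect pooling weights each study by 1/SE²; the random-effects
variant adds the DerSimonian-Laird between-study variance τ².  Cochran's Q
(with I² = max(0, (Q − df)/Q)) quantifies heterogeneity.  Heterogeneity is
flagged, never used to switch models automatically — the caller chooses
fixed vs random effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["MetaResult", "fixed_effect_meta", "random_effects_meta"]


@dataclass(frozen=True)
class MetaResult:
    model: str
    beta: float
    se: float
    p: float
    q: float
    df: int
    p_q: float
    i2: float
    tau2: float
    k: int

    @property
    def heterogeneous(self) -> bool:
        """Cochran's Q significant at 0.05 (report flag only)."""
        return self.p_q < 0.05


def _check(betas, ses):
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.shape != ses.shape or betas.ndim != 1:
        raise ValueError("betas and ses must be 1-D and equally long")
    if betas.size == 0:
        raise ValueError("no studies to pool")
    if np.any(ses <= 0) or not np.all(np.isfinite(betas) & np.isfinite(ses)):
        raise ValueError("SEs must be positive and finite")
    return betas, ses


def _q_stats(betas, ses):
    w = 1.0 / ses**2
    pooled = float(np.sum(w * betas) / np.sum(w))
    q = float(np.sum(w * (betas - pooled) ** 2)) if betas.size > 1 else 0.0
    df = betas.size - 1
    p_q = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    i2 = (q - df) / q if q > df else 0.0
    return w, pooled, q, df, p_q, i2


def fixed_effect_meta(betas, ses) -> MetaResult:
    """Fixed-effect (inverse-variance) pooled estimate.

    pooled = Σwβ/Σw with w = 1/SE²; SE = 1/√Σw.  Equivalent to the
    intercept of a weighted least-squares fit of the betas on a constant.
    """
    betas, ses = _check(betas, ses)
    w, pooled, q, df, p_q, i2 = _q_stats(betas, ses)
    se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(2 * stats.norm.sf(abs(pooled) / se))
    return MetaResult("fixed", pooled, se, p, q, df, p_q, i2, 0.0, betas.size)


def random_effects_meta(betas, ses) -> MetaResult:
    """DerSimonian-Laird random-effects pooled estimate.

    τ² = max(0, (Q − df) / (Σw − Σw²/Σw)); studies are re-weighted by
    1/(SE² + τ²).  Requires k >= 2.  Homogeneous inputs (Q <= df) give
    τ² = 0 and reduce exactly to the fixed-effect result.
    """
    betas, ses = _check(betas, ses)
    if betas.size < 2:
        raise ValueError("random-effects pooling needs k >= 2 studies")
    w, _, q, df, p_q, i2 = _q_stats(betas, ses)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (ses**2 + tau2)
    pooled = float(np.sum(w_star * betas) / np.sum(w_star))
    se = float(1.0 / np.sqrt(np.sum(w_star)))
    p = float(2 * stats.norm.sf(abs(pooled) / se))
    return MetaResult("random", pooled, se, p, q, df, p_q, i2, tau2, betas.size)
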