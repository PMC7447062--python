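"""Allele-level multivariable MR with horizontal-pleiotropy diagnostics.

Instead of one weighted score, each SNP contributes a pair of effects: its
published exposure effect (treated as known, two-sample style) and its
allele-class effect (h1, h2 or h3) on the pregnancy outcome, estimated
per SNP from the duo data.  Valid instruments put these pairs on a line
through the origin; the pleiotropy residual-sum-and-outlier procedure
tests departures with three tests — a global residual test, per-variant
outlier tests (Bonferroni across variants) and a distortion test for the
shift in slope caused by removing flagged outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import ModelSpec, orthogonal_polynomials
from .scores import DuoHaplotypes

__all__ = [
    "IvwFit",
    "PressoResult",
    "per_snp_allele_effects",
    "ivw_fit",
    "global_outlier_distortion",
]

ALLELE_CLASSES = ("h1", "h2", "h3")


def per_snp_allele_effects(
    haplotypes: DuoHaplotypes,
    phenotypes: pd.DataFrame,
    spec: ModelSpec,
    weights=None,
) -> pd.DataFrame:
    """Per-SNP regression of the outcome on the three allele indicators.

    For each SNP, fits ``Y ~ h1_j + h2_j + h3_j + Cov`` by least squares
    (batched numpy; the designs differ only in the three allele columns).
    Returns one row per (variant, allele class) with the coefficient and
    SE, plus the exposure-side effect from ``weights`` when given.
    Monomorphic SNPs are skipped and reported in ``attrs['skipped']``.
    """
    df = pd.DataFrame({"pregnancy_id": haplotypes.pregnancy_ids}).merge(
        phenotypes, on="pregnancy_id"
    )
    if len(df) != haplotypes.n_duos:
        raise ValueError("phenotype table does not cover all duos")
    y_all = df[spec.outcome].to_numpy(dtype=float)
    cov_cols = list(spec.covariates)
    need = [spec.outcome, *cov_cols] + (
        ["gestational_days"] if spec.resolved_gestation_adjust() else []
    )
    keep = ~df[list(dict.fromkeys(need))].isna().any(axis=1).to_numpy()
    y_all = y_all[keep]
    blocks = [np.ones((keep.sum(), 1))]
    if cov_cols:
        blocks.append(df.loc[keep, cov_cols].to_numpy(dtype=float))
    if spec.resolved_gestation_adjust():
        blocks.append(
            orthogonal_polynomials(
                df.loc[keep, "gestational_days"].to_numpy(dtype=float),
                spec.gestation_degree,
            )
        )
    C = np.column_stack(blocks)

    wmap = {}
    if weights is not None:
        wmap = {w.variant_id: w.weight for w in weights}

    rows = []
    skipped = []
    for j, vid in enumerate(haplotypes.variant_ids):
        H = np.column_stack(
            [haplotypes.h1[keep, j], haplotypes.h2[keep, j], haplotypes.h3[keep, j]]
        )
        ok = ~np.isnan(H).any(axis=1)
        Hj, yj, Cj = H[ok], y_all[ok], C[ok]
        if np.ptp(Hj, axis=0).min() == 0:
            skipped.append(vid)
            continue
        X = np.column_stack([Hj, Cj])
        xtx = X.T @ X
        beta = np.linalg.solve(xtx, X.T @ yj)
        resid = yj - X @ beta
        dof = len(yj) - X.shape[1]
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(xtx)
        for k, cls in enumerate(ALLELE_CLASSES):
            rows.append(
                {
                    "variant_id": vid,
                    "allele_class": cls,
                    "beta_out": float(beta[k]),
                    "se_out": float(np.sqrt(cov[k, k])),
                    "beta_exp": wmap.get(vid, np.nan),
                    "se_exp": 0.0,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = skipped
    return out


@dataclass(frozen=True)
class IvwFit:
    """Zero-intercept inverse-variance-weighted proportionality fit."""

    slope: float
    se: float
    rss: float
    n_variants: int


def ivw_fit(beta_exp, beta_out, se_out) -> IvwFit:
    """Weighted zero-intercept regression of outcome on exposure effects.

    slope = Σw x y / Σw x² with w = 1/SE_out²; RSS is the weighted
    residual sum of squares.  Requires >= 3 variants.
    """
    x = np.asarray(beta_exp, dtype=float)
    y = np.asarray(beta_out, dtype=float)
    s = np.asarray(se_out, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 variants for the IVW fit")
    if np.all(s == 0):
        # degenerate, exact-proportionality check only
        slope = float(np.sum(x * y) / np.sum(x * x))
        resid = y - slope * x
        if not np.allclose(resid, 0):
            raise ValueError("zero SEs with non-proportional effects")
        return IvwFit(slope, 0.0, 0.0, x.size)
    if np.any(s <= 0):
        raise ValueError("outcome SEs must be positive")
    w = 1.0 / s**2
    sxx = float(np.sum(w * x * x))
    slope = float(np.sum(w * x * y) / sxx)
    se = float(1.0 / np.sqrt(sxx))
    rss = float(np.sum(w * (y - slope * x) ** 2))
    return IvwFit(slope, se, rss, x.size)


@dataclass
class PressoResult:
    """Global, outlier and distortion test results.

    ``global_p`` is the parametric-simulation rank p of the observed
    leave-one-out RSS; ``outlier_p`` is per-variant, with ``outliers``
    flagged at the Bonferroni-adjusted threshold alpha/N.  Slopes before
    and after outlier removal quantify distortion.
    """

    slope_raw: float
    se_raw: float
    slope_corrected: float
    se_corrected: float
    rss_obs: float
    global_p: float
    outlier_p: np.ndarray
    outliers: list = field(default_factory=list)
    distortion_p: float = float("nan")
    n_sim: int = 0


def _loo_slopes(x, y, w):
    """Leave-one-out IVW slopes, vectorised (1-D or (n_sim, N) y)."""
    num = np.sum(w * x * y, axis=-1, keepdims=True) - w * x * y
    den = np.sum(w * x * x) - w * x * x
    return num / den


def global_outlier_distortion(
    beta_exp,
    beta_out,
    se_out,
    n_sim: int = 1000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    variant_ids=None,
) -> PressoResult:
    """Run the three pleiotropy tests on per-variant effect pairs.

    Under the no-pleiotropy null, outcome effects are simulated from
    normal(leave-one-out prediction, SE); the observed leave-one-out
    weighted RSS is ranked within the simulated RSS distribution (global
    test), each observed squared residual within its simulated
    counterparts (outlier test, Bonferroni at ``alpha``/N), and the
    slope displacement after removing flagged outliers within the
    displacement distribution from removing random subsets of the same
    size (distortion test).  Exposure effects are treated as known
    constants (two-sample setting).  Deterministic under a fixed seed;
    the global p lies in [1/(n_sim+1), 1].
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    x = np.asarray(beta_exp, dtype=float)
    y = np.asarray(beta_out, dtype=float)
    s = np.asarray(se_out, dtype=float)
    N = x.size
    if N < 4:
        raise ValueError("need >= 4 variants")
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    if variant_ids is None:
        variant_ids = list(range(N))

    fit = ivw_fit(x, y, s)
    if fit.se == 0.0:  # exact proportionality with zero SEs
        return PressoResult(
            slope_raw=fit.slope,
            se_raw=0.0,
            slope_corrected=fit.slope,
            se_corrected=0.0,
            rss_obs=0.0,
            global_p=1.0,
            outlier_p=np.ones(N),
            outliers=[],
            distortion_p=float("nan"),
            n_sim=n_sim,
        )

    w = 1.0 / s**2
    loo = _loo_slopes(x, y, w)
    resid_obs = w * (y - loo * x) ** 2
    rss_obs = float(np.sum(resid_obs))

    y_sim = rng.normal(loo * x, s, size=(n_sim, N))
    loo_sim = _loo_slopes(x, y_sim, w)
    resid_sim = w * (y_sim - loo_sim * x) ** 2
    rss_sim = resid_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    outlier_p = (1 + np.sum(resid_sim >= resid_obs, axis=0)) / (n_sim + 1)
    flagged = np.flatnonzero(outlier_p < alpha / N)
    if flagged.size == N:
        raise ValueError("all variants flagged as outliers: no stable subset")

    keep = np.setdiff1d(np.arange(N), flagged)
    if keep.size >= 3:
        fit_c = ivw_fit(x[keep], y[keep], s[keep])
    else:
        fit_c = fit
    distortion_p = float("nan")
    if flagged.size > 0 and keep.size >= 3:
        d_obs = fit_c.slope - fit.slope
        disp = np.empty(n_sim)
        for b in range(n_sim):
            drop = rng.choice(N, size=flagged.size, replace=False)
            kb = np.setdiff1d(np.arange(N), drop)
            fb = ivw_fit(x[kb], y[kb], s[kb])
            disp[b] = fb.slope - fit.slope
        distortion_p = float(
            (1 + np.sum(np.abs(disp) >= abs(d_obs))) / (n_sim + 1)
        )

    return PressoResult(
        slope_raw=fit.slope,
        se_raw=fit.se,
        slope_corrected=fit_c.slope,
        se_corrected=fit_c.se,
        rss_obs=rss_obs,
        global_p=global_p,
        outlier_p=outlier_p,
        outliers=[variant_ids[i] for i in flagged],
        distortion_p=distortion_p,
        n_sim=n_sim,
    )
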