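"""Published coefficient tables as machine-readable worked examples.

The package ships the printed haplotype-score coefficients of the source
cohort study (maternal trait scores x birth outcomes; infant birth-weight
score x birth outcomes and maternal pregnancy phenotypes) together with
the printed maternal/fetal contrasts and ratio causal estimates, so the
contrast and ratio arithmetic can be checked end-to-end against printed
numbers without any cohort data.

Printed numbers are rounded, so recomputation is compared under a
rounding-aware tolerance: inputs printed with unit-in-the-last-place u_i
entering a linear combination Σ c_i b_i allow an output discrepancy of
Σ |c_i| · f · u_i plus half the ULP of the printed output (f = the input
ULP fraction).  Some printed contrast rows pooled per-dataset contrasts
rather than contrasting the pooled coefficients, and are not recoverable
from the printed inputs at any rounding tolerance; such rows carry
``consistent = 0`` and are excluded from the pass/fail contract.
"""

from __future__ import annotations

import importlib.resources as resources

import numpy as np
import pandas as pd

from .assoc import HaplotypeFit
from .effects import CONTRAST_VECTORS, TraitMeta, contrast, ratio_causal

__all__ = [
    "TRAIT_SD",
    "ADULT_TRAIT_SD",
    "BIRTHWEIGHT_SD_ADJUSTED",
    "BIRTHWEIGHT_SD_RAW",
    "GESTATION_SD",
    "load_published_effects",
    "load_published_ratios",
    "fit_from_printed",
    "printed_ulp",
    "contrast_tolerance",
    "check_paper_fixtures",
]

#: 1-SD values of the maternal traits, in trait units.
TRAIT_SD = {"height": 6.4, "bmi": 4.0, "bp": 5.8, "fpg": 0.36}
#: 1-SD values assumed for the adult offspring phenotypes.
ADULT_TRAIT_SD = {"height": 6.4, "bmi": 4.0, "bp": 6.9, "fpg": 0.37, "t2d": 1.81}
#: 1 SD of gestational-age-adjusted birth weight, grams.
BIRTHWEIGHT_SD_ADJUSTED = 426.0
#: 1 SD of unadjusted birth weight, grams.
BIRTHWEIGHT_SD_RAW = 484.0
#: 1 SD of gestational duration, days.
GESTATION_SD = 11.4


def _load(name: str) -> pd.DataFrame:
    with resources.files("duomr").joinpath("data", name).open("rt") as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def load_published_effects() -> pd.DataFrame:
    """Printed haplotype coefficients and contrasts, one row per
    (table, trait, outcome, contrast kind).  Values are printed strings."""
    return _load("published_effects.tsv")


def load_published_ratios() -> pd.DataFrame:
    """Printed paternal-instrument ratio causal estimates."""
    return _load("published_ratios.tsv")


def fit_from_printed(
    beta_h1: float, beta_h2: float, beta_h3: float, outcome: str = "", trait: str = ""
) -> HaplotypeFit:
    """Wrap printed haplotype coefficients as a fit (identity covariance),
    so the contrast point estimates can be recomputed through the standard
    estimator.  The printed tables carry no coefficient covariance, so SEs
    from this object are meaningless placeholders."""
    return HaplotypeFit(
        outcome=outcome,
        dataset="published",
        beta=np.array([beta_h1, beta_h2, beta_h3], dtype=float),
        cov=np.eye(3),
        n_used=0,
        family="linear",
        trait=trait,
    )


def printed_ulp(s: str) -> float:
    """Unit in the last place of a printed decimal (handles e-notation)."""
    s = s.strip().lower().replace("−", "-")
    if "e" in s:
        mant, exp = s.split("e")
        return printed_ulp(mant) * 10.0 ** int(exp)
    if "." in s:
        return 10.0 ** -(len(s.split(".")[1]))
    return 1.0


def contrast_tolerance(
    inputs: list[str],
    coeffs,
    output: str,
    input_ulp_fraction: float = 0.5,
) -> float:
    """Rounding-aware tolerance for a linear combination of printed values.

    tol = Σ |c_i| · f · ulp(input_i) + ½ ulp(output).
    """
    coeffs = np.asarray(coeffs, dtype=float)
    tol = sum(
        abs(c) * input_ulp_fraction * printed_ulp(s)
        for c, s in zip(coeffs, inputs, strict=True)
    )
    return float(tol + 0.5 * printed_ulp(output))


def _ratio_tolerance(num: str, den: str, sd: float, output: str, frac: float) -> float:
    n, d = float(num.replace("−", "-")), float(den.replace("−", "-"))
    tol = (
        sd / abs(d) * frac * printed_ulp(num)
        + sd * abs(n) / d**2 * frac * printed_ulp(den)
    )
    return float(tol + 0.5 * printed_ulp(output))


def check_paper_fixtures(
    effects: pd.DataFrame | None = None,
    ratios: pd.DataFrame | None = None,
    input_ulp_fraction: float = 1.0,
) -> pd.DataFrame:
    """Recompute every printed contrast and ratio and compare to print.

    Returns a per-row report (recomputed value, printed value, tolerance,
    pass flag, difference) — a report only, it never raises.  Rows with
    ``consistent = 0`` are known not to be recoverable from the printed
    inputs (pooling-order artefact) and are reported but not expected to
    pass.
    """
    if effects is None:
        effects = load_published_effects()
    if ratios is None:
        ratios = load_published_ratios()
    rows = []
    for _, r in effects.iterrows():
        c = CONTRAST_VECTORS[r["kind"]]
        fit = fit_from_printed(
            *(float(r[k].replace("−", "-")) for k in ("beta_h1", "beta_h2", "beta_h3")),
            outcome=r["outcome"],
            trait=r["trait"],
        )
        got = contrast(fit, r["kind"]).estimate
        want = float(r["expected"].replace("−", "-"))
        tol = contrast_tolerance(
            [r["beta_h1"], r["beta_h2"], r["beta_h3"]],
            c,
            r["expected"],
            input_ulp_fraction,
        )
        rows.append(
            {
                "table": r["table"],
                "trait": r["trait"],
                "outcome": r["outcome"],
                "quantity": r["kind"],
                "recomputed": got,
                "printed": want,
                "tolerance": tol,
                "difference": got - want,
                "consistent": int(r["consistent"]),
                "passed": abs(got - want) <= tol,
            }
        )
    for _, r in ratios.iterrows():
        sd = float(r["sd"])
        meta = TraitMeta(name="fetal_growth", sd=sd)
        est = ratio_causal(
            (float(r["beta_h3_out"].replace("−", "-")), 1.0),
            (float(r["beta_h3_growth"].replace("−", "-")), 1e-12),
            trait_meta=meta,
        )
        got = est.per_sd
        want = float(r["expected"].replace("−", "-"))
        tol = _ratio_tolerance(
            r["beta_h3_out"], r["beta_h3_growth"], sd, r["expected"], input_ulp_fraction
        )
        rows.append(
            {
                "table": r["table"],
                "trait": "fetal_growth",
                "outcome": r["outcome"],
                "quantity": "causal_ratio",
                "recomputed": got,
                "printed": want,
                "tolerance": tol,
                "difference": got - want,
                "consistent": int(r["consistent"]),
                "passed": abs(got - want) <= tol,
            }
        )
    return pd.DataFrame(rows)
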