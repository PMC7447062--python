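"""Readers and writers for the tab-delimited formats used throughout the package.

Four external formats are supported: SNP weight files (per-allele effect
sizes in trait units), phased VCF 4.x plus a duo pedigree, per-pregnancy
phenotype tables, and flat result tables.  All tables are UTF-8 TSV with a
header row; missing phenotype values are coded ``NA``.  Coordinates follow
the 1-based VCF convention and alleles must match the weight file exactly
(no strand flipping); mismatching variants are excluded and counted, never
silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "VariantWeight",
    "PhasedDuos",
    "FormatError",
    "read_weights",
    "write_weights",
    "read_pedigree",
    "read_phased_duos",
    "read_phenotypes",
    "write_phenotypes",
    "write_results",
    "read_results",
    "PHENOTYPE_COLUMNS",
]

NA_TOKEN = "NA"
_VALID_ALLELES = frozenset("ACGT")

#: Quantitative / categorical phenotype columns of a per-pregnancy table.
PHENOTYPE_COLUMNS = [
    "pregnancy_id",
    "maternal_age",
    "maternal_height",
    "maternal_bmi",
    "sbp",
    "dbp",
    "fpg",
    "gestational_days",
    "preterm",
    "birth_weight",
    "birth_length",
    "adult_trait",
    "fetal_sex",
    "dataset",
]

_NUMERIC_PHENO = [
    "maternal_age",
    "maternal_height",
    "maternal_bmi",
    "sbp",
    "dbp",
    "fpg",
    "gestational_days",
    "preterm",
    "birth_weight",
    "birth_length",
    "adult_trait",
    "fetal_sex",
]


class FormatError(ValueError):
    """Malformed input file; the message names the offending line."""


@dataclass(frozen=True)
class VariantWeight:
    """One SNP of a weighted genetic score.

    ``weight`` is in trait units per copy of ``effect_allele``; ``pos`` is
    1-based.  Within a weight set the (chrom, pos, allele-pair) coordinate
    must be unique.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    weight: float
    trait: str = ""

    def __post_init__(self) -> None:
        if self.effect_allele not in _VALID_ALLELES:
            raise FormatError(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in _VALID_ALLELES:
            raise FormatError(f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise FormatError(
                f"{self.variant_id}: effect and other allele are both "
                f"{self.effect_allele!r}"
            )
        if not math.isfinite(self.weight):
            raise FormatError(f"{self.variant_id}: non-finite weight")


_WEIGHT_FIELDS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "weight",
    "trait",
]


def read_weights(path) -> list[VariantWeight]:
    """Read a SNP weight TSV and return validated records.

    The file must carry a header naming at least the six mandatory fields
    (``trait`` is optional).  Duplicate (chrom, pos, allele-pair)
    coordinates are rejected.  Records are returned sorted by (chrom, pos)
    so parsing is independent of file order.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [f for f in _WEIGHT_FIELDS[:6] if f not in header]
        if missing:
            raise FormatError(f"{path}: header missing fields {missing}")
        idx = {name: header.index(name) for name in _WEIGHT_FIELDS if name in header}
        out: list[VariantWeight] = []
        seen: set[tuple] = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                w = VariantWeight(
                    variant_id=parts[idx["variant_id"]],
                    chrom=parts[idx["chrom"]],
                    pos=int(parts[idx["pos"]]),
                    effect_allele=parts[idx["effect_allele"]],
                    other_allele=parts[idx["other_allele"]],
                    weight=float(parts[idx["weight"]]),
                    trait=parts[idx["trait"]] if "trait" in idx else "",
                )
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            key = (w.chrom, w.pos, frozenset((w.effect_allele, w.other_allele)))
            if key in seen:
                raise FormatError(
                    f"{path}:{lineno}: duplicate variant at {w.chrom}:{w.pos} "
                    f"{w.effect_allele}/{w.other_allele}"
                )
            seen.add(key)
            out.append(w)
    out.sort(key=lambda w: (w.chrom, w.pos))
    return out


def write_weights(weights, path) -> None:
    """Write weight records as TSV (sorted canonical order, full precision)."""
    rows = sorted(weights, key=lambda w: (w.chrom, w.pos))
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(_WEIGHT_FIELDS) + "\n")
        for w in rows:
            fh.write(
                f"{w.variant_id}\t{w.chrom}\t{w.pos}\t{w.effect_allele}\t"
                f"{w.other_allele}\t{w.weight!r}\t{w.trait}\n"
            )


@dataclass
class PhasedDuos:
    """Phased mother-child genotypes over a SNP panel, recoded to
    effect-allele indicators.

    ``mother`` and ``child`` are ``(n_duos, n_variants, 2)`` int8 arrays of
    0/1 indicators (1 = effect allele).  The child's first allele is the
    maternal-origin allele under the default ``maternal-first`` convention.
    ``exclusions`` reports weight-set variants not usable from the VCF.
    """

    pregnancy_ids: list[str]
    variant_ids: list[str]
    mother: np.ndarray
    child: np.ndarray
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "reason"])
    )

    @property
    def n_duos(self) -> int:
        return len(self.pregnancy_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)


def read_pedigree(path) -> pd.DataFrame:
    """Read a duo pedigree TSV mapping child to mother sample IDs."""
    ped = pd.read_csv(path, sep="\t", dtype=str)
    need = {"child_id", "mother_id", "pregnancy_id"}
    if not need.issubset(ped.columns):
        raise FormatError(f"{path}: pedigree requires columns {sorted(need)}")
    return ped


def read_phased_duos(
    vcf_path, pedigree_path, weights, child_order: str = "maternal-first"
) -> PhasedDuos:
    """Read phased duo genotypes for the variants of a weight set.

    Matching is on (chrom, pos, allele pair); sites whose REF/ALT do not
    equal the weight file's allele pair are excluded with reason
    ``allele_mismatch``, and panel variants absent from the VCF with reason
    ``missing``.  Genotypes are recoded so 1 means the effect allele.
    Unphased genotypes ("/") raise :class:`FormatError`.

    ``child_order`` declares the phase convention of the child's GT field:
    ``maternal-first`` (default, Shapeit2-style duo output) or
    ``paternal-first``.
    """
    if child_order not in ("maternal-first", "paternal-first"):
        raise ValueError(f"unknown child_order {child_order!r}")
    ped = read_pedigree(pedigree_path)
    weights = sorted(weights, key=lambda w: (w.chrom, w.pos))
    want = {(w.chrom, w.pos): w for w in weights}

    vcf = pysam.VariantFile(str(vcf_path))
    samples = list(vcf.header.samples)
    sample_idx = {s: i for i, s in enumerate(samples)}
    for col in ("child_id", "mother_id"):
        unknown = set(ped[col]) - set(samples)
        if unknown:
            raise FormatError(f"{col} not found in VCF: {sorted(unknown)[:5]}")

    found: dict[tuple, np.ndarray] = {}
    excluded: list[tuple[str, str]] = []
    for rec in vcf:
        key = (rec.chrom, rec.pos)
        w = want.get(key)
        if w is None:
            continue
        alts = rec.alts or ()
        if len(alts) != 1 or {rec.ref, alts[0]} != {w.effect_allele, w.other_allele}:
            excluded.append((w.variant_id, "allele_mismatch"))
            continue
        gt_matrix = np.empty((len(samples), 2), dtype=np.int8)
        for i, sample in enumerate(rec.samples.values()):
            if not sample.phased:
                raise FormatError(
                    f"unphased genotype at {rec.chrom}:{rec.pos} "
                    f"sample {samples[i]}"
                )
            a, b = sample["GT"]
            gt_matrix[i, 0], gt_matrix[i, 1] = a, b
        if w.effect_allele == rec.ref:
            gt_matrix = 1 - gt_matrix
        found[key] = gt_matrix
    vcf.close()

    kept = [w for w in weights if (w.chrom, w.pos) in found]
    for w in weights:
        if (w.chrom, w.pos) not in found and w.variant_id not in {
            v for v, _ in excluded
        }:
            excluded.append((w.variant_id, "missing"))

    n_duos, n_var = len(ped), len(kept)
    mother = np.zeros((n_duos, n_var, 2), dtype=np.int8)
    child = np.zeros((n_duos, n_var, 2), dtype=np.int8)
    m_rows = ped["mother_id"].map(sample_idx).to_numpy()
    c_rows = ped["child_id"].map(sample_idx).to_numpy()
    for j, w in enumerate(kept):
        gt = found[(w.chrom, w.pos)]
        mother[:, j, :] = gt[m_rows]
        child[:, j, :] = gt[c_rows]
    if child_order == "paternal-first":
        child = child[:, :, ::-1]

    exclusions = pd.DataFrame(excluded, columns=["variant_id", "reason"])
    return PhasedDuos(
        pregnancy_ids=list(ped["pregnancy_id"]),
        variant_ids=[w.variant_id for w in kept],
        mother=mother,
        child=child,
        exclusions=exclusions,
    )


def read_phenotypes(path) -> pd.DataFrame:
    """Read a per-pregnancy phenotype TSV (``NA`` = missing).

    Checks that the preterm flag, where present, is consistent with
    gestational days (< 259) and that quantitative fields are finite.
    """
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)
    if "pregnancy_id" not in df.columns:
        raise FormatError(f"{path}: phenotype table requires pregnancy_id")
    for col in _NUMERIC_PHENO:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
            if np.isinf(df[col].to_numpy(dtype=float, na_value=np.nan)).any():
                raise FormatError(f"{path}: non-finite values in {col}")
    if {"preterm", "gestational_days"}.issubset(df.columns):
        both = df["preterm"].notna() & df["gestational_days"].notna()
        expect = (df.loc[both, "gestational_days"] < 259).astype(int)
        if not (df.loc[both, "preterm"].astype(int) == expect).all():
            raise FormatError(
                f"{path}: preterm flag inconsistent with gestational_days"
            )
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


_RESULT_COLUMNS = [
    "trait",
    "outcome",
    "dataset",
    "term",
    "beta",
    "se",
    "p",
    "n",
]

#: Row order of one haplotype fit in a result table.
RESULT_TERMS = ["h1", "h2", "h3", "maternal", "fetal"]


def write_results(rows, path) -> None:
    """Write a flat result table (one row per coefficient or contrast).

    ``rows`` is an iterable of dicts with keys ``trait, outcome, dataset,
    term, beta, se, p, n``.  Betas are written with ``repr`` so a
    write-read round trip is lossless; rows are sorted canonically.
    """
    df = pd.DataFrame(list(rows), columns=_RESULT_COLUMNS)
    df = df.sort_values(
        ["trait", "outcome", "dataset", "term"],
        key=lambda s: s.map(
            {t: i for i, t in enumerate(RESULT_TERMS)}
        ) if s.name == "term" else s,
        kind="stable",
    )
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(_RESULT_COLUMNS) + "\n")
        for _, r in df.iterrows():
            fh.write(
                f"{r.trait}\t{r.outcome}\t{r.dataset}\t{r.term}\t"
                f"{float(r.beta)!r}\t{float(r.se)!r}\t{float(r.p)!r}\t"
                f"{int(r.n)}\n"
            )


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: result table missing columns {missing}")
    return df
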