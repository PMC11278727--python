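"""Reading, validating and writing GWAS summary statistics and LD references.

All file contact of the pipeline goes through this module. Formats are fixed
tab-separated dialects (see the README); no auto-detection of alternative
GWAS header conventions is attempted, by design.

Coordinates are 1-based, windows inclusive on both ends. Alleles are single
ACGT bases (indels and multi-allelics are out of scope).
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "VariantAssociation",
    "SumStats",
    "LDReference",
    "read_sumstats",
    "read_ld",
    "write_results",
    "read_results",
    "write_sumstats",
    "write_ld",
]

VALID_ALLELES = frozenset("ACGT")

SUMSTATS_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]
BINARY_EXTRA_COLUMNS = ["n_case", "n_control"]

RESULT_COLUMNS = [
    "exposure_id",
    "method",
    "n_iv",
    "theta",
    "se",
    "or",
    "ci_low",
    "ci_high",
    "pvalue",
    "steiger_direction",
    "steiger_pvalue",
    "iv_ids",
]


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary-statistics row.

    ``beta`` is per effect-allele copy: per-SD units for quantitative
    exposures, log-odds for a binary outcome. ``eaf`` may be NaN only when
    palindromic variants are dropped downstream (the fixed policy here), in
    which case it is not needed for strand inference.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: float
    n_case: float | None = None
    n_control: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", str(self.effect_allele).upper())
        object.__setattr__(self, "other_allele", str(self.other_allele).upper())
        self.validate()

    def validate(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.variant_id}: non-ACGT effect allele {self.effect_allele!r}"
            )
        if self.other_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.variant_id}: non-ACGT other allele {self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.variant_id}: identical alleles")
        if not (self.pos >= 1):
            raise ValidationError(f"{self.variant_id}: pos must be >= 1")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValidationError(f"{self.variant_id}: se must be finite and > 0")
        if not math.isnan(self.eaf) and not (0.0 <= self.eaf <= 1.0):
            raise ValidationError(f"{self.variant_id}: eaf outside [0, 1]")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValidationError(f"{self.variant_id}: pvalue outside (0, 1]")
        if not (self.n >= 2):
            raise ValidationError(f"{self.variant_id}: n must be >= 2")

    @property
    def zscore(self) -> float:
        return self.beta / self.se

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)


@dataclass
class SumStats:
    """A full summary-statistics table for one trait, keyed by variant id."""

    trait_id: str
    trait_type: str  # "quantitative" | "binary"
    records: dict[str, VariantAssociation] = field(default_factory=dict)
    n_rejected: int = 0
    rejection_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValidationError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary":
            for rec in self.records.values():
                if rec.n_case is None or rec.n_control is None:
                    raise ValidationError(
                        f"{rec.variant_id}: binary trait requires n_case/n_control"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.records

    def __getitem__(self, variant_id: str) -> VariantAssociation:
        return self.records[variant_id]


class LDReference:
    """Pairwise signed-r LD structure with variant positions.

    Absent pairs mean r = 0; the diagonal is exactly 1; storage is symmetric
    by construction (keys canonicalised by sorting).
    """

    def __init__(
        self,
        positions: dict[str, tuple[str, int]] | None = None,
        r: dict[tuple[str, str], float] | None = None,
    ) -> None:
        self.positions: dict[str, tuple[str, int]] = dict(positions or {})
        self._r: dict[tuple[str, str], float] = {}
        for (a, b), value in (r or {}).items():
            self.set_r(a, b, value)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set_r(self, a: str, b: str, value: float) -> None:
        if a == b:
            if not math.isclose(value, 1.0, rel_tol=0, abs_tol=1e-9):
                raise ValidationError(f"self-pair ({a},{b}) must have r = 1")
            return
        if abs(value) > 1.0 + 1e-12:
            raise ValidationError(f"|r| > 1 for pair ({a},{b}): {value}")
        self._r[self._key(a, b)] = float(np.clip(value, -1.0, 1.0))

    def r(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r.get(self._key(a, b), 0.0)

    def r2(self, a: str, b: str) -> float:
        value = self.r(a, b)
        return value * value

    def pairs(self):
        return self._r.items()

    def update(self, other: "LDReference") -> None:
        """Merge another reference in-place (used when pooling simulated panels)."""
        self.positions.update(other.positions)
        for (a, b), value in other.pairs():
            self.set_r(a, b, value)


def _require_columns(df: pd.DataFrame, required: list[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_sumstats(path: str | os.PathLike, trait_type: str) -> SumStats:
    """Parse a summary-statistics TSV into a validated :class:`SumStats`.

    Rows violating per-variant invariants are rejected and counted (with a
    per-row diagnostic in ``rejection_reasons``); a duplicated variant id is
    an error, as is a missing required column.
    """
    path = os.fspath(path)
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str})
    required = list(SUMSTATS_COLUMNS)
    if trait_type == "binary":
        required += BINARY_EXTRA_COLUMNS
    _require_columns(df, required, path)

    dup = df["variant_id"][df["variant_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(
            f"{path}: duplicate variant_id(s): {', '.join(sorted(set(dup)))}"
        )

    records: dict[str, VariantAssociation] = {}
    rejections: list[str] = []
    missing_eaf = 0
    for row in df.itertuples(index=False):
        try:
            eaf = float(row.eaf) if not pd.isna(row.eaf) else float("nan")
            if math.isnan(eaf):
                missing_eaf += 1
            rec = VariantAssociation(
                variant_id=str(row.variant_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                effect_allele=str(row.effect_allele),
                other_allele=str(row.other_allele),
                eaf=eaf,
                beta=float(row.beta),
                se=float(row.se),
                pvalue=float(row.pvalue),
                n=float(row.n),
                n_case=float(row.n_case) if trait_type == "binary" else None,
                n_control=float(row.n_control) if trait_type == "binary" else None,
            )
        except (ValidationError, ValueError) as exc:
            rejections.append(str(exc))
            continue
        records[rec.variant_id] = rec

    if missing_eaf:
        warnings.warn(
            f"{path}: {missing_eaf} row(s) with missing eaf; acceptable only "
            "because palindromic variants are dropped rather than frequency-aligned",
            stacklevel=2,
        )
    trait_id = os.path.splitext(os.path.basename(path))[0]
    return SumStats(
        trait_id=trait_id,
        trait_type=trait_type,
        records=records,
        n_rejected=len(rejections),
        rejection_reasons=rejections,
    )


def write_sumstats(sumstats: SumStats, path: str | os.PathLike) -> None:
    """Inverse of :func:`read_sumstats`, value-preserving to 12 significant digits."""
    binary = sumstats.trait_type == "binary"
    cols = SUMSTATS_COLUMNS + (BINARY_EXTRA_COLUMNS if binary else [])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in sumstats.records.values():
            row = [
                rec.variant_id,
                rec.chrom,
                str(rec.pos),
                rec.effect_allele,
                rec.other_allele,
                _fmt(rec.eaf),
                _fmt(rec.beta),
                _fmt(rec.se),
                _fmt(rec.pvalue),
                _fmt(rec.n),
            ]
            if binary:
                row += [_fmt(rec.n_case), _fmt(rec.n_control)]
            fh.write("\t".join(row) + "\n")


def _fmt(x: float | None) -> str:
    if x is None:
        return "NA"
    return format(float(x), ".12g")


def read_ld(path: str | os.PathLike, strict_ld: bool = True) -> LDReference:
    """Read an LD reference directory (``positions.tsv`` + ``ld.tsv``).

    The symmetric closure is applied on read; absent pairs mean r = 0.
    Conflicting duplicate entries for a pair are an error. A self-pair row
    with r != 1 is an error under ``strict_ld`` (default) or coerced to 1
    otherwise.
    """
    path = os.fspath(path)
    pos_path = os.path.join(path, "positions.tsv")
    ld_path = os.path.join(path, "ld.tsv")
    pos_df = pd.read_csv(pos_path, sep="\t", dtype={"variant_id": str, "chrom": str})
    _require_columns(pos_df, ["variant_id", "chrom", "pos"], pos_path)
    ld_df = pd.read_csv(ld_path, sep="\t", dtype={"id_a": str, "id_b": str})
    _require_columns(ld_df, ["id_a", "id_b", "r"], ld_path)

    ref = LDReference()
    for row in pos_df.itertuples(index=False):
        ref.positions[str(row.variant_id)] = (str(row.chrom), int(row.pos))

    seen: dict[tuple[str, str], float] = {}
    for row in ld_df.itertuples(index=False):
        a, b, r = str(row.id_a), str(row.id_b), float(row.r)
        if a == b:
            if not math.isclose(r, 1.0, rel_tol=0, abs_tol=1e-9):
                if strict_ld:
                    raise ValidationError(
                        f"{ld_path}: self-pair ({a},{a}) with r = {r} != 1"
                    )
                r = 1.0
            continue
        key = LDReference._key(a, b)
        if key in seen and not math.isclose(seen[key], r, rel_tol=1e-9, abs_tol=1e-12):
            raise ValidationError(
                f"{ld_path}: conflicting r values for pair ({a},{b}): "
                f"{seen[key]} vs {r}"
            )
        seen[key] = r
        ref.set_r(a, b, r)
    return ref


def write_ld(ref: LDReference, path: str | os.PathLike) -> None:
    """Write an LD reference directory in the dialect :func:`read_ld` expects."""
    os.makedirs(path, exist_ok=True)
    with open(os.path.join(path, "positions.tsv"), "w", encoding="utf-8") as fh:
        fh.write("variant_id\tchrom\tpos\n")
        for vid, (chrom, pos) in sorted(ref.positions.items()):
            fh.write(f"{vid}\t{chrom}\t{pos}\n")
    with open(os.path.join(path, "ld.tsv"), "w", encoding="utf-8") as fh:
        fh.write("id_a\tid_b\tr\n")
        for (a, b), r in sorted(ref.pairs()):
            fh.write(f"{a}\t{b}\t{_fmt(r)}\n")


def write_results(results, path: str | os.PathLike) -> None:
    """Write MR results as the fixed-dialect TSV, one row per (exposure, method).

    Round-tripping through :func:`read_results` recovers every numeric field
    to at least 10 significant digits.
    """
    results = list(results)
    if not results:
        warnings.warn("write_results called with an empty collection", stacklevel=2)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for res in results:
            direction = "exposure_to_outcome" if res.steiger_correct else "uncertain"
            row = [
                res.exposure_id,
                res.method,
                str(res.n_iv),
                _fmt(res.theta),
                _fmt(res.se_theta),
                _fmt(res.or_),
                _fmt(res.ci_low),
                _fmt(res.ci_high),
                _fmt(res.pvalue),
                direction,
                _fmt(res.steiger_pvalue),
                ",".join(res.iv_ids),
            ]
            fh.write("\t".join(row) + "\n")


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    """Read a results TSV back into a DataFrame (round-trip counterpart)."""
    df = pd.read_csv(path, sep="\t", dtype={"exposure_id": str, "iv_ids": str})
    _require_columns(df, RESULT_COLUMNS, os.fspath(path))
    return df
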