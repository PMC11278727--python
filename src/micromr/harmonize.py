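"""Aligning exposure and outcome effects onto a shared effect allele.

Palindromic variants (A/T or C/G pairs) are dropped outright — no
frequency-based strand inference. Allele-set mismatches that no swap or
strand complement can resolve are dropped as ``allele_mismatch``. Variants
rarer than the MAF threshold (inclusive at the boundary, judged on the
exposure-study frequency) are dropped as ``maf``. The exposure effect
orientation is never altered; only the outcome record is re-expressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import UsageError
from .sumstats_io import SumStats, VariantAssociation
from .instruments import InstrumentSet

__all__ = [
    "COMPLEMENT",
    "HarmonizedInstrument",
    "Exclusion",
    "is_palindromic",
    "align",
    "harmonize_set",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEFAULT_MAF_THRESHOLD = 0.01


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is its own reverse complement ({A,T} or {C,G})."""
    return COMPLEMENT[effect_allele] == other_allele


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An instrument with exposure and outcome effects on one effect allele."""

    variant_id: str
    effect_allele: str
    other_allele: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    eaf: float
    n_x: float
    n_y: float
    f_stat: float
    n_case_y: float | None = None
    n_control_y: float | None = None


@dataclass(frozen=True)
class Exclusion:
    variant_id: str
    reason: str  # palindrome | allele_mismatch | maf | missing_in_outcome


def align(
    exposure_rec: VariantAssociation,
    outcome_rec: VariantAssociation,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    f_stat: float | None = None,
) -> HarmonizedInstrument | Exclusion:
    """Harmonize one exposure/outcome record pair.

    Cases, tested in order: palindromic pair -> drop; identical allele pairs
    -> copy; swapped alleles -> negate the outcome beta; strand-complement
    match (with or without swap) -> complement then proceed; anything else
    -> ``allele_mismatch``. After alignment a MAF <= threshold (exposure
    frequency) excludes the variant.
    """
    if exposure_rec.variant_id != outcome_rec.variant_id:
        raise UsageError(
            f"variant_id mismatch: {exposure_rec.variant_id} vs {outcome_rec.variant_id}"
        )
    vid = exposure_rec.variant_id
    ea_x, oa_x = exposure_rec.effect_allele, exposure_rec.other_allele
    ea_y, oa_y = outcome_rec.effect_allele, outcome_rec.other_allele

    if is_palindromic(ea_x, oa_x) or is_palindromic(ea_y, oa_y):
        return Exclusion(vid, "palindrome")

    beta_y = None
    if (ea_y, oa_y) == (ea_x, oa_x):
        beta_y = outcome_rec.beta
    elif (ea_y, oa_y) == (oa_x, ea_x):
        beta_y = -outcome_rec.beta
    else:
        ea_c, oa_c = COMPLEMENT[ea_y], COMPLEMENT[oa_y]
        if (ea_c, oa_c) == (ea_x, oa_x):
            beta_y = outcome_rec.beta
        elif (ea_c, oa_c) == (oa_x, ea_x):
            beta_y = -outcome_rec.beta
    if beta_y is None:
        return Exclusion(vid, "allele_mismatch")

    eaf = exposure_rec.eaf
    if not math.isnan(eaf) and min(eaf, 1.0 - eaf) <= maf_threshold:
        return Exclusion(vid, "maf")

    if f_stat is None:
        z = exposure_rec.beta / exposure_rec.se
        f_stat = z * z
    return HarmonizedInstrument(
        variant_id=vid,
        effect_allele=ea_x,
        other_allele=oa_x,
        beta_x=exposure_rec.beta,
        se_x=exposure_rec.se,
        beta_y=beta_y,
        se_y=outcome_rec.se,
        eaf=eaf,
        n_x=exposure_rec.n,
        n_y=outcome_rec.n,
        f_stat=f_stat,
        n_case_y=outcome_rec.n_case,
        n_control_y=outcome_rec.n_control,
    )


def harmonize_set(
    instruments: InstrumentSet,
    outcome: SumStats,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
) -> tuple[list[HarmonizedInstrument], list[Exclusion]]:
    """Harmonize every selected instrument against the outcome study.

    Instruments absent from the outcome are excluded as
    ``missing_in_outcome``. The returned harmonized + excluded lists jointly
    account for every input instrument (conservation).
    """
    harmonized: list[HarmonizedInstrument] = []
    exclusions: list[Exclusion] = []
    for cand in instruments.members:
        vid = cand.assoc.variant_id
        if vid not in outcome:
            exclusions.append(Exclusion(vid, "missing_in_outcome"))
            continue
        result = align(
            cand.assoc, outcome[vid], maf_threshold=maf_threshold, f_stat=cand.f_stat
        )
        if isinstance(result, Exclusion):
            exclusions.append(result)
        else:
            harmonized.append(result)
    return harmonized, exclusions
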