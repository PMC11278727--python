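"""Instrument selection: significance filter, greedy LD clumping, F screen.

The selection pipeline is significance -> clump -> F-filter, with strict
inequalities at both thresholds (keep p < p_threshold; drop F < f_min).
Defaults: p_threshold 1e-8, clump r^2 0.001, 10 Mb window, minimum F 10.

Note the genome-wide significance default is 1e-8 (not the conventional
5e-8); this mirrors the analysis being reproduced and can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DomainError, ValidationError
from .sumstats_io import LDReference, SumStats, VariantAssociation

__all__ = [
    "InstrumentCandidate",
    "InstrumentSet",
    "f_statistic",
    "f_statistic_from_r2",
    "significance_filter",
    "clump",
    "select_instruments",
]

DEFAULT_P_THRESHOLD = 1e-8
DEFAULT_R2_THRESHOLD = 0.001
DEFAULT_WINDOW_BP = 10_000_000
DEFAULT_MIN_F = 10.0


def f_statistic(beta: float, se: float) -> float:
    """Single-variant instrument-strength F, the squared z-score (beta/se)^2."""
    if se <= 0:
        raise DomainError("se must be > 0")
    z = beta / se
    return z * z


def f_statistic_from_r2(r2: float, n: float) -> float:
    """Alternative F from explained variance: r2 * (n - 2) / (1 - r2)."""
    if not (0 <= r2 < 1):
        raise DomainError("r2 must be in [0, 1)")
    if n <= 2:
        raise DomainError("n must be > 2")
    return r2 * (n - 2) / (1 - r2)


@dataclass(frozen=True)
class InstrumentCandidate:
    """A variant association together with its instrument-strength F."""

    assoc: VariantAssociation
    f_stat: float

    @classmethod
    def from_assoc(cls, assoc: VariantAssociation) -> "InstrumentCandidate":
        return cls(assoc=assoc, f_stat=f_statistic(assoc.beta, assoc.se))


@dataclass
class InstrumentSet:
    """Selected instruments plus the disposition of every input variant.

    ``selection_log`` maps variant_id to one of: ``kept``, ``dropped_p``,
    ``dropped_F``, ``clumped_away_by:<index id>``.
    """

    exposure_id: str
    members: list[InstrumentCandidate] = field(default_factory=list)
    selection_log: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def variant_ids(self) -> list[str]:
        return [c.assoc.variant_id for c in self.members]


def significance_filter(
    sumstats: SumStats, p_threshold: float = DEFAULT_P_THRESHOLD
) -> list[VariantAssociation]:
    """Keep rows with pvalue strictly below the threshold (boundary excluded)."""
    if not (0 < p_threshold < 1):
        raise DomainError("p_threshold must be in (0, 1)")
    return [rec for rec in sumstats.records.values() if rec.pvalue < p_threshold]


def _canonical_order(rec: VariantAssociation):
    # ties on p broken lexicographically so output is input-order independent
    return (rec.pvalue, rec.chrom, rec.pos, rec.variant_id)


def clump(
    candidates,
    ld: LDReference,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    window_bp: int = DEFAULT_WINDOW_BP,
    exposure_id: str = "",
) -> InstrumentSet:
    """Greedy LD clumping.

    Repeatedly take the remaining candidate with the smallest p-value as the
    index variant, then remove every remaining candidate on the same
    chromosome within ``window_bp`` (inclusive) whose r^2 with the index
    exceeds ``r2_threshold``. Clumping uses r^2 = r*r from the signed
    reference; the sign is irrelevant here. Cross-chromosome pairs are never
    clumped, whatever the recorded r.
    """
    candidates = list(candidates)
    for rec in candidates:
        if rec.variant_id not in ld.positions:
            raise ValidationError(
                f"candidate {rec.variant_id} absent from the LD reference positions"
            )
    remaining = sorted(candidates, key=_canonical_order)
    kept: list[InstrumentCandidate] = []
    log: dict[str, str] = {}
    while remaining:
        index = remaining.pop(0)
        kept.append(InstrumentCandidate.from_assoc(index))
        log[index.variant_id] = "kept"
        idx_chrom, idx_pos = ld.positions[index.variant_id]
        survivors = []
        for rec in remaining:
            chrom, pos = ld.positions[rec.variant_id]
            in_window = chrom == idx_chrom and abs(pos - idx_pos) <= window_bp
            if in_window and ld.r2(index.variant_id, rec.variant_id) > r2_threshold:
                log[rec.variant_id] = f"clumped_away_by:{index.variant_id}"
            else:
                survivors.append(rec)
        remaining = survivors
    return InstrumentSet(exposure_id=exposure_id, members=kept, selection_log=log)


def select_instruments(
    sumstats: SumStats,
    ld: LDReference,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    f_min: float = DEFAULT_MIN_F,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> InstrumentSet:
    """Full instrument selection for one exposure.

    Composition: significance filter, then clumping, then the weak-instrument
    screen (drop F < f_min; F equal to the threshold is retained). The
    selection log accounts for every variant in the input.
    """
    significant = significance_filter(sumstats, p_threshold)
    clumped = clump(
        significant,
        ld,
        r2_threshold=r2_threshold,
        window_bp=window_bp,
        exposure_id=sumstats.trait_id,
    )
    log = {vid: "dropped_p" for vid in sumstats.records}
    log.update(clumped.selection_log)
    members = []
    for cand in clumped.members:
        if cand.f_stat < f_min:
            log[cand.assoc.variant_id] = "dropped_F"
        else:
            members.append(cand)
    return InstrumentSet(
        exposure_id=sumstats.trait_id, members=members, selection_log=log
    )
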