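import math

import pytest
from scipy import stats

from micromr.harmonize import harmonize_set
from micromr.instruments import InstrumentCandidate, InstrumentSet
from micromr.sumstats_io import SumStats, VariantAssociation


def make_assoc(
    variant_id="rs1",
    chrom="1",
    pos=1000,
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.01,
    pvalue=None,
    n=10_000,
    n_case=None,
    n_control=None,
):
    """Build a VariantAssociation; p defaults to the two-sided Wald p of beta/se."""
    if pvalue is None:
        pvalue = max(2 * stats.norm.sf(abs(beta / se)), 1e-320)
    return VariantAssociation(
        variant_id=variant_id,
        chrom=chrom,
        pos=pos,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=eaf,
        beta=beta,
        se=se,
        pvalue=pvalue,
        n=n,
        n_case=n_case,
        n_control=n_control,
    )


def make_sumstats(records, trait_id="exp", trait_type="quantitative"):
    return SumStats(
        trait_id=trait_id,
        trait_type=trait_type,
        records={r.variant_id: r for r in records},
    )


def harmonized_from_sim(sim, maf_threshold=0.01):
    """Push every simulated exposure variant through real harmonization."""
    members = [
        InstrumentCandidate.from_assoc(rec)
        for rec in sim.exposure_sumstats.records.values()
    ]
    inst = InstrumentSet(exposure_id=sim.exposure_sumstats.trait_id, members=members)
    harmonized, _ = harmonize_set(inst, sim.outcome_sumstats, maf_threshold=maf_threshold)
    return harmonized


@pytest.fixture
def assoc_factory():
    return make_assoc


def write_tsv(path, header, rows):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path


SUMSTATS_HEADER = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]


def sumstats_row(vid, chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
                 beta=0.1, se=0.01, pvalue=1e-10, n=10_000):
    return [vid, chrom, pos, ea, oa, eaf, beta, se, pvalue, n]
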