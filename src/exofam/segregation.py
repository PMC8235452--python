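"""Co-segregation classification of a candidate variant in a pedigree.

After the discovery filter, candidate variants are genotyped in additional
affected and unaffected relatives to ask whether the variant tracks with
the phenotype.  The three-way call used here is a declared operational
convention (the underlying study design reports segregation only
qualitatively):

* ``full``    — every genotyped affected member carries the variant and no
  genotyped unaffected member does;
* ``none``    — at least one genotyped affected member is a non-carrier AND
  at least one genotyped unaffected member is a carrier (both directions
  violated);
* ``partial`` — exactly one of the two directions is violated.

Members with unknown affection status are excluded from the tallies;
"confirmed negative" members (radiographically cleared) are pooled with the
unaffected.  Reduced penetrance and phenocopies are deliberately not
modelled in the call.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .cohort import Affection, Family, Genotype, VariantKey

__all__ = ["SegregationCall", "SegregationResult", "classify_segregation"]

_CARRIER = (Genotype.HET, Genotype.HOM_ALT)
_UNAFFECTED_POOL = (Affection.UNAFFECTED, Affection.CONFIRMED_NEGATIVE)


@dataclass(frozen=True)
class SegregationResult:
    variant: VariantKey
    gene: str
    family_id: str
    n_affected_genotyped: int
    n_affected_carriers: int
    n_unaffected_genotyped: int
    n_unaffected_carriers: int
    call: str  # {"full", "partial", "none"}
    #: True when no additional affected or no unaffected member (beyond the
    #: discovery set) was genotyped, so the call rests on little evidence.
    low_information: bool = False


def classify_segregation(
    variant: VariantKey,
    family: Family,
    genotypes: Mapping[str, Genotype],
    gene: str = "",
    discovery_samples: frozenset[str] = frozenset(),
) -> SegregationResult:
    """Classify co-segregation of ``variant`` with affection in ``family``.

    ``genotypes`` maps individual ids to genotype calls at the variant site
    (typically from targeted follow-up genotyping).  Members without a
    non-missing genotype or with unknown affection are excluded.
    ``discovery_samples`` names the exome discovery set; the call itself
    tallies every genotyped member, but the low-information flag is raised
    when no affected member beyond the discovery set, or no unaffected
    member at all, was genotyped.
    """
    affected_genotyped = affected_carriers = 0
    unaffected_genotyped = unaffected_carriers = 0
    extra_affected = 0
    for m in family.members:
        g = genotypes.get(m.individual_id, Genotype.MISSING)
        if g is Genotype.MISSING:
            continue
        if m.affection is Affection.AFFECTED:
            affected_genotyped += 1
            if m.individual_id not in discovery_samples:
                extra_affected += 1
            if g in _CARRIER:
                affected_carriers += 1
        elif m.affection in _UNAFFECTED_POOL:
            unaffected_genotyped += 1
            if g in _CARRIER:
                unaffected_carriers += 1
    if affected_genotyped + unaffected_genotyped == 0:
        raise ValueError(
            f"no genotyped member of family {family.family_id} for {variant}"
        )
    affected_violated = affected_carriers < affected_genotyped
    unaffected_violated = unaffected_carriers > 0
    if not affected_violated and not unaffected_violated:
        call = "full"
    elif affected_violated and unaffected_violated:
        call = "none"
    else:
        call = "partial"
    return SegregationResult(
        variant=variant,
        gene=gene,
        family_id=family.family_id,
        n_affected_genotyped=affected_genotyped,
        n_affected_carriers=affected_carriers,
        n_unaffected_genotyped=unaffected_genotyped,
        n_unaffected_carriers=unaffected_carriers,
        call=call,
        low_information=(extra_affected == 0 or unaffected_genotyped == 0),
    )
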