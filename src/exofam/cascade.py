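"""Per-family variant filter cascade.

Each family's variant calls pass through five stages, in order:

1. consequence — keep protein-altering classes (non-synonymous SNVs, coding
   indels, stop gains, splice-site variants); synonymous and other classes
   are dropped;
2. artifact strip — drop sites on a caller-supplied blacklist of known
   calling artifacts;
3. frequency — keep variants novel in the reference population or with
   population allele frequency strictly below the threshold (default 0.05,
   deliberately permissive for a condition affecting 2-3% of the
   population);
4. damaging evidence — for variants annotated in the prediction database,
   require at least ``damaging_min_predictors`` of the four in-silico tools
   (SIFT, Polyphen2, LRT, MutationTaster) to score the variant damaging;
   unannotated variants are retained by default since the rule cannot be
   evaluated for them;
5. family sharing — keep only variants carried (>=1 alt allele) by every
   sequenced member of the family.

Membership in the retained set is order-independent (the stages are pure
predicates and the result is their intersection); the order above only
shapes the per-stage funnel counts.  The cascade never looks across
families — cross-family products live in :mod:`exofam.aggregate`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .cohort import AnnotatedVariant, Consequence, Family, Genotype, VariantKey

__all__ = [
    "FilterConfig",
    "FilterFunnel",
    "DEFAULT_WHITELIST",
    "passes_consequence",
    "passes_artifact",
    "passes_frequency",
    "passes_damaging",
    "shared_by_all_sequenced",
    "run_cascade",
]

#: All protein-altering consequence classes (everything except "other").
DEFAULT_WHITELIST = frozenset(
    c for c in Consequence if c is not Consequence.OTHER
)

_CARRIER_GENOTYPES = (Genotype.HET, Genotype.HOM_ALT)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and rule switches of the filter cascade.

    The artifact blacklist is keyed on exact variant identity
    (chrom, pos, ref, alt); it defaults to empty because no published
    artifact list accompanies the study design this pipeline models.
    """

    maf_threshold: float = 0.05
    consequence_whitelist: frozenset[Consequence] = DEFAULT_WHITELIST
    damaging_min_predictors: int = 1
    retain_if_unannotated: bool = True
    drop_artifacts: bool = True
    artifact_blacklist: frozenset[VariantKey] = frozenset()

    def __post_init__(self) -> None:
        if not 0 < self.maf_threshold <= 1:
            raise ValueError(
                f"maf_threshold must be in (0, 1], got {self.maf_threshold}"
            )
        if not 1 <= self.damaging_min_predictors <= 4:
            raise ValueError(
                "damaging_min_predictors must be in 1..4, got "
                f"{self.damaging_min_predictors}"
            )


@dataclass
class FilterFunnel:
    """Ordered per-stage (name, n_in, n_out) audit counts for one family."""

    family_id: str
    stages: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int) -> None:
        self.stages.append((name, n_in, n_out))

    @property
    def is_monotone(self) -> bool:
        return all(n_out <= n_in for _, n_in, n_out in self.stages)

    @property
    def final_count(self) -> int:
        return self.stages[-1][2] if self.stages else 0


def passes_consequence(variant: AnnotatedVariant, config: FilterConfig) -> bool:
    """True iff the consequence class is on the protein-altering whitelist."""
    return variant.consequence in config.consequence_whitelist


def passes_artifact(variant: AnnotatedVariant, config: FilterConfig) -> bool:
    """True unless the variant is a flagged/blacklisted calling artifact."""
    if not config.drop_artifacts:
        return True
    return not (
        variant.artifact_flag or variant.key in config.artifact_blacklist
    )


def passes_frequency(variant: AnnotatedVariant, config: FilterConfig) -> bool:
    """True iff novel (no population record) or strictly below the MAF cut.

    The boundary is exclusive: a variant at exactly the threshold frequency
    is dropped.
    """
    return variant.pop_af is None or variant.pop_af < config.maf_threshold


def passes_damaging(variant: AnnotatedVariant, config: FilterConfig) -> bool:
    """Damaging-evidence rule; applies only to database-annotated variants."""
    if not variant.annotated_in_db:
        return config.retain_if_unannotated
    return variant.n_damaging >= config.damaging_min_predictors


def shared_by_all_sequenced(variant: AnnotatedVariant, family: Family) -> bool:
    """True iff every sequenced member carries at least one alt allele.

    A missing genotype in any sequenced member fails the test (conservative:
    sharing cannot be asserted without a call).  Raises if no sequenced
    member has a genotype at all, since the rule is then unevaluable.
    """
    genotypes = [
        variant.genotypes.get(m.individual_id, Genotype.MISSING)
        for m in family.sequenced_members
    ]
    if all(g is Genotype.MISSING for g in genotypes):
        raise ValueError(
            f"no sequenced member of family {family.family_id} genotyped "
            f"for {variant.key}"
        )
    return all(g in _CARRIER_GENOTYPES for g in genotypes)


def run_cascade(
    variants: Sequence[AnnotatedVariant],
    family: Family,
    config: FilterConfig = FilterConfig(),
) -> tuple[list[AnnotatedVariant], FilterFunnel]:
    """Apply the five filter stages to one family's variants.

    Returns the retained variants sorted by (chrom, pos, alt) and the
    per-stage funnel.
    """
    stages = [
        ("consequence", lambda v: passes_consequence(v, config)),
        ("artifact", lambda v: passes_artifact(v, config)),
        ("frequency", lambda v: passes_frequency(v, config)),
        ("damaging", lambda v: passes_damaging(v, config)),
        ("family_sharing", lambda v: shared_by_all_sequenced(v, family)),
    ]
    funnel = FilterFunnel(family.family_id)
    current = list(variants)
    for name, predicate in stages:
        kept = [v for v in current if predicate(v)]
        funnel.add(name, len(current), len(kept))
        current = kept
    current.sort(key=lambda v: (v.chrom, v.pos, v.alt))
    return current, funnel
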