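"""Synthetic multigeneration-family exome cohorts with planted truths.

The generator emulates the inputs of a family-based variant prioritization
study: 23 multigeneration pedigrees with three to five sequenced affected
members each, annotated variant calls with reference-population allele
frequencies (including novel sites), consequence classes, and four-way
in-silico damaging predictions, plus a GMT term-set annotation.

Two kinds of truth are planted so downstream stages can be tested for
recovery:

* per family, a set of low-frequency damaging variants carried by every
  sequenced member (forced heterozygous in one founder of the affected
  lineage and transmitted down it), alongside decoy variants that each fail
  exactly one filter stage — absent from >=1 sequenced member, too common
  in the population, scored benign by all predictors, or of a
  non-protein-altering consequence class;
* across families, one term set receives an excess share of the planted
  variants' genes, so the enrichment stage has a known best category.

Default cohort shape: per-family planted counts are drawn from a lognormal
with median 51 clipped to [11, 128]; population frequencies follow a
mixture of 12% novel, 18% below 0.001, 22% in 0.001-0.01, and 48% in
0.01-0.05 (log-uniform within bins).  Genotype transmission is Mendelian
apart from the deliberate conditioning on the planted lineage.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort import (
    Affection,
    AnnotatedVariant,
    Consequence,
    Family,
    Genotype,
    Individual,
    PREDICTORS,
    Prediction,
    Sex,
    TermSet,
    VariantKey,
    VcfDialect,
    DEFAULT_DIALECT,
    write_pedigree,
    write_term_sets,
    write_variants,
)

__all__ = [
    "SimulationParams",
    "TruthTable",
    "SimulatedCohort",
    "simulate_pedigree",
    "transmit_genotypes",
    "offspring_genotype",
    "sample_maf",
    "simulate_cohort",
]

_BASES = "ACGT"
_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")

#: Consequence-class mixture of the retained-variant universe being
#: emulated (protein-altering classes only; shares 88/4/2/2/2/2/1 percent).
CONSEQUENCE_MASSES: dict[Consequence, float] = {
    Consequence.NONSYNONYMOUS_SNV: 1281 / 1448,
    Consequence.NONFRAMESHIFT_DELETION: 52 / 1448,
    Consequence.NONFRAMESHIFT_INSERTION: 34 / 1448,
    Consequence.FRAMESHIFT_DELETION: 25 / 1448,
    Consequence.STOPGAIN: 22 / 1448,
    Consequence.FRAMESHIFT_INSERTION: 22 / 1448,
    Consequence.SPLICE_SITE: 12 / 1448,
}


def _default_maf_masses() -> dict[str, float]:
    return {"novel": 0.12, "<0.001": 0.18, "0.001-0.01": 0.22, "0.01-0.05": 0.48}


def _default_decoy_rates() -> dict[str, float]:
    return {
        "non_shared": 1.0,
        "high_maf": 0.5,
        "all_benign": 0.5,
        "non_whitelisted": 0.5,
    }


@dataclass
class SimulationParams:
    """Knobs of the synthetic cohort; defaults are the emulated study shape."""

    n_families: int = 23
    sequenced_per_family: tuple[int, int] = (3, 5)
    pedigree_depth: int = 3
    n_background_genes: int = 18000
    n_term_sets: int = 120
    genes_per_term: int = 150
    #: Probability that a planted variant's gene is drawn from the planted
    #: term instead of uniformly from the gene pool (the planted effect).
    planted_term_fraction: float = 0.02
    variants_per_family: tuple[int, int] = (11, 128)
    variants_per_family_median: float = 51.0
    variants_per_family_log_sd: float = 0.45
    maf_masses: dict[str, float] = field(default_factory=_default_maf_masses)
    #: P[>=1 predictor scores a planted variant damaging].
    prediction_sensitivity: float = 1.0
    #: Fraction of planted variants absent from the prediction database.
    unannotated_fraction: float = 0.05
    #: Decoy counts per family as a fraction of that family's planted count.
    decoy_rates: dict[str, float] = field(default_factory=_default_decoy_rates)
    penetrance: float = 1.0
    phenocopy_rate: float = 0.0
    contigs: tuple[str, ...] = tuple(str(c) for c in range(1, 23))

    def __post_init__(self) -> None:
        total = sum(self.maf_masses.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"maf_masses sum to {total}, expected 1")
        lo, hi = self.sequenced_per_family
        if not 1 <= lo <= hi:
            raise ValueError("sequenced_per_family range is degenerate")
        lo, hi = self.variants_per_family
        if not 1 <= lo <= hi:
            raise ValueError("variants_per_family range is degenerate")
        if self.pedigree_depth < 2:
            raise ValueError("pedigree_depth must be >= 2")


@dataclass
class TruthTable:
    """Planted and decoy variants with their expected cascade outcomes."""

    #: family_id -> variant key -> gene symbol for planted variants.
    planted: dict[str, dict[VariantKey, str]]
    #: family_id -> variant key -> decoy class name.
    decoys: dict[str, dict[VariantKey, str]]
    #: family_id -> keys expected to survive the full cascade.
    expected_retained: dict[str, set[VariantKey]]
    planted_term_id: str

    def write(self, path: str | Path) -> None:
        lines = [f"#planted_term={self.planted_term_id}"]
        lines.append(
            "family_id\tchrom\tpos\tref\talt\tgene\trole\texpected_retained"
        )
        for fid in sorted(self.planted):
            for key, gene in self.planted[fid].items():
                kept = int(key in self.expected_retained[fid])
                lines.append(
                    f"{fid}\t{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\t"
                    f"{gene}\tplanted\t{kept}"
                )
            for key, role in self.decoys.get(fid, {}).items():
                lines.append(
                    f"{fid}\t{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\t"
                    f"\tdecoy:{role}\t0"
                )
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------


def _generation_of(individual_id: str) -> int:
    # ids look like FAM01-II-3
    return _ROMAN.index(individual_id.rsplit("-", 2)[-2]) + 1


def _build_pedigree(
    params: SimulationParams, rng: np.random.Generator, family_id: str
) -> tuple[Family, frozenset[str]]:
    lo, hi = params.sequenced_per_family
    n_seq = int(rng.integers(lo, hi + 1))
    depth = params.pedigree_depth

    # raw member records: iid -> [father, mother, sex]
    raw: dict[str, tuple[str | None, str | None, Sex]] = {}
    carriers: set[str] = set()

    def new_id(gen: int, idx: int) -> str:
        return f"{family_id}-{_ROMAN[gen - 1]}-{idx}"

    founder_father = new_id(1, 1)
    founder_mother = new_id(1, 2)
    raw[founder_father] = (None, None, Sex.MALE)
    raw[founder_mother] = (None, None, Sex.FEMALE)
    carriers.add(founder_father)

    couples: list[tuple[str, str, bool]] = [
        (founder_father, founder_mother, True)
    ]
    for gen in range(2, depth + 1):
        idx = 1
        children: list[str] = []
        for father, mother, couple_carries in couples:
            n_kids = (
                int(rng.integers(2, 5)) if gen == 2 else int(rng.integers(1, 4))
            )
            for j in range(n_kids):
                iid = new_id(gen, idx)
                idx += 1
                sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
                raw[iid] = (father, mother, sex)
                # first child of a carrier couple inherits the risk
                # haplotype for sure so the lineage never dies out early
                if couple_carries and (j == 0 or rng.random() < 0.5):
                    carriers.add(iid)
                children.append(iid)
        if gen < depth:
            next_couples = []
            for child in children:
                spouse = new_id(gen, idx)
                idx += 1
                child_sex = raw[child][2]
                spouse_sex = (
                    Sex.FEMALE if child_sex is Sex.MALE else Sex.MALE
                )
                raw[spouse] = (None, None, spouse_sex)
                father_id = child if child_sex is Sex.MALE else spouse
                mother_id = spouse if child_sex is Sex.MALE else child
                next_couples.append((father_id, mother_id, child in carriers))
            couples = next_couples

    # Promote non-carrier children of carriers (in generation order, so
    # promotions can cascade) until enough carriers exist to sequence.
    target = n_seq + 1
    ordered = sorted(raw, key=lambda iid: (_generation_of(iid), iid))
    while len(carriers) < target:
        promotable = [
            iid
            for iid in ordered
            if iid not in carriers
            and (raw[iid][0] in carriers or raw[iid][1] in carriers)
        ]
        if not promotable:
            break
        carriers.add(promotable[int(rng.integers(len(promotable)))])

    # Affection from carrier status (full penetrance by default).
    affection: dict[str, Affection] = {}
    for iid in ordered:
        if iid in carriers:
            affected = rng.random() < params.penetrance
        else:
            affected = rng.random() < params.phenocopy_rate
        affection[iid] = (
            Affection.AFFECTED if affected else Affection.UNAFFECTED
        )

    candidates = [
        iid
        for iid in ordered
        if iid in carriers and affection[iid] is Affection.AFFECTED
    ]
    if len(candidates) < n_seq:
        raise ValueError(
            f"cannot place {n_seq} sequenced affected members in family "
            f"{family_id}: only {len(candidates)} affected carriers"
        )
    by_gen: dict[int, list[str]] = {}
    for iid in candidates:
        by_gen.setdefault(_generation_of(iid), []).append(iid)
    sequenced: list[str] = []
    if len(by_gen) >= 2 and n_seq >= 2:
        gens = sorted(by_gen)[:2]
        for g in gens:
            pick = by_gen[g][int(rng.integers(len(by_gen[g])))]
            sequenced.append(pick)
    remaining = [c for c in candidates if c not in sequenced]
    n_more = n_seq - len(sequenced)
    if n_more > 0:
        picks = rng.choice(len(remaining), size=n_more, replace=False)
        sequenced.extend(remaining[int(i)] for i in sorted(picks))
    sequenced_set = set(sequenced)

    members = []
    for iid in ordered:
        father, mother, sex = raw[iid]
        aff = affection[iid]
        if aff is Affection.UNAFFECTED and iid not in carriers:
            if rng.random() < 0.2:
                aff = Affection.CONFIRMED_NEGATIVE
        cobb: tuple[float, ...] = ()
        if aff is Affection.AFFECTED:
            n_curves = 1 if rng.random() < 0.8 else 2
            cobb = tuple(
                float(rng.integers(12, 61)) for _ in range(n_curves)
            )
        members.append(
            Individual(
                individual_id=iid,
                family_id=family_id,
                father_id=father,
                mother_id=mother,
                sex=sex,
                affection=aff,
                sequenced=iid in sequenced_set,
                cobb_angles=cobb,
            )
        )
    return Family(family_id, tuple(members)), frozenset(carriers)


def simulate_pedigree(
    params: SimulationParams, seed: int, family_id: str = "FAM01"
) -> Family:
    """Simulate one multigeneration family with sequenced affected members.

    The requested number of sequenced members (drawn from
    ``params.sequenced_per_family``) are affected risk-haplotype carriers
    placed across at least two generations whenever possible.
    """
    rng = np.random.default_rng(seed)
    family, _carriers = _build_pedigree(params, rng, family_id)
    return family


# ---------------------------------------------------------------------------
# Genotype transmission
# ---------------------------------------------------------------------------

_ALLELES = {
    Genotype.HOM_REF: (0, 0),
    Genotype.HET: (0, 1),
    Genotype.HOM_ALT: (1, 1),
}
_FROM_COUNT = {0: Genotype.HOM_REF, 1: Genotype.HET, 2: Genotype.HOM_ALT}


def offspring_genotype(
    father: Genotype, mother: Genotype, rng: np.random.Generator
) -> Genotype:
    """One fair Mendelian transmission: one random allele from each parent."""
    fa = _ALLELES[father][int(rng.integers(2))]
    ma = _ALLELES[mother][int(rng.integers(2))]
    return _FROM_COUNT[fa + ma]


def _topological_members(family: Family) -> list[Individual]:
    placed: dict[str, int] = {}

    def depth(iid: str) -> int:
        if iid in placed:
            return placed[iid]
        m = family.member(iid)
        d = 0
        for parent in (m.father_id, m.mother_id):
            if parent is not None:
                d = max(d, depth(parent) + 1)
        placed[iid] = d
        return d

    return sorted(
        family.members, key=lambda m: (depth(m.individual_id), m.individual_id)
    )


def transmit_genotypes(
    family: Family,
    founder_allele_freqs: Mapping[VariantKey, float | None],
    planted_keys: Iterable[VariantKey] = (),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    carriers: frozenset[str] | None = None,
) -> dict[VariantKey, dict[str, Genotype]]:
    """Drop genotypes through the pedigree for every variant.

    Founders draw each allele Bernoulli(maf) (novel sites use frequency 0);
    every non-founder inherits one allele from each parent.  Planted
    variants are instead forced heterozygous in one affected founder and
    transmitted alt-first along the carrier lineage (``carriers`` defaults
    to the affected members), so every carrier is heterozygous and every
    non-carrier is homozygous reference.

    Raises when a planted variant cannot be transmitted — a carrier whose
    parents are present in the pedigree but none of them carries.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    planted = set(planted_keys)
    if carriers is None:
        carriers = frozenset(
            m.individual_id for m in family.affected_members
        )
    ordered = _topological_members(family)
    risk_founder: str | None = None
    for m in ordered:
        if m.is_founder and m.individual_id in carriers:
            risk_founder = m.individual_id
            break
    if planted and risk_founder is None:
        raise ValueError(
            f"family {family.family_id}: no carrier founder to seed planted "
            "variants"
        )
    out: dict[VariantKey, dict[str, Genotype]] = {}
    for key, maf in founder_allele_freqs.items():
        p = 0.0 if maf is None else float(maf)
        alleles: dict[str, tuple[int, int]] = {}
        for m in ordered:
            iid = m.individual_id
            if key in planted:
                if iid == risk_founder:
                    alleles[iid] = (0, 1)
                elif m.is_founder:
                    alleles[iid] = (0, 0)
                elif iid in carriers:
                    parent_ids = [m.father_id, m.mother_id]
                    if not any(pid in carriers for pid in parent_ids if pid):
                        raise ValueError(
                            f"planted transmission infeasible: carrier {iid} "
                            f"of family {family.family_id} has no carrier "
                            "parent"
                        )
                    alleles[iid] = (0, 1)
                else:
                    alleles[iid] = (0, 0)
            elif m.is_founder:
                alleles[iid] = (
                    int(rng.random() < p),
                    int(rng.random() < p),
                )
            else:
                inherited = []
                for pid in (m.father_id, m.mother_id):
                    if pid is None:
                        inherited.append(int(rng.random() < p))
                    else:
                        pair = alleles[pid]
                        inherited.append(pair[int(rng.integers(2))])
                alleles[iid] = (inherited[0], inherited[1])
        out[key] = {
            iid: _FROM_COUNT[a + b] for iid, (a, b) in alleles.items()
        }
    return out


# ---------------------------------------------------------------------------
# Variant annotation sampling
# ---------------------------------------------------------------------------

_MAF_BIN_BOUNDS = {
    "<0.001": (1e-5, 1e-3),
    "0.001-0.01": (1e-3, 1e-2),
    "0.01-0.05": (1e-2, 5e-2),
}


def sample_maf(
    params: SimulationParams, rng: np.random.Generator, size: int
) -> list[float | None]:
    """Draw population allele frequencies from the configured bin mixture.

    Within each bin the frequency is log-uniform; novel sites are None.
    """
    bins = list(params.maf_masses)
    masses = np.array([params.maf_masses[b] for b in bins])
    choices = rng.choice(len(bins), size=size, p=masses / masses.sum())
    out: list[float | None] = []
    for c in choices:
        name = bins[int(c)]
        if name == "novel":
            out.append(None)
        else:
            lo, hi = _MAF_BIN_BOUNDS[name]
            value = math.exp(rng.uniform(math.log(lo), math.log(hi)))
            out.append(float(f"{value:.6g}"))
    return out


def _sample_alleles(
    rng: np.random.Generator, consequence: Consequence
) -> tuple[str, str]:
    bases = [_BASES[int(rng.integers(4))] for _ in range(5)]
    anchor = bases[0]
    if consequence in (
        Consequence.NONSYNONYMOUS_SNV,
        Consequence.STOPGAIN,
        Consequence.SPLICE_SITE,
        Consequence.OTHER,
    ):
        ref = anchor
        alt = _BASES[(_BASES.index(anchor) + 1 + int(rng.integers(3))) % 4]
        return ref, alt
    if consequence is Consequence.NONFRAMESHIFT_DELETION:
        return anchor + "".join(bases[1:4]), anchor
    if consequence is Consequence.FRAMESHIFT_DELETION:
        return anchor + bases[1], anchor
    if consequence is Consequence.NONFRAMESHIFT_INSERTION:
        return anchor, anchor + "".join(bases[1:4])
    return anchor, anchor + bases[1]  # frameshift insertion


def _sample_consequence(rng: np.random.Generator) -> Consequence:
    classes = list(CONSEQUENCE_MASSES)
    masses = np.array([CONSEQUENCE_MASSES[c] for c in classes])
    return classes[int(rng.choice(len(classes), p=masses / masses.sum()))]


def _damaging_predictions(
    rng: np.random.Generator,
) -> dict[str, Prediction]:
    preds = {
        p: (
            Prediction.DAMAGING if rng.random() < 0.5 else Prediction.BENIGN
        )
        for p in PREDICTORS
    }
    if all(v is Prediction.BENIGN for v in preds.values()):
        preds[PREDICTORS[int(rng.integers(4))]] = Prediction.DAMAGING
    return preds


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedCohort:
    """In-memory synthetic cohort plus its on-disk representation."""

    params: SimulationParams
    seed: int
    families: list[Family]
    carriers_by_family: dict[str, frozenset[str]]
    variants_by_family: dict[str, list[AnnotatedVariant]]
    #: planted-variant genotypes over *all* family members (the follow-up
    #: genotyping surface used by the segregation stage).
    followup_genotypes: dict[str, dict[VariantKey, dict[str, Genotype]]]
    term_sets: list[TermSet]
    background_genes: frozenset[str]
    truth: TruthTable

    @property
    def sequenced_samples(self) -> list[str]:
        return [
            m.individual_id
            for fam in self.families
            for m in fam.members
            if m.sequenced
        ]

    def all_variants(self) -> list[AnnotatedVariant]:
        order = {c: i for i, c in enumerate(self.params.contigs)}
        flat = [
            v for fid in sorted(self.variants_by_family)
            for v in self.variants_by_family[fid]
        ]
        flat.sort(key=lambda v: (order.get(v.chrom, 99), v.pos, v.alt))
        return flat

    def write(
        self, out_dir: str | Path, dialect: VcfDialect = DEFAULT_DIALECT
    ) -> dict[str, Path]:
        """Write cohort.vcf, cohort.ped, terms.gmt, truth.tsv, followup.vcf."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out / "cohort.vcf",
            "ped": out / "cohort.ped",
            "gmt": out / "terms.gmt",
            "truth": out / "truth.tsv",
            "followup_vcf": out / "followup.vcf",
        }
        write_variants(
            self.all_variants(),
            self.sequenced_samples,
            paths["vcf"],
            dialect=dialect,
            contigs=self.params.contigs,
        )
        write_pedigree(self.families, paths["ped"])
        write_term_sets(self.term_sets, paths["gmt"])
        self.truth.write(paths["truth"])

        # follow-up VCF: planted variants only, genotyped in every family
        # member (affected and unaffected), emulating targeted re-genotyping
        all_members = [
            m.individual_id for fam in self.families for m in fam.members
        ]
        followup_variants = []
        for fid in sorted(self.followup_genotypes):
            lookup = {
                v.key: v for v in self.variants_by_family[fid]
            }
            for key, genos in self.followup_genotypes[fid].items():
                v = lookup[key]
                followup_variants.append(
                    AnnotatedVariant(
                        chrom=v.chrom,
                        pos=v.pos,
                        ref=v.ref,
                        alt=v.alt,
                        gene=v.gene,
                        consequence=v.consequence,
                        pop_af=v.pop_af,
                        predictions=dict(v.predictions),
                        annotated_in_db=v.annotated_in_db,
                        genotypes=dict(genos),
                    )
                )
        order = {c: i for i, c in enumerate(self.params.contigs)}
        followup_variants.sort(
            key=lambda v: (order.get(v.chrom, 99), v.pos, v.alt)
        )
        write_variants(
            followup_variants,
            all_members,
            paths["followup_vcf"],
            dialect=dialect,
            contigs=self.params.contigs,
        )
        return paths


def _draw_variant_count(
    params: SimulationParams, rng: np.random.Generator
) -> int:
    lo, hi = params.variants_per_family
    raw = rng.lognormal(
        math.log(params.variants_per_family_median),
        params.variants_per_family_log_sd,
    )
    return int(np.clip(round(raw), lo, hi))


def simulate_cohort(
    params: SimulationParams, seed: int = 0
) -> SimulatedCohort:
    """Generate a full synthetic cohort with recorded ground truth."""
    rng = np.random.default_rng(seed)
    pool = [f"G{i:05d}" for i in range(1, params.n_background_genes + 1)]
    pool_arr = np.array(pool)
    term_sets = []
    for t in range(1, params.n_term_sets + 1):
        genes = rng.choice(
            pool_arr, size=params.genes_per_term, replace=False
        )
        term_sets.append(
            TermSet(f"TS{t:04d}", f"geneset_{t:04d}", frozenset(map(str, genes)))
        )
    planted_term = term_sets[0]
    planted_term_genes = sorted(planted_term.genes)

    used_sites: set[tuple[str, int]] = set()

    def new_site() -> tuple[str, int]:
        while True:
            chrom = params.contigs[int(rng.integers(len(params.contigs)))]
            pos = int(rng.integers(1, 10_000_000))
            if (chrom, pos) not in used_sites:
                used_sites.add((chrom, pos))
                return chrom, pos

    families: list[Family] = []
    carriers_by_family: dict[str, frozenset[str]] = {}
    variants_by_family: dict[str, list[AnnotatedVariant]] = {}
    followup: dict[str, dict[VariantKey, dict[str, Genotype]]] = {}
    truth_planted: dict[str, dict[VariantKey, str]] = {}
    truth_decoys: dict[str, dict[VariantKey, str]] = {}
    truth_expected: dict[str, set[VariantKey]] = {}

    for f in range(1, params.n_families + 1):
        fid = f"FAM{f:02d}"
        family, carriers = _build_pedigree(params, rng, fid)
        families.append(family)
        carriers_by_family[fid] = carriers
        sequenced_ids = [m.individual_id for m in family.sequenced_members]

        n_planted = _draw_variant_count(params, rng)
        mafs = sample_maf(params, rng, n_planted)
        planted_variants: list[AnnotatedVariant] = []
        truth_planted[fid] = {}
        truth_expected[fid] = set()
        for i in range(n_planted):
            if rng.random() < params.planted_term_fraction:
                gene = planted_term_genes[
                    int(rng.integers(len(planted_term_genes)))
                ]
            else:
                gene = pool[int(rng.integers(len(pool)))]
            consequence = _sample_consequence(rng)
            chrom, pos = new_site()
            ref, alt = _sample_alleles(rng, consequence)
            unannotated = rng.random() < params.unannotated_fraction
            retained = True
            if unannotated:
                predictions = {p: Prediction.MISSING for p in PREDICTORS}
            elif rng.random() < params.prediction_sensitivity:
                predictions = _damaging_predictions(rng)
            else:
                predictions = {p: Prediction.BENIGN for p in PREDICTORS}
                retained = False
            v = AnnotatedVariant(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene=gene,
                consequence=consequence,
                pop_af=mafs[i],
                predictions=predictions,
                annotated_in_db=not unannotated,
            )
            planted_variants.append(v)
            truth_planted[fid][v.key] = gene
            if retained:
                truth_expected[fid].add(v.key)

        freqs = {v.key: v.pop_af for v in planted_variants}
        genos = transmit_genotypes(
            family,
            freqs,
            planted_keys=list(freqs),
            rng=rng,
            carriers=carriers,
        )
        followup[fid] = genos
        for v in planted_variants:
            v.genotypes = {s: genos[v.key][s] for s in sequenced_ids}

        # decoys: each class fails exactly one stage
        decoy_variants: list[AnnotatedVariant] = []
        truth_decoys[fid] = {}
        for role, rate in params.decoy_rates.items():
            n_decoys = max(1, int(round(rate * n_planted)))
            decoy_mafs = sample_maf(params, rng, n_decoys)
            for j in range(n_decoys):
                chrom, pos = new_site()
                consequence = (
                    Consequence.OTHER
                    if role == "non_whitelisted"
                    else _sample_consequence(rng)
                )
                ref, alt = _sample_alleles(rng, consequence)
                if role == "high_maf":
                    pop_af = float(f"{rng.uniform(0.05, 0.5):.6g}")
                else:
                    pop_af = decoy_mafs[j]
                if role == "all_benign":
                    predictions = {p: Prediction.BENIGN for p in PREDICTORS}
                else:
                    predictions = _damaging_predictions(rng)
                genotypes = {s: Genotype.HET for s in sequenced_ids}
                if role == "non_shared":
                    dropout = sequenced_ids[
                        int(rng.integers(len(sequenced_ids)))
                    ]
                    genotypes[dropout] = Genotype.HOM_REF
                v = AnnotatedVariant(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=pool[int(rng.integers(len(pool)))],
                    consequence=consequence,
                    pop_af=pop_af,
                    predictions=predictions,
                    annotated_in_db=True,
                    genotypes=genotypes,
                )
                decoy_variants.append(v)
                truth_decoys[fid][v.key] = role
        variants_by_family[fid] = planted_variants + decoy_variants

    truth = TruthTable(
        planted=truth_planted,
        decoys=truth_decoys,
        expected_retained=truth_expected,
        planted_term_id=planted_term.term_id,
    )
    return SimulatedCohort(
        params=params,
        seed=seed,
        families=families,
        carriers_by_family=carriers_by_family,
        variants_by_family=variants_by_family,
        followup_genotypes=followup,
        term_sets=term_sets,
        background_genes=frozenset(pool),
        truth=truth,
    )
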