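"""Domain model and file I/O for family-based exome variant prioritization.

This module defines the shared vocabulary of the pipeline — pedigree members
and families, annotated variants, gene sets — together with readers and
writers for the plain-text carriers of each: PED-style pedigrees (six
standard columns plus two extension columns for the sequenced flag and Cobb
angles), VCF with annotation INFO keys (gene symbol, consequence class,
population allele frequency, and four in-silico damaging predictions), and
GMT gene-set files.

Coordinates are 1-based VCF convention and alleles are taken as written:
the pipeline trusts its variant caller and performs no indel
re-normalization or liftover.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pysam

log = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "Affection",
    "Consequence",
    "Genotype",
    "Prediction",
    "PREDICTORS",
    "VariantKey",
    "Individual",
    "Family",
    "AnnotatedVariant",
    "TermSet",
    "VcfDialect",
    "read_pedigree",
    "write_pedigree",
    "read_variants",
    "write_variants",
    "read_term_sets",
    "write_term_sets",
]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    # Radiographically examined and found unaffected (pedigree annotation
    # "confirmed negative"); pooled with UNAFFECTED in segregation calls.
    CONFIRMED_NEGATIVE = "confirmed_negative"
    UNKNOWN = "unknown"


class Consequence(str, Enum):
    NONSYNONYMOUS_SNV = "nonsynonymous_SNV"
    NONFRAMESHIFT_DELETION = "nonframeshift_deletion"
    NONFRAMESHIFT_INSERTION = "nonframeshift_insertion"
    FRAMESHIFT_DELETION = "frameshift_deletion"
    FRAMESHIFT_INSERTION = "frameshift_insertion"
    STOPGAIN = "stopgain"
    SPLICE_SITE = "splice_site"
    OTHER = "other"


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


class Prediction(str, Enum):
    DAMAGING = "damaging"
    BENIGN = "benign"
    MISSING = "missing"


#: The four in-silico damaging predictors carried per variant.
PREDICTORS = ("SIFT", "Polyphen2", "LRT", "MutationTaster")

# dbNSFP-style letter codes.  "D" is damaging/deleterious for all four tools;
# MutationTaster additionally uses "A" (disease_causing_automatic).
_DAMAGING_CODES = {"D", "A"}
_BENIGN_CODES = {"T", "B", "N", "P"}


class VariantKey(NamedTuple):
    """Exact identity of a decomposed variant; equality on all four fields."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        chrom, pos, ref, alt = text.split(":")
        return cls(chrom, int(pos), ref, alt)


@dataclass(frozen=True)
class Individual:
    """A pedigree member.

    ``sequenced`` marks membership in the exome discovery set; the
    shared-by-all filtering rule quantifies over sequenced members only, so
    the flag is always explicit and never inferred from affection status.
    ``cobb_angles`` lists spinal curvature magnitudes in degrees (one per
    curve; double/triple curves have several entries).
    """

    individual_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN
    sequenced: bool = False
    cobb_angles: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.affection is Affection.AFFECTED:
            for angle in self.cobb_angles:
                if angle < 10:
                    raise ValueError(
                        f"{self.family_id}/{self.individual_id}: affected with "
                        f"Cobb angle {angle} < 10 degrees violates the "
                        "radiographic inclusion criterion"
                    )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass(frozen=True)
class Family:
    """A pedigree: members linked by parental ids.

    Invariants enforced on construction: individual ids unique within the
    family, parental links resolve within the family and are acyclic, at
    least one member is sequenced, and every sequenced member is affected
    (study design: only affected relatives enter the discovery exome set).
    """

    family_id: str
    members: tuple[Individual, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.members:
            if m.individual_id in seen:
                raise ValueError(
                    f"duplicate individual_id {self.family_id}/{m.individual_id}"
                )
            seen.add(m.individual_id)
        for m in self.members:
            for parent in (m.father_id, m.mother_id):
                if parent is not None and parent not in seen:
                    raise ValueError(
                        f"parent id {parent!r} of {self.family_id}/"
                        f"{m.individual_id} not found in family"
                    )
        if not any(m.sequenced for m in self.members):
            raise ValueError(f"family {self.family_id} has no sequenced member")
        for m in self.members:
            if m.sequenced and m.affection is not Affection.AFFECTED:
                raise ValueError(
                    f"sequenced member {self.family_id}/{m.individual_id} is "
                    "not affected"
                )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        by_id = {m.individual_id: m for m in self.members}
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(iid: str) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise ValueError(
                    f"parental links of family {self.family_id} contain a cycle"
                )
            state[iid] = 0
            m = by_id[iid]
            for parent in (m.father_id, m.mother_id):
                if parent is not None:
                    visit(parent)
            state[iid] = 1

        for iid in by_id:
            visit(iid)

    def member(self, individual_id: str) -> Individual:
        for m in self.members:
            if m.individual_id == individual_id:
                return m
        raise KeyError(f"{self.family_id}/{individual_id}")

    @property
    def sequenced_members(self) -> tuple[Individual, ...]:
        return tuple(m for m in self.members if m.sequenced)

    @property
    def affected_members(self) -> tuple[Individual, ...]:
        return tuple(
            m for m in self.members if m.affection is Affection.AFFECTED
        )


@dataclass
class AnnotatedVariant:
    """One decomposed (site, alt allele) with annotations and genotypes.

    ``pop_af`` is the reference-population allele frequency; ``None`` means
    the site is absent from the frequency database, i.e. novel.
    ``annotated_in_db`` records whether the site appears in the prediction
    database at all; when it is False every predictor entry is missing and
    the damaging-evidence filter does not apply.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: Consequence
    pop_af: float | None = None
    predictions: dict[str, Prediction] = field(default_factory=dict)
    annotated_in_db: bool = False
    artifact_flag: bool = False
    genotypes: dict[str, Genotype] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.alt == self.ref:
            raise ValueError(f"alt equals ref at {self.chrom}:{self.pos}")
        if self.pop_af is not None and not 0.0 <= self.pop_af <= 1.0:
            raise ValueError(f"pop_af {self.pop_af} outside [0, 1]")
        for p in PREDICTORS:
            self.predictions.setdefault(p, Prediction.MISSING)
        if not self.annotated_in_db and any(
            v is not Prediction.MISSING for v in self.predictions.values()
        ):
            raise ValueError(
                f"{self.key}: predictions present but annotated_in_db is False"
            )

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)

    @property
    def n_damaging(self) -> int:
        return sum(
            1 for v in self.predictions.values() if v is Prediction.DAMAGING
        )

    def is_carrier(self, sample_id: str) -> bool:
        """True if the sample carries at least one alt allele."""
        return self.genotypes.get(sample_id, Genotype.MISSING) in (
            Genotype.HET,
            Genotype.HOM_ALT,
        )


@dataclass(frozen=True)
class TermSet:
    """A named gene set (GO-like term, pathway, or cytogenetic band)."""

    term_id: str
    term_name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"term {self.term_id} has an empty gene set")
        upper = frozenset(g.upper() for g in self.genes)
        object.__setattr__(self, "genes", upper)


# ---------------------------------------------------------------------------
# Pedigree I/O
# ---------------------------------------------------------------------------

_SEX_FROM_PED = {"1": Sex.MALE, "2": Sex.FEMALE}
_SEX_TO_PED = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_AFF_FROM_PED = {
    "1": Affection.UNAFFECTED,
    "2": Affection.AFFECTED,
    "3": Affection.CONFIRMED_NEGATIVE,
}
_AFF_TO_PED = {
    Affection.UNAFFECTED: "1",
    Affection.AFFECTED: "2",
    Affection.CONFIRMED_NEGATIVE: "3",
    Affection.UNKNOWN: "0",
}


def _parse_cobb(token: str) -> tuple[float, ...]:
    token = token.strip()
    if token in ("", ".", "-", "0"):
        return ()
    return tuple(float(t) for t in token.split(","))


def read_pedigree(path: str | Path) -> list[Family]:
    """Read a PED-style pedigree file into :class:`Family` objects.

    Columns: family_id, individual_id, father_id, mother_id, sex, affection,
    and two optional extensions: a sequenced flag (1/0) and a comma-separated
    list of Cobb angles in degrees ("." when none recorded).  Parent id "0"
    means unknown (stored as None).  Affection codes: 1 unaffected,
    2 affected, 3 confirmed negative, anything else unknown.
    """
    rows: dict[str, list[Individual]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected >=6 whitespace-delimited "
                    f"columns, got {len(parts)}"
                )
            fid, iid, father, mother, sex, aff = parts[:6]
            sequenced = len(parts) > 6 and parts[6] == "1"
            cobb = _parse_cobb(parts[7]) if len(parts) > 7 else ()
            ind = Individual(
                individual_id=iid,
                family_id=fid,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex=_SEX_FROM_PED.get(sex, Sex.UNKNOWN),
                affection=_AFF_FROM_PED.get(aff, Affection.UNKNOWN),
                sequenced=sequenced,
                cobb_angles=cobb,
            )
            if fid not in rows:
                rows[fid] = []
                order.append(fid)
            rows[fid].append(ind)
    return [Family(fid, tuple(rows[fid])) for fid in order]


def write_pedigree(families: Iterable[Family], path: str | Path) -> None:
    """Write families in the PED-with-extensions layout read_pedigree accepts."""
    with open(path, "w") as fh:
        for fam in families:
            for m in fam.members:
                cobb = ",".join(f"{a:g}" for a in m.cobb_angles) or "."
                fh.write(
                    "\t".join(
                        [
                            fam.family_id,
                            m.individual_id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            _SEX_TO_PED[m.sex],
                            _AFF_TO_PED[m.affection],
                            "1" if m.sequenced else "0",
                            cobb,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Variant I/O
# ---------------------------------------------------------------------------


def _default_prediction_keys() -> dict[str, str]:
    return {
        "SIFT": "SIFT_PRED",
        "Polyphen2": "PP2_PRED",
        "LRT": "LRT_PRED",
        "MutationTaster": "MT_PRED",
    }


@dataclass(frozen=True)
class VcfDialect:
    """Names of the INFO keys carrying the annotations the pipeline consumes."""

    gene_key: str = "GENE"
    consequence_key: str = "CSQCLASS"
    af_key: str = "EXAC_AF"
    prediction_keys: Mapping[str, str] = field(
        default_factory=_default_prediction_keys
    )
    artifact_key: str | None = None


DEFAULT_DIALECT = VcfDialect()


def _info_for_alt(value, alt_index: int):
    """Pick the per-alt entry of an INFO value (scalar or per-alt tuple)."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        if len(value) >= alt_index:
            return value[alt_index - 1]
        return value[0] if value else None
    return value


def _normalize_prediction(code) -> Prediction:
    if code is None:
        return Prediction.MISSING
    code = str(code).strip()
    if not code or code == ".":
        return Prediction.MISSING
    if code.upper() in _DAMAGING_CODES:
        return Prediction.DAMAGING
    if code.upper() in _BENIGN_CODES:
        return Prediction.BENIGN
    return Prediction.MISSING


def _genotype_for_alt(gt: tuple | None, alt_index: int) -> Genotype:
    if gt is None or len(gt) == 0 or any(a is None for a in gt):
        return Genotype.MISSING
    n_alt = sum(1 for a in gt if a == alt_index)
    if n_alt == 0:
        return Genotype.HOM_REF
    if n_alt == 1:
        return Genotype.HET
    return Genotype.HOM_ALT


def read_variants(
    path: str | Path,
    dialect: VcfDialect = DEFAULT_DIALECT,
    known_samples: set[str] | None = None,
) -> list[AnnotatedVariant]:
    """Read an annotated VCF into one :class:`AnnotatedVariant` per alt allele.

    Multiallelic records are decomposed; a sample called 1/2 is a het
    carrier of both alt entries.  A record lacking the population-AF key is
    novel (``pop_af`` None); a record lacking every prediction key is
    unannotated in the prediction database.  Samples absent from
    ``known_samples`` (when given) are kept with a warning; unparsable
    genotypes become missing with a logged count.
    """
    variants: list[AnnotatedVariant] = []
    n_bad_gt = 0
    n_multi_gene = 0
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if known_samples is not None:
            unknown = [s for s in samples if s not in known_samples]
            if unknown:
                log.warning(
                    "%d VCF sample(s) absent from pedigree (kept): %s",
                    len(unknown),
                    ", ".join(unknown[:10]),
                )
        for rec in vf:
            alts = rec.alts or ()
            for ai, alt in enumerate(alts, start=1):
                gene_raw = _info_for_alt(rec.info.get(dialect.gene_key), ai)
                gene = str(gene_raw) if gene_raw is not None else ""
                if "&" in gene or "," in gene:
                    gene = gene.replace(",", "&").split("&")[0]
                    n_multi_gene += 1
                csq_raw = _info_for_alt(
                    rec.info.get(dialect.consequence_key), ai
                )
                try:
                    consequence = Consequence(str(csq_raw))
                except ValueError:
                    consequence = Consequence.OTHER
                af_raw = _info_for_alt(rec.info.get(dialect.af_key), ai)
                # htslib stores Float INFO as 32-bit; re-round to the 6
                # significant digits the dialect writes
                pop_af = (
                    None if af_raw is None else float(f"{float(af_raw):.6g}")
                )
                predictions: dict[str, Prediction] = {}
                any_pred_key = False
                for predictor, key in dialect.prediction_keys.items():
                    raw = _info_for_alt(rec.info.get(key), ai)
                    if raw is not None:
                        any_pred_key = True
                    predictions[predictor] = _normalize_prediction(raw)
                if not any_pred_key:
                    predictions = {p: Prediction.MISSING for p in PREDICTORS}
                artifact = bool(
                    dialect.artifact_key
                    and dialect.artifact_key in rec.info
                )
                genotypes: dict[str, Genotype] = {}
                for s in samples:
                    try:
                        gt = rec.samples[s].get("GT")
                        genotypes[s] = _genotype_for_alt(gt, ai)
                    except Exception:
                        genotypes[s] = Genotype.MISSING
                        n_bad_gt += 1
                variants.append(
                    AnnotatedVariant(
                        chrom=str(rec.chrom),
                        pos=int(rec.pos),
                        ref=str(rec.ref),
                        alt=str(alt),
                        gene=gene,
                        consequence=consequence,
                        pop_af=pop_af,
                        predictions=predictions,
                        annotated_in_db=any_pred_key,
                        artifact_flag=artifact,
                        genotypes=genotypes,
                    )
                )
    if n_bad_gt:
        log.warning("%d genotype(s) could not be parsed; set to missing", n_bad_gt)
    if n_multi_gene:
        log.warning(
            "%d record(s) listed several gene symbols; first symbol taken",
            n_multi_gene,
        )
    return variants


_GT_TO_VCF = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def write_variants(
    variants: Sequence[AnnotatedVariant],
    samples: Sequence[str],
    path: str | Path,
    dialect: VcfDialect = DEFAULT_DIALECT,
    contigs: Sequence[str] | None = None,
    fill: Genotype = Genotype.HOM_REF,
) -> None:
    """Write biallelic VCF v4.2 records with the dialect's INFO keys.

    Samples missing from a variant's genotype map receive ``fill``
    (defaults to hom_ref: the variant was not called in them).
    """
    if contigs is None:
        seen: list[str] = []
        for v in variants:
            if v.chrom not in seen:
                seen.append(v.chrom)
        contigs = seen
    lines = ["##fileformat=VCFv4.2"]
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    lines.append(
        f'##INFO=<ID={dialect.gene_key},Number=1,Type=String,'
        'Description="Gene symbol">'
    )
    lines.append(
        f'##INFO=<ID={dialect.consequence_key},Number=1,Type=String,'
        'Description="Consequence class">'
    )
    lines.append(
        f'##INFO=<ID={dialect.af_key},Number=1,Type=Float,'
        'Description="Reference population allele frequency">'
    )
    for predictor, key in dialect.prediction_keys.items():
        lines.append(
            f'##INFO=<ID={key},Number=1,Type=String,'
            f'Description="{predictor} prediction (D damaging)">'
        )
    if dialect.artifact_key:
        lines.append(
            f'##INFO=<ID={dialect.artifact_key},Number=0,Type=Flag,'
            'Description="Known artifact">'
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
    )
    for v in variants:
        info = [
            f"{dialect.gene_key}={v.gene}",
            f"{dialect.consequence_key}={v.consequence.value}",
        ]
        if v.pop_af is not None:
            info.append(f"{dialect.af_key}={v.pop_af:.6g}")
        if v.annotated_in_db:
            code = {
                Prediction.DAMAGING: "D",
                Prediction.BENIGN: "T",
                Prediction.MISSING: ".",
            }
            for predictor, key in dialect.prediction_keys.items():
                info.append(f"{key}={code[v.predictions[predictor]]}")
        if v.artifact_flag and dialect.artifact_key:
            info.append(dialect.artifact_key)
        gts = "\t".join(
            _GT_TO_VCF[v.genotypes.get(s, fill)] for s in samples
        )
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t"
            + ";".join(info)
            + f"\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Gene-set (GMT) I/O
# ---------------------------------------------------------------------------


def read_term_sets(path: str | Path) -> list[TermSet]:
    """Read a GMT file: term_id <TAB> description <TAB> gene [<TAB> gene ...].

    Gene symbols are uppercased and deduplicated.  Lines with fewer than
    three fields are rejected with their line number.
    """
    terms: list[TermSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs term, description and "
                    f">=1 gene, got {len(parts)} field(s)"
                )
            genes = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
            if not genes:
                raise ValueError(f"{path}:{lineno}: no gene symbols on line")
            terms.append(TermSet(parts[0], parts[1], genes))
    return terms


def write_term_sets(terms: Iterable[TermSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in terms:
            fh.write(
                "\t".join([t.term_id, t.term_name, *sorted(t.genes)]) + "\n"
            )
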