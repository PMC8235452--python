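import pytest

from exofam.cohort import (
    Affection,
    AnnotatedVariant,
    Consequence,
    Family,
    Genotype,
    Individual,
    Prediction,
    PREDICTORS,
    Sex,
)


def make_individual(iid, fid="FAM01", aff=Affection.UNAFFECTED, seq=False,
                    father=None, mother=None, sex=Sex.UNKNOWN, cobb=()):
    return Individual(
        individual_id=iid,
        family_id=fid,
        father_id=father,
        mother_id=mother,
        sex=sex,
        affection=aff,
        sequenced=seq,
        cobb_angles=tuple(cobb),
    )


def make_variant(chrom="1", pos=100, ref="A", alt="T", gene="GENE1",
                 consequence=Consequence.NONSYNONYMOUS_SNV, pop_af=0.01,
                 damaging=("SIFT",), annotated=True, genotypes=None,
                 artifact=False):
    """A protein-altering, low-frequency, damaging variant by default."""
    if annotated:
        predictions = {
            p: Prediction.DAMAGING if p in damaging else Prediction.BENIGN
            for p in PREDICTORS
        }
    else:
        predictions = {p: Prediction.MISSING for p in PREDICTORS}
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence=consequence,
        pop_af=pop_af,
        predictions=predictions,
        annotated_in_db=annotated,
        artifact_flag=artifact,
        genotypes=dict(genotypes or {}),
    )


@pytest.fixture
def trio_family():
    """Father, mother, one sequenced affected child."""
    return Family(
        "FAM01",
        (
            make_individual("F", sex=Sex.MALE),
            make_individual("M", sex=Sex.FEMALE),
            make_individual(
                "C", aff=Affection.AFFECTED, seq=True, father="F", mother="M",
                cobb=(25.0,),
            ),
        ),
    )


@pytest.fixture
def three_sequenced_family():
    """Three sequenced affected siblings plus unaffected parents."""
    members = [
        make_individual("F", sex=Sex.MALE),
        make_individual("M", sex=Sex.FEMALE),
    ]
    for i in range(1, 4):
        members.append(
            make_individual(
                f"S{i}", aff=Affection.AFFECTED, seq=True,
                father="F", mother="M",
            )
        )
    return Family("FAM01", tuple(members))


def all_carrier_genotypes(family, genotype=Genotype.HET):
    return {m.individual_id: genotype for m in family.sequenced_members}
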