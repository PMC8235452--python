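"""Filter-cascade predicates, funnel, and brute-force equivalence."""
import numpy as np
import pytest

from exofam.cascade import (
    DEFAULT_WHITELIST,
    FilterConfig,
    passes_artifact,
    passes_consequence,
    passes_damaging,
    passes_frequency,
    run_cascade,
    shared_by_all_sequenced,
)
from exofam.cohort import Consequence, Genotype, VariantKey
from conftest import make_variant

CFG = FilterConfig()


def brute_force_retained(variants, family, config):
    """Independent oracle: intersection of the per-predicate pass sets."""
    passing = []
    for v in variants:
        if (
            passes_consequence(v, config)
            and passes_artifact(v, config)
            and passes_frequency(v, config)
            and passes_damaging(v, config)
            and shared_by_all_sequenced(v, family)
        ):
            passing.append(v)
    return sorted(passing, key=lambda v: (v.chrom, v.pos, v.alt))


class TestPredicates:
    @pytest.mark.parametrize(
        "consequence,expected",
        [
            (Consequence.STOPGAIN, True),
            (Consequence.SPLICE_SITE, True),
            (Consequence.NONSYNONYMOUS_SNV, True),
            (Consequence.FRAMESHIFT_INSERTION, True),
            (Consequence.OTHER, False),  # synonymous and the like
        ],
    )
    def test_consequence_whitelist(self, consequence, expected):
        v = make_variant(consequence=consequence)
        assert passes_consequence(v, CFG) is expected

    @pytest.mark.parametrize(
        "pop_af,expected",
        [
            (0.04, True),
            (None, True),  # novel sites are retained
            (0.05, False),  # boundary is exclusive
            (0.2, False),
        ],
    )
    def test_frequency_rule(self, pop_af, expected):
        assert passes_frequency(make_variant(pop_af=pop_af), CFG) is expected

    def test_one_damaging_predictor_suffices(self):
        assert passes_damaging(make_variant(damaging=("SIFT",)), CFG)

    def test_all_benign_fails(self):
        assert not passes_damaging(make_variant(damaging=()), CFG)

    def test_unannotated_not_subject_to_damaging_rule(self):
        v = make_variant(annotated=False)
        assert passes_damaging(v, CFG)
        assert not passes_damaging(
            v, FilterConfig(retain_if_unannotated=False)
        )

    def test_min_predictors_threshold(self):
        v = make_variant(damaging=("SIFT", "LRT"))
        assert passes_damaging(v, FilterConfig(damaging_min_predictors=2))
        assert not passes_damaging(v, FilterConfig(damaging_min_predictors=3))

    def test_artifact_blacklist_and_switch(self):
        v = make_variant()
        blocked = FilterConfig(artifact_blacklist=frozenset({v.key}))
        assert not passes_artifact(v, blocked)
        assert passes_artifact(v, FilterConfig())
        lenient = FilterConfig(
            drop_artifacts=False, artifact_blacklist=frozenset({v.key})
        )
        assert passes_artifact(v, lenient)


class TestSharing:
    def test_all_carriers_shared(self, three_sequenced_family):
        v = make_variant(genotypes={"S1": Genotype.HET, "S2": Genotype.HET,
                                    "S3": Genotype.HOM_ALT})
        assert shared_by_all_sequenced(v, three_sequenced_family)

    def test_one_non_carrier_breaks_sharing(self, three_sequenced_family):
        v = make_variant(genotypes={"S1": Genotype.HET, "S2": Genotype.HET,
                                    "S3": Genotype.HOM_REF})
        assert not shared_by_all_sequenced(v, three_sequenced_family)

    def test_missing_genotype_breaks_sharing(self, three_sequenced_family):
        v = make_variant(genotypes={"S1": Genotype.HET, "S2": Genotype.HET,
                                    "S3": Genotype.MISSING})
        assert not shared_by_all_sequenced(v, three_sequenced_family)

    def test_single_sequenced_member_vacuously_shared(self, trio_family):
        v = make_variant(genotypes={"C": Genotype.HET})
        assert shared_by_all_sequenced(v, trio_family)

    def test_no_genotyped_sequenced_member_errors(self, three_sequenced_family):
        v = make_variant(genotypes={})
        with pytest.raises(ValueError, match="FAM01"):
            shared_by_all_sequenced(v, three_sequenced_family)


class TestCascade:
    def test_five_variant_funnel(self, three_sequenced_family):
        carriers = {"S1": Genotype.HET, "S2": Genotype.HET, "S3": Genotype.HET}
        one_out = dict(carriers, S3=Genotype.HOM_REF)
        variants = [
            make_variant(pos=1, genotypes=carriers),  # passes everything
            make_variant(pos=2, consequence=Consequence.OTHER,
                         genotypes=carriers),
            make_variant(pos=3, pop_af=0.2, genotypes=carriers),
            make_variant(pos=4, damaging=(), genotypes=carriers),
            make_variant(pos=5, genotypes=one_out),
        ]
        retained, funnel = run_cascade(variants, three_sequenced_family, CFG)
        assert [v.pos for v in retained] == [1]
        assert [(n_in, n_out) for _, n_in, n_out in funnel.stages] == [
            (5, 4), (4, 4), (4, 3), (3, 2), (2, 1)
        ]
        assert funnel.is_monotone

    def test_empty_input(self, three_sequenced_family):
        retained, funnel = run_cascade([], three_sequenced_family, CFG)
        assert retained == []
        assert all(n_in == n_out == 0 for _, n_in, n_out in funnel.stages)

    def test_identity_configuration_retains_everything(
        self, three_sequenced_family
    ):
        config = FilterConfig(
            maf_threshold=1.0,
            consequence_whitelist=frozenset(Consequence),
            retain_if_unannotated=True,
        )
        carriers = {"S1": Genotype.HET, "S2": Genotype.HET, "S3": Genotype.HET}
        variants = [
            make_variant(pos=p, pop_af=af, consequence=c, genotypes=carriers)
            for p, af, c in [
                (1, 0.3, Consequence.OTHER),
                (2, None, Consequence.NONSYNONYMOUS_SNV),
                (3, 0.9999, Consequence.SPLICE_SITE),
            ]
        ]
        retained, _ = run_cascade(variants, three_sequenced_family, config)
        assert retained == sorted(
            variants, key=lambda v: (v.chrom, v.pos, v.alt)
        )

    def test_retained_satisfy_every_predicate(self, three_sequenced_family):
        variants = _random_variants(np.random.default_rng(0), 50)
        retained, _ = run_cascade(variants, three_sequenced_family, CFG)
        for v in retained:
            assert passes_consequence(v, CFG)
            assert passes_artifact(v, CFG)
            assert passes_frequency(v, CFG)
            assert passes_damaging(v, CFG)
            assert shared_by_all_sequenced(v, three_sequenced_family)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_intersection(
        self, seed, three_sequenced_family
    ):
        """Membership is stage-order independent: cascade == oracle."""
        rng = np.random.default_rng(seed)
        variants = _random_variants(rng, int(rng.integers(1, 51)))
        retained, funnel = run_cascade(variants, three_sequenced_family, CFG)
        assert retained == brute_force_retained(
            variants, three_sequenced_family, CFG
        )
        assert funnel.is_monotone


def _random_variants(rng, n):
    consequences = list(Consequence)
    gts = [Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT, Genotype.MISSING]
    out = []
    for i in range(n):
        annotated = rng.random() < 0.8
        out.append(
            make_variant(
                pos=i + 1,
                pop_af=None if rng.random() < 0.2 else float(rng.uniform(0, 0.2)),
                consequence=consequences[int(rng.integers(len(consequences)))],
                damaging=tuple(
                    p for p in ("SIFT", "Polyphen2", "LRT", "MutationTaster")
                    if rng.random() < 0.4
                ) if annotated else (),
                annotated=annotated,
                artifact=rng.random() < 0.05,
                genotypes={
                    # S1 always called so the sharing rule stays evaluable
                    "S1": gts[int(rng.integers(3))],
                    "S2": gts[int(rng.integers(4))],
                    "S3": gts[int(rng.integers(4))],
                },
            )
        )
    return out
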