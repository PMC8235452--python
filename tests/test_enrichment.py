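"""Overrepresentation statistics against exact rational-arithmetic oracles."""
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy.stats import hypergeom as scipy_hypergeom

from exofam.cohort import TermSet
from exofam.enrichment import (
    EnrichmentInput,
    bh_adjust,
    ease_score,
    enrich,
    hypergeom_right_tail,
    map_to_universe,
)


def exact_right_tail(k, n, K, N):
    """Oracle: exact rational summation of the hypergeometric tail."""
    total = Fraction(0)
    for i in range(k, min(n, K) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return total


class TestHypergeomRightTail:
    def test_tail_from_zero_is_one(self):
        assert hypergeom_right_tail(0, 5, 4, 20) == 1.0

    def test_worked_example(self):
        # k=2,n=5,K=4,N=20: (C(4,2)C(16,3)+C(4,3)C(16,2)+C(4,4)C(16,1))/C(20,5)
        expected = float(exact_right_tail(2, 5, 4, 20))
        assert expected == pytest.approx(0.2487, abs=5e-5)
        assert hypergeom_right_tail(2, 5, 4, 20) == pytest.approx(
            expected, rel=1e-12
        )

    def test_certain_configuration(self):
        assert hypergeom_right_tail(7, 7, 7, 7) == 1.0

    def test_impossible_configurations_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_right_tail(5, 4, 10, 20)  # k > n
        with pytest.raises(ValueError):
            hypergeom_right_tail(5, 10, 4, 20)  # k > K

    def test_agrees_with_scipy_survival_function(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            N = int(rng.integers(2, 2000))
            n = int(rng.integers(1, N + 1))
            K = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            ours = hypergeom_right_tail(k, n, K, N)
            ref = float(scipy_hypergeom.sf(k - 1, N, K, n))
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-300)

    def test_exact_oracle_small_grid(self):
        """Exhaustive (k,n,K) cross-check for small universes."""
        for N in range(1, 16):
            for n in range(N + 1):
                for K in range(N + 1):
                    for k in range(min(n, K) + 1):
                        ours = hypergeom_right_tail(k, n, K, N)
                        exact = float(exact_right_tail(k, n, K, N))
                        assert ours == pytest.approx(exact, rel=1e-12)


class TestEaseScore:
    def test_singleton_hit_carries_no_evidence(self):
        assert ease_score(1, 5, 4, 20) == 1.0

    def test_k_zero_defined_as_one(self):
        assert ease_score(0, 5, 4, 20) == 1.0

    def test_matches_shifted_table(self):
        # one list hit removed: tail at k-1 with list size n-1
        expected = float(exact_right_tail(1, 4, 4, 20))
        assert ease_score(2, 5, 4, 20) == pytest.approx(expected, rel=1e-12)

    def test_always_at_least_fisher(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            N = int(rng.integers(2, 300))
            n = int(rng.integers(1, N + 1))
            K = int(rng.integers(1, N + 1))
            k = int(rng.integers(1, min(n, K) + 1))
            fisher = hypergeom_right_tail(k, n, K, N)
            # conservativeness up to the 1e-12 relative accuracy of the
            # log-space tail computation
            assert ease_score(k, n, K, N) >= fisher * (1 - 1e-12)


class TestBHAdjust:
    def test_hand_worked_step_up(self):
        # 0.01*3/1=0.03, 0.02*3/2=0.03, 0.03*3/3=0.03
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.1] * 5) == pytest.approx([0.1] * 5)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(size=50)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        assert bh_adjust(p) == pytest.approx(ref)

    def test_capped_at_one_and_order_preserving(self):
        p = [0.9, 0.95, 0.99]
        adj = bh_adjust(p)
        assert np.all(adj <= 1.0)
        assert list(np.argsort(adj)) == list(np.argsort(p))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestMapToUniverse:
    def test_partial_overlap(self):
        genes = {f"G{i}" for i in range(1160)}
        background = {f"G{i}" for i in range(14, 5000)}
        mappable, unmapped = map_to_universe(genes, background)
        assert len(mappable) == 1146
        assert len(unmapped) == 14

    def test_subset_is_identity(self):
        mappable, unmapped = map_to_universe({"A"}, {"A", "B"})
        assert mappable == {"A"} and not unmapped

    def test_disjoint_sets_error(self):
        with pytest.raises(ValueError, match="maps"):
            map_to_universe({"A"}, {"B"})


class TestEnrich:
    @pytest.mark.parametrize(
        "k,expected_pct",
        [(36, 3.14), (5, 0.44), (17, 1.48), (347, 30.28)],
    )
    def test_percentage_column_at_n_1146(self, k, expected_pct):
        """Hit percentages of a 1146-gene mappable list, two decimals."""
        background = [f"G{i:05d}" for i in range(5000)]
        gene_list = frozenset(background[:1146])
        term = TermSet("T1", "term", frozenset(background[:k]))
        (result,) = enrich(
            EnrichmentInput(
                gene_list=gene_list,
                term_sets=[term],
                background=frozenset(background),
            )
        )
        assert result.k == k and result.n == 1146
        assert result.pct == expected_pct

    def test_fold_is_one_when_proportions_match(self):
        background = [f"G{i}" for i in range(100)]
        gene_list = frozenset(background[:50])  # half the universe
        term = TermSet("T", "t", frozenset(background[40:60]))  # k/n = K/N
        (result,) = enrich(
            EnrichmentInput(
                gene_list=gene_list,
                term_sets=[term],
                background=frozenset(background),
            )
        )
        assert result.fold == pytest.approx(1.0)

    def test_fold_scale_invariance(self):
        # doubling K and N together leaves fold unchanged
        k, n = 6, 50
        for K, N in [(20, 200), (40, 400), (200, 2000)]:
            fold = (k / n) / (K / N)
            assert fold == pytest.approx((k / n) / (2 * K / (2 * N)))

    def test_min_count_suppression_and_sorting(self):
        background = [f"G{i}" for i in range(200)]
        gene_list = frozenset(background[:40])
        terms = [
            TermSet("BIG", "hit often", frozenset(background[:30])),
            TermSet("ONE", "single hit", frozenset([background[0]] + background[150:160])),
            TermSet("NULL", "no hits", frozenset(background[100:120])),
        ]
        results = enrich(
            EnrichmentInput(
                gene_list=gene_list,
                term_sets=terms,
                background=frozenset(background),
            )
        )
        ids = [r.term_id for r in results]
        assert "ONE" not in ids  # k=1 < min_count
        assert "NULL" not in ids
        assert ids == ["BIG"]

    def test_ease_flag_switches_statistic(self):
        background = [f"G{i}" for i in range(200)]
        gene_list = frozenset(background[:40])
        terms = [TermSet("T", "t", frozenset(background[:30]))]
        base = dict(
            gene_list=gene_list, term_sets=terms,
            background=frozenset(background),
        )
        (with_ease,) = enrich(EnrichmentInput(ease=True, **base))
        (fisher,) = enrich(EnrichmentInput(ease=False, **base))
        assert with_ease.p_raw >= fisher.p_raw
        assert fisher.p_raw == pytest.approx(
            hypergeom_right_tail(fisher.k, fisher.n, fisher.K, fisher.N)
        )
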