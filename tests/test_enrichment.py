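"""Exact binomial/hypergeometric tests, BH adjustment, and the three
enrichment frameworks, validated against brute-force enumeration."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from qtlome import (
    GeneRecord,
    GenomeAssembly,
    benjamini_hochberg,
    binomial_two_sided,
    chromosome_enrichment,
    count_features,
    hypergeom_upper,
    make_grid,
    trait_window_enrichment,
    window_enrichment,
)


def binom_two_sided_oracle(observed: int, n: int, p: float) -> float:
    """Sum of all pmf values not exceeding pmf(observed), by enumeration.

    The pmf is enumerated in log space so large n cannot overflow."""
    from math import exp, lgamma, log

    def log_pmf(k):
        return (
            lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)
            + k * log(p) + (n - k) * log(1 - p)
        )

    pmf = [exp(log_pmf(k)) for k in range(n + 1)]
    cutoff = pmf[observed] * (1 + 1e-7)
    return min(1.0, sum(v for v in pmf if v <= cutoff))


def hypergeom_upper_oracle(q: int, m: int, n_rest: int, k: int) -> float:
    """P(X >= q) as an exact combinatorial fraction."""
    total = Fraction(0)
    for x in range(q, min(m, k) + 1):
        total += Fraction(comb(m, x) * comb(n_rest, k - x), comb(m + n_rest, k))
    return float(total)


class TestBinomialTwoSided:
    def test_worked_example_eight_of_ten_fair(self):
        assert binomial_two_sided(8, 10, 0.5) == pytest.approx(112 / 1024, abs=1e-12)

    def test_mode_observation_gives_p_one(self):
        assert binomial_two_sided(5, 10, 0.5) == pytest.approx(1.0)

    def test_extreme_tail_matches_enumeration(self):
        assert binomial_two_sided(0, 10, 0.9) == pytest.approx(
            binom_two_sided_oracle(0, 10, 0.9), abs=1e-12
        )

    @pytest.mark.parametrize("p_null", [0.0, 1.0, -0.1])
    def test_degenerate_null_rejected(self, p_null):
        with pytest.raises(ValueError):
            binomial_two_sided(1, 10, p_null)

    def test_grid_against_oracle(self):
        for n in (7, 23, 60):
            for p in (0.08, 0.5, 0.77):
                for obs in range(0, n + 1, 3):
                    assert binomial_two_sided(obs, n, p) == pytest.approx(
                        binom_two_sided_oracle(obs, n, p), abs=1e-10
                    )


class TestHypergeomUpper:
    def test_worked_combinatorial_example(self):
        # C(10,3)C(40,2) + C(10,4)C(40,1) + C(10,5) over C(50,5)
        assert hypergeom_upper(3, 10, 40, 5) == pytest.approx(
            102_252 / 2_118_760, abs=1e-12
        )

    def test_zero_observed_is_certain(self):
        assert hypergeom_upper(0, 10, 40, 5) == 1.0

    def test_degenerate_population_gives_one(self):
        assert hypergeom_upper(7, 50, 0, 50) == pytest.approx(1.0)

    def test_impossible_observation_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper(6, 10, 40, 5)

    def test_grid_against_oracle(self):
        for m, n_rest, k in ((10, 40, 5), (25, 25, 10), (3, 97, 50)):
            for q in range(0, min(m, k) + 1):
                assert hypergeom_upper(q, m, n_rest, k) == pytest.approx(
                    hypergeom_upper_oracle(q, m, n_rest, k), abs=1e-10
                )


class TestBenjaminiHochberg:
    def test_stepup_by_hand(self):
        adjusted = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.7])[0] == pytest.approx(0.7)

    def test_never_decreases_and_never_exceeds_one(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(1e-6, 1, size=100)
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
        # monotone over the sorted order
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 0.0])


ASM = GenomeAssembly(
    "toy",
    (("chr1", 5_000_000), ("chr2", 3_000_000), ("chr3", 2_000_000)),
)


class TestChromosomeEnrichment:
    def test_expectation_is_n_times_p(self):
        tests = chromosome_enrichment(ASM, {"chr1": 500, "chr2": 300, "chr3": 200})
        by = {t.unit: t for t in tests}
        assert by["chr1"].expected == pytest.approx(1000 * 0.5)
        assert by["chr1"].direction == "neutral"
        assert by["chr1"].p_raw == pytest.approx(1.0)

    def test_excess_is_enriched_with_enumerated_p(self):
        tests = chromosome_enrichment(ASM, {"chr1": 500, "chr2": 300, "chr3": 350})
        chr3 = next(t for t in tests if t.unit == "chr3")
        assert chr3.direction == "enriched"
        assert chr3.p_raw == pytest.approx(
            binom_two_sided_oracle(350, 1150, 0.2), rel=1e-9
        )

    def test_empty_chromosome_is_depleted(self):
        tests = chromosome_enrichment(ASM, {"chr1": 40, "chr2": 10, "chr3": 0})
        chr3 = next(t for t in tests if t.unit == "chr3")
        assert chr3.direction == "depleted"
        assert chr3.p_raw == pytest.approx(binom_two_sided_oracle(0, 50, 0.2), rel=1e-9)

    def test_bh_is_applied_across_chromosomes(self):
        tests = chromosome_enrichment(ASM, {"chr1": 900, "chr2": 80, "chr3": 20})
        assert all(t.p_adj is not None and t.p_adj >= t.p_raw for t in tests)


class TestWindowEnrichment:
    def _grid(self, Q, qtl_positions, gene_positions):
        grid = make_grid(ASM, 1_000_000)
        qtl = [Q(start=p, end=p + 1, qtl_id=f"q{i}")
               for i, p in enumerate(qtl_positions)]
        genes = [GeneRecord("chr1", p, p + 10, f"g{i}")
                 for i, p in enumerate(gene_positions)]
        return count_features(grid, qtl, genes)

    def test_null_proportional_window_is_unremarkable(self, Q):
        grid = self._grid(Q, [100, 1_000_100], [200, 1_000_200])
        tests, skipped = window_enrichment(grid)
        assert all(t.p_raw == pytest.approx(1.0) for t in tests)

    def test_zero_gene_window_skipped_with_reason(self, Q):
        grid = self._grid(Q, [100, 2_000_100], [200])
        tests, skipped = window_enrichment(grid)
        assert any(s.reason == "zero_genes" and s.unit.startswith("chr1:2000000")
                   for s in skipped)
        assert all(not t.unit.startswith("chr1:2000000") for t in tests)

    def test_no_genes_at_all_is_an_error(self, Q):
        grid = make_grid(ASM, 1_000_000)
        with pytest.raises(ValueError):
            window_enrichment(grid)


class TestTraitWindowEnrichment:
    def test_singleton_label_has_closed_form_p(self, Q, assembly):
        # one labelled QTL among N in window W: P(X>=1) = m/N
        qtl = [Q(start=i * 10, end=i * 10 + 1, qtl_id=f"q{i}", trait="common")
               for i in range(9)]
        qtl.append(Q(chrom="chr2", start=50, end=51, qtl_id="rare1", trait="rare"))
        grid = count_features(make_grid(assembly, 1_000_000), qtl)
        tests = trait_window_enrichment(grid, qtl, level="trait")
        rare = next(t for t in tests if t.trait_label == "rare")
        assert rare.q_obs == 1 and rare.k == 1 and rare.m == 1
        assert rare.p_raw == pytest.approx(rare.m / 10)

    def test_no_test_for_absent_window_label_pairs(self, Q, assembly):
        qtl = [
            Q(start=10, end=11, trait="growth", qtl_id="a"),
            Q(chrom="chr2", start=10, end=11, trait="milk", qtl_id="b"),
        ]
        grid = count_features(make_grid(assembly, 1_000_000), qtl)
        tests = trait_window_enrichment(grid, qtl, level="trait")
        pairs = {(t.window.split(":")[0], t.trait_label) for t in tests}
        assert pairs == {("chr1", "growth"), ("chr2", "milk")}

    def test_unknown_level_rejected(self, Q, assembly):
        grid = count_features(make_grid(assembly, 1_000_000), [Q()])
        with pytest.raises(ValueError):
            trait_window_enrichment(grid, [Q()], level="phenome")

    def test_bh_family_modes_both_run(self, Q, assembly):
        qtl = [Q(start=i * 100, end=i * 100 + 1, qtl_id=f"q{i}",
                 trait=["growth", "milk"][i % 2]) for i in range(20)]
        grid = count_features(make_grid(assembly, 1_000_000), qtl)
        for family in ("per_label", "global"):
            tests = trait_window_enrichment(grid, qtl, level="trait", bh_family=family)
            assert all(t.p_adj is not None for t in tests)
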