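from fractions import Fraction

import pytest
from hypothesis import given, strategies as st

from phytamyloid import (
    GenomeSource,
    ProteinRecord,
    ProteomeSummary,
    Region,
    adjust_bh,
    compare_species,
    coverage,
    fisher_exact_2x2,
    fraction_flagged,
    length_stats,
    subset_by_genome,
)

from .oracles import bh_step_up, fisher_two_sided_exact


def _proteome(n, length=100):
    return [ProteinRecord(f"p{i}", "A" * length) for i in range(n)]


class TestFractionFlagged:
    @pytest.mark.parametrize("n_flagged,n,expected", [(2, 8, 25.0), (0, 5, 0.0),
                                                      (5, 5, 100.0)])
    def test_arithmetic(self, n_flagged, n, expected):
        proteome = _proteome(n)
        flags = {f"p{i}": i < n_flagged for i in range(n)}
        assert fraction_flagged(proteome, flags) == expected

    def test_empty_proteome_errors(self):
        with pytest.raises(ValueError):
            fraction_flagged([], {})

    def test_invariant_under_reordering(self):
        proteome = _proteome(6)
        flags = {"p0": True, "p3": True}
        assert fraction_flagged(proteome, flags) == fraction_flagged(
            proteome[::-1], flags
        )


class TestCoverage:
    def test_partial(self):
        proteome = [ProteinRecord("a", "A" * 150), ProteinRecord("b", "A" * 50)]
        regions = {"a": [Region(0, 30, "AR")], "b": [Region(10, 30, "AR")]}
        assert coverage(proteome, regions) == 25.0

    def test_no_regions(self):
        assert coverage(_proteome(3), {}) == 0.0

    def test_fully_covered_single_protein(self):
        proteome = [ProteinRecord("a", "A" * 80)]
        assert coverage(proteome, {"a": [Region(0, 80, "AR")]}) == 100.0

    def test_overlapping_regions_not_double_counted(self):
        proteome = [ProteinRecord("a", "A" * 100)]
        regions = {"a": [Region(0, 60, "AR"), Region(40, 100, "AR")]}
        assert coverage(proteome, regions) == 100.0


class TestLengthStats:
    def test_median_and_mode(self):
        regions = [Region(0, n, "AR") for n in (5, 7, 7, 9)]
        assert length_stats(regions) == (7.0, 7)

    def test_even_median_and_mode_tie_smallest(self):
        regions = [Region(0, 6, "AR"), Region(0, 7, "AR")]
        assert length_stats(regions) == (6.5, 6)

    def test_single_region(self):
        assert length_stats([Region(0, 10, "AR")]) == (10.0, 10)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            length_stats([])


class TestSubsetByGenome:
    def test_subsetting(self):
        proteome = [
            ProteinRecord(f"c{i}", "A", genome_source=GenomeSource.CHLOROPLAST)
            for i in range(3)
        ] + [ProteinRecord(f"n{i}", "A", genome_source=GenomeSource.NUCLEAR)
             for i in range(7)]
        assert len(subset_by_genome(proteome, "chloroplast")) == 3
        assert subset_by_genome(proteome, GenomeSource.MITOCHONDRION) == []

    def test_unknown_records_excluded_from_named_subsets(self):
        proteome = [ProteinRecord("u", "A")]  # genome_source defaults to unknown
        assert subset_by_genome(proteome, "nuclear") == []
        assert len(subset_by_genome(proteome, "unknown")) == 1


class TestFisherExact:
    def test_extreme_table(self):
        # only 2 of the 252 equi-marginal tables are this unbalanced
        assert fisher_exact_2x2(5, 0, 0, 5) == pytest.approx(2 / 252)

    def test_balanced_table(self):
        assert fisher_exact_2x2(1, 1, 1, 1) == 1.0

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fisher_exact_2x2(0, 0, 1, 1)

    def test_matches_exact_enumeration(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            expected = float(fisher_two_sided_exact(a, b, c, d))
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                expected, rel=1e-10
            )


class TestAdjustBH:
    def test_step_up_formula(self):
        assert adjust_bh([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_identity(self):
        assert adjust_bh([0.5]) == [0.5]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_textbook_step_up_and_is_monotone(self, pvals):
        got = adjust_bh(pvals)
        assert got == pytest.approx(bh_step_up(pvals))
        order = sorted(range(len(pvals)), key=lambda i: pvals[i])
        adjusted_sorted = [got[i] for i in order]
        assert all(a <= b + 1e-15 for a, b in zip(adjusted_sorted,
                                                  adjusted_sorted[1:]))
        assert all(0 <= v <= 1 for v in got)

    def test_cross_check_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        pvals = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205]
        _, expected, _, _ = statsmodels.multipletests(pvals, method="fdr_bh")
        assert adjust_bh(pvals) == pytest.approx(list(expected))


class TestCompareSpecies:
    def test_identical_summaries_give_p_one(self):
        s = [ProteomeSummary("a", 100, 50), ProteomeSummary("b", 100, 50)]
        frame = compare_species(s)
        assert len(frame) == 1
        assert frame["p_adjusted"].iloc[0] == 1.0

    def test_three_species_three_pairs(self):
        s = [
            ProteomeSummary("a", 100, 20),
            ProteomeSummary("b", 100, 50),
            ProteomeSummary("c", 100, 80),
        ]
        frame = compare_species(s)
        assert len(frame) == 3
        assert set(frame.columns) == {"species_a", "species_b", "p", "p_adjusted"}

    def test_requires_two(self):
        with pytest.raises(ValueError):
            compare_species([ProteomeSummary("a", 10, 1)])
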