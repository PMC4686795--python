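"""Genome model: matchings, breakpoint-graph decomposition, distances."""

from fractions import Fraction

import pytest
from hypothesis import given

from hultman import (
    Chromosome,
    ExtremityMatching,
    Genome,
    GenomeError,
    algebraic_distance,
    dcj_distance,
    decompose,
    genome_to_matching,
    identity_circular,
    identity_with_linear,
)
from hultman.genomes import head, tail

from conftest import count_components, genomes


def matching(n, *edges):
    return ExtremityMatching(n=n, edges=frozenset(edges))


class TestMatchingConstruction:
    def test_linear_four_gene_chain(self):
        g = Genome((Chromosome((1, 2, 3, 4), is_linear=True),))
        m = genome_to_matching(g)
        assert m.edges == frozenset(
            {(head(1), tail(2)), (head(2), tail(3)), (head(3), tail(4))}
        )
        assert m.unsaturated == (tail(1), head(4))

    def test_single_gene_circular_is_perfect(self):
        m = genome_to_matching(Genome((Chromosome((1,), is_linear=False),)))
        assert m.edges == frozenset({(tail(1), head(1))})
        assert m.is_perfect()

    def test_single_gene_linear_is_empty(self):
        m = genome_to_matching(Genome((Chromosome((1,), is_linear=True),)))
        assert m.edges == frozenset()
        assert m.unsaturated == (1, 2)

    def test_negative_gene_orientation_flips_extremities(self):
        # (1 -2) circular: head(1)-head(2) and tail(2)-tail(1)
        m = genome_to_matching(Genome((Chromosome((1, -2), is_linear=False),)))
        assert m.edges == frozenset({(head(1), head(2)), (tail(1), tail(2))})

    def test_duplicate_gene_label_names_offender(self):
        with pytest.raises(GenomeError, match="3"):
            Genome(
                (
                    Chromosome((1, 3), is_linear=True),
                    Chromosome((-3, 2), is_linear=True),
                )
            )

    def test_missing_gene_label_rejected(self):
        with pytest.raises(GenomeError, match="missing"):
            Genome((Chromosome((1, 4), is_linear=True),))

    def test_matching_rejects_resaturated_vertex(self):
        with pytest.raises(GenomeError, match="saturated twice"):
            matching(2, (1, 2), (2, 3))


class TestIdentities:
    def test_circular_identity(self):
        g = identity_circular(3)
        assert g.chromosomes == (Chromosome((1, 2, 3), is_linear=False),)
        assert identity_circular(1).n == 1
        assert identity_circular(9).n == 9

    @pytest.mark.parametrize("n", [0, -2])
    def test_circular_identity_rejects_nonpositive(self, n):
        with pytest.raises(GenomeError):
            identity_circular(n)

    def test_linear_identity_splits_evenly(self):
        g = identity_with_linear(4, 2)
        assert g.chromosomes == (
            Chromosome((1, 2), is_linear=True),
            Chromosome((3, 4), is_linear=True),
        )
        assert identity_with_linear(2, 2).chromosomes == (
            Chromosome((1,), is_linear=True),
            Chromosome((2,), is_linear=True),
        )
        # remainder goes to the first chromosomes
        sizes = [len(c) for c in identity_with_linear(7, 3).chromosomes]
        assert sizes == [3, 2, 2]

    def test_linear_identity_zero_is_circular(self):
        assert identity_with_linear(3, 0) == identity_circular(3)

    @pytest.mark.parametrize("ell", [-1, 5])
    def test_linear_identity_range_checked(self, ell):
        with pytest.raises(GenomeError):
            identity_with_linear(4, ell)

    @given(genomes())
    def test_matching_size_accounts_for_telomeres(self, g):
        m = genome_to_matching(g)
        assert 2 * len(m.edges) + 2 * g.num_linear == 2 * g.n


class TestDecompose:
    def test_worked_nine_gene_example(self, figure_pair):
        a, b = figure_pair
        s = decompose(a.matching(), b.matching())
        assert (s.cycles, s.paths) == (2, 1)

    @pytest.mark.parametrize("n", [1, 3, 6])
    def test_identity_vs_itself_all_two_cycles(self, n):
        m = identity_circular(n).matching()
        s = decompose(m, m)
        assert (s.cycles, s.paths) == (n, 0)

    def test_two_empty_matchings_give_singleton_paths(self):
        m = matching(1)
        s = decompose(m, m)
        assert (s.cycles, s.paths, s.even_paths) == (0, 2, 2)
        assert s.path_edge_lengths == (0, 0)

    def test_reversal_of_two_gene_circular_genome_is_one_cycle(self):
        a = Genome((Chromosome((1, 2), is_linear=False),))
        b = Genome((Chromosome((1, -2), is_linear=False),))
        s = decompose(a.matching(), b.matching())
        assert (s.cycles, s.paths) == (1, 0)

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(GenomeError):
            decompose(matching(1), matching(2))

    @given(genomes(), genomes())
    def test_symmetric_in_arguments(self, a, b):
        if a.n != b.n:
            return
        assert decompose(a.matching(), b.matching()) == decompose(
            b.matching(), a.matching()
        )

    @given(genomes())
    def test_perfect_vs_perfect_has_no_paths(self, g):
        # compare against the circular identity after dropping linear chromosomes
        circ = Genome(
            tuple(Chromosome(c.genes, is_linear=False) for c in g.chromosomes)
        )
        s = decompose(circ.matching(), identity_circular(g.n).matching())
        assert s.paths == 0
        assert s.path_edge_lengths == ()
        # cycle lengths (in edges) over a perfect/perfect pair sum to 2n
        assert 2 * len(circ.matching().edges) == 2 * g.n

    @given(genomes(), genomes())
    def test_component_count_matches_union_find(self, a, b):
        if a.n != b.n:
            return
        ma, mb = a.matching(), b.matching()
        s = decompose(ma, mb)
        expected = count_components(2 * a.n, list(ma.edges) + list(mb.edges))
        assert s.cycles + s.paths == expected


class TestDistances:
    def test_identical_circular_genomes_at_zero(self):
        i5 = identity_circular(5)
        assert dcj_distance(i5, i5) == 0
        assert algebraic_distance(i5, i5) == 0

    def test_identical_linear_singleton_at_zero(self):
        g = Genome((Chromosome((1,), is_linear=True),))
        # the two singleton paths have 0 edges, which counts as even
        assert dcj_distance(g, g) == 0
        assert algebraic_distance(g, g) == 0

    def test_worked_example_distances(self, figure_pair):
        a, b = figure_pair
        s = decompose(a.matching(), b.matching())
        # the single path has odd edge count, so no even paths
        assert s.even_paths == 0
        assert dcj_distance(a, b) == 7
        assert algebraic_distance(a, b) == Fraction(13, 2)

    def test_linear_vs_circular_singleton(self):
        lin = Genome((Chromosome((1,), is_linear=True),))
        circ = Genome((Chromosome((1,), is_linear=False),))
        assert algebraic_distance(lin, circ) == Fraction(1, 2)

    def test_gene_set_mismatch_rejected(self):
        with pytest.raises(GenomeError, match="gene sets differ"):
            dcj_distance(identity_circular(3), identity_circular(4))

    def test_zero_algebraic_distance_iff_equal_matchings(self):
        # exhaustive over all matching pairs for n <= 3
        from hultman import EnumerationSpec, enumerate_matchings

        for n in (1, 2, 3):
            ms = list(enumerate_matchings(EnumerationSpec(2 * n, "all")))
            for ma in ms:
                for mb in ms:
                    s = decompose(ma, mb)
                    d = Fraction(n) - s.cycles - Fraction(s.paths, 2)
                    assert (d == 0) == (ma.edges == mb.edges)


class TestGenomeEquality:
    def test_circular_rotation_and_reflection(self):
        a = Genome((Chromosome((1, 2, 3), is_linear=False),))
        b = Genome((Chromosome((2, 3, 1), is_linear=False),))
        c = Genome((Chromosome((-3, -2, -1), is_linear=False),))
        assert a == b == c
        assert hash(a) == hash(b) == hash(c)

    def test_linear_reversal(self):
        a = Genome((Chromosome((1, 2), is_linear=True),))
        b = Genome((Chromosome((-2, -1), is_linear=True),))
        assert a == b

    def test_distinct_genomes_differ(self):
        a = Genome((Chromosome((1, 2), is_linear=True),))
        b = Genome((Chromosome((1, -2), is_linear=True),))
        assert a != b

    @given(genomes())
    def test_random_genome_equals_itself_rebuilt(self, g):
        rebuilt = Genome(g.chromosomes)
        assert g == rebuilt
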