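"""Co-occurrence distance: worked example, oracle equivalence, metric properties."""

import itertools
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cooccnet import (
    ConditionalProfile,
    attribute_distance,
    attribute_distance_bruteforce,
    conditional_profile,
    gene_distance,
    pairwise_distance_matrix,
)
from cooccnet.cooccurrence import DistanceMatrix
from cooccnet.errors import (
    CooccnetError,
    UnknownAttributeError,
    UnknownGeneError,
    VocabularyTooLargeError,
)

from conftest import make_table, random_profile_pair, random_table


class TestConditionalProfile:
    def test_worked_example_profiles(self, worked_example_table):
        t = worked_example_table
        fam = conditional_profile(t, "FAM171B", "mutation_type")
        assert fam.probs == {"Missense": Fraction(2, 3), "Nonsense": Fraction(1, 3)}
        assert fam.support == 3
        abca = conditional_profile(t, "ABCA6", "mutation_type")
        assert abca.probs == {"Missense": Fraction(1)}
        assert abca.support == 1

    def test_single_record_gene_is_degenerate(self):
        t = make_table([("X", "RNA", "C>T"), ("Y", "Silent", "A>G")])
        prof = conditional_profile(t, "X", "mutation_type")
        assert prof.probs == {"RNA": Fraction(1)}

    def test_unknown_lookups_name_the_culprit(self, worked_example_table):
        with pytest.raises(UnknownGeneError, match="TP53"):
            conditional_profile(worked_example_table, "TP53", "mutation_type")
        with pytest.raises(UnknownAttributeError, match="strand"):
            conditional_profile(worked_example_table, "ABCA6", "strand")


class TestAttributeDistance:
    def test_worked_example_both_attributes(self, worked_example_table):
        t = worked_example_table
        d1 = attribute_distance(
            conditional_profile(t, "FAM171B", "mutation_type"),
            conditional_profile(t, "ABCA6", "mutation_type"),
        )
        assert d1.value == Fraction(1, 3)
        d2 = attribute_distance(
            conditional_profile(t, "FAM171B", "nucleotide_change"),
            conditional_profile(t, "ABCA6", "nucleotide_change"),
        )
        assert d2.value == Fraction(2, 3)

    def test_identical_profiles_give_zero(self):
        p = ConditionalProfile(
            "g", "a", {"x": Fraction(1, 2), "y": Fraction(1, 2)}, 2
        )
        assert attribute_distance(p, p).value == 0

    def test_disjoint_supports_give_one(self):
        p = ConditionalProfile("g1", "a", {"x": Fraction(1)}, 1)
        q = ConditionalProfile("g2", "a", {"y": Fraction(1)}, 1)
        assert attribute_distance(p, q).value == 1

    def test_attribute_mismatch_rejected(self):
        p = ConditionalProfile("g1", "a", {"x": Fraction(1)}, 1)
        q = ConditionalProfile("g2", "b", {"x": Fraction(1)}, 1)
        with pytest.raises(CooccnetError, match="mismatch"):
            attribute_distance(p, q)


class TestBruteforceOracle:
    def test_worked_example_subset_sums_and_argmax(self, worked_example_table):
        """The two candidate subset sums are 2/3 and 4/3; the winner is 4/3."""
        t = worked_example_table
        abca = conditional_profile(t, "ABCA6", "mutation_type")
        fam = conditional_profile(t, "FAM171B", "mutation_type")
        # enumerate by hand: w = {Missense} gives P_ABCA6(Missense) +
        # P_FAM171B(Nonsense) = 1 + 1/3 = 4/3; w = {Nonsense} gives
        # 0 + 2/3 = 2/3.
        sums = {
            w: abca.mass(frozenset(w)) + fam.mass(frozenset({"Missense", "Nonsense"}) - frozenset(w))
            for w in [("Missense",), ("Nonsense",)]
        }
        assert sums[("Missense",)] == Fraction(4, 3)
        assert sums[("Nonsense",)] == Fraction(2, 3)
        res = attribute_distance_bruteforce(abca, fam)
        assert res.value == Fraction(1, 3)
        assert res.argmax_subset == frozenset({"Missense"})

    def test_identical_profiles_argmax_empty(self):
        p = ConditionalProfile("g", "a", {"x": Fraction(1, 2), "y": Fraction(1, 2)}, 2)
        res = attribute_distance_bruteforce(p, p)
        assert res.value == 0
        assert res.argmax_subset == frozenset()

    def test_size_guard(self):
        n = 25
        p = ConditionalProfile(
            "g1", "a", {f"c{i}": Fraction(1, n) for i in range(n)}, n
        )
        with pytest.raises(VocabularyTooLargeError):
            attribute_distance_bruteforce(p, p)

    def test_fast_path_matches_enumeration_on_random_profiles(self):
        """Closed form == literal 2^K subset maximum, exactly, on 50 pairs."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            p, q = random_profile_pair(rng, max_categories=6)
            fast = attribute_distance(p, q).value
            brute = attribute_distance_bruteforce(p, q).value
            assert fast == brute  # both exact rationals


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    counts_p=st.lists(st.integers(0, 8), min_size=1, max_size=6),
    counts_q=st.lists(st.integers(0, 8), min_size=1, max_size=6),
)
def test_fast_path_equals_bruteforce_property(counts_p, counts_q):
    """Subset-maximization identity holds for arbitrary rational profiles."""
    def to_profile(counts, gene):
        total = sum(counts)
        if total == 0:
            counts = [1] + counts[1:]
            total = sum(counts)
        probs = {
            f"c{i}": Fraction(c, total) for i, c in enumerate(counts) if c > 0
        }
        return ConditionalProfile(gene, "a", probs, total)

    p, q = to_profile(counts_p, "x"), to_profile(counts_q, "y")
    assert attribute_distance(p, q).value == attribute_distance_bruteforce(p, q).value


class TestGeneDistance:
    def test_worked_example_value(self, worked_example_table):
        assert gene_distance(worked_example_table, "FAM171B", "ABCA6") == Fraction(1, 2)

    def test_self_distance_zero_and_symmetry(self, worked_example_table):
        t = worked_example_table
        assert gene_distance(t, "ABCA6", "ABCA6") == 0
        assert gene_distance(t, "ABCA6", "FAM171B") == gene_distance(
            t, "FAM171B", "ABCA6"
        )

    def test_unknown_gene(self, worked_example_table):
        with pytest.raises(UnknownGeneError):
            gene_distance(worked_example_table, "FAM171B", "NOPE")


class TestPairwiseMatrix:
    def test_worked_example_matrix(self, worked_example_table):
        m = pairwise_distance_matrix(worked_example_table)
        assert m.genes == ["ABCA6", "FAM171B"]
        np.testing.assert_allclose(m.values, [[0.0, 0.5], [0.5, 0.0]])
        assert m.divisor_m_minus_1 == 2

    def test_identical_single_record_genes_all_zero(self):
        rows = [(f"G{i}", "Missense", "G>T") for i in range(5)]
        m = pairwise_distance_matrix(make_table(rows))
        np.testing.assert_array_equal(m.values, np.zeros((5, 5)))

    def test_matches_pairwise_gene_distance(self):
        """Vectorized matrix equals the exact pairwise path on 20 genes."""
        rng = np.random.default_rng(3)
        table = random_table(rng, n_genes=20, n_records=120)
        m = pairwise_distance_matrix(table)
        for i, j in itertools.combinations(range(len(m.genes)), 2):
            exact = gene_distance(table, m.genes[i], m.genes[j])
            assert abs(m.values[i, j] - float(exact)) < 1e-12

    def test_record_order_irrelevant(self):
        rng = np.random.default_rng(11)
        table = random_table(rng, n_genes=6, n_records=40)
        shuffled_rows = [
            (r.gene, r.attributes["mutation_type"], r.attributes["nucleotide_change"])
            for r in table.records
        ]
        rng.shuffle(shuffled_rows)
        m1 = pairwise_distance_matrix(table)
        m2 = pairwise_distance_matrix(make_table(shuffled_rows))
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_single_gene_rejected(self):
        with pytest.raises(CooccnetError, match="at least 2"):
            pairwise_distance_matrix(make_table([("X", "Silent", "A>G")]))

    def test_tsv_round_trip(self, worked_example_table, tmp_path):
        m = pairwise_distance_matrix(worked_example_table)
        path = tmp_path / "m.tsv"
        m.to_tsv(path)
        back = DistanceMatrix.from_tsv(path)
        assert back.genes == m.genes
        np.testing.assert_allclose(back.values, m.values, atol=1e-9)

    def test_edge_list_long_format(self, worked_example_table):
        m = pairwise_distance_matrix(worked_example_table)
        edges = m.edge_list(threshold=0.5)
        assert list(edges.columns) == ["gene_a", "gene_b", "distance", "similarity"]
        assert edges.iloc[0].tolist() == ["ABCA6", "FAM171B", 0.5, 0.5]
        assert m.edge_list(threshold=0.4).empty


@pytest.fixture(scope="module")
def tables():
    rng = np.random.default_rng(2024)
    return [
        random_table(
            rng,
            n_genes=int(rng.integers(2, 9)),
            n_records=int(rng.integers(10, 40)),
        )
        for _ in range(15)
    ]


class TestMetricProperties:
    """Range, symmetry, identity, zero-characterization, triangle inequality."""

    def test_range_symmetry_identity(self, tables):
        for table in tables:
            m = pairwise_distance_matrix(table)
            assert (m.values >= 0).all() and (m.values <= 1).all()
            np.testing.assert_array_equal(m.values, m.values.T)
            np.testing.assert_array_equal(np.diag(m.values), 0.0)

    def test_zero_iff_identical_profiles(self, tables):
        for table in tables:
            for x, y in itertools.combinations(table.gene_index, 2):
                same = all(
                    conditional_profile(table, x, a).probs
                    == conditional_profile(table, y, a).probs
                    for a in table.attribute_names
                )
                d = gene_distance(table, x, y)
                assert (d == 0) == same

    def test_triangle_inequality(self, tables):
        # averages of total-variation distances are metrics
        for table in tables:
            m = pairwise_distance_matrix(table)
            n = len(m.genes)
            for i, j, k in itertools.permutations(range(n), 3):
                assert m.values[i, k] <= m.values[i, j] + m.values[j, k] + 1e-12
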