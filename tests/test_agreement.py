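"""Pairwise character-agreement counting, percentages and delimitation."""

import pytest
from hypothesis import given, settings, strategies as st

from morphotax.agreement import (
    GENUS_THRESHOLD,
    SPECIES_THRESHOLD,
    PairwiseComparison,
    UndefinedPercentageError,
    compare_pair,
    delimit,
    difference_percent,
    pairwise_table,
)
from morphotax.io import read_tnt
from morphotax.model import CellScore, UnknownOTUError
from morphotax.simulate import SimulationConfig, generate_matrix, plant_pair

from conftest import random_matrix


class TestComparePair:
    def test_hand_enumerated_example(self):
        # A = (0, 1, ?, 0, {0,1}); B = (0, 0, 1, ?, 1)
        m = read_tnt("xread 5 2 A 01?0[01] B 001?1")
        c = compare_pair(m, "A", "B")
        assert (c.green, c.yellow, c.blue, c.overlap) == (1, 1, 1, 3)
        assert c.character_lists["green"] == [1]
        assert c.character_lists["blue"] == [2]
        assert c.character_lists["yellow"] == [5]

    def test_self_comparison(self):
        m = random_matrix(n_taxa=4, n_chars=30, seed=5)
        scored = sum(1 for cell in m.row("t1") if cell.is_scored)
        c = compare_pair(m, "t1", "t1")
        assert (c.green, c.yellow, c.blue) == (scored, 0, 0)

    def test_unknown_otu(self):
        m = random_matrix(seed=1)
        with pytest.raises(UnknownOTUError):
            compare_pair(m, "t0", "nope")

    def test_intersecting_polymorphic_sets_are_yellow(self):
        m = read_tnt("xread 1 2 A [01] B [12]")
        c = compare_pair(m, "A", "B")
        assert (c.green, c.yellow, c.blue) == (0, 1, 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_symmetry_and_conservation_fuzzed(self, seed):
        m = random_matrix(n_taxa=6, n_chars=25, seed=seed)
        for a in m.otu_labels:
            for b in m.otu_labels:
                ab = compare_pair(m, a, b)
                ba = compare_pair(m, b, a)
                assert (ab.green, ab.yellow, ab.blue) == (ba.green, ba.yellow, ba.blue)
                assert ab.green + ab.yellow + ab.blue == ab.overlap

    def test_single_otu_characters_do_not_count(self):
        # character 3 scored only in A: removing it changes nothing
        m5 = read_tnt("xread 3 2 A 010 B 1?0")
        m4 = read_tnt("xread 2 2 A 00 B 10")  # same minus character 2
        c5 = compare_pair(m5, "A", "B")
        c4 = compare_pair(m4, "A", "B")
        assert (c5.green, c5.yellow, c5.blue) == (c4.green, c4.yellow, c4.blue)


class TestDifferencePercent:
    def test_zero_difference(self):
        c = PairwiseComparison("a", "b", green=40, yellow=0, blue=0)
        assert difference_percent(c, "strict")[0] == 0.0

    def test_printed_strict_example(self):
        # three outright differences in an overlap of 55 -> 5.5%
        c = PairwiseComparison("a", "b", green=52, yellow=0, blue=3)
        assert difference_percent(c, "strict")[0] == 5.5

    def test_half_credit_arithmetic(self):
        c = PairwiseComparison("a", "b", green=7, yellow=2, blue=1)
        assert difference_percent(c, "half_credit")[0] == 20.0

    def test_zero_overlap_is_undefined(self):
        c = PairwiseComparison("a", "b", green=0, yellow=0, blue=0)
        with pytest.raises(UndefinedPercentageError):
            difference_percent(c)

    @given(
        green=st.integers(0, 100),
        yellow=st.integers(0, 100),
        blue=st.integers(0, 100),
    )
    @settings(derandomize=True, max_examples=100)
    def test_strict_never_exceeds_half_credit(self, green, yellow, blue):
        if green + yellow + blue == 0:
            return
        c = PairwiseComparison("a", "b", green=green, yellow=yellow, blue=blue)
        s = difference_percent(c, "strict")[1]
        h = difference_percent(c, "half_credit")[1]
        assert s <= h
        assert (s == h) == (yellow == 0)


class TestDelimit:
    @pytest.mark.parametrize(
        "blue,expected",
        [
            (0, "indistinct"),
            (1, "indistinct"),
            (5, "indistinct"),
            (SPECIES_THRESHOLD, "species_level"),  # boundary inclusive
            (12, "species_level"),
            (GENUS_THRESHOLD, "genus_level"),
            (15, "genus_level"),
        ],
    )
    def test_thresholds(self, blue, expected):
        c = PairwiseComparison("a", "b", green=50, yellow=0, blue=blue)
        assert delimit(c).classification == expected

    def test_half_credit_basis(self):
        c = PairwiseComparison("a", "b", green=10, yellow=4, blue=4)
        assert delimit(c, basis="blue").classification == "indistinct"
        assert delimit(c, basis="blue_plus_half").classification == "species_level"

    def test_degenerate_overlap_flagged(self):
        c = PairwiseComparison("a", "b", green=0, yellow=0, blue=0)
        r = delimit(c)
        assert r.classification == "indistinct" and r.degenerate


class TestPairwiseTable:
    def test_pair_combinatorics(self):
        m = random_matrix(n_taxa=4, n_chars=20, seed=7)
        rows = pairwise_table(m, m.otu_labels)
        assert len(rows) == 6

    def test_needs_two_otus(self):
        m = random_matrix(seed=7)
        with pytest.raises(ValueError):
            pairwise_table(m, ["t0"])


class TestPlantedPairs:
    @pytest.mark.parametrize("seed", range(100))
    def test_exact_recovery_over_seeds(self, seed):
        cfg = SimulationConfig(n_taxa=8, n_characters=60, seed=seed, missing_rate=0.3)
        m, _ = generate_matrix(cfg)
        rng_counts = (seed % 5, (seed // 5) % 4, seed % 7)
        g, y, b = rng_counts
        planted = plant_pair(m, "otu002", g, y, b, seed=seed + 1)
        c = compare_pair(planted, "otu002", "planted")
        assert (c.green, c.yellow, c.blue) == (g, y, b)

    def test_pure_blue_pair_delimits_genus_level(self):
        cfg = SimulationConfig(n_taxa=6, n_characters=40, seed=0, missing_rate=0.2)
        m, _ = generate_matrix(cfg)
        planted = plant_pair(m, "otu001", 0, 0, 15, seed=2)
        c = compare_pair(planted, "otu001", "planted")
        assert delimit(c).classification == "genus_level"

    def test_insufficient_scored_cells(self):
        m = read_tnt("xread 3 2 A 01? B 111")
        with pytest.raises(ValueError):
            plant_pair(m, "A", 2, 1, 1, seed=0)
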