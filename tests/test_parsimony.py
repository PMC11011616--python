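"""Parsimony scoring, homoplasy indices, search, consensus and Bremer
support, cross-checked against independent oracles."""

import dendropy
import numpy as np
import pytest

from morphotax.io import read_tnt
from morphotax.model import AnalysisSettings, CellScore, CharacterMatrix, configure
from morphotax.parsimony import (
    bremer_support,
    char_min_max,
    exhaustive_search,
    heuristic_search,
    implied_weight_score,
    tree_length,
)
from morphotax.simulate import SimulationConfig, generate_matrix
from morphotax.trees import (
    Topology,
    enumerate_topologies,
    n_unrooted_topologies,
    random_topology,
    read_newick,
    read_tread,
    strict_consensus,
)

from conftest import brute_force_length, random_matrix


class TestTreeLength:
    def test_invariant_character_costs_nothing(self):
        m = read_tnt("xread 1 4 A 1 B 1 C 1 D 1")
        t = Topology.from_nested((("A", "B"), ("C", "D")))
        assert tree_length(m, t).length == 0

    def test_ordered_vs_unordered_two_taxa(self):
        m = read_tnt("xread 1 2 A 0 B 2")
        t = Topology.from_nested(("A", "B"))
        assert tree_length(m, t).length == 1
        m.ordered_flags = [True]
        assert tree_length(m, t).length == 2

    @pytest.mark.parametrize("seed", range(12))
    def test_dp_equals_brute_force_enumeration(self, seed):
        m = random_matrix(n_taxa=5, n_chars=8, seed=seed)
        for i, t in enumerate(enumerate_topologies(m.otu_labels)):
            if i >= 4:
                break
            assert tree_length(m, t).length == brute_force_length(m, t)

    def test_length_root_and_leaf_order_invariant(self):
        m = random_matrix(n_taxa=6, n_chars=15, seed=3)
        t = random_topology(m.otu_labels, np.random.default_rng(0))
        base = tree_length(m, t).length
        # permute matrix rows: same leaves, different storage order
        perm = [3, 1, 5, 0, 4, 2]
        m2 = CharacterMatrix(
            [m.otu_labels[i] for i in perm],
            m.n_characters,
            [m.cells[i] for i in perm],
            list(m.ordered_flags),
        )
        assert tree_length(m2, t).length == base
        # re-read the same topology from newick (different vertex numbering)
        t2 = read_newick(t.to_newick())[0]
        assert tree_length(m, t2).length == base

    def test_polytomy_rejected_unless_resolving(self):
        m = random_matrix(n_taxa=5, n_chars=6, seed=1)
        star = Topology.star(m.otu_labels)
        with pytest.raises(ValueError):
            tree_length(m, star)
        best = min(
            tree_length(m, t).length for t in enumerate_topologies(m.otu_labels)
        )
        assert tree_length(m, star, resolve_polytomies=True).length == best

    def test_leaf_mismatch_rejected(self):
        m = random_matrix(n_taxa=5, seed=1)
        t = Topology.from_nested((("A", "B"), ("C", "D")))
        with pytest.raises(ValueError):
            tree_length(m, t)

    @pytest.mark.parametrize("seed", range(6))
    def test_length_bounds_and_index_ranges(self, seed):
        m = random_matrix(n_taxa=6, n_chars=20, seed=seed)
        t = random_topology(m.otu_labels, np.random.default_rng(seed))
        sc = tree_length(m, t)
        assert sc.length >= sc.sum_min
        if sc.length > 0:
            assert 0 < sc.ci <= 1
        if sc.sum_max > sc.sum_min:
            assert 0 <= sc.ri <= 1

    def test_binary_recode_never_costs_more(self):
        # collapsing an ordered multistate character to binary (0 vs rest)
        # can only lose steps
        for seed in range(5):
            m = random_matrix(n_taxa=6, n_chars=1, seed=seed, n_states=4,
                              ordered_first=1, missing_rate=0, polymorphism_rate=0)
            recoded_cells = [
                [CellScore.scored(0 if 0 in row[0].states else 1)]
                for row in m.cells
            ]
            m2 = CharacterMatrix(m.otu_labels, 1, recoded_cells, [True])
            t = random_topology(m.otu_labels, np.random.default_rng(seed))
            assert tree_length(m2, t).length <= tree_length(m, t).length


class TestCharMinMax:
    def test_binary_three_two(self):
        m = read_tnt("xread 1 5 A 0 B 0 C 0 D 1 E 1")
        assert char_min_max(m) == [(1, 2)]

    def test_ordered_brute_force_example(self):
        m = read_tnt("xread 1 4 A 0 B 1 C 2 D 2")
        m.ordered_flags = [True]
        assert char_min_max(m) == [(2, 3)]

    def test_character_scored_once_is_inert(self):
        m = read_tnt("xread 1 4 A 1 B ? C ? D -")
        assert char_min_max(m) == [(0, 0)]

    @pytest.mark.parametrize("seed", range(10))
    def test_min_max_bracket_realized_steps(self, seed):
        """m_i = min over all trees, g_i = star-tree score: every realized
        per-character step count must fall in [m_i, g_i], and the minimum
        over all topologies must equal m_i exactly."""
        m = random_matrix(n_taxa=5, n_chars=6, seed=seed)
        mg = char_min_max(m)
        per_tree = []
        for t in enumerate_topologies(m.otu_labels):
            fits = tree_length(m, t).per_character
            per_tree.append([f.steps for f in fits])
            for (mi, gi), f in zip(mg, fits):
                assert mi <= f.steps <= gi if gi > 0 else f.steps == 0
        realized_min = [min(col) for col in zip(*per_tree)]
        assert realized_min == [mi for mi, _ in mg]


class TestImpliedWeighting:
    def test_zero_iff_homoplasy_free(self):
        cfg = SimulationConfig(n_taxa=6, n_characters=12, seed=4, missing_rate=0,
                               noise_free=True)
        m, true_tree = generate_matrix(cfg)
        assert implied_weight_score(m, true_tree, k=9) == 0.0
        # a worse tree must have a positive fit
        worse = next(
            t for t in enumerate_topologies(m.otu_labels) if t != true_tree
        )
        assert implied_weight_score(m, worse, k=9) > 0

    def test_single_extra_step_k9(self):
        # one character with h=1 on this tree: 1/(1+9)
        m = read_tnt("xread 1 4 A 0 B 1 C 0 D 1")
        t = Topology.from_nested((("A", "B"), ("C", "D")))
        assert implied_weight_score(m, t, k=9) == pytest.approx(0.1)

    def test_concavity_prefers_concentrated_homoplasy(self):
        # h = (2, 0) scores 2/11 < h = (1, 1) scoring 2/10 at k = 9
        k = 9.0
        concentrated = 2 / (2 + k)
        spread = 2 * (1 / (1 + k))
        assert concentrated < spread

    def test_extended_downweights_missing_rich_characters(self):
        # two characters with identical conflict, one riddled with missing
        # entries in extra OTUs: extended mode must punish it harder
        text = "xread 2 6 A 00 B 11 C 00 D 11 E ?0 F ?1"
        m = read_tnt(text)
        # make character 1 missing-rich instead
        m_missing_first = read_tnt("xread 2 6 A 00 B 11 C 00 D 11 E 0? F 1?")
        t = Topology.from_nested(((("A", "C"), "E"), (("B", "D"), "F")))
        std = implied_weight_score(m, t, k=9, extended=False)
        ext = implied_weight_score(m, t, k=9, extended=True)
        ext_swapped = implied_weight_score(m_missing_first, t, k=9, extended=True)
        assert std <= ext  # smaller k_i inflates the fit of homoplastic chars
        assert ext == pytest.approx(ext_swapped)  # symmetric treatment

    def test_invalid_k(self):
        m = random_matrix(seed=0)
        t = random_topology(m.otu_labels, np.random.default_rng(0))
        with pytest.raises(ValueError):
            implied_weight_score(m, t, k=0)


class TestSearch:
    def test_enumeration_counts(self):
        assert sum(1 for _ in enumerate_topologies(list("ABCD"))) == 3
        assert sum(1 for _ in enumerate_topologies(list("ABCDEF"))) == 105
        assert n_unrooted_topologies(6) == 105

    def test_exhaustive_cap(self):
        m = random_matrix(n_taxa=10, seed=0)
        with pytest.raises(ValueError):
            exhaustive_search(m)

    def test_noise_free_matrix_has_unique_generating_mpt(self):
        cfg = SimulationConfig(n_taxa=8, n_characters=20, seed=11, missing_rate=0,
                               noise_free=True)
        m, true_tree = generate_matrix(cfg)
        res = exhaustive_search(m)
        assert len(res.best_trees) == 1
        assert res.best_trees[0] == true_tree
        assert tree_length(m, res.best_trees[0]).ri == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_heuristic_matches_exhaustive_oracle(self, seed):
        n_taxa = 6 + seed % 3  # 6..8 taxa
        m = random_matrix(n_taxa=n_taxa, n_chars=12, seed=seed)
        ex = exhaustive_search(m)
        he = heuristic_search(m, n_starts=3, seed=seed)
        assert he.best_score == pytest.approx(ex.best_score)

    def test_duplicated_otu_adds_no_length(self):
        m = random_matrix(n_taxa=6, n_chars=15, seed=2, missing_rate=0)
        dup = CharacterMatrix(
            m.otu_labels + ["t0_copy"],
            m.n_characters,
            [list(r) for r in m.cells] + [list(m.cells[0])],
            list(m.ordered_flags),
        )
        assert (
            heuristic_search(dup, n_starts=3, seed=5).best_score
            == exhaustive_search(m).best_score
        )

    def test_seed_reproducibility(self):
        m = random_matrix(n_taxa=7, n_chars=12, seed=8)
        a = heuristic_search(m, n_starts=2, seed=123)
        b = heuristic_search(m, n_starts=2, seed=123)
        assert a.best_score == b.best_score
        assert [t.bipartitions() for t in a.best_trees] == [
            t.bipartitions() for t in b.best_trees
        ]

    def test_seed_mandatory(self):
        m = random_matrix(seed=0)
        with pytest.raises(ValueError):
            heuristic_search(m, seed=None)


class TestConsensus:
    def test_identity(self):
        t = Topology.from_nested(((("A", "B"), "C"), ("D", "E")))
        assert strict_consensus([t, t]) == t

    def test_all_topologies_give_star(self):
        trees = list(enumerate_topologies(list("ABCDE")))
        cons = strict_consensus(trees)
        assert cons.bipartitions() == frozenset()

    def test_single_shared_clade(self):
        a = Topology.from_nested(((("A", "B"), "C"), ("D", ("E", "F"))))
        b = Topology.from_nested(((("A", "B"), "D"), ("C", ("E", "F"))))
        cons = strict_consensus([a, b])
        assert cons.has_clade({"A", "B"})
        assert cons.has_clade({"E", "F"})
        assert len(cons.bipartitions()) == 2

    def test_mismatched_leafsets_rejected(self):
        a = Topology.from_nested((("A", "B"), ("C", "D")))
        b = Topology.from_nested((("A", "B"), ("C", "E")))
        with pytest.raises(ValueError):
            strict_consensus([a, b])

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_dendropy(self, seed):
        """Independent cross-check of the bipartition intersection against
        dendropy's strict consensus."""
        rng = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(7)]
        trees = [random_topology(labels, rng) for _ in range(4)]
        ours = strict_consensus(trees)
        tns = dendropy.TaxonNamespace()
        dtrees = dendropy.TreeList(
            [
                dendropy.Tree.get(
                    data=t.to_newick(), schema="newick", taxon_namespace=tns
                )
                for t in trees
            ]
        )
        dcons = dtrees.consensus(min_freq=1.0)
        theirs = read_newick(dcons.as_string(schema="newick").replace("[&R] ", ""))[0]
        assert ours.bipartitions() == theirs.bipartitions()


class TestBremer:
    def test_planted_clade_decay_equals_support(self):
        # 7 taxa; one clade {t0,t1,t2} marked by 3 clean characters and
        # nothing else informative: decay must be exactly 3
        labels = [f"t{i}" for i in range(7)]
        cells = [
            [CellScore.scored(1 if i < 3 else 0) for _ in range(3)]
            for i in range(7)
        ]
        m = CharacterMatrix(labels, 3, cells)
        decay = bremer_support(m, max_extra_steps=4)
        clade = frozenset({"t3", "t4", "t5", "t6"})  # encoded away from t0
        assert decay[clade] == 3

    def test_unsupported_matrix_has_no_clades(self):
        m = read_tnt("xread 2 4 A 00 B 00 C 00 D 00")
        assert bremer_support(m, max_extra_steps=2) == {}

    def test_max_extra_validation(self):
        m = random_matrix(seed=0)
        with pytest.raises(ValueError):
            bremer_support(m, max_extra_steps=0)


class TestTreeIO:
    def test_tread_parenthetical(self):
        trees = read_tread("tread 'trees'\n(A (B (C D)));")
        assert trees[0] == Topology.from_nested(("A", ("B", ("C", "D"))))

    def test_newick_roundtrip(self):
        t = Topology.from_nested(((("A", "B"), "C"), ("D", "E")))
        assert read_newick(t.to_newick())[0] == t


class TestConfiguredScoring:
    def test_exclusions_change_active_leafset(self):
        m = random_matrix(n_taxa=7, n_chars=10, seed=4)
        conf = configure(m, AnalysisSettings(excluded_otus=["t5", "t6"]))
        res = exhaustive_search(conf)
        assert set(res.best_trees[0].leaf_label.values()) == {
            "t0", "t1", "t2", "t3", "t4"
        }
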