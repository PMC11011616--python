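"""Matrix parsing, writing, patching and configuration."""

import pytest

from morphotax.io import (
    read_nexus,
    read_patches,
    read_settings,
    read_tnt,
    write_nexus,
    write_patches,
    write_settings,
    write_tnt,
)
from morphotax.model import (
    AnalysisSettings,
    CellScore,
    CharacterMatrix,
    DimensionMismatchError,
    DuplicateTaxonError,
    IllegalSymbolError,
    PatchMismatchError,
    ScorePatch,
    UnclosedBracketError,
    UnknownOTUError,
    apply_patches,
    configure,
)
from morphotax.simulate import SimulationConfig, generate_matrix

from conftest import random_matrix


class TestReadTnt:
    def test_toy_example(self, toy_matrix):
        m = toy_matrix
        assert m.n_otus == 2 and m.n_characters == 4
        assert m.cell("B", 2) == CellScore.scored(0, 1)
        assert m.cell("B", 3).status == "inapplicable"
        assert m.cell("A", 3).status == "missing"
        assert m.cell("A", 1) == CellScore.scored(0)

    def test_letter_state_symbols(self):
        m = read_tnt("xread 2 1 A 9V")
        assert m.cell("A", 2) == CellScore.scored(31)

    def test_quoted_title_and_semicolon(self):
        m = read_tnt("xread 'a title'\n2 2\nA 01\nB 10\n;")
        assert m.otu_labels == ["A", "B"]

    @pytest.mark.parametrize(
        "text,exc",
        [
            ("xread 4 2 A 010 B 0101", DimensionMismatchError),  # short row
            ("xread 4 2 A 0100 B 0[011", UnclosedBracketError),
            ("xread 4 2 A 0100 A 0101", DuplicateTaxonError),
            ("xread 4 2 A 0100 B 01z1", IllegalSymbolError),
            ("xread 4 3 A 0100 B 0101", DimensionMismatchError),  # taxon count
        ],
    )
    def test_parse_errors_name_the_line(self, text, exc):
        with pytest.raises(exc) as err:
            read_tnt(text)
        assert "line" in str(err.value)


class TestNexus:
    def test_polymorphic_braces(self):
        nex = (
            "#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=2 NCHAR=3;\n"
            'FORMAT DATATYPE=STANDARD SYMBOLS="012" MISSING=? GAP=-;\n'
            "MATRIX\nA 0{01}2\nB 1?-\n;\nEND;\n"
        )
        m = read_nexus(nex)
        assert m.cell("A", 2) == CellScore.scored(0, 1)
        assert m.cell("B", 2).status == "missing"
        assert m.cell("B", 3).status == "inapplicable"

    def test_missing_nchar_is_an_error(self):
        nex = "#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=2;\nMATRIX\nA 01\nB 10\n;\nEND;\n"
        with pytest.raises(DimensionMismatchError):
            read_nexus(nex)

    @pytest.mark.parametrize("seed", range(5))
    def test_roundtrip_identity_both_formats(self, seed):
        m = random_matrix(n_taxa=6, n_chars=12, seed=seed)
        assert read_tnt(write_tnt(m)).cells == m.cells
        assert read_nexus(write_nexus(m)).cells == m.cells
        # labels survive too (modulo whitespace normalization)
        assert read_tnt(write_tnt(m)).otu_labels == m.otu_labels

    def test_cell_count_conserved(self):
        m = random_matrix(n_taxa=8, n_chars=20, seed=3)
        c = m.status_counts()
        assert sum(c.values()) == m.n_otus * m.n_characters


class TestPatches:
    def base(self):
        return read_tnt("xread 3 2 Diamantinasaurus_matildae 001 Other 110")

    def test_apply_recorded_change(self):
        m = self.base()
        p = ScorePatch("Diamantinasaurus matildae", 1, CellScore.scored(0), CellScore.scored(1))
        out, log = apply_patches(m, [p])
        assert out.cell("Diamantinasaurus_matildae", 1) == CellScore.scored(1)
        assert m.cell("Diamantinasaurus_matildae", 1) == CellScore.scored(0)  # original intact
        assert len(log) == 1

    def test_empty_patch_list_is_identity(self):
        m = self.base()
        out, log = apply_patches(m, [])
        assert out == m and log == []

    def test_strict_mismatch_detected(self):
        m = self.base()
        p = ScorePatch("Other", 1, CellScore.scored(0), CellScore.missing())
        with pytest.raises(PatchMismatchError):
            apply_patches(m, [p], strict=True)
        out, _ = apply_patches(m, [p], strict=False)
        assert out.cell("Other", 1).status == "missing"

    def test_unknown_otu(self):
        p = ScorePatch("Nobody", 1, CellScore.scored(0), CellScore.scored(1))
        with pytest.raises(UnknownOTUError):
            apply_patches(self.base(), [p])

    def test_order_independent_on_distinct_cells(self):
        m = self.base()
        p1 = ScorePatch("Other", 1, CellScore.scored(1), CellScore.scored(0))
        p2 = ScorePatch("Other", 3, CellScore.scored(0), CellScore.scored(1))
        a, _ = apply_patches(m, [p1, p2])
        b, _ = apply_patches(m, [p2, p1])
        assert a == b

    def test_patch_tsv_roundtrip(self):
        patches = [
            ScorePatch("A", 3, CellScore.scored(1), CellScore.scored(0, 1)),
            ScorePatch("B", 1, CellScore.missing(), CellScore.scored(0)),
        ]
        assert read_patches(write_patches(patches)) == patches


class TestConfigure:
    def test_ordering_and_exclusion(self):
        m = random_matrix(n_taxa=6, n_chars=10, seed=1, ordered_first=0)
        s = AnalysisSettings(ordered_characters=[2, 5], excluded_otus=["t0", "t3"])
        out = configure(m, s)
        assert out.ordered_flags == [False, True, False, False, True] + [False] * 5
        assert sum(out.active_otus) == 4
        assert out.active_otu_labels() == ["t1", "t2", "t4", "t5"]

    def test_empty_exclusions_keep_all_active(self):
        m = random_matrix(seed=2)
        out = configure(m, AnalysisSettings())
        assert all(out.active_otus)

    def test_out_of_range_ordering_index(self):
        m = random_matrix(n_chars=6, seed=2)
        with pytest.raises(IndexError):
            configure(m, AnalysisSettings(ordered_characters=[7]))

    def test_unknown_excluded_taxon(self):
        m = random_matrix(seed=2)
        with pytest.raises(UnknownOTUError):
            configure(m, AnalysisSettings(excluded_otus=["nope"]))

    def test_settings_file_roundtrip(self):
        s = AnalysisSettings(
            ordered_characters=[11, 14],
            excluded_otus=["Astrophocaudia slaughteri"],
            weighting="extended_implied",
            k=9.0,
            missing_downweight=True,
            seed=42,
        )
        assert read_settings(write_settings(s)) == s


class TestSimulatedRoundtrip:
    def test_simulated_matrix_survives_both_formats(self):
        cfg = SimulationConfig(n_taxa=12, n_characters=30, seed=9, missing_rate=0.4,
                               polymorphism_rate=0.05)
        m, _ = generate_matrix(cfg)
        assert read_tnt(write_tnt(m)).cells == m.cells
        assert read_nexus(write_nexus(m)).cells == m.cells
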