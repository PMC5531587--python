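"""Consensus lines, pattern construction, similarity sets and extension."""

import math

import numpy as np
import pytest

from breps.msa import Alignment, ConsensusColumn, PrealignedMsaAligner, StubMsaAligner, run_msa
from breps.patterns import (
    Pattern,
    PatternConfig,
    PositionSpec,
    build_pattern,
    derive_similarity_sets,
    extend_pattern,
    parse_prosite,
    pattern_complexity,
)
from breps.verification import match_pattern
from conftest import make_record


def col(index, symbol, residues, gap_fraction=0.0):
    return ConsensusColumn(
        index=index, symbol=symbol, residues=frozenset(residues),
        gap_fraction=gap_fraction,
    )


def literal_cols(text):
    return [col(i, "*", c) for i, c in enumerate(text)]


class TestConsensus:
    def test_identical_sequences_fully_conserved(self):
        recs = [make_record(a, sequence="MKWVTF") for a in "AB"]
        aln = run_msa(recs, StubMsaAligner())
        assert aln.consensus_line() == "******"

    def test_strong_weak_and_none_symbols(self):
        aln = Alignment(accessions=["a", "b"], rows=["FSAK", "WTGC"])
        # F/W strong (FYW), S/T strong (STA), A/G weak (SAG), K/C none
        assert aln.consensus_line() == "::. "

    def test_gapped_column_is_unconserved(self):
        aln = Alignment(accessions=["a", "b"], rows=["A-C", "AAC"])
        cols = aln.columns()
        assert aln.consensus_line() == "* *"
        assert cols[1].gap_fraction == 0.5
        assert cols[1].residues == frozenset("A")

    def test_prealigned_passthrough(self):
        aln = Alignment(accessions=["a", "b"], rows=["AC", "AC"])
        assert run_msa([make_record("a"), make_record("b")],
                       PrealignedMsaAligner(aln)) is aln

    def test_stub_rejects_unequal_lengths(self):
        recs = [make_record("A", sequence="AAAA"), make_record("B", sequence="AAA")]
        with pytest.raises(ValueError, match="equal-length"):
            run_msa(recs, StubMsaAligner())

    def test_mutated_family_mostly_conserved(self):
        from breps.synthetic import FamilySpec, generate_families

        spec = FamilySpec("FAM0", ("1.1.1.1",), ancestor_length=200,
                          n_members=5, substitution_rate=0.03, seed=4,
                          conserved_blocks=((20, 12), (100, 12)))
        ds = generate_families([spec], n_decoys=0)
        aln = run_msa(ds.records, StubMsaAligner())
        frac = aln.consensus_line().count("*") / aln.n_columns
        # P(column untouched) = (1-0.03)^5 ~ 0.86; allow generous slack below
        assert frac > 0.7


class TestBuildPattern:
    CFG = PatternConfig(min_informative=1)

    def test_wildcard_run_merged(self):
        cols = [col(0, "*", "A"), col(1, "*", "D"), col(2, " ", "GY"),
                col(3, " ", "SW"), col(4, "*", "C")]
        p = build_pattern(cols, self.CFG)
        assert p.to_prosite() == "A-D-x(2)-C"

    def test_all_wildcard_returns_none(self):
        cols = [col(i, " ", "AC") for i in range(10)]
        assert build_pattern(cols, self.CFG) is None

    def test_strong_column_becomes_residue_set(self):
        cols = literal_cols("AAA") + [col(3, ":", "FW")] + literal_cols("CCC")
        p = build_pattern(cols, self.CFG)
        assert p.to_prosite() == "A-A-A-[FW]-C-C-C"

    def test_weak_column_default_wildcard_optionally_set(self):
        cols = literal_cols("AAA") + [col(3, ".", "AG")] + literal_cols("CCC")
        assert build_pattern(cols, self.CFG).to_prosite() == "A-A-A-x-C-C-C"
        cfg = PatternConfig(min_informative=1, weak_as_set=True)
        assert build_pattern(cols, cfg).to_prosite() == "A-A-A-[AG]-C-C-C"

    def test_leading_trailing_wildcards_trimmed(self):
        cols = [col(0, " ", "AC")] + literal_cols("AAAAAA") + [col(7, " ", "AC")]
        p = build_pattern(cols, self.CFG)
        assert p.to_prosite() == "A-A-A-A-A-A"

    def test_gap_columns_widen_wildcard_span(self):
        cols = (literal_cols("AA")
                + [col(2, " ", "XY"), col(3, " ", "A", gap_fraction=0.5)]
                + [col(4, "*", "C"), col(5, "*", "C")])
        p = build_pattern(cols, self.CFG)
        assert p.to_prosite() == "A-A-x(1,2)-C-C"

    def test_min_informative_gate(self):
        cols = literal_cols("AAAAA")
        assert build_pattern(cols, PatternConfig(min_informative=6)) is None
        assert build_pattern(cols, PatternConfig(min_informative=5)) is not None

    def test_nonstandard_residue_columns_become_wildcards(self):
        cols = literal_cols("AAA") + [col(3, "*", "X")] + literal_cols("CCC")
        p = build_pattern(cols, self.CFG)
        assert p.to_prosite() == "A-A-A-x-C-C-C"


class TestSimilaritySets:
    TABLE = {
        ("E", "N"): "D", ("E", "K"): "Q", ("M", "V"): "IL", ("H", "R"): "KQ",
        ("F", "W"): "Y", ("K", "N"): "E", ("L", "V"): "I", ("H", "K"): "NQR",
        ("K", "Q"): "R", ("Q", "R"): "K", ("I", "M"): "L", ("A", "T"): "S",
        ("F", "I"): "LM", ("N", "Q"): "DEHK", ("F", "M"): "L", ("D", "Q"): "E",
    }

    def test_selected_pairs(self):
        sets = derive_similarity_sets()
        assert sets.get("E", "N") == frozenset("D")
        assert sets.get("F", "W") == frozenset("Y")

    def test_threshold_above_max_yields_empty_map(self):
        assert len(derive_similarity_sets(threshold=100.0)) == 0

    def test_asymmetric_matrix_rejected(self):
        class Lopsided:
            def __getitem__(self, key):
                a, b = key
                return 1.0 if a < b else 2.0

        with pytest.raises(ValueError, match="asymmetric"):
            derive_similarity_sets(Lopsided())


class TestExtension:
    def _pattern(self, *positions):
        return Pattern(id="P", positions=tuple(positions))

    def test_pair_positions_widened(self):
        sets = derive_similarity_sets()
        p = self._pattern(
            PositionSpec("residue_set", frozenset("FW")),
            PositionSpec("literal", frozenset("A")),
            PositionSpec("residue_set", frozenset("FI")),
        )
        e = extend_pattern(p, sets)
        assert e.flavor == "extended"
        assert e.positions[0].residues == frozenset("FWY")
        assert e.positions[1].residues == frozenset("A")  # literal untouched
        assert e.positions[2].residues == frozenset("FILM")

    def test_multi_residue_position_combines_all_pair_sets(self):
        sets = derive_similarity_sets()
        p = self._pattern(PositionSpec("residue_set", frozenset("FWI")))
        e = extend_pattern(p, sets)
        # FW -> Y, FI -> LM, WI -> (empty)
        assert e.positions[0].residues == frozenset("FWIYLM")

    def test_extension_requires_standard_flavor(self):
        sets = derive_similarity_sets()
        p = self._pattern(PositionSpec("residue_set", frozenset("FW")))
        extended = extend_pattern(p, sets)
        with pytest.raises(ValueError, match="standard"):
            extend_pattern(extended, sets)

    def test_positionwise_superset(self):
        sets = derive_similarity_sets()
        p = self._pattern(
            PositionSpec("residue_set", frozenset("NQ")),
            PositionSpec("wildcard", min_repeat=2, max_repeat=3),
            PositionSpec("residue_set", frozenset("HK")),
        )
        e = extend_pattern(p, sets)
        for std, ext in zip(p.positions, e.positions):
            assert std.residues <= ext.residues
            assert (std.min_repeat, std.max_repeat) == (ext.min_repeat, ext.max_repeat)


class TestComplexity:
    def test_all_literal_pattern(self):
        p = parse_prosite("-".join("A" * 10))
        assert pattern_complexity(p) == pytest.approx(10.0)

    def test_widening_strictly_decreases_complexity(self):
        narrow = Pattern("P", (PositionSpec("residue_set", frozenset("FW")),))
        wide = Pattern("P", (PositionSpec("residue_set", frozenset("FWYL")),))
        assert pattern_complexity(wide) < pattern_complexity(narrow)

    def test_empty_pattern_zero(self):
        assert pattern_complexity(Pattern("P", ())) == 0.0

    def test_wildcards_contribute_nothing(self):
        p = parse_prosite("A-x(5)-C")
        assert pattern_complexity(p) == pytest.approx(2.0)


class TestSerialization:
    @pytest.mark.parametrize(
        "text", ["A-x(2)-[FWY]-C", "M-K-W", "A-x(2,5)-C", "[DE]-x-[KR]"]
    )
    def test_prosite_round_trip(self, text):
        assert parse_prosite(text).to_prosite() == text

    def test_regex_semantics(self):
        p = parse_prosite("A-x(2)-[FWY]-C")
        assert p.to_regex() == "A[ACDEFGHIKLMNPQRSTVWY]{2}[FWY]C"
        assert match_pattern(p, "AGGYC") == [(0, 5)]
        assert match_pattern(p, "AXXYC") == []  # X never matches
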