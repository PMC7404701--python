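"""Occurrence/release parameters A, A_E, W and the A binning."""

from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from colpep import (
    ActivityRecord,
    PeptideActivityDB,
    ProteinRecord,
    classify_A,
    count_occurrences,
    digest,
    profile_occurrence,
    profile_release,
    resolve_enzymes,
)
from colpep.profiling import format_frequency

seq_strategy = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=60)


class TestCountOccurrences:
    @pytest.mark.parametrize(
        "sequence, peptide, expected",
        [
            ("AAA", "AA", 2),  # overlapping matches count
            ("GKGFRL", "GF", 1),
            ("GKGFRL", "WW", 0),
            ("PGLPGL", "PGL", 2),
            ("GGGG", "G", 4),
        ],
    )
    def test_overlapping_counts(self, sequence, peptide, expected):
        assert count_occurrences(sequence, peptide) == expected

    def test_empty_peptide_rejected(self):
        with pytest.raises(ValueError):
            count_occurrences("AAA", "")


class TestClassifyA:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (0.834, "major"),
            (0.5, "major"),
            (0.499, "moderate"),
            (0.238, "moderate"),
            (0.1, "moderate"),
            (0.099, "minor"),
            (0.073, "minor"),
            (0.001, "minor"),
            (0.0, "none"),
            (Fraction(1, 2), "major"),
        ],
    )
    def test_bin_boundaries(self, value, expected):
        assert classify_A(value) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_A(-0.1)


class TestOccurrence:
    def test_toy_protein_against_fixture(self, toy, db):
        profiles = {p.activity_code: p for p in profile_occurrence(toy, db)}
        assert profiles["ah"].a_count == 2  # GF and RL
        assert profiles["ah"].A == Fraction(1, 3)
        assert profiles["ah"].bin == "moderate"
        assert profiles["dpp"].a_count == 2
        assert profiles["dpp"].A == Fraction(1, 3)

    def test_planted_motif_copies(self, db):
        protein = ProteinRecord(id="p", sequence="PGLPGL")
        profiles = {p.activity_code: p for p in profile_occurrence(protein, db)}
        assert profiles["ah"].a_count == 2
        assert profiles["ah"].A == Fraction(1, 3)

    def test_empty_db_gives_empty_profile(self, toy):
        assert profile_occurrence(toy, PeptideActivityDB()) == []

    def test_zero_count_activities_omitted_unless_requested(self, db):
        protein = ProteinRecord(id="p", sequence="PPPP")
        assert profile_occurrence(protein, db) == []
        full = profile_occurrence(protein, db, include_zero=True)
        assert {p.activity_code for p in full} == set(db.activity_codes())
        assert all(p.bin == "none" for p in full)

    def test_db_monotonicity(self, toy, db):
        base = {p.activity_code: p.a_count for p in profile_occurrence(toy, db)}
        bigger = PeptideActivityDB(list(db.records) + [ActivityRecord("GK", "ah")])
        grown = {p.activity_code: p.a_count for p in profile_occurrence(toy, bigger)}
        assert all(grown[code] >= count for code, count in base.items())


class TestRelease:
    def test_pepsin_releases_rl(self, toy, db, ruleset):
        occ = profile_occurrence(toy, db)
        result = digest(toy, resolve_enzymes(["pepsin"], ruleset))
        rel = {p.activity_code: p for p in profile_release(toy, result, db, occ)}
        assert rel["ah"].d_count == 1  # fragment RL
        assert rel["ah"].A_E == Fraction(1, 6)
        assert rel["ah"].W == Fraction(1, 2)
        assert rel["dpp"].W == Fraction(1, 2)

    def test_trypsin_releases_nothing_from_toy(self, toy, db, ruleset):
        occ = profile_occurrence(toy, db)
        result = digest(toy, resolve_enzymes(["trypsin"], ruleset))
        rel = {p.activity_code: p for p in profile_release(toy, result, db, occ)}
        assert rel["ah"].d_count == 0
        assert rel["ah"].A_E == 0
        assert rel["ah"].W == 0  # A > 0, nothing released

    def test_w_undefined_when_activity_absent(self, ruleset):
        protein = ProteinRecord(id="p", sequence="PPPP")
        db = PeptideActivityDB([ActivityRecord("GF", "ah")])
        occ = profile_occurrence(protein, db)
        result = digest(protein, resolve_enzymes(["pepsin"], ruleset))
        rel = profile_release(protein, result, db, occ)
        assert rel[0].A_E == 0 and rel[0].W is None

    def test_substring_containment_is_not_release(self, db, ruleset):
        # GFR contains GF but only whole-fragment identity counts
        protein = ProteinRecord(id="p", sequence="KGFRA")
        occ = profile_occurrence(protein, db)
        result = digest(protein, resolve_enzymes(["trypsin"], ruleset))
        assert [f for f, _, _ in result.fragments] == ["K", "GFR", "A"]
        rel = {p.activity_code: p for p in profile_release(protein, result, db, occ)}
        assert rel["ah"].d_count == 0

    def test_mismatched_protein_rejected(self, toy, db, ruleset):
        other = ProteinRecord(id="other", sequence="GKGFRL")
        result = digest(other, resolve_enzymes(["pepsin"], ruleset))
        with pytest.raises(ValueError, match="other"):
            profile_release(toy, result, db, profile_occurrence(toy, db))

    @given(seq_strategy)
    def test_release_dominated_by_occurrence(self, db, ruleset, seq):
        protein = ProteinRecord(id="p", sequence=seq)
        occ = profile_occurrence(protein, db, include_zero=True)
        result = digest(protein, list(ruleset.values()))
        a_by_code = {p.activity_code: p.A for p in occ}
        for rel in profile_release(protein, result, db, occ):
            A = a_by_code[rel.activity_code]
            assert 0 <= rel.A_E <= A <= protein.n_residues
            if A > 0:
                assert rel.W is not None and 0 <= rel.W <= 1
            else:
                assert rel.W is None


@pytest.mark.parametrize(
    "value, expected",
    [
        (None, ""),
        (Fraction(0), ""),
        (Fraction(1, 2403), ""),  # rounds to 0.000 -> omitted
        (Fraction(1, 6), "0.167"),
        (Fraction(1), "1.000"),
    ],
)
def test_report_frequency_formatting(value, expected):
    assert format_frequency(value) == expected
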