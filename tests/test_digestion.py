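"""Cleavage-rule engine: rule windows, cut sites, fragments, DH_t."""

import itertools
import random
from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from colpep import (
    CleavageRule,
    Constraint,
    EnzymeSpec,
    ProteinRecord,
    digest,
    find_cut_sites,
    parse_ruleset,
    resolve_enzymes,
)
from colpep.synthetic import oracle_cut_sites

seq_strategy = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=50)

RULESET_YAML = """
enzymes:
  - name: trypsin
    ec: 3.4.21.4
    rules:
      - P1: {allow: KR}
        P1': {deny: P}
  - name: pepsin
    ec: 3.4.23.1
    rules:
      - P1: {allow: FL}
"""


class TestParseRuleset:
    def test_trypsin_entry(self, tmp_path):
        path = tmp_path / "rules.yaml"
        path.write_text(RULESET_YAML)
        specs = parse_ruleset(path)
        trypsin = specs["trypsin"]
        assert len(trypsin.rules) == 1
        assert trypsin.rules[0].window["P1"].residues == frozenset("KR")
        assert trypsin.rules[0].window["P1'"].kind == "deny"
        assert specs["pepsin"].rules[0].window["P1"].residues == frozenset("FL")

    def test_empty_allow_set_rejected(self, tmp_path):
        path = tmp_path / "rules.yaml"
        path.write_text("enzymes:\n  - name: bad\n    rules:\n      - P1: {allow: ''}\n")
        with pytest.raises(ValueError, match="bad.*rule 0"):
            parse_ruleset(path)

    def test_rule_without_p1_rejected(self, tmp_path):
        path = tmp_path / "rules.yaml"
        path.write_text("enzymes:\n  - name: bad\n    rules:\n      - P2: {allow: A}\n")
        with pytest.raises(ValueError, match="P1"):
            parse_ruleset(path)

    def test_empty_rule_list_rejected(self, tmp_path):
        path = tmp_path / "rules.yaml"
        path.write_text("enzymes:\n  - name: bad\n    rules: []\n")
        with pytest.raises(ValueError, match="empty rule list"):
            parse_ruleset(path)

    def test_nonstandard_residue_rejected(self, tmp_path):
        path = tmp_path / "rules.yaml"
        path.write_text("enzymes:\n  - name: bad\n    rules:\n      - P1: {allow: KX}\n")
        with pytest.raises(ValueError):
            parse_ruleset(path)

    def test_unknown_enzyme_name_resolution(self, ruleset):
        with pytest.raises(KeyError, match="elastase"):
            resolve_enzymes(["elastase"], ruleset)


class TestCutSites:
    @pytest.mark.parametrize(
        "sequence, enzymes, expected",
        [
            ("GKGFRL", ["trypsin"], (1, 4)),
            ("GKGFRPL", ["trypsin"], (1,)),  # Arg-Pro bond protected
            ("GKGFRL", ["pepsin"], (3,)),  # terminal Leu has no following bond
            ("GKGFRL", ["pepsin", "trypsin"], (1, 3, 4)),
        ],
    )
    def test_hand_enumerated_sites(self, ruleset, sequence, enzymes, expected):
        protein = ProteinRecord(id="t", sequence=sequence)
        assert find_cut_sites(protein, resolve_enzymes(enzymes, ruleset)) == expected

    def test_requires_at_least_one_enzyme(self, toy):
        with pytest.raises(ValueError):
            find_cut_sites(toy, [])

    def test_allow_constraint_fails_off_the_end(self):
        # P2 must be G, but bond 0 has no P2 residue
        rule = CleavageRule(
            {"P1": Constraint("allow", frozenset("K")), "P2": Constraint("allow", frozenset("G"))}
        )
        enz = EnzymeSpec("e", "", (rule,))
        assert find_cut_sites(ProteinRecord(id="t", sequence="KA"), [enz]) == ()
        assert find_cut_sites(ProteinRecord(id="t", sequence="GKA"), [enz]) == (1,)

    def test_deny_constraint_satisfied_off_the_end(self):
        rule = CleavageRule(
            {"P1": Constraint("allow", frozenset("K")), "P2": Constraint("deny", frozenset("G"))}
        )
        enz = EnzymeSpec("e", "", (rule,))
        assert find_cut_sites(ProteinRecord(id="t", sequence="KA"), [enz]) == (0,)
        assert find_cut_sites(ProteinRecord(id="t", sequence="GKA"), [enz]) == ()


class TestDigest:
    @pytest.mark.parametrize(
        "sequence, enzymes, fragments, dh_t",
        [
            ("GKGFRL", ["trypsin"], ["GK", "GFR", "L"], Fraction(40)),
            ("GKGFRL", ["pepsin"], ["GKGF", "RL"], Fraction(20)),
            ("GKGFRL", ["pepsin", "trypsin"], ["GK", "GF", "R", "L"], Fraction(60)),
            ("AAAA", ["trypsin"], ["AAAA"], Fraction(0)),
        ],
    )
    def test_fragments_and_dh(self, ruleset, sequence, enzymes, fragments, dh_t):
        result = digest(
            ProteinRecord(id="t", sequence=sequence), resolve_enzymes(enzymes, ruleset)
        )
        assert [f for f, _, _ in result.fragments] == fragments
        assert result.dh_t == dh_t
        assert len(result.fragments) == len(result.cut_sites) + 1

    def test_single_residue_chain(self, ruleset):
        result = digest(ProteinRecord(id="t", sequence="K"), resolve_enzymes(["trypsin"], ruleset))
        assert result.dh_t == 0
        assert [f for f, _, _ in result.fragments] == ["K"]

    @given(seq_strategy)
    def test_fragment_conservation(self, ruleset, seq):
        protein = ProteinRecord(id="t", sequence=seq)
        result = digest(protein, list(ruleset.values()))
        assert "".join(f for f, _, _ in result.fragments) == seq
        starts = [a for _, a, _ in result.fragments]
        ends = [b for _, _, b in result.fragments]
        assert starts[0] == 0 and ends[-1] == len(seq)
        assert all(e == s for e, s in zip(ends[:-1], starts[1:]))

    @given(seq_strategy, st.permutations(["pepsin", "trypsin", "chymotrypsin"]))
    def test_enzyme_order_invariance(self, ruleset, seq, order):
        protein = ProteinRecord(id="t", sequence=seq)
        baseline = digest(protein, resolve_enzymes(["pepsin", "trypsin", "chymotrypsin"], ruleset))
        permuted = digest(protein, resolve_enzymes(order, ruleset))
        assert permuted.cut_sites == baseline.cut_sites
        assert permuted.fragments == baseline.fragments
        assert permuted.dh_t == baseline.dh_t

    @given(seq_strategy)
    def test_union_property_and_dh_bounds(self, ruleset, seq):
        protein = ProteinRecord(id="t", sequence=seq)
        for a, b in itertools.combinations(["pepsin", "trypsin", "stem_bromelain"], 2):
            sites_a = set(find_cut_sites(protein, resolve_enzymes([a], ruleset)))
            sites_b = set(find_cut_sites(protein, resolve_enzymes([b], ruleset)))
            combo = digest(protein, resolve_enzymes([a, b], ruleset))
            assert set(combo.cut_sites) == sites_a | sites_b
            dh_a = digest(protein, resolve_enzymes([a], ruleset)).dh_t
            dh_b = digest(protein, resolve_enzymes([b], ruleset)).dh_t
            assert max(dh_a, dh_b) <= combo.dh_t <= dh_a + dh_b
            if sites_a.isdisjoint(sites_b):
                assert combo.dh_t == dh_a + dh_b

    @given(seq_strategy)
    def test_engine_matches_naive_bruteforce(self, ruleset, seq):
        protein = ProteinRecord(id="t", sequence=seq)
        enzymes = list(ruleset.values())
        assert list(find_cut_sites(protein, enzymes)) == oracle_cut_sites(seq, enzymes)
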