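"""Digestion, modification enumeration, masses, decoys, and the candidate index."""
from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lectern.digest import (
    CandidateIndex,
    CleavageRule,
    ModificationScheme,
    TRYPSIN,
    Peptide,
    digest,
    enumerate_modified_forms,
    make_decoy,
    peptide_mass,
    precursor_window,
    read_fasta,
    sequence_mass,
)
from lectern.masses import AA_MASS, CANONICAL, WATER

peptide_strategy = st.text(alphabet=CANONICAL, min_size=3, max_size=12)


def oracle_digest(protein: str, rule: CleavageRule) -> set[tuple[str, int]]:
    """Exhaustive substring enumeration: a substring is a digest product iff
    its ends are cleavage boundaries and it spans <= max_missed internal sites."""
    sites = {
        i + 1
        for i in range(len(protein) - 1)
        if protein[i] in rule.cut_after and protein[i + 1] not in rule.suppress_before
    }
    bounds = sorted({0, len(protein)} | sites)
    out = set()
    for a, b in itertools.combinations(bounds, 2):
        internal = sum(1 for s in sites if a < s < b)
        if internal <= rule.max_missed:
            out.add((protein[a:b], internal))
    return out


class TestDigest:
    def test_proline_suppression_example(self):
        assert {s for s, m in digest("AKPRGK", CleavageRule(frozenset("RK"), frozenset("P"), 0))} == {
            "AKPR",
            "GK",
        }

    def test_missed_cleavage_example(self):
        assert {s for s, _ in digest("AKPRGK", TRYPSIN)} == {"AKPR", "GK", "AKPRGK"}

    def test_no_sites_returns_protein(self):
        assert digest("AGAGAG", TRYPSIN) == [("AGAGAG", 0)]

    def test_empty_protein(self):
        assert digest("", TRYPSIN) == []

    @given(
        protein=st.text(alphabet="AKRPG", min_size=1, max_size=40),
        max_missed=st.integers(min_value=0, max_value=3),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_exhaustive_oracle(self, protein, max_missed):
        rule = CleavageRule(frozenset("RK"), frozenset("P"), max_missed)
        assert set(digest(protein, rule)) == oracle_digest(protein, rule)

    @given(protein=st.text(alphabet="ACDKRG", min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_zero_missed_count_is_sites_plus_one(self, protein):
        rule = CleavageRule(frozenset("RK"), frozenset(), 0)
        sites = sum(
            1 for i in range(len(protein) - 1) if protein[i] in "RK"
        )
        assert len(digest(protein, rule)) == sites + 1

    def test_rule_string_parsing(self):
        rule = CleavageRule.from_string("[RK]|{P}", max_missed=2)
        assert rule.cut_after == frozenset("RK")
        assert rule.suppress_before == frozenset("P")
        assert rule.max_missed == 2
        with pytest.raises(ValueError):
            CleavageRule.from_string("RK|P")


def oracle_forms(sequence: str, scheme: ModificationScheme) -> set[tuple]:
    """Brute force over all 2^sites x N-term choices, filtered by budget."""
    var_sites = [i for i, aa in enumerate(sequence) if aa in scheme.variable_mods]
    out = set()
    for r in range(len(var_sites) + 1):
        for combo in itertools.combinations(var_sites, r):
            for nterm in [None, *scheme.nterm_mods]:
                used = r + (1 if nterm is not None else 0)
                if used > scheme.max_variable:
                    continue
                deltas = tuple(
                    scheme.static_mods.get(aa, 0.0)
                    + (scheme.variable_mods[aa] if i in combo else 0.0)
                    for i, aa in enumerate(sequence)
                )
                out.add((deltas, nterm))
    return out


class TestModifiedForms:
    SCHEME = ModificationScheme(
        static_mods={"C": 57.02146},
        variable_mods={"M": 15.994915, "N": 0.984016, "Q": 0.984016},
        nterm_mods=(42.010565, 43.005814, -17.026549, 25.980265),
        max_variable=2,
    )

    def test_acm_example_has_ten_forms(self):
        forms = enumerate_modified_forms("ACM", self.SCHEME)
        assert len(forms) == 10

    def test_unmodifiable_peptide_single_form(self):
        assert len(enumerate_modified_forms("AAA", ModificationScheme())) == 1

    def test_deamidation_choice_example(self):
        scheme = ModificationScheme(variable_mods={"N": 0.984016, "Q": 0.984016}, max_variable=1)
        forms = enumerate_modified_forms("NQ", scheme)
        assert len(forms) == 3

    @given(sequence=st.text(alphabet="ACMNQG", min_size=1, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force(self, sequence):
        got = {(f.mod_deltas, f.nterm_delta) for f in enumerate_modified_forms(sequence, self.SCHEME)}
        assert got == oracle_forms(sequence, self.SCHEME)
        # all emitted forms are distinct
        assert len(got) == len(enumerate_modified_forms(sequence, self.SCHEME))


class TestMass:
    def test_glycine(self):
        assert sequence_mass("G") == pytest.approx(AA_MASS["G"] + WATER, abs=1e-9)
        assert sequence_mass("G") == pytest.approx(75.03203, abs=1e-4)

    def test_carbamidomethyl_cysteine(self):
        assert sequence_mass("C", (57.02146,)) == pytest.approx(178.041210, abs=1e-5)

    def test_zero_mods_equal_no_mods(self):
        assert sequence_mass("PEPTIDEK", (0.0,) * 8) == sequence_mass("PEPTIDEK")

    def test_unknown_residue_named(self):
        with pytest.raises(KeyError, match="B"):
            sequence_mass("AB")

    def test_peptide_field_consistency(self):
        for form in enumerate_modified_forms("ACMNK", TestModifiedForms.SCHEME):
            assert form.neutral_mass == pytest.approx(peptide_mass(form), abs=1e-6)


class TestDecoy:
    @given(sequence=peptide_strategy, seed=st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=150, deadline=None)
    def test_permutation_mass_and_cterm_preserved(self, sequence, seed):
        target = Peptide(
            sequence=sequence,
            mod_deltas=tuple(0.0 for _ in sequence),
            nterm_delta=None,
            neutral_mass=sequence_mass(sequence),
        )
        decoy = make_decoy(target, seed)
        assert sorted(decoy.sequence) == sorted(sequence)
        assert decoy.sequence[-1] == sequence[-1]
        assert decoy.neutral_mass == pytest.approx(target.neutral_mass, abs=1e-6)
        assert decoy.is_decoy and decoy.source_target == target.modified_sequence

    def test_mods_travel_with_residues(self):
        target = Peptide(
            sequence="MACK",
            mod_deltas=(15.994915, 0.0, 57.02146, 0.0),
            nterm_delta=None,
            neutral_mass=sequence_mass("MACK", (15.994915, 0.0, 57.02146, 0.0)),
        )
        decoy = make_decoy(target, 3)
        per_residue = dict(zip(decoy.sequence, decoy.mod_deltas))
        assert per_residue["M"] == 15.994915
        assert per_residue["C"] == 57.02146

    def test_length_two_is_flagged_collision(self):
        target = Peptide("AK", (0.0, 0.0), None, sequence_mass("AK"))
        decoy = make_decoy(target, 0)
        assert decoy.sequence == "AK" and decoy.collision

    def test_frozen_shuffle_regression(self):
        target = Peptide("PEPTIDEK", (0.0,) * 8, None, sequence_mass("PEPTIDEK"))
        assert make_decoy(target, 7).sequence == "PDEPIETK"
        assert make_decoy(target, 7).sequence == "PDEPIETK"  # stable across calls


class TestPrecursorWindow:
    def test_twenty_ppm_at_kilodalton(self):
        from lectern.masses import PROTON

        mz = (1000.0 + 2 * PROTON) / 2
        lo, hi = precursor_window(mz, 2, 20.0)
        assert lo == pytest.approx(999.98, abs=1e-6)
        assert hi == pytest.approx(1000.02, abs=1e-6)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            precursor_window(500.0, 2, 0.0)
        with pytest.raises(ValueError):
            precursor_window(500.0, 0, 20.0)
        with pytest.raises(ValueError):
            precursor_window(0.5, 1, 20.0)


class TestCandidateIndex:
    @staticmethod
    def _peptide(mass: float, tag: int) -> Peptide:
        return Peptide("AAAAAA", (0.0,) * 6, None, mass, missed_cleavages=tag % 2)

    def test_interval_query_example(self):
        index = CandidateIndex([self._peptide(m, i) for i, m in enumerate((100.0, 200.0, 300.0))])
        assert [p.neutral_mass for p in index.query(150.0, 250.0)] == [200.0]
        assert [p.neutral_mass for p in index.query(0.0, 1e6)] == [100.0, 200.0, 300.0]

    def test_matches_linear_scan(self, rng):
        masses = rng.uniform(500.0, 3000.0, size=1000)
        peptides = [self._peptide(float(m), i) for i, m in enumerate(masses)]
        index = CandidateIndex(peptides)
        for _ in range(100):
            a, b = np.sort(rng.uniform(400.0, 3100.0, size=2))
            got = {id(p) for p in index.query(a, b)}
            expected = {id(p) for p in index.peptides if a <= p.neutral_mass <= b}
            assert got == expected
            # ascending-mass order
            out = index.query(a, b)
            assert all(x.neutral_mass <= y.neutral_mass for x, y in zip(out, out[1:]))


class TestReadFasta:
    def test_single_record(self, tmp_path):
        path = tmp_path / "one.fasta"
        path.write_text(">p1 test protein\nAKPRGK\n")
        records = read_fasta(path)
        assert len(records) == 1
        assert records[0].id == "p1"
        assert records[0].sequence == "AKPRGK"

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        assert read_fasta(path) == []

    def test_lowercase_uppercased(self, tmp_path):
        path = tmp_path / "lower.fasta"
        path.write_text(">p1\nakr\n")
        assert read_fasta(path)[0].sequence == "AKR"

    def test_malformed_header_names_line(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text("AKPRGK\n>p1\nAK\n")
        with pytest.raises(ValueError, match="line 1"):
            read_fasta(path)
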