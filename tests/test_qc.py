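"""Structure parsing, alignment metrics, quality scores and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gemprokit.qc import (align_structure_to_wt, classify_group, rank_structures,
                          resolution_score, score_structure)
from gemprokit.structures import (MODEL, NMR, XRAY, PdbParseError, StructureRecord,
                                  parse_pdb)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestParsePdb:
    def test_resolution_from_remark(self):
        text = ("REMARK   2 RESOLUTION.    2.00 ANGSTROMS.\n"
                "ATOM      1  CA  ALA A   1       0.000   0.000   0.000"
                "  1.00  0.00           C\n")
        s = parse_pdb(text, "x")
        assert s.resolution == 2.0 and s.method == XRAY

    def test_nmr_without_resolution(self):
        text = ("EXPDTA    SOLUTION NMR\n"
                "ATOM      1  CA  ALA A   1       0.000   0.000   0.000"
                "  1.00  0.00           C\n")
        s = parse_pdb(text, "x")
        assert s.resolution is None and s.method == NMR

    def test_seqres_longer_than_atoms(self):
        from gemprokit.fixtures import build_peptide
        from gemprokit.structures import write_pdb

        struct = build_peptide("ALAKEWGTRD", -139, 135)
        struct.chains["A"].seqres = "ALAKEWGTRD"
        chain = struct.chains["A"]
        chain.residues = [r for r in chain.residues if r.number != 5]
        s = parse_pdb(write_pdb(struct), "x")
        assert len(s.first_chain().reported_sequence) == 10
        assert len(s.first_chain().observed_sequence) == 9

    def test_no_atoms_is_error(self):
        with pytest.raises(PdbParseError, match="no ATOM"):
            parse_pdb("REMARK   2 RESOLUTION. 2.0 ANGSTROMS.\n", "x")

    def test_malformed_coordinate_names_line(self):
        text = ("ATOM      1  CA  ALA A   1       x.000   0.000   0.000"
                "  1.00  0.00           C\n")
        with pytest.raises(PdbParseError, match="line 1"):
            parse_pdb(text, "x")


class TestAlignment:
    def test_identical_sequences(self):
        a = align_structure_to_wt("MKTAYIAK", "MKTAYIAK")
        assert a.identity_fraction == 1.0 and a.completeness_fraction == 1.0
        assert not a.mutations and not a.interior_gaps

    def test_interior_deletion(self):
        a = align_structure_to_wt("MKTAYIAK", "MKTYIAK")
        assert a.completeness_fraction == pytest.approx(7 / 8)
        assert a.identity_fraction == pytest.approx(7 / 8)
        assert a.interior_gaps == [(4, 1)]
        assert not a.mutations

    def test_point_mutation_keeps_completeness(self):
        """Completeness disregards exact matches: a mutated residue is resolved."""
        a = align_structure_to_wt("MKTAYIAK", "MKTVYIAK")
        assert a.identity_fraction == pytest.approx(0.875)
        assert a.completeness_fraction == 1.0
        assert a.mutations == [(4, "A", "V")]

    def test_terminal_gap_reduces_completeness_only(self):
        a = align_structure_to_wt("MKTAYIAK", "TAYIAK")
        assert a.completeness_fraction == pytest.approx(6 / 8)
        assert a.terminal_gap_lengths == (2, 0)
        assert not a.interior_gaps

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_structure_to_wt("", "MKT")

    @given(st.text(AA, min_size=1, max_size=30),
           st.text(AA, min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_identity_never_exceeds_completeness(self, wt, obs):
        a = align_structure_to_wt(wt, obs)
        assert a.identity_fraction <= a.completeness_fraction + 1e-12
        assert 0.0 <= a.identity_fraction <= 1.0


def _xray(structure_id="s", resolution=2.0):
    return StructureRecord(structure_id, XRAY, resolution)


class TestScoring:
    def test_maximal_case(self):
        aln = align_structure_to_wt("MKTAYIAK", "MKTAYIAK")
        score = score_structure(aln, _xray(resolution=1.0))
        assert score.combined == 1.0 and score.group == "I"

    def test_weighted_sum_arithmetic(self):
        """0.5*0.9 + 0.3*0.8 + 0.2*s_res(3.0) = 0.79 with s_res(3.0) = 0.5."""
        wt = "A" * 10
        obs = "G" + "A" * 7  # 7 matches, 1 mismatch, 2 C-terminal missing
        aln = align_structure_to_wt(wt, obs)
        assert aln.identity_fraction == pytest.approx(0.7)
        assert aln.completeness_fraction == pytest.approx(0.8)
        score = score_structure(aln, _xray(resolution=3.0))
        assert resolution_score(_xray(resolution=3.0)) == pytest.approx(0.5)
        assert score.combined == pytest.approx(0.5 * 0.7 + 0.3 * 0.8 + 0.2 * 0.5)

    def test_model_score_from_tm_and_ss(self):
        aln = align_structure_to_wt("MKTAYIAK", "MKTAYIAK")
        model = StructureRecord("m1", MODEL, tm_score=0.8)
        comp = {"H": 0.5, "E": 0.25, "-": 0.25}
        score = score_structure(aln, model, ss_ref=comp, ss_model=dict(comp))
        assert score.combined == pytest.approx(0.5 * 0.8 + 0.5 * 1.0)

    def test_model_without_tm_score_is_error(self):
        aln = align_structure_to_wt("MKTAYIAK", "MKTAYIAK")
        with pytest.raises(ValueError, match="TM-score"):
            score_structure(aln, StructureRecord("m1", MODEL))

    def test_combined_stays_in_unit_interval(self):
        aln = align_structure_to_wt("MKTAYIAK", "W")
        score = score_structure(aln, _xray(resolution=9.0))
        assert 0.0 < score.combined <= 1.0


class TestGroups:
    def test_perfect_match_group_one(self):
        aln = align_structure_to_wt("MKTAYIAK", "MKTAYIAK")
        assert classify_group(aln, _xray(resolution=2.0)) == "I"

    def test_single_point_mutation_group_two(self):
        aln = align_structure_to_wt("MKTAYIAK", "MKTVYIAK")
        assert classify_group(aln, _xray(resolution=2.2)) == "II"

    def test_long_interior_gap_group_three(self):
        wt = "MKTAYIAKWE" + "RTYIPGHQCD" + "HLVNMQEDWF"
        obs = wt[:10] + wt[20:]  # 10-residue interior gap, 10-residue flanks
        aln = align_structure_to_wt(wt, obs)
        assert sum(length for _, length in aln.interior_gaps) == 10
        assert classify_group(aln, _xray()) == "III"

    def test_three_sequential_mutations_group_three(self):
        wt = "MKTAYIAKWERT"
        obs = "MKTGGGAKWERT"  # run of 3 consecutive mismatches
        aln = align_structure_to_wt(wt, obs)
        assert classify_group(aln, _xray()) == "III"

    def test_poor_resolution_blocks_group_one(self):
        aln = align_structure_to_wt("MKTAYIAK", "MKTAYIAK")
        assert classify_group(aln, _xray(resolution=3.5)) == "III"


class TestRanking:
    def _candidate(self, sid, combined, s_si=0.9, resolution=2.0, method=XRAY):
        from gemprokit.qc import QualityScore

        struct = StructureRecord(sid, method, resolution,
                                 tm_score=0.8 if method == MODEL else None)
        return struct, QualityScore(s_si=s_si, s_res=0.7, combined=combined, group="I")

    def test_sorted_by_combined(self):
        cands = [self._candidate("a", 0.9), self._candidate("b", 0.95),
                 self._candidate("c", 0.7)]
        ordered, rep = rank_structures("g", cands)
        assert [s.structure_id for s, _ in ordered] == ["b", "a", "c"]
        assert rep[0].structure_id == "b"

    def test_resolution_tie_break(self):
        cands = [self._candidate("hi", 0.9, resolution=2.5),
                 self._candidate("lo", 0.9, resolution=2.0)]
        ordered, _ = rank_structures("g", cands)
        assert ordered[0][0].structure_id == "lo"

    def test_experimental_preferred_over_model(self):
        cands = [self._candidate("mod", 0.9, method=MODEL),
                 self._candidate("exp", 0.9)]
        ordered, _ = rank_structures("g", cands)
        assert ordered[0][0].structure_id == "exp"

    def test_matches_independent_sort(self):
        rng = np.random.default_rng(11)
        cands = [self._candidate(f"s{i:02d}", float(rng.choice([0.5, 0.7, 0.9])),
                                 s_si=float(rng.choice([0.6, 0.8])),
                                 resolution=float(rng.choice([1.5, 2.0, 2.5])))
                 for i in range(50)]
        ordered, _ = rank_structures("g", cands)
        oracle = sorted(cands, key=lambda it: (-it[1].combined, -it[1].s_si,
                                               it[0].resolution, it[0].structure_id))
        assert [s.structure_id for s, _ in ordered] == \
            [s.structure_id for s, _ in oracle]

    def test_deterministic_under_permutation(self):
        rng = np.random.default_rng(5)
        cands = [self._candidate(f"s{i}", float(rng.uniform(0.3, 1.0)))
                 for i in range(20)]
        ordered1, _ = rank_structures("g", cands)
        perm = [cands[i] for i in rng.permutation(len(cands))]
        ordered2, _ = rank_structures("g", perm)
        assert [s.structure_id for s, _ in ordered1] == \
            [s.structure_id for s, _ in ordered2]

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError):
            rank_structures("g", [])
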