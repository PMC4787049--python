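"""SASA, secondary structure, contacts, depth and the 29-feature profile."""

import numpy as np
import pytest

from gemprokit.fixtures import (OPEN_PHI, OPEN_PSI, build_peptide, make_dimer_ssbond_pdb,
                                make_hairpin_pdb, make_helix_pdb)
from gemprokit.props import (FEATURE_NAMES, assign_secondary_structure,
                             assign_surface_buried, compute_residue_depth,
                             compute_sasa, count_contacts, count_ss_bonds,
                             property_vector, ss_composition)
from gemprokit.structures import Atom, ChainRecord, Residue, parse_pdb


def _single_atom_chain(element="C", radius=None):
    return ChainRecord("A", [Residue(1, "ALA", [Atom("CA", element, np.zeros(3))])])


class TestSasa:
    @pytest.mark.parametrize("element,r_vdw", [("C", 1.70), ("N", 1.55), ("S", 1.80)])
    def test_isolated_atom_matches_sphere_area(self, element, r_vdw):
        res = compute_sasa(_single_atom_chain(element))
        exact = 4 * np.pi * (r_vdw + 1.4) ** 2
        assert res.total == pytest.approx(exact, rel=0.02)

    def test_disjoint_atoms_additive(self):
        chain = ChainRecord("A", [
            Residue(1, "ALA", [Atom("CA", "C", np.zeros(3))]),
            Residue(2, "ALA", [Atom("CA", "C", np.array([100.0, 0, 0]))]),
        ])
        total = compute_sasa(chain).total
        single = compute_sasa(_single_atom_chain()).total
        assert total == pytest.approx(2 * single, rel=1e-9)

    def test_convergence_with_lattice_density(self):
        chain = build_peptide("AKWDE", OPEN_PHI, OPEN_PSI).chains["A"]
        coarse = compute_sasa(chain, n_points=960).total
        fine = compute_sasa(chain, n_points=3840).total
        assert abs(coarse - fine) / fine < 0.01

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            compute_sasa(_single_atom_chain(), n_points=30)

    def test_rotation_invariance(self):
        chain = build_peptide("AKWDE", OPEN_PHI, OPEN_PSI).chains["A"]
        ref = compute_sasa(chain).total
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        rotated = chain.copy()
        for r in rotated.residues:
            for a in r.atoms:
                a.coord = rot @ a.coord + np.array([3.0, -2.0, 1.0])
        assert compute_sasa(rotated).total == pytest.approx(ref, rel=5e-3)


class TestSurfaceBuried:
    def test_strict_threshold(self):
        assert assign_surface_buried(np.array([3.01, 3.00, 0.0])) == \
            ["SURFACE", "BURIED", "BURIED"]

    def test_extended_tripeptide_all_surface(self):
        chain = build_peptide("AKD", OPEN_PHI, OPEN_PSI).chains["A"]
        sasa = compute_sasa(chain)
        assert assign_surface_buried(sasa.per_residue) == ["SURFACE"] * 3


def independent_ks_hbonds(chain):
    """Independent Kabsch-Sander energy evaluation (direct formula, no shared code)."""
    res = chain.residues
    coords = {(r.number, a.name): a.coord for r in res for a in r.atoms}
    bonds = set()
    numbers = [r.number for r in res]
    for i in numbers:
        if (i, "C") not in coords or (i, "O") not in coords:
            continue
        for j in numbers:
            if abs(i - j) < 2 or (j, "N") not in coords or (j - 1, "C") not in coords \
                    or (j - 1, "O") not in coords:
                continue
            d = coords[(j - 1, "C")] - coords[(j - 1, "O")]
            h = coords[(j, "N")] + d / np.linalg.norm(d)
            e = 27.888 * (1 / np.linalg.norm(coords[(i, "O")] - coords[(j, "N")])
                          + 1 / np.linalg.norm(coords[(i, "C")] - h)
                          - 1 / np.linalg.norm(coords[(i, "O")] - h)
                          - 1 / np.linalg.norm(coords[(i, "C")] - coords[(j, "N")]))
            if e < -0.5:
                bonds.add((i, j))
    return bonds


class TestSecondaryStructure:
    def test_ideal_helix_core_labeled_h(self, helix_structure):
        ss = assign_secondary_structure(helix_structure.first_chain())
        assert "".join(ss[2:10]) == "H" * 8
        assert "H" not in (ss[0], ss[1], ss[10], ss[11])

    def test_helix_hbond_ladder_matches_independent_oracle(self, helix_structure):
        from gemprokit.props import _hbond_matrix

        chain = helix_structure.first_chain()
        hb = _hbond_matrix(chain)
        ours = {(chain.residues[i].number, chain.residues[j].number)
                for i in range(len(chain.residues))
                for j in range(len(chain.residues)) if hb[i, j]}
        assert ours == independent_ks_hbonds(chain)
        assert ours == {(i, i + 4) for i in range(1, 9)}

    def test_helix_consistent_with_mdtraj_dssp(self, helix_structure, tmp_path):
        mdtraj = pytest.importorskip("mdtraj")
        from gemprokit.structures import write_pdb

        path = tmp_path / "helix.pdb"
        path.write_text(write_pdb(helix_structure))
        dssp = mdtraj.compute_dssp(mdtraj.load(str(path)), simplified=True)[0]
        ours = assign_secondary_structure(helix_structure.first_chain())
        for i, label in enumerate(ours):
            if label == "H":  # our helix core must lie inside mdtraj's helix
                assert dssp[i] == "H"

    def test_dipeptide_unassigned(self):
        chain = build_peptide("AA", -57, -47).chains["A"]
        assert assign_secondary_structure(chain) == ["-", "-"]

    def test_hairpin_strand_cores_labeled_e(self):
        struct = parse_pdb(make_hairpin_pdb(), "hairpin")
        ss = assign_secondary_structure(struct.first_chain())
        # each 6-residue strand has E in its core
        assert "E" in ss[1:5] and "E" in ss[7:11]
        assert "H" not in ss

    def test_composition_sums_to_one(self, helix_structure):
        comp = ss_composition(assign_secondary_structure(helix_structure.first_chain()))
        assert sum(comp.values()) == pytest.approx(1.0)


class TestSsBonds:
    def test_cutoff_flip(self):
        for dist, expected in ((4.9, 1), (5.1, 0)):
            struct = parse_pdb(make_dimer_ssbond_pdb(dist), "d")
            merged = ChainRecord("X", struct.chains["A"].residues
                                 + [r for r in struct.chains["B"].residues])
            assert count_ss_bonds(merged) == expected

    def test_no_cysteines(self):
        chain = build_peptide("AKD", OPEN_PHI, OPEN_PSI).chains["A"]
        assert count_ss_bonds(chain) == 0

    def test_each_sulfur_used_once(self):
        residues = [Residue(i + 1, "CYS",
                            [Atom("SG", "S", np.array([x, 0.0, 0.0]))])
                    for i, x in enumerate([0.0, 2.0, 4.0])]
        # middle SG within 5 A of both neighbors; greedy pairing uses it once
        assert count_ss_bonds(ChainRecord("A", residues)) == 1


class TestContacts:
    def test_distant_residues_no_contact(self):
        chain = ChainRecord("A", [
            Residue(1, "ALA", [Atom("CA", "C", np.zeros(3))]),
            Residue(10, "ALA", [Atom("CA", "C", np.array([50.0, 0, 0]))]),
        ])
        assert count_contacts(chain) == 0

    def test_matches_brute_force_recount(self):
        chain = build_peptide("AKWDEFGHIK", -57, -47).chains["A"]
        fast = count_contacts(chain)
        atoms = [(r.number, a.coord) for r in chain.residues for a in r.atoms
                 if a.element != "H"]
        slow = sum(1 for i in range(len(atoms)) for j in range(i + 1, len(atoms))
                   if abs(atoms[i][0] - atoms[j][0]) >= 3
                   and np.linalg.norm(atoms[i][1] - atoms[j][1]) <= 4.5)
        assert fast == slow

    def test_rotation_invariance(self):
        chain = build_peptide("AKWDEFGH", -57, -47).chains["A"]
        ref = count_contacts(chain)
        rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
        moved = chain.copy()
        for r in moved.residues:
            for a in r.atoms:
                a.coord = rot @ a.coord + 7.0
        assert count_contacts(moved) == ref


class TestResidueDepth:
    def test_single_atom_depth_is_expanded_radius(self):
        chain = _single_atom_chain()
        sasa = compute_sasa(chain)
        depth = compute_residue_depth(chain, sasa)
        assert depth[0] == pytest.approx(1.70 + 1.4, rel=1e-3)

    def test_central_atom_deeper_than_shell(self):
        center = Residue(1, "ALA", [Atom("CA", "C", np.zeros(3))])
        shell = []
        golden = (1 + 5 ** 0.5) / 2
        verts = [(0, 1, golden), (0, -1, golden), (0, 1, -golden), (0, -1, -golden),
                 (1, golden, 0), (-1, golden, 0), (1, -golden, 0), (-1, -golden, 0),
                 (golden, 0, 1), (-golden, 0, 1), (golden, 0, -1), (-golden, 0, -1)]
        for k, v in enumerate(verts):
            pos = 3.5 * np.asarray(v) / np.linalg.norm(v)
            shell.append(Residue(k + 2, "ALA", [Atom("CA", "C", pos)]))
        chain = ChainRecord("A", [center] + shell)
        sasa = compute_sasa(chain)
        depth = compute_residue_depth(chain, sasa)
        assert depth[0] > max(depth[1:])

    def test_translation_invariance(self):
        chain = build_peptide("AKD", OPEN_PHI, OPEN_PSI).chains["A"]
        sasa = compute_sasa(chain)
        ref = compute_residue_depth(chain, sasa)
        moved = chain.copy()
        for r in moved.residues:
            for a in r.atoms:
                a.coord = a.coord + np.array([10.0, -5.0, 2.0])
        out = compute_residue_depth(moved, compute_sasa(moved))
        assert np.allclose(out, ref, rtol=1e-6)


class TestPropertyVector:
    def test_ovality_closed_form(self):
        """ovality = SASA / n_res^(2/3): 8 residues make the denominator 4."""
        chain = build_peptide("A" * 8, OPEN_PHI, OPEN_PSI).chains["A"]
        vec = property_vector(chain)
        assert vec["ovality"] == pytest.approx(vec["sasa_total"] / 4.0)

    def test_all_lysine_percentages(self):
        chain = build_peptide("KKKK", OPEN_PHI, OPEN_PSI).chains["A"]
        vec = property_vector(chain)
        assert vec["pct_positive"] == 100.0
        assert vec["pct_nonpolar"] == 0.0

    def test_has_exactly_29_features(self):
        chain = build_peptide("AKD", OPEN_PHI, OPEN_PSI).chains["A"]
        vec = property_vector(chain)
        assert len(vec) == 29 and tuple(vec) == FEATURE_NAMES

    @pytest.mark.parametrize("seed", range(5))
    def test_percentage_invariants_on_random_fixtures(self, seed):
        from gemprokit.fixtures import random_sequence

        seq = random_sequence(12, seed)
        chain = build_peptide(seq, OPEN_PHI, OPEN_PSI).chains["A"]
        vec = property_vector(chain)
        assert vec["pct_buried"] + vec["pct_surface"] == pytest.approx(100.0)
        ss_sum = sum(vec[k] for k in ("pct_helix_H", "pct_strand_E", "pct_310_G",
                                      "pct_pi_I", "pct_turn_T", "pct_bend_S",
                                      "pct_bridge_B", "pct_disordered"))
        assert ss_sum == pytest.approx(100.0)
        quartet = sum(vec[f"pct_{c}"] for c in
                      ("nonpolar", "polar", "positive", "negative"))
        assert quartet == pytest.approx(100.0)
        if vec["pct_surface"] > 0:
            surf = sum(vec[f"pct_surface_{c}"] for c in
                       ("nonpolar", "polar", "positive", "negative"))
            assert surf == pytest.approx(100.0)
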