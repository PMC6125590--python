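"""Tail building, charge models and rigid ligand offsets."""

import io

import numpy as np
import pytest

from tailbind.errors import (IncompleteStructureError, InvalidSelectionError,
                             ParseError)
from tailbind.io import read_structure, read_pqr, write_pqr
from tailbind.structure import (ALPHA_TAIL_SEQUENCE, BETA_TAIL_SEQUENCE,
                                Atom, OffsetLadder, Structure, assign_charges,
                                build_tail, formal_residue_charges,
                                offset_ladder_structures, offset_ligand)

PDB_ONE_ATOM = (
    "ATOM      1  CA  GLY A   1      11.000  22.000  33.000  1.00  0.00"
    "           C  \n"
)
PDB_TWO_CHAINS = PDB_ONE_ATOM + (
    "ATOM      2  CA  ALA B   5       1.000   2.000   3.000  1.00  0.00"
    "           C  \n"
)


class TestPdbParsing:
    def test_single_atom_record_identity(self):
        s = read_structure(io.StringIO(PDB_ONE_ATOM))
        assert s.n_atoms == 1
        np.testing.assert_allclose(s.coords[0], [11.0, 22.0, 33.0])
        assert str(s.residue_name[0]) == "GLY"
        assert str(s.element[0]).upper() == "C"

    def test_two_chain_groups(self):
        s = read_structure(io.StringIO(PDB_TWO_CHAINS))
        groups = s.chain_groups()
        assert set(groups) == {"A", "B"}
        assert len(groups["A"]) == len(groups["B"]) == 1

    def test_truncated_coordinates_raise(self):
        bad = "ATOM      1  CA  GLY A   1      11.000  22.0\n"
        with pytest.raises(ParseError):
            read_structure(io.StringIO(bad))


class TestBuildTail:
    @pytest.mark.parametrize("sequence", [BETA_TAIL_SEQUENCE,
                                          ALPHA_TAIL_SEQUENCE, "GA", "K"])
    def test_residue_count_matches_sequence(self, sequence):
        frag = build_tail(None, sequence)
        residues = frag.residue_ids(np.arange(frag.n_atoms))
        assert len(residues) == len(sequence)

    def test_beta_tail_has_19_residues(self):
        frag = build_tail(None, BETA_TAIL_SEQUENCE)
        assert len({(c, r) for c, r, _ in
                    frag.residue_ids(np.arange(frag.n_atoms))}) == 19

    def test_empty_sequence_is_empty_fragment(self):
        assert build_tail(None, "").n_atoms == 0

    def test_unknown_letter_rejected(self):
        with pytest.raises(ValueError):
            build_tail(None, "AXA")

    def test_alpha_tail_acidic_residue_count(self):
        frag = build_tail(None, ALPHA_TAIL_SEQUENCE)
        acidic = {
            (c, r) for c, r, name in frag.residue_ids(np.arange(frag.n_atoms))
            if name in ("ASP", "GLU")
        }
        assert len(acidic) == 8

    def test_backbone_geometry(self):
        frag = build_tail(None, "AAAA")
        for resid in range(1, 5):
            idx = {str(frag.name[i]): i
                   for i in frag.select(residues=(resid, resid))}
            n_ca = np.linalg.norm(frag.coords[idx["CA"]] - frag.coords[idx["N"]])
            ca_c = np.linalg.norm(frag.coords[idx["C"]] - frag.coords[idx["CA"]])
            assert n_ca == pytest.approx(1.458, abs=0.02)
            assert ca_c == pytest.approx(1.525, abs=0.02)
        # trans peptide: successive CA separated by ~3.8 Å
        ca = frag.coords[frag.name.astype(str) == "CA"]
        np.testing.assert_allclose(
            np.linalg.norm(np.diff(ca, axis=0), axis=1), 3.8, atol=0.1)

    def test_numbering_continues_from_anchor(self):
        frag = build_tail(None, "GG", start_residue=430, chain_id="B")
        assert sorted(set(frag.residue_index.tolist())) == [430, 431]


class TestAssignCharges:
    def test_beta_tail_net_charge(self):
        frag = assign_charges(build_tail(None, BETA_TAIL_SEQUENCE))
        assert np.nansum(frag.charge) == pytest.approx(-11.0)
        assert formal_residue_charges(BETA_TAIL_SEQUENCE) == -11

    def test_polyglycine_is_neutral(self):
        frag = assign_charges(build_tail(None, "GGGGG"))
        assert np.nansum(frag.charge) == pytest.approx(0.0)

    def test_total_equals_signed_ionizable_count(self):
        seq = "KDERGAK"
        frag = assign_charges(build_tail(None, seq))
        assert np.nansum(frag.charge) == pytest.approx(
            formal_residue_charges(seq))

    def test_termini_flag_adds_zwitterion(self):
        frag = build_tail(None, "GG")
        neutral = assign_charges(frag)
        zwit = assign_charges(frag, charge_termini=True)
        assert np.nansum(neutral.charge) == pytest.approx(0.0)
        assert np.nansum(zwit.charge) == pytest.approx(0.0)
        assert (zwit.charge != neutral.charge).sum() == 2

    def test_missing_carrier_atom_raises(self):
        atoms = [Atom(1, "CA", "C", "ASP", 1, "A", [0, 0, 0]),
                 Atom(2, "CB", "C", "ASP", 1, "A", [1.5, 0, 0])]
        s = Structure.from_atoms(atoms)
        with pytest.raises(IncompleteStructureError):
            assign_charges(s)

    def test_radii_assigned_by_element(self):
        frag = assign_charges(build_tail(None, "A"))
        radii = {str(n): r for n, r in zip(frag.name, frag.radius)}
        assert radii["N"] == pytest.approx(1.55)
        assert radii["O"] == pytest.approx(1.52)
        assert radii["CA"] == pytest.approx(1.70)

    def test_pqr_round_trip(self, tmp_path):
        frag = assign_charges(build_tail(None, "DKG"))
        path = tmp_path / "tail.pqr"
        write_pqr(frag, path)
        back = read_pqr(path)
        np.testing.assert_allclose(back.charge, frag.charge, atol=1e-4)
        np.testing.assert_allclose(back.radius, frag.radius, atol=1e-4)
        s2 = assign_charges(frag, model="pqr", pqr_source=back)
        np.testing.assert_allclose(s2.charge, frag.charge, atol=1e-4)


class TestOffsets:
    def test_zero_distance_is_identity(self, two_group_structure):
        out = offset_ligand(two_group_structure, "ligand", 0.0)
        np.testing.assert_array_equal(out.coords, two_group_structure.coords)

    def test_center_of_mass_displaced_exactly(self, two_group_structure):
        out = offset_ligand(two_group_structure, "ligand", 5.0)
        idx = two_group_structure.group("ligand")
        shift = out.coords[idx].mean(0) - two_group_structure.coords[idx].mean(0)
        np.testing.assert_allclose(shift, [0.0, 5.0, 0.0], atol=1e-12)
        np.testing.assert_array_equal(
            out.coords[two_group_structure.group("tail")],
            two_group_structure.coords[two_group_structure.group("tail")])

    @pytest.mark.parametrize("a,b", [(3.0, 4.0), (5.0, 15.0), (0.0, 7.5)])
    def test_offsets_are_additive(self, two_group_structure, a, b):
        one = offset_ligand(offset_ligand(two_group_structure, "ligand", a),
                            "ligand", b)
        both = offset_ligand(two_group_structure, "ligand", a + b)
        np.testing.assert_allclose(one.coords, both.coords, atol=1e-12)

    def test_intra_ligand_distances_preserved(self, two_group_structure, rng):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        idx = two_group_structure.group("ligand")
        before = two_group_structure.coords[idx]
        after = offset_ligand(two_group_structure, "ligand", 17.3,
                              axis=axis).coords[idx]
        d0 = np.linalg.norm(before[:, None] - before[None], axis=-1)
        d1 = np.linalg.norm(after[:, None] - after[None], axis=-1)
        np.testing.assert_allclose(d0, d1, atol=1e-10)

    def test_non_unit_axis_rejected(self, two_group_structure):
        with pytest.raises(ValueError):
            offset_ligand(two_group_structure, "ligand", 5.0, axis=(0, 2, 0))

    def test_empty_group_rejected(self, two_group_structure):
        with pytest.raises(InvalidSelectionError):
            offset_ligand(two_group_structure, np.array([], dtype=int), 5.0)

    def test_default_ladder_generates_six_structures(self, two_group_structure):
        out = offset_ladder_structures(two_group_structure, "ligand")
        assert sorted(out) == [5.0, 15.0, 25.0, 35.0, 45.0, 55.0]

    def test_ladder_validation(self):
        with pytest.raises(ValueError):
            OffsetLadder(distances=(5.0, 5.0))
        with pytest.raises(ValueError):
            OffsetLadder(axis=(0, 0, 2))
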