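import logging

import numpy as np
import pytest

from rnassess import (MappingError, ParseError, Structure, build_duplex,
                      map_residues, read_structure, select_atoms, write_pdb)
from rnassess.structure_io import EmptyStructureError, standard_parent

MINI_PDB = """\
ATOM      1  C1'   G A   1      -2.477   5.399   0.000  1.00 30.00           C
ATOM      2  N9    G A   1      -1.289   4.551   0.000  1.00 30.00           N
ATOM      3  C8    G A   1       0.023   4.962   0.000  1.00 30.00           C
END
"""

MINI_CIF = """\
data_mini
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_comp_id
_atom_site.auth_asym_id
_atom_site.auth_atom_id
_atom_site.pdbx_PDB_model_num
ATOM 1 C "C1'" . G A 1 1 ? -2.477 5.399 0.000 1.00 30.00 1 G A "C1'" 1
ATOM 2 N N9 . G A 1 1 ? -1.289 4.551 0.000 1.00 30.00 1 G A N9 1
ATOM 3 C C8 . G A 1 1 ? 0.023 4.962 0.000 1.00 30.00 1 G A C8 1
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  C1'   G A   1      -2.477   5.399   0.000  1.00 30.00           C
ATOM      2  N9    G A   1      -1.289   4.551   0.000  1.00 30.00           N
ENDMDL
MODEL        2
ATOM      1  C1'   G A   1       9.000   9.000   9.000  1.00 30.00           C
ATOM      2  N9    G A   1       8.000   8.000   8.000  1.00 30.00           N
ENDMDL
END
"""

ALTLOC_PDB = """\
ATOM      1  C1'A  G A   1      -2.477   5.399   0.000  0.30 30.00           C
ATOM      2  C1'B  G A   1       1.000   1.000   1.000  0.70 30.00           C
ATOM      3  N9    G A   1      -1.289   4.551   0.000  1.00 30.00           N
END
"""


class TestReadStructure:
    def test_mini_pdb_counts(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINI_PDB)
        s = read_structure(p)
        assert len(s.chains) == 1
        residues = list(s.residues())
        assert len(residues) == 1
        assert len(residues[0].atoms) == 3
        assert residues[0].key == ("A", 1, "")
        assert residues[0].standard_parent == "G"

    def test_mmcif_equivalent_to_pdb(self, tmp_path):
        pp = tmp_path / "mini.pdb"
        pc = tmp_path / "mini.cif"
        pp.write_text(MINI_PDB)
        pc.write_text(MINI_CIF)
        sp = read_structure(pp)
        sc = read_structure(pc)
        assert [r.key for r in sp.residues()] == [r.key for r in sc.residues()]
        for rp, rc in zip(sp.residues(), sc.residues()):
            assert [a.name for a in rp.atoms] == [a.name for a in rc.atoms]
            for ap, ac in zip(rp.atoms, rc.atoms):
                assert np.allclose(ap.position, ac.position, atol=1e-6)

    def test_two_models_keeps_first_and_warns(self, tmp_path, caplog):
        p = tmp_path / "two.pdb"
        p.write_text(TWO_MODEL_PDB)
        with caplog.at_level(logging.WARNING):
            s = read_structure(p)
        res = next(s.residues())
        assert np.allclose(res.atom("C1'").position, [-2.477, 5.399, 0.0])
        assert any("MODEL" in rec.message for rec in caplog.records)

    def test_altloc_resolved_by_occupancy(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        s = read_structure(p)
        res = next(s.residues())
        assert len(res.atoms) == 2  # one C1' conformer + N9
        assert np.allclose(res.atom("C1'").position, [1.0, 1.0, 1.0])

    def test_waters_dropped(self, tmp_path):
        text = MINI_PDB.replace("END\n", "") + (
            "HETATM    4  O   HOH A 101      0.000   0.000   0.000"
            "  1.00 30.00           O\nEND\n")
        p = tmp_path / "wat.pdb"
        p.write_text(text)
        s = read_structure(p)
        assert all(r.res_name != "HOH" for r in s.residues())

    def test_hetero_ligand_flagged(self, tmp_path):
        text = MINI_PDB.replace("END\n", "") + (
            "HETATM    4  S   SAM A 201      0.000   0.000   9.000"
            "  1.00 30.00           S\nEND\n")
        p = tmp_path / "lig.pdb"
        p.write_text(text)
        s = read_structure(p)
        lig = [r for r in s.residues() if r.res_name == "SAM"]
        assert len(lig) == 1 and lig[0].is_hetero
        assert not lig[0].is_nucleotide

    def test_missing_file(self, tmp_path):
        with pytest.raises(ParseError):
            read_structure(tmp_path / "nope.pdb")

    def test_empty_structure(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("HETATM    1  O   HOH A   1      0.000   0.000   0.000"
                     "  1.00  0.00           O\nEND\n")
        with pytest.raises(EmptyStructureError):
            read_structure(p)


class TestRoundTrip:
    def test_pdb_round_trip(self, tmp_path, duplex12):
        s, _ = duplex12
        path = tmp_path / "rt.pdb"
        write_pdb(s, path)
        s2 = read_structure(path)
        assert [r.key for r in s.residues()] == [r.key for r in s2.residues()]
        for r1, r2 in zip(s.residues(), s2.residues()):
            assert [a.name for a in r1.atoms] == [a.name for a in r2.atoms]
            for a1, a2 in zip(r1.atoms, r2.atoms):
                assert np.allclose(a1.position, a2.position, atol=1e-3)
                assert a1.element == a2.element


class TestStandardParent:
    @pytest.mark.parametrize("name,parent", [
        ("A", "A"), ("G", "G"), ("PSU", "U"), ("2MG", "G"), ("OMC", "C"),
        ("ALA", "A"), ("SAM", None), ("MG", None)])
    def test_table(self, name, parent):
        assert standard_parent(name) == parent


class TestSelectAtoms:
    def test_heavy_excludes_hydrogens(self, duplex8):
        s, _ = duplex8
        res = next(s.residues()).atoms
        from rnassess.structure_io import Atom, Residue
        r = Residue("A", 1, "", "G",
                    atoms=[*[a for a in res],
                           Atom("H1'", "H", [0, 0, 0])])
        names = [a.name for a in select_atoms(r, "heavy")]
        assert "H1'" not in names

    def test_purine_base_ring(self, duplex8):
        s, _ = duplex8
        g = next(r for r in s.residues() if r.res_name == "G")
        names = [a.name for a in select_atoms(g, "base")]
        assert set(names) == {"N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"}
        assert len(names) == 9

    def test_backbone_missing_phosphate(self, duplex8):
        s, _ = duplex8
        res = next(s.residues())
        from rnassess.structure_io import Residue
        r = Residue("A", 1, "", res.res_name,
                    atoms=[a for a in res.atoms
                           if a.name not in ("P", "OP1", "OP2")])
        names = {a.name for a in select_atoms(r, "backbone")}
        assert "P" not in names and "OP1" not in names
        assert {"O5'", "C5'", "C4'", "C3'", "O3'"} <= names

    def test_canonical_ordering_is_stable(self, duplex8):
        s, _ = duplex8
        res = next(s.residues())
        shuffled = res.atoms[::-1]
        from rnassess.structure_io import Residue
        r2 = Residue("A", 1, "", res.res_name, atoms=shuffled)
        assert ([a.name for a in select_atoms(res, "heavy")]
                == [a.name for a in select_atoms(r2, "heavy")])


def _brute_force_offset_mapping(model, reference):
    """Oracle: best constant-offset identifier match per chain."""
    pairs = []
    for cid_m, res_m in model.chains:
        best = None
        for cid_r, res_r in reference.chains:
            for off in range(-200, 201):
                cand = []
                ref_by_num = {(r.seq_number): r for r in res_r}
                for m in res_m:
                    r = ref_by_num.get(m.seq_number - off)
                    if r is not None and r.standard_parent == m.standard_parent:
                        cand.append((m.key, r.key))
                if best is None or len(cand) > len(best):
                    best = cand
        pairs.extend(best or [])
    return pairs


class TestMapResidues:
    def test_identity(self, duplex12):
        s, _ = duplex12
        m = map_residues(s, s, strategy="identifier")
        assert m.coverage == 1.0
        assert all(a == b for a, b in m.pairs)

    def test_self_identifier_always_identity(self, duplex8):
        s, _ = duplex8
        m = map_residues(s, s)
        assert m.strategy == "identifier"
        assert sorted(m.pairs) == [(r.key, r.key) for r in s.residues()]

    def test_reference_missing_residues(self, duplex12):
        s, _ = duplex12
        ref = s.copy()
        new_chains = []
        for cid, residues in ref.chains:
            if cid == "A":
                residues = [r for r in residues if r.seq_number not in (5, 6, 7)]
            new_chains.append((cid, residues))
        ref = Structure(id="ref", chains=new_chains)
        m = map_residues(s, ref, strategy="identifier")
        n_total = sum(1 for _ in s.residues())
        assert len(m) == n_total - 3
        mapped_ref = {r for _, r in m.pairs}
        for num in (5, 6, 7):
            assert ("A", num, "") not in mapped_ref

    def test_offset_alignment_recovers_all(self, duplex12):
        s, _ = duplex12
        model = s.copy()
        for _, residues in model.chains:
            for r in residues:
                r.seq_number += 10
        model = Structure(id="m", chains=model.chains)
        m = map_residues(model, s, strategy="alignment")
        oracle = _brute_force_offset_mapping(model, s)
        assert sorted(m.pairs) == sorted(oracle)
        assert len(m) == sum(1 for _ in s.residues())

    def test_alignment_invariant_to_offset(self, duplex8):
        s, _ = duplex8
        results = []
        for off in (0, 7, 100):
            model = s.copy()
            for _, residues in model.chains:
                for r in residues:
                    r.seq_number += off
            model = Structure(id=f"m{off}", chains=model.chains)
            m = map_residues(model, s, strategy="alignment")
            results.append([(mk[0], mk[1] - off, mk[2], rk) for mk, rk in m.pairs])
        assert results[0] == results[1] == results[2]

    def test_low_coverage_raises(self, duplex12):
        s, _ = duplex12
        other, _ = build_duplex("AAAAAAAAAAAA")
        with pytest.raises(MappingError):
            map_residues(other, s, strategy="identifier", min_coverage=0.9)
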