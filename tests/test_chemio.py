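import io

import numpy as np
import pytest

from mgvs.chemio import (
    MoleculeParseError,
    ReceptorParseError,
    ReceptorStructure,
    compute_properties,
    parse_molecule,
    read_receptor,
    read_smiles_file,
    sa_score,
    write_receptor_pdb,
    write_smiles_file,
)
from mgvs.synthfix import make_flat_receptor


def test_parse_smiles_canonicalizes():
    rec = parse_molecule("OCC", "m1")
    assert rec.smiles == parse_molecule("CCO", "m2").smiles
    assert rec.heavy_atoms == 3
    assert rec.id == "m1"


def test_parse_errors_name_the_record():
    with pytest.raises(MoleculeParseError, match="bad1"):
        parse_molecule("C(C)(C)(C)(C)C", "bad1")  # 5-valent carbon
    with pytest.raises(MoleculeParseError, match="bad2"):
        parse_molecule("not_a_smiles", "bad2")
    with pytest.raises(MoleculeParseError, match="bad3"):
        parse_molecule("   ", "bad3")


def test_parse_molblock():
    from rdkit import Chem

    block = Chem.MolToMolBlock(Chem.MolFromSmiles("c1ccccc1"))
    rec = parse_molecule(block, "benz")
    assert rec.smiles == "c1ccccc1"


def test_smiles_file_round_trip(tmp_path):
    recs = [parse_molecule(s, f"m{i}") for i, s in enumerate(["CCO", "c1ccccc1", "CC(=O)O"])]
    path = tmp_path / "x.smi"
    write_smiles_file(recs, path)
    back = read_smiles_file(path)
    assert [(r.id, r.smiles) for r in back] == [(r.id, r.smiles) for r in recs]


def test_smiles_file_skips_comments_and_blank_lines():
    recs = read_smiles_file(io.StringIO("# header\n\nCCO m1\n"))
    assert len(recs) == 1 and recs[0].id == "m1"


def test_properties_sanity():
    p = compute_properties(parse_molecule("CC(=O)Nc1ccc(O)cc1", "apap"))
    assert abs(p.mw - 151.16) < 0.5
    assert p.hbd == 2 and p.hba == 2
    assert 0.0 <= p.qed <= 1.0
    assert 1.0 <= p.sa <= 10.0


def test_sa_score_monotone_in_complexity():
    simple = parse_molecule("CCO", "a").mol
    ring = parse_molecule("C1CCCC1C", "b").mol
    caged = parse_molecule("C1C2CC3CC1CC(C2)C3", "c").mol  # bridged polycycle
    assert 1.0 <= sa_score(simple) < sa_score(ring) < sa_score(caged) <= 10.0


def _pdb_text(rec):
    buf = io.StringIO()
    write_receptor_pdb(rec, buf)
    return buf.getvalue()


def test_receptor_pdb_round_trip():
    rec = make_flat_receptor()
    text = _pdb_text(rec)
    back = read_receptor(text, box_center=rec.box_center, box_edge=rec.box_edge)
    assert len(back.atoms) == len(rec.atoms)
    assert [a.atom_id for a in back.atoms] == [a.atom_id for a in rec.atoms]
    assert np.allclose(back.coords(), rec.coords(), atol=1.5e-3)  # PDB has 3 decimals


def test_receptor_drops_waters_and_hetero():
    text = (
        "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N\n"
        "HETATM    2  O   HOH A  99       5.000   0.000   0.000  1.00  0.00           O\n"
        "HETATM    3  C1  LIG A 100       6.000   0.000   0.000  1.00  0.00           C\n"
        "END\n"
    )
    rec = read_receptor(text, box_center=(0, 0, 0))
    assert len(rec.atoms) == 1 and rec.atoms[0].resname == "GLY"


def test_receptor_attaches_explicit_polar_hydrogens():
    text = (
        "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N\n"
        "ATOM      2  H   GLY A   1       0.000   0.000   1.010  1.00  0.00           H\n"
        "END\n"
    )
    rec = read_receptor(text, box_center=(0, 0, 0))
    assert len(rec.atoms) == 1  # H is attached, not a standalone atom
    assert 0 in rec.polar_h and len(rec.polar_h[0]) == 1


def test_box_membership_and_validation():
    rec = make_flat_receptor(box_edge=10.0)
    assert rec.in_box(rec.box_center + 4.9)
    assert not rec.in_box(rec.box_center + np.array([5.1, 0, 0]))
    with pytest.raises(ValueError):
        ReceptorStructure(atoms=[], box_center=np.zeros(3), box_edge=0.0)
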