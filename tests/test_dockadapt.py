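import math

import numpy as np
import pytest
from rdkit import Chem

from mgvs.chemio import parse_molecule
from mgvs.dockadapt import (
    ConformerError,
    DockingResult,
    EngineError,
    best_result,
    cluster_conformers,
    delta_vina,
    generate_conformers,
    parse_vina_output,
    relax,
    score_pose,
    vina_efficiency,
    write_poses_sdf,
)


@pytest.fixture(scope="module")
def flexible():
    return parse_molecule("CCCCCCO", "hexanol")


def test_conformers_deterministic_for_fixed_seed(flexible):
    a = generate_conformers(flexible, n=5, seed=7)
    b = generate_conformers(flexible, n=5, seed=7)
    assert a.n_conformers == b.n_conformers
    for i in range(a.n_conformers):
        assert np.allclose(a.coords(i), b.coords(i))


def test_conformer_error_names_molecule():
    # an impossible embedding target is hard to construct; use n=0 instead
    rec = parse_molecule("CCO", "tiny")
    with pytest.raises(ConformerError, match="tiny"):
        generate_conformers(rec, n=0, seed=0)


def test_clustering_collapses_duplicate_conformers(flexible):
    cs = generate_conformers(flexible, n=4, seed=3)
    # duplicate every conformer exactly; clustering must remove the copies
    dup = Chem.Mol(cs.mol_h)
    for conf in list(cs.mol_h.GetConformers()):
        dup.AddConformer(Chem.Conformer(conf), assignId=True)
    cs_dup = type(cs)(rec=cs.rec, mol_h=dup, energies=cs.energies * 2)
    clustered = cluster_conformers(cs_dup, rmsd_cutoff=0.5)
    assert clustered.n_conformers <= cs.n_conformers


def test_relax_lowers_energy_vs_single_point(flexible):
    from rdkit.Chem import AllChem

    raw = generate_conformers(flexible, n=3, seed=1)
    props = AllChem.MMFFGetMoleculeProperties(raw.mol_h)
    start = [
        AllChem.MMFFGetMoleculeForceField(raw.mol_h, props, confId=c.GetId()).CalcEnergy()
        for c in raw.mol_h.GetConformers()
    ]
    cs = relax(raw)
    assert len(cs.energies) == cs.n_conformers
    assert all(math.isfinite(e) for e in cs.energies)
    assert all(e <= s + 1e-6 for s, e in zip(start, cs.energies))


def test_score_pose_one_result_per_conformer(flexible, flat_receptor, mock_engine):
    cs = relax(cluster_conformers(generate_conformers(flexible, n=4, seed=2)))
    results = score_pose(cs, flat_receptor, mock_engine)
    assert len(results) == cs.n_conformers
    assert {r.mol_id for r in results} == {"hexanol"}
    assert {r.engine for r in results} == {"mock"}
    for r in results:
        assert math.isfinite(r.vina)
        assert r.heavy_atoms == 7
        # mock engine translates the pose into the box
        assert flat_receptor.in_box(r.pose_coords().mean(axis=0))


def test_best_result_min_vina_ties_by_conformer_index():
    def res(v, i):
        return DockingResult(mol_id="m", pose_mol=Chem.MolFromSmiles("C"),
                             vina=v, heavy_atoms=1, engine="mock", conformer_idx=i)

    assert best_result([res(-5.0, 0), res(-6.0, 1)]).conformer_idx == 1
    assert best_result([res(-6.0, 2), res(-6.0, 0)]).conformer_idx == 0
    with pytest.raises(ValueError):
        best_result([])


def test_vina_efficiency_and_delta():
    assert vina_efficiency(-8.0, 20) == -0.4
    with pytest.raises(ValueError):
        vina_efficiency(-8.0, 0)
    assert delta_vina(-9.0, -8.0) == -1.0
    assert delta_vina(-7.5, -8.0) == 0.5


def test_parse_vina_stdout_table():
    text = (
        "mode |   affinity | dist from best mode\n"
        "     | (kcal/mol) | rmsd l.b.| rmsd u.b.\n"
        "-----+------------+----------+----------\n"
        "   1       -7.1         0.000      0.000\n"
        "   2       -6.5         1.402      2.110\n"
    )
    assert parse_vina_output(text) == -7.1


def test_parse_vina_remark_lines():
    text = (
        "REMARK VINA RESULT:    -6.2      0.000      0.000\n"
        "REMARK VINA RESULT:    -6.9      1.300      2.500\n"
    )
    assert parse_vina_output(text) == -6.9


def test_parse_vina_rejects_malformed_output():
    with pytest.raises(EngineError, match="badmol"):
        parse_vina_output("REMARK VINA RESULT: oops\n", "badmol")
    with pytest.raises(EngineError, match="no score"):
        parse_vina_output("nothing here\n")
    with pytest.raises(EngineError, match="malformed"):
        parse_vina_output("-----+----\n   1   not_a_number\n")


def test_write_poses_sdf_round_trip(flexible, flat_receptor, mock_engine, tmp_path):
    cs = generate_conformers(flexible, n=2, seed=0)
    results = score_pose(cs, flat_receptor, mock_engine)
    path = tmp_path / "poses.sdf"
    write_poses_sdf(results, path)
    back = [m for m in Chem.SDMolSupplier(str(path), removeHs=False)]
    assert len(back) == len(results)
    for mol, r in zip(back, results):
        assert mol.GetProp("_Name") == r.mol_id
        assert abs(float(mol.GetProp("vina")) - r.vina) < 1e-3
        assert np.allclose(mol.GetConformer().GetPositions(), r.pose_coords(), atol=1e-3)
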