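import numpy as np
import pytest
from rdkit import Chem

from mgvs.chemio import parse_molecule
from mgvs.gedsearch import anonymize, exact_ged
from mgvs.synthfix import (
    InteractionSpec,
    MockEngine,
    make_flat_receptor,
    make_generated_set,
    make_library,
    mock_score,
    plant_complex,
)

from conftest import TINY_SEEDS


def test_library_is_deterministic():
    a = make_library(TINY_SEEDS, edit_radius=2, n_members=30, rng_seed=5)
    b = make_library(TINY_SEEDS, edit_radius=2, n_members=30, rng_seed=5)
    assert [(m.id, m.smiles) for m in a.records()] == [(m.id, m.smiles) for m in b.records()]
    c = make_library(TINY_SEEDS, edit_radius=2, n_members=30, rng_seed=6)
    assert [m.smiles for m in a.records()] != [m.smiles for m in c.records()]


def test_library_provenance_bounds_ged():
    lib = make_library(TINY_SEEDS, edit_radius=2, n_members=25, rng_seed=1)
    seed_graphs = {
        f"seed{k}": anonymize(parse_molecule(s, f"seed{k}")) for k, s in enumerate(TINY_SEEDS)
    }
    for rec, (seed_id, ops) in lib.members:
        d = exact_ged(seed_graphs[seed_id], anonymize(rec), max_d=len(ops))
        assert d is not None and d <= len(ops)


def test_library_members_are_valid_single_fragments():
    lib = make_library(TINY_SEEDS, edit_radius=2, n_members=40, rng_seed=2)
    for rec in lib.records():
        assert len(Chem.GetMolFrags(rec.mol)) == 1
        assert rec.heavy_atoms >= 2


def test_generated_set_ids_and_determinism():
    gen = make_generated_set(n=10, rng_seed=3)
    assert [r.id for r in gen] == [f"gen{i}" for i in range(10)]
    again = make_generated_set(n=10, rng_seed=3)
    assert [r.smiles for r in gen] == [r.smiles for r in again]


def test_mock_score_depends_only_on_canonical_smiles(flat_receptor):
    a = parse_molecule("OCC", "a")
    b = parse_molecule("CCO", "b")
    assert mock_score(a, None, flat_receptor, 0) == mock_score(b, None, flat_receptor, 0)
    assert mock_score(a, None, flat_receptor, 0) != mock_score(a, None, flat_receptor, 1)


def test_mock_score_size_term_and_perturbation_bounds(flat_receptor):
    rec = parse_molecule("CCCCCCCCCC", "decane")  # 10 heavy atoms
    s = mock_score(rec, None, flat_receptor, 0, perturbation=1.5)
    assert abs(s - (-3.0)) <= 1.5


def test_mock_score_out_of_box_penalty(flat_receptor):
    rec = parse_molecule("CCO", "m")
    inside = np.tile(flat_receptor.box_center, (3, 1))
    outside = inside + 100.0
    s_in = mock_score(rec, inside, flat_receptor, 0)
    s_out = mock_score(rec, outside, flat_receptor, 0)
    assert s_out == pytest.approx(s_in + 10.0)


def test_mock_score_overrides(flat_receptor):
    rec = parse_molecule("CCO", "m")
    s = mock_score(rec, None, flat_receptor, 0, score_overrides={rec.smiles: -42.0})
    assert s == -42.0


def test_mock_engine_docks_into_box(flat_receptor):
    from mgvs.dockadapt import generate_conformers

    cs = generate_conformers(parse_molecule("CCCCO", "m"), n=1, seed=0)
    engine = MockEngine(rng_seed=0)
    score, coords = engine.dock(cs.rec, cs.mol_h, 0, flat_receptor)
    assert np.allclose(coords.mean(axis=0), flat_receptor.box_center, atol=1e-9)
    assert np.isfinite(score)


def test_flat_receptor_shape():
    rec = make_flat_receptor(box_edge=12.0)
    assert rec.box_edge == 12.0
    assert {a.resname for a in rec.atoms} == {"GLY", "ALA", "SER"}
    # residues sit outside the box so they never collide with docked poses
    assert all(not rec.in_box(a.xyz) for a in rec.atoms)


def test_plant_complex_realizes_requested_geometry():
    c = plant_complex([InteractionSpec("hbond", 3.3, 150.0), InteractionSpec("salt_bridge", 3.5)])
    by_kind = {item["kind"]: item for item in c.intended}
    assert by_kind["hbond"]["realized_distance"] == pytest.approx(3.3, abs=1e-9)
    assert by_kind["hbond"]["realized_angle"] == pytest.approx(150.0, abs=1e-9)
    assert by_kind["salt_bridge"]["realized_distance"] == pytest.approx(3.5, abs=1e-9)
    c.self_check()  # no unintended specific contacts


def test_plant_complex_rejects_unknown_kind():
    with pytest.raises(ValueError, match="unknown interaction kind"):
        plant_complex([InteractionSpec("covalent", 1.5)])


def test_planted_pose_lies_in_box(all_kinds_complex):
    rec = all_kinds_complex.receptor
    coords = all_kinds_complex.pose.pose_coords()
    assert rec.in_box(coords.mean(axis=0))
    assert all(rec.in_box(p) for p in coords)
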