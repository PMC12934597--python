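import numpy as np
import pytest

from mgvs.plinter import (
    SPECIFIC_KINDS,
    Interaction,
    InteractionCutoffs,
    add_polar_hydrogens,
    detect_interactions,
    match_interactions,
    shared_interaction_stats,
    write_interactions_tsv,
)
from mgvs.synthfix import InteractionSpec, plant_complex

from conftest import interaction_signature


def ix(kind, lig, prot, res=("A", 1, "", "GLY"), dist=3.0, subtype=""):
    return Interaction(
        kind=kind, ligand_atoms=frozenset(lig), protein_atoms=frozenset(prot),
        residue_key=res, distance=dist, subtype=subtype,
    )


def test_cutoffs_validation_and_scaling():
    with pytest.raises(ValueError):
        InteractionCutoffs(hbond_dist=0.0)
    with pytest.raises(ValueError):
        InteractionCutoffs(hbond_angle=200.0)
    scaled = InteractionCutoffs().scaled(1.2)
    assert scaled.hbond_dist == pytest.approx(3.5 * 1.2)
    assert scaled.hbond_angle == 120.0  # angles not scaled


def test_add_polar_hydrogens_geometry(flat_receptor):
    bare = type(flat_receptor)(
        atoms=list(flat_receptor.atoms), box_center=flat_receptor.box_center,
        box_edge=flat_receptor.box_edge, polar_h={}, name=flat_receptor.name,
    )
    rec = add_polar_hydrogens(bare)
    assert rec.polar_h  # some donors got hydrogens
    for idx, hs in rec.polar_h.items():
        d_xyz = rec.atoms[idx].xyz
        elem = rec.atoms[idx].element
        expected = {"N": 1.01, "O": 0.96, "S": 1.34}[elem]
        for h in hs:
            assert np.linalg.norm(h - d_xyz) == pytest.approx(expected, abs=1e-6)


def test_detects_every_planted_kind(all_kinds_complex):
    ints = detect_interactions(all_kinds_complex.pose, all_kinds_complex.receptor)
    kinds = {i.kind for i in ints}
    assert kinds >= {"hbond", "hydrophobic", "salt_bridge", "pi_stack", "pi_cation"}
    subtypes = {i.subtype for i in ints if i.kind == "pi_stack"}
    assert subtypes == {"parallel", "perpendicular"}
    # realized distances match the planted geometry
    by_kind = {}
    for i in ints:
        by_kind.setdefault(i.kind, []).append(i)
    assert min(i.distance for i in by_kind["hbond"]) == pytest.approx(3.2, abs=1e-6)
    assert min(i.distance for i in by_kind["salt_bridge"]) == pytest.approx(3.8, abs=1e-6)


def test_detection_results_deduplicated_and_sorted(all_kinds_complex):
    ints = detect_interactions(all_kinds_complex.pose, all_kinds_complex.receptor)
    keys = [(i.kind, i.ligand_atoms, i.protein_atoms) for i in ints]
    assert len(keys) == len(set(keys))
    order = [(i.kind, i.distance) for i in ints]
    assert order == sorted(order)


def test_distance_boundaries_inclusive():
    at = plant_complex([InteractionSpec("hydrophobic", 3.8)])
    ints = detect_interactions(at.pose, at.receptor)
    assert any(i.kind == "hydrophobic" for i in ints)
    beyond = plant_complex([InteractionSpec("hydrophobic", 3.82)])
    ints = detect_interactions(beyond.pose, beyond.receptor)
    assert not any(i.kind == "hydrophobic" for i in ints)


def test_hbond_angle_boundary():
    good = plant_complex([InteractionSpec("hbond", 3.2, 121.0)])
    assert any(i.kind == "hbond" for i in detect_interactions(good.pose, good.receptor))
    bad = plant_complex([InteractionSpec("hbond", 3.2, 119.0)])
    assert not any(i.kind == "hbond" for i in detect_interactions(bad.pose, bad.receptor))


def test_pi_stack_angle_windows():
    tilted = plant_complex([InteractionSpec("pi_stack", 3.6, 40.0, subtype="parallel")])
    # 40 deg: outside the parallel window (<=30) and the perpendicular one (>=50)
    ints = [i for i in detect_interactions(tilted.pose, tilted.receptor) if i.kind == "pi_stack"]
    assert ints == []


def test_match_levels_and_scopes():
    res_a, res_b = ("A", 1, "", "GLY"), ("A", 2, "", "SER")
    q = [ix("hbond", {0}, {"A:1::GLY:O"}, res_a), ix("hydrophobic", {3}, {"A:2::SER:CB"}, res_b)]
    # hit reproduces the hbond at the same residue but a different atom
    h = [ix("hbond", {0}, {"A:1::GLY:N"}, res_a)]
    res_level = match_interactions(q, h, level="residue", scope="all")
    assert (res_level.query_count, res_level.shared) == (2, 1)
    assert res_level.any_shared and not res_level.all_shared
    atom_level = match_interactions(q, h, level="atom", scope="all")
    assert atom_level.shared == 0
    specific = match_interactions(q, h, level="residue", scope="specific-only")
    assert (specific.query_count, specific.shared) == (1, 1)
    assert specific.all_shared
    assert specific.per_kind == {"hbond": (1, 1)}


def test_match_rejects_unknown_level_and_scope():
    with pytest.raises(ValueError, match="level"):
        match_interactions([], [], level="bond")
    with pytest.raises(ValueError, match="scope"):
        match_interactions([], [], scope="some")


def test_specific_kinds_exclude_hydrophobic():
    assert "hydrophobic" not in SPECIFIC_KINDS
    assert SPECIFIC_KINDS == {"hbond", "salt_bridge", "pi_cation", "pi_stack"}


def test_shared_interaction_stats_requires_hits():
    with pytest.raises(ValueError):
        shared_interaction_stats([])
    with pytest.raises(ValueError):
        shared_interaction_stats([("q1", [])])


def test_write_interactions_tsv(all_kinds_complex, tmp_path):
    import pandas as pd

    ints = detect_interactions(all_kinds_complex.pose, all_kinds_complex.receptor)
    path = tmp_path / "ints.tsv"
    write_interactions_tsv({"pose1": ints}, path)
    df = pd.read_csv(path, sep="\t")
    assert len(df) == len(ints)
    assert set(df["kind"]) == {i.kind for i in ints}


def test_rigid_motion_invariance(all_kinds_complex):
    from conftest import apply_rigid_motion, random_rigid_motion

    base = interaction_signature(
        detect_interactions(all_kinds_complex.pose, all_kinds_complex.receptor), ndigits=4
    )
    rng = np.random.default_rng(11)
    for _ in range(3):
        q, t = random_rigid_motion(rng)
        rec, pose = apply_rigid_motion(all_kinds_complex, q, t)
        moved = interaction_signature(detect_interactions(pose, rec), ndigits=4)
        assert moved == base
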