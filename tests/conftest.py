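import numpy as np
import pytest
from rdkit import Chem, RDLogger

from mgvs.chemio import MoleculeRecord, ReceptorAtom, ReceptorStructure, parse_molecule
from mgvs.dockadapt import DockingResult
from mgvs.synthfix import InteractionSpec, MockEngine, make_flat_receptor, plant_complex

RDLogger.DisableLog("rdApp.*")


TINY_SEEDS = ["CCCCO", "c1ccccc1", "CC(C)CO", "C1CCCC1C", "CCOCC", "c1ccncc1"]


@pytest.fixture(scope="session")
def flat_receptor():
    return make_flat_receptor()


@pytest.fixture(scope="session")
def mock_engine():
    return MockEngine(rng_seed=0)


@pytest.fixture(scope="session")
def all_kinds_complex():
    """One planted complex exercising every interaction kind at
    comfortable (non-boundary) geometry."""
    return plant_complex(
        [
            InteractionSpec("hbond", 3.2, 160.0),
            InteractionSpec("hydrophobic", 3.5),
            InteractionSpec("salt_bridge", 3.8),
            InteractionSpec("pi_stack", 3.6, subtype="parallel"),
            InteractionSpec("pi_stack", 4.9, 70.0, subtype="perpendicular"),
            InteractionSpec("pi_cation", 3.7),
        ]
    )


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random proper rotation and a translation."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q, rng.uniform(-25.0, 25.0, 3)


def apply_rigid_motion(complex_, q, t):
    """Return (receptor, pose) with every coordinate mapped x -> qx + t."""
    rec = complex_.receptor
    atoms = [
        ReceptorAtom(
            name=a.name, resname=a.resname, chain=a.chain, resnum=a.resnum,
            icode=a.icode, element=a.element, xyz=q @ a.xyz + t,
        )
        for a in rec.atoms
    ]
    polar_h = {k: [q @ h + t for h in v] for k, v in rec.polar_h.items()}
    moved_rec = ReceptorStructure(
        atoms=atoms, box_center=q @ rec.box_center + t,
        box_edge=rec.box_edge, polar_h=polar_h, name=rec.name,
    )
    mol = Chem.Mol(complex_.pose.pose_mol)
    conf = mol.GetConformer()
    for i in range(mol.GetNumAtoms()):
        p = np.array(conf.GetAtomPosition(i))
        conf.SetAtomPosition(i, [float(x) for x in (q @ p + t)])
    pose = DockingResult(
        mol_id=complex_.pose.mol_id, pose_mol=mol, vina=complex_.pose.vina,
        heavy_atoms=complex_.pose.heavy_atoms, engine=complex_.pose.engine,
    )
    return moved_rec, pose


def interaction_signature(interactions, ndigits=6):
    """Hashable rigid-motion-invariant summary of an interaction list."""
    return sorted(
        (
            ix.kind,
            ix.subtype,
            tuple(sorted(ix.ligand_atoms)),
            tuple(sorted(ix.protein_atoms)),
            round(ix.distance, ndigits),
            None if ix.angle is None else round(ix.angle, max(ndigits - 2, 1)),
        )
        for ix in interactions
    )
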