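"""Synthetic inputs for exercising the screening pipeline: toy compound
libraries built by known edit sequences, planted protein-ligand
complexes with exactly realized interaction geometry, and a
deterministic mock docking engine.

Every fixture is regenerable from (specification, seed) alone.  The
mock engine's score is dominated by a size term (-0.3 kcal/mol per
heavy atom) plus a bounded pseudo-random perturbation, which reproduces
the well-known size bias of empirical docking scores and makes ligand
efficiency normalization meaningful in tests.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chemio import MoleculeRecord, ReceptorAtom, ReceptorStructure, parse_molecule
from .dockadapt import DockingResult
from .plinter import SPECIFIC_KINDS, InteractionCutoffs, detect_interactions
from .residues import get_template

__all__ = [
    "ToyLibrary",
    "InteractionSpec",
    "PlantedComplex",
    "MockEngine",
    "make_library",
    "make_generated_set",
    "make_flat_receptor",
    "plant_complex",
    "mock_score",
]


# --------------------------------------------------------------------------
# mock docking engine
# --------------------------------------------------------------------------


def mock_score(
    rec: MoleculeRecord,
    pose: np.ndarray | None,
    receptor: ReceptorStructure,
    rng_seed: int,
    perturbation: float = 1.5,
    score_overrides: dict | None = None,
) -> float:
    """Deterministic stand-in for an empirical docking score.

    score = -0.3 * heavy_atoms + U, with U a stable-hash pseudo-random
    value in [-perturbation, +perturbation] keyed on (canonical SMILES,
    receptor name, seed).  Identical molecules (same canonical SMILES)
    always score identically.  A pose whose centroid lies outside the
    docking box takes a +10 kcal/mol penalty, worse than any in-box
    pose of a comparable molecule.
    """
    smiles = rec.smiles
    if score_overrides and smiles in score_overrides:
        base = float(score_overrides[smiles])
    else:
        digest = hashlib.sha256(f"{smiles}|{receptor.name}|{rng_seed}".encode()).digest()
        u = int.from_bytes(digest[:8], "big") / 2**64  # uniform [0, 1)
        base = -0.3 * rec.heavy_atoms + perturbation * (2.0 * u - 1.0)
    if pose is not None and not receptor.in_box(np.asarray(pose).mean(axis=0)):
        base += 10.0
    return base


class MockEngine:
    """Docking-engine adapter around :func:`mock_score`.

    The "docking" move is a rigid translation of the conformer centroid
    to the box center, so poses always land in the box and the whole
    chain stays deterministic.
    """

    name = "mock"

    def __init__(self, rng_seed: int = 0, perturbation: float = 1.5, score_overrides: dict | None = None):
        self.rng_seed = int(rng_seed)
        self.perturbation = float(perturbation)
        self.score_overrides = dict(score_overrides) if score_overrides else None

    def dock(self, rec, mol_h, conf_idx, receptor):
        coords = np.array(mol_h.GetConformer(conf_idx).GetPositions())
        coords = coords - coords.mean(axis=0) + receptor.box_center
        score = mock_score(
            rec, coords, receptor, self.rng_seed,
            perturbation=self.perturbation, score_overrides=self.score_overrides,
        )
        return score, coords


def make_flat_receptor(name: str = "toybox", box_edge: float = 20.0) -> ReceptorStructure:
    """Minimal three-residue receptor used when only a docking box (not
    interaction geometry) is needed."""
    atoms = []
    for i, resname in enumerate(("GLY", "ALA", "SER"), start=1):
        tmpl = get_template(resname)
        shift = np.array([0.0, 0.0, 6.0 * i + 15.0])
        for nm in tmpl.atom_names:
            atoms.append(
                ReceptorAtom(
                    name=nm, resname=resname, chain="A", resnum=i, icode="",
                    element=nm[0], xyz=tmpl.coords[nm] + shift,
                )
            )
    return ReceptorStructure(atoms=atoms, box_center=np.zeros(3), box_edge=box_edge, name=name)


# --------------------------------------------------------------------------
# toy libraries
# --------------------------------------------------------------------------


@dataclass
class ToyLibrary:
    """Library members derived from seed compounds by recorded random
    edit sequences; the anonymous-graph GED of a member to its seed is
    at most the recorded edit count by construction."""

    seed_smiles: list[str]
    members: list[tuple[MoleculeRecord, tuple[str, tuple[str, ...]]]]
    build_seed: int

    def records(self) -> list[MoleculeRecord]:
        return [m for m, _ in self.members]


def _try_edit(mol: Chem.Mol, op: str, rng: np.random.Generator) -> Chem.Mol | None:
    """Apply one chemically valid edit; return the sanitized result or
    None if the chosen site does not admit the edit."""
    rw = Chem.RWMol(mol)
    n = rw.GetNumAtoms()
    if op == "add":
        cands = [a.GetIdx() for a in rw.GetAtoms() if a.GetImplicitValence() > 0]
        if not cands:
            return None
        tgt = int(rng.choice(cands))
        new = rw.AddAtom(Chem.Atom(6))
        rw.AddBond(tgt, new, Chem.BondType.SINGLE)
    elif op == "remove":
        if n < 4:
            return None
        cands = [a.GetIdx() for a in rw.GetAtoms() if a.GetDegree() == 1]
        if not cands:
            return None
        rw.RemoveAtom(int(rng.choice(cands)))
    elif op == "close":
        dm = Chem.GetDistanceMatrix(mol)
        pairs = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if dm[i, j] in (4, 5)
            and mol.GetAtomWithIdx(i).GetImplicitValence() > 0
            and mol.GetAtomWithIdx(j).GetImplicitValence() > 0
        ]
        if not pairs:
            return None
        i, j = pairs[int(rng.integers(len(pairs)))]
        rw.AddBond(int(i), int(j), Chem.BondType.SINGLE)
    elif op == "open":
        ri = mol.GetRingInfo()
        bonds = [
            b.GetIdx()
            for b in mol.GetBonds()
            if ri.NumBondRings(b.GetIdx()) > 0
            and b.GetBondType() == Chem.BondType.SINGLE
            and not b.GetIsAromatic()
        ]
        if not bonds:
            return None
        b = mol.GetBondWithIdx(int(rng.choice(bonds)))
        rw.RemoveBond(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
    else:
        raise ValueError(f"unknown edit op {op!r}")
    try:
        out = rw.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    if len(Chem.GetMolFrags(out)) != 1:
        return None
    return out


def make_library(
    seeds: list[str],
    edit_radius: int = 2,
    n_members: int = 100,
    rng_seed: int = 0,
) -> ToyLibrary:
    """Grow a toy library by applying random chemically valid edits
    (terminal atom add/remove, 5/6-ring open/close) to the seeds.

    Deterministic per ``rng_seed``; each member records its seed id and
    the applied edit sequence, whose length upper-bounds the true
    anonymous-graph GED to the seed.
    """
    rng = np.random.default_rng(rng_seed)
    seed_mols = []
    for k, smi in enumerate(seeds):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"invalid seed SMILES: {smi!r}")
        seed_mols.append((f"seed{k}", mol))
    members = []
    ops = np.array(["add", "remove", "close", "open"])
    for i in range(n_members):
        seed_id, seed_mol = seed_mols[int(rng.integers(len(seed_mols)))]
        mol = Chem.Mol(seed_mol)
        applied: list[str] = []
        n_edits = int(rng.integers(0, edit_radius + 1))
        for _ in range(n_edits):
            for _attempt in range(8):
                op = str(rng.choice(ops))
                edited = _try_edit(mol, op, rng)
                if edited is not None:
                    mol = edited
                    applied.append(op)
                    break
        rec = parse_molecule(Chem.MolToSmiles(mol), f"{seed_id}_m{i}", source="library:toy")
        members.append((rec, (seed_id, tuple(applied))))
    return ToyLibrary(seed_smiles=list(seeds), members=members, build_seed=rng_seed)


#: small drug-like scaffolds (5/6-membered rings only, no PAINS motifs,
#: masses inside the default drug-like window) used as a stand-in for a
#: generative model's output
GENERATED_POOL = [
    "Cc1ccccc1C(=O)Nc1ccccc1",
    "CC(=O)Nc1ccc(O)cc1",
    "CC(C)Cc1ccc(C(C)C(=O)O)cc1",
    "COc1ccc(CCN(C)C)cc1",
    "O=C(O)c1ccccc1Nc1ccccc1",
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "Clc1ccc(OCC(=O)N2CCCCC2)cc1",
    "c1ccc(Cn2ccnc2)cc1",
    "CCOC(=O)c1ccccc1N",
    "O=S(=O)(N)c1ccc(Cl)cc1",
    "CC(C)NCC(O)c1ccc(O)cc1",
    "c1ccc(-c2ccncc2)cc1",
    "O=C(Nc1ccccn1)c1ccco1",
    "CN1CCN(c2ccccc2)CC1",
    "CC(=O)Oc1ccccc1C(=O)O",
    "Cc1cccc(NC(=O)c2ccncc2)c1",
    "OCC1CCCN1Cc1ccccc1",
    "Fc1ccc(C2CCNCC2)cc1",
    "COc1cccc(C(=O)NCCO)c1",
    "Cc1nccn1Cc1ccccc1",
    "O=C(NC1CCCCC1)c1cccnc1",
    "CCN(CC)C(=O)c1ccc(N)cc1",
    "CSc1ccccc1C(=O)NC",
    "OC(c1ccccc1)c1ccccc1",
]


def make_generated_set(n: int = 20, rng_seed: int = 0) -> list[MoleculeRecord]:
    """A trivial "generator": sample drug-like scaffolds and perturb
    them with 0-2 methyl decorations.  Stands in for an SBDD model's
    output set at test scale."""
    rng = np.random.default_rng(rng_seed)
    records = []
    for i in range(n):
        smi = GENERATED_POOL[int(rng.integers(len(GENERATED_POOL)))]
        mol = Chem.MolFromSmiles(smi)
        for _ in range(int(rng.integers(0, 3))):
            edited = _try_edit(mol, "add", rng)
            if edited is not None:
                mol = edited
        records.append(parse_molecule(Chem.MolToSmiles(mol), f"gen{i}", source="generated"))
    return records


# --------------------------------------------------------------------------
# planted complexes
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class InteractionSpec:
    """One interaction to realize: kind, target distance (A), and for
    hydrogen bonds the D-H-A angle / for pi-stacking the plane angle
    flavor ("parallel" or "perpendicular")."""

    kind: str
    distance: float
    angle: float | None = None
    subtype: str = ""


@dataclass
class PlantedComplex:
    receptor: ReceptorStructure
    pose: DockingResult
    intended: list[dict]

    def self_check(self, tol_dist: float = 0.05, tol_angle: float = 2.0) -> None:
        """Verify realized geometry against the spec and confirm that
        detection at 1.2x-scaled distance cutoffs sees no directional
        (specific-kind) contacts beyond the intended (kind, residue)
        pairs.  Hydrophobic contacts are exempt from the cross-talk
        check: at inflated cutoffs a planted aromatic fragment grazes
        non-ring apolar carbons of its own site residue, which is
        physically correct and does not affect boundary tests."""
        for item in self.intended:
            if abs(item["realized_distance"] - item["spec_distance"]) > tol_dist:
                raise AssertionError(f"planted {item['kind']}: distance off target: {item}")
            if item.get("spec_angle") is not None and abs(
                item["realized_angle"] - item["spec_angle"]
            ) > tol_angle:
                raise AssertionError(f"planted {item['kind']}: angle off target: {item}")
        scaled = InteractionCutoffs().scaled(1.2)
        seen = {
            (ix.kind, ix.residue_key)
            for ix in detect_interactions(self.pose, self.receptor, scaled)
            if ix.kind in SPECIFIC_KINDS
        }
        allowed = {(item["kind"], item["residue_key"]) for item in self.intended}
        extra = seen - allowed
        if extra:
            raise AssertionError(f"unintended interactions within 1.2x cutoffs: {sorted(extra)}")


def _embed(smiles: str) -> Chem.Mol:
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = 7
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"embedding failed for fragment {smiles!r}")
    AllChem.MMFFOptimizeMolecule(mol)
    return mol


def _unit(v):
    return v / np.linalg.norm(v)


def _rotation_between(a, b) -> np.ndarray:
    """Rotation matrix sending unit vector a to unit vector b."""
    a, b = _unit(np.asarray(a, float)), _unit(np.asarray(b, float))
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any perpendicular axis
        perp = np.array([1.0, 0, 0]) if abs(a[0]) < 0.9 else np.array([0, 1.0, 0])
        v = _unit(np.cross(a, perp))
        return 2.0 * np.outer(v, v) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _place_residue(resname: str, anchor_names: list[str], site: np.ndarray):
    """Rigid-place a residue template so the centroid of ``anchor_names``
    sits at ``site`` with the residue bulk pointing along -x.
    Returns (coords dict name->xyz, h_coords dict name->[xyz])."""
    tmpl = get_template(resname)
    anchor = np.mean([tmpl.coords[n] for n in anchor_names], axis=0)
    bulk = np.mean([tmpl.coords[n] for n in tmpl.atom_names], axis=0)
    rot = _rotation_between(bulk - anchor, np.array([-1.0, 0.0, 0.0]))
    coords = {n: rot @ (tmpl.coords[n] - anchor) + site for n in tmpl.atom_names}
    h_coords = {
        n: [rot @ (h - anchor) + site for h in hs] for n, hs in tmpl.h_coords.items()
    }
    return tmpl, coords, h_coords


def _place_ring_residue(resname: str, ring_names: tuple[str, ...], site: np.ndarray, normal):
    """Place a residue so its aromatic ring center is at ``site`` with
    the ring normal along ``normal``."""
    tmpl = get_template(resname)
    ring_xyz = np.array([tmpl.coords[n] for n in ring_names])
    center = ring_xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(ring_xyz - center)
    rot = _rotation_between(vt[2], normal)
    coords = {n: rot @ (tmpl.coords[n] - center) + site for n in tmpl.atom_names}
    h_coords = {
        n: [rot @ (h - center) + site for h in hs] for n, hs in tmpl.h_coords.items()
    }
    return tmpl, coords, h_coords


def _frame_place(mol: Chem.Mol, origin_idx: int, axis_idx: int, plane_idx: int,
                 target_origin, target_axis_point, plane_toward) -> np.ndarray:
    """Rigid transform of a fragment conformer mapping atom
    ``origin_idx`` exactly onto ``target_origin`` and the
    origin->axis_idx direction exactly onto the direction toward
    ``target_axis_point``; the origin->plane_idx direction is rotated
    into the half-plane of ``plane_toward``."""
    xyz = np.array(mol.GetConformer().GetPositions())
    o = xyz[origin_idx]
    e1 = _unit(xyz[axis_idx] - o)
    p = xyz[plane_idx] - o
    e2 = _unit(p - np.dot(p, e1) * e1)
    e3 = np.cross(e1, e2)
    f1 = _unit(np.asarray(target_axis_point, float) - np.asarray(target_origin, float))
    q = np.asarray(plane_toward, float)
    q = q - np.dot(q, f1) * f1
    f2 = _unit(q)
    f3 = np.cross(f1, f2)
    rot = np.column_stack([f1, f2, f3]) @ np.column_stack([e1, e2, e3]).T
    return (xyz - o) @ rot.T + np.asarray(target_origin, float)


def _hbond_h_position(d_xyz, a_xyz, r: float, angle_deg: float) -> np.ndarray:
    """Position for the donor hydrogen at bond length ``r`` from the
    donor realizing an exact D-H-A angle (in the z=0 plane, y >= 0)."""
    d = float(np.linalg.norm(np.asarray(a_xyz) - np.asarray(d_xyz)))
    theta = np.radians(angle_deg)
    # triangle D-H-A with |DH| = r, angle at H = theta: solve |HA|
    ha = r * np.cos(theta) + np.sqrt(d * d - (r * np.sin(theta)) ** 2)
    # local frame: A at origin, D at (d, 0, 0)
    x = (d * d + ha * ha - r * r) / (2.0 * d)
    y = np.sqrt(max(r * r - (x - d) ** 2, 0.0))
    local = np.array([x, y, 0.0])
    u = _unit(np.asarray(d_xyz) - np.asarray(a_xyz))
    # rotate the local +x axis onto u; the plane choice is free
    rot = _rotation_between(np.array([1.0, 0.0, 0.0]), u)
    return np.asarray(a_xyz) + rot @ local


_SITE_SPACING = 30.0


def plant_complex(specs: list[InteractionSpec]) -> PlantedComplex:
    """Build a minimal receptor + posed ligand realizing each requested
    interaction at its exact geometry, one isolated site per spec.

    Sites are spaced 30 A apart so interactions cannot cross-talk; a
    self-check validates the realized geometry (within 0.05 A / 2 deg)
    and the absence of unintended contacts within 1.2x of any distance
    cutoff.
    """
    rec_atoms: list[ReceptorAtom] = []
    polar_h_by_key: dict[tuple, list[np.ndarray]] = {}
    frag_mols: list[Chem.Mol] = []
    frag_coords: list[np.ndarray] = []
    intended: list[dict] = []

    for i, spec in enumerate(specs):
        site = np.array([0.0, 0.0, _SITE_SPACING * i])
        resnum = i + 1
        if spec.kind == "hbond":
            angle = spec.angle if spec.angle is not None else 160.0
            tmpl, coords, h_coords = _place_residue("GLY", ["O"], site)
            frag = _embed("CO")  # methanol: ligand donor
            o_idx = next(a.GetIdx() for a in frag.GetAtoms() if a.GetSymbol() == "O")
            h_idx = next(
                nb.GetIdx() for nb in frag.GetAtomWithIdx(o_idx).GetNeighbors() if nb.GetAtomicNum() == 1
            )
            c_idx = next(
                nb.GetIdx() for nb in frag.GetAtomWithIdx(o_idx).GetNeighbors() if nb.GetAtomicNum() == 6
            )
            xyz = np.array(frag.GetConformer().GetPositions())
            r = float(np.linalg.norm(xyz[h_idx] - xyz[o_idx]))
            d_pos = site + np.array([spec.distance, 0.0, 0.0])
            h_pos = _hbond_h_position(d_pos, site, r, angle)
            placed = _frame_place(frag, o_idx, h_idx, c_idx, d_pos, h_pos, np.array([1.0, 0.0, 0.0]))
            realized_d = float(np.linalg.norm(placed[o_idx] - coords["O"]))
            v1 = placed[o_idx] - placed[h_idx]
            v2 = coords["O"] - placed[h_idx]
            realized_a = float(np.degrees(np.arccos(np.clip(
                np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1))))
            frag_mols.append(frag)
            frag_coords.append(placed)
            res_key = ("A", resnum, "", "GLY")
            intended.append(dict(kind="hbond", residue_key=res_key,
                                 spec_distance=spec.distance, realized_distance=realized_d,
                                 spec_angle=angle, realized_angle=realized_a))
        elif spec.kind == "hydrophobic":
            tmpl, coords, h_coords = _place_residue("ALA", ["CB"], site)
            frag = _embed("C")  # methane
            c_idx = next(a.GetIdx() for a in frag.GetAtoms() if a.GetSymbol() == "C")
            xyz = np.array(frag.GetConformer().GetPositions())
            placed = xyz - xyz[c_idx] + site + np.array([spec.distance, 0.0, 0.0])
            realized_d = float(np.linalg.norm(placed[c_idx] - coords["CB"]))
            frag_mols.append(frag)
            frag_coords.append(placed)
            res_key = ("A", resnum, "", "ALA")
            intended.append(dict(kind="hydrophobic", residue_key=res_key,
                                 spec_distance=spec.distance, realized_distance=realized_d,
                                 spec_angle=None, realized_angle=None))
        elif spec.kind == "salt_bridge":
            tmpl, coords, h_coords = _place_residue("ASP", ["OD1", "OD2"], site)
            frag = _embed("C[N+](C)(C)C")  # tetramethylammonium: no N-H donors
            n_idx = next(a.GetIdx() for a in frag.GetAtoms() if a.GetSymbol() == "N")
            xyz = np.array(frag.GetConformer().GetPositions())
            placed = xyz - xyz[n_idx] + site + np.array([spec.distance, 0.0, 0.0])
            centroid = (coords["OD1"] + coords["OD2"]) / 2.0
            realized_d = float(np.linalg.norm(placed[n_idx] - centroid))
            frag_mols.append(frag)
            frag_coords.append(placed)
            res_key = ("A", resnum, "", "ASP")
            intended.append(dict(kind="salt_bridge", residue_key=res_key,
                                 spec_distance=spec.distance, realized_distance=realized_d,
                                 spec_angle=None, realized_angle=None))
        elif spec.kind == "pi_stack":
            subtype = spec.subtype or "parallel"
            plane_angle = spec.angle if spec.angle is not None else (0.0 if subtype == "parallel" else 90.0)
            ring_names = get_template("PHE").aromatic_rings[0]
            tmpl, coords, h_coords = _place_ring_residue("PHE", ring_names, site, np.array([1.0, 0.0, 0.0]))
            frag = _embed("c1ccccc1")
            ring_idx = [a.GetIdx() for a in frag.GetAtoms() if a.GetAtomicNum() == 6]
            xyz = np.array(frag.GetConformer().GetPositions())
            center = xyz[ring_idx].mean(axis=0)
            _, _, vt = np.linalg.svd(xyz[ring_idx] - center)
            th = np.radians(plane_angle)
            target_normal = np.array([np.cos(th), 0.0, np.sin(th)])
            rot = _rotation_between(vt[2], target_normal)
            target_center = site + np.array([spec.distance, 0.0, 0.0])
            placed = (xyz - center) @ rot.T + target_center
            pc = np.array([coords[n] for n in ring_names])
            pcen = pc.mean(axis=0)
            _, _, pvt = np.linalg.svd(pc - pcen)
            lcen = placed[ring_idx].mean(axis=0)
            _, _, lvt = np.linalg.svd(placed[ring_idx] - lcen)
            realized_d = float(np.linalg.norm(lcen - pcen))
            realized_a = float(np.degrees(np.arccos(np.clip(abs(np.dot(pvt[2], lvt[2])), 0, 1))))
            frag_mols.append(frag)
            frag_coords.append(placed)
            res_key = ("A", resnum, "", "PHE")
            intended.append(dict(kind="pi_stack", residue_key=res_key, subtype=subtype,
                                 spec_distance=spec.distance, realized_distance=realized_d,
                                 spec_angle=plane_angle, realized_angle=realized_a))
        elif spec.kind == "pi_cation":
            ring_names = get_template("PHE").aromatic_rings[0]
            tmpl, coords, h_coords = _place_ring_residue("PHE", ring_names, site, np.array([1.0, 0.0, 0.0]))
            frag = _embed("C[N+](C)(C)C")
            n_idx = next(a.GetIdx() for a in frag.GetAtoms() if a.GetSymbol() == "N")
            xyz = np.array(frag.GetConformer().GetPositions())
            placed = xyz - xyz[n_idx] + site + np.array([spec.distance, 0.0, 0.0])
            pc = np.array([coords[n] for n in ring_names])
            realized_d = float(np.linalg.norm(placed[n_idx] - pc.mean(axis=0)))
            frag_mols.append(frag)
            frag_coords.append(placed)
            res_key = ("A", resnum, "", "PHE")
            intended.append(dict(kind="pi_cation", residue_key=res_key,
                                 spec_distance=spec.distance, realized_distance=realized_d,
                                 spec_angle=None, realized_angle=None))
        else:
            raise ValueError(f"unknown interaction kind {spec.kind!r}")

        resname = intended[-1]["residue_key"][3]
        atom_start = len(rec_atoms)
        name_to_idx = {}
        for nm in tmpl.atom_names:
            name_to_idx[nm] = len(rec_atoms)
            rec_atoms.append(
                ReceptorAtom(
                    name=nm, resname=resname, chain="A", resnum=resnum, icode="",
                    element=nm[0], xyz=coords[nm],
                )
            )
        for nm, hs in h_coords.items():
            polar_h_by_key[name_to_idx[nm]] = [np.asarray(h) for h in hs]

    # assemble the multi-fragment ligand pose
    combined = frag_mols[0]
    for frag in frag_mols[1:]:
        combined = Chem.CombineMols(combined, frag)
    Chem.SanitizeMol(combined)  # CombineMols drops ring/aromaticity perception
    all_coords = np.vstack(frag_coords)
    conf = Chem.Conformer(combined.GetNumAtoms())
    for i in range(combined.GetNumAtoms()):
        conf.SetAtomPosition(i, [float(x) for x in all_coords[i]])
    combined = Chem.Mol(combined)
    combined.RemoveAllConformers()
    combined.AddConformer(conf, assignId=True)

    lig_center = all_coords.mean(axis=0)
    span = float(np.max(np.abs(all_coords - lig_center))) * 2 + 20.0
    receptor = ReceptorStructure(
        atoms=rec_atoms,
        box_center=lig_center,
        box_edge=span,
        polar_h=polar_h_by_key,
        name="planted",
    )
    pose = DockingResult(
        mol_id="planted_ligand",
        pose_mol=combined,
        vina=0.0,
        heavy_atoms=sum(1 for a in combined.GetAtoms() if a.GetAtomicNum() > 1),
        engine="planted",
    )
    complex_ = PlantedComplex(receptor=receptor, pose=pose, intended=intended)
    complex_.self_check()
    return complex_
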