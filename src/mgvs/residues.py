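"""Amino-acid residue templates: SMILES with PDB atom-name mappings.

A single registry drives both the protein-side chemical typing used by
interaction detection (donors, acceptors, charged groups, aromatic
rings, apolar carbons are all derived from the template molecule with
RDKit, never hard-coded) and the idealized 3D residue geometries used
by the synthetic-complex builder.

Templates are free amino acids; in a chain the backbone N keeps a
single amide hydrogen and the C-terminal oxygens are treated as
deprotonated, which is handled by the H-count overrides below.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

__all__ = ["ResidueTemplate", "get_template", "known_residues"]

# SMILES written so that RDKit heavy-atom parse order matches the name list.
_REGISTRY: dict[str, tuple[str, list[str]]] = {
    "GLY": ("NCC(=O)O", ["N", "CA", "C", "O", "OXT"]),
    "ALA": ("NC(C)C(=O)O", ["N", "CA", "CB", "C", "O", "OXT"]),
    "VAL": ("NC(C(C)C)C(=O)O", ["N", "CA", "CB", "CG1", "CG2", "C", "O", "OXT"]),
    "LEU": ("NC(CC(C)C)C(=O)O", ["N", "CA", "CB", "CG", "CD1", "CD2", "C", "O", "OXT"]),
    "ILE": ("NC(C(C)CC)C(=O)O", ["N", "CA", "CB", "CG2", "CG1", "CD1", "C", "O", "OXT"]),
    "PRO": ("N1CCCC1C(=O)O", ["N", "CD", "CG", "CB", "CA", "C", "O", "OXT"]),
    "SER": ("NC(CO)C(=O)O", ["N", "CA", "CB", "OG", "C", "O", "OXT"]),
    "THR": ("NC(C(O)C)C(=O)O", ["N", "CA", "CB", "OG1", "CG2", "C", "O", "OXT"]),
    "CYS": ("NC(CS)C(=O)O", ["N", "CA", "CB", "SG", "C", "O", "OXT"]),
    "MET": ("NC(CCSC)C(=O)O", ["N", "CA", "CB", "CG", "SD", "CE", "C", "O", "OXT"]),
    "PHE": ("NC(Cc1ccccc1)C(=O)O", ["N", "CA", "CB", "CG", "CD1", "CE1", "CZ", "CE2", "CD2", "C", "O", "OXT"]),
    "TYR": ("NC(Cc1ccc(O)cc1)C(=O)O", ["N", "CA", "CB", "CG", "CD1", "CE1", "CZ", "OH", "CE2", "CD2", "C", "O", "OXT"]),
    "TRP": ("NC(Cc1c[nH]c2ccccc12)C(=O)O", ["N", "CA", "CB", "CG", "CD1", "NE1", "CE2", "CZ2", "CH2", "CZ3", "CE3", "CD2", "C", "O", "OXT"]),
    # neutral His, NE2-H tautomer (ND1 is the acceptor)
    "HIS": ("NC(Cc1c[nH]cn1)C(=O)O", ["N", "CA", "CB", "CG", "CD2", "NE2", "CE1", "ND1", "C", "O", "OXT"]),
    # doubly protonated (cationic) His
    "HIP": ("NC(Cc1c[nH]c[nH+]1)C(=O)O", ["N", "CA", "CB", "CG", "CD2", "NE2", "CE1", "ND1", "C", "O", "OXT"]),
    "LYS": ("NC(CCCC[NH3+])C(=O)O", ["N", "CA", "CB", "CG", "CD", "CE", "NZ", "C", "O", "OXT"]),
    "ARG": ("NC(CCCNC(=[NH2+])N)C(=O)O", ["N", "CA", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2", "C", "O", "OXT"]),
    "ASP": ("NC(CC(=O)[O-])C(=O)O", ["N", "CA", "CB", "CG", "OD1", "OD2", "C", "O", "OXT"]),
    "GLU": ("NC(CCC(=O)[O-])C(=O)O", ["N", "CA", "CB", "CG", "CD", "OE1", "OE2", "C", "O", "OXT"]),
    "ASN": ("NC(CC(=O)N)C(=O)O", ["N", "CA", "CB", "CG", "OD1", "ND2", "C", "O", "OXT"]),
    "GLN": ("NC(CCC(=O)N)C(=O)O", ["N", "CA", "CB", "CG", "CD", "OE1", "NE2", "C", "O", "OXT"]),
}

# protonation-state aliases mapped onto base templates
_ALIASES = {"HID": "HIS", "HIE": "HIS", "CYX": "CYS", "ASH": "ASP", "GLH": "GLU", "LYN": "LYS"}

# in-chain overrides of the free-amino-acid hydrogen counts
_CHAIN_H_OVERRIDES = {"N": 1, "O": 0, "OXT": 0}
_CHAIN_H_OVERRIDES_PRO = {"N": 0, "O": 0, "OXT": 0}


@dataclass(frozen=True)
class ResidueTemplate:
    """Chemical typing and idealized geometry for one residue type.

    All sets contain PDB atom names.  ``coords`` maps heavy-atom names
    to idealized 3D positions (embedded and MMFF-relaxed once,
    deterministic); ``h_coords`` maps donor heavy-atom names to the
    positions of their hydrogens in the same frame.
    """

    name: str
    atom_names: tuple[str, ...]
    donors: frozenset[str]        # N/O/S carrying >= 1 H in chain context
    donor_h_count: dict[str, int]
    acceptors: frozenset[str]
    apolar_carbons: frozenset[str]
    positive_groups: tuple[frozenset[str], ...]
    negative_groups: tuple[frozenset[str], ...]
    aromatic_rings: tuple[tuple[str, ...], ...]
    bonds: tuple[tuple[str, str], ...]
    coords: dict[str, np.ndarray]
    h_coords: dict[str, list[np.ndarray]]


def known_residues() -> set[str]:
    return set(_REGISTRY) | set(_ALIASES)


def _charged_groups(mol: Chem.Mol, sign: int) -> list[set[int]]:
    """Charge centers: the formally charged atom plus same-element
    resonance partners on its adjacent carbon (carboxylate oxygens,
    guanidinium nitrogens)."""
    groups = []
    for atom in mol.GetAtoms():
        q = atom.GetFormalCharge()
        if q == 0 or (q > 0) != (sign > 0):
            continue
        members = {atom.GetIdx()}
        for nb in atom.GetNeighbors():
            if nb.GetSymbol() != "C":
                continue
            partners = [
                x.GetIdx()
                for x in nb.GetNeighbors()
                if x.GetIdx() != atom.GetIdx() and x.GetSymbol() == atom.GetSymbol()
            ]
            if partners:
                members.update(partners)
        groups.append(members)
    # merge overlapping groups (e.g. doubly listed resonance partners)
    merged: list[set[int]] = []
    for g in groups:
        for m in merged:
            if m & g:
                m.update(g)
                break
        else:
            merged.append(g)
    return merged


@lru_cache(maxsize=None)
def get_template(resname: str) -> ResidueTemplate:
    resname = resname.upper()
    resname = _ALIASES.get(resname, resname)
    if resname not in _REGISTRY:
        raise KeyError(f"no residue template for {resname!r}")
    smiles, names = _REGISTRY[resname]
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None and mol.GetNumHeavyAtoms() == len(names), resname
    mol_h = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = 20240901
    if AllChem.EmbedMolecule(mol_h, params) != 0:
        raise RuntimeError(f"failed to embed residue template {resname}")
    AllChem.MMFFOptimizeMolecule(mol_h)
    conf = mol_h.GetConformer()

    idx_name = {i: names[i] for i in range(len(names))}
    overrides = _CHAIN_H_OVERRIDES_PRO if resname == "PRO" else _CHAIN_H_OVERRIDES

    donors, acceptors, apolar = set(), set(), set()
    donor_h_count: dict[str, int] = {}
    coords: dict[str, np.ndarray] = {}
    h_coords: dict[str, list[np.ndarray]] = {}
    for i, name in idx_name.items():
        atom = mol_h.GetAtomWithIdx(i)
        coords[name] = np.array(conf.GetAtomPosition(i))
        sym = atom.GetSymbol()
        h_idx = [nb.GetIdx() for nb in atom.GetNeighbors() if nb.GetAtomicNum() == 1]
        n_h = overrides.get(name, len(h_idx))
        if sym in ("N", "O", "S"):
            if n_h >= 1:
                donors.add(name)
                donor_h_count[name] = n_h
                h_coords[name] = [np.array(conf.GetAtomPosition(h)) for h in h_idx[:n_h]]
            q = atom.GetFormalCharge()
            if q <= 0 and (sym == "O" or n_h == 0):
                acceptors.add(name)
        elif sym == "C":
            heavy_nbs = [nb for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1]
            if all(nb.GetSymbol() == "C" for nb in heavy_nbs):
                apolar.add(name)

    pos = tuple(
        frozenset(idx_name[i] for i in g) for g in _charged_groups(mol, +1)
    )
    neg = tuple(
        frozenset(idx_name[i] for i in g) for g in _charged_groups(mol, -1)
    )
    rings = []
    ri = mol.GetRingInfo()
    for ring in ri.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            rings.append(tuple(idx_name[i] for i in ring))
    bonds = tuple(
        (idx_name[b.GetBeginAtomIdx()], idx_name[b.GetEndAtomIdx()])
        for b in mol.GetBonds()
    )
    return ResidueTemplate(
        name=resname,
        atom_names=tuple(names),
        donors=frozenset(donors),
        donor_h_count=donor_h_count,
        acceptors=frozenset(acceptors),
        apolar_carbons=frozenset(apolar),
        positive_groups=pos,
        negative_groups=neg,
        aromatic_rings=tuple(rings),
        bonds=bonds,
        coords=coords,
        h_coords=h_coords,
    )
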