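"""Molecule and receptor I/O plus the molecular properties used for
filtering and reporting.

Molecules are thin wrappers around RDKit mols that remember their
identifier and provenance.  Receptors are protein-only atom lists parsed
from PDB text together with the docking box definition.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, QED, rdMolDescriptors

__all__ = [
    "MoleculeRecord",
    "PropertyRecord",
    "ReceptorAtom",
    "ReceptorStructure",
    "MoleculeParseError",
    "ReceptorParseError",
    "parse_molecule",
    "read_smiles_file",
    "read_sdf",
    "write_smiles_file",
    "compute_properties",
    "sa_score",
    "read_receptor",
    "write_receptor_pdb",
    "write_property_table",
]


class MoleculeParseError(ValueError):
    """Raised when a molecule record cannot be parsed or sanitized."""


class ReceptorParseError(ValueError):
    """Raised for malformed or empty receptor PDB input."""


@dataclass(frozen=True)
class MoleculeRecord:
    """A parsed heavy-atom molecular graph with identity and provenance.

    `smiles` is always the canonical SMILES of the sanitized molecule;
    the RDKit mol keeps hydrogens implicit unless they were explicit in
    the input.
    """

    id: str
    smiles: str
    mol: Chem.Mol
    source: str = "generated"

    @property
    def heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    def __repr__(self) -> str:  # Mol object is noise in logs
        return f"MoleculeRecord(id={self.id!r}, smiles={self.smiles!r}, source={self.source!r})"


@dataclass(frozen=True)
class PropertyRecord:
    """Molecular properties reported and filtered on by the pipeline.

    qed is the quantitative estimate of drug-likeness in [0, 1]
    (Bickerton-style desirability product, delegated to RDKit); sa is a
    synthetic-accessibility estimate in [1, 10], lower = easier.
    """

    mw: float
    heavy_atoms: int
    qed: float
    sa: float
    logp: float
    hbd: int
    hba: int
    rot_bonds: int


def parse_molecule(text: str, id: str, source: str = "generated") -> MoleculeRecord:
    """Parse a SMILES string or an SDF molblock into a MoleculeRecord.

    Input containing an ``M  END`` line is treated as a molblock,
    anything else as SMILES.  Sanitization (valence check + aromatic
    perception) is applied; failures raise :class:`MoleculeParseError`
    naming the offending record id.
    """
    if not text or not text.strip():
        raise MoleculeParseError(f"molecule {id!r}: empty input")
    if "M  END" in text:
        mol = Chem.MolFromMolBlock(text, sanitize=True, removeHs=False)
    else:
        mol = Chem.MolFromSmiles(text.strip(), sanitize=True)
    if mol is None:
        raise MoleculeParseError(f"molecule {id!r}: unparseable or valence-violating input: {text.strip()[:80]!r}")
    if mol.GetNumHeavyAtoms() < 1:
        raise MoleculeParseError(f"molecule {id!r}: no heavy atoms")
    mol.SetProp("_Name", id)
    return MoleculeRecord(id=id, smiles=Chem.MolToSmiles(mol), mol=mol, source=source)


def read_smiles_file(path_or_text, source: str = "library") -> list[MoleculeRecord]:
    """Read a ``SMILES<TAB>id`` file (whitespace-separated also accepted).

    Lines starting with ``#`` and blank lines are skipped; records
    without an explicit id are numbered by line.
    """
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    else:
        with open(path_or_text) as fh:
            text = fh.read()
    records = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        smi = parts[0]
        mol_id = parts[1] if len(parts) > 1 else f"line{lineno}"
        records.append(parse_molecule(smi, mol_id, source=source))
    return records


def read_sdf(path, source: str = "library") -> list[MoleculeRecord]:
    """Read a multi-record SDF file; record ids come from the title line."""
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=False)
    records = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise MoleculeParseError(f"SDF record #{i + 1} in {path}: unparseable")
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf{i + 1}"
        records.append(MoleculeRecord(id=mol_id, smiles=Chem.MolToSmiles(mol), mol=mol, source=source))
    return records


def write_smiles_file(records: list[MoleculeRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.smiles}\t{rec.id}\n")


def sa_score(mol: Chem.Mol) -> float:
    """Synthetic-accessibility estimate in [1, 10] (lower = easier).

    A complexity-penalty score in the spirit of fragment-based SA
    estimators: molecule size, stereocenters, spiro and bridgehead
    atoms, macrocycles, and unusual-element content each add to the
    penalty, which is squashed onto the conventional 1-10 scale.  It is
    deterministic, monotone in structural complexity, and suitable for
    the relative comparisons the pipeline makes; it is not calibrated
    against any external fragment-frequency database.
    """
    n = mol.GetNumHeavyAtoms()
    if n < 1:
        return 1.0
    ri = mol.GetRingInfo()
    size_penalty = n ** 1.005 - n
    n_chiral = len(Chem.FindMolChiralCenters(mol, includeUnassigned=True, useLegacyImplementation=False))
    stereo_penalty = math.log10(n_chiral + 1)
    n_spiro = rdMolDescriptors.CalcNumSpiroAtoms(mol)
    n_bridge = rdMolDescriptors.CalcNumBridgeheadAtoms(mol)
    spiro_penalty = 2.0 * math.log10(n_spiro + 1)
    bridge_penalty = 2.0 * math.log10(n_bridge + 1)
    macro_penalty = math.log10(2.0) if any(len(r) > 8 for r in ri.AtomRings()) else 0.0
    common = {"C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "H"}
    n_unusual = sum(1 for a in mol.GetAtoms() if a.GetSymbol() not in common)
    n_charged = sum(1 for a in mol.GetAtoms() if a.GetFormalCharge() != 0)
    exotic_penalty = 0.5 * n_unusual + 0.2 * n_charged
    penalty = (
        0.5 * size_penalty
        + 1.5 * stereo_penalty
        + spiro_penalty
        + bridge_penalty
        + macro_penalty
        + exotic_penalty
    )
    return 1.0 + 9.0 * (1.0 - math.exp(-penalty / 4.0))


def compute_properties(rec: MoleculeRecord) -> PropertyRecord:
    """Compute the full property block for one molecule.

    QED, logP (Crippen), H-bond donor/acceptor counts and rotatable
    bonds are delegated to RDKit; SA comes from :func:`sa_score`.
    Bit-identical across repeated calls.
    """
    mol = rec.mol
    return PropertyRecord(
        mw=Descriptors.MolWt(mol),
        heavy_atoms=mol.GetNumHeavyAtoms(),
        qed=QED.qed(mol),
        sa=sa_score(mol),
        logp=Crippen.MolLogP(mol),
        hbd=rdMolDescriptors.CalcNumHBD(mol),
        hba=rdMolDescriptors.CalcNumHBA(mol),
        rot_bonds=rdMolDescriptors.CalcNumRotatableBonds(mol),
    )


def write_property_table(records: list[MoleculeRecord], path) -> None:
    """Write a TSV property table (one row per molecule)."""
    import pandas as pd

    rows = []
    for rec in records:
        p = compute_properties(rec)
        rows.append(
            {
                "id": rec.id,
                "smiles": rec.smiles,
                "mw": round(p.mw, 3),
                "heavy_atoms": p.heavy_atoms,
                "qed": round(p.qed, 4),
                "sa": round(p.sa, 4),
                "logp": round(p.logp, 4),
                "hbd": p.hbd,
                "hba": p.hba,
                "rot_bonds": p.rot_bonds,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Receptor structures
# --------------------------------------------------------------------------

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # common protonation-state variants
    "HID", "HIE", "HIP", "CYX", "ASH", "GLH", "LYN",
}


@dataclass(frozen=True)
class ReceptorAtom:
    name: str
    resname: str
    chain: str
    resnum: int
    icode: str
    element: str
    xyz: np.ndarray

    @property
    def residue_key(self) -> tuple[str, int, str, str]:
        return (self.chain, self.resnum, self.icode, self.resname)

    @property
    def atom_id(self) -> str:
        return f"{self.chain}:{self.resnum}{self.icode.strip()}:{self.resname}:{self.name}"


@dataclass
class ReceptorStructure:
    """Protein atoms (waters and hetero ligands excluded) plus the
    docking box.  Residue numbering is preserved verbatim from the PDB.

    ``polar_h`` maps the index of a donor heavy atom in ``atoms`` to the
    coordinates of its (explicit or idealized) hydrogens; it is filled
    either from explicit H records at parse time or by
    :func:`mgvs.plinter.add_polar_hydrogens`.
    """

    atoms: list[ReceptorAtom]
    box_center: np.ndarray
    box_edge: float = 20.0
    polar_h: dict[int, list[np.ndarray]] = field(default_factory=dict)
    name: str = "receptor"

    def __post_init__(self):
        if self.box_edge <= 0:
            raise ValueError("box_edge must be > 0")
        self.box_center = np.asarray(self.box_center, dtype=float)
        for a in self.atoms:
            if not np.all(np.isfinite(a.xyz)):
                raise ReceptorParseError(f"non-finite coordinates on atom {a.atom_id}")

    def residues(self) -> dict[tuple, list[int]]:
        """Map residue key -> indices into ``atoms``, in file order."""
        out: dict[tuple, list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.residue_key, []).append(i)
        return out

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms]) if self.atoms else np.zeros((0, 3))

    def in_box(self, xyz: np.ndarray) -> bool:
        half = self.box_edge / 2.0
        return bool(np.all(np.abs(np.asarray(xyz, dtype=float) - self.box_center) <= half))


def _infer_element(atom_name: str, resname: str) -> str:
    """Infer element from a PDB atom name when the element column is blank.

    Protein context: names starting with a digit are hydrogens
    (e.g. 1HB); two-letter names are checked against known protein
    elements before falling back to the first letter ("CA" in a protein
    residue is a carbon, not calcium).
    """
    name = atom_name.strip()
    if not name:
        return ""
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    if not name:
        return ""
    first = name[0].upper()
    if first == "H":
        return "H"
    if first in {"C", "N", "O", "S", "P"}:
        return first
    if name[:2].upper() in {"FE", "ZN", "MG", "MN", "SE"}:
        return name[:2].capitalize()
    return first


def read_receptor(pdb_text: str, box_center, box_edge: float = 20.0, name: str = "receptor") -> ReceptorStructure:
    """Parse receptor PDB text, keeping only protein ATOM records.

    Waters and hetero ligands are dropped, alternate locations other
    than 'A'/blank are skipped, and elements are inferred from the atom
    name when the element column is blank.  Explicit protein hydrogens
    are attached to their nearest heavy atom (<= 1.3 A) as polar_h
    entries rather than kept as atoms.
    """
    atoms: list[ReceptorAtom] = []
    hydrogens: list[ReceptorAtom] = []
    saw_atom_record = False
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        saw_atom_record = True
        resname = line[17:20].strip()
        if line.startswith("HETATM") and resname not in _STANDARD_AA:
            continue  # waters (HOH) and bound ligands
        if resname == "HOH" or resname == "WAT":
            continue
        if resname not in _STANDARD_AA:
            continue  # non-protein ATOM record (e.g. nucleic acid)
        altloc = line[16]
        if altloc not in (" ", "A"):
            continue
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError:
            raise ReceptorParseError(f"line {lineno}: non-numeric coordinates") from None
        atom_name = line[12:16].strip()
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = _infer_element(line[12:16], resname)
        element = element.capitalize()
        icode = line[26]
        atom = ReceptorAtom(
            name=atom_name,
            resname=resname,
            chain=line[21],
            resnum=int(line[22:26]),
            icode=icode if icode != " " else "",
            element=element,
            xyz=np.array([x, y, z]),
        )
        (hydrogens if element == "H" else atoms).append(atom)
    if not saw_atom_record:
        raise ReceptorParseError("no ATOM/HETATM records in input")
    if not atoms:
        raise ReceptorParseError("no protein atoms after filtering")
    rec = ReceptorStructure(atoms=atoms, box_center=box_center, box_edge=box_edge, name=name)
    # attach explicit hydrogens to their donor heavy atoms
    for h in hydrogens:
        best_i, best_d = None, 1.3
        for i, a in enumerate(atoms):
            if a.residue_key != h.residue_key:
                continue
            d = float(np.linalg.norm(a.xyz - h.xyz))
            if d < best_d:
                best_i, best_d = i, d
        if best_i is not None:
            rec.polar_h.setdefault(best_i, []).append(h.xyz)
    return rec


def write_receptor_pdb(rec: ReceptorStructure, path) -> None:
    """Write the receptor (with any attached hydrogens) as PDB text."""
    lines = []
    serial = 0
    for i, a in enumerate(rec.atoms):
        serial += 1
        lines.append(_pdb_line(serial, a.name, a.resname, a.chain, a.resnum, a.icode, a.xyz, a.element))
        for j, h in enumerate(rec.polar_h.get(i, ()), start=1):
            serial += 1
            hname = f"H{a.name[1:]}{j if len(rec.polar_h[i]) > 1 else ''}"[:4]
            lines.append(_pdb_line(serial, hname, a.resname, a.chain, a.resnum, a.icode, h, "H"))
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def _pdb_line(serial, name, resname, chain, resnum, icode, xyz, element) -> str:
    nm = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {nm:<4.4s} {resname:<3s} {chain}{resnum:4d}{icode or ' '}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )
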