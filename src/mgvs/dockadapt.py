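"""Conformer generation, clustering, force-field relaxation, and the
pluggable docking-engine contract.

The engine contract is text-level and minimal: an engine takes a
molecule, starting coordinates and a receptor (with docking box) and
returns a score in kcal/mol plus the scored pose.  The deterministic
mock engine (:mod:`mgvs.synthfix`) and an external Vina-family
executable both satisfy it, so the rest of the pipeline never knows
which is in use.
"""

from __future__ import annotations

import shutil
import subprocess
import warnings
from dataclasses import dataclass
from typing import Protocol

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.ML.Cluster import Butina

from .chemio import MoleculeRecord, ReceptorStructure

__all__ = [
    "ConformerSet",
    "DockingResult",
    "DockingEngine",
    "ExternalVinaEngine",
    "ConformerError",
    "EngineError",
    "generate_conformers",
    "cluster_conformers",
    "relax",
    "score_pose",
    "best_result",
    "vina_efficiency",
    "delta_vina",
    "parse_vina_output",
    "write_poses_sdf",
]


class ConformerError(RuntimeError):
    """3D embedding failed for a molecule."""


class EngineError(RuntimeError):
    """Docking engine invocation or output parsing failed."""


@dataclass
class ConformerSet:
    """Explicit-hydrogen molecule with one or more 3D conformers.

    Atom order is identical across conformers by construction (they live
    on the same mol object).  ``energies[i]`` is the force-field strain
    energy of conformer i in kcal/mol (NaN before relaxation).
    """

    rec: MoleculeRecord
    mol_h: Chem.Mol
    energies: list[float]

    @property
    def n_conformers(self) -> int:
        return self.mol_h.GetNumConformers()

    def coords(self, conf_idx: int) -> np.ndarray:
        return np.array(self.mol_h.GetConformer(conf_idx).GetPositions())


@dataclass(frozen=True)
class DockingResult:
    """Best-mode pose and score for one conformer of one molecule.

    vina_eff is exactly vina / heavy_atoms (ligand efficiency); the
    pose mol carries explicit hydrogens and a single conformer.
    """

    mol_id: str
    pose_mol: Chem.Mol
    vina: float
    heavy_atoms: int
    engine: str
    conformer_idx: int = 0

    @property
    def vina_eff(self) -> float:
        return vina_efficiency(self.vina, self.heavy_atoms)

    def pose_coords(self) -> np.ndarray:
        return np.array(self.pose_mol.GetConformer().GetPositions())


class DockingEngine(Protocol):
    name: str

    def dock(
        self, rec: MoleculeRecord, mol_h: Chem.Mol, conf_idx: int, receptor: ReceptorStructure
    ) -> tuple[float, np.ndarray]:
        """Return (vina score kcal/mol, posed coordinates for mol_h's atoms)."""
        ...


def generate_conformers(rec: MoleculeRecord, n: int = 5, seed: int = 0) -> ConformerSet:
    """Embed up to ``n`` distinct 3D conformers with the
    distance-geometry ETKDG method; deterministic for a fixed seed.
    Hydrogens are added before embedding."""
    mol_h = Chem.AddHs(rec.mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    ids = AllChem.EmbedMultipleConfs(mol_h, numConfs=n, params=params)
    if len(ids) == 0:
        raise ConformerError(f"molecule {rec.id!r}: 3D embedding failed")
    return ConformerSet(rec=rec, mol_h=mol_h, energies=[float("nan")] * len(ids))


def _heavy_rms_matrix(cs: ConformerSet) -> list[float]:
    """Condensed lower-triangle matrix of heavy-atom RMSDs after optimal
    rigid superposition (no atom-order remapping)."""
    mol = Chem.RemoveHs(cs.mol_h)
    dists = []
    n = mol.GetNumConformers()
    ids = [c.GetId() for c in mol.GetConformers()]
    for i in range(1, n):
        for j in range(i):
            dists.append(AllChem.GetConformerRMS(mol, ids[i], ids[j], prealigned=False))
    return dists


def cluster_conformers(cs: ConformerSet, rmsd_cutoff: float = 1.0) -> ConformerSet:
    """Butina (sphere-exclusion) clustering on pairwise heavy-atom RMSD;
    keeps one centroid per cluster.  Butina seeds clusters from the
    largest neighborhoods, and the seed point is the cluster centroid.
    """
    if cs.n_conformers <= 1:
        return cs
    dists = _heavy_rms_matrix(cs)
    clusters = Butina.ClusterData(dists, cs.n_conformers, rmsd_cutoff, isDistData=True)
    keep = sorted(c[0] for c in clusters)
    new_mol = Chem.Mol(cs.mol_h)
    new_mol.RemoveAllConformers()
    ids = [c.GetId() for c in cs.mol_h.GetConformers()]
    for k in keep:
        conf = Chem.Conformer(cs.mol_h.GetConformer(ids[k]))
        new_mol.AddConformer(conf, assignId=True)
    return ConformerSet(rec=cs.rec, mol_h=new_mol, energies=[cs.energies[k] for k in keep])


def relax(cs: ConformerSet, max_iters: int = 500) -> ConformerSet:
    """MMFF94 force-field relaxation of every conformer.

    Per-conformer energies are recorded; unparameterizable molecules are
    passed through unrelaxed with a warning rather than dropped.
    """
    mol = Chem.Mol(cs.mol_h)
    if not AllChem.MMFFHasAllMoleculeParams(mol):
        warnings.warn(f"molecule {cs.rec.id!r}: MMFF94 parameters unavailable, skipping relaxation")
        return ConformerSet(rec=cs.rec, mol_h=mol, energies=list(cs.energies))
    results = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=max_iters)
    energies = [float(e) for _converged, e in results]
    return ConformerSet(rec=cs.rec, mol_h=mol, energies=energies)


def score_pose(
    cs: ConformerSet, receptor: ReceptorStructure, engine: DockingEngine
) -> list[DockingResult]:
    """Dock/score every conformer through the engine adapter; one
    DockingResult (best mode) per conformer."""
    results = []
    ids = [c.GetId() for c in cs.mol_h.GetConformers()]
    for i, conf_id in enumerate(ids):
        vina, pose = engine.dock(cs.rec, cs.mol_h, conf_id, receptor)
        pose_mol = Chem.Mol(cs.mol_h)
        pose_mol.RemoveAllConformers()
        conf = Chem.Conformer(cs.mol_h.GetNumAtoms())
        for a in range(cs.mol_h.GetNumAtoms()):
            conf.SetAtomPosition(a, [float(x) for x in pose[a]])
        pose_mol.AddConformer(conf, assignId=True)
        results.append(
            DockingResult(
                mol_id=cs.rec.id,
                pose_mol=pose_mol,
                vina=float(vina),
                heavy_atoms=cs.rec.heavy_atoms,
                engine=engine.name,
                conformer_idx=i,
            )
        )
    return results


def best_result(results: list[DockingResult]) -> DockingResult:
    """Representative result: minimum vina score, ties broken by lowest
    conformer index."""
    if not results:
        raise ValueError("best_result requires at least one result")
    return min(results, key=lambda r: (r.vina, r.conformer_idx))


def vina_efficiency(vina: float, heavy_atoms: int) -> float:
    """Vina score divided by heavy-atom count (ligand efficiency); the
    size-corrected metric used for ranking."""
    if heavy_atoms < 1:
        raise ValueError("heavy_atoms must be >= 1")
    return vina / heavy_atoms


def delta_vina(hit_vina: float, ref_vina: float) -> float:
    """Search-hit score minus reference score; negative = hit better.
    The reference may be the query compound or the crystal ligand."""
    return hit_vina - ref_vina


# --------------------------------------------------------------------------
# External Vina-family engine
# --------------------------------------------------------------------------


def parse_vina_output(text: str, mol_id: str = "?") -> float:
    """Extract the best-mode affinity (kcal/mol) from Vina-family output.

    Understands both the stdout results table (``mode | affinity``
    header followed by numbered rows) and ``REMARK VINA RESULT`` lines
    from output PDBQT files.
    """
    best = None
    in_table = False
    for line in text.splitlines():
        if "REMARK VINA RESULT" in line:
            try:
                val = float(line.split(":", 1)[-1].split()[0])
            except (ValueError, IndexError):
                raise EngineError(f"molecule {mol_id!r}: malformed REMARK VINA RESULT line: {line!r}")
            best = val if best is None else min(best, val)
            continue
        if line.strip().startswith("-----+"):
            in_table = True
            continue
        if in_table:
            parts = line.split()
            if len(parts) >= 2 and parts[0].isdigit():
                try:
                    val = float(parts[1])
                except ValueError:
                    raise EngineError(f"molecule {mol_id!r}: malformed score table row: {line!r}")
                best = val if best is None else min(best, val)
            else:
                in_table = False
    if best is None:
        raise EngineError(f"molecule {mol_id!r}: no score found in engine output")
    return best


class ExternalVinaEngine:
    """Adapter for a Vina-family executable (AutoDock Vina, QuickVina2).

    Ligand/receptor PDBQT preparation shells out to Open Babel; only the
    documented output grammar of the engine is relied on, so any
    Vina-compatible program works.  Missing executables are a
    configuration error at construction time.
    """

    def __init__(self, exe: str, prep_exe: str = "obabel", exhaustiveness: int | None = None):
        self.exe = shutil.which(exe)
        if self.exe is None:
            raise EngineError(f"docking executable not found on PATH: {exe!r}")
        self.prep_exe = shutil.which(prep_exe)
        if self.prep_exe is None:
            raise EngineError(f"structure preparation tool not found on PATH: {prep_exe!r}")
        self.exhaustiveness = exhaustiveness
        self.name = f"exe:{exe}"

    def dock(self, rec, mol_h, conf_idx, receptor):
        import tempfile
        from pathlib import Path

        from .chemio import write_receptor_pdb

        with tempfile.TemporaryDirectory() as tmp:
            tmp = Path(tmp)
            lig_sdf = tmp / "ligand.sdf"
            writer = Chem.SDWriter(str(lig_sdf))
            writer.write(mol_h, confId=conf_idx)
            writer.close()
            lig_pdbqt = tmp / "ligand.pdbqt"
            rec_pdb = tmp / "receptor.pdb"
            rec_pdbqt = tmp / "receptor.pdbqt"
            write_receptor_pdb(receptor, rec_pdb)
            for cmd in (
                [self.prep_exe, str(lig_sdf), "-O", str(lig_pdbqt)],
                [self.prep_exe, str(rec_pdb), "-xr", "-O", str(rec_pdbqt)],
            ):
                proc = subprocess.run(cmd, capture_output=True, text=True)
                if proc.returncode != 0:
                    raise EngineError(f"molecule {rec.id!r}: preparation failed: {proc.stderr[-500:]}")
            out_pdbqt = tmp / "out.pdbqt"
            cx, cy, cz = receptor.box_center
            cmd = [
                self.exe,
                "--receptor", str(rec_pdbqt),
                "--ligand", str(lig_pdbqt),
                "--center_x", str(cx), "--center_y", str(cy), "--center_z", str(cz),
                "--size_x", str(receptor.box_edge),
                "--size_y", str(receptor.box_edge),
                "--size_z", str(receptor.box_edge),
                "--out", str(out_pdbqt),
            ]
            if self.exhaustiveness is not None:
                cmd += ["--exhaustiveness", str(self.exhaustiveness)]
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                raise EngineError(f"molecule {rec.id!r}: engine failed: {proc.stderr[-500:]}")
            score = parse_vina_output(proc.stdout, rec.id)
            pose = _read_best_pose_pdbqt(out_pdbqt.read_text(), mol_h)
            return score, pose


def _read_best_pose_pdbqt(text: str, mol_h: Chem.Mol) -> np.ndarray:
    """Heavy-atom coordinates of the first model in a Vina output PDBQT,
    padded with the input hydrogen positions when the engine dropped
    non-polar hydrogens."""
    coords = []
    for line in text.splitlines():
        if line.startswith("ENDMDL"):
            break
        if line.startswith(("ATOM", "HETATM")):
            coords.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    base = np.array(mol_h.GetConformer().GetPositions())
    heavy = [a.GetIdx() for a in mol_h.GetAtoms() if a.GetAtomicNum() > 1]
    out = base.copy()
    for idx, c in zip(heavy, coords):
        out[idx] = c
    return out


def write_poses_sdf(results: list[DockingResult], path) -> None:
    """Write docked poses as SDF with score tags."""
    writer = Chem.SDWriter(str(path))
    writer.SetProps(["vina", "vina_eff", "engine"])
    for r in results:
        mol = Chem.Mol(r.pose_mol)
        mol.SetProp("_Name", r.mol_id)
        mol.SetProp("vina", f"{r.vina:.4f}")
        mol.SetProp("vina_eff", f"{r.vina_eff:.6f}")
        mol.SetProp("engine", r.engine)
        writer.write(mol)
    writer.close()
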