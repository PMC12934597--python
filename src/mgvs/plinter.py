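"""Geometric protein-ligand interaction detection and query/hit
interaction matching.

Detection emits typed noncovalent contacts (hydrogen bonds,
hydrophobic contacts, salt bridges, pi-stacking, pi-cation) from pure
geometry at configurable cutoffs.  All distance bounds are inclusive
(<=) and angle minima inclusive (>=).  Matching compares the
interactions of a search-hit pose against those of its query pose at
atom or residue resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem

from .chemio import ReceptorStructure
from .dockadapt import DockingResult
from .residues import _charged_groups, get_template, known_residues

__all__ = [
    "InteractionCutoffs",
    "Interaction",
    "MatchSummary",
    "add_polar_hydrogens",
    "detect_interactions",
    "match_interactions",
    "shared_interaction_stats",
    "SPECIFIC_KINDS",
]

#: the "specific" (directional, non-hydrophobic) interaction kinds
SPECIFIC_KINDS = frozenset({"hbond", "salt_bridge", "pi_cation", "pi_stack"})

ALL_KINDS = ("hbond", "hydrophobic", "salt_bridge", "pi_cation", "pi_stack")


@dataclass(frozen=True)
class InteractionCutoffs:
    """Geometric cutoff criteria.

    Distances in Angstrom, angles in degrees.  The hydrogen bond uses a
    donor-acceptor heavy-atom distance plus a minimum D-H-A angle;
    pi distances are ring-center-to-center (or center-to-cation).  The
    plane-angle windows and lateral ring offset complete the
    pi-stacking geometry.
    """

    hbond_dist: float = 3.5
    hbond_angle: float = 120.0
    hydrophobic_dist: float = 3.8
    salt_dist: float = 4.0
    pistack_parallel_dist: float = 4.0
    pistack_perp_dist: float = 5.5
    pication_dist: float = 4.0
    pistack_parallel_angle: float = 30.0
    pistack_perp_angle_min: float = 50.0
    pistack_perp_angle_max: float = 90.0
    pistack_offset: float = 2.0

    def __post_init__(self):
        for name in (
            "hbond_dist", "hydrophobic_dist", "salt_dist",
            "pistack_parallel_dist", "pistack_perp_dist", "pication_dist",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("hbond_angle", "pistack_parallel_angle",
                     "pistack_perp_angle_min", "pistack_perp_angle_max"):
            if not (0.0 <= getattr(self, name) <= 180.0):
                raise ValueError(f"{name} must be within [0, 180] degrees")

    def scaled(self, factor: float) -> "InteractionCutoffs":
        """All distance cutoffs multiplied by ``factor`` (angle windows
        unchanged); used by fixture self-checks."""
        return replace(
            self,
            hbond_dist=self.hbond_dist * factor,
            hydrophobic_dist=self.hydrophobic_dist * factor,
            salt_dist=self.salt_dist * factor,
            pistack_parallel_dist=self.pistack_parallel_dist * factor,
            pistack_perp_dist=self.pistack_perp_dist * factor,
            pication_dist=self.pication_dist * factor,
            pistack_offset=self.pistack_offset * factor,
        )


@dataclass(frozen=True)
class Interaction:
    """One typed geometric contact between the ligand pose and a
    receptor residue.

    ``ligand_atoms`` holds heavy-atom indices into the pose molecule
    (a full ring or charge group for pi/salt interactions);
    ``protein_atoms`` holds receptor atom-id strings.  ``angle`` is the
    D-H-A angle for hydrogen bonds and the ring-plane angle for
    pi-stacking, otherwise None.
    """

    kind: str
    ligand_atoms: frozenset
    protein_atoms: frozenset
    residue_key: tuple
    distance: float
    angle: float | None = None
    subtype: str = ""

    @property
    def atom_match_key(self):
        return (self.kind, self.protein_atoms)

    @property
    def residue_match_key(self):
        return (self.kind, self.residue_key)


@dataclass(frozen=True)
class MatchSummary:
    level: str   # "atom" | "residue"
    scope: str   # "specific-only" | "all"
    query_count: int
    shared: int
    all_shared: bool
    any_shared: bool
    per_kind: dict = field(default_factory=dict)  # kind -> (query_count, shared)


# --------------------------------------------------------------------------
# receptor hydrogen placement
# --------------------------------------------------------------------------

_H_BOND_LENGTH = {"N": 1.01, "O": 0.96, "S": 1.34}


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("zero-length vector")
    return v / n


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(v, ref))


def _rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = _unit(axis)
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    x, y, z = axis
    return np.array([
        [c + x * x * (1 - c), x * y * (1 - c) - z * s, x * z * (1 - c) + y * s],
        [y * x * (1 - c) + z * s, c + y * y * (1 - c), y * z * (1 - c) - x * s],
        [z * x * (1 - c) - y * s, z * y * (1 - c) + x * s, c + z * z * (1 - c)],
    ])


def add_polar_hydrogens(rec: ReceptorStructure) -> ReceptorStructure:
    """Place idealized hydrogens on donor heavy atoms that lack explicit
    ones.

    Geometry is idealized from the residue's local covalent frame
    (tetrahedral for sp3, trigonal for amides/guanidinium, bisector for
    two-neighbor donors); rotor orientations are deterministic but not
    optimized against the environment.  Existing explicit hydrogens are
    kept untouched.
    """
    residues = rec.residues()
    atom_pos = {
        (a.residue_key, a.name): (i, a.xyz) for i, a in enumerate(rec.atoms)
    }
    new_polar_h = {k: list(v) for k, v in rec.polar_h.items()}
    for res_key, indices in residues.items():
        resname = res_key[3]
        if resname not in known_residues():
            warnings.warn(f"residue {res_key}: no template, hydrogens not placed")
            continue
        tmpl = get_template(resname)
        nbs_of = {}
        for a, b in tmpl.bonds:
            nbs_of.setdefault(a, []).append(b)
            nbs_of.setdefault(b, []).append(a)
        for donor in tmpl.donors:
            key = (res_key, donor)
            if key not in atom_pos:
                continue
            d_idx, d_xyz = atom_pos[key]
            if new_polar_h.get(d_idx):
                continue  # explicit hydrogens present
            n_h = tmpl.donor_h_count.get(donor, 1)
            if n_h == 0:
                continue
            nb_names = [n for n in nbs_of.get(donor, []) if (res_key, n) in atom_pos]
            nb_xyz = [atom_pos[(res_key, n)][1] for n in nb_names]
            elem = rec.atoms[d_idx].element
            length = _H_BOND_LENGTH.get(elem, 1.0)
            hs = _ideal_h_positions(d_xyz, nb_xyz, nb_names, res_key, atom_pos, nbs_of, n_h, length)
            if hs:
                new_polar_h[d_idx] = hs
    out = ReceptorStructure(
        atoms=list(rec.atoms),
        box_center=rec.box_center,
        box_edge=rec.box_edge,
        polar_h=new_polar_h,
        name=rec.name,
    )
    return out


def _ideal_h_positions(d_xyz, nb_xyz, nb_names, res_key, atom_pos, nbs_of, n_h, length):
    if not nb_xyz:
        return []
    if len(nb_xyz) >= 2:
        # fixed donor between two heavy neighbors: H on the outward bisector
        direction = -sum(_unit(x - d_xyz) for x in nb_xyz)
        try:
            direction = _unit(direction)
        except ValueError:
            return []
        return [d_xyz + length * direction]
    # single heavy neighbor: build a reference frame from the grandparent
    w = _unit(nb_xyz[0] - d_xyz)
    ref = None
    for gname in nbs_of.get(nb_names[0], []):
        if gname != nb_names[0] and (res_key, gname) in atom_pos:
            g_xyz = atom_pos[(res_key, gname)][1]
            perp = g_xyz - nb_xyz[0]
            perp = perp - np.dot(perp, w) * w
            if np.linalg.norm(perp) > 1e-6:
                ref = _unit(perp)
                break
    if ref is None:
        ref = _any_perpendicular(w)
    if n_h == 2:  # planar amide/guanidinium NH2
        dirs = []
        for sign in (1.0, -1.0):
            dirs.append(np.cos(np.radians(120)) * w + sign * np.sin(np.radians(120)) * ref)
        return [d_xyz + length * _unit(v) for v in dirs]
    # tetrahedral: 1 or 3 hydrogens at 109.5 deg from the heavy bond
    out = []
    azimuths = [0.0] if n_h == 1 else [60.0, 180.0, 300.0]
    for az in azimuths:
        u = _rotation(w, az) @ ref
        v = np.cos(np.radians(109.5)) * w + np.sin(np.radians(109.5)) * u
        out.append(d_xyz + length * _unit(v))
    return out


# --------------------------------------------------------------------------
# ligand typing
# --------------------------------------------------------------------------


@dataclass
class _LigandTyping:
    donors: dict            # heavy idx -> list of H coords
    acceptors: list
    apolar: list
    pos_groups: list        # list of sets of heavy idx
    neg_groups: list
    rings: list             # list of tuples of heavy idx


def _type_ligand(mol: Chem.Mol, coords: np.ndarray) -> _LigandTyping:
    donors, acceptors, apolar = {}, [], []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 1:
            continue
        idx = atom.GetIdx()
        sym = atom.GetSymbol()
        h_idx = [nb.GetIdx() for nb in atom.GetNeighbors() if nb.GetAtomicNum() == 1]
        if sym in ("N", "O", "S"):
            if atom.GetTotalNumHs(includeNeighbors=True) > len(h_idx):
                raise ValueError(
                    "ligand pose must carry explicit hydrogens on donor heteroatoms"
                )
            if h_idx:
                donors[idx] = [coords[h] for h in h_idx]
            q = atom.GetFormalCharge()
            if q <= 0 and (sym == "O" or not h_idx):
                acceptors.append(idx)
        elif sym == "C":
            heavy_nbs = [nb for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1]
            if all(nb.GetSymbol() == "C" for nb in heavy_nbs):
                apolar.append(idx)
    pos = [set(g) for g in _charged_groups(mol, +1)]
    neg = [set(g) for g in _charged_groups(mol, -1)]
    rings = [
        tuple(r)
        for r in mol.GetRingInfo().AtomRings()
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in r)
    ]
    return _LigandTyping(donors, acceptors, apolar, pos, neg, rings)


def _ring_plane(coords: np.ndarray):
    """Least-squares ring plane: (centroid, unit normal)."""
    center = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - center)
    return center, vt[2]


def _plane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    c = abs(float(np.dot(n1, n2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _ring_offset(c1, n1, c2, n2) -> float:
    """Lateral displacement: distance from each ring center to the
    projection of the other center onto its plane; the smaller of the
    two is used."""
    d = c2 - c1
    off1 = np.linalg.norm(d - np.dot(d, n1) * n1)
    off2 = np.linalg.norm(-d - np.dot(-d, n2) * n2)
    return float(min(off1, off2))


def _angle_deg(a, b, c) -> float:
    """Angle at vertex b of points a-b-c."""
    v1, v2 = a - b, c - b
    cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))


# --------------------------------------------------------------------------
# detection
# --------------------------------------------------------------------------


def detect_interactions(
    pose: DockingResult,
    rec: ReceptorStructure,
    cutoffs: InteractionCutoffs | None = None,
) -> list[Interaction]:
    """Detect all typed contacts between a docked ligand pose and the
    receptor.

    The ligand pose must carry explicit hydrogens; receptor polar
    hydrogens are placed with idealized geometry if absent.  Duplicate
    contacts per (kind, partners) keep the geometrically shortest
    instance, and hydrophobic contacts between rings that pi-stack are
    discarded.
    """
    cutoffs = cutoffs or InteractionCutoffs()
    if not rec.polar_h:
        rec = add_polar_hydrogens(rec)

    mol = pose.pose_mol
    lig_xyz = pose.pose_coords()
    lig = _type_ligand(mol, lig_xyz)

    # protein typing, per residue, from templates
    prot_donors = []     # (atom_idx, [H coords])
    prot_acceptors = []  # atom_idx
    prot_apolar = []
    prot_pos, prot_neg = [], []   # (set of atom_idx, residue_key)
    prot_rings = []               # (tuple of atom_idx, residue_key)
    residues = rec.residues()
    atom_lookup = {(a.residue_key, a.name): i for i, a in enumerate(rec.atoms)}
    for res_key, indices in residues.items():
        resname = res_key[3]
        if resname not in known_residues():
            warnings.warn(f"residue {res_key}: unknown type, skipped")
            continue
        tmpl = get_template(resname)
        his_cationic = False
        if resname in ("HIS", "HID", "HIE"):
            nd1 = atom_lookup.get((res_key, "ND1"))
            ne2 = atom_lookup.get((res_key, "NE2"))
            his_cationic = (
                nd1 is not None and ne2 is not None
                and rec.polar_h.get(nd1) and rec.polar_h.get(ne2)
            )
        for name in tmpl.donors:
            i = atom_lookup.get((res_key, name))
            if i is not None and rec.polar_h.get(i):
                prot_donors.append((i, rec.polar_h[i]))
        for name in tmpl.acceptors:
            if name == "N":
                continue  # in-chain backbone nitrogen is never an acceptor
            i = atom_lookup.get((res_key, name))
            if i is not None:
                prot_acceptors.append(i)
        for name in tmpl.apolar_carbons:
            i = atom_lookup.get((res_key, name))
            if i is not None:
                prot_apolar.append(i)
        groups = list(tmpl.positive_groups)
        if his_cationic:
            groups.append(frozenset({"ND1", "NE2"}))
        for g in groups:
            idxs = {atom_lookup.get((res_key, n)) for n in g}
            if None not in idxs:
                prot_pos.append((idxs, res_key))
        for g in tmpl.negative_groups:
            idxs = {atom_lookup.get((res_key, n)) for n in g}
            if None not in idxs:
                prot_neg.append((idxs, res_key))
        for ring in tmpl.aromatic_rings:
            idxs = tuple(atom_lookup.get((res_key, n)) for n in ring)
            if None not in idxs:
                prot_rings.append((idxs, res_key))

    p_xyz = rec.coords()
    found: list[Interaction] = []

    def add(kind, lig_atoms, prot_idx_set, res_key, dist, angle=None, subtype=""):
        found.append(
            Interaction(
                kind=kind,
                ligand_atoms=frozenset(lig_atoms),
                protein_atoms=frozenset(rec.atoms[i].atom_id for i in prot_idx_set),
                residue_key=res_key,
                distance=float(dist),
                angle=None if angle is None else float(angle),
                subtype=subtype,
            )
        )

    # hydrogen bonds: ligand donor -> protein acceptor
    for d_idx, h_list in lig.donors.items():
        for a_i in prot_acceptors:
            dist = np.linalg.norm(lig_xyz[d_idx] - p_xyz[a_i])
            if dist > cutoffs.hbond_dist:
                continue
            best = max(_angle_deg(lig_xyz[d_idx], h, p_xyz[a_i]) for h in h_list)
            if best >= cutoffs.hbond_angle:
                add("hbond", {d_idx}, {a_i}, rec.atoms[a_i].residue_key, dist, best,
                    subtype="ligand-donor")
    # hydrogen bonds: protein donor -> ligand acceptor
    for d_i, h_list in prot_donors:
        for a_idx in lig.acceptors:
            dist = np.linalg.norm(p_xyz[d_i] - lig_xyz[a_idx])
            if dist > cutoffs.hbond_dist:
                continue
            best = max(_angle_deg(p_xyz[d_i], h, lig_xyz[a_idx]) for h in h_list)
            if best >= cutoffs.hbond_angle:
                add("hbond", {a_idx}, {d_i}, rec.atoms[d_i].residue_key, dist, best,
                    subtype="protein-donor")

    # hydrophobic contacts
    for c_idx in lig.apolar:
        for c_i in prot_apolar:
            dist = np.linalg.norm(lig_xyz[c_idx] - p_xyz[c_i])
            if dist <= cutoffs.hydrophobic_dist:
                add("hydrophobic", {c_idx}, {c_i}, rec.atoms[c_i].residue_key, dist)

    # salt bridges (both charge orientations)
    for lg_groups, pg_groups in ((lig.pos_groups, prot_neg), (lig.neg_groups, prot_pos)):
        for lg in lg_groups:
            lc = lig_xyz[list(lg)].mean(axis=0)
            for pg, res_key in pg_groups:
                pc = p_xyz[list(pg)].mean(axis=0)
                dist = np.linalg.norm(lc - pc)
                if dist <= cutoffs.salt_dist:
                    add("salt_bridge", lg, pg, res_key, dist)

    # pi-stacking
    stacked_pairs = []
    for lring in lig.rings:
        lc, ln = _ring_plane(lig_xyz[list(lring)])
        for pring, res_key in prot_rings:
            pc, pn = _ring_plane(p_xyz[list(pring)])
            dist = np.linalg.norm(lc - pc)
            angle = _plane_angle(ln, pn)
            offset = _ring_offset(lc, ln, pc, pn)
            parallel = (
                dist <= cutoffs.pistack_parallel_dist
                and angle <= cutoffs.pistack_parallel_angle
                and offset <= cutoffs.pistack_offset
            )
            perpendicular = (
                dist <= cutoffs.pistack_perp_dist
                and cutoffs.pistack_perp_angle_min <= angle <= cutoffs.pistack_perp_angle_max
                and offset <= cutoffs.pistack_offset
            )
            if parallel or perpendicular:
                add("pi_stack", lring, set(pring), res_key, dist, angle,
                    subtype="parallel" if parallel else "perpendicular")
                stacked_pairs.append((set(lring), set(pring)))

    # pi-cation (both orientations)
    for lring in lig.rings:
        lc, _ = _ring_plane(lig_xyz[list(lring)])
        for pg, res_key in prot_pos:
            pc = p_xyz[list(pg)].mean(axis=0)
            dist = np.linalg.norm(lc - pc)
            if dist <= cutoffs.pication_dist:
                add("pi_cation", lring, pg, res_key, dist)
    for lg in lig.pos_groups:
        lc = lig_xyz[list(lg)].mean(axis=0)
        for pring, res_key in prot_rings:
            pc, _ = _ring_plane(p_xyz[list(pring)])
            dist = np.linalg.norm(lc - pc)
            if dist <= cutoffs.pication_dist:
                add("pi_cation", lg, set(pring), res_key, dist)

    # refinement: drop hydrophobic contacts inside pi-stacked ring pairs
    prot_id_of = {rec.atoms[i].atom_id: i for i in range(len(rec.atoms))}
    refined = []
    for ix in found:
        if ix.kind == "hydrophobic":
            l_atom = next(iter(ix.ligand_atoms))
            p_atom = prot_id_of[next(iter(ix.protein_atoms))]
            if any(l_atom in ls and p_atom in ps for ls, ps in stacked_pairs):
                continue
        refined.append(ix)

    # deduplicate per (kind, partners): keep the shortest instance
    best: dict[tuple, Interaction] = {}
    for ix in refined:
        key = (ix.kind, ix.ligand_atoms, ix.protein_atoms)
        if key not in best or ix.distance < best[key].distance:
            best[key] = ix
    out = sorted(
        best.values(), key=lambda x: (x.kind, x.distance, sorted(x.protein_atoms))
    )
    return out


# --------------------------------------------------------------------------
# matching
# --------------------------------------------------------------------------


def _apply_scope(ints: list[Interaction], scope: str) -> list[Interaction]:
    if scope == "all":
        return list(ints)
    if scope == "specific-only":
        return [i for i in ints if i.kind in SPECIFIC_KINDS]
    raise ValueError(f"unknown scope {scope!r} (expected 'specific-only' or 'all')")


def match_interactions(
    query_ints: list[Interaction],
    hit_ints: list[Interaction],
    level: str = "residue",
    scope: str = "all",
) -> MatchSummary:
    """Count how many query interactions the hit pose reproduces.

    At the atom level a query interaction is matched when some hit
    interaction has the same kind and the same protein atom id(s); at
    the residue level the same kind and the same residue.  Scope
    ``specific-only`` restricts both sides to the directional kinds
    (everything but hydrophobic contacts) before matching.
    """
    if level not in ("atom", "residue"):
        raise ValueError(f"unknown level {level!r} (expected 'atom' or 'residue')")
    q = _apply_scope(query_ints, scope)
    h = _apply_scope(hit_ints, scope)
    if level == "atom":
        hit_keys = {i.atom_match_key for i in h}
        matched = [i for i in q if i.atom_match_key in hit_keys]
    else:
        hit_keys = {i.residue_match_key for i in h}
        matched = [i for i in q if i.residue_match_key in hit_keys]
    per_kind = {}
    for kind in ALL_KINDS:
        qk = sum(1 for i in q if i.kind == kind)
        mk = sum(1 for i in matched if i.kind == kind)
        if qk:
            per_kind[kind] = (qk, mk)
    shared = len(matched)
    return MatchSummary(
        level=level,
        scope=scope,
        query_count=len(q),
        shared=shared,
        all_shared=(shared == len(q)),
        any_shared=(shared > 0),
        per_kind=per_kind,
    )


def shared_interaction_stats(entries: list[tuple]) -> dict:
    """Aggregate matching statistics over (query_id, [hit summaries]).

    Returns per-kind and overall proportions of hits sharing *all* and
    *at least one* of the query's interactions (hits pooled across
    queries; a hit enters a kind's pool only when its query makes that
    kind), plus per-query rollups: the fraction of queries whose first
    (top-1) hit, or any hit, shares all / at least one interaction.
    """
    if not entries or not any(summaries for _, summaries in entries):
        raise ValueError("shared_interaction_stats requires at least one query with hits")
    kind_pool: dict[str, list[tuple[bool, bool]]] = {}
    overall: list[tuple[bool, bool]] = []
    top1_all = top1_any = anyhit_all = anyhit_any = 0
    n_queries = 0
    for _query_id, summaries in entries:
        if not summaries:
            continue
        n_queries += 1
        for s in summaries:
            overall.append((s.all_shared, s.any_shared))
            for kind, (qk, mk) in s.per_kind.items():
                kind_pool.setdefault(kind, []).append((mk == qk, mk > 0))
        top1_all += summaries[0].all_shared
        top1_any += summaries[0].any_shared
        anyhit_all += any(s.all_shared for s in summaries)
        anyhit_any += any(s.any_shared for s in summaries)

    def frac(pool):
        n = len(pool)
        return {
            "all": sum(a for a, _ in pool) / n,
            "at_least_1": sum(b for _, b in pool) / n,
            "n": n,
        }

    table = {kind: frac(pool) for kind, pool in sorted(kind_pool.items())}
    table["overall"] = frac(overall)
    return {
        "by_kind": table,
        "per_query": {
            "top1_all": top1_all / n_queries,
            "top1_at_least_1": top1_any / n_queries,
            "any_hit_all": anyhit_all / n_queries,
            "any_hit_at_least_1": anyhit_any / n_queries,
            "n_queries": n_queries,
        },
    }


def write_interactions_tsv(pose_ints: dict[str, list[Interaction]], path) -> None:
    import pandas as pd

    rows = []
    for pose_id, ints in pose_ints.items():
        for ix in ints:
            ch, num, icode, resname = ix.residue_key
            rows.append({
                "pose_id": pose_id,
                "kind": ix.kind,
                "subtype": ix.subtype,
                "ligand_atoms": ",".join(map(str, sorted(ix.ligand_atoms))),
                "protein_atoms": ";".join(sorted(ix.protein_atoms)),
                "residue": f"{ch}:{num}{icode}:{resname}",
                "distance": round(ix.distance, 3),
                "angle": "" if ix.angle is None else round(ix.angle, 2),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
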