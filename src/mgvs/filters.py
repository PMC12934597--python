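"""Three-part compound filter applied to generated molecules before
query selection: PAINS substructures, drug-like property ranges, and
structural rules against geometries that dock unreliably (cumulated
double bonds; ring systems outside plain 5/6-membered chemistry).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import yaml
from rdkit import Chem
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

from .chemio import MoleculeRecord, compute_properties

__all__ = [
    "Violation",
    "FilterReport",
    "FilterConfig",
    "ConfigurationError",
    "cumulated_double_bond_check",
    "ring_system_check",
    "pains_check",
    "drug_like_check",
    "apply_filter_stack",
    "load_pains_catalog",
]


class ConfigurationError(ValueError):
    """Bad filter configuration (inverted range, malformed catalog)."""


@dataclass(frozen=True)
class Violation:
    rule: str
    detail: str


@dataclass(frozen=True)
class FilterReport:
    id: str
    passed: bool
    failures: tuple[Violation, ...]


#: default drug-like property windows; logp/hbd/hba/rot_bonds are
#: one-sided caps in the usual rule-of-five spirit, fully configurable.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "mw": (150.0, 500.0),
    "logp": (-math.inf, 5.0),
    "hbd": (0, 5),
    "hba": (0, 10),
    "rot_bonds": (0, 10),
}


@dataclass(frozen=True)
class FilterConfig:
    enable_structure: bool = True
    enable_pains: bool = True
    enable_properties: bool = True
    property_ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    pains_families: tuple[str, ...] = ("A", "B", "C")
    pains_catalog_path: str | None = None  # custom SMARTS file overrides families
    allowed_ring_sizes: tuple[int, ...] = (5, 6)
    max_fused_rings: int = 4
    fused_count_unit: str = "rings"  # or "atoms": count atoms in the fused system

    @classmethod
    def from_yaml(cls, path) -> "FilterConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in (
            "enable_structure", "enable_pains", "enable_properties",
            "pains_catalog_path", "max_fused_rings", "fused_count_unit",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "pains_families" in raw:
            kwargs["pains_families"] = tuple(raw["pains_families"])
        if "allowed_ring_sizes" in raw:
            kwargs["allowed_ring_sizes"] = tuple(raw["allowed_ring_sizes"])
        if "property_ranges" in raw:
            ranges = dict(DEFAULT_RANGES)
            for k, v in raw["property_ranges"].items():
                lo = -math.inf if v[0] is None else float(v[0])
                hi = math.inf if v[1] is None else float(v[1])
                ranges[k] = (lo, hi)
            kwargs["property_ranges"] = ranges
        return cls(**kwargs)


def cumulated_double_bond_check(rec: MoleculeRecord) -> Violation | None:
    """Flag allene-like motifs: a carbon carrying two or more
    non-aromatic double bonds (cumulated, strained).  Conjugated dienes
    and aromatic systems pass, as do hypervalent oxo groups (sulfonyl,
    phosphoryl, nitro): every true cumulene (allene, ketene, isocyanate,
    carbodiimide) has a carbon at its center.
    """
    for atom in rec.mol.GetAtoms():
        if atom.GetAtomicNum() != 6:
            continue
        n_double = sum(
            1
            for b in atom.GetBonds()
            if b.GetBondType() == Chem.BondType.DOUBLE and not b.GetIsAromatic()
        )
        if n_double >= 2:
            return Violation("cumulated_double_bond", f"atom index {atom.GetIdx()} carries {n_double} double bonds")
    return None


def _fused_systems(rings: list[tuple[int, ...]]) -> list[list[int]]:
    """Connected components of the ring-adjacency graph (rings as nodes,
    an edge where two rings share at least one atom)."""
    g = nx.Graph()
    g.add_nodes_from(range(len(rings)))
    sets = [set(r) for r in rings]
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            if sets[i] & sets[j]:
                g.add_edge(i, j)
    return [sorted(c) for c in nx.connected_components(g)]


def ring_system_check(rec: MoleculeRecord, config: FilterConfig | None = None) -> list[Violation]:
    """Ring rules: (a) every SSSR ring must be 5- or 6-membered, (b) no
    fused system of more than four rings, (c) no fused system whose
    ring-adjacency graph contains a cycle (bridged/cage topologies such
    as adamantane)."""
    config = config or FilterConfig()
    rings = [tuple(r) for r in Chem.GetSSSR(rec.mol)]
    violations: list[Violation] = []
    for r in rings:
        if len(r) not in config.allowed_ring_sizes:
            violations.append(Violation("ring_size", f"{len(r)}-membered ring"))
    systems = _fused_systems(rings)
    for comp in systems:
        if len(comp) < 2:
            continue
        if config.fused_count_unit == "rings":
            size = len(comp)
        else:
            size = len(set().union(*(set(rings[i]) for i in comp)))
        if size > config.max_fused_rings:
            violations.append(
                Violation("fused_count", f"fused system of {size} {config.fused_count_unit}")
            )
        # a tree of k fused rings has k-1 adjacency edges; more => loop
        sets = [set(rings[i]) for i in comp]
        n_edges = sum(
            1 for i in range(len(sets)) for j in range(i + 1, len(sets)) if sets[i] & sets[j]
        )
        if n_edges > len(comp) - 1:
            violations.append(Violation("ring_loop", f"ring-adjacency cycle among {len(comp)} rings"))
    return violations


_RDKIT_PAINS = {
    "A": FilterCatalogParams.FilterCatalogs.PAINS_A,
    "B": FilterCatalogParams.FilterCatalogs.PAINS_B,
    "C": FilterCatalogParams.FilterCatalogs.PAINS_C,
}


def load_pains_catalog(config: FilterConfig | None = None):
    """Build the PAINS matcher: either a custom SMARTS file
    (``SMARTS<whitespace>name`` per line) or the packaged RDKit PAINS
    families.  Malformed custom entries raise ConfigurationError.
    Returns a list of (name, query-mol) pairs.
    """
    config = config or FilterConfig()
    if config.pains_catalog_path is not None:
        entries: list[tuple[str, Chem.Mol]] = []
        with open(config.pains_catalog_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                smarts = parts[0]
                name = parts[1].strip() if len(parts) > 1 else f"pattern_{lineno}"
                query = Chem.MolFromSmarts(smarts)
                if query is None:
                    raise ConfigurationError(
                        f"{config.pains_catalog_path}:{lineno}: malformed SMARTS {smarts!r}"
                    )
                entries.append((name, query))
        return entries
    params = FilterCatalogParams()
    for fam in config.pains_families:
        if fam not in _RDKIT_PAINS:
            raise ConfigurationError(f"unknown PAINS family {fam!r} (expected A/B/C)")
        params.AddCatalog(_RDKIT_PAINS[fam])
    return FilterCatalog(params)


def pains_check(rec: MoleculeRecord, catalog=None) -> list[str]:
    """Return the names of every matched PAINS pattern (empty = pass)."""
    if catalog is None:
        catalog = load_pains_catalog()
    if isinstance(catalog, list):  # custom SMARTS entries
        return [name for name, query in catalog if rec.mol.HasSubstructMatch(query)]
    return [e.GetDescription() for e in catalog.GetMatches(rec.mol)]


def drug_like_check(rec: MoleculeRecord, ranges: dict | None = None) -> list[Violation]:
    """One violation per property outside its configured [min, max]."""
    ranges = ranges if ranges is not None else DEFAULT_RANGES
    props = compute_properties(rec)
    violations = []
    for name, (lo, hi) in ranges.items():
        if lo > hi:
            raise ConfigurationError(f"inverted range for {name}: [{lo}, {hi}]")
        value = getattr(props, name)
        if not (lo <= value <= hi):
            violations.append(
                Violation(f"property:{name}", f"{name}={value:.3g} outside [{lo:.3g}, {hi:.3g}]")
            )
    return violations


def apply_filter_stack(
    records: list[MoleculeRecord], config: FilterConfig | None = None
) -> tuple[list[MoleculeRecord], list[FilterReport]]:
    """Run all enabled sub-filters over every molecule.

    A molecule survives iff every enabled sub-filter passes; reports are
    emitted for every input and input order is preserved among
    survivors.
    """
    config = config or FilterConfig()
    catalog = load_pains_catalog(config) if config.enable_pains else None
    survivors: list[MoleculeRecord] = []
    reports: list[FilterReport] = []
    for rec in records:
        failures: list[Violation] = []
        if config.enable_structure:
            v = cumulated_double_bond_check(rec)
            if v is not None:
                failures.append(v)
            failures.extend(ring_system_check(rec, config))
        if config.enable_pains:
            for name in pains_check(rec, catalog):
                failures.append(Violation("pains", name))
        if config.enable_properties:
            failures.extend(drug_like_check(rec, config.property_ranges))
        passed = not failures
        reports.append(FilterReport(id=rec.id, passed=passed, failures=tuple(failures)))
        if passed:
            survivors.append(rec)
    return survivors, reports


def write_filter_report(reports: list[FilterReport], path) -> None:
    import pandas as pd

    rows = []
    for r in reports:
        if r.failures:
            for v in r.failures:
                rows.append({"id": r.id, "passed": r.passed, "rule": v.rule, "detail": v.detail})
        else:
            rows.append({"id": r.id, "passed": True, "rule": "", "detail": ""})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
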