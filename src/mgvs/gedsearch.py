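"""Graph-edit-distance similarity search over anonymous molecular
topologies.

A molecule's *anonymous graph* is its heavy-atom connectivity with all
element, charge, aromaticity and bond-order labels stripped.  The edit
set consists of the four connectivity-preserving operations

* add a terminal node (with its single edge),
* delete a degree-1 node (with its edge),
* add an edge between existing nodes (ring closure),
* delete an edge whose removal keeps the graph connected (ring opening),

so the GED between two topologies is the shortest-path distance in the
lattice of anonymous graphs under single edits.  Because every edit is
invertible the distance is symmetric, and as a shortest-path metric it
satisfies the triangle inequality.

A compound library is pre-indexed by bucketing compounds under a
canonical key of their anonymous graph; a query then expands edit
shells outward from its own key, resolving buckets shell by shell so
closer topologies are exhausted before farther ones.  ``exact_ged`` is
an independent admissible best-first search usable as an oracle for
the index traversal.
"""

from __future__ import annotations

import gzip
import heapq
import itertools
import json
from dataclasses import dataclass, field

from rdkit import Chem

from .chemio import MoleculeRecord
from .fingerprints import circular_fingerprint, path_fingerprint, tanimoto_distance

__all__ = [
    "AnonymousGraph",
    "SearchHit",
    "GEDIndex",
    "anonymize",
    "canonical_key",
    "edit_neighbors",
    "exact_ged",
    "exact_ged_reference",
    "degree_sequence",
    "graph_lower_bound",
    "make_expansion_cache",
    "build_index",
    "query_index",
]


@dataclass(frozen=True)
class AnonymousGraph:
    """Simple undirected unlabeled graph with node ids 0..n-1."""

    n_nodes: int
    edges: frozenset  # of (u, v) tuples with u < v

    def __post_init__(self):
        for u, v in self.edges:
            if u == v:
                raise ValueError("self-loops are not allowed")
            if not (0 <= u < v < self.n_nodes):
                raise ValueError(f"edge ({u},{v}) out of range for n={self.n_nodes}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def is_connected(self) -> bool:
        if self.n_nodes <= 1:
            return True
        adj = self.adjacency()
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for w in adj[u]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return len(seen) == self.n_nodes


@dataclass(frozen=True)
class SearchHit:
    query_id: str
    hit_id: str
    ged: int
    daylight_dist: float
    ecfp4_dist: float

    def sort_key(self):
        return (self.ged, self.daylight_dist, self.hit_id)


def anonymize(rec: MoleculeRecord) -> AnonymousGraph:
    """Strip a molecule to its heavy-atom skeleton (hydrogens excluded,
    all atom/bond labels dropped)."""
    mol = Chem.RemoveHs(rec.mol)
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    remap = {idx: i for i, idx in enumerate(heavy)}
    edges = set()
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in remap and j in remap:
            u, v = sorted((remap[i], remap[j]))
            edges.add((u, v))
    return AnonymousGraph(n_nodes=len(heavy), edges=frozenset(edges))


def canonical_key(g: AnonymousGraph) -> str:
    """Canonical string key: two anonymous graphs share a key iff they
    are isomorphic.

    The graph is encoded as an unlabeled skeleton (every node a bare
    heavy atom, every edge a single bond, valence checks disabled) and
    canonicalized with the toolkit's canonical-ranking algorithm, which
    is stable across runs and platforms.
    """
    if not g.is_connected():
        raise ValueError("canonical_key requires a connected graph")
    rw = Chem.RWMol()
    for _ in range(g.n_nodes):
        a = Chem.Atom(6)
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    for u, v in g.edges:
        rw.AddBond(u, v, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.FastFindRings(mol)
    return Chem.MolToSmiles(mol, canonical=True)


def _renumber_without(g: AnonymousGraph, drop: int) -> AnonymousGraph:
    remap = {u: (u if u < drop else u - 1) for u in range(g.n_nodes) if u != drop}
    edges = frozenset(
        (min(remap[u], remap[v]), max(remap[u], remap[v]))
        for u, v in g.edges
        if u != drop and v != drop
    )
    return AnonymousGraph(n_nodes=g.n_nodes - 1, edges=edges)


def _connected_without_edge(g: AnonymousGraph, edge: tuple[int, int]) -> bool:
    adj = g.adjacency()
    u0, v0 = edge
    adj[u0].discard(v0)
    adj[v0].discard(u0)
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for w in adj[u]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == g.n_nodes


def edit_neighbors(g: AnonymousGraph):
    """Yield every graph reachable from ``g`` by one edit (with
    isomorphic duplicates; callers deduplicate by canonical key)."""
    degree = [0] * g.n_nodes
    for u, v in g.edges:
        degree[u] += 1
        degree[v] += 1
    # terminal node additions
    for u in range(g.n_nodes):
        yield AnonymousGraph(g.n_nodes + 1, g.edges | {(u, g.n_nodes)})
    # terminal node deletions
    if g.n_nodes > 1:
        for u in range(g.n_nodes):
            if degree[u] == 1:
                yield _renumber_without(g, u)
    # edge additions (ring closures)
    for u, v in itertools.combinations(range(g.n_nodes), 2):
        if (u, v) not in g.edges:
            yield AnonymousGraph(g.n_nodes, g.edges | {(u, v)})
    # edge deletions that keep the graph connected (ring openings)
    for e in g.edges:
        if _connected_without_edge(g, e):
            yield AnonymousGraph(g.n_nodes, g.edges - {e})


def _lower_bound(n1: int, m1: int, n2: int, m2: int) -> int:
    """Admissible GED lower bound: node edits change (n, m-n) by
    (+-1, 0), edge edits by (0, +-1), so at least |dn| node edits and
    |d(m-n)| edge edits are needed."""
    return abs(n1 - n2) + abs((m1 - n1) - (m2 - n2))


def degree_sequence(g: AnonymousGraph) -> tuple[int, ...]:
    """Non-increasing degree sequence."""
    deg = [0] * g.n_nodes
    for u, v in g.edges:
        deg[u] += 1
        deg[v] += 1
    return tuple(sorted(deg, reverse=True))


def _degree_lb(d1: tuple[int, ...], d2: tuple[int, ...]) -> int:
    """Admissible GED lower bound from degree sequences.

    Pad the shorter sequence with zeros (a node not yet added has
    degree 0) and take the L1 distance of the sorted sequences, which
    is the minimum-cost matching for 1-D multisets.  Every edit changes
    at most two degree entries by 1 each (edge edits touch two
    endpoints; node edits create/remove a degree-1 entry and shift one
    neighbor), so the matching distance moves by at most 2 per edit and
    ceil(L1/2) never overestimates.  It also changes by at most 1 per
    edit, making it a consistent A* heuristic.
    """
    k = max(len(d1), len(d2))
    a = list(d1) + [0] * (k - len(d1))
    b = list(d2) + [0] * (k - len(d2))
    l1 = sum(abs(x - y) for x, y in zip(a, b))
    return (l1 + 1) // 2


def graph_lower_bound(g1: AnonymousGraph, g2: AnonymousGraph) -> int:
    """Best available admissible lower bound on GED(g1, g2)."""
    return max(
        _lower_bound(g1.n_nodes, g1.n_edges, g2.n_nodes, g2.n_edges),
        _degree_lb(degree_sequence(g1), degree_sequence(g2)),
    )


def _expand_fresh(key: str, g: AnonymousGraph):
    # entries are mutable: [graph, degree sequence, canonical key or None].
    # The key is filled lazily by the caller only for neighbors that
    # survive heuristic pruning -- canonicalization dominates runtime.
    return [[nb, degree_sequence(nb), None] for nb in edit_neighbors(g)]


def make_expansion_cache():
    """Memoized single-edit expansion (canonical key -> neighbor
    entries).  Neighborhoods are query-independent, so one cache can be
    shared by every GED computation of the same search, amortizing both
    neighbor generation and (lazily filled) canonicalization.
    """
    cache: dict[str, list] = {}

    def expand(key: str, g: AnonymousGraph):
        out = cache.get(key)
        if out is None:
            out = _expand_fresh(key, g)
            cache[key] = out
        return out

    return expand


def exact_ged(
    g1: AnonymousGraph, g2: AnonymousGraph, max_d: int = 12, expand=None
) -> int | None:
    """Exact graph edit distance by admissible best-first (A*) search
    over edit sequences; returns None if the distance exceeds ``max_d``.
    ``expand`` may be a shared :func:`make_expansion_cache` instance.
    """
    if max_d < 0:
        raise ValueError("max_d must be >= 0")
    if not g1.is_connected() or not g2.is_connected():
        raise ValueError("exact_ged requires connected graphs")
    expand = expand or _expand_fresh
    k_target = canonical_key(g2)
    k_start = canonical_key(g1)
    if k_start == k_target:
        return 0
    n2, m2 = g2.n_nodes, g2.n_edges
    d_target = degree_sequence(g2)

    def h_of(n: int, m: int, deg) -> int:
        return max(_lower_bound(n, m, n2, m2), _degree_lb(deg, d_target))

    h0 = h_of(g1.n_nodes, g1.n_edges, degree_sequence(g1))
    if h0 > max_d:
        return None
    # Both heuristic components are consistent (each edit changes them
    # by at most 1), so the depth at pop time is the exact distance to
    # that state and the goal test is done at pop, not at generation.
    # Ties on f prefer deeper states (-d), which reaches the goal with
    # far fewer expansions without affecting optimality.
    counter = itertools.count()
    heap = [(h0, 0, next(counter), k_start, g1)]
    best_g: dict[str, int] = {k_start: 0}
    while heap:
        f, negd, _, key, g = heapq.heappop(heap)
        d = -negd
        if f > max_d:
            return None
        if key == k_target:
            return d
        if best_g.get(key, d) < d:
            continue  # stale entry
        for entry in expand(key, g):
            nb, ndeg, nk = entry
            nd = d + 1
            h = h_of(nb.n_nodes, nb.n_edges, ndeg)
            if nd + h > max_d:
                continue
            if nk is None:
                nk = canonical_key(nb)
                entry[2] = nk
            if best_g.get(nk, nd + 1) <= nd:
                continue
            best_g[nk] = nd
            heapq.heappush(heap, (nd + h, -nd, next(counter), nk, nb))
    return None


def exact_ged_reference(g1: AnonymousGraph, g2: AnonymousGraph, max_d: int = 12) -> int | None:
    """Brute-force GED oracle: plain breadth-first enumeration of edit
    shells from ``g1`` with no heuristic or pruning beyond canonical
    deduplication.  Exponentially slower than :func:`exact_ged`; exists
    only to validate the optimized search on toy-sized problems.
    """
    if max_d < 0:
        raise ValueError("max_d must be >= 0")
    k_target = canonical_key(g2)
    frontier = {canonical_key(g1): g1}
    if k_target in frontier:
        return 0
    seen = set(frontier)
    for depth in range(1, max_d + 1):
        nxt: dict[str, AnonymousGraph] = {}
        for g in frontier.values():
            for nb in edit_neighbors(g):
                nk = canonical_key(nb)
                if nk in seen:
                    continue
                seen.add(nk)
                if nk == k_target:
                    return depth
                nxt[nk] = nb
        frontier = nxt
        if not frontier:
            return None
    return None


@dataclass
class GEDIndex:
    """Bucketed anonymous-topology index over a compound library.

    ``buckets`` maps each canonical key to the ids of all library
    compounds with that topology; ``key_graphs`` keeps one
    representative anonymous graph per key; ``lattice`` links bucket
    keys at edit distance 1 (symmetric).
    """

    buckets: dict[str, list[str]] = field(default_factory=dict)
    key_graphs: dict[str, AnonymousGraph] = field(default_factory=dict)
    lattice: dict[str, set[str]] = field(default_factory=dict)
    molecules: dict[str, MoleculeRecord] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.molecules)

    def save(self, path) -> None:
        payload = {
            "format": "mgvs-gix/1",
            "params": self.params,
            "compounds": [
                {"id": rec.id, "smiles": rec.smiles, "source": rec.source}
                for rec in self.molecules.values()
            ],
        }
        with gzip.open(path, "wt") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "GEDIndex":
        from .chemio import parse_molecule

        with gzip.open(path, "rt") as fh:
            payload = json.load(fh)
        if payload.get("format") != "mgvs-gix/1":
            raise ValueError(f"unrecognized index format in {path}")
        library = [
            parse_molecule(c["smiles"], c["id"], source=c.get("source", "library"))
            for c in payload["compounds"]
        ]
        return build_index(library, **payload.get("params", {}))


def build_index(library: list[MoleculeRecord], build_lattice: bool = True, **params) -> GEDIndex:
    """Bucket a library by canonical anonymous-graph key and (optionally)
    precompute lattice edges between keys at edit distance 1."""
    index = GEDIndex(params={"build_lattice": build_lattice, **params})
    for rec in library:
        if rec.id in index.molecules:
            raise ValueError(f"duplicate compound id {rec.id!r} in library")
        g = anonymize(rec)
        if not g.is_connected():
            raise ValueError(f"compound {rec.id!r} is disconnected (multi-fragment)")
        key = canonical_key(g)
        index.buckets.setdefault(key, []).append(rec.id)
        index.key_graphs.setdefault(key, g)
        index.molecules[rec.id] = rec
    if build_lattice:
        keys = set(index.buckets)
        for key, g in index.key_graphs.items():
            for nb in edit_neighbors(g):
                nk = canonical_key(nb)
                if nk in keys and nk != key:
                    index.lattice.setdefault(key, set()).add(nk)
                    index.lattice.setdefault(nk, set()).add(key)
    return index


def query_index(
    index: GEDIndex,
    query: MoleculeRecord,
    max_ged: int = 12,
    max_hits: int = 1000,
) -> list[SearchHit]:
    """Exact analog search: one A* graph-edit-distance computation per
    topology bucket, processed in ascending lower-bound order.

    Early stop is lossless: once the compounds already resolved at
    distance < L (the next bucket's lower bound) number at least
    ``max_hits``, no remaining bucket can enter the top ``max_hits``
    under the (ged, Daylight distance, id) ordering.  Returned hits are
    sorted by that ordering and truncated to ``max_hits``.
    """
    qg = anonymize(query)
    if not qg.is_connected():
        raise ValueError(f"query {query.id!r} is disconnected")
    qkey = canonical_key(qg)

    order = sorted(
        (
            (graph_lower_bound(qg, g) if key != qkey else 0, key)
            for key, g in index.key_graphs.items()
        ),
    )
    resolved: dict[str, int] = {}
    expand = make_expansion_cache()

    def n_better_than(L: int) -> int:
        return sum(len(index.buckets[k]) for k, d in resolved.items() if d < L)

    for lb, key in order:
        if lb > max_ged:
            break
        if n_better_than(lb) >= max_hits:
            break
        if key == qkey:
            resolved[key] = 0
            continue
        d = exact_ged(qg, index.key_graphs[key], max_d=max_ged, expand=expand)
        if d is not None:
            resolved[key] = d

    q_path = path_fingerprint(query)
    q_circ = circular_fingerprint(query)
    hits: list[SearchHit] = []
    for key, ged in resolved.items():
        for hit_id in index.buckets[key]:
            rec = index.molecules[hit_id]
            hits.append(
                SearchHit(
                    query_id=query.id,
                    hit_id=hit_id,
                    ged=ged,
                    daylight_dist=tanimoto_distance(q_path, path_fingerprint(rec)),
                    ecfp4_dist=tanimoto_distance(q_circ, circular_fingerprint(rec)),
                )
            )
    hits.sort(key=SearchHit.sort_key)
    return hits[:max_hits]
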