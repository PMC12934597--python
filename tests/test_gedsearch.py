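import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgvs.chemio import parse_molecule
from mgvs.gedsearch import (
    AnonymousGraph,
    GEDIndex,
    anonymize,
    build_index,
    canonical_key,
    degree_sequence,
    edit_neighbors,
    exact_ged,
    exact_ged_reference,
    graph_lower_bound,
    query_index,
)


def graph_of(smiles):
    return anonymize(parse_molecule(smiles, smiles))


def path_graph(n):
    return AnonymousGraph(n, frozenset((i, i + 1) for i in range(n - 1)))


def cycle_graph(n):
    return AnonymousGraph(n, frozenset({(i, (i + 1) % n) if i + 1 < n else (0, n - 1) for i in range(n)}))


@st.composite
def connected_graphs(draw, max_n=7):
    """Random connected graph: a random spanning tree plus extra edges."""
    n = draw(st.integers(min_value=1, max_value=max_n))
    edges = set()
    for v in range(1, n):
        u = draw(st.integers(min_value=0, max_value=v - 1))
        edges.add((u, v))
    candidates = [(u, v) for u in range(n) for v in range(u + 1, n) if (u, v) not in edges]
    for e in candidates:
        if draw(st.booleans()) and draw(st.booleans()):
            edges.add(e)
    return AnonymousGraph(n, frozenset(edges))


def test_anonymize_strips_element_and_bond_labels():
    keys = {canonical_key(graph_of(s)) for s in ("c1ccccc1", "C1CCCCC1", "c1ccncc1")}
    assert len(keys) == 1
    assert canonical_key(graph_of("CCO")) == canonical_key(graph_of("CCC"))


@settings(max_examples=60, deadline=None)
@given(connected_graphs(), st.randoms(use_true_random=False))
def test_canonical_key_is_relabel_invariant(g, rnd):
    perm = list(range(g.n_nodes))
    rnd.shuffle(perm)
    relabeled = AnonymousGraph(
        g.n_nodes, frozenset(tuple(sorted((perm[u], perm[v]))) for u, v in g.edges)
    )
    assert canonical_key(g) == canonical_key(relabeled)


def test_canonical_key_separates_nonisomorphic_graphs():
    # same node and edge counts, different structure
    star = AnonymousGraph(4, frozenset({(0, 1), (0, 2), (0, 3)}))
    assert canonical_key(path_graph(4)) != canonical_key(star)


@settings(max_examples=40, deadline=None)
@given(connected_graphs(max_n=6))
def test_edit_neighbors_are_connected_and_reversible(g):
    key = canonical_key(g)
    for nb in edit_neighbors(g):
        assert nb.is_connected()
        # terminal add/delete moves a node and its edge together; edge
        # add/delete moves only an edge
        delta = (nb.n_nodes - g.n_nodes, nb.n_edges - g.n_edges)
        assert delta in {(1, 1), (-1, -1), (0, 1), (0, -1)}
        back = {canonical_key(x) for x in edit_neighbors(nb)}
        assert key in back  # every edit has an inverse edit


def test_exact_ged_known_values():
    assert exact_ged(path_graph(3), path_graph(3)) == 0
    assert exact_ged(path_graph(3), path_graph(4)) == 1
    assert exact_ged(cycle_graph(6), path_graph(6)) == 1  # delete one cycle edge
    assert exact_ged(graph_of("Cc1ccccc1"), graph_of("c1ccccc1")) == 1
    assert exact_ged(path_graph(2), cycle_graph(6)) == 5
    assert exact_ged(path_graph(2), cycle_graph(6), max_d=4) is None


@settings(max_examples=30, deadline=None)
@given(connected_graphs(max_n=6), connected_graphs(max_n=6))
def test_exact_ged_agrees_with_brute_force(g1, g2):
    assert exact_ged(g1, g2, max_d=3) == exact_ged_reference(g1, g2, max_d=3)


@settings(max_examples=30, deadline=None)
@given(connected_graphs(max_n=6), connected_graphs(max_n=6))
def test_lower_bound_is_admissible(g1, g2):
    d = exact_ged(g1, g2, max_d=4)
    if d is not None:
        assert graph_lower_bound(g1, g2) <= d


def test_degree_sequence():
    assert degree_sequence(path_graph(4)) == (2, 2, 1, 1)
    assert degree_sequence(cycle_graph(5)) == (2, 2, 2, 2, 2)


@pytest.fixture(scope="module")
def toy_index():
    lib = [
        ("CCCC", "butane"),
        ("CCCCC", "pentane"),
        ("CC(C)C", "isobutane"),
        ("C1CCCCC1", "cyclohexane"),
        ("c1ccccc1", "benzene"),       # same bucket as cyclohexane
        ("Cc1ccccc1", "toluene"),
        ("CCO", "ethanol_c3"),         # 3-node path
    ]
    return build_index([parse_molecule(s, i) for s, i in lib])


def test_build_index_buckets_by_topology(toy_index):
    key = canonical_key(graph_of("C1CCCCC1"))
    assert sorted(toy_index.buckets[key]) == ["benzene", "cyclohexane"]


def test_build_index_rejects_duplicates_and_fragments():
    with pytest.raises(ValueError, match="duplicate"):
        build_index([parse_molecule("CC", "a"), parse_molecule("CCC", "a")])
    with pytest.raises(ValueError, match="disconnected"):
        build_index([parse_molecule("CC.CC", "frag")])


def test_query_results_match_pairwise_oracle(toy_index):
    query = parse_molecule("CCCC", "q")
    hits = query_index(toy_index, query, max_ged=3, max_hits=100)
    got = {h.hit_id: h.ged for h in hits}
    qg = anonymize(query)
    expected = {}
    for hit_id, rec in toy_index.molecules.items():
        d = exact_ged_reference(qg, anonymize(rec), max_d=3)
        if d is not None:
            expected[hit_id] = d
    assert got == expected


def test_query_hits_sorted_and_truncated(toy_index):
    query = parse_molecule("CCCC", "q")
    hits = query_index(toy_index, query, max_ged=3, max_hits=100)
    keys = [h.sort_key() for h in hits]
    assert keys == sorted(keys)
    top2 = query_index(toy_index, query, max_ged=3, max_hits=2)
    assert [h.hit_id for h in top2] == [h.hit_id for h in hits[:2]]


def test_query_early_stop_is_lossless(toy_index):
    # a ged-0 bucket large enough to satisfy max_hits immediately
    query = parse_molecule("C1CCCCC1", "q")
    hits = query_index(toy_index, query, max_ged=3, max_hits=2)
    assert {h.hit_id for h in hits} == {"benzene", "cyclohexane"}
    assert all(h.ged == 0 for h in hits)


def test_index_save_load_round_trip(toy_index, tmp_path):
    path = tmp_path / "toy.gix"
    toy_index.save(path)
    back = GEDIndex.load(path)
    assert back.size == toy_index.size
    assert set(back.buckets) == set(toy_index.buckets)
    q = parse_molecule("CCCC", "q")
    assert [h.hit_id for h in query_index(back, q, max_ged=2, max_hits=10)] == [
        h.hit_id for h in query_index(toy_index, q, max_ged=2, max_hits=10)
    ]
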