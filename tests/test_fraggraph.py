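import numpy as np
import pytest

from bruteforce import brute_bridges, brute_fragment_depths, brute_two_cuts
from fragrank.chem import MetaboliteEdge, MetaboliteGraph, MetaboliteNode
from fragrank.fixtures import random_metabolite_graph
from fragrank.fraggraph import (
    DEFAULT_RULES,
    FragmentGraphTooLarge,
    CacheMismatchError,
    build_fragmentation_graph,
    depth_one_fragments,
    find_bridges,
    find_two_cuts,
    fragment_mass,
    load_cache,
    make_decoy,
    rule_hash,
    save_cache,
)

H = 1.007825


def _graph(n, edges, masses=None, mol_id="g"):
    nodes = tuple(
        MetaboliteNode(frozenset({i}), (masses or [10.0 * (i + 1) for i in range(n)])[i])
        for i in range(n)
    )
    return MetaboliteGraph(mol_id, nodes, tuple(edges))


def path_graph(n, bond="CC"):
    return _graph(n, [MetaboliteEdge(i, i + 1, bond) for i in range(n - 1)])


def cycle_graph(n, bond="CC"):
    edges = [MetaboliteEdge(i, (i + 1) % n, bond) for i in range(n)]
    return _graph(n, edges)


def test_path_edges_are_all_bridges():
    assert find_bridges(path_graph(3)) == [0, 1]


def test_cycle_has_no_bridges_and_all_pairs_are_two_cuts():
    g6 = cycle_graph(6)
    assert find_bridges(g6) == []
    assert len(find_two_cuts(g6)) == 15  # C(6,2)


def test_triangle_two_cuts():
    assert len(find_two_cuts(cycle_graph(3))) == 3


def test_tree_has_no_two_cuts():
    assert find_two_cuts(path_graph(5)) == []


def test_parallel_edges_are_not_bridges():
    g = _graph(2, [MetaboliteEdge(0, 1, "CC"), MetaboliteEdge(0, 1, "CC")])
    assert find_bridges(g) == []
    assert find_two_cuts(g) == [(0, 1)]


@pytest.mark.parametrize("trial", range(60))
def test_cut_enumeration_matches_bruteforce(rng, trial):
    n = int(rng.integers(2, 11))
    g = random_metabolite_graph(
        rng, n, int(rng.integers(0, 4)), allow_parallel=bool(rng.integers(0, 2))
    )
    assert find_bridges(g) == sorted(brute_bridges(g))
    assert find_two_cuts(g) == brute_two_cuts(g)


def test_ethanol_depth_one_fragments(ethanol_graph):
    frags = depth_one_fragments(ethanol_graph)
    assert len(frags) == 4  # both sides of each of the two bridges
    assert all(f.depth == 1 for f in frags)


def test_single_node_graph_is_root_only():
    g = _graph(1, [])
    assert depth_one_fragments(g) == []
    fg = build_fragmentation_graph(g)
    assert len(fg) == 1 and fg.root.bond_type == "root"


def test_ethanol_fragmentation_graph(ethanol_fg):
    """Path-shaped molecule: root, 4 depth-1 sides, and the middle node at
    depth 2 (the intersection of the two large depth-1 fragments)."""
    assert len(ethanol_fg) == 6
    depths = sorted(f.depth for f in ethanol_fg.fragments)
    assert depths == [0, 1, 1, 1, 1, 2]


def test_hydrogen_rearrangement_offsets(ethanol_graph):
    """Severed O-C bonds move one hydrogen to the heteroatom side."""
    oh_node = next(
        i for i, n in enumerate(ethanol_graph.nodes) if abs(n.mass - 17.0027) < 1e-3
    )
    mass = fragment_mass(ethanol_graph, 1 << oh_node)
    assert mass == pytest.approx(17.0027 + H, abs=1e-4)
    # the carbon side of the same cut gains nothing
    rest = ((1 << ethanol_graph.n_nodes) - 1) ^ (1 << oh_node)
    carbon_side = fragment_mass(ethanol_graph, rest)
    expected = sum(
        n.mass for i, n in enumerate(ethanol_graph.nodes) if i != oh_node
    )
    assert carbon_side == pytest.approx(expected, abs=1e-6)


@pytest.mark.parametrize("trial", range(40))
def test_fragment_sets_match_bruteforce(rng, trial):
    n = int(rng.integers(2, 10))
    g = random_metabolite_graph(
        rng, n, int(rng.integers(0, 3)), allow_parallel=bool(rng.integers(0, 2))
    )
    fg = build_fragmentation_graph(g)
    impl = {f.bitvector: f.depth for f in fg.fragments}
    assert impl == brute_fragment_depths(g)


def test_fragment_count_monotone_in_budgets(rng):
    for _ in range(10):
        g = random_metabolite_graph(rng, int(rng.integers(3, 9)), 2)
        counts = {}
        for mb in (0, 1, 2, 3):
            for mt in (0, 1, 2):
                counts[(mb, mt)] = len(build_fragmentation_graph(g, mb, mt))
        for (mb, mt), c in counts.items():
            if (mb + 1, mt) in counts:
                assert counts[(mb + 1, mt)] >= c
            if (mb, mt + 1) in counts:
                assert counts[(mb, mt + 1)] >= c


def test_deep_fragments_are_parent_intersections(rng):
    """Construction identity: every depth>=2 fragment equals some parent
    ANDed with a depth-1 fragment."""
    for _ in range(20):
        g = random_metabolite_graph(rng, int(rng.integers(3, 10)), int(rng.integers(0, 3)))
        fg = build_fragmentation_graph(g)
        d1 = [f.bitvector for f in fg.fragments if f.depth == 1]
        for f in fg.fragments:
            if f.depth < 2:
                continue
            assert any(
                fg.fragments[p].bitvector & d == f.bitvector
                for p in f.parents
                for d in d1
            )


def test_dag_structure(ethanol_fg):
    assert ethanol_fg.fragments[0].depth == 0
    for i, f in enumerate(ethanol_fg.fragments[1:], 1):
        assert f.parents, f"fragment {i} unreachable"
        assert all(
            ethanol_fg.fragments[p].depth == f.depth - 1 for p in f.parents
        )
    bitvectors = [f.bitvector for f in ethanol_fg.fragments]
    assert len(set(bitvectors)) == len(bitvectors)


def test_fragment_cap_raises():
    g = cycle_graph(12)
    with pytest.raises(FragmentGraphTooLarge):
        build_fragmentation_graph(g, max_fragments=5)


def test_decoy_preserves_structure(rng):
    g = random_metabolite_graph(rng, 6, 2)
    fg = build_fragmentation_graph(g)
    decoy = make_decoy(fg, seed=5)
    assert decoy.is_decoy and not decoy.decoy_warning
    assert decoy.root.mass == fg.root.mass
    assert sorted(f.mass for f in decoy.fragments[1:]) == sorted(
        f.mass for f in fg.fragments[1:]
    )
    assert [f.depth for f in decoy.fragments] == [f.depth for f in fg.fragments]
    assert [f.bond_type for f in decoy.fragments] == [
        f.bond_type for f in fg.fragments
    ]
    assert decoy.edges == fg.edges
    # determinism, and some mass actually moved
    again = make_decoy(fg, seed=5)
    assert [f.mass for f in again.fragments] == [f.mass for f in decoy.fragments]
    assert any(
        a.mass != b.mass for a, b in zip(decoy.fragments[1:], fg.fragments[1:])
    )


def test_decoy_of_tiny_graph_is_flagged():
    fg = build_fragmentation_graph(_graph(1, []))
    decoy = make_decoy(fg, seed=1)
    assert decoy.decoy_warning
    assert [f.mass for f in decoy.fragments] == [f.mass for f in fg.fragments]


def test_cache_roundtrip(tmp_path, ethanol_fg):
    path = tmp_path / "cache.json"
    save_cache(path, [ethanol_fg])
    loaded = load_cache(path)
    assert set(loaded) == {"ethanol"}
    fg2 = loaded["ethanol"]
    assert [f.bitvector for f in fg2.fragments] == [
        f.bitvector for f in ethanol_fg.fragments
    ]
    assert [round(f.mass, 6) for f in fg2.fragments] == [
        round(f.mass, 6) for f in ethanol_fg.fragments
    ]
    other_rules = dict(DEFAULT_RULES, CC=(H, 0.0))
    assert rule_hash(other_rules) != rule_hash(DEFAULT_RULES)
    with pytest.raises(CacheMismatchError):
        load_cache(path, rules=other_rules)
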