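"""Fragmentation-graph construction by bridge and 2-cut enumeration.

Collision-induced dissociation is modelled as repeated cleavage events on the
metabolite graph: a *bridge* cut severs one edge whose removal disconnects
the current fragment, a *2-cut* severs a pair of non-bridge edges whose joint
removal disconnects it.  Fragments are encoded as bitvectors over metabolite
graph nodes and arranged in a rooted DAG whose source is the intact molecule.
A root-to-fragment path may use at most ``max_bridges`` bridge cuts and at
most ``max_two_cuts`` 2-cuts (defaults 2 and 1, so depth is at most 3).

Children of a fragment are the two sides of each bridge and each 2-cut of
its induced subgraph, so every depth-n fragment arises from a genuine
cleavage event of its parent; as a consequence each such fragment also
equals the bitwise AND of a parent with a depth-one fragment, which the
bitvector encoding makes cheap to verify and exploit for deduplication.

Fragment masses are the summed node masses plus per-severed-edge hydrogen
offsets from a configurable rearrangement rule table; the default table moves
one hydrogen to the heteroatom side of a severed N-C or O-C bond and leaves
C-C cuts unadjusted.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .chem import (
    MONOISOTOPIC_MASS,
    MetaboliteEdge,
    MetaboliteGraph,
)

H_MASS = MONOISOTOPIC_MASS["H"]

#: bond_type -> (offset added to the heteroatom side, offset to the other
#: side) in Da, applied per severed edge.  Data, not code: pass a custom
#: table to :func:`build_fragmentation_graph` to change the chemistry.
DEFAULT_RULES: dict[str, tuple[float, float]] = {
    "NC": (H_MASS, 0.0),
    "OC": (H_MASS, 0.0),
    "CC": (0.0, 0.0),
    "SC": (H_MASS, 0.0),
    "OP": (H_MASS, 0.0),
    "PC": (H_MASS, 0.0),
}

#: The nine bond-type labels a non-root fragment can carry: three bridge
#: labels plus the six unordered 2-cut combinations (lexicographic).
BRIDGE_LABELS = ("CC", "NC", "OC")
TWO_CUT_LABELS = ("CC_CC", "CC_NC", "CC_OC", "NC_NC", "NC_OC", "OC_OC")
BOND_TYPE_LABELS = BRIDGE_LABELS + TWO_CUT_LABELS


def rule_hash(rules: dict[str, tuple[float, float]]) -> str:
    """Stable digest of a rearrangement rule table (keys cache validity)."""
    payload = json.dumps(
        {k: [round(a, 6), round(b, 6)] for k, (a, b) in sorted(rules.items())}
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:16]


class FragmentGraphTooLarge(RuntimeError):
    def __init__(self, molecule_id: str, cap: int):
        super().__init__(
            f"fragmentation graph of {molecule_id!r} exceeds {cap} fragments"
        )
        self.molecule_id = molecule_id


@dataclass
class Fragment:
    """A connected sub-structure of the metabolite graph.

    ``bitvector`` is an integer bitmask over metabolite-graph nodes (bit i
    set = node i present).  ``bond_type`` is the label of the cut that first
    produced the fragment (``root`` for the intact molecule).
    """

    bitvector: int
    mass: float
    depth: int
    bond_type: str
    parents: list[int] = field(default_factory=list)


@dataclass
class FragmentationGraph:
    molecule_id: str
    n_nodes: int
    fragments: list[Fragment]  # fragments[0] is the root
    edges: list[tuple[int, int, str]]  # (parent idx, child idx, bond_type)
    max_bridges: int = 2
    max_two_cuts: int = 1
    rules_digest: str = ""
    is_decoy: bool = False
    decoy_warning: bool = False

    @property
    def root(self) -> Fragment:
        return self.fragments[0]

    def __len__(self) -> int:
        return len(self.fragments)


# ---------------------------------------------------------------------------
# Bridges and 2-cuts


def _adjacency(edges: Sequence[tuple[int, int, int]]):
    adj: dict[int, list[tuple[int, int]]] = {}
    for idx, u, v in edges:
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    return adj


def _bridges_with_sides(
    nodes: Iterable[int], edges: Sequence[tuple[int, int, int]]
) -> list[tuple[int, int]]:
    """Bridges of the (multi)graph with the bitmask of one side each.

    Iterative Tarjan; parallel edges are handled by tracking the incoming
    edge index instead of the parent vertex, so a doubled edge is never
    reported as a bridge.  For a bridge, the returned mask is the DFS
    subtree below it, i.e. exactly the component cut off by removing it.
    """
    adj = _adjacency(edges)
    disc: dict[int, int] = {}
    low: dict[int, int] = {}
    submask: dict[int, int] = {}
    bridges: list[tuple[int, int]] = []
    timer = 0
    for start in nodes:
        if start in disc:
            continue
        stack = [(start, -1, iter(adj.get(start, ())))]
        disc[start] = low[start] = timer
        submask[start] = 1 << start
        timer += 1
        while stack:
            node, in_edge, it = stack[-1]
            advanced = False
            for nbr, eidx in it:
                if eidx == in_edge:
                    continue
                if nbr in disc:
                    low[node] = min(low[node], disc[nbr])
                else:
                    disc[nbr] = low[nbr] = timer
                    submask[nbr] = 1 << nbr
                    timer += 1
                    stack.append((nbr, eidx, iter(adj.get(nbr, ()))))
                    advanced = True
                    break
            if not advanced:
                stack.pop()
                if stack:
                    pnode = stack[-1][0]
                    low[pnode] = min(low[pnode], low[node])
                    submask[pnode] |= submask[node]
                    if low[node] > disc[pnode]:
                        bridges.append((in_edge, submask[node]))
    return bridges


def _bridge_set(
    nodes: Iterable[int], edges: Sequence[tuple[int, int, int]]
) -> set[int]:
    return {eidx for eidx, _ in _bridges_with_sides(nodes, edges)}


def find_bridges(g: MetaboliteGraph) -> list[int]:
    """Indices of edges whose single removal disconnects the graph."""
    edges = [(k, e.u, e.v) for k, e in enumerate(g.edges)]
    return sorted(_bridge_set(range(g.n_nodes), edges))


def find_two_cuts(g: MetaboliteGraph) -> list[tuple[int, int]]:
    """All unordered pairs of non-bridge edges whose joint removal
    disconnects the graph (pairs involving a bridge are compositions of
    sequential bridge cuts and are excluded)."""
    edges = [(k, e.u, e.v) for k, e in enumerate(g.edges)]
    return _two_cut_pairs(range(g.n_nodes), edges)


def _two_cut_pairs(
    nodes: Iterable[int], edges: Sequence[tuple[int, int, int]]
) -> list[tuple[int, int]]:
    nodes = list(nodes)
    bridges = _bridge_set(nodes, edges)
    non_bridges = [e for e in edges if e[0] not in bridges]
    pairs: set[tuple[int, int]] = set()
    for k, _, _ in non_bridges:
        remaining = [e for e in edges if e[0] != k]
        # removing a non-bridge keeps the graph connected; every *new*
        # bridge pairs with it as a 2-cut
        for f in _bridge_set(nodes, remaining):
            if f not in bridges:
                pairs.add((min(k, f), max(k, f)))
    return sorted(pairs)


# ---------------------------------------------------------------------------
# Fragment masses and connectivity over bitvectors


def _node_masses(g: MetaboliteGraph) -> list[float]:
    return [n.mass for n in g.nodes]


def fragment_mass(
    g: MetaboliteGraph,
    bitvector: int,
    rules: dict[str, tuple[float, float]] = DEFAULT_RULES,
) -> float:
    """Mass of the substructure: member node masses plus the rule-table
    hydrogen offsets for every boundary (severed) edge."""
    mass = 0.0
    bv = bitvector
    masses = _node_masses(g)
    while bv:
        i = (bv & -bv).bit_length() - 1
        mass += masses[i]
        bv &= bv - 1
    for e in g.edges:
        u_in = bool(bitvector >> e.u & 1)
        v_in = bool(bitvector >> e.v & 1)
        if u_in == v_in:
            continue
        hetero_off, other_off = rules.get(e.bond_type, (0.0, 0.0))
        inside = e.u if u_in else e.v
        if e.hetero is not None and e.hetero == inside:
            mass += hetero_off
        elif e.hetero is None:
            mass += other_off  # symmetric bond: both sides get the same
        else:
            mass += other_off
    return mass


def _bulk_masses(
    g: MetaboliteGraph,
    masks: Sequence[int],
    rules: dict[str, tuple[float, float]],
) -> np.ndarray:
    """Vectorized :func:`fragment_mass` over many bitvectors at once."""
    n = g.n_nodes
    nbytes = (n + 7) // 8
    raw = b"".join(m.to_bytes(nbytes, "little") for m in masks)
    bits = np.unpackbits(
        np.frombuffer(raw, dtype=np.uint8).reshape(len(masks), nbytes),
        axis=1,
        bitorder="little",
    )[:, :n].astype(np.float64)
    node_masses = np.array([nd.mass for nd in g.nodes])
    total = bits @ node_masses
    if g.edges:
        eu = np.array([e.u for e in g.edges])
        ev = np.array([e.v for e in g.edges])
        off_u = np.empty(len(g.edges))
        off_v = np.empty(len(g.edges))
        for k, e in enumerate(g.edges):
            hetero_off, other_off = rules.get(e.bond_type, (0.0, 0.0))
            off_u[k] = hetero_off if e.hetero == e.u else other_off
            off_v[k] = hetero_off if e.hetero == e.v else other_off
        in_u = bits[:, eu]
        in_v = bits[:, ev]
        boundary = in_u != in_v
        total += (boundary * (in_u * off_u + in_v * off_v)).sum(axis=1)
    return total


def _connected_mask(adj: list[int], mask: int) -> bool:
    if mask == 0:
        return False
    seed = mask & -mask
    seen = seed
    frontier = seed
    while frontier:
        nxt = 0
        v = frontier
        while v:
            i = (v & -v).bit_length() - 1
            nxt |= adj[i]
            v &= v - 1
        frontier = nxt & mask & ~seen
        seen |= frontier
    return seen == mask


# ---------------------------------------------------------------------------
# Depth-one fragments


def _cut_sides(
    g: MetaboliteGraph, parent_mask: int, removed: tuple[int, ...]
) -> tuple[int, int] | None:
    """Split ``parent_mask`` by deleting the edges in ``removed``; returns
    the two sides, or None if the deletion leaves the subgraph connected or
    shatters it into more than two pieces."""
    adj = [0] * g.n_nodes
    for k, e in enumerate(g.edges):
        if k in removed:
            continue
        if parent_mask >> e.u & 1 and parent_mask >> e.v & 1:
            adj[e.u] |= 1 << e.v
            adj[e.v] |= 1 << e.u
    first = parent_mask & -parent_mask
    seen = first
    frontier = first
    while frontier:
        nxt = 0
        v = frontier
        while v:
            i = (v & -v).bit_length() - 1
            nxt |= adj[i]
            v &= v - 1
        frontier = nxt & parent_mask & ~seen
        seen |= frontier
    if seen == parent_mask:
        return None
    side_a, side_b = seen, parent_mask & ~seen
    # verify the second side is a single component
    if not _connected_mask(adj, side_b):
        return None
    return side_a, side_b


def _pair_label(a: str, b: str) -> str:
    return "_".join(sorted((a, b)))


def depth_one_fragments(
    g: MetaboliteGraph, rules: dict[str, tuple[float, float]] = DEFAULT_RULES
) -> list[Fragment]:
    """Both sides of every bridge and every 2-cut of the whole graph,
    deduplicated by bitvector (keeping the lexicographically smallest
    bond-type label)."""
    full = (1 << g.n_nodes) - 1
    found: dict[int, str] = {}

    def record(mask: int, label: str) -> None:
        prev = found.get(mask)
        if prev is None or label < prev:
            found[mask] = label

    for b in find_bridges(g):
        sides = _cut_sides(g, full, (b,))
        if sides is None:  # parallel-edge artefact; cannot happen for bridges
            continue
        label = g.edges[b].bond_type
        record(sides[0], label)
        record(sides[1], label)
    for i, j in find_two_cuts(g):
        sides = _cut_sides(g, full, (i, j))
        if sides is None:
            continue
        label = _pair_label(g.edges[i].bond_type, g.edges[j].bond_type)
        record(sides[0], label)
        record(sides[1], label)
    return [
        Fragment(
            bitvector=mask,
            mass=fragment_mass(g, mask, rules),
            depth=1,
            bond_type=label,
        )
        for mask, label in sorted(found.items())
    ]


# ---------------------------------------------------------------------------
# Full fragmentation graph


def _children_of(
    g: MetaboliteGraph, parent_mask: int, want_bridges: bool, want_two_cuts: bool
) -> list[tuple[int, str, bool]]:
    """Single-event children of the induced subgraph on ``parent_mask``.

    Returns (child mask, bond-type label, is_two_cut) triples, both sides of
    every cut.  Skips 2-cut search on trees (edge count = node count - 1).
    """
    sub_edges = [
        (k, e.u, e.v)
        for k, e in enumerate(g.edges)
        if parent_mask >> e.u & 1 and parent_mask >> e.v & 1
    ]
    sub_nodes = [i for i in range(g.n_nodes) if parent_mask >> i & 1]
    out: list[tuple[int, str, bool]] = []
    if want_bridges:
        for b, side in _bridges_with_sides(sub_nodes, sub_edges):
            label = g.edges[b].bond_type
            out.append((side, label, False))
            out.append((parent_mask ^ side, label, False))
    is_tree = len(sub_edges) == len(sub_nodes) - 1
    if want_two_cuts and not is_tree:
        for i, j in _two_cut_pairs(sub_nodes, sub_edges):
            sides = _cut_sides(g, parent_mask, (i, j))
            if sides is None:
                continue
            label = _pair_label(g.edges[i].bond_type, g.edges[j].bond_type)
            out.append((sides[0], label, True))
            out.append((sides[1], label, True))
    return out


def build_fragmentation_graph(
    g: MetaboliteGraph,
    max_bridges: int = 2,
    max_two_cuts: int = 1,
    rules: dict[str, tuple[float, float]] = DEFAULT_RULES,
    max_fragments: int = 100_000,
) -> FragmentationGraph:
    """Enumerate all fragments reachable within the cut budgets.

    The search runs breadth-first over (bitvector, bridges used, 2-cuts
    used) states with Pareto pruning on the budget pair, so a fragment
    reachable both by two bridge cuts and by one 2-cut keeps both budget
    states for its descendants.  Fragments are deduplicated by bitvector at
    their minimum depth; DAG edges connect each fragment to its depth-1
    parents on minimum-depth paths.

    Raises :class:`FragmentGraphTooLarge` past ``max_fragments`` distinct
    fragments.
    """
    full = (1 << g.n_nodes) - 1
    # bitvector -> set of Pareto-minimal (n_bridges, n_two_cuts) used
    states: dict[int, set[tuple[int, int]]] = {full: {(0, 0)}}
    depth: dict[int, int] = {full: 0}
    # candidate edges: (parent mask, child mask, label, parent path length)
    cand_edges: dict[tuple[int, int], list[tuple[str, int]]] = {}
    queue: list[tuple[int, int, int]] = [(full, 0, 0)]

    def dominated(mask: int, nb: int, nt: int) -> bool:
        return any(
            pb <= nb and pt <= nt for pb, pt in states.get(mask, ())
        )

    # a tree has no non-bridge edges anywhere, so 2-cut search is moot
    graph_is_tree = len(g.edges) == g.n_nodes - 1

    while queue:
        next_queue: list[tuple[int, int, int]] = []
        for mask, nb, nt in queue:
            want_b = nb < max_bridges
            want_t = nt < max_two_cuts and not graph_is_tree
            if not (want_b or want_t):
                continue
            for child, label, is_two in _children_of(g, mask, want_b, want_t):
                cnb, cnt = (nb, nt + 1) if is_two else (nb + 1, nt)
                path_len = nb + nt
                cand_edges.setdefault((mask, child), []).append(
                    (label, path_len)
                )
                if dominated(child, cnb, cnt):
                    continue
                kept = {
                    s
                    for s in states.get(child, set())
                    if not (cnb <= s[0] and cnt <= s[1])
                }
                kept.add((cnb, cnt))
                states[child] = kept
                if child not in depth:
                    depth[child] = cnb + cnt
                    if len(depth) > max_fragments:
                        raise FragmentGraphTooLarge(
                            g.molecule_id, max_fragments
                        )
                next_queue.append((child, cnb, cnt))
        queue = next_queue

    order = sorted(depth, key=lambda m: (depth[m], -m))
    order.remove(full)
    order.insert(0, full)
    index = {m: i for i, m in enumerate(order)}

    # fragment bond types: smallest label among minimum-depth in-edges
    bond_type: dict[int, str] = {full: "root"}
    edges: list[tuple[int, int, str]] = []
    parents: dict[int, list[int]] = {m: [] for m in order}
    for (pmask, cmask), labels in sorted(
        cand_edges.items(), key=lambda kv: (index[kv[0][1]], index[kv[0][0]])
    ):
        if depth[cmask] != depth[pmask] + 1:
            continue
        usable = sorted(
            label for label, plen in labels if plen == depth[pmask]
        )
        if not usable:
            continue
        label = usable[0]
        edges.append((index[pmask], index[cmask], label))
        parents[cmask].append(index[pmask])
        if cmask not in bond_type or label < bond_type[cmask]:
            bond_type[cmask] = label

    masses = _bulk_masses(g, order, rules)
    fragments = [
        Fragment(
            bitvector=m,
            mass=masses[i],
            depth=depth[m],
            bond_type=bond_type[m],
            parents=parents[m],
        )
        for i, m in enumerate(order)
    ]
    return FragmentationGraph(
        molecule_id=g.molecule_id,
        n_nodes=g.n_nodes,
        fragments=fragments,
        edges=edges,
        max_bridges=max_bridges,
        max_two_cuts=max_two_cuts,
        rules_digest=rule_hash(rules),
    )


# ---------------------------------------------------------------------------
# Decoys


def make_decoy(fg: FragmentationGraph, seed: int) -> FragmentationGraph:
    """Shuffle non-root fragment masses to build a decoy graph.

    Topology, depths and bond-type labels are untouched; the root
    (precursor) mass is preserved; the non-root masses are a uniform random
    permutation of the originals, deterministic for a given seed.
    """
    n_nonroot = len(fg.fragments) - 1
    if n_nonroot < 2:
        return replace(fg, is_decoy=True, decoy_warning=True)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_nonroot)
    masses = [fg.fragments[1 + i].mass for i in range(n_nonroot)]
    new_fragments = [replace(fg.fragments[0])]
    for i in range(n_nonroot):
        new_fragments.append(
            replace(fg.fragments[1 + i], mass=masses[perm[i]])
        )
    return replace(fg, fragments=new_fragments, is_decoy=True)


# ---------------------------------------------------------------------------
# Cache serialization


def fragmentation_graph_to_dict(fg: FragmentationGraph) -> dict:
    return {
        "molecule_id": fg.molecule_id,
        "n_nodes": fg.n_nodes,
        "max_bridges": fg.max_bridges,
        "max_two_cuts": fg.max_two_cuts,
        "is_decoy": fg.is_decoy,
        "fragments": [
            [f.bitvector, round(f.mass, 6), f.depth, f.bond_type, f.parents]
            for f in fg.fragments
        ],
        "edges": fg.edges,
    }


def fragmentation_graph_from_dict(d: dict, rules_digest: str) -> FragmentationGraph:
    fragments = [
        Fragment(
            bitvector=bv, mass=mass, depth=depth, bond_type=bt, parents=pa
        )
        for bv, mass, depth, bt, pa in d["fragments"]
    ]
    return FragmentationGraph(
        molecule_id=d["molecule_id"],
        n_nodes=d["n_nodes"],
        fragments=fragments,
        edges=[tuple(e) for e in d["edges"]],
        max_bridges=d["max_bridges"],
        max_two_cuts=d["max_two_cuts"],
        rules_digest=rules_digest,
        is_decoy=d.get("is_decoy", False),
    )


class CacheMismatchError(RuntimeError):
    """The cache was built with a different rearrangement rule table."""


def save_cache(
    path, graphs: Iterable[FragmentationGraph], rules=DEFAULT_RULES
) -> None:
    payload = {
        "rules_digest": rule_hash(rules),
        "graphs": {
            fg.molecule_id: fragmentation_graph_to_dict(fg) for fg in graphs
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_cache(path, rules=DEFAULT_RULES) -> dict[str, FragmentationGraph]:
    with open(path) as fh:
        payload = json.load(fh)
    digest = rule_hash(rules)
    if payload.get("rules_digest") != digest:
        raise CacheMismatchError(
            f"cache at {path} was built with rule digest "
            f"{payload.get('rules_digest')}, expected {digest}"
        )
    return {
        mid: fragmentation_graph_from_dict(d, digest)
        for mid, d in payload["graphs"].items()
    }
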