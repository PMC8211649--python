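"""Independent brute-force oracles for graph-cut enumeration.

Everything here works on explicit node/edge sets with plain BFS connectivity
checks, deliberately sharing no code path with the package's Tarjan-based
implementation.
"""

from __future__ import annotations

import itertools
from collections import deque

from fragrank.chem import MetaboliteGraph


def _connected(nodes, edges) -> bool:
    nodes = list(nodes)
    if not nodes:
        return False
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen = {nodes[0]}
    stack = [nodes[0]]
    while stack:
        for w in adj[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == len(nodes)


def _components(nodes, edges):
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen = set()
    out = []
    for n in nodes:
        if n in seen:
            continue
        comp = {n}
        stack = [n]
        while stack:
            for w in adj[stack.pop()]:
                if w not in comp:
                    comp.add(w)
                    stack.append(w)
        seen |= comp
        out.append(comp)
    return out


def brute_bridges(g: MetaboliteGraph) -> list[int]:
    """Edges whose single removal disconnects the graph, by trying each."""
    nodes = range(g.n_nodes)
    edges = [(k, e.u, e.v) for k, e in enumerate(g.edges)]
    out = []
    for k, _, _ in edges:
        rest = [(u, v) for kk, u, v in edges if kk != k]
        if not _connected(nodes, rest):
            out.append(k)
    return out


def brute_two_cuts(g: MetaboliteGraph) -> list[tuple[int, int]]:
    """All non-bridge edge pairs whose joint removal disconnects the graph,
    by trying every pair."""
    nodes = range(g.n_nodes)
    edges = [(k, e.u, e.v) for k, e in enumerate(g.edges)]
    bridges = set(brute_bridges(g))
    out = []
    for (k1, _, _), (k2, _, _) in itertools.combinations(edges, 2):
        if k1 in bridges or k2 in bridges:
            continue
        rest = [(u, v) for kk, u, v in edges if kk not in (k1, k2)]
        if not _connected(nodes, rest):
            out.append((min(k1, k2), max(k1, k2)))
    return sorted(out)


def brute_fragment_depths(
    g: MetaboliteGraph, max_bridges: int = 2, max_two_cuts: int = 1
) -> dict[int, int]:
    """Exhaustive cut application: repeatedly cut bridges and 2-cuts of every
    intermediate fragment in all orders within the budgets.

    Returns bitvector -> minimum number of cut events needed.
    """
    full = frozenset(range(g.n_nodes))
    all_edges = [(k, e.u, e.v) for k, e in enumerate(g.edges)]
    depth: dict[frozenset, int] = {full: 0}
    seen_states = set()
    queue = deque([(full, 0, 0)])
    while queue:
        mask, nb, nt = queue.popleft()
        if (mask, nb, nt) in seen_states:
            continue
        seen_states.add((mask, nb, nt))
        d = nb + nt
        sub = [(k, u, v) for k, u, v in all_edges if u in mask and v in mask]
        sub_nodes = sorted(mask)
        bridges = [
            k
            for k, _, _ in sub
            if not _connected(
                sub_nodes, [(u, v) for kk, u, v in sub if kk != k]
            )
        ]
        children = []
        if nb < max_bridges:
            for k in bridges:
                rest = [(u, v) for kk, u, v in sub if kk != k]
                for comp in _components(sub_nodes, rest):
                    children.append((frozenset(comp), nb + 1, nt))
        if nt < max_two_cuts:
            bridge_set = set(bridges)
            for (k1, _, _), (k2, _, _) in itertools.combinations(sub, 2):
                if k1 in bridge_set or k2 in bridge_set:
                    continue
                rest = [(u, v) for kk, u, v in sub if kk not in (k1, k2)]
                if _connected(sub_nodes, rest):
                    continue
                comps = _components(sub_nodes, rest)
                if len(comps) == 2:
                    for comp in comps:
                        children.append((frozenset(comp), nb, nt + 1))
        for cmask, cnb, cnt in children:
            if cmask not in depth or depth[cmask] > d + 1:
                depth[cmask] = d + 1
            queue.append((cmask, cnb, cnt))
    return {sum(1 << i for i in m): d for m, d in depth.items()}


def brute_fdr(scores_targets, scores_decoys, cutoff) -> float:
    """FDR at a cutoff by explicit double counting."""
    n_t = sum(1 for s in scores_targets if s >= cutoff)
    n_d = sum(1 for s in scores_decoys if s >= cutoff)
    return n_d / n_t if n_t else 0.0
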