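"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own data structures and
algorithms: networks are plain (nodes, weighted-edge-list) tuples, the
similarity formulas are evaluated literally from explicit intersection
enumeration, and graphlet orbits are assigned by trying all node
permutations against a hand-written reference table of the nine 2-4-node
graphlets.
"""

from __future__ import annotations

import itertools
import math


# -- similarity measures ------------------------------------------------


def brute_coexsim(nodes1, edges1, nodes2, edges2):
    """Literal evaluation of size_rel * sig_coex.

    ``edges*`` are lists of (u, v, w) triples with u != v; the edge (u, v)
    is the same as (v, u).
    """
    def lookup(edges, a, b):
        for (u, v, w) in edges:
            if {u, v} == {a, b}:
                return w
        return None

    common_nodes = [n for n in nodes1 if n in nodes2]
    ns = len(common_nodes)
    size_rel = ns / math.sqrt(len(nodes1) * len(nodes2))
    w1 = sum(w for (_, _, w) in edges1) / len(edges1)
    w2 = sum(w for (_, _, w) in edges2) / len(edges2)
    common = []
    for (u, v, w) in edges1:
        wb = lookup(edges2, u, v)
        if wb is not None:
            common.append((w, wb))
    if not common:
        return 0.0
    w31 = sum(a for a, _ in common) / len(common)
    w32 = sum(b for _, b in common) / len(common)
    sig = (w31 + w32) / (2.0 * math.sqrt(w1) * math.sqrt(w2))
    return size_rel * sig


def brute_fuzzy(edges1, edges2):
    """Literal sum(min)/sum(max) over the union of the two edge sets."""
    def membership(edges, a, b):
        for (u, v, w) in edges:
            if {u, v} == {a, b}:
                return w
        return 0.0

    universe = {frozenset((u, v)) for (u, v, _) in edges1}
    universe |= {frozenset((u, v)) for (u, v, _) in edges2}
    mins = maxs = 0.0
    for pair in universe:
        a, b = tuple(pair)
        m1, m2 = membership(edges1, a, b), membership(edges2, a, b)
        mins += min(m1, m2)
        maxs += max(m1, m2)
    return mins / maxs


# -- graphlet orbits ----------------------------------------------------

# the nine connected graphlets on 2-4 nodes: (edge list, node -> orbit id)
REFERENCE_GRAPHLETS = [
    ([(0, 1)], {0: 0, 1: 0}),                                        # edge
    ([(0, 1), (1, 2)], {0: 1, 1: 2, 2: 1}),                           # path P3
    ([(0, 1), (1, 2), (0, 2)], {0: 3, 1: 3, 2: 3}),                   # triangle
    ([(0, 1), (1, 2), (2, 3)], {0: 4, 1: 5, 2: 5, 3: 4}),             # path P4
    ([(0, 3), (1, 3), (2, 3)], {0: 6, 1: 6, 2: 6, 3: 7}),             # star
    ([(0, 1), (1, 2), (2, 3), (0, 3)], {0: 8, 1: 8, 2: 8, 3: 8}),     # cycle C4
    ([(0, 3), (1, 2), (1, 3), (2, 3)], {0: 9, 1: 10, 2: 10, 3: 11}),  # paw
    ([(0, 2), (0, 3), (1, 2), (1, 3), (2, 3)], {0: 12, 1: 12, 2: 13, 3: 13}),  # diamond
    ([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)], {0: 14, 1: 14, 2: 14, 3: 14}),  # K4
]

N_ORBITS4 = 15


def _induced_edges(edge_set, sub):
    return {frozenset((a, b)) for (a, b) in itertools.combinations(sub, 2)
            if frozenset((a, b)) in edge_set}


def _is_connected(sub, edges):
    seen = {sub[0]}
    frontier = [sub[0]]
    while frontier:
        cur = frontier.pop()
        for other in sub:
            if other not in seen and frozenset((cur, other)) in edges:
                seen.add(other)
                frontier.append(other)
    return len(seen) == len(sub)


def brute_orbit_counts(nodes, edge_pairs):
    """Per-node orbit counts for 2-4-node graphlets by full enumeration.

    ``edge_pairs`` is an iterable of (u, v) pairs.  For every connected
    induced subgraph of 2-4 nodes, every permutation of its nodes is
    tried against each reference graphlet with matching size and edge
    count; the first isomorphism found assigns the orbits.
    """
    nodes = sorted(nodes)
    edge_set = {frozenset(e) for e in edge_pairs}
    counts = {n: [0] * N_ORBITS4 for n in nodes}
    for k in (2, 3, 4):
        for sub in itertools.combinations(nodes, k):
            induced = _induced_edges(edge_set, sub)
            if not induced or not _is_connected(sub, induced):
                continue
            matched = False
            for ref_edges, orbit_map in REFERENCE_GRAPHLETS:
                if len(ref_edges) != len(induced) or len(orbit_map) != k:
                    continue
                for perm in itertools.permutations(range(k)):
                    # perm maps subgraph position -> reference node
                    mapped = {frozenset((perm[sub.index(a)], perm[sub.index(b)]))
                              for pair in induced for a, b in [tuple(pair)]}
                    if mapped == {frozenset(e) for e in ref_edges}:
                        for i, n in enumerate(sub):
                            counts[n][orbit_map[perm[i]]] += 1
                        matched = True
                        break
                if matched:
                    break
            assert matched, f"no reference graphlet matched subgraph {sub}"
    return counts
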