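"""Graphlet orbit counting and the graphlet correlation distance (GCD).

Graphlets are small connected induced subgraphs; an *orbit* is an
automorphism-equivalence class of node positions within a graphlet.  The
vector of per-node orbit counts summarizes each node's local topology,
and the Spearman correlation matrix between orbit-count columns (the
graphlet correlation matrix, GCM) summarizes a whole network.  The GCD
between two networks is the Euclidean distance between their GCMs.

Two orbit sets are supported:

* ``orbits4`` — the 15 orbits of the nine graphlets on 2–4 nodes,
  numbered 0–14 in the standard order (orbit 0 is the edge orbit, so its
  count equals node degree; orbit 3 is the triangle orbit, etc.).
* ``orbits5`` — the 73 orbits of the 2–5-node graphlets.  Orbits 0–14
  coincide with ``orbits4``; the 5-node orbits 15–72 follow a
  deterministic canonical order (graphlets sorted by edge count, then
  maximum degree, then degree sequence, then canonical certificate;
  orbits within a graphlet sorted by degree, then sorted neighbour
  degrees).

Edge weights are ignored here: GCD is defined on unweighted graphs, so a
weighted network is binarized by edge presence before counting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .network import SimilarityMatrix, WeightedNetwork

__all__ = [
    "OrbitCountMatrix",
    "GraphletCorrelationMatrix",
    "ORBIT_SETS",
    "n_orbits",
    "count_orbits",
    "graphlet_correlation_matrix",
    "gcd",
    "gcd_to_similarity",
]

ORBIT_SETS = {"orbits4": 4, "orbits5": 5}


# ----------------------------------------------------------------------
# orbit catalogue: enumerate all connected graphs on 2..k nodes once,
# group them by isomorphism, and assign global orbit ids
# ----------------------------------------------------------------------


def _edge_mask(edges: frozenset[frozenset[int]], k: int) -> int:
    """Bitmask over the C(k,2) node pairs in lexicographic order."""
    pairs = list(itertools.combinations(range(k), 2))
    mask = 0
    for bit, (i, j) in enumerate(pairs):
        if frozenset((i, j)) in edges:
            mask |= 1 << bit
    return mask


def _permute_mask(mask: int, perm: tuple[int, ...], k: int) -> int:
    pairs = list(itertools.combinations(range(k), 2))
    index = {frozenset(p): b for b, p in enumerate(pairs)}
    out = 0
    for bit, (i, j) in enumerate(pairs):
        if mask >> bit & 1:
            out |= 1 << index[frozenset((perm[i], perm[j]))]
    return out


def _is_connected_mask(mask: int, k: int) -> bool:
    pairs = list(itertools.combinations(range(k), 2))
    adj: list[set[int]] = [set() for _ in range(k)]
    for bit, (i, j) in enumerate(pairs):
        if mask >> bit & 1:
            adj[i].add(j)
            adj[j].add(i)
    seen = {0}
    stack = [0]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == k


def _degrees(mask: int, k: int) -> list[int]:
    pairs = list(itertools.combinations(range(k), 2))
    deg = [0] * k
    for bit, (i, j) in enumerate(pairs):
        if mask >> bit & 1:
            deg[i] += 1
            deg[j] += 1
    return deg


@dataclass(frozen=True)
class _Graphlet:
    size: int
    canon_mask: int          # minimum edge bitmask over all node permutations
    node_orbit: tuple[int, ...]  # global orbit id of each node of the canonical form


@lru_cache(maxsize=None)
def _orbit_catalogue(max_size: int) -> dict[tuple[int, int], "_Graphlet"]:
    """Map (size, canonical mask) -> graphlet with global orbit ids.

    Orbits are numbered consecutively: all orbits of smaller graphlets
    precede those of larger ones, graphlets of equal size are ordered by
    (edge count, max degree, degree sequence, canonical mask), and orbits
    within a graphlet by (degree, sorted neighbour degrees, min canonical
    node index).  For sizes 2–4 this reproduces the standard 15-orbit
    numbering.
    """
    catalogue: dict[tuple[int, int], _Graphlet] = {}
    next_orbit = 0
    for k in range(2, max_size + 1):
        perms = list(itertools.permutations(range(k)))
        seen_canon: set[int] = set()
        reps = []
        for mask in range(1 << (k * (k - 1) // 2)):
            if not _is_connected_mask(mask, k):
                continue
            canon = min(_permute_mask(mask, p, k) for p in perms)
            if canon in seen_canon:
                continue
            seen_canon.add(canon)
            deg = _degrees(canon, k)
            reps.append((sum(deg) // 2, max(deg), tuple(sorted(deg)), canon))
        reps.sort()
        for _, _, _, canon in reps:
            # automorphism orbits of the canonical representative
            autos = [p for p in perms if _permute_mask(canon, p, k) == canon]
            orbit_of: dict[int, set[int]] = {}
            for node in range(k):
                cls = frozenset(p[node] for p in autos)
                orbit_of.setdefault(min(cls), set()).update(cls)
            deg = _degrees(canon, k)
            pairs = list(itertools.combinations(range(k), 2))
            nbrs: list[list[int]] = [[] for _ in range(k)]
            for bit, (i, j) in enumerate(pairs):
                if canon >> bit & 1:
                    nbrs[i].append(j)
                    nbrs[j].append(i)
            keyed = sorted(
                orbit_of.items(),
                key=lambda kv: (
                    deg[kv[0]],
                    tuple(sorted(deg[n] for n in nbrs[kv[0]])),
                    kv[0],
                ),
            )
            node_orbit = [0] * k
            for _, members in keyed:
                for m in members:
                    node_orbit[m] = next_orbit
                next_orbit += 1
            catalogue[(k, canon)] = _Graphlet(k, canon, tuple(node_orbit))
    return catalogue


@lru_cache(maxsize=None)
def n_orbits(orbit_set: str) -> int:
    cat = _orbit_catalogue(ORBIT_SETS[orbit_set])
    return 1 + max(max(g.node_orbit) for g in cat.values())


@lru_cache(maxsize=None)
def _classifier(max_size: int):
    """Return a cached mapping from raw local edge masks to node orbits."""
    catalogue = _orbit_catalogue(max_size)
    cache: dict[tuple[int, int], tuple[int, ...]] = {}

    def classify(mask: int, k: int) -> tuple[int, ...]:
        """Orbit id of each of the k local nodes of the induced subgraph."""
        hit = cache.get((k, mask))
        if hit is not None:
            return hit
        best_canon = None
        best_perm = None
        for p in itertools.permutations(range(k)):
            m = _permute_mask(mask, p, k)
            if best_canon is None or m < best_canon:
                best_canon, best_perm = m, p
        glet = catalogue[(k, best_canon)]
        # best_perm maps local node i to canonical node best_perm[i]
        orbits = tuple(glet.node_orbit[best_perm[i]] for i in range(k))
        cache[(k, mask)] = orbits
        return orbits

    return classify


@dataclass
class OrbitCountMatrix:
    """Per-node orbit participation counts (nodes x orbits)."""

    node_labels: list[str]
    counts: np.ndarray  # shape (n_nodes, n_orbits), nonnegative ints
    orbit_set: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=self.node_labels,
            columns=[f"O{i}" for i in range(self.counts.shape[1])],
        )


@dataclass
class GraphletCorrelationMatrix:
    """Symmetric orbit x orbit Spearman correlation matrix, unit diagonal."""

    values: np.ndarray
    orbit_set: str


def _connected_subgraphs(adj: dict[int, set[int]], max_size: int):
    """ESU enumeration of connected induced subgraphs of size 2..max_size.

    Yields node tuples in increasing label order of the root; each
    connected subgraph is produced exactly once.
    """
    nodes = sorted(adj)

    def extend(sub: list[int], extension: set[int], v: int):
        if len(sub) >= 2:
            yield tuple(sub)
        if len(sub) == max_size:
            return
        ext = set(extension)
        while ext:
            w = ext.pop()
            # exclusive neighbourhood: neighbours of w not adjacent to sub
            new_ext = ext | {u for u in adj[w] if u > v and u not in sub and all(u not in adj[s] for s in sub)}
            yield from extend(sub + [w], new_ext, v)

    for v in nodes:
        yield from extend([v], {u for u in adj[v] if u > v}, v)


def count_orbits(net: WeightedNetwork, orbit_set: str = "orbits4") -> OrbitCountMatrix:
    """Count per-node graphlet-orbit participation.

    The network is binarized by edge presence (weights ignored).  Every
    connected induced subgraph on 2..k nodes is enumerated once with the
    ESU algorithm and classified up to isomorphism; each of its nodes is
    credited in the orbit it occupies.
    """
    if orbit_set not in ORBIT_SETS:
        raise ValueError(f"orbit_set must be one of {sorted(ORBIT_SETS)}")
    max_size = ORBIT_SETS[orbit_set]
    labels = sorted(net.nodes)
    index = {lab: i for i, lab in enumerate(labels)}
    adj: dict[int, set[int]] = {i: set() for i in range(len(labels))}
    for u, v in net.edges:
        adj[index[u]].add(index[v])
        adj[index[v]].add(index[u])
    counts = np.zeros((len(labels), n_orbits(orbit_set)), dtype=np.int64)
    classify = _classifier(max_size)
    for sub in _connected_subgraphs(adj, max_size):
        k = len(sub)
        mask = 0
        for bit, (a, b) in enumerate(itertools.combinations(range(k), 2)):
            if sub[b] in adj[sub[a]]:
                mask |= 1 << bit
        orbits = classify(mask, k)
        for node, orb in zip(sub, orbits):
            counts[node, orb] += 1
    return OrbitCountMatrix(node_labels=labels, counts=counts, orbit_set=orbit_set)


def graphlet_correlation_matrix(counts: OrbitCountMatrix) -> GraphletCorrelationMatrix:
    """Spearman correlations between orbit-count columns.

    A dummy all-ones row is appended before ranking so that orbit columns
    that are constant on the real nodes (typically all-zero) still yield
    finite correlations — the standard GCM construction.  Columns that
    remain constant after the dummy row get correlation 1 with identical
    columns and 0 otherwise.
    """
    if len(counts.node_labels) < 2:
        raise ValueError("graphlet correlation matrix requires >= 2 nodes")
    mat = np.vstack([counts.counts, np.ones((1, counts.counts.shape[1]), dtype=np.int64)])
    p = mat.shape[1]
    # Spearman = Pearson on average ranks; computed directly because
    # scipy.stats.spearmanr refuses matrices containing constant columns,
    # which legitimately occur here (rare orbits)
    ranks = np.apply_along_axis(stats.rankdata, 0, mat)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.asarray(rho, dtype=float).reshape(p, p)
    if np.isnan(rho).any():
        const = np.array([np.unique(col).size == 1 for col in mat.T])
        for i, j in zip(*np.where(np.isnan(rho))):
            if const[i] or const[j]:
                rho[i, j] = 1.0 if np.array_equal(mat[:, i], mat[:, j]) else 0.0
    np.fill_diagonal(rho, 1.0)
    return GraphletCorrelationMatrix(values=rho, orbit_set=counts.orbit_set)


def gcd(n1: WeightedNetwork, n2: WeightedNetwork, orbit_set: str = "orbits4") -> float:
    """Graphlet correlation distance between two networks.

    Euclidean norm of the upper-triangle difference of the two graphlet
    correlation matrices; zero for identical graphs.
    """
    g1 = graphlet_correlation_matrix(count_orbits(n1, orbit_set)).values
    g2 = graphlet_correlation_matrix(count_orbits(n2, orbit_set)).values
    iu = np.triu_indices_from(g1, k=1)
    return float(np.linalg.norm(g1[iu] - g2[iu]))


def gcd_to_similarity(
    distances: SimilarityMatrix, verbatim: bool = False
) -> SimilarityMatrix:
    """Normalize a GCD distance matrix into a similarity matrix.

    The default transform is ``(max - d) / max``: 1 at distance zero, 0
    at the maximum observed distance.  ``verbatim=True`` applies the
    uncorrected form ``(d - max) / max`` (which maps distance zero to -1)
    for auditability.
    """
    d = distances.values.to_numpy(dtype=float)
    dmax = float(d.max())
    if dmax <= 0.0:
        raise ValueError("all distances are zero; similarity normalization degenerate")
    sim = (d - dmax) / dmax if verbatim else (dmax - d) / dmax
    return SimilarityMatrix(
        values=pd.DataFrame(sim, index=distances.values.index, columns=distances.values.columns),
        measure_name="gcd-similarity (verbatim)" if verbatim else "gcd-similarity",
    )
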