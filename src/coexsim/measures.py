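"""Pairwise similarity measures for weighted coexpression networks.

Two complementary measures are implemented:

* **COEXsim** — a node-based similarity.  It is the product of the
  relative size of the common subnetwork,

      size_rel = NS_common / (sqrt(NS_1) * sqrt(NS_2)),

  and the coexpression significance of the common subnetwork,

      sig_coex = (w3_1 + w3_2) / (2 * sqrt(w1) * sqrt(w2)),

  where ``NS`` are node counts, ``w1``/``w2`` are the mean edge weights
  of the two networks and ``w3_1``/``w3_2`` are the mean weights of the
  common edges under each parent's weighting.  COEXsim is 1 for a
  network against itself and 0 when the node or edge intersection is
  empty; it may exceed 1 when common edges are heavier than the network
  averages.

* **Fuzzy set similarity** — an edge-based weighted Jaccard index.  Each
  network is a fuzzy set over edges with membership equal to the edge
  weight (0 for absent edges); the similarity is the ratio of the
  sigma-counts of the fuzzy intersection and union,

      sim_fuzzy = sum_x min(mu_1(x), mu_2(x)) / sum_x max(mu_1(x), mu_2(x)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .network import CommonSubnetwork, WeightedNetwork, canonical_edge

__all__ = [
    "PairScore",
    "common_subnetwork",
    "size_rel",
    "sig_coex",
    "coexsim",
    "fuzzy_similarity",
    "score_pair",
]


def _geometric_mean(a: float, b: float) -> float:
    # exact when a == b, so self-similarity is exactly 1
    return a if a == b else math.sqrt(a * b)


@dataclass(frozen=True)
class PairScore:
    """Full record of one pairwise comparison."""

    label_a: str
    label_b: str
    coexsim: float
    fuzzy: float
    size_rel: float
    sig_coex: float
    n_common_nodes: int
    n_common_edges: int


def common_subnetwork(n1: WeightedNetwork, n2: WeightedNetwork) -> CommonSubnetwork:
    """Exact intersection of two networks.

    Nodes are the node-set intersection (isolated common nodes included);
    edges are the pairs present in both networks, carrying both parents'
    weights.  Empty intersections are legal.
    """
    nodes = frozenset(n1.nodes & n2.nodes)
    small, big = (n1, n2) if n1.n_edges <= n2.n_edges else (n2, n1)
    edges: dict[tuple[str, str], tuple[float, float]] = {}
    for e, w in small.edges.items():
        wb = big.edges.get(e)
        if wb is not None:
            edges[e] = (w, wb) if small is n1 else (wb, w)
    return CommonSubnetwork(nodes=nodes, edges=edges)


def size_rel(
    n1: WeightedNetwork, n2: WeightedNetwork, common: CommonSubnetwork | None = None
) -> float:
    """Relative common-subnetwork size: NS_common / sqrt(NS_1 * NS_2)."""
    if n1.n_nodes == 0 or n2.n_nodes == 0:
        raise ValueError("size_rel requires both networks to have at least one node")
    if common is None:
        common = common_subnetwork(n1, n2)
    return common.n_nodes / _geometric_mean(float(n1.n_nodes), float(n2.n_nodes))


def sig_coex(
    n1: WeightedNetwork, n2: WeightedNetwork, common: CommonSubnetwork | None = None
) -> float:
    """Coexpression significance of the common subnetwork.

    Mean common-edge weight (averaged over both parents' weightings)
    normalized by the geometric mean of the parents' mean edge weights.
    Zero when there are no common edges.
    """
    w1 = n1.mean_weight()  # raises on an edgeless parent
    w2 = n2.mean_weight()
    if common is None:
        common = common_subnetwork(n1, n2)
    if common.n_edges == 0:
        return 0.0
    w31, w32 = common.mean_weights()
    return (w31 + w32) / (2.0 * _geometric_mean(w1, w2))


def coexsim(n1: WeightedNetwork, n2: WeightedNetwork) -> float:
    """COEXsim = size_rel * sig_coex.  Symmetric; 1 for identical networks."""
    return score_pair(n1, n2).coexsim


def score_pair(n1: WeightedNetwork, n2: WeightedNetwork) -> PairScore:
    """Compute COEXsim, fuzzy similarity and their components for a pair."""
    common = common_subnetwork(n1, n2)
    sr = size_rel(n1, n2, common)
    sc = sig_coex(n1, n2, common)
    return PairScore(
        label_a=n1.label,
        label_b=n2.label,
        coexsim=sr * sc,
        fuzzy=fuzzy_similarity(n1, n2),
        size_rel=sr,
        sig_coex=sc,
        n_common_nodes=common.n_nodes,
        n_common_edges=common.n_edges,
    )


def fuzzy_similarity(n1: WeightedNetwork, n2: WeightedNetwork) -> float:
    """Weighted Jaccard index over the union of the two edge sets.

    Membership of an edge is its weight (0 if absent), and set
    cardinality is the sigma-count, so the measure is
    sum(min)/sum(max) over the edge universe.  Edges absent from both
    networks contribute 0 to both sums, so restricting the universe to
    the union of edge sets is exact.
    """
    if not n1.edges and not n2.edges:
        raise ValueError("fuzzy similarity undefined for two edgeless networks (0/0)")
    mins = 0.0
    maxs = 0.0
    for e in n1.edges.keys() | n2.edges.keys():
        a = n1.edges.get(e, 0.0)
        b = n2.edges.get(e, 0.0)
        mins += min(a, b)
        maxs += max(a, b)
    return mins / maxs
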