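"""Domain types and I/O for weighted coexpression networks.

A coexpression network is an undirected graph whose nodes are genes and
whose edges carry a weight in ``(0, 1]`` expressing the strength of
coexpression between the two genes.  Networks are the unit of comparison
for every similarity measure in this package.

Edges are stored canonically: an edge is an unordered pair, kept as a
tuple with the endpoints in lexicographic order, so ``(a, b)`` and
``(b, a)`` denote the same edge.  Self-loops are forbidden; isolated
nodes are legal and count toward node sizes.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "WeightedNetwork",
    "CommonSubnetwork",
    "SimilarityMatrix",
    "NetworkFormatError",
    "canonical_edge",
    "read_edge_list",
    "write_edge_list",
    "read_adjacency",
    "read_similarity_matrix",
    "write_similarity_matrix",
]


class NetworkFormatError(ValueError):
    """Raised when an input file violates the network format contract."""


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Return the canonical (lexicographically sorted) form of an edge."""
    if u == v:
        raise ValueError(f"self-loop on node {u!r}")
    return (u, v) if u < v else (v, u)


@dataclass
class WeightedNetwork:
    """Undirected weighted graph of gene nodes.

    Parameters
    ----------
    label:
        Text identifier used in similarity matrices and reports.
    nodes:
        Set of gene identifiers.  May include isolated nodes.
    edges:
        Mapping from canonical node pair to weight in ``(0, 1]``.
    """

    label: str
    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = set(self.nodes)
        canon: dict[tuple[str, str], float] = {}
        for (u, v), w in dict(self.edges).items():
            e = canonical_edge(u, v)
            canon[e] = max(w, canon.get(e, 0.0))
        self.edges = canon
        self.validate()

    # -- invariants ---------------------------------------------------

    def validate(self) -> None:
        for (u, v), w in self.edges.items():
            if u == v:
                raise ValueError(f"self-loop on node {u!r} in network {self.label!r}")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(
                    f"edge ({u!r}, {v!r}) references a node outside the node set "
                    f"of network {self.label!r}"
                )
            if not (0.0 < w <= 1.0):
                raise ValueError(
                    f"edge ({u!r}, {v!r}) of network {self.label!r} has weight "
                    f"{w!r} outside (0, 1]"
                )

    # -- basic statistics ---------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def mean_weight(self) -> float:
        """Arithmetic mean edge weight; raises on an edgeless network."""
        if not self.edges:
            raise ValueError(f"network {self.label!r} has no edges; mean weight undefined")
        return math.fsum(self.edges.values()) / len(self.edges)

    def weight(self, u: str, v: str) -> float:
        """Weight of edge (u, v), or 0.0 if the edge is absent."""
        return self.edges.get(canonical_edge(u, v), 0.0)

    def adjacency_sets(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def copy(self, label: str | None = None) -> "WeightedNetwork":
        return WeightedNetwork(
            label=self.label if label is None else label,
            nodes=set(self.nodes),
            edges=dict(self.edges),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges


@dataclass(frozen=True)
class CommonSubnetwork:
    """Exact intersection of two networks.

    Nodes present in both parents and edges present in both parents; each
    common edge carries the weight it has in each parent so that the
    coexpression-significance term can average them.
    """

    nodes: frozenset[str]
    # canonical edge -> (weight in first parent, weight in second parent)
    edges: Mapping[tuple[str, str], tuple[float, float]]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def mean_weights(self) -> tuple[float, float]:
        """Mean common-edge weight under each parent's weighting.

        Raises if there are no common edges; callers adopt the convention
        that an empty common edge set has zero coexpression significance.
        """
        if not self.edges:
            raise ValueError("common subnetwork has no edges")
        k = len(self.edges)
        w1 = math.fsum(a for a, _ in self.edges.values()) / k
        w2 = math.fsum(b for _, b in self.edges.values()) / k
        return w1, w2


@dataclass
class SimilarityMatrix:
    """Labeled square (or rectangular) matrix of pairwise scores.

    ``values`` is a pandas DataFrame indexed by row/column labels;
    ``measure_name`` names the measure that produced it.
    """

    values: pd.DataFrame
    measure_name: str = ""

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)

    @property
    def labels(self) -> list[str]:
        return list(self.values.index)

    @property
    def is_square(self) -> bool:
        return list(self.values.index) == list(self.values.columns)

    def loc(self, a: str, b: str) -> float:
        return float(self.values.loc[a, b])


# ----------------------------------------------------------------------
# readers / writers
# ----------------------------------------------------------------------

_TRANSFORMS = ("abs", "clamp01", "none")


def _transform_weight(w: float, mode: str) -> float:
    if mode == "abs":
        return abs(w)
    if mode == "clamp01":
        return min(w, 1.0)
    return w


def read_edge_list(
    path: str | Path,
    weight_transform: str = "abs",
    label: str | None = None,
) -> WeightedNetwork:
    """Read a weighted edge list (TSV: node_a, node_b, weight).

    Lines starting with ``#`` are treated as comments/headers.  Duplicate
    edges keep the maximum weight.  Self-loop rows are skipped with a
    warning.  ``weight_transform='abs'`` maps signed correlations to
    magnitudes before the ``(0, 1]`` range check.
    """
    if weight_transform not in _TRANSFORMS:
        raise ValueError(f"weight_transform must be one of {_TRANSFORMS}")
    path = Path(path)
    net = WeightedNetwork(label=label if label is not None else path.stem)
    n_rows = 0
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (row[0].startswith("#")):
                # "#isolated <node>" comment rows carry degree-0 nodes so
                # that write/read round-trips preserve the node set
                if row and row[0] == "#isolated" and len(row) > 1:
                    net.nodes.add(row[1].strip())
                    n_rows += 1
                continue
            if len(row) < 3:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected at least 3 columns, got {len(row)}"
                )
            u, v, raw = row[0].strip(), row[1].strip(), row[2].strip()
            try:
                w = float(raw)
            except ValueError as exc:
                raise NetworkFormatError(
                    f"{path}:{lineno}: weight {raw!r} is not a number"
                ) from exc
            n_rows += 1
            if u == v:
                warnings.warn(
                    f"{path}:{lineno}: self-loop on {u!r} skipped", stacklevel=2
                )
                net.nodes.add(u)
                continue
            w = _transform_weight(w, weight_transform)
            if not (0.0 < w <= 1.0):
                raise NetworkFormatError(
                    f"{path}:{lineno}: weight {raw} is outside (0, 1] after "
                    f"transform {weight_transform!r}"
                )
            e = canonical_edge(u, v)
            net.nodes.update(e)
            net.edges[e] = max(w, net.edges.get(e, 0.0))
    if n_rows == 0:
        raise NetworkFormatError(f"{path}: empty edge list")
    net.validate()
    return net


def write_edge_list(net: WeightedNetwork, path: str | Path) -> None:
    """Write a network as a canonical edge-list TSV (sorted edges).

    Isolated nodes are recorded as comment lines so round-trips preserve
    the node set.
    """
    path = Path(path)
    connected = {n for e in net.edges for n in e}
    with path.open("w", newline="") as fh:
        fh.write("#node_a\tnode_b\tweight\n")
        for n in sorted(net.nodes - connected):
            fh.write(f"#isolated\t{n}\n")
        for (u, v) in sorted(net.edges):
            fh.write(f"{u}\t{v}\t{net.edges[(u, v)]:.17g}\n")


def read_adjacency(
    path: str | Path, threshold: float = 0.0, label: str | None = None
) -> WeightedNetwork:
    """Read a square labeled adjacency CSV into a network.

    Off-diagonal entries with ``|value| > threshold`` become edges with
    weight ``|value|``.  The matrix must be symmetric to 1e-8.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] != df.shape[1] or list(df.index) != list(df.columns):
        raise NetworkFormatError(f"{path}: adjacency matrix is not square/labeled")
    vals = df.to_numpy(dtype=float)
    if abs(vals - vals.T).max(initial=0.0) > 1e-8:
        raise NetworkFormatError(f"{path}: adjacency matrix is asymmetric beyond 1e-8")
    net = WeightedNetwork(label=label if label is not None else path.stem)
    net.nodes.update(df.index)
    labels = list(df.index)
    for i, u in enumerate(labels):
        for j in range(i + 1, len(labels)):
            w = abs(vals[i, j])
            if w > threshold:
                net.edges[canonical_edge(u, labels[j])] = w
    net.validate()
    return net


def write_similarity_matrix(matrix: SimilarityMatrix, path: str | Path) -> None:
    """Write a similarity matrix as a labeled TSV with 5-decimal values."""
    matrix.values.to_csv(Path(path), sep="\t", float_format="%.5f")


def read_similarity_matrix(path: str | Path, measure_name: str = "") -> SimilarityMatrix:
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return SimilarityMatrix(values=df, measure_name=measure_name)
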