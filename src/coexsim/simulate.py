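"""Synthetic weighted-network generators with controlled overlap.

These generators emulate the study designs the similarity measures are
meant for: sets of gene coexpression networks of a few hundred nodes in
which some networks are "siblings" (high node and edge overlap with
jittered weights, like coexpression networks of related biological
processes or modules) and others are unrelated controls.

Topology is Erdős–Rényi at a chosen density; weights are i.i.d. from a
uniform or beta distribution restricted to (0, 1].  A *perturbed pair*
shares a controlled fraction of nodes with its base network, retains
each base edge independently with a retention probability, jitters the
retained weights with truncated Gaussian noise, and fills the remainder
of the network with fresh nodes and fresh edges at the base density.
Planted groups stack these two primitives into the
similar-groups-plus-controls design used for threshold calibration.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass

import numpy as np

from .network import WeightedNetwork, canonical_edge

__all__ = [
    "GeneratorConfig",
    "random_network",
    "perturbed_pair",
    "planted_groups",
]

_DIST_RE = re.compile(r"^(uniform|beta)\(([^,]+),([^)]+)\)$")


def _parse_distribution(spec: str) -> tuple[str, float, float]:
    m = _DIST_RE.match(spec.replace(" ", ""))
    if not m:
        raise ValueError(
            f"weight_distribution {spec!r} must look like 'uniform(a,b)' or 'beta(a,b)'"
        )
    name, a, b = m.group(1), float(m.group(2)), float(m.group(3))
    if not (0 < a <= 1 and 0 < b <= 1) and name == "uniform":
        raise ValueError("uniform bounds must lie in (0, 1]")
    if name == "uniform" and a > b:
        raise ValueError("uniform lower bound exceeds upper bound")
    if name == "beta" and (a <= 0 or b <= 0):
        raise ValueError("beta shape parameters must be positive")
    return name, a, b


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic-network generator.

    node_overlap and edge_retention only matter for derived (perturbed)
    networks; weight_jitter_sd is the s.d. of the truncated Gaussian
    noise added to retained weights.
    """

    n_nodes: int = 120
    edge_density: float = 0.2
    weight_distribution: str = "uniform(0.05,0.95)"
    node_overlap: float = 0.8
    edge_retention: float = 0.8
    weight_jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes <= 0:
            raise ValueError("n_nodes must be positive")
        if not (0 < self.edge_density <= 1):
            raise ValueError("edge_density must be in (0, 1]")
        if not (0 <= self.node_overlap <= 1):
            raise ValueError("node_overlap must be in [0, 1]")
        if not (0 <= self.edge_retention <= 1):
            raise ValueError("edge_retention must be in [0, 1]")
        if self.weight_jitter_sd < 0:
            raise ValueError("weight_jitter_sd must be >= 0")
        _parse_distribution(self.weight_distribution)


def _draw_weights(rng: np.random.Generator, n: int, spec: str) -> np.ndarray:
    name, a, b = _parse_distribution(spec)
    if name == "uniform":
        w = rng.uniform(a, b, size=n)
    else:
        w = rng.beta(a, b, size=n)
    # keep strictly inside (0, 1]
    return np.clip(w, 1e-12, 1.0)


def _jitter(rng: np.random.Generator, w: np.ndarray, sd: float) -> np.ndarray:
    if sd == 0:
        return w
    return np.clip(w + rng.normal(0.0, sd, size=w.shape), 1e-12, 1.0)


def random_network(
    config: GeneratorConfig,
    label: str,
    rng: np.random.Generator | None = None,
    node_names: list[str] | None = None,
) -> WeightedNetwork:
    """Erdős–Rényi network at ``edge_density`` with i.i.d. weights.

    Reproducible from ``config.seed`` (or an explicit ``rng``, used by
    the multi-network generators to derive independent streams).
    ``node_names`` overrides the default ``g0000 ...`` naming, e.g. to
    plant node overlap between networks.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_nodes
    nodes = node_names if node_names is not None else [f"g{i:04d}" for i in range(n)]
    if len(nodes) != n:
        raise ValueError("node_names length must equal n_nodes")
    if config.edge_density * n * (n - 1) / 2 < 1:
        warnings.warn(
            "expected edge count below 1; network may be edgeless", stacklevel=2
        )
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(iu.size) < config.edge_density
    weights = _draw_weights(rng, int(present.sum()), config.weight_distribution)
    net = WeightedNetwork(label=label, nodes=set(nodes))
    for (i, j), w in zip(zip(iu[present], ju[present]), weights):
        net.edges[canonical_edge(nodes[i], nodes[j])] = float(w)
    net.validate()
    return net


def perturbed_pair(
    base: WeightedNetwork,
    config: GeneratorConfig,
    label: str | None = None,
    rng: np.random.Generator | None = None,
) -> WeightedNetwork:
    """Sibling of ``base`` with controlled node and edge overlap.

    Keeps ``ceil(node_overlap * n)`` of the base's nodes; each base edge
    among kept nodes is retained independently with probability
    ``edge_retention`` and its weight jittered by truncated Gaussian
    noise clamped back into (0, 1].  The remaining nodes are fresh
    (unique to the derived network) and all node pairs involving a fresh
    node are rewired at the base's configured edge density with fresh
    weights.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if label is None:
        label = f"{base.label}_sib"
    base_nodes = sorted(base.nodes)
    n = len(base_nodes)
    n_keep = math.ceil(config.node_overlap * n)
    keep = (
        {str(x) for x in rng.choice(base_nodes, size=n_keep, replace=False)}
        if n_keep
        else set()
    )
    fresh = [f"{label}.f{i:04d}" for i in range(n - n_keep)]
    nodes = sorted(keep) + fresh
    net = WeightedNetwork(label=label, nodes=set(nodes))

    kept_edges = [e for e in base.edges if e[0] in keep and e[1] in keep]
    retained = rng.random(len(kept_edges)) < config.edge_retention
    w = _jitter(
        rng,
        np.array([base.edges[e] for e in kept_edges], dtype=float),
        config.weight_jitter_sd,
    )
    for e, ok, wi in zip(kept_edges, retained, w):
        if ok:
            net.edges[e] = float(wi)

    # fresh wiring: pairs with at least one fresh endpoint
    fresh_set = set(fresh)
    pairs = [
        canonical_edge(a, b)
        for i, a in enumerate(nodes)
        for b in nodes[i + 1 :]
        if a in fresh_set or b in fresh_set
    ]
    if pairs:
        present = rng.random(len(pairs)) < config.edge_density
        fw = _draw_weights(rng, int(present.sum()), config.weight_distribution)
        k = 0
        for e, ok in zip(pairs, present):
            if ok:
                net.edges[e] = float(fw[k])
                k += 1
    net.validate()
    return net


def planted_groups(
    k_groups: int,
    members_per_group: int,
    within_config: GeneratorConfig,
    between_overlap: float = 0.1,
    n_controls: int = 0,
    control_group: str = "control",
) -> tuple[list[WeightedNetwork], dict[str, str]]:
    """Groups of perturbed siblings plus optional unrelated controls.

    Each group has its own base network; members are independent
    perturbed siblings of that base, so within-group node/edge overlap
    is governed by ``within_config``.  All bases (and controls) share a
    common core of ``round(between_overlap * n)`` node names, holding
    cross-group node overlap near ``between_overlap`` while their edges
    and weights stay independent.

    Returns the list of networks and a label -> group-name map (the
    group-membership table consumed by threshold evaluation).
    """
    if between_overlap >= within_config.node_overlap:
        raise ValueError("between_overlap must be below the within-group node_overlap")
    if k_groups < 1 or members_per_group < 1:
        raise ValueError("need at least one group and one member")
    rng_root = np.random.SeedSequence(within_config.seed)
    streams = [np.random.default_rng(s) for s in rng_root.spawn(k_groups + n_controls)]
    n = within_config.n_nodes
    n_core = int(round(between_overlap * n))
    core = [f"core{i:04d}" for i in range(n_core)]
    networks: list[WeightedNetwork] = []
    groups: dict[str, str] = {}
    for g in range(k_groups):
        gname = f"group{g + 1}"
        names = core + [f"{gname}.g{i:04d}" for i in range(n - n_core)]
        base = random_network(within_config, f"{gname}_base", rng=streams[g], node_names=names)
        for m in range(members_per_group):
            label = f"{gname}_m{m + 1}"
            networks.append(perturbed_pair(base, within_config, label=label, rng=streams[g]))
            groups[label] = gname
    for c in range(n_controls):
        rng = streams[k_groups + c]
        label = f"{control_group}_m{c + 1}"
        names = core + [f"{label}.g{i:04d}" for i in range(n - n_core)]
        networks.append(random_network(within_config, label, rng=rng, node_names=names))
        groups[label] = control_group
    return networks, groups
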