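"""Synthetic graph-pair generator with a planted shared module.

Emulates metabolite co-perturbation networks at benchmark scale: connected
weighted graphs of 100–10,000 nodes with average unweighted degree 5–25,
positive edge weights, and a small shared module S (0.5–1% of nodes) whose
edges form a planted path or clique with a controlled weight contrast —
the ratio of the mean planted-edge weight to the mean background-edge weight.

Generation is three-phased: (1) grow a uniformly random labeled tree and add
uniformly random extra edges until the target density is reached, which makes
connectivity certain with predictable run time; (2) plant the module pattern
and set its edge weights to hit the requested contrast exactly; (3) prune
random non-bridge background edges to restore the requested density, since
planting may have added edges.  Background weights are drawn Uniform(0.5, 1.5)
— positive, bounded and mean 1, so contrast reads directly as the planted
mean.  The tree-first construction carries a slight bias in the distribution
over connected graphs; it is accepted for its determinism and speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graphs import GraphError, NodeModule, canonical_edge, validate_graph

__all__ = [
    "GenParams",
    "random_connected_graph",
    "plant_module",
    "rewire_to_density",
    "generate_pair",
    "measure_contrast",
]

BACKGROUND_WEIGHT_LOW = 0.5
BACKGROUND_WEIGHT_HIGH = 1.5


@dataclass(frozen=True)
class GenParams:
    """Parameters of one synthetic graph-pair cell.

    ``avg_degree`` is the average unweighted node degree (edge count is
    round(n*d/2)); ``module_fraction`` the fraction of nodes placed in S;
    ``contrast`` the target ratio of mean planted to mean background weight.
    """

    n_nodes: int
    avg_degree: float
    module_fraction: float
    contrast: float
    pattern: str = "clique"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 5:
            raise ValueError("need at least 5 nodes")
        if self.target_edges < self.n_nodes - 1:
            raise ValueError(
                f"avg_degree {self.avg_degree} is below the connectivity floor "
                f"for {self.n_nodes} nodes"
            )
        if self.target_edges > self.n_nodes * (self.n_nodes - 1) // 2:
            raise ValueError("requested edges exceed the complete graph")
        if not 0.0 < self.module_fraction <= 1.0:
            raise ValueError("module_fraction must lie in (0, 1]")
        if self.module_size < 2:
            raise ValueError("module_fraction yields a module of fewer than 2 nodes")
        if self.contrast < 0.0:
            raise ValueError("contrast must be nonnegative")
        if self.pattern not in ("path", "clique"):
            raise ValueError("pattern must be 'path' or 'clique'")

    @property
    def target_edges(self) -> int:
        return round(self.n_nodes * self.avg_degree / 2.0)

    @property
    def module_size(self) -> int:
        return round(self.module_fraction * self.n_nodes)


def _labels(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"n{i:0{width}d}" for i in range(n)]


def random_connected_graph(n_nodes: int, avg_degree: float, seed) -> nx.Graph:
    """Connected graph with round(n*d/2) edges: random tree + random fill-ins.

    The first n-1 edges form a uniformly random labeled tree (via a random
    Prüfer sequence); remaining edges are sampled uniformly from the absent
    pairs.  Weights are i.i.d. Uniform(0.5, 1.5).
    """
    target = round(n_nodes * avg_degree / 2.0)
    if target < n_nodes - 1:
        raise ValueError("avg_degree below the connectivity floor")
    if target > n_nodes * (n_nodes - 1) // 2:
        raise ValueError("requested edges exceed the complete graph")
    rng = np.random.default_rng(seed)
    labels = _labels(n_nodes)

    if n_nodes == 1:
        raise ValueError("need at least 2 nodes")
    if n_nodes == 2:
        tree = nx.Graph([(0, 1)])
    else:
        prufer = rng.integers(0, n_nodes, size=n_nodes - 2).tolist()
        tree = nx.from_prufer_sequence(prufer)

    G = nx.Graph()
    G.add_nodes_from(labels)
    edges = {canonical_edge(labels[u], labels[v]) for u, v in tree.edges}
    while len(edges) < target:
        u, v = rng.integers(0, n_nodes, size=2)
        if u == v:
            continue
        e = canonical_edge(labels[u], labels[v])
        if e not in edges:
            edges.add(e)
    for u, v in sorted(edges):
        G.add_edge(u, v, weight=float(rng.uniform(BACKGROUND_WEIGHT_LOW,
                                                  BACKGROUND_WEIGHT_HIGH)))
    return validate_graph(G)


def _pattern_edges(S: NodeModule, pattern: str) -> frozenset[tuple[str, str]]:
    ordered = sorted(S.labels)
    if pattern == "path":
        pairs = zip(ordered, ordered[1:])
    elif pattern == "clique":
        pairs = (
            (ordered[i], ordered[j])
            for i in range(len(ordered))
            for j in range(i + 1, len(ordered))
        )
    else:
        raise ValueError("pattern must be 'path' or 'clique'")
    return frozenset(canonical_edge(u, v) for u, v in pairs)


def plant_module(
    G: nx.Graph, S: NodeModule, pattern: str, contrast: float, seed=None
) -> tuple[nx.Graph, NodeModule]:
    """Plant a path or clique on S and set its weights to the target contrast.

    Missing pattern edges are added; every pattern edge is then assigned the
    identical weight contrast * mean(background), which realizes the requested
    ratio of means exactly.  The planted edge set is recorded on the returned
    module.  ``seed`` is accepted for interface symmetry with the other
    generator steps; the weight rule is deterministic and does not consume it.
    """
    if len(S) < 2:
        raise GraphError("planting needs a module of at least 2 nodes")
    if not S.label_set <= set(G.nodes):
        raise GraphError("module labels absent from graph")
    planted = _pattern_edges(S, pattern)
    H = G.copy()
    for u, v in sorted(planted):
        if not H.has_edge(u, v):
            H.add_edge(u, v, weight=0.0)
    background = [
        data["weight"]
        for u, v, data in H.edges(data=True)
        if canonical_edge(u, v) not in planted
    ]
    if not background:
        raise GraphError("no background edges left to define contrast against")
    w = contrast * float(np.mean(background))
    for u, v in planted:
        H.edges[u, v]["weight"] = w
    return H, NodeModule(S.labels, planted_edges=planted)


def rewire_to_density(
    G: nx.Graph, target_edge_count: int, protected_edges, seed
) -> nx.Graph:
    """Prune random non-bridge, non-protected edges down to the target count.

    Bridges are recomputed after every removal so the graph stays connected;
    protected (planted) edges are never candidates.
    """
    protected = {canonical_edge(u, v) for u, v in (protected_edges or ())}
    H = G.copy()
    if H.number_of_edges() < target_edge_count:
        raise GraphError("target edge count exceeds the current edge count")
    rng = np.random.default_rng(seed)
    while H.number_of_edges() > target_edge_count:
        bridges = {canonical_edge(u, v) for u, v in nx.bridges(H)}
        candidates = sorted(
            e
            for e in (canonical_edge(u, v) for u, v in H.edges)
            if e not in protected and e not in bridges
        )
        if not candidates:
            raise GraphError(
                f"no removable edge left at {H.number_of_edges()} edges "
                f"(target {target_edge_count}): all remaining edges are "
                f"protected or bridges"
            )
        u, v = candidates[int(rng.integers(0, len(candidates)))]
        H.remove_edge(u, v)
    return H


def measure_contrast(G: nx.Graph, planted_edges) -> float:
    """Realized contrast: mean planted weight over mean non-planted weight."""
    planted = {canonical_edge(u, v) for u, v in planted_edges}
    if not planted:
        raise GraphError("no planted edges to measure")
    missing = [e for e in planted if not G.has_edge(*e)]
    if missing:
        raise GraphError(f"planted edges absent from graph: {sorted(missing)[:5]}")
    others = [
        data["weight"]
        for u, v, data in G.edges(data=True)
        if canonical_edge(u, v) not in planted
    ]
    if not others:
        raise GraphError("no non-planted edges to compare against")
    planted_mean = float(np.mean([G.edges[u, v]["weight"] for u, v in sorted(planted)]))
    return planted_mean / float(np.mean(others))


def generate_pair(params: GenParams) -> tuple[nx.Graph, nx.Graph, NodeModule]:
    """Generate an independent background pair sharing one planted module.

    Sub-seeds for the two backgrounds, the module choice and the two pruning
    passes are spawned from ``params.seed``, so the whole pair is a pure
    function of the parameters.  Both graphs receive the identical pattern on
    the identical S at the same requested contrast (realized weights differ
    because each graph's background mean differs).
    """
    ss = np.random.SeedSequence(params.seed)
    seed_g1, seed_g2, seed_S, seed_r1, seed_r2 = ss.spawn(5)

    G1 = random_connected_graph(params.n_nodes, params.avg_degree, seed_g1)
    G2 = random_connected_graph(params.n_nodes, params.avg_degree, seed_g2)

    labels = sorted(G1.nodes)
    rng_S = np.random.default_rng(seed_S)
    chosen = sorted(rng_S.choice(len(labels), size=params.module_size, replace=False))
    S = NodeModule(tuple(labels[i] for i in chosen))

    G1, S = plant_module(G1, S, params.pattern, params.contrast)
    G2, S = plant_module(G2, S, params.pattern, params.contrast)

    G1 = rewire_to_density(G1, params.target_edges, S.planted_edges, seed_r1)
    G2 = rewire_to_density(G2, params.target_edges, S.planted_edges, seed_r2)
    return G1, G2, S
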