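"""Weighted labeled graphs, node modules, file I/O and harmonization.

Graphs are undirected :class:`networkx.Graph` objects whose nodes are unique,
case-sensitive string labels and whose edges carry a real ``weight`` attribute
(a dimensionless connection strength).  A :class:`NodeModule` is an ordered set
of node labels — the candidate shared community S — optionally annotated with
the edges that were planted into it by the synthetic generator.

Two graphs being compared need not share their full label sets; only the
module itself must exist in both.  The two harmonization strategies offered
here (:func:`harmonize_by_removal`, :func:`harmonize_by_isolation`) make a
mismatched pair comparable without changing any existing edge weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import networkx as nx

__all__ = [
    "GraphError",
    "NodeModule",
    "read_graph",
    "write_graph",
    "read_module",
    "write_module",
    "new_graph",
    "validate_graph",
    "absolute_weights",
    "harmonize_by_removal",
    "harmonize_by_isolation",
]


class GraphError(ValueError):
    """Malformed graph input or an operation that would produce one."""


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Undirected edge as a label-sorted pair; the storage convention."""
    return (u, v) if u <= v else (v, u)


@dataclass
class NodeModule:
    """An ordered set of node labels S, the candidate shared module.

    ``planted_edges`` is populated only by the synthetic generator and records
    which label pairs constitute the planted path/clique pattern.
    """

    labels: tuple[str, ...]
    planted_edges: Optional[frozenset[tuple[str, str]]] = field(default=None)

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        if len(self.labels) < 1:
            raise GraphError("a node module needs at least one label")
        if len(set(self.labels)) != len(self.labels):
            raise GraphError("duplicate labels in node module")
        if self.planted_edges is not None:
            self.planted_edges = frozenset(
                canonical_edge(u, v) for u, v in self.planted_edges
            )

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in set(self.labels)

    @property
    def label_set(self) -> frozenset[str]:
        return frozenset(self.labels)


def new_graph(edges: Iterable[tuple[str, str, float]]) -> nx.Graph:
    """Build a weighted graph from (u, v, weight) triples, validating as we go."""
    G = nx.Graph()
    for u, v, w in edges:
        _add_edge_checked(G, str(u), str(v), float(w), where="input")
    validate_graph(G)
    return G


def _add_edge_checked(G: nx.Graph, u: str, v: str, w: float, where: str) -> None:
    if u == v:
        raise GraphError(f"self-loop {u!r} rejected ({where})")
    if G.has_edge(u, v) and G.edges[u, v]["weight"] != w:
        raise GraphError(
            f"duplicate edge {u!r}-{v!r} with conflicting weight ({where})"
        )
    G.add_edge(u, v, weight=w)


def validate_graph(G: nx.Graph) -> nx.Graph:
    """Assert the structural invariants; returns the graph for chaining."""
    if G.number_of_nodes() == 0:
        raise GraphError("empty graph rejected")
    for u, v, data in G.edges(data=True):
        if u == v:
            raise GraphError(f"self-loop at {u!r}")
        if "weight" not in data:
            raise GraphError(f"edge {u!r}-{v!r} has no weight")
    return G


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_graph(path: str | Path, format: str = "edgelist") -> nx.Graph:
    """Read a weighted graph from an edge-list or GraphML file.

    The edge-list dialect is whitespace-separated ``label label weight`` rows;
    lines starting with ``#`` are comments.  Negative weights are preserved at
    read time — taking absolute values is a separate explicit step
    (:func:`absolute_weights`).
    """
    path = Path(path)
    if format == "graphml":
        G = nx.read_graphml(path)
        H = nx.Graph()
        for u, v, data in G.edges(data=True):
            _add_edge_checked(H, str(u), str(v), float(data["weight"]), where=str(path))
        for node in G.nodes:
            H.add_node(str(node))
        return validate_graph(H)
    if format != "edgelist":
        raise ValueError(f"unknown graph format {format!r}")

    G = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 3:
                raise GraphError(
                    f"{path}:{lineno}: expected 'label label weight', got {stripped!r}"
                )
            u, v, raw = parts
            try:
                w = float(raw)
            except ValueError:
                raise GraphError(
                    f"{path}:{lineno}: weight {raw!r} is not a number"
                ) from None
            _add_edge_checked(G, u, v, w, where=f"{path}:{lineno}")
    return validate_graph(G)


def write_graph(G: nx.Graph, path: str | Path, format: str = "edgelist") -> None:
    """Write a graph; edge-list rows are emitted in canonical sorted order."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(G, path)
        return
    if format != "edgelist":
        raise ValueError(f"unknown graph format {format!r}")
    lines = []
    for u, v in sorted(canonical_edge(u, v) for u, v in G.edges):
        w = G.edges[u, v]["weight"]
        lines.append(f"{u} {v} {w!r}")
    path.write_text("\n".join(lines) + "\n")


def read_module(path: str | Path) -> NodeModule:
    """Read a node module file: one label per line, '#' comments allowed."""
    labels = []
    for line in Path(path).read_text().splitlines():
        stripped = line.strip()
        if stripped and not stripped.startswith("#"):
            labels.append(stripped)
    if not labels:
        raise GraphError(f"{path}: module file contains no labels")
    return NodeModule(tuple(labels))


def write_module(S: NodeModule, path: str | Path) -> None:
    Path(path).write_text("\n".join(S.labels) + "\n")


# ---------------------------------------------------------------------------
# Preprocessing / harmonization
# ---------------------------------------------------------------------------

def absolute_weights(G: nx.Graph) -> nx.Graph:
    """Replace every weight with its absolute value; topology unchanged.

    Negative weights arise in metabolite co-perturbation networks between a
    substrate and product around a perturbed enzyme; the magnitude still
    expresses connection strength.
    """
    H = G.copy()
    for u, v, data in H.edges(data=True):
        data["weight"] = abs(data["weight"])
    return H


def harmonize_by_removal(
    G1: nx.Graph, G2: nx.Graph, S: NodeModule
) -> tuple[nx.Graph, NodeModule]:
    """Drop module nodes absent from the tester G2 from both S and proposer G1.

    Returns the pruned proposer and module; after this, S ⊆ V(G1) ∩ V(G2).
    Raises :class:`GraphError` if nothing of the module survives.
    """
    missing = [lab for lab in S.labels if lab not in G2]
    kept = tuple(lab for lab in S.labels if lab in G2)
    if not kept:
        raise GraphError("module vanishes under removal")
    H1 = G1.copy()
    H1.remove_nodes_from(lab for lab in missing if lab in H1)
    return H1, NodeModule(kept, planted_edges=S.planted_edges)


def harmonize_by_isolation(G1: nx.Graph, G2: nx.Graph) -> tuple[nx.Graph, nx.Graph]:
    """Extend both graphs to the union label set, adding missing nodes isolated.

    No existing edge or weight is touched; added nodes have degree zero.  This
    can only dilute the encoding signal, never create a spurious one.
    """
    union = set(G1.nodes) | set(G2.nodes)
    H1, H2 = G1.copy(), G2.copy()
    H1.add_nodes_from(union - set(G1.nodes))
    H2.add_nodes_from(union - set(G2.nodes))
    return H1, H2
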