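"""Probability-diffusion walker encoding of a node module as a bitstring.

The alternate-hypothesis code for a module S in a graph G works like this: one
node of S (the start) is named outright at a cost of log2|V| bits; a
deterministic walker then diffuses probability mass outward from the S-nodes
found so far and visits unvisited nodes in descending order of received mass,
appending a 1-bit when the visited node belongs to S and a 0-bit otherwise.
Nodes of S the walker never reaches are "hardcoded" at log2|V| bits each.  The
total alternate encoding length in bits is

    I_A = (|S| - found + 1) * log2(|V|) + l - 1

where ``l`` is the bitstring length and ``found`` the number of 1-bits.  A
tightly connected, heavily weighted S concentrates the diffusion, keeps the
bitstring short, and so compresses well relative to the log2|V|-per-node null
code — that compression is what the significance machinery turns into a
p-value bound.

Determinism is essential: the decoder replays the identical walk, so the
(start, bitstring) pair uniquely identifies the found subset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import networkx as nx

from .graphs import GraphError, NodeModule

__all__ = ["Encoding", "diffuse", "encode_from_start", "encode_module", "decode"]


@dataclass(frozen=True)
class Encoding:
    """Result of encoding a module in a graph under the alternate hypothesis."""

    start: str
    bits: str
    module_size: int
    n_nodes: int

    def __post_init__(self) -> None:
        if not self.bits or self.bits[0] != "1":
            raise ValueError("bitstring must start with 1 (the start node is in S)")

    @property
    def l(self) -> int:
        """Bitstring length in bits."""
        return len(self.bits)

    @property
    def found(self) -> int:
        """Number of module nodes captured by the walk (1-bits)."""
        return self.bits.count("1")

    @property
    def i_alt(self) -> float:
        """Alternate-hypothesis encoding length I_A in bits."""
        return (self.module_size - self.found + 1) * math.log2(self.n_nodes) + self.l - 1

    def to_record(self) -> dict:
        """Small JSON-serializable audit record."""
        return {
            "start": self.start,
            "bitstring": self.bits,
            "l": self.l,
            "found": self.found,
            "I_A": self.i_alt,
        }


def _weighted_neighbors(G: nx.Graph, node: str) -> list[tuple[str, float]]:
    # sorted for order-independent float accumulation
    return sorted((v, data["weight"]) for v, data in G[node].items())


def diffuse(
    G: nx.Graph, visited: frozenset[str] | set[str], frontier: frozenset[str] | set[str]
) -> dict[str, float]:
    """Spread one unit of probability mass from the frontier to unvisited nodes.

    Each frontier node carries an equal 1/|frontier| share and splits it over
    its unvisited neighbors proportionally to edge weight.  A frontier node
    with no unvisited neighbors (or only zero-weight ones) passes its share
    through its visited neighbors — one level deep — onto *their* unvisited
    neighbors; mass that finds no unvisited target at that depth is lost.
    Returned masses are nonnegative and sum to at most 1.
    """
    if not frontier:
        raise ValueError("frontier must be non-empty")
    if not set(frontier) <= set(visited):
        raise ValueError("frontier must be a subset of visited")
    share = 1.0 / len(frontier)
    masses: dict[str, float] = {}

    def deposit(targets: list[tuple[str, float]], amount: float) -> None:
        total = sum(w for _, w in targets)
        if total <= 0.0:
            return
        for v, w in targets:
            if w > 0.0:
                masses[v] = masses.get(v, 0.0) + amount * (w / total)

    for f in sorted(frontier):
        nbrs = _weighted_neighbors(G, f)
        unvis = [(v, w) for v, w in nbrs if v not in visited]
        if sum(w for _, w in unvis) > 0.0:
            deposit(unvis, share)
            continue
        # pass-through: route the share via visited neighbors, one hop
        vis = [(v, w) for v, w in nbrs if v in visited]
        total_vis = sum(w for _, w in vis)
        if total_vis <= 0.0:
            continue  # share lost
        for v, w in vis:
            two_hop = [
                (u, w2) for u, w2 in _weighted_neighbors(G, v) if u not in visited
            ]
            deposit(two_hop, share * (w / total_vis))
    return masses


def _argmax_mass(masses: Mapping[str, float]) -> tuple[str, float]:
    # descending mass, ties broken by ascending label
    best = min(masses.items(), key=lambda kv: (-kv[1], kv[0]))
    return best


def encode_from_start(G: nx.Graph, S: NodeModule, start: str) -> Encoding:
    """Run the walker from a given start node of S and return its encoding.

    The walk halts when all of S has been found, when every remaining mass
    falls below the stop threshold 1/|V|^2, or after |V| visits; module nodes
    still unfound at the halt are accounted through the hardcoding term of
    I_A rather than the bitstring.
    """
    s_set = S.label_set
    if start not in s_set:
        raise GraphError(f"start {start!r} is not in the module")
    if not s_set <= set(G.nodes):
        missing = sorted(s_set - set(G.nodes))
        raise GraphError(f"module labels absent from graph: {missing}")

    n = G.number_of_nodes()
    threshold = 1.0 / (n * n)
    visited = {start}
    found = {start}
    bits = ["1"]
    while len(found) < len(s_set) and len(visited) < n:
        masses = diffuse(G, visited, frontier=found)
        if not masses:
            break
        node, mass = _argmax_mass(masses)
        if mass < threshold:
            break
        visited.add(node)
        if node in s_set:
            found.add(node)
            bits.append("1")
        else:
            bits.append("0")
    return Encoding(start=start, bits="".join(bits), module_size=len(s_set), n_nodes=n)


def encode_module(G: nx.Graph, S: NodeModule) -> Encoding:
    """Encoding of minimal I_A over all start nodes, ties to the smallest label.

    The start's identity is already paid for by the log2|V| term, so choosing
    the best start keeps the code decodable while tightening the bound.
    """
    best: Encoding | None = None
    for start in sorted(S.labels):
        enc = encode_from_start(G, S, start)
        if best is None or enc.i_alt < best.i_alt:
            best = enc
    assert best is not None
    return best


def decode(G: nx.Graph, start: str, bits: str) -> NodeModule:
    """Replay the walker to recover the found subset from (start, bitstring).

    The replay uses the identical diffusion and tie-breaking rules as
    :func:`encode_from_start`; the bits themselves tell the decoder which
    visited nodes belong to the module, which is exactly the information the
    walker needs to reproduce its own frontier.
    """
    if not bits or bits[0] != "1":
        raise ValueError("bitstring must begin with 1")
    if start not in G:
        raise GraphError(f"start {start!r} not in graph")
    n = G.number_of_nodes()
    threshold = 1.0 / (n * n)
    visited = {start}
    found = [start]
    for bit in bits[1:]:
        if len(visited) >= n:
            raise ValueError("bitstring longer than the walker's natural halt")
        masses = diffuse(G, visited, frontier=set(found))
        if not masses:
            raise ValueError("bitstring longer than the walker's natural halt")
        node, mass = _argmax_mass(masses)
        if mass < threshold:
            raise ValueError("bitstring longer than the walker's natural halt")
        visited.add(node)
        if bit == "1":
            found.append(node)
    return NodeModule(tuple(found))
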