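"""Undirected, unweighted sample-level graph with per-edge support counts.

Nodes are sample ids, an edge denotes inferred direct dependence between
two ChIP-seq samples; ``support`` records in how many algorithms the edge
was discovered, ``annotations`` holds labels such as gold-standard flags.
Self-loops are rejected at insertion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .io import canonical_pair

__all__ = ["Network"]

Edge = tuple[str, str]


@dataclass
class Network:
    nodes: set[str] = field(default_factory=set)
    support: dict[Edge, int] = field(default_factory=dict)
    annotations: dict[Edge, set[str]] = field(default_factory=dict)

    @property
    def edges(self) -> set[Edge]:
        return set(self.support)

    def add_node(self, node: str) -> None:
        self.nodes.add(node)

    def add_edge(self, a: str, b: str, support: int = 1) -> None:
        pair = canonical_pair(a, b)  # raises on self-loop
        self.nodes.update(pair)
        self.support[pair] = support

    def has_edge(self, a: str, b: str) -> bool:
        return canonical_pair(a, b) in self.support

    def annotate(self, a: str, b: str, label: str) -> None:
        pair = canonical_pair(a, b)
        if pair not in self.support:
            raise KeyError(f"no edge {pair}")
        self.annotations.setdefault(pair, set()).add(label)

    def degree(self, node: str) -> int:
        return sum(1 for e in self.support if node in e)

    def neighbours(self, node: str) -> set[str]:
        return {a if b == node else b for a, b in self.support if node in (a, b)}

    def n_edges(self) -> int:
        return len(self.support)

    def subgraph(self, keep: Iterable[str]) -> "Network":
        """Induced subgraph on ``keep``; support and annotations carried over."""
        keep = set(keep)
        sub = Network(nodes=keep & self.nodes)
        for (a, b), s in self.support.items():
            if a in keep and b in keep:
                sub.support[(a, b)] = s
                if (a, b) in self.annotations:
                    sub.annotations[(a, b)] = set(self.annotations[(a, b)])
        return sub

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), s in self.support.items():
            g.add_edge(a, b, support=s)
        return g

    @classmethod
    def from_edges(cls, edges: Iterable[Edge], nodes: Iterable[str] | None = None) -> "Network":
        net = cls()
        if nodes is not None:
            net.nodes.update(nodes)
        for a, b in edges:
            net.add_edge(a, b)
        return net
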