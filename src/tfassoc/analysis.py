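"""Topology metrics and neighbourhood analyses of the association network.

Degree distribution, degree-resolved clustering coefficients, and mean
neighbour degree probe whether the graph is scale-free-like (it is not
expected to be: node degrees of co-binding TFs take a wide range of values
and similar-degree nodes attach to each other). First-neighbour profiles
resolve each node's neighbourhood by cell type; subnetwork extraction pulls
out a seed set (e.g. all samples of one TF family) plus its first
neighbours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

from .io import SampleMetadata
from .network import Network

__all__ = [
    "NeighbourProfile",
    "degree_distribution",
    "clustering_by_degree",
    "mean_neighbour_degree",
    "first_neighbour_profile",
    "extract_subnetwork",
]


@dataclass
class NeighbourProfile:
    """Cell-type composition of one node's first neighbours; counts sum to
    the node's degree."""

    node: str
    counts: dict[str, int]


def degree_distribution(network: Network) -> dict[int, int]:
    """Histogram degree -> node count over all nodes, including degree 0;
    counts sum to |V|."""
    hist: dict[int, int] = {}
    for node in network.nodes:
        d = network.degree(node)
        hist[d] = hist.get(d, 0) + 1
    return hist


def _local_clustering(network: Network, node: str) -> float:
    """2 * triangles(v) / (deg (deg - 1)); defined as 0 for degree < 2 so
    degree-class averages always exist."""
    nbrs = sorted(network.neighbours(node))
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(
        1
        for i in range(k)
        for j in range(i + 1, k)
        if network.has_edge(nbrs[i], nbrs[j])
    )
    return 2.0 * links / (k * (k - 1))


def clustering_by_degree(network: Network) -> dict[int, float]:
    """Mean local clustering coefficient within each degree class."""
    sums: dict[int, list[float]] = {}
    for node in network.nodes:
        sums.setdefault(network.degree(node), []).append(
            _local_clustering(network, node)
        )
    return {d: sum(v) / len(v) for d, v in sums.items()}


def mean_neighbour_degree(network: Network) -> dict[int, float]:
    """For each degree class k, the average (over nodes of degree k) of the
    mean degree of their neighbours. Degree-0 nodes are omitted (no
    neighbours to average)."""
    sums: dict[int, list[float]] = {}
    for node in network.nodes:
        nbrs = network.neighbours(node)
        if not nbrs:
            continue
        mean_nd = sum(network.degree(m) for m in nbrs) / len(nbrs)
        sums.setdefault(network.degree(node), []).append(mean_nd)
    return {d: sum(v) / len(v) for d, v in sums.items()}


def first_neighbour_profile(
    network: Network, metadata: list[SampleMetadata]
) -> list[NeighbourProfile]:
    """Per node, the number of first-neighbour nodes of each cell type.

    Profiles are returned in sorted node order; an isolated node has an
    empty count map.
    """
    cell_of = {m.sample_id: m.cell_type for m in metadata}
    missing = [n for n in network.nodes if n not in cell_of]
    if missing:
        raise KeyError(f"node(s) missing from metadata: {sorted(missing)}")
    profiles = []
    for node in sorted(network.nodes):
        counts: dict[str, int] = {}
        for nbr in network.neighbours(node):
            ct = cell_of[nbr]
            counts[ct] = counts.get(ct, 0) + 1
        profiles.append(NeighbourProfile(node, counts))
    return profiles


def extract_subnetwork(
    network: Network, node_filter: Callable[[str], bool]
) -> Network:
    """Induced subgraph on the nodes selected by ``node_filter`` plus their
    first neighbours (e.g. all GATA samples and their closest neighbours)."""
    seeds = {n for n in network.nodes if node_filter(n)}
    if not seeds:
        warnings.warn("node filter matched nothing; returning empty network",
                      stacklevel=2)
        return Network()
    keep = set(seeds)
    for node in seeds:
        keep |= network.neighbours(node)
    return network.subgraph(keep)
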