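"""Consensus TF association network: vote over per-algorithm networks.

An edge enters the consensus iff it was discovered by at least
``min_support`` of the input algorithms (default 3 of 4). The node universe
is carried through unchanged; isolated nodes are pruned only on demand,
with the removed count reported.
"""

from __future__ import annotations

from collections import Counter

from .io import GoldStandard, SampleMetadata, canonical_pair
from .network import Network

__all__ = ["consensus_network", "prune_isolated", "annotate_with_gold"]

HIGH_CONFIDENCE = "string_high_confidence"
PHYSICAL = "string_physical"


def consensus_network(networks: list[Network], min_support: int) -> Network:
    """Keep edges present in >= ``min_support`` input networks.

    All inputs must share the same node universe. Per-edge support (number
    of algorithms that found it) is recorded. min_support = 1 gives the
    union, min_support = len(networks) the intersection.
    """
    if not networks:
        raise ValueError("no input networks")
    if not 1 <= min_support <= len(networks):
        raise ValueError(
            f"min_support must be in [1, {len(networks)}], got {min_support}"
        )
    universe = networks[0].nodes
    for net in networks[1:]:
        if net.nodes != universe:
            raise ValueError("input networks have mismatched node universes")
    votes = Counter(edge for net in networks for edge in net.edges)
    out = Network(nodes=set(universe))
    for (a, b), count in votes.items():
        if count >= min_support:
            out.add_edge(a, b, support=count)
    return out


def prune_isolated(network: Network) -> tuple[Network, int]:
    """Drop degree-0 nodes; returns (pruned network, number removed)."""
    connected = {node for edge in network.edges for node in edge}
    removed = len(network.nodes) - len(connected)
    pruned = Network(
        nodes=connected,
        support=dict(network.support),
        annotations={e: set(a) for e, a in network.annotations.items()},
    )
    return pruned, removed


def annotate_with_gold(
    network: Network,
    gold: GoldStandard,
    metadata: list[SampleMetadata],
) -> Network:
    """Label edges whose TF pair is a gold-standard interaction.

    An edge gets ``string_high_confidence`` if the TF names of its two
    endpoint samples form a retained gold pair, and additionally
    ``string_physical`` if that pair carries the physical-action flag.
    Edges between two samples of the same TF are never labelled. The input
    network is annotated in place and returned.
    """
    tf_of = {m.sample_id: m.tf_name for m in metadata}
    missing = [n for n in network.nodes if n not in tf_of]
    if missing:
        raise KeyError(f"node(s) missing from metadata: {sorted(missing)}")
    for a, b in network.edges:
        tfa, tfb = tf_of[a], tf_of[b]
        if tfa == tfb:
            continue
        pair = canonical_pair(tfa, tfb)
        if pair in gold.scores:
            network.annotate(a, b, HIGH_CONFIDENCE)
            if pair in gold.physical:
                network.annotate(a, b, PHYSICAL)
    return network
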