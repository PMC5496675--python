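"""Benchmark a sample-level network against a protein-interaction gold
standard.

The sample graph is collapsed to unordered TF-name pairs restricted to the
TFs covered by the gold standard; a confusion matrix is then taken over the
universe of all C(u, 2) unordered pairs of those u TFs, so tp + fp + tn +
fn is a constant of the universe and tp + fn depends only on the gold
standard. Precision and recall are reported as percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .io import GoldStandard, SampleMetadata, canonical_pair
from .network import Network

__all__ = ["ConfusionCounts", "collapse_to_tf_pairs", "confusion_counts",
           "benchmark_network", "write_benchmark_report"]

Pair = tuple[str, str]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def precision_pct(self) -> float:
        """100 * tp / (tp + fp); 0 when nothing was predicted."""
        denom = self.tp + self.fp
        return 100.0 * self.tp / denom if denom else 0.0

    @property
    def recall_pct(self) -> float:
        """100 * tp / (tp + fn); 0 when the gold standard is empty."""
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom else 0.0


def collapse_to_tf_pairs(
    network: Network,
    metadata: list[SampleMetadata],
    tf_universe: set[str],
) -> set[Pair]:
    """Predicted TF pairs: {A, B} iff A != B, both in ``tf_universe``, and
    at least one network edge joins a sample of A to a sample of B.
    Same-TF edges and edges touching TFs outside the universe are dropped.
    """
    tf_of = {m.sample_id: m.tf_name for m in metadata}
    pairs: set[Pair] = set()
    for a, b in network.edges:
        tfa, tfb = tf_of[a], tf_of[b]
        if tfa == tfb or tfa not in tf_universe or tfb not in tf_universe:
            continue
        pairs.add(canonical_pair(tfa, tfb))
    return pairs


def confusion_counts(
    predicted: set[Pair],
    gold_positive: set[Pair],
    tf_universe: set[str],
) -> ConfusionCounts:
    """Confusion matrix over all C(u, 2) unordered pairs of the universe."""
    for pair in predicted | gold_positive:
        if not set(pair) <= tf_universe:
            raise ValueError(f"pair {pair} outside the TF universe")
    predicted = {canonical_pair(*p) for p in predicted}
    gold_positive = {canonical_pair(*p) for p in gold_positive}
    u = len(tf_universe)
    n_pairs = u * (u - 1) // 2
    tp = len(predicted & gold_positive)
    fp = len(predicted - gold_positive)
    fn = len(gold_positive - predicted)
    tn = n_pairs - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def benchmark_network(
    network: Network,
    metadata: list[SampleMetadata],
    gold: GoldStandard,
    tf_universe: set[str] | None = None,
) -> ConfusionCounts:
    """Collapse a sample network to TF pairs and score it against the gold
    standard. The universe defaults to the TFs present in the gold standard
    restricted to TFs actually assayed in the metadata."""
    if tf_universe is None:
        assayed = {m.tf_name for m in metadata}
        tf_universe = gold.tf_universe() & assayed
    predicted = collapse_to_tf_pairs(network, metadata, tf_universe)
    gold_positive = {p for p in gold.scores if set(p) <= tf_universe}
    return confusion_counts(predicted, gold_positive, tf_universe)


def write_benchmark_report(
    rows: list[tuple[str, ConfusionCounts]], path: str | Path
) -> None:
    """TSV report, one row per method: method, tp, fp, tn, fn,
    precision_pct, recall_pct (percentages to 2 decimals)."""
    with open(path, "w") as fh:
        fh.write("method\ttp\tfp\ttn\tfn\tprecision_pct\trecall_pct\n")
        for method, c in rows:
            fh.write(
                f"{method}\t{c.tp}\t{c.fp}\t{c.tn}\t{c.fn}"
                f"\t{c.precision_pct:.2f}\t{c.recall_pct:.2f}\n"
            )
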