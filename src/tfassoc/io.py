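"""Readers and writers for the external formats the pipeline touches.

Conventions, fixed once and used everywhere:

* Genomic intervals are BED-style 0-based half-open ``[start, end)``, so
  "overlap of at least 1 bp" is exactly "non-empty intersection" and
  bookended intervals (``a.end == b.start``) do not overlap.
* TF names are uppercased on ingest so that mixed-case sample annotations
  (``Gata2``) unify with protein identifiers (``GATA2``).
* Gold-standard protein pairs are stored unordered, canonically as a
  lexicographically sorted tuple; self-pairs are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

__all__ = [
    "GenomicSegment",
    "SampleMetadata",
    "GoldStandard",
    "FormatError",
    "read_bed",
    "write_bed",
    "read_metadata",
    "write_metadata",
    "read_string_table",
    "write_string_table",
    "write_network",
    "read_network",
    "canonical_pair",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass(frozen=True, order=True)
class GenomicSegment:
    """A genomic interval, 0-based half-open ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicSegment") -> bool:
        """True iff the half-open intersection spans >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class SampleMetadata:
    """One ChIP-seq profile: a single TF assayed in a single cell type."""

    sample_id: str
    tf_name: str
    cell_type: str
    peak_path: str = ""

    def __post_init__(self) -> None:
        if not self.tf_name:
            raise ValueError(f"sample {self.sample_id!r}: empty TF name")
        object.__setattr__(self, "tf_name", self.tf_name.upper())


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered pair as a sorted tuple; raises on self-pairs."""
    if a == b:
        raise ValueError(f"self-pair: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class GoldStandard:
    """Set of unordered protein pairs with a confidence score and an
    optional 'physical interaction' flag (STRING-derived).

    ``scores`` maps each canonical pair to its (maximum) combined score;
    ``physical`` is the subset of pairs flagged by the action keyword.
    """

    scores: dict[tuple[str, str], int] = field(default_factory=dict)
    physical: set[tuple[str, str]] = field(default_factory=set)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self.scores)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self.scores

    def __len__(self) -> int:
        return len(self.scores)

    def tf_universe(self) -> set[str]:
        """All proteins appearing in at least one retained pair."""
        return {name for pair in self.scores for name in pair}


# ---------------------------------------------------------------------------
# BED

_BED_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(path: str | Path) -> list[GenomicSegment]:
    """Read a BED3+ file; columns beyond the third are ignored.

    Track/browser/comment lines and blank lines are skipped. Malformed
    coordinates raise :class:`FormatError` naming the offending line.
    """
    segments: list[GenomicSegment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom, s, e = fields[0], fields[1], fields[2]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            try:
                segments.append(GenomicSegment(chrom, start, end))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return segments


def write_bed(segments: list[GenomicSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\n")


# ---------------------------------------------------------------------------
# Sample metadata

_META_COLUMNS = ("sample_id", "tf", "cell_type", "peak_path")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read the sample sheet: a TSV with header sample_id, tf, cell_type,
    peak_path. Duplicate sample ids are an error."""
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        header = header_line.split("\t")
        missing = [c for c in _META_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
        idx = {c: header.index(c) for c in _META_COLUMNS}
        records: list[SampleMetadata] = []
        seen: set[str] = set()
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            try:
                rec = SampleMetadata(
                    sample_id=fields[idx["sample_id"]],
                    tf_name=fields[idx["tf"]],
                    cell_type=fields[idx["cell_type"]],
                    peak_path=fields[idx["peak_path"]],
                )
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if rec.sample_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate sample_id {rec.sample_id!r}")
            seen.add(rec.sample_id)
            records.append(rec)
    return records


def write_metadata(records: list[SampleMetadata], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_META_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.tf_name}\t{r.cell_type}\t{r.peak_path}\n")


# ---------------------------------------------------------------------------
# STRING-style interaction table


def read_string_table(
    path: str | Path,
    min_score: int = 500,
    action_keyword: str | None = None,
    name_map: dict[str, str] | None = None,
) -> GoldStandard:
    """Read a STRING protein-links style flat file into a :class:`GoldStandard`.

    The file is whitespace- or tab-separated with a header containing at
    least ``protein1 protein2 combined_score`` and optionally ``action``.
    Pairs with combined score >= ``min_score`` (default 500, the
    high-confidence cut) are retained, canonicalized unordered, self-pairs
    dropped. If ``action_keyword`` is given (e.g. ``"binding"``), a pair is
    flagged physical when any of its rows carries that keyword.

    ``name_map`` optionally translates identifiers (e.g. sample TF names to
    database protein names) before canonicalization.
    """
    gold = GoldStandard()
    with open(path) as fh:
        header = fh.readline().split()
        try:
            i1, i2, isc = (
                header.index("protein1"),
                header.index("protein2"),
                header.index("combined_score"),
            )
        except ValueError as exc:
            raise FormatError(f"{path}: header must name protein1, protein2, combined_score") from exc
        iact = header.index("action") if "action" in header else None
        for lineno, raw in enumerate(fh, start=2):
            fields = raw.split()
            if not fields:
                continue
            a, b = fields[i1].upper(), fields[i2].upper()
            if name_map is not None:
                a, b = name_map.get(a, a), name_map.get(b, b)
            try:
                score = int(fields[isc])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer combined_score") from exc
            if score < min_score or a == b:
                continue
            pair = canonical_pair(a, b)
            gold.scores[pair] = max(score, gold.scores.get(pair, 0))
            if (
                action_keyword is not None
                and iact is not None
                and len(fields) > iact
                and fields[iact] == action_keyword
            ):
                gold.physical.add(pair)
    return gold


def write_string_table(
    rows: list[tuple[str, str, int, str]], path: str | Path
) -> None:
    """Write (protein1, protein2, combined_score, action) rows in the
    STRING flat-file dialect. Empty action renders as '-'."""
    with open(path, "w") as fh:
        fh.write("protein1 protein2 combined_score action\n")
        for a, b, score, action in rows:
            fh.write(f"{a} {b} {score} {action or '-'}\n")


# ---------------------------------------------------------------------------
# Network serialization (edge-list TSV and GraphML)


def write_network(network, path: str | Path, format: str = "tsv") -> None:
    """Write a :class:`~tfassoc.network.Network`.

    ``tsv`` is the canonical form: columns node_a, node_b, support_count,
    annotations (comma-joined, '-' if none), edges in lexicographic order.
    ``graphml`` targets Cytoscape import.
    """
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tsupport_count\tannotations\n")
            for a, b in sorted(network.edges):
                ann = ",".join(sorted(network.annotations.get((a, b), ()))) or "-"
                fh.write(f"{a}\t{b}\t{network.support.get((a, b), 1)}\t{ann}\n")
    elif format == "graphml":
        g = nx.Graph()
        g.add_nodes_from(sorted(network.nodes))
        for a, b in sorted(network.edges):
            g.add_edge(
                a,
                b,
                support=int(network.support.get((a, b), 1)),
                annotations=",".join(sorted(network.annotations.get((a, b), ()))),
            )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format: {format!r}")


def read_network(path: str | Path):
    """Read an edge-list TSV written by :func:`write_network`.

    Isolated nodes are not representable in the edge list, so the node set
    of the round-tripped network is the set of endpoint nodes.
    """
    from .network import Network

    net = Network()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["node_a", "node_b", "support_count"]:
            raise FormatError(f"{path}: not a network edge-list TSV")
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            a, b, support, ann = line.split("\t")
            net.add_edge(a, b, support=int(support))
            if ann != "-":
                net.annotations[canonical_pair(a, b)] = set(ann.split(","))
    return net
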