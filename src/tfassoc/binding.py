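"""Multi-sample TF-binding profile: the n x p binary occupancy matrix.

Rows are the merged union of all samples' peaks (overlap >= 1 bp merged,
transitively); columns are samples; entry (i, j) is 1 iff sample j has at
least one peak intersecting merged segment i. Pairwise Pearson correlation
of the 0/1 columns (the phi coefficient), hierarchical clustering of the
correlation matrix, and correlation-threshold graphs are built from it.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import GenomicSegment, SampleMetadata, read_bed
from .network import Network

__all__ = [
    "BindingMatrix",
    "CorrelationMatrix",
    "Dendrogram",
    "merge_segments",
    "build_matrix",
    "pearson_matrix",
    "cluster_samples",
    "correlation_graph",
    "write_matrix",
    "read_matrix",
]


@dataclass
class BindingMatrix:
    """Binary occupancy matrix X with its row segments and column samples."""

    segments: list[GenomicSegment]
    sample_ids: list[str]
    values: np.ndarray  # shape (n, p), dtype int8, entries in {0, 1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        n, p = self.values.shape
        if n != len(self.segments) or p != len(self.sample_ids):
            raise ValueError("matrix shape does not match segment/sample labels")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def subsample_rows(self, k: int, seed: int) -> "BindingMatrix":
        """Seeded uniform row subsample (without replacement), keeping row
        order; a tractability hook for very large segment counts."""
        if k >= self.n:
            return self
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(self.n, size=k, replace=False))
        return BindingMatrix(
            [self.segments[i] for i in idx], list(self.sample_ids), self.values[idx]
        )


@dataclass
class CorrelationMatrix:
    sample_ids: list[str]
    values: np.ndarray  # (p, p), symmetric, unit diagonal; NaN where undefined

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def merge_segments(segments: list[GenomicSegment]) -> list[GenomicSegment]:
    """Merge intervals that share >= 1 bp, transitively closed.

    Bookended intervals (end == start) share 0 bp and are kept separate.
    Output is sorted by (chrom, start) and pairwise disjoint; idempotent.
    """
    merged: list[GenomicSegment] = []
    cur: GenomicSegment | None = None
    for seg in sorted(segments):
        if cur is not None and seg.chrom == cur.chrom and seg.start < cur.end:
            if seg.end > cur.end:
                cur = GenomicSegment(cur.chrom, cur.start, seg.end)
        else:
            if cur is not None:
                merged.append(cur)
            cur = seg
    if cur is not None:
        merged.append(cur)
    return merged


def _overlapping_rows(
    starts: list[int], ends: list[int], peak: GenomicSegment
) -> range:
    """Indices of sorted disjoint rows intersecting ``peak`` (same chrom)."""
    lo = bisect_right(ends, peak.start)  # first row with end > peak.start
    hi = bisect_left(starts, peak.end)  # first row with start >= peak.end
    return range(lo, hi)


def build_matrix(
    metadata: list[SampleMetadata],
    row_subsample: int | None = None,
    seed: int | None = None,
) -> BindingMatrix:
    """Build the occupancy matrix from per-sample BED files.

    Rows are the merged union of all peaks; X[i, j] = 1 iff sample j has a
    peak with non-empty intersection with row i. Every row therefore has at
    least one 1. ``row_subsample`` optionally keeps a seeded uniform subset
    of rows for downstream tractability.
    """
    peaks_by_sample = {m.sample_id: read_bed(m.peak_path) for m in metadata}
    all_peaks = [seg for peaks in peaks_by_sample.values() for seg in peaks]
    if not all_peaks:
        raise ValueError("no peaks: the union of all samples' peak sets is empty")
    rows = merge_segments(all_peaks)

    by_chrom: dict[str, tuple[list[int], list[int], list[int]]] = {}
    for i, seg in enumerate(rows):
        starts, ends, idx = by_chrom.setdefault(seg.chrom, ([], [], []))
        starts.append(seg.start)
        ends.append(seg.end)
        idx.append(i)

    X = np.zeros((len(rows), len(metadata)), dtype=np.int8)
    for j, m in enumerate(metadata):
        for peak in peaks_by_sample[m.sample_id]:
            if peak.chrom not in by_chrom:
                continue
            starts, ends, idx = by_chrom[peak.chrom]
            for k in _overlapping_rows(starts, ends, peak):
                X[idx[k], j] = 1

    bm = BindingMatrix(rows, [m.sample_id for m in metadata], X)
    if row_subsample is not None:
        if seed is None:
            raise ValueError("row_subsample requires a seed")
        bm = bm.subsample_rows(row_subsample, seed)
    return bm


def pearson_matrix(X: BindingMatrix) -> CorrelationMatrix:
    """Pairwise Pearson correlation of the 0/1 columns.

    On binary data this equals the phi coefficient of each pair's 2x2
    contingency table. Entries involving a constant column are undefined
    and set to NaN (diagonal stays 1), with a warning.
    """
    if X.p < 2:
        raise ValueError("need at least two samples")
    V = X.values.astype(float)
    constant = V.std(axis=0) == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        C = np.corrcoef(V, rowvar=False)
    if constant.any():
        bad = [X.sample_ids[j] for j in np.flatnonzero(constant)]
        warnings.warn(
            f"constant column(s) {bad}: correlation undefined, set to NaN",
            stacklevel=2,
        )
        C[constant, :] = np.nan
        C[:, constant] = np.nan
    np.fill_diagonal(C, 1.0)
    return CorrelationMatrix(list(X.sample_ids), C)


@dataclass
class Dendrogram:
    """Agglomeration trace: each merge is (members_a, members_b, height)
    with members as sorted tuples of sample ids; ``leaf_order`` is the
    deterministic left-to-right leaf sequence."""

    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]
    leaf_order: list[str]

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]


def cluster_samples(C: CorrelationMatrix, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering on distance 1 - r.

    Supports complete, average and single linkage. Ties are broken by
    merging the lexicographically smallest candidate pair (clusters compared
    by their sorted member tuples), which makes the trace deterministic.
    """
    if linkage not in ("complete", "average", "single"):
        raise ValueError(f"unknown linkage: {linkage!r}")
    if np.isnan(C.values).any():
        raise ValueError("correlation matrix contains NaN; drop constant columns first")
    D = 1.0 - C.values
    p = len(C.sample_ids)
    # clusters: ordered member index lists (order = leaf order within cluster)
    clusters: dict[int, list[int]] = {i: [i] for i in range(p)}
    key = {i: (C.sample_ids[i],) for i in range(p)}  # sorted member names

    def dist(a: int, b: int) -> float:
        block = D[np.ix_(clusters[a], clusters[b])]
        if linkage == "complete":
            return float(block.max())
        if linkage == "average":
            return float(block.mean())
        return float(block.min())

    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []
    next_id = p
    while len(clusters) > 1:
        ids = sorted(clusters)
        best: tuple[float, tuple[str, ...], tuple[str, ...], int, int] | None = None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                d = dist(a, b)
                ka, kb = sorted((key[a], key[b]))
                cand = (d, ka, kb, a, b)
                if best is None or cand < best:
                    best = cand
        d, ka, kb, a, b = best
        merges.append((ka, kb, d))
        # lexicographically smaller cluster goes left in the leaf order
        left, right = (a, b) if key[a] <= key[b] else (b, a)
        clusters[next_id] = clusters[left] + clusters[right]
        key[next_id] = tuple(sorted(key[a] + key[b]))
        del clusters[a], clusters[b], key[a], key[b]
        next_id += 1
    (root,) = clusters.values()
    return Dendrogram(merges, [C.sample_ids[i] for i in root])


def correlation_graph(
    C: CorrelationMatrix,
    threshold: float | None = None,
    edge_budget: int | None = None,
) -> Network:
    """Graph over samples from the marginal correlation matrix.

    Exactly one of ``threshold`` (keep r >= threshold) or ``edge_budget``
    (keep the top-k entries by r, all ties at the cut included) must be
    given. NaN entries (constant columns) never form edges; all samples are
    retained as nodes.
    """
    if (threshold is None) == (edge_budget is None):
        raise ValueError("give exactly one of threshold / edge_budget")
    ids = C.sample_ids
    p = len(ids)
    scored = [
        (C.values[i, j], i, j)
        for i in range(p)
        for j in range(i + 1, p)
        if not np.isnan(C.values[i, j])
    ]
    net = Network(nodes=set(ids))
    if threshold is not None:
        kept = [(i, j) for r, i, j in scored if r >= threshold]
    elif edge_budget >= len(scored):
        kept = [(i, j) for _, i, j in scored]
    else:
        scored.sort(key=lambda t: -t[0])
        cut = scored[edge_budget - 1][0] if edge_budget > 0 else np.inf
        kept = [(i, j) for r, i, j in scored if r >= cut]
    for i, j in kept:
        net.add_edge(ids[i], ids[j])
    return net


# ---------------------------------------------------------------------------
# Sparse triplet serialization


def write_matrix(X: BindingMatrix, path: str | Path) -> None:
    """Serialize as sparse triplets (row_index, col_index, 1) preceded by
    ``#segment`` and ``#sample`` header lines defining the axes."""
    with open(path, "w") as fh:
        for seg in X.segments:
            fh.write(f"#segment\t{seg.chrom}\t{seg.start}\t{seg.end}\n")
        for sid in X.sample_ids:
            fh.write(f"#sample\t{sid}\n")
        rows, cols = np.nonzero(X.values)
        for i, j in zip(rows, cols):
            fh.write(f"{i}\t{j}\t1\n")


def read_matrix(path: str | Path) -> BindingMatrix:
    segments: list[GenomicSegment] = []
    sample_ids: list[str] = []
    triplets: list[tuple[int, int]] = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "#segment":
                segments.append(GenomicSegment(fields[1], int(fields[2]), int(fields[3])))
            elif fields[0] == "#sample":
                sample_ids.append(fields[1])
            elif line.strip():
                triplets.append((int(fields[0]), int(fields[1])))
    X = np.zeros((len(segments), len(sample_ids)), dtype=np.int8)
    for i, j in triplets:
        X[i, j] = 1
    return BindingMatrix(segments, sample_ids, X)
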