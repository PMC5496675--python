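"""Synthetic multi-sample binding data from a planted TF interaction graph.

The generator is a latent Gaussian copula: a precision matrix with unit
diagonal and ``-coupling_strength`` at the planted edges (rescaled to
diagonal dominance when needed, to keep it positive definite) defines the
joint distribution of p latent variables; each of the n genomic segments
draws one latent vector, and column j is binarized at the quantile of its
marginal binding rate. Planted edges therefore carry elevated *partial*
correlation — exactly the signal the graphical-model estimators target —
while non-adjacent pairs are conditionally independent.

Cell-type block structure is modelled two ways: planted edges can be
biased to fall within blocks, and an extra within-block latent coupling
can be switched on. Samples are laid out one TF per sample by default.

Everything is seeded; the same seed reproduces bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg
from scipy.stats import norm

from .binding import BindingMatrix
from .io import (
    GenomicSegment,
    GoldStandard,
    SampleMetadata,
    canonical_pair,
    write_bed,
    write_metadata,
    write_string_table,
)
from .network import Network

__all__ = [
    "PlantedModel",
    "simulate_binding",
    "matrix_to_peaks",
    "make_gold_standard",
    "write_gold_standard",
    "truth_network",
]

IndexEdge = tuple[int, int]


@dataclass
class PlantedModel:
    """A planted TF-interaction model driving the synthetic binding matrix."""

    truth_edges: set[IndexEdge]  # pairs of column indices, i < j
    p_samples: int
    n_segments: int
    cell_types: list[str]  # one per sample
    coupling_strength: float = 0.3
    block_coupling: float = 0.0
    marginal_rate: float = 0.2
    genome_spec: list[tuple[str, int]] = field(default_factory=list)
    segment_length: int = 200
    gap: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.marginal_rate < 1:
            raise ValueError("marginal_rate must be in (0, 1)")
        if self.coupling_strength < 0:
            raise ValueError("coupling_strength must be >= 0")
        for i, j in self.truth_edges:
            if i == j:
                raise ValueError("truth graph must not contain self-loops")
            if not (0 <= i < self.p_samples and 0 <= j < self.p_samples):
                raise ValueError("truth edge index out of range")
        if len(self.cell_types) != self.p_samples:
            raise ValueError("need one cell type per sample")
        if not self.genome_spec:
            # default genome: one chromosome just large enough for the tiling
            span = self.n_segments * (self.segment_length + self.gap)
            self.genome_spec = [("chr1", span)]

    @classmethod
    def random(
        cls,
        p_samples: int,
        n_edges: int,
        n_segments: int,
        seed: int,
        n_blocks: int = 4,
        within_block_bias: float = 0.0,
        **kwargs,
    ) -> "PlantedModel":
        """Random planted graph with ``n_edges`` edges over ``p_samples``
        nodes split into ``n_blocks`` contiguous cell-type blocks.
        ``within_block_bias`` in [0, 1] is the fraction of edges forced to
        lie within blocks (the rest drawn uniformly)."""
        rng = np.random.default_rng(seed)
        block_size = -(-p_samples // n_blocks)
        cell_types = [f"celltype{i // block_size}" for i in range(p_samples)]
        all_pairs = [(i, j) for i in range(p_samples) for j in range(i + 1, p_samples)]
        within = [e for e in all_pairs if cell_types[e[0]] == cell_types[e[1]]]
        if n_edges > len(all_pairs):
            raise ValueError("more edges requested than pairs available")
        n_within = min(int(round(within_block_bias * n_edges)), len(within))
        chosen: set[IndexEdge] = set(
            tuple(within[k]) for k in rng.choice(len(within), n_within, replace=False)
        )
        remaining = [e for e in all_pairs if e not in chosen]
        extra = rng.choice(len(remaining), n_edges - len(chosen), replace=False)
        chosen.update(tuple(remaining[k]) for k in extra)
        return cls(
            truth_edges=chosen,
            p_samples=p_samples,
            n_segments=n_segments,
            cell_types=cell_types,
            seed=seed,
            **kwargs,
        )

    def sample_metadata(self, peak_dir: str | Path = "") -> list[SampleMetadata]:
        """One sample per TF: sample ids s00, s01, ...; TF names TF00, ..."""
        peak_dir = Path(peak_dir) if peak_dir else None
        records = []
        for i in range(self.p_samples):
            sid = f"s{i:02d}"
            path = str(peak_dir / f"{sid}.bed") if peak_dir else ""
            records.append(
                SampleMetadata(sid, f"TF{i:02d}", self.cell_types[i], path)
            )
        return records


def _tile_segments(model: PlantedModel) -> list[GenomicSegment]:
    """Deterministic disjoint tiling: row i -> a fixed interval, chromosomes
    filled in order."""
    step = model.segment_length + model.gap
    segments: list[GenomicSegment] = []
    chrom_iter = iter(model.genome_spec)
    chrom, length = next(chrom_iter)
    pos = 0
    for _ in range(model.n_segments):
        while pos + model.segment_length > length:
            try:
                chrom, length = next(chrom_iter)
            except StopIteration:
                raise ValueError(
                    "genome too small for the requested segment tiling"
                ) from None
            pos = 0
        segments.append(GenomicSegment(chrom, pos, pos + model.segment_length))
        pos += step
    return segments


def _latent_correlation(model: PlantedModel) -> np.ndarray:
    p = model.p_samples
    omega = np.eye(p)
    for i, j in model.truth_edges:
        omega[i, j] = omega[j, i] = -model.coupling_strength
    if model.block_coupling:
        for i in range(p):
            for j in range(i + 1, p):
                if model.cell_types[i] == model.cell_types[j]:
                    omega[i, j] -= model.block_coupling
                    omega[j, i] = omega[i, j]
    off = omega - np.eye(p)
    max_rowsum = np.abs(off).sum(axis=1).max()
    if max_rowsum >= 1.0:
        off *= 0.95 / max_rowsum  # restore strict diagonal dominance
        omega = np.eye(p) + off
    if linalg.eigvalsh(omega).min() <= 1e-10:
        raise ValueError(
            "latent precision matrix is not positive definite; "
            "lower coupling_strength or block_coupling"
        )
    sigma = linalg.inv(omega)
    d = np.sqrt(np.diag(sigma))
    return sigma / np.outer(d, d)


def simulate_binding(model: PlantedModel) -> tuple[BindingMatrix, set[IndexEdge]]:
    """Draw the n x p binary matrix from the planted copula model.

    Returns the matrix (rows are the deterministic segment tiling) and the
    planted edge set. Column j's expected mean is ``marginal_rate``.
    """
    corr = _latent_correlation(model)
    rng = np.random.default_rng(model.seed)
    L = linalg.cholesky(corr, lower=True)
    Z = rng.standard_normal((model.n_segments, model.p_samples)) @ L.T
    X = (Z <= norm.ppf(model.marginal_rate)).astype(np.int8)
    segments = _tile_segments(model)
    sample_ids = [m.sample_id for m in model.sample_metadata()]
    return BindingMatrix(segments, sample_ids, X), set(model.truth_edges)


def matrix_to_peaks(
    X: BindingMatrix,
    out_dir: str | Path,
    metadata: list[SampleMetadata],
) -> tuple[list[SampleMetadata], Path]:
    """Write one BED file per sample (row i's interval appears in sample
    j's file iff X[i, j] = 1) and the metadata TSV pointing at them.

    Rebuilding the matrix from the emitted files reproduces X exactly, up
    to dropping all-zero rows (segments no sample binds do not exist in
    peak space).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if len(metadata) != X.p:
        raise ValueError("need one metadata record per column")
    records = []
    for j, m in enumerate(metadata):
        path = out_dir / f"{m.sample_id}.bed"
        write_bed([X.segments[i] for i in np.flatnonzero(X.values[:, j])], path)
        records.append(SampleMetadata(m.sample_id, m.tf_name, m.cell_type, str(path)))
    meta_path = out_dir / "metadata.tsv"
    write_metadata(records, meta_path)
    return records, meta_path


def make_gold_standard(
    truth_pairs: set[tuple[str, str]],
    tf_universe: list[str],
    noise_fp: float = 0.0,
    noise_fn: float = 0.0,
    seed: int = 0,
    physical_fraction: float = 0.3,
) -> GoldStandard:
    """Gold standard = truth pairs minus seeded false-negative dropouts
    plus seeded spurious pairs, with high-confidence scores (>= 500).

    ``noise_fn`` is the per-true-pair dropout probability; ``noise_fp`` the
    per-non-true-pair inclusion probability over the TF universe. A seeded
    ``physical_fraction`` of retained pairs is flagged as physical.
    """
    if not (0 <= noise_fp < 1 and 0 <= noise_fn < 1):
        raise ValueError("noise rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    truth = {canonical_pair(*p) for p in truth_pairs}
    tfs = sorted(tf_universe)
    gold = GoldStandard()
    kept = [p for p in sorted(truth) if rng.random() >= noise_fn]
    spurious = [
        canonical_pair(tfs[i], tfs[j])
        for i in range(len(tfs))
        for j in range(i + 1, len(tfs))
        if canonical_pair(tfs[i], tfs[j]) not in truth and rng.random() < noise_fp
    ]
    for pair in kept + spurious:
        gold.scores[pair] = int(rng.integers(500, 1000))
        if rng.random() < physical_fraction:
            gold.physical.add(pair)
    return gold


def write_gold_standard(gold: GoldStandard, path: str | Path) -> None:
    """Emit the gold standard in the STRING flat-file dialect."""
    rows = [
        (a, b, gold.scores[(a, b)], "binding" if (a, b) in gold.physical else "")
        for a, b in sorted(gold.scores)
    ]
    write_string_table(rows, path)


def truth_network(model: PlantedModel) -> Network:
    """The planted graph as a sample-level Network (ground truth)."""
    meta = model.sample_metadata()
    net = Network(nodes={m.sample_id for m in meta})
    for i, j in model.truth_edges:
        net.add_edge(meta[i].sample_id, meta[j].sample_id)
    return net
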