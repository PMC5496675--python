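"""Model/results interface over the whole pipeline.

:class:`TFAssociationModel` wraps a binding matrix plus sample metadata;
``fit()`` runs the chosen direct-dependence estimators at a matched edge
budget (or per-algorithm thresholds), votes them into the consensus
network, and returns a :class:`TFAssociationResults` carrying the
dependence matrices, the per-algorithm and consensus networks, topology
diagnostics and — when a gold standard is supplied — the benchmark table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import analysis, inference
from .benchmark import ConfusionCounts, benchmark_network
from .binding import (
    BindingMatrix,
    CorrelationMatrix,
    build_matrix,
    correlation_graph,
    pearson_matrix,
)
from .consensus import annotate_with_gold, consensus_network, prune_isolated
from .io import GoldStandard, SampleMetadata
from .network import Network

__all__ = ["TFAssociationModel", "TFAssociationResults"]


@dataclass
class TFAssociationResults:
    """Fitted pipeline state: one dependence matrix and network per
    algorithm, the consensus network, and diagnostics."""

    model: "TFAssociationModel"
    dependence: dict[str, inference.DependenceMatrix]
    networks: dict[str, Network]
    consensus: Network
    min_support: int
    correlation: CorrelationMatrix
    params: dict = field(default_factory=dict)

    # -- diagnostics -----------------------------------------------------
    def degree_distribution(self) -> dict[int, int]:
        return analysis.degree_distribution(self.consensus)

    def clustering_by_degree(self) -> dict[int, float]:
        return analysis.clustering_by_degree(self.consensus)

    def mean_neighbour_degree(self) -> dict[int, float]:
        return analysis.mean_neighbour_degree(self.consensus)

    def first_neighbour_profiles(self):
        return analysis.first_neighbour_profile(self.consensus, self.model.metadata)

    def pruned_consensus(self) -> tuple[Network, int]:
        return prune_isolated(self.consensus)

    # -- benchmarking ----------------------------------------------------
    def benchmark(
        self, gold: GoldStandard | None = None
    ) -> list[tuple[str, ConfusionCounts]]:
        """Precision/recall of each per-algorithm network and the consensus
        against the gold standard, as (method, counts) rows."""
        gold = gold if gold is not None else self.model.gold
        if gold is None:
            raise ValueError("no gold standard supplied")
        rows = [
            (tag, benchmark_network(net, self.model.metadata, gold))
            for tag, net in self.networks.items()
        ]
        rows.append(
            ("consensus", benchmark_network(self.consensus, self.model.metadata, gold))
        )
        return rows

    def summary(self) -> str:
        """Human-readable fit summary."""
        pruned, removed = self.pruned_consensus()
        lines = [
            "TF association network fit",
            "==========================",
            f"samples (p): {self.model.X.p}    segments (n): {self.model.X.n}",
            f"algorithms: {', '.join(self.networks)}",
            f"consensus rule: edge in >= {self.min_support} algorithms",
            "",
            f"{'network':<14}{'edges':>8}",
        ]
        for tag, net in self.networks.items():
            lines.append(f"{tag:<14}{net.n_edges():>8}")
        lines.append(f"{'consensus':<14}{self.consensus.n_edges():>8}")
        lines.append("")
        lines.append(
            f"consensus connected nodes: {len(pruned.nodes)} "
            f"({removed} isolated removed)"
        )
        if self.model.gold is not None:
            lines += ["", f"{'method':<14}{'TP':>5}{'FP':>5}{'TN':>6}{'FN':>5}"
                          f"{'prec%':>8}{'recall%':>9}"]
            for method, c in self.benchmark():
                lines.append(
                    f"{method:<14}{c.tp:>5}{c.fp:>5}{c.tn:>6}{c.fn:>5}"
                    f"{c.precision_pct:>8.2f}{c.recall_pct:>9.2f}"
                )
        return "\n".join(lines)

    def plot_degree_distribution(self, ax=None):
        """Bar plot of the consensus degree histogram (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        hist = self.degree_distribution()
        ax.bar(list(hist), [hist[k] for k in hist])
        ax.set_xlabel("degree")
        ax.set_ylabel("number of nodes")
        return ax


class TFAssociationModel:
    """Consensus graphical-model analysis of a multi-sample binding matrix.

    Parameters
    ----------
    X : BindingMatrix
        Binary occupancy matrix (merged segments x samples).
    metadata : list of SampleMetadata
        One record per column of ``X`` (TF name, cell type).
    gold : GoldStandard, optional
        Protein-interaction gold standard used by ``summary()`` and
        ``TFAssociationResults.benchmark``.
    """

    def __init__(
        self,
        X: BindingMatrix,
        metadata: list[SampleMetadata],
        gold: GoldStandard | None = None,
    ):
        by_id = {m.sample_id: m for m in metadata}
        missing = [s for s in X.sample_ids if s not in by_id]
        if missing:
            raise ValueError(f"metadata missing for sample(s): {missing}")
        self.X = X
        self.metadata = [by_id[s] for s in X.sample_ids]
        self.gold = gold

    @classmethod
    def from_metadata(
        cls,
        metadata: list[SampleMetadata],
        gold: GoldStandard | None = None,
        row_subsample: int | None = None,
        seed: int | None = None,
    ) -> "TFAssociationModel":
        """Build the binding matrix from the per-sample peak files named in
        the metadata, then construct the model."""
        X = build_matrix(metadata, row_subsample=row_subsample, seed=seed)
        return cls(X, metadata, gold=gold)

    def correlation(self) -> CorrelationMatrix:
        return pearson_matrix(self.X)

    def correlation_graph(
        self, threshold: float | None = None, edge_budget: int | None = None
    ) -> Network:
        """Marginal-correlation baseline graph (no conditioning)."""
        return correlation_graph(self.correlation(), threshold, edge_budget)

    def fit(
        self,
        algorithms: tuple[str, ...] = inference.ALGORITHMS,
        edge_budget: int | None = None,
        thresholds: dict[str, float] | None = None,
        min_support: int = 3,
        seed: int = 0,
        shrinkage: float | str = "auto",
        rho: float = 0.05,
        n_resample: int = 50,
        steps_L: int = 5,
        alpha_randomization: float = 0.2,
        n_restarts: int = 3,
        annotate: bool = True,
    ) -> TFAssociationResults:
        """Run the chosen estimators and build the consensus network.

        Edge selection is by a single matched ``edge_budget`` per algorithm
        (so algorithms contribute comparable edge counts) or by explicit
        per-algorithm ``thresholds``; exactly one must be given. The
        Bayesian-network skeleton is inherently binary, so a budget keeps
        all its edges. ``min_support`` is the consensus vote (default: 3 of
        the 4 algorithms).
        """
        if (edge_budget is None) == (thresholds is None):
            raise ValueError("give exactly one of edge_budget / thresholds")
        unknown = set(algorithms) - set(inference.ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithm(s): {sorted(unknown)}")
        if not 1 <= min_support <= len(algorithms):
            raise ValueError(
                f"min_support must be in [1, {len(algorithms)}], got {min_support}"
            )
        dependence: dict[str, inference.DependenceMatrix] = {}
        for tag in algorithms:
            if tag == "ggm":
                M = inference.ggm_scores(self.X, shrinkage=shrinkage)
            elif tag == "glasso":
                M = inference.glasso_scores(self.X, rho=rho)
            elif tag == "regression":
                M = inference.regression_scores(
                    self.X,
                    n_resample=n_resample,
                    steps_L=steps_L,
                    alpha_randomization=alpha_randomization,
                    seed=seed,
                )
            else:
                M = inference.bn_skeleton(self.X, n_restarts=n_restarts, seed=seed)
            dependence[tag] = inference.symmetrize(M)

        networks = {
            tag: inference.select_edges(
                M,
                threshold=None if thresholds is None else thresholds[tag],
                edge_budget=edge_budget,
            )
            for tag, M in dependence.items()
        }
        cons = consensus_network(list(networks.values()), min_support)
        if annotate and self.gold is not None:
            annotate_with_gold(cons, self.gold, self.metadata)
        return TFAssociationResults(
            model=self,
            dependence=dependence,
            networks=networks,
            consensus=cons,
            min_support=min_support,
            correlation=self.correlation(),
            params={
                "edge_budget": edge_budget,
                "thresholds": thresholds,
                "seed": seed,
                "shrinkage": shrinkage,
                "rho": rho,
                "n_resample": n_resample,
                "steps_L": steps_L,
                "n_restarts": n_restarts,
            },
        )
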