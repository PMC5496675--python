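"""Direct-dependence estimators over the binary binding matrix.

Four independent routes to a p x p matrix of conditional-dependence scores
between samples, each consuming the 0/1 columns as numeric data:

* :func:`ggm_scores` — shrinkage partial correlation (Gaussian graphical
  model with an analytic ridge toward the identity correlation target);
* :func:`glasso_scores` / :func:`glasso_precision` — L1-penalized sparse
  precision matrix (graphical lasso), scores are the implied partial
  correlations;
* :func:`regression_scores` — stability selection over randomized LARS
  regressions of each sample on all others (selection frequencies);
* :func:`bn_skeleton` — undirected skeleton of a BIC-optimal Bayesian
  network found by greedy hill-climbing with random restarts.

Scores are turned into undirected networks by :func:`symmetrize` (average
the two directed influences) and :func:`select_edges` (threshold or edge
budget; the diagonal — self-influence — is always ignored).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lars_path

from .binding import BindingMatrix
from .network import Network

__all__ = [
    "DependenceMatrix",
    "ggm_scores",
    "glasso_precision",
    "glasso_scores",
    "regression_scores",
    "bn_skeleton",
    "symmetrize",
    "select_edges",
]

ALGORITHMS = ("ggm", "glasso", "regression", "bayes_net")


@dataclass
class DependenceMatrix:
    """p x p real-valued direct-dependence scores from one algorithm.

    The diagonal (self-influence) is ignored by all consumers. For
    asymmetric estimators (regression) entry (i, j) is the influence of
    sample i on sample j.
    """

    sample_ids: list[str]
    values: np.ndarray
    algorithm_tag: str
    symmetric_flag: bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = len(self.sample_ids)
        if self.values.shape != (p, p):
            raise ValueError("values must be p x p")
        if self.symmetric_flag and not np.allclose(
            self.values, self.values.T, equal_nan=True
        ):
            raise ValueError("symmetric_flag set but values are not symmetric")


def _standardize(X: BindingMatrix) -> np.ndarray:
    V = X.values.astype(float)
    mu = V.mean(axis=0)
    sd = V.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [X.sample_ids[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant column(s) {bad}: cannot standardize")
    return (V - mu) / sd


def _pcor_from_precision(omega: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return pcor


def shrinkage_intensity(Z: np.ndarray) -> float:
    """Analytic variance-minimizing shrinkage weight toward the identity
    correlation target: lambda* = sum Var(r_ij) / sum r_ij^2 over i != j,
    clipped to [0, 1]. Z must be column-standardized (ddof=1)."""
    n, p = Z.shape
    R = (Z.T @ Z) / (n - 1)
    # per-observation products w_kij; variance of the mean estimates Var(r)
    W_mean = R * (n - 1) / n
    sum_sq = np.zeros((p, p))
    for k in range(n):
        sum_sq += (np.outer(Z[k], Z[k]) - W_mean) ** 2
    var_r = n / (n - 1) ** 3 * sum_sq
    off = ~np.eye(p, dtype=bool)
    denom = (R[off] ** 2).sum()
    if denom == 0:
        return 1.0
    return float(np.clip(var_r[off].sum() / denom, 0.0, 1.0))


def ggm_scores(
    X: BindingMatrix, shrinkage: float | str = "auto"
) -> DependenceMatrix:
    """Shrinkage partial correlations: every pair conditioned on all
    remaining samples.

    The sample correlation matrix R is shrunk toward the identity,
    R* = (1 - lambda) R + lambda I, with lambda chosen by the analytic
    variance-minimizing formula when ``shrinkage="auto"``; the partial
    correlation is read off the inverse, pcor_ij = -Omega_ij /
    sqrt(Omega_ii Omega_jj).
    """
    if X.p < 3:
        raise ValueError("partial correlation needs at least 3 samples")
    Z = _standardize(X)
    n = Z.shape[0]
    R = (Z.T @ Z) / (n - 1)
    np.fill_diagonal(R, 1.0)
    lam = shrinkage_intensity(Z) if shrinkage == "auto" else float(shrinkage)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("shrinkage intensity must be in [0, 1]")
    R_shrunk = (1.0 - lam) * R + lam * np.eye(X.p)
    try:
        omega = linalg.inv(R_shrunk)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "correlation matrix is singular; use shrinkage > 0"
        ) from exc
    return DependenceMatrix(
        list(X.sample_ids), _pcor_from_precision(omega), "ggm", True
    )


def glasso_precision(
    S: np.ndarray,
    rho: float,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Sparse precision matrix by the graphical lasso.

    Maximizes log det(Theta) - trace(S Theta) - rho * ||Theta||_1 (penalty
    on off-diagonal entries) by block coordinate descent over lasso
    subproblems. Returns ``(precision, partial_correlations)``. rho = 0
    reduces to the plain matrix inverse.
    """
    S = np.asarray(S, dtype=float)
    if rho < 0:
        raise ValueError("rho must be >= 0")
    if not np.allclose(S, S.T):
        raise ValueError("S must be symmetric")
    if rho == 0:
        try:
            theta = linalg.inv(S)
        except linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("S is singular; use rho > 0") from exc
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                _, theta = _sk_graphical_lasso(S, alpha=rho, tol=tol, max_iter=max_iter)
            except ConvergenceWarning as exc:
                raise RuntimeError(
                    f"graphical lasso did not converge in {max_iter} iterations: {exc}"
                ) from exc
        theta = (theta + theta.T) / 2.0
    return theta, _pcor_from_precision(theta)


def glasso_scores(
    X: BindingMatrix, rho: float, tol: float = 1e-4, max_iter: int = 200
) -> DependenceMatrix:
    """Graphical-lasso dependence scores from the sample correlation matrix
    of the standardized 0/1 columns."""
    Z = _standardize(X)
    n = Z.shape[0]
    R = (Z.T @ Z) / (n - 1)
    np.fill_diagonal(R, 1.0)
    _, pcor = glasso_precision(R, rho, tol=tol, max_iter=max_iter)
    return DependenceMatrix(list(X.sample_ids), pcor, "glasso", True)


def regression_scores(
    X: BindingMatrix,
    n_resample: int = 100,
    steps_L: int = 5,
    alpha_randomization: float = 0.2,
    seed: int = 0,
) -> DependenceMatrix:
    """Stability-selection regression scores (randomized-LARS frequencies).

    For each target sample t, ``n_resample`` LARS fits of column t on all
    other columns are run, each on a seeded half-sample of rows with
    predictor columns rescaled by random weights drawn uniformly from
    [alpha_randomization, 1]. The score of predictor j on target t is the
    fraction of fits in which j enters within the first ``steps_L`` path
    steps. Scores are asymmetric and lie in [0, 1]; the diagonal is 0.
    """
    p = X.p
    if steps_L >= p:
        raise ValueError(f"steps_L ({steps_L}) must be < number of samples ({p})")
    if n_resample < 2 or n_resample % 2 != 0:
        raise ValueError("n_resample must be an even integer >= 2")
    Z = _standardize(X)
    n = Z.shape[0]
    half = n // 2
    scores = np.zeros((p, p))
    root = np.random.SeedSequence(seed)
    for t, child in enumerate(root.spawn(p)):
        rng = np.random.default_rng(child)
        others = np.array([j for j in range(p) if j != t])
        counts = np.zeros(p - 1)
        for _ in range(n_resample):
            rows = rng.choice(n, size=half, replace=False)
            weights = rng.uniform(alpha_randomization, 1.0, size=p - 1)
            A = Z[np.ix_(rows, others)] * weights
            y = Z[rows, t]
            _, active, _ = lars_path(A, y, method="lar", max_iter=steps_L)
            counts[active[:steps_L]] += 1
        scores[others, t] = counts / n_resample
    return DependenceMatrix(list(X.sample_ids), scores, "regression", False)


# ---------------------------------------------------------------------------
# Bayesian network skeleton (hill-climbing, BIC)


class _BicCache:
    """Decomposable BIC for binary variables: local score of node v given a
    parent set is the multinomial log-likelihood minus 0.5 log(n) * 2^|Pa|
    (one free Bernoulli parameter per parent configuration)."""

    def __init__(self, X: np.ndarray):
        self.X = X
        self.n = X.shape[0]
        self._cache: dict[tuple[int, frozenset[int]], float] = {}

    def local(self, v: int, parents: frozenset[int]) -> float:
        key = (v, parents)
        if key in self._cache:
            return self._cache[key]
        pa = sorted(parents)
        if pa:
            code = self.X[:, pa] @ (1 << np.arange(len(pa)))
        else:
            code = np.zeros(self.n, dtype=int)
        joint = np.bincount(code * 2 + self.X[:, v], minlength=(1 << len(pa)) * 2)
        joint = joint.reshape(-1, 2)
        row_tot = joint.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(joint > 0, joint * np.log(joint / row_tot), 0.0).sum()
        score = float(ll) - 0.5 * np.log(self.n) * (1 << len(pa))
        self._cache[key] = score
        return score


def _has_path(parents: dict[int, set[int]], src: int, dst: int, p: int) -> bool:
    """True iff a directed path src -> ... -> dst exists (arcs u -> v mean
    u in parents[v])."""
    children: dict[int, list[int]] = {i: [] for i in range(p)}
    for v, pa in parents.items():
        for u in pa:
            children[u].append(v)
    stack, seen = [src], {src}
    while stack:
        node = stack.pop()
        if node == dst:
            return True
        for c in children[node]:
            if c not in seen:
                seen.add(c)
                stack.append(c)
    return False


def _hill_climb(
    cache: _BicCache,
    p: int,
    start_parents: dict[int, set[int]],
    max_parents: int,
) -> tuple[dict[int, set[int]], float]:
    parents = {v: set(pa) for v, pa in start_parents.items()}
    local = {v: cache.local(v, frozenset(parents[v])) for v in range(p)}
    while True:
        best_gain = 0.0
        best_move = None
        for u in range(p):
            for v in range(p):
                if u == v:
                    continue
                if u in parents[v]:
                    # delete u -> v
                    gain = cache.local(v, frozenset(parents[v] - {u})) - local[v]
                    if gain > best_gain + 1e-12:
                        best_gain, best_move = gain, ("del", u, v)
                    # reverse u -> v (becomes v -> u)
                    if len(parents[u]) < max_parents:
                        tmp = {w: set(pa) for w, pa in parents.items()}
                        tmp[v].discard(u)
                        if not _has_path(tmp, u, v, p):
                            gain = (
                                cache.local(v, frozenset(parents[v] - {u}))
                                - local[v]
                                + cache.local(u, frozenset(parents[u] | {v}))
                                - local[u]
                            )
                            if gain > best_gain + 1e-12:
                                best_gain, best_move = gain, ("rev", u, v)
                elif len(parents[v]) < max_parents and not _has_path(parents, v, u, p):
                    # add u -> v (acyclic iff no existing path v -> u)
                    gain = cache.local(v, frozenset(parents[v] | {u})) - local[v]
                    if gain > best_gain + 1e-12:
                        best_gain, best_move = gain, ("add", u, v)
        if best_move is None:
            break
        op, u, v = best_move
        if op == "add":
            parents[v].add(u)
        elif op == "del":
            parents[v].discard(u)
        else:
            parents[v].discard(u)
            parents[u].add(v)
            local[u] = cache.local(u, frozenset(parents[u]))
        local[v] = cache.local(v, frozenset(parents[v]))
    return parents, sum(local.values())


def bn_skeleton(
    X: BindingMatrix,
    n_restarts: int = 5,
    seed: int = 0,
    max_parents: int = 5,
    node_cap: int = 60,
) -> DependenceMatrix:
    """Skeleton (directions discarded) of the best BIC-scoring Bayesian
    network found by greedy hill-climbing with seeded random restarts.

    The climb starts from the empty DAG and additionally from
    ``n_restarts`` random DAGs (a random topological order with sparse
    random arcs); single-arc addition, deletion and reversal moves are
    applied greedily and the BIC score never decreases along a climb.
    Returns a binary symmetric DependenceMatrix (1 = arc in the best DAG,
    either direction).
    """
    V = X.values
    if not np.isin(V, (0, 1)).all():
        raise ValueError("Bayesian-network learning requires binary entries")
    p = X.p
    if p > node_cap:
        raise ValueError(
            f"p = {p} exceeds the hill-climbing cap ({node_cap}); "
            "raise node_cap explicitly or subsample columns"
        )
    cache = _BicCache(V.astype(int))
    rng = np.random.default_rng(seed)
    best_parents, best_score = _hill_climb(
        cache, p, {v: set() for v in range(p)}, max_parents
    )
    for _ in range(n_restarts):
        order = rng.permutation(p)
        start: dict[int, set[int]] = {v: set() for v in range(p)}
        for i in range(p):
            for j in range(i + 1, p):
                if rng.random() < 0.15 and len(start[order[j]]) < max_parents:
                    start[order[j]].add(int(order[i]))
        parents, score = _hill_climb(cache, p, start, max_parents)
        if score > best_score:
            best_parents, best_score = parents, score
    A = np.zeros((p, p))
    for v, pa in best_parents.items():
        for u in pa:
            A[u, v] = A[v, u] = 1.0
    return DependenceMatrix(list(X.sample_ids), A, "bayes_net", True)


# ---------------------------------------------------------------------------


def symmetrize(M: DependenceMatrix) -> DependenceMatrix:
    """Average the two directed influences: out[i, j] = (M[i, j] +
    M[j, i]) / 2. Symmetric input is returned unchanged (fixed point)."""
    if M.symmetric_flag:
        return M
    out = (M.values + M.values.T) / 2.0
    np.fill_diagonal(out, np.diag(M.values))
    return DependenceMatrix(list(M.sample_ids), out, M.algorithm_tag, True)


def select_edges(
    M: DependenceMatrix,
    threshold: float | None = None,
    edge_budget: int | None = None,
) -> Network:
    """Threshold a symmetric dependence matrix into an undirected network.

    Exactly one of ``threshold`` (keep |score| >= threshold) or
    ``edge_budget`` (keep the top-k pairs by |score|, ties at the cut
    included) must be given. The diagonal never yields edges: a TF's
    influence on itself is not modelled. All samples remain as nodes.
    """
    if not M.symmetric_flag:
        raise ValueError("symmetrize the matrix before edge selection")
    if (threshold is None) == (edge_budget is None):
        raise ValueError("give exactly one of threshold / edge_budget")
    ids = M.sample_ids
    p = len(ids)
    scored = [
        (abs(M.values[i, j]), i, j) for i in range(p) for j in range(i + 1, p)
    ]
    net = Network(nodes=set(ids))
    if threshold is not None:
        kept = [(i, j) for s, i, j in scored if s >= threshold]
    elif edge_budget >= len(scored):
        kept = [(i, j) for s, i, j in scored if s > 0]
    else:
        scored.sort(key=lambda t: -t[0])
        cut = scored[edge_budget - 1][0] if edge_budget > 0 else np.inf
        kept = [(i, j) for s, i, j in scored if s >= cut and s > 0]
    for i, j in kept:
        net.add_edge(ids[i], ids[j])
    return net


# ---------------------------------------------------------------------------
# Serialization: dense TSV with sample ids on both axes; the algorithm tag
# and symmetry flag ride along in comment headers.


def write_dependence(M: DependenceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#algorithm\t{M.algorithm_tag}\n")
        fh.write(f"#symmetric\t{int(M.symmetric_flag)}\n")
        fh.write("\t" + "\t".join(M.sample_ids) + "\n")
        for sid, row in zip(M.sample_ids, M.values):
            fh.write(sid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_dependence(path) -> DependenceMatrix:
    with open(path) as fh:
        tag = fh.readline().rstrip("\n").split("\t")[1]
        symmetric = bool(int(fh.readline().rstrip("\n").split("\t")[1]))
        ids = fh.readline().rstrip("\n").split("\t")[1:]
        values = np.loadtxt(fh, usecols=range(1, len(ids) + 1), ndmin=2)
    return DependenceMatrix(ids, values, tag, symmetric)
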