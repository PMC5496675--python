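# Methods

## Binding matrix construction

Peaks are BED-style 0-based half-open intervals. Two peaks overlap iff
their half-open intersection is non-empty, i.e. they share at least one
base; bookended intervals (`end == start`) do **not** overlap and are kept
separate by the merge. Rows of the binding matrix are the transitive
closure of this overlap relation over the union of all samples' peaks,
sorted by (chromosome, start); entry (i, j) is 1 iff sample j has at least
one peak intersecting row i, so every row has at least one 1 by
construction. Row/segment lookup uses binary search over the sorted
disjoint row intervals, and tests cross-check it against an interval-tree
recount and a per-base painting oracle.

For very large segment counts a seeded uniform row subsample can be taken
(`build_matrix(..., row_subsample, seed)`); all estimators here operate on
columns, and subsampling rows trades variance for tractability without
changing the estimands.

On 0/1 columns the Pearson correlation equals the phi coefficient of the
pair's 2×2 contingency table. All-zero (or constant) columns leave the
correlation undefined: those entries are set to NaN with a warning, the
column is kept in the matrix, and correlation-based graphs simply never
draw edges to it.

## Hierarchical clustering

Agglomerative clustering on the distance 1 − r with complete linkage by
default (average and single are available). Because downstream outputs
should not depend on dictionary order, ties between candidate merges are
broken deterministically: among equal-distance pairs the lexicographically
smallest pair of clusters (compared by their sorted member-id tuples) is
merged, and the lexicographically smaller cluster is placed on the left of
the leaf order. The naive O(p³) agglomeration is fine at the sample counts
this package targets (hundreds of columns); merge heights are verified
against `scipy.cluster.hierarchy` on tie-free instances.

## Direct-dependence estimators

All four estimators consume the binary columns as numeric data after
column standardization — statistically impure for Gaussian-likelihood
methods, but deliberate: the binary matrix *is* the object of interest,
the latent signal survives binarization (attenuated by roughly the factor
φ(z)²/(q(1−q)) for binding rate q), and the estimators are used as edge
*rankers*, not as calibrated likelihood models.

**Shrinkage GGM.** The sample correlation matrix R is shrunk toward the
identity, R* = (1−λ)R + λI, with λ chosen by the analytic
variance-minimising formula λ* = Σ<sub>i≠j</sub> Var̂(r<sub>ij</sub>) /
Σ<sub>i≠j</sub> r<sub>ij</sub>², clipped to [0,1]; partial correlations
are read off the inverse. With λ = 0 this reduces to classical partial
correlation, and the tests require exact (1e−8) agreement with the
residual-regression definition on small instances. Edge significance is by
ranking only; no local-fdr step is applied — ranking is all the consensus
vote needs, and it avoids a null-model fit on small p.

**Graphical lasso.** The L1-penalised precision matrix (off-diagonal
penalty ρ, default 0.05) is obtained from scikit-learn's block
coordinate-descent solver; dependence scores are the implied partial
correlations. The ρ = 0 limit must equal the plain matrix inverse and the
two-variable problem must match its closed-form soft-threshold solution —
both are asserted in tests, keeping the third-party solver honest.
Convergence tolerance 1e−4 on the dual gap (the solver's natural scale),
200 iterations max, with non-convergence raised as an error.

**Stability-selection regression.** For each target column, LARS paths of
the target on all other columns are fitted on `n_resample` seeded
half-samples of the rows, with each predictor rescaled by a random weight
in [α, 1] (α = 0.2). The score of predictor → target is the fraction of
fits in which the predictor enters within the first L path steps (L = 5
default). Plain selection frequency is used rather than area-based
scoring: it is the simplest variant, and the frequency scale [0,1] makes
budgets comparable across targets. Scores are asymmetric; the consensus
pipeline averages the two directions.

**Bayesian-network skeleton.** Greedy hill-climbing over DAGs
(add/delete/reverse single arcs) maximising the decomposable BIC for
binary variables — local score = multinomial log-likelihood −
½ log(n)·2^|parents| — with seeded random restarts, a parent-count cap
(default 5) and a node-count guard (default 60). BIC was preferred over
BDe because it has no prior hyperparameter and an exhaustive-search oracle
(all 543 DAGs on 4 nodes) keeps the climber honest in tests; directions
are discarded to yield the skeleton. The skeleton is already binary, so an
edge budget keeps all its edges; the other three algorithms are trimmed to
their top-budget edges (ties at the cut included).

## Consensus and benchmarking

Per-algorithm networks are selected at one matched edge budget so that the
vote is not dominated by whichever algorithm is most liberal; the
consensus keeps edges found by ≥ `min_support` algorithms (default 3 of
4). The node universe is carried through consensus unchanged and isolated
nodes are pruned only on export, with the removed count reported.

For benchmarking, the sample-level graph is collapsed to TF-name pairs
over the universe of gold-covered TFs that were actually assayed:
{A, B} is predicted iff some edge joins a sample of A to a sample of B,
same-TF edges are discarded, and the confusion matrix is taken over all
C(u,2) unordered pairs, so tp+fp+tn+fn is a universe constant and tp+fn
depends only on the gold standard. Gold positives are the pairs with
combined score ≥ 500 (the high-confidence cut); the "binding" action
keyword marks physical interactions but only annotates — it does not
redefine positives. Percentages are computed exactly and printed to two
decimals; published operating points are compared within ±0.01 percentage
points since printed tables mix rounding and truncation at 2 dp.

## Synthetic data

The generator is a latent Gaussian copula. A precision matrix with unit
diagonal and −`coupling_strength` (default 0.3) at planted edges defines
the latent law; if the off-diagonal row sums reach 1 the off-diagonals are
rescaled to strict diagonal dominance (keeping positive definiteness, at
the cost of diluting the per-edge coupling for high-degree nodes). Each of
the n segments draws one latent vector and each column is binarized at the
quantile of its marginal binding rate (default 0.2, a realistic per-sample
occupancy for a pooled peak union). Planted edges thus carry elevated
*partial* correlation and non-adjacent pairs are conditionally
independent — precisely the estimand of the graphical-model estimators,
which makes edge recovery a well-posed test. Cell-type structure enters
either as a within-block bias on where planted edges fall or as an extra
within-block latent coupling.

Rows are tiled deterministically onto the synthetic genome (length 200,
gap 100 by default), so synthetic rows never overlap; interval merging is
exercised by dedicated fixtures with random overlapping intervals instead.
Matrix → peaks → matrix round-trips exactly, up to dropping all-zero rows
(segments nobody binds do not exist in peak space).

What the generator does **not** emulate: peak-height signal, genomic
sequence or motif content, non-stationary peak density, mappability
artefacts, and the heavy cross-sample dependence of real peak callers.
Passing recovery tests therefore demonstrates correctness of the
estimators and plumbing on data whose dependence structure is known, not
performance on real compendia.

## Default study sizes

Recovery experiments use a planted 20-sample / 30-edge graph at n = 2000
segments with coupling 0.3 and one sample per TF; per-algorithm budgets
are matched to the planted edge count (30) and the consensus vote is 3 of
4. The stability-selection stage uses 50 resamples and L = 5 at this size
(100 resamples and L = 2 in the focused planted-signal unit test). The
"end-to-end identity" scenario derives a noiseless gold standard from the
planted graph, so the planted network must benchmark at precision =
recall = 100% — a check of the whole file-level plumbing rather than of
estimator power.

## Known limitations

* Gaussian estimators on binary data are rank-consistent but their scores
  are attenuated; absolute score thresholds are therefore less portable
  than edge budgets, which is why budgets are the default selection rule.
* Hill-climbing BN learning is a local search; restarts mitigate but do
  not eliminate local optima, and runtime grows quickly past ~60 nodes
  (the guard cap).
* The consensus is count-based (an edge is in or out per algorithm);
  score-weighted consensus is deliberately out of scope.
* Mapping sample TF names to gold-standard protein identifiers is the
  caller's responsibility (`read_string_table(..., name_map=...)`);
  no orthology inference is attempted.
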