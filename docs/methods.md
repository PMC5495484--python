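# Methods

`influmax` implements an influence-maximization workflow for directed gene
regulatory networks: candidate regulator→target edges are weighted by
time-lagged transfer entropy with permutation significance, source sets are
scored by the network cover of an absorbing random-walk diffusion, and a
hypercube min-max ant system searches for maximally influential node sets.
This note records the models, their assumptions, the parameter choices, and
the limits of what the synthetic test bed demonstrates.

## Transfer-entropy edge weighting

**Model.** For regulator series *x* and target series *y*, the transfer
entropy at lag *k* is the conditional mutual information

T<sub>x→y</sub>(k) = Σ P(y<sub>t</sub>, y<sub>t−1</sub>, x<sub>t−k</sub>)
log [ P(y<sub>t</sub>, y<sub>t−1</sub>, x<sub>t−k</sub>) P(y<sub>t−1</sub>)
/ ( P(y<sub>t−1</sub>, x<sub>t−k</sub>) P(y<sub>t</sub>, y<sub>t−1</sub>) ) ],

i.e. the information the regulator's lagged past carries about the target
beyond the target's own immediate past. It is directional and model-free,
but assumes stationarity over the sampled window and a first-order target
memory (only y<sub>t−1</sub> is conditioned on).

**Estimator.** Each series is mean-centered and scaled by its maximum
absolute centered value into [−1, 1]. The joint distribution of the triples
(y<sub>t</sub>, y<sub>t−1</sub>, x<sub>t−k</sub>) is estimated with a
Gaussian *product* kernel whose per-axis bandwidth follows Scott's rule,
h<sub>i</sub> = σ̂<sub>i</sub> m<sup>−1/7</sup> (m = number of triples,
σ̂ with one delta degree of freedom), evaluated on a regular grid over
[−1, 1]³ and renormalized to sum to one. The default grid is 10 points per
axis (10³ total): finer grids change TE values only marginally while
slowing the permutation loop linearly. Marginals are obtained by grid
summation, 0·log(0/·) terms contribute zero, and the plug-in TE of a valid
joint is nonnegative up to round-off. The product kernel (rather than a
full-covariance kernel) makes the estimator separable: under permutation
of the regulator only the x-axis kernel matrix changes, so the null
distribution costs one small einsum per permutation instead of a full
density fit. Tests pin the grid values against a naive per-point
kernel-sum oracle at 1e−12.

**Significance.** The regulator series is cut into consecutive blocks of 3
time points (a trailing remainder stays as a short block) and the block
order is shuffled, which destroys cross-series coupling while retaining
local autocorrelation. One set of `n_perm` permutations is drawn per edge
and reused across lags. Per lag, the robust distance
(T<sub>obs</sub> − median(T<sub>perm</sub>)) / MAD(T<sub>perm</sub>)
standardizes the observed TE against its null; if the MAD is zero the
1.4826-scaled standard deviation substitutes, and if that is also zero the
distance is 0. The lag maximizing the robust distance is chosen (ties go
to the smallest lag, favoring faster regulation), and the empirical
p-value at that lag uses the add-one estimator
(#{T<sub>perm</sub> ≥ T<sub>obs</sub>} + 1)/(n_perm + 1), whose smallest
attainable value is exactly 1/(n_perm + 1). An edge is accepted only at
that minimum — no permutation reached the observed TE.

Because the lag is selected to maximize evidence over six candidate lags,
the acceptance rule is mildly anti-conservative relative to a single-lag
test: the null acceptance rate is bounded by roughly
|lags|/(n_perm + 1) rather than 1/(n_perm + 1). At the default 50,000
permutations this is ~1.2e−4; at the test-scale 999 permutations the
measured null rate is ~0.4%. Calibration at a single fixed lag is exact
and is tested separately.

**Defaults.** Lags 0–5 (matching the Spearman lag range; 0–25 min at
5-minute sampling), base-2 logarithms (bits; affects absolute values, not
rankings or p-values), block length 3, `n_perm` 50,000 (tests use
hundreds–thousands). The lagged Spearman alternative pairs x[:n−k] with
y[k:] per lag, keeps the signed maximum rho by default (an absolute-value
option serves repressive interactions), and filters with
Benjamini–Hochberg FDR at 1% using the analytic Spearman p-value at the
best lag.

## Diffusion scoring

The weighted digraph is row-normalized into transition probabilities
p<sub>ij</sub> = w<sub>ij</sub>/Σ<sub>j</sub>w<sub>ij</sub>; nodes without
out-edges keep an all-zero row, so walks stop at dead ends (no teleport).
Given sources S and transit nodes T = V∖S, the expected-visit matrix
solves H = P<sub>ST</sub> + H P<sub>TT</sub>, computed per source from the
transposed system (I − P<sub>TT</sub>)′h′ = p′ with LGMRES to residual
1e−10, falling back to the truncated recurrence when the iterative solver
does not converge. Tiny negative round-off is clipped to zero. If T
contains a closed recurrent class reachable from S with no leakage, H
diverges; the solver then raises an error carrying the residual rather
than returning a finite pretense.

A transit node is covered when its visit mass exceeds θ = 1e−4 (the
published threshold, exposed as a parameter). The default aggregation
sums visit mass over sources before thresholding — the cover on nodes in
T — and a literal per-(source, node) double-sum variant is retained as an
option; the unique cover never exceeds the double sum. The summed
out-edge weight of the sources breaks ties between sets with identical
covers, preferring sources that transmit more information. Both omega
(cover on T) and omega + |S| (cover including sources) are reported,
since published cover percentages are ambiguous about counting sources.

The optimizer's scorer exploits that the unique cover needs only the
*total* visit mass per node: v = colsum(P<sub>ST</sub>) + v P<sub>TT</sub>
is a single dense solve per candidate set instead of |S| sparse solves,
memoized by source set. Tests cross-check this fast path against the full
expected-visits route.

## Ant optimization

The search for argmax<sub>|S|=K</sub> Ω follows the hypercube min-max ant
system. Ants build candidate sets by sampling nodes without replacement
with probability ∝ u<sub>i</sub><sup>α</sup> r<sub>i</sub><sup>β</sup>
(u: summed out-edge weight, r: pheromone in [0, 1], α = β = 1),
renormalizing after each draw; if all remaining probabilities vanish the
remaining slots fill uniformly. Each set is refined by stochastic hill
climbing: since flipping a single membership bit would break |S| = K, a
move swaps one member for one non-member and is kept only on strict
lexicographic (omega, tiebreak) improvement. Three solutions are tracked
(iteration-best, restart-best, overall-best) and the pheromone moves
toward their weighted membership average, r ← r + d(r_avg − r) with
learning rate d = 0.2 (the published "evaporation rate"; the update rule
has no separate decay). The fraction weights shift in stages
(1,0,0) → (2/3,1/3,0) → (1/3,2/3,0) → (0,1/3,2/3) as the pheromone
convergence factor passes 0.4/0.6/0.8 — the paper-standard progression
from exploration toward the restart- and overall-best solutions; stage
thresholds and the 0.5 pheromone initialization are this package's
choices, as no published values exist. A restart ends when the pheromone
sum changes by less than 1e−4 (with a 10,000-iteration guard); the best
solution over all restarts is returned.

Presets: slow — 8 restarts, 64 ants, 32 local steps (the two published
values, 16 and 32, disagree; 32 is the default and both are shipped);
fast — 4 restarts, 16 ants, 8 local steps. The influence ranking runs the
optimizer for each K in a range (default 1–50, three repetitions) and
counts how often each node appears in a solution.

## Topology comparison

Thirteen standard centralities (degree, strength, betweenness, alpha/Katz,
eigenvector, authority, hub, 2-step ego size, subgraph centrality,
1−constraint, PageRank, closeness, articulation flag) are delegated to
networkx; shortest-path metrics read distance = 1/weight so strong edges
are short, eigenvector and HITS scores are computed from deterministic
dense eigendecompositions, and undirected-only metrics (subgraph,
articulation, constraint) use the undirected projection. Top-k sets
(default k = 24; binary metrics return all flagged nodes) are compared by
Jaccard index, and directed reachability between two sets is the fraction
of the target set reachable from the origin set after removing the sets'
overlap from both sides — undefined (reported as missing) when nothing
remains.

## Synthetic test bed

`simulate_lagged_expression` emulates short uniformly sampled time courses
(default 41 points, mirroring a 5-minute cell-cycle series): unregulated
genes are independent unit Gaussians; a planted target is
coupling·f(x<sub>t−lag</sub>) plus N(0, noise_sd²) observation noise
(linear or tanh-saturating f; defaults lag 3, coupling 0.9, noise 0.1 —
a strong coupling regime in which ~40-point series carry detectable
signal). An optional shared damped sinusoid mimics decaying cell-cycle
synchrony for stress-testing the permutation null. What it does *not*
model: measurement-specific noise structure, multi-regulator targets,
feedback loops, nonstationary amplitudes; passing recovery tests shows
estimator correctness under the stated generative model, not performance
on real expression data.

`random_weighted_digraph` draws m distinct directed edges with uniform
weights; the `n_regulators` option restricts out-edges to a small
regulator subset, reproducing the sink-heavy structure of real regulatory
networks (inferred networks here run ~1.5 edges per node, and most genes
regulate nothing). Sink-heavy graphs always leak walk mass, keeping
expected visits finite — diffusion validation uses 30 nodes, 60 edges,
10 regulators. `planted_influencer_graph` gives each of its root nodes a
disjoint strong-weighted out-tree plus negligible-weight decoy edges
between internal nodes of different trees, so the root set is provably
the unique cover optimum for K = #roots (verified by exhaustive
enumeration in tests); decoy transition probabilities sit orders of
magnitude below θ.

## Numerical and scale choices

- Grid 10³, permutations at test scale 99–999 (default 50,000), solver
  residual 1e−10, cover threshold θ = 1e−4, TE oracle agreement pinned at
  1e−12, solver/oracle agreement at 1e−8.
- Validation problem sizes: 100 × 30-node graphs for solver equivalence;
  100 replicates for lag/direction recovery (n_perm = 500); 500 null
  pairs for type-I control (n_perm = 999); 51 15-node instances for
  optimality against exhaustive enumeration; 20 planted-influencer seeds
  for ranking recovery; one fixed 60-node planted hierarchy (4 roots with
  depth-3 binary trees plus decoys) for fast/slow preset agreement.
  Preset agreement is evaluated on a structured network deliberately:
  selection counts are only reproducible across optimizer settings when
  the network has a genuine influence hierarchy — on structureless graphs
  the slots beyond the few useful sources are filled by interchangeable
  nodes, and their counts record arbitrary tie-breaking rather than
  anything about the optimizer.
  `scripts/acceptance.py` re-measures the same quantities at somewhat
  smaller replicate counts and prints them as JSON.
- Determinism: every stochastic stage consumes an explicit
  `numpy.random.Generator`; per-edge and per-run streams are spawned from
  the master seed, so outputs are byte-identical across reruns and
  independent of evaluation order.

## Known limitations

- The KDE plug-in TE is biased at 41 time points; the permutation test
  calibrates acceptance but absolute TE values should be compared only
  within a run.
- Lag selection by robust distance inflates the per-edge false-positive
  rate by about the number of candidate lags; at the default 50,000
  permutations this is negligible, at small test scales it is not.
- The diffusion model ignores edge signs (activation vs repression);
  repressive edges contribute visit mass like activating ones.
- Ant optimization carries no optimality guarantee; agreement with
  exhaustive enumeration is demonstrated only at small instance sizes.
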