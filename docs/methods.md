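# Methods

## Model and criterion

The package partitions the N nodes of a feature-rich network into K
non-overlapping communities by least-squares approximation of both data
matrices at once.  With `s_ik` the 0/1 membership indicators, the feature
table and the link matrix are modelled as

    y_iv = Σ_k c_kv s_ik + f_iv          p_ij = Σ_k λ_kj s_ik + e_ij

with residuals `f`, `e` to be made small.  The second equation is the
*nonsummability* link model: each community gets a full vector `λ_k` of
column-wise link intensities rather than one scalar, so a node's network
row `p_i` enters the algebra exactly like a feature vector and the two
matrices can share one K-means-style machinery.  Because each node belongs
to exactly one community, the summed squared residuals collapse to

    F(S, C, Λ) = Σ_k Σ_{i∈S_k} [ ρ·d_e(y_i, c_k) + ξ·d_e(p_i, λ_k) ],

with `d_e` the squared Euclidean distance, and alternating minimization
applies: the Minimum Distance rule is optimal for fixed centers, and
within-cluster means are optimal for a fixed partition (first-order
conditions).  Hence the squared-Euclidean variant has a non-increasing
criterion trajectory and terminates at a partition fixed point; this is
asserted by the test suite on every fit.

### Metric variants

* **Manhattan** substitutes `d_m(f,g) = Σ_t |f_t − g_t|` into the same
  loop.  Centers remain within-cluster *means* by default, reproducing the
  plain algorithm with the metric swapped, even though medians are the true
  minimizer of the Manhattan criterion; `median_centers=True` exposes the
  theoretically consistent choice.  With mean centers the criterion is not
  guaranteed monotone, so the loop also watches for partition cycles.
* **Cosine** uses `d_c(f,g) = 1 − cos(f,g)`.  For unit vectors
  `d_e = 2·d_c`, so the variant presumes unit-normed data rows — the
  pipeline row-norms `Y` and `P` when this metric is selected — and
  re-norms the mean centers after every update.  Re-norming breaks
  least-squares optimality, so convergence is again protected by cycle
  detection on the partition sequence in addition to the fixed-point stop
  and `max_iter`.  Rows that are exactly zero are assigned cosine distance
  1 to every center (cos = 0), a bounded, symmetric convention.

### Seeding, restarts, ties, degeneracies

Seeding is farthest-point (MaxMin): the first seed is a uniformly random
node, each further seed the unchosen node maximizing the sum of combined
distances to all seeds so far.  `n_init` restarts are run with fresh first
seeds and the run with the smallest final criterion is kept; benchmark runs
use `n_init=10`, single CLI runs default to 1.  All ties (assignment,
seeding, restart selection) break to the smallest index, making every run a
deterministic function of the RNG seed.  If a cluster empties during
assignment it is reseeded from the node farthest (in combined distance)
from the emptied cluster's center, excluding nodes that are sole members of
their cluster; the moved node then sits at distance 0 from its new center,
so descent is preserved and the output always has K nonempty clusters.
Fitting K clusters to fewer than K distinct node profiles is an error.
Convergence is partition equality — no criterion-epsilon stop — with
`max_iter` defaulting to 100.  The network diagonal participates in the
network distances like any other column; nothing in the model excludes it.

## Standardization

Features: z-scoring (population standard deviation, divide-by-N — the
K-means data-recovery convention) or range scaling (center by mean, divide
by max − min); both reject constant columns by name.  Categorical columns
are one-hot encoded *before* scaling, so the dummies are treated as
ordinary numeric columns; the encoding itself is this package's documented
choice for feeding categorical labels to a numeric criterion.  Network:
the modularity shift `p_ij − p_i+ p_+j / p_++` (output has all row and
column sums zero) or the scale shift `p_ij − mean(P)` (output grand mean
zero).  The default selection, `network_std="auto"`, uses the modularity
shift for purely quantitative data and the scale shift whenever any
categorical feature is present, the pairing that behaves best across the
benchmark grid; every choice can be overridden per run.  Edge lists are
symmetrized by default (last duplicate wins; summing available behind a
flag), and a `directed` flag preserves asymmetric input as read.

## Synthetic benchmark generator

The generator emulates the planted-partition study design and is the
package's test bed:

* community sizes: random compositions of N (uniform cut points, rejection
  until every size ≥ `min_size`); `min_size=30` keeps edge probabilities
  meaningful in every block;
* network: within-community edges Bernoulli(p), between Bernoulli(q),
  symmetric, zero diagonal;
* quantitative features: per-community Gaussians, center components
  Uniform(−α, α), diagonal variances Uniform(0.05, 0.1); smaller α means
  heavier intermix;
* categorical features: per-feature category count L_v drawn from
  {2, …, L_max}; planted centers drawn so that no two coincide on more than
  half the features (capped rejection); an entry copies its community
  center with probability ε, else is uniform over the feature's categories,
  so the per-entry match probability is ε + (1 − ε)/L_v and *larger ε means
  more homogeneous communities* — oriented this way so that the benchmark
  grid's third parameter is monotone in difficulty for categorical data
  exactly as α is for quantitative data (0.9 easier than 0.7);
* noise: ⌈V/2⌉ appended columns of uniform noise over the global [min, max]
  of the original quantitative data ("half the data replicated as noise",
  read as appending, not replacing);
* mixed data: equal numbers of quantitative and categorical features.

Canonical problem sizes: small N=200, K=5, 5 features per type, L_max=10;
medium N=1000, K=10, 10 features per type, L_max=15.  The community count
and feature counts are this package's defaults, fixed once; benchmark
summaries inherit whatever sensitivity remains to that choice.  What the generator does *not* emulate
about real data: degree heterogeneity and overlapping communities (pure
planted-partition blocks), weighted or asymmetric links, correlated or
non-Gaussian features, and missing values.  Passing benchmarks therefore
demonstrate correct recovery under the stated generative model, not
performance on real networks.

## Evaluation

ARI is the Hubert–Arabie adjusted Rand index computed from the contingency
table with exact integer pair counts; it is 1 iff the partitions coincide
and 0 against the trivial one-cluster partition, and the tests verify exact
agreement with an O(N²) pair-counting oracle and with an independent
reference implementation.  NMI uses arithmetic-mean normalization
(MI / ((H(S)+H(T))/2)); when both entropies vanish the partitions are both
trivial and 1.0 is returned.

## Benchmark harness and problem sizes

`kefrin benchmark` and `scripts/acceptance.py` run the 8-setting grid
p ∈ {0.9, 0.7} × q ∈ {0.3, 0.6} × third ∈ {0.9, 0.7}, where the third
parameter is α for quantitative and ε for categorical features (both for
mixed), with 10 generated datasets per cell and `n_init=10` per fit —
seconds per small cell and well under a minute per medium cell on one CPU.
Reported numbers are per-cell means (with standard deviations) of the ARI
against the planted partition, plus the grand mean over the eight settings.

## Known limitations

* K, ρ and ξ are user inputs; no automatic selection.
* Dense matrices throughout — appropriate up to a few thousand nodes.
* The cosine and mean-center Manhattan variants carry no monotonicity
  guarantee; cycle detection makes termination, not optimality, certain.
* One-hot + z-scoring gives rare categories large weights; this mirrors the
  plain-numeric treatment of dummies and is not a calibrated encoding.
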