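# kefrin

Community detection in **feature-rich (node-attributed) networks** by an
extension of batch K-means.  A community here is a set of nodes that is both
densely interconnected and homogeneous in its node features; the package
finds a hard partition that is good in *both* senses at once, which matters
wherever graphs come with measurements at the nodes — gene or protein
interaction networks with expression profiles, social networks with actor
attributes, co-purchase graphs with product descriptors.

## The model

Given a feature table `Y` (N×V) and a link matrix `P` (N×N), each community
`S_k` carries a **two-fold center**: a feature-space vector `c_k` and a
network-space vector of per-column link intensities `λ_k` (so rows of `P`
are treated exactly like feature vectors).  The data are least-squares
approximated as `Y ≈ S C`, `P ≈ S Λ`, and the combined criterion

    F(S, C, Λ) = Σ_k Σ_{i∈S_k} [ ρ·d(y_i, c_k) + ξ·d(p_i, λ_k) ]

is minimized by alternating, K-means style, between (1) the *Minimum
Distance rule* — assign each node to the community minimizing its combined
distance — and (2) recomputing the centers as within-cluster means.  The
distance `d` is squared Euclidean (the exact least-squares case, with
guaranteed monotone descent), Manhattan, or cosine (`1 − cos`; data rows
and centers are unit-normed, a high-dimension-friendly variant).  `ρ` and
`ξ` weigh the two data sources and default to 1.  Seeding is
farthest-point (MaxMin): a random first node, then repeatedly the node
maximizing the summed combined distance to the seeds already chosen.

Standardization operators matching the method: z-scoring or range scaling
for features (categorical columns are one-hot encoded first), and for the
network either the **modularity shift** `p_ij − p_i+ p_+j / p_++`
(subtracting the degree-product null expectation) or the **scale shift**
`p_ij − mean(P)`.  A planted-partition benchmark generator (network blocks
with within/between edge probabilities p/q, Gaussian quantitative features
with center spread α, categorical features with homogeneity ε, optional
uniform noise features) and exact ARI/NMI partition metrics are included.

## Worked example

```python
from kefrin import GeneratorConfig, generate, KefrinModel

dataset = generate(GeneratorConfig(n=200, k=5, p=0.9, q=0.3, alpha=0.9, rng_seed=7),
                   flavor="quantitative")
model = KefrinModel(dataset.features, dataset.network, k=5, metric="manhattan")
results = model.fit(n_init=10, seed=1)
print(results.summary())
print(results.score(dataset.truth))
```

prints

```
Extended K-means (feature-rich network) results
===============================================
nodes:             200
features (design): 5
communities (K):   5
metric:            manhattan
rho / xi:          1 / 1
criterion:         14697
iterations:        2 (converged: True)
restarts:          10
cluster sizes:     30, 75, 34, 30, 31
{'ari': 1.0, 'nmi': 1.0}
```

i.e. on a 200-node network of 5 planted communities (within-edge
probability 0.9, between 0.3, well-spread Gaussian features) the Manhattan
variant converges in two alternation rounds and recovers the planted
partition exactly (ARI = NMI = 1).

The same pipeline is available from the shell:

```sh
kefrin generate --flavor quantitative --size small --seed 7 --output data/
kefrin run --features data/features.csv --network data/network.tsv \
           --k 5 --metric manhattan --n-init 10 --seed 1 --output pred.tsv
kefrin evaluate --truth data/truth.tsv --pred pred.tsv
kefrin benchmark --flavor mixed --size small --replicates 10 --seed 3
```

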