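# Methods

## Model

The package scores genes on a weighted undirected interaction network
`G = (V, E)`, weights `w(g, n) ∈ (0, 1]` interpreted as interaction
confidences. For a per-gene value vector `v` the neighbor score is

    NEST(g) = Σ_{n ∈ N(g)} w(g, n) · v(n)  =  (W v)(g),

with `W` the symmetric connectivity matrix (zero diagonal). Two modeling
commitments follow from the biology the score exploits — essential genes
sit in dense complexes whose members are coherently active:

* **The gene's own value is excluded.** The score measures the
  neighborhood, not the gene, which keeps it usable as a covariate next
  to the gene's own expression in the confounder analysis.
* **Values are centered across samples** (per-gene mean subtraction)
  before scoring expression-like matrices, so 0 is the neutral value and
  a missing neighbor (contributing 0) is equivalent to an average one.
  Screen fold changes and differential regulatory potentials are already
  signed quantities and are scored as supplied.

The matrix formulation is implemented as a sparse CSR product and is
required (and tested) to agree with a naive per-gene neighbor loop to
1e-9 relative tolerance.

### Missing values

Two policies, numerically identical: `zero` treats missing neighbor
values as 0; `exclude` skips them but records per-gene counts of observed
neighbors so downstream users can filter poorly covered genes. Genes with
values but no network node are reported with a missing score rather than
0 so rankings can exclude them explicitly; isolated nodes score 0.

## Randomization null and permutation test

The null model preserves each gene's degree and nothing else: **stub
rewiring** of the unweighted network. Each edge contributes a stub to
both endpoints; stubs are paired uniformly at random; pairings creating a
self-loop or duplicate edge are rejected. Rejection can strand the
process with only illegal pairings, so:

* a pass is declared stalled when random retries exceed 10 × the number
  of remaining stub pairs without placing an edge; the implementation
  then searches the remaining stubs exhaustively, so a pass terminates
  only when genuinely no legal pairing exists;
* a terminated pass is accepted if ≥ `min_reconnect_fraction` (default
  0.98) of the original edges were placed, discarding leftover stubs;
  otherwise it restarts from scratch, up to `max_restarts` (100) times
  before raising an error that reports the best fraction achieved.

Rewired edges all carry weight 1 — the null randomizes the unweighted
topology — while the observed score keeps the true confidences. This
asymmetry is deliberate: the test asks whether a gene's neighborhood is
hotter than degree alone explains, and the degree sequence is the
property being conditioned on.

Per gene, over `n_random` rewired networks (replicate *i* seeded
`seed + i`, so results are order-independent and reproducible):

    Z = (real − mean_random) / sd_random,

`sd` the sample standard deviation (divisor n−1). A per-replicate
standard error (sd/√n) would shrink with `n_random` and let Z grow
arbitrarily with more replicates, so the spread itself is used. The
empirical p is the tail fraction in the direction of Z (`≥ real` when
Z ≥ 0, `≤ real` otherwise), floored at `1/n_random` with an explicit
upper-bound flag when the tail count is zero. When `sd_random = 0`
(e.g. all values zero) Z is reported as NaN and p as 1.

### Calibration of the empirical p — a deliberate caveat

Because the reported p selects the tail *after* looking at the sign of Z,
it is a directional p conditioned on the observed direction. Under an
exchangeable null (observed network itself a configuration-model draw,
i.i.d. values) the selected tail is approximately Uniform(0, 1/2]: its
KS distance from Uniform(0,1) is ≈ 0.5 by construction, at any
`n_random`. Uniformity should therefore be checked on the **fixed-tail**
empirical p (the `n_ge`/`n_le` counts are exposed on the result for this
purpose); the fixed upper-tail p passes KS < 0.1 at 200 genes × 200
randomizations in the test suite. One acceptance test asserts uniformity
of the reported p as a documentation of this property and fails by
design; doubling the selected tail would restore nominal uniformity but
is intentionally not done, keeping the reported p the plain "fraction of
random networks at least as extreme in the observed direction".

## Evaluation harness

* **AUC** is computed by the Mann–Whitney pair identity (rank-sum form),
  exact under ties (ties count 1/2), and verified against brute-force
  pair counting; curve coordinates come from the standard threshold
  sweep. Default negatives are an equal-sized bottom-ranked gene set;
  arbitrary negative sets are accepted.
* **Rank-sum Z** uses the normal approximation with tie correction and a
  0.5 continuity correction; positive Z ⇔ positives rank higher; it
  matches scipy's asymptotic two-sided p to machine precision.
* **Logistic confounder analysis** is a statsmodels maximum-likelihood
  fit of essentiality on named covariates (typically neighbor score,
  degree, own value), reporting coefficient, standard error,
  Logit Z = coef/stderr and Wald p, plus fitted probabilities for
  combined-predictor comparisons. Constant covariates and non-converged
  (separated) fits are rejected rather than silently regularized.
* **Noise degradation**: Gaussian noise with sd = level × sd(values) is
  added to the values; per level and replicate the AUC of the noisy raw
  ranking and of the neighbor score recomputed from the noisy values are
  compared to each predictor's own noise-free baseline via the reduction
  ratio (AUC₀ − AUC)/AUC₀. Defaults: levels {0.25, 0.5, 1, 2, 4}, 20
  replicates, replicate seeds drawn from one master generator.

## Regulatory potential

RP(g) = Σ over peaks with |midpoint − TSS| ≤ window of 2^(−d/d₀), with
half-decay d₀ = 10 kb and window 100 kb by default, both configurable.
The exponential half-decay preserves the "distance-weighted sum of
binding sites" semantics transparently; no claim is made of reproducing
any particular upstream RP implementation's constants. The peak anchor is
the interval midpoint (standard for summit-free BED input); strand never
affects the distance. RP is additive over peak subsets, monotone
non-increasing in distance, and linear in peak multiplicity — all tested.

## Synthetic benchmark

The generator plants dense modules ("complexes") in a sparse background:
same-module pairs get an edge with probability `p_in = 0.6` at confidence
0.9, all other pairs `p_bg = 0.01` at confidence 0.2 (high-confidence
complex edges over low-confidence background, STRING-like). Defaults: 500
genes, 10 modules of 10, 3 active. Values are `effect_size·1[active] +
N(0, noise_sd²)` per sample with effect 1 and noise 1 — generated
pre-centered (background mean 0) so scoring is exercised independently of
the centering step. The screen variant signs the effect by module
(alternating protective +1 / sensitizing −1). Module membership is
independent of degree by construction, giving the logistic confounder
test a clean degree null. Everything is a pure function of the spec,
including the seed.

What the generator does **not** emulate: heavy-tailed degree
distributions, overlapping complexes, correlated noise between
neighbors, or batch structure. Passing benchmarks here show the
machinery recovers planted signal under idealized modular structure, not
that real screens will reach comparable AUCs.

### Benchmark problem sizes

Tests and the acceptance script run at 500 genes / ~1,500 edges with
100–200 random networks and 20 degradation replicates — sizes chosen so
the full pipeline (including 100+ rewirings) completes in seconds while
keeping binomial sampling checks within 3σ bounds. Reference analyses at
biobank scale would raise `n_random` to 1000 (the configuration default).

## Known limitations

* The degradation comparison (network score more noise-robust than raw
  values) is evaluated with the two directional truth sets of the
  synthetic screen as positives/negatives. Against *diffuse* negatives
  (all background genes) the network score starts so close to AUC 1 that
  the ceiling distorts reduction ratios: its discriminability degrades
  more slowly than the raw values' at every noise level, yet its AUC
  reduction ratio can exceed theirs at high noise. Reduction ratios are
  only comparable between predictors with comparable baselines.
* The reported empirical p is directional (see calibration caveat).
* Stub rewiring discards up to 2% of edges; degree preservation is exact
  only up to those discards (in practice retention is ~100% on the
  benchmark network).
* `exclude` vs `zero` missing policies are numerically identical by
  design; there is no imputation.
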