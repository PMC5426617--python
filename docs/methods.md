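# Methods

This note documents the statistical procedures implemented in
`cooccurnet`, the defaults and why they were chosen, what the synthetic
benchmark does and does not emulate, and the package's known limitations.

## Class-1 null models: from a sparse matrix to a network

### Tie-breaking noise for Spearman on sparse data

Spearman's ρ on an OTU × location abundance matrix is computed between row
rank vectors. When most entries are zero (sparse surveys run ~85% zeros)
the average-rank convention for ties makes shared absences look like
strong positive association, and the distribution of pairwise scores
becomes a pathological mixture of atoms. The correction samples total
orders consistent with the data's partial order: every entry receives
i.i.d. uniform noise on (−b, b) with

* Δ — the minimum absolute difference between distinct matrix values,
  computed once on the raw matrix;
* b = Δ/1000.

Because b < Δ/2, no strictly ordered pair of entries can reverse, while
tied entries receive a uniformly random relative order. After the noise
step rows are tie-free and ρ is evaluated in closed form,
ρ = 1 − 6Σrᵢ²/(L(L²−1)) (equivalently, Pearson on ranks; both paths agree
to 1e−12 and are cross-checked in the tests). Note the leading "1 −" —
an occasionally mistyped term that the identity-ordering requirement
ρ(x, x) = 1 pins down unambiguously.

Each Monte-Carlo replicate draws its noise from an independent child
generator derived from the master seed via `numpy.random.SeedSequence`
spawn keys, so replicate r is reproducible in isolation and whole runs
are byte-identical given a seed.

### Permutation null and threshold choice

An element-wise random permutation of the (noise-added) matrix preserves
the abundance value distribution exactly while destroying all between-OTU
dependence. Sweeping the threshold τ over a grid (default 0 … 1, step
0.01) and recording the fraction of all N OTUs in the largest connected
component produces, for the permuted treatment, a sigmoidal collapse. The
*noise transition* is the smallest grid value whose permuted-treatment
fraction drops below a cutoff (default 1%): below it the network would
admit edges that an all-noise matrix also produces. The working threshold
defaults to the transition plus a margin of 0.05 ("slightly above"), and a
`statistics_sweep` utility tabulates every statistic across the whole
grid, because conclusions should be shown to be robust to the threshold
within the admissible range.

Two caveats are worth stating. First, the 1%-of-N rule is scale
dependent: for N ≲ 200 OTUs, 1% of N is fewer than two nodes, so the rule
effectively demands an edge-free permuted network and pushes the
transition to the maximum null |ρ| (≈0.40 for N = 150, L = 100); for
N in the thousands it tolerates small spurious components and sits much
lower (≈0.30 at N ≈ 1600, L ≈ 150). Second, the transition is estimated
from a single permutation draw, so it inherits that draw's extreme-value
noise of roughly one grid step.

### Thresholding, ensembles, consensus

Edges connect pairs with |ρ| strictly greater than τ; the sign of ρ is
kept as an edge attribute (strong mutual exclusion also forms an edge),
and degree-zero nodes are removed by convention, so the network has
n ≤ N nodes. Repeating noise → correlation → threshold (default 2000
replicates) gives an ensemble of equally plausible networks. The
consensus network keeps edges present in at least a support fraction
(default 90%, inclusive at the boundary) of replicates; consensus nodes
are simply the endpoints of retained edges, and each edge records its
support, mean |ρ|, and majority sign.

## Class-2 null models: testing network structure

Given a derived network, two random-graph ensembles control for
connectivity:

* **Erdős–Rényi.** p is matched to the mean degree. Two published
  parameterizations of the same target exist — p = ⟨k⟩/n (spreading 2m
  stubs over the n² adjacency cells; 0.0388 for the reference case
  n = 300, ⟨k⟩ = 11.64) and p = ⟨k⟩/(n−1) (the exact G(n, p) moment
  match). The package defaults to the first, which the reference
  distributions were generated with, and exposes the second behind
  `recipe="pairs"`; they differ by (n−1)/n.
* **Chung-Lu.** Pair (i, j) is an edge with probability
  min(1, kᵢkⱼ/2m) for an expected degree sequence kᵢ taken from a
  representative replicate (the one whose edge count is the ensemble
  median). The cap keeps probabilities valid for heavy-tailed sequences;
  capped pairs are counted and reported.

Both samplers emit simple graphs by construction and drop singletons
before statistics, mirroring the derived-network convention (this
slightly inflates the null mean degree — a real phenomenon of the
convention, reproduced rather than hidden; `keep_singletons=True`
restores the inclusive variant).

Null distributions are empirical: each statistic is evaluated on every
draw, draws where it is undefined are skipped and counted, and the
observed value receives the add-one p-value
p = (1 + #{null at least as extreme})/(1 + replicates) plus a z-score.
Two-sided p doubles the smaller tail.

### Network statistics

* Average degree ⟨k⟩ = 2m/n on the singleton-free node set.
* Mean path length l = Σᵢ≠ⱼ dᵢⱼ/(n(n−1)) and diameter max dᵢⱼ, computed
  on the largest connected component (the mean is undefined across
  components); the component count is reported alongside.
* Global clustering (transitivity) via the matrix recipe R = Q·Q,
  U = strict upper triangle of R, c = Σ(U∘Q)/ΣU — the proportion of open
  triangles closed by a third edge. The recipe is verified exactly
  against brute-force triple enumeration in the tests.
* Maximum modularity by greedy agglomeration (CNM), delegated to
  python-igraph's `community_fastgreedy` — the standard, deterministic
  implementation of the algorithm — returning the maximum of
  Q = Σ_g(e_gg − a_g²) along the merge path and its partition.
  Modularity is computed on the whole graph including small components,
  which matters at high thresholds where disconnected cliques carry most
  of the score. A reproducibility remark: on ER reference ensembles
  (n = 300, p = 0.0388) this implementation — and equally R igraph's
  `cluster_fast_greedy` — concentrates tightly around Q ≈ 0.25; some
  published baselines for the same ensemble report lower values,
  consistent with weaker greedy optimizers, so modularity comparisons
  across implementations deserve caution.
* Fixed-partition modularity scores an externally given labelling (e.g.
  phyla) with the same formula and no optimization.
* The mixing table gives the fraction of edges joining each pair of label
  categories: within-category edges count 1/m on the diagonal,
  cross-category edges ½/m in each symmetric cell, so the table is
  symmetric and all cells sum to 1; "All" marginals are row/column sums.
  Unlabelled nodes fall in an explicit "Other" category.

### OTU classification

Generalists occupy strictly more than 80 locations; specialists occupy
strictly fewer than 10 locations with mean abundance over occupied sites
strictly above 18. Occupancy means strictly positive abundance. The
boundary semantics are deliberately strict (e.g. a row total of exactly 5
survives the "fewer than 5" filter). Reported OTU totals for the
reference soil survey differ by one between sources (4,087 vs 4,088
pre-filter); the operations here are defined by the rules, not the
counts.

## The synthetic benchmark

### Count model

Counts are gamma-Poisson (negative binomial): OTU i at location ℓ has
mean c·exp(aᵢ + σ_e·zᵢℓ) with

* aᵢ ~ Normal(0, σ_a), σ_a = 1.5 — spreads base abundances so occupancy
  is heavy-tailed across OTUs, from near-absent taxa to near-generalists;
* zᵢℓ ~ Normal(0, 1) — per-location environmental response, scaled by
  σ_e = 4 (strong gradients on the log scale, the main source of the
  heavy upper tail of counts);
* NB shape 5 — mild per-entry overdispersion; the marginal tail heaviness
  comes from the lognormal rate mixing, not from entry-level noise, and a
  much smaller shape would inject independent presence/absence noise that
  masks any planted structure;
* the global scale c is solved by root-finding so the *expected* zero
  fraction equals the target sparsity (default 0.85); the achievable
  target is floored at 1 − 10⁻⁴ zeros removed, i.e. `target_sparsity=0`
  means "essentially dense". Realized sparsity lands within ±0.03 of the
  target or generation fails loudly.

Zeros arise from the count model itself (small rates). An independent
Bernoulli zero mask was considered and rejected: it decouples the
presence patterns of planted partners, which is precisely the signal a
rank correlation on sparse data has to work with.

### Planted couplings

A planted pair (or triad) with strength s ∈ [0, 1] shares an
environmental factor on an s-fraction of locations: on those sites every
member's latent response *is* the common factor (negated for a
mutual-exclusion partner, sign −), elsewhere responses are independent.
The latent correlation between partners is therefore exactly s, and —
the important property at high sparsity — partners agree on *which*
sites they occupy, not merely on the ordering within jointly occupied
sites. A Gaussian blend with the same nominal correlation couples
presence sets only quadratically; at 85% zeros even s = 1 then stays
below any admissible threshold, because the tie-break correction
deliberately randomizes the ranks of shared absences. Expected |ρ|
increases monotonically with s, reaching ≈1 on dense matrices at s = 1.

Planted OTUs must be prevalent enough for the coupling to be observable:
a coupling confined to a handful of occupied sites cannot constrain
ranks. Their base abundances are therefore raised (never lowered) by
root-finding, jointly with the global scale, until each planted OTU's
expected occupancy reaches `planted_occupancy` (default 0.33 — prevalent
but well short of generalist; 60 planted OTUs at 0.33 fit inside the
occupancy budget N·0.15 that 85% sparsity imposes). A planted load that
cannot fit raises an error up front. Triads attach three members to one
factor, so recovered triads close triangles — letting the pipeline's
headline signal, elevated clustering, be exercised against ground truth.

`recovery_metrics` scores any inferred network against the planted edge
set (precision, recall, F1, with explicit `None` sentinels for undefined
ratios). The benchmark regime of the regression tests — 30 disjoint
planted pairs at s = 0.9 in a 150 × 100 matrix at 85% sparsity, threshold
at the noise transition + 0.05 — attains mean F1 ≥ 0.8 over 20 seeds on a
single-replicate network.

### What the generator does not emulate

Real surveys are compositional (sequencing depth varies by site; counts
are closed), taxa covary through shared phylogeny and through more than
one environmental axis, and spatial autocorrelation links nearby sites.
None of this is modelled; compositional effects in particular are out of
scope. Passing recovery tests therefore demonstrates that the pipeline
detects monotone co-occurrence under realistic sparsity and tail
behaviour — not that it is robust to compositional artefacts.

## Numerical choices and degenerate inputs

* Constant matrices have no Δ and are rejected; constant rows (possible
  only in the uncorrected average-rank treatment) get ρ = 0 against all
  partners.
* The correlation diagonal is fixed at 1 and excluded from thresholding
  and distributions.
* Strictness: edges require |ρ| > τ (strict); consensus support uses ≥
  (inclusive); the min-total filter keeps row sums ≥ the threshold.
* Empty or near-empty derived networks short-circuit the null-model and
  significance stages of the pipeline (recorded in the manifest) instead
  of fabricating degenerate comparisons; statistics undefined on a graph
  are reported as missing, never as 0.
* Tie-breaks in the greedy merge sequence follow igraph's internal
  deterministic order; results are stable for a fixed graph.
* All Monte-Carlo loops use spawned child generators keyed by replicate
  index; no global random state is touched.

## Limitations

* The noise-transition rule's scale dependence (above) makes auto
  thresholds conservative for small OTU panels.
* Greedy agglomeration is a heuristic lower bound on the true maximum
  modularity and is implementation-sensitive across ecosystems (see the
  reproducibility remark); within this package it is deterministic.
* p-values from 2000-replicate nulls resolve to ≥ 1/2001; far-tail
  significance is reported at that floor together with the z-score.
* The pipeline's Chung-Lu parameterization uses one representative
  replicate's degree sequence; ensembles whose replicates differ wildly
  in density would deserve per-replicate nulls instead.
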