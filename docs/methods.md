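# Methods

## Problem setting

A single-gene knockout screen measures genome-wide expression (log2
fold changes against a pooled wild-type reference, M-values) once per
deletion strain, usually with a small number of biological replicates and
a block of wild-type replicates. `prcnet` addresses two questions on such
data:

1. **How much of a directed transcriptional network is identifiable at
   all**, given that only a fraction *q* of genes has been knocked out —
   the network-inferability theory (`prcnet.networks`).
2. **How to estimate the identifiable link strengths without bias from
   measurement noise**, and how to use replicate variability to discard
   hopeless candidates — partial response coefficients with the noise
   cutoff (`prcnet.prc`, `prcnet.noise`, `prcnet.pipeline`,
   `prcnet.model`).

## Linear stationary model

Observed log-expression is modelled as `0 = A (y − y_ref) + B u`,
`y_obs = y + ε`, with `A_ij` the direct effect of gene *j* on gene *i*
(`A_ii := −1` by convention, so strengths are relative to the restoring
force), `u` the persistent perturbation forces, and
`ε ~ N(0, σ² D)`, `D = diag(r_1 … r_N)`, `r_i = σ_i²/σ²` known from
replicates. The observation covariance is
`C = A⁻¹ B Bᵀ A⁻ᵀ + σ² D`. Whitening by `D^{-1/2}` and maximising the
Gaussian likelihood gives an eigenproblem of the whitened sample
covariance: with ascending eigenvalues Λ and eigenvectors U,

* `σ̂²` = mean of the N₀ smallest eigenvalues, where N₀ is the number of
  unperturbed observables in the current data subset (known from the
  experimental design, not estimated);
* signal singular values `sqrt(max(Λ_k − σ̂², 0))` for k > N₀ (negative
  differences clipped, with a warning);
* when the covariance is rank-deficient (fewer independent profiles than
  genes) it is shrunk as `(1−ε)S + εI`, ε = 0.05 by default. The shrink
  changes eigenvalues, not eigenvectors, so it affects the noise-level
  estimate but none of the link-strength estimators.

## Link-strength estimators

**Case N₀ = 1** (the target *i* is the only unperturbed observable after
its own perturbation experiments are removed): the smallest-eigenvalue
eigenvector *u* of the whitened covariance is the stationarity constraint
of row *i*, and

```
A_ij / A_ii = (u_j / √r_j) / (u_i / √r_i).
```

Measurement noise shifts eigenvalues but not eigenvectors, which makes the
estimator asymptotically unbiased to noise — the property that separates
partial response coefficients from partial correlations. When all genes
are perturbed one by one, cycling the target through the network recovers
the complete relative interaction matrix (verified to 1e−6 on noise-free
data in the test suite).

**Case N₀ > 1**: the strength of a candidate link j → i is only bracketed.

* *Minimum*: gene *j* is removed from the observables while its
  perturbation experiments stay in the sample set. The reduced row
  coefficients `A'_il/A'_ii` (from the null-space eigenvectors of the
  reduced whitened covariance) explain *i* by every route avoiding *j*;
  the residual `y_i + Σ_l (A'_il/A'_ii) y_l` is paired with `y_j` in a
  two-node errors-in-variables problem with effective residual noise
  ratio `r_i + Σ_l (A'_il/A'_ii)² r_l`. The component ordering puts the
  residual of the *target* first, the source second, so an absent link
  yields a ratio near zero rather than a divergence.
* *Maximum*: the same two-node problem on `(y_i, y_j)` directly — the
  total effect of *j* on *i* through all routes.

A link is classified **non-inferable** when the bootstrap interval of
(max − min) excludes zero while the interval of the minimum includes zero:
alternative routes could fully explain the target.

### Null-space dimension of the reduced system

The design count of unperturbed observables is only the generic upper
bound on the reduced system's no-signal subspace: exact alternative-route
constraints make perturbation-response directions degenerate, and that
degeneracy *is* the inferability signal. The implementation therefore
reads the realised null dimension off the spectrum (eigenvalues within a
factor 8 of the smallest, or below 1e−9 of the largest) and caps it at
the design count. Two guard rails matter in practice: a reduced system
with a single observable has nothing to explain the target with (the
residual is `y_i` itself), and when the null directions carry no weight
on the target the same fallback applies. Both situations occur routinely
at high knockout coverage.

### Wild-type replicates in the covariance

The subnetwork sample set always includes the wild-type replicate block.
Beyond supplying the noise model, those columns carry independent noise in
every direction of gene space, which keeps sampled response directions
separated from the no-signal subspace even when a subnetwork has more
genes than knockouts — without them, any direction unsupported by data is
an exact in-sample "constraint" and every minimum strength collapses to
zero.

## Noise model and the cutoff

Replicate residuals `δ_in = log2 r_in − ⟨log2 r_in⟩_n` from the wild-type
block give per-gene standard deviations σ_i, the pooled σ², and the
whitening ratios r_i (constant-replicate genes are assigned the pooled σ
and logged). Pooled z-scores can be fitted with a central, zero-location
t distribution by maximum likelihood; heavy-tailed replicate variability
yields df near 10, normal data a large df. A gene *responds* to a
knockout when its replicate-averaged log2 fold change exceeds the
replicate-variability null (sd σ_i/√n_rep; normal quantiles by default, t
quantiles when a fitted df is attached); multiple testing uses
Benjamini–Hochberg at the node FDR, or Bonferroni α/N for challenge-style
replication.

## Pipeline variants

* **prc** — every gene is a candidate target of every perturbed source; no
  sparsity assumption.
* **subnetwork** — candidates restricted to the significant responders of
  each source (the noise cutoff). This both removes noise-sensitive nodes
  and acts as a sparsity constraint, which is why it can outperform the
  noise-free inferability bound F(q): non-responding alternative routes
  are deleted before inference.
* **clustering** — genes co-expressed under all perturbations are merged
  (average-linkage hierarchical clustering on 1 − |Pearson r|, cut at
  1 − threshold) and treated as single nodes; two-gene clusters with
  exactly one perturbed member are additionally tested directly. The
  default threshold is 0.995: under the linear generator, targets of a
  common strong regulator reach correlations above 0.9–0.98 without being
  functionally interchangeable, and merging them dilutes true links and
  manufactures false ones on expansion; 0.995 captures genuine duplicates
  (which is what perturbing one member of a co-expressed pair can speak
  for) while leaving co-regulated genes separate. The threshold is
  exposed as configuration.

Significance of a link is the two-sided fraction of residual-bootstrap
minimum strengths crossing zero (δ draws added to the replicate-averaged
knockout profiles, 200 draws by default, floored at 1/(n_boot+1)),
BH-corrected across each subnetwork's candidates. Note the floor
interacts with BH: with fewer than ~100 bootstrap samples no link can
clear a 5% FDR in a large subnetwork, so the bootstrap count should not
be reduced aggressively.

Seeding: one master seed; per-source generator streams are spawned from a
`SeedSequence` in sorted source order, so results are independent of
iteration order and bit-reproducible.

## Synthetic data

The linear generator solves `y = −A⁻¹ B u` exactly per experiment; edge
weights are uniform in ±[0.5, 1.5] (redrawn until A is stable), knockouts
are fixed strong forces (−5 on the log2 scale, roughly a 30-fold
knockdown) shared by the replicates of a strain, and measurement noise is
Gaussian with sd equal to 10% of the expression level (constant
0.1·log2 e on the log2 scale; a fold-change-proportional mode with floor
0.01 is also available). Wild-type replicates are pure noise around the
reference. The nonlinear generator uses Hill-type production (activation
`x^h/(K^h+x^h)`, repression `K^h/(K^h+x^h)`, h ∈ {1,2}, K log-uniform in
[0.3, 3], maximal rates log-uniform in [1, 4], basal rate 0.1) with unit
linear degradation; a knockout clamps the gene at the expression floor
10⁻³ and the steady state is found by root-finding with a relaxation
fallback; non-convergent experiments are excluded with a warning.

What the generators do not emulate: array-technology dye bias, correlated
biological variation across genes, unspecific/stress perturbations,
transients, and saturation-limited responses in the linear model. Passing
tests therefore demonstrate correctness of the estimators and the
counting theory under the stated model, not performance on any particular
real compendium. One consequence of the linear model is worth noting:
targets of a very high-degree regulator are almost perfectly co-linear,
so their joint response can reconstruct the removed source in the
minimum-strength construction and out-hub links become harder than they
would be with saturating kinetics — benchmarks therefore use networks of
40–100 nodes where hub degrees stay moderate.

## Inferability theory

For a realised perturbed set, an edge s → t is inferable iff s is
perturbed and (a) t is perturbed and every out-neighbour of s is
perturbed, or (b) t is unperturbed, every other out-neighbour of s and
every out-neighbour of t is perturbed. Under independent Bernoulli(q)
perturbation the per-edge probability is exactly
`q^{k+1} + (1−q) q^{k+l−m}` with k, l the source/target out-degrees and m
their shared-target count, so the closed-form F(q) with the empirical
per-edge (k, l, m) distribution equals the exact motif-mode expectation —
the exhaustive-enumeration oracle confirms this on single-edge and chain
networks before anything else in the build. The *refined* mode deletes,
before testing an edge into t, every out-neighbour of t whose own link
from t is already flagged, iterating to a fixed point (the result is
monotone, hence order-independent). I_F is the trapezoid area of F over a
101-point uniform grid (sub-0.1% quadrature error); I_F* replaces the
joint (k, l, m) distribution by the product of the edge-marginal
out-degree distributions with m hypergeometric, as independence implies.

The noise-free numerical check generates exact linear screens with random
per-node forces (for genericity of the response directions), flags each
true link by whether its minimum strength is bounded away from zero
(tolerance 1e−4; the N₀=1 row estimate when applicable), applies the same
target-neighbour removal iteration, and compares per-edge with refined
counting; agreement is essentially exact (≥ 95% asserted, typically
100%) for 100-node networks across q ∈ {0.25, 0.5, 0.75, 1}.

## Network generators

Scale-free directed networks use power-law attachment weights
(`Pareto(1, γ−1)`, truncated at n−1): `round(n⟨k⟩)` distinct unordered
pairs are inserted with stub probability proportional to weight, then
oriented from the higher-degree endpoint to the lower ("outgoing hubs");
"incoming hubs" is the same graph with every direction inverted. Random
networks insert the same number of uniformly chosen pairs with random
orientation. Self-loops and bidirectional pairs are excluded throughout;
an infeasible edge budget raises rather than truncating silently.

## Problem sizes and defaults used in validation

Structural orderings use n = 300, γ = 2.5, ⟨k⟩ = 3; the I_F/I_F*
correlation uses 24 mixed-ensemble networks at n = 150; theory-agreement
checks use n = 100; pipeline trends use n = 60 (replicates 2/4/8 and
coverage 0.25/0.5/1.0) and the three-method comparison n = 40 — sizes at
which a full run of every benchmark completes in a few minutes while all
qualitative results (orderings, monotone trends, exceeding F(q) at low
coverage) are stable across seeds. DREAM-style challenge scoring
(AUROC/AUPR against gold standards, p-values from exponential-tail or
location-scale-t fits to sampled null distributions, overall score
−½·log10 of the product of the two geometric-mean p-values) is validated
on synthetic gold standards and known null distributions; scoring real
challenge submissions requires the organiser-distributed files, which are
not bundled.

## Known limitations

* The minimum strength is a lower bound; for inferable links with strong
  alternative correlations it can sit well below the planted value, and
  its bootstrap significance — not its magnitude — carries the decision.
* The maximum strength is a total effect; with additional perturbation
  sources present its errors-in-variables estimate can exceed the true
  total effect. It is used only for the inferability classification.
* With fewer independent profiles than subnetwork genes the no-signal
  subspace mixes unsampled directions with true constraints; the
  wild-type block mitigates but does not remove this, and minimum
  strengths become conservative.
* Degenerate smallest eigenvalues leave the null-space orientation to
  sampling noise; ties are broken deterministically and flagged.
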