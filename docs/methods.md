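# Methods

## Model

The package scores genes on a cancer-specific directed network by a random
walk with restart whose transition rule is biased toward high-out-degree
neighbors, with known cancer genes supplying the restart distribution and
somatic mutation status acting as a posterior filter. The model's
assumptions, in order of appearance:

* **Differential coexpression marks cancer-relevant interactions.** A gene
  pair whose Pearson correlation is significant in exactly one of the
  tumor/normal conditions carries condition-specific signal; pairs
  significant in both (constitutive coupling) or in neither are dropped.
  Significance is a two-sided test of the t statistic
  `t = r·sqrt((m−2)/(1−r²))` with `m−2` degrees of freedom, threshold
  p < 0.05 strict on both sides of the XOR. No multiple-testing correction
  is applied — the selection rule is the raw threshold, so ~5% of null
  pairs are significant per condition by construction and the null
  differential-pair rate is `2·0.05·0.95 ≈ 0.095`. A corollary worth
  knowing: even a perfectly coexpressed tumor pair fails the XOR with
  probability ~0.05 (whenever the normal side crosses the threshold by
  chance), so per-edge recovery of a strong planted edge plateaus at ~0.95
  regardless of sample size.
* **Edge direction comes from prior knowledge only.** Correlation is
  symmetric; the directed reference network decides which of `i→j`, `j→i`
  (or both) survive the intersection. Nodes that keep no edges stay in the
  node set and become dangling rows of the walk.
* **Information flows preferentially toward hubs.** From node `i` the
  walker picks out-neighbor `j` with probability proportional to `j`'s
  out-degree, mixed with a uniform teleport term weighted `1−α`. The
  teleport mass is spread over *all* columns — the only reading under
  which rows sum to 1 — and rows with a zero denominator (dangling nodes,
  or nodes all of whose out-neighbors are sinks) are uniform `1/n`.
* **Known cancer genes are good restart targets.** The restart vector is
  built by normalizing betweenness and Katz centrality each to sum 1 over
  all network genes, averaging the two values per seed, zeroing non-seeds,
  and renormalizing. Seeds absent from the network are dropped with a
  warning; an empty or zero-mass seed set falls back to the uniform
  restart. The alternative normalization (over seeds only) changes only
  the relative weighting among seeds; the implemented order is recorded in
  the run metadata.
* **Drivers must be mutated somewhere in the cohort.** The final ranking
  keeps genes with an SNV or a GISTIC ±2 call (high-level amplification or
  homozygous deletion — low-level ±1 calls do not count) in at least one
  sample. The filter is cohort-level because the ranking is cohort-level.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha_mix` (α) | 0.85 | weight of the degree-biased term vs the uniform teleport in each transition row |
| `d` | 0.85 | walk damping; `1−d` is the per-step restart probability |
| `eps` (ε) | 1e−8 | stop when the *squared* score change `Σ(Δr)²` falls below it |
| `max_iter` | 1000 | iteration cap; non-convergence is flagged, not fatal |
| `katz_fraction` | 0.85 | Katz damping as a fraction of the convergence bound `1/λ₁` |
| `p_threshold` | 0.05 | coexpression significance cutoff, strict |
| `bc_undirected` | off | compute betweenness on the undirected projection instead |

The Katz damping is deliberately parameterized relative to the spectral
radius λ₁ of the adjacency (absolute damping would diverge whenever it
exceeds `1/λ₁`); on a nilpotent adjacency (λ₁ = 0) the fraction is used
directly, since every damping converges there. The Katz closed form
`(I − αAᵀ)⁻¹·1` is the k-from-0 walk-count series, so every score is ≥ 1;
the constant offset only partially washes out of the prior, and the choice
is recorded in the run metadata. Betweenness uses directed shortest paths
and the printed scale factor `2/(n²−3n+2)` — the undirected convention
applied verbatim; the constant is immaterial because the prior is
renormalized. For n < 3 the factor is undefined and betweenness returns
zeros with a warning.

## Numerical choices

* Convergence uses the squared-difference sum exactly as defined (not its
  root). That bounds the per-sweep change, not the distance to the fixed
  point: at ε = 1e−8 the converged vector sits ~1e−5 from the true
  stationary point. Tests that compare against the closed-form solve
  `(1−d)(I − dPᵀ)⁻¹·prior` therefore tighten ε to 1e−14, which brings the
  gap to ~1e−7.
* For `d < 1` the fixed point is unique, so `r(0)` affects only the
  transient; the tumor-mean initialization is honored anyway so iteration
  counts are meaningful.
* The transition matrix is stored factored (sparse neighbor weights +
  scalar teleport + dangling mask); `Pᵀr` products never materialize the
  dense matrix, and row-stochasticity is validated to 1e−9 before any walk.
* All downstream sorts break score ties by gene identifier ascending, so
  every output is a pure function of (inputs, parameters, rng seed) and
  reruns are byte-identical.
* Undefined correlations (zero-variance genes) are flagged and treated as
  non-significant; boundary p = 0.05 is non-significant everywhere.
* Correlations are computed only on genes shared by both expression
  matrices and the reference network — genes outside the reference can
  never contribute an edge to the intersection, so this is purely an
  efficiency choice.
* Missing expression values are a hard error (no imputation); gene
  identifiers are opaque case-sensitive strings (no aliasing).

## Synthetic cohorts

The `fixtures` module generates the inputs the method assumes rather than
imitating any real cohort. Defaults: 300 genes, 3 planted blocks of 10
drivers, 150 tumor + 150 normal samples, within-block tumor correlation
0.7, preferential-attachment reference network (3 out-edges per node) with
guaranteed intra-block wiring, driver mutation rate 0.3 per sample vs 0.02
for passengers, 30% of driver events emitted as ±2 CNV calls, seed set
covering half the drivers plus 10 decoys. Sample sizes and the number of
planted drivers are desk-scale stand-ins for a tumor cohort; rates were
chosen so that drivers are clearly but not trivially enriched (a driver is
mutated in ~45 of 150 samples, a passenger in ~3).

Block correlation uses the shared-factor construction
`x = sqrt(ρ)·f + sqrt(1−ρ)·e`, which hits the target pairwise correlation
exactly in expectation; an affine shift makes abundances non-negative
without touching correlations. The generator does **not** reproduce real
expression marginals (library-size variation, count noise, heteroscedastic
RSEM-style abundance), mutation hotspots, or the modular topology of real
interactomes. Passing tests on these fixtures therefore demonstrate that
the implementation is correct and that the pipeline recovers signal of the
kind it assumes — not that the method will rank well on any particular
tumor cohort. On the default fixture the planted signal saturates the
top-30 (precision 1.0), so the ablation modes tie there; they separate
only on weaker, noisier inputs.

## Design choices where the design was open

* Degree centrality is the **out**-degree row sum, matching its use in the
  transition rule; the generic "edges incident to the vertex" reading is
  ambiguous on a digraph.
* Betweenness defaults to the directed graph (`bc_undirected` is the
  escape hatch) — the reference graph is directed and the walk respects
  direction.
* Seed deletion in the subsampling experiment is uniform without
  replacement; "accuracy" in its summary is top-N precision.
* SNV input is accepted both as a binary matrix and as a (gene, sample)
  pair list, since MAF-style call sets reduce to pairs.
* Benchmark genes absent from the network still count in the recall
  denominator: recall is relative to the benchmark as given.
* When the ranking is shorter than the evaluation depth the
  precision-recall curve ends early rather than padding.

## Limitations

* The p < 0.05 edge rule is uncorrected; at genome scale the differential
  network contains a large absolute number of false edges by design.
* Exact betweenness is O(n·m); the implementation targets desk-scale
  networks (up to ~2·10⁴ nodes), with no sampled approximation.
* The mutation filter is binary and cohort-level; recurrence, functional
  impact and per-patient rankings are out of scope.
* The walk scores are relative within one run; scores are not comparable
  across networks or cohorts.
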