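# driver-irw

Prioritization of candidate cancer **driver genes** by a degree-biased
random walk with restart on a cancer-specific interaction network, for
computational biologists working with matched tumor/normal expression,
somatic mutation calls, and a directed reference interaction network.

Most mutated genes in a tumor are passengers; the few drivers tend to sit
at topologically important positions of condition-specific interaction
networks. This package ranks genes by combining three signals:

1. **A cancer-specific network.** Pearson coexpression (with two-sided
   p-values from the t transform) is computed separately on tumor and
   normal expression; a gene pair is a *differential edge* when it is
   significant (p < 0.05, strict) in exactly one condition. The directed
   reference network is then intersected with these pairs — direction from
   the reference, evidence from the differential coexpression.
2. **A degree-biased walk.** On the resulting graph with 0–1 adjacency
   `A`, the walker moves from gene *i* to out-neighbor *j* with
   probability proportional to *j*'s out-degree, mixed with a uniform
   teleport term:

   ```
   P[i,j] = α · DC⁺_j · A[i,j] / Σ_{v∈N⁺(i)} DC⁺_v  +  (1−α)/n      (α = 0.85)
   ```

   with a uniform row `1/n` when the denominator is zero (dangling nodes,
   or nodes whose out-neighbors are all sinks). Scores iterate to the
   stationary point of

   ```
   r(t+1) = d · Pᵀ r(t) + (1−d) · prior_p                           (d = 0.85)
   ```

   stopping when `Σ_i (r_i(t+1) − r_i(t))² < 1e−8` (at most 1000
   iterations). The restart prior `prior_p` places mass on known
   cancer-associated **seed genes** in proportion to the mean of their
   normalized betweenness and Katz centralities; `r(0)` is the normalized
   mean tumor expression.
3. **A mutation post-filter.** Only genes mutated in at least one sample —
   an SNV, or a GISTIC copy-number call of +2/−2 — appear in the final
   ranking.

Rankings are evaluated by top-N precision and recall against a benchmark
gene set, and two ablations are built in: a uniform-neighbor transition
(RW_UniTr) and a seedless uniform restart (IRW_withoutS), plus a
seed-subsampling robustness experiment.

## Worked example

No downloads are needed: the `fixtures` module generates a full synthetic
cohort with planted driver blocks. `python examples/run_pipeline.py` prints:

```
cancer-specific network: 300 genes, 159 edges
walk converged in 16 iterations (final diff 6.76e-09)
288 mutated genes ranked

rank  gene   score        driver?  mutated samples
   1  g002  0.096395   yes      43
   2  g003  0.076624   yes      46
   3  g001  0.072951   yes      56
   ...

top-30 precision 1.00, recall 1.00 against the planted drivers
```

All 30 planted drivers land in the top 30 of 288 mutated genes (a random
ranking would place about 3 there). `examples/ablations.py`,
`examples/seed_robustness.py` and `examples/build_network.py` walk through
the other capabilities.

The same pipeline runs from files via the CLI:

```bash
driver-irw simulate --seed 1 --out fixture/          # write a synthetic input bundle
driver-irw run --tumor-expr fixture/tumor_expression.tsv \
    --normal-expr fixture/normal_expression.tsv \
    --network fixture/reference_network.tsv \
    --snv fixture/snv_matrix.tsv --cnv fixture/cnv_gistic.tsv \
    --seeds fixture/seed_genes.txt --out run/
driver-irw eval --ranking run/ranking.tsv \
    --benchmark fixture/benchmark_genes.txt --top-n 30
```

Inputs are plain TSV/text: expression as genes × samples with a header
row, the network as a two-column edge list, SNVs as a binary matrix or a
(gene, sample) pair list, CNVs as a GISTIC-thresholded integer matrix,
gene sets as one symbol per line.

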