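# Methods

## The two-stress-event model

The package analyses a repeated-stress design with five conditions:
baseline (`T1_0h`), 3 h and 48 h into a first stress event (`T1_3h`,
`T1_48h`), and 3 h and 48 h into a second event after recovery (`T2_3h`,
`T2_48h`), each with replicated RNA-seq counts. Two contrasts define
transcriptional memory: the first-event response (`T1_3h` vs `T1_0h`) and
the change at the second event relative to the first (`T2_3h` vs `T1_3h`).
A stress-memory gene (SMG) is differentially expressed in **both**
contrasts; its pair of directions gives four classes — `[+/+]`, `[−/−]`,
`[+/−]`, `[−/+]`. Genes significant in only one contrast are non-memory by
definition, so the SMG set is always contained in the intersection of the
two DEG sets. The 48-h conditions never enter classification; they exist
for the DEG-count-reduction statistic (percent decrease in DEG number from
first- to second-event contrasts against baseline).

## Differential expression

The DE core is deliberately minimal and fully self-contained; it does not
attempt numerical parity with GLM-based DE packages, and its correctness
criterion is recovery of planted effects in simulation.

* **Normalization** — median-of-ratios: per sample, the median over genes
  (with positive geometric mean) of count / geometric mean. Factors are
  relative, so a common scaling of all samples cancels in fold changes but
  not in normalized counts.
* **Dispersion** — method of moments on normalized counts pooled within
  conditions having ≥ 2 replicates: `α̂ = max(0, (s² − μ̄)/μ̄²)`, averaged
  across eligible conditions, then shrunk toward the 10%-trimmed mean of
  all per-gene estimates with weight 0.3 (default). Shrinkage stabilises
  the 3-replicate estimates without a full empirical-Bayes fit.
* **Wald contrast** — `log2FC = log2((m_alt + c)/(m_ref + c))` with
  pseudocount `c = 0.5` on normalized condition means, and
  `se = (1/ln 2)·sqrt((1/(m_alt+c) + α)/n_alt + (1/(m_ref+c) + α)/n_ref)`,
  the delta-method error under `var = μ + αμ²`. The pseudocount appears in
  the standard error as well as the fold change so that a zero-count
  condition yields a finite (large-z) statistic rather than an undefined
  one; p-values are two-sided normal tails. No covariates, shrunken fold
  changes, independent filtering or outlier handling.
* **Multiple testing** — Benjamini–Hochberg step-up, implemented directly
  (≈ 6 lines) and cross-checked against `statsmodels` in the test suite.
* **DEG thresholds** — strict inequalities: `padj < 0.05` and
  `|log2FC| > 1`. A gene at exactly `log2FC = 1` is not a DEG.

## Enrichment

Term enrichment (TF families, or any gene → term mapping) uses the
one-sided hypergeometric upper tail on the 2×2 table of a gene set against
the disjoint remainder of the universe, BH-corrected across terms within a
run. An overlapping variant (set vs whole universe) is available via
`background="universe"`. Odds ratios come from the same table, with the
Haldane–Anscombe 0.5 correction only when a zero cell would make the ratio
undefined. The one-decimal percentages reported throughout use
round-half-away-from-zero, matching how such tables are conventionally
printed.

## Hub detection

Maximal cliques are enumerated with Bron–Kerbosch with pivoting
(`networkx.find_cliques`); MCC sums `(|C|−1)!` over the maximal cliques
(size ≥ 2) containing a node, so isolated nodes score 0 and nodes whose
edges lie in no triangle score their degree. MCODE follows its three
stages: vertex weight = k × density of the highest k-core of the closed
neighborhood (weight 0 below the degree cutoff of 2); complexes grown from
the highest-weight unused seed, admitting neighbors with weight
≥ (1 − vwp) × seed weight (vwp = 0.2), each vertex used once; complexes
lacking a 2-core are discarded, haircut reduces a complex to its 2-core
(equivalent to iterated removal of degree-1 vertices), fluff is off by
default, and score = density × size. Hub TFs are the intersection of the
MCC top-k (k = 10 default) with members of MCODE complexes of ≥ 4 nodes;
both rules are configurable, since published analyses rarely state how the
two method outputs were combined. Edge lists are read STRING-style with a
default confidence threshold of 400 (medium confidence on the 0–1000
scale).

## Motif scanning

PWMs are built from MEME-minimal count matrices with pseudocount ε = 0.1
times the background frequency per cell. Window scores are log2-odds in
bits, integer-scaled at 1/1000 bit per cell; the null distribution of the
integer score of a background word is computed exactly by column-wise
convolution, so every hit's p-value `P(score ≥ s)` is exact rather than
approximated. Zero-probability cells (only possible at ε = 0) are capped
at −20 bits to bound the DP table; this leaves high-score p-values
untouched. Scanning covers both strands by default, skips windows
containing N, and reports hits with `p < 1e-4` (strict), with offsets given
in forward coordinates of the promoter. A gene is a predicted target of a
TF if it has at least one surviving hit; multi-TF results are summarised
as upset-style membership-pattern counts plus the all-TF intersection.

Promoters are the 1 kb immediately upstream of the gene feature's 5′ end
(the TSS proxy when transcript-level annotation is absent): `[S−1000, S−1]`
for a + strand gene starting at S, `[E+1, E+1000]` reverse-complemented for
a − strand gene ending at E, truncated at contig edges and skipped (with a
warning) when empty. No masking of overlaps with neighboring genes is
applied.

## Synthetic data

The generator emulates the study design at desk scale with exact planted
truth. Per-gene baseline means are natural-log-normal (μ = 5, σ = 1, i.e.
median ≈ 150 counts); condition means apply the class's log2 effects
exactly (`±β1` at `T1_3h`, `±β2` at `T2_3h` relative to `T1_3h`; 48-h
conditions reuse their event's 3-h mean); counts are negative-binomial with
per-gene dispersion drawn log-normally (σ = 0.25) around the configured
α = 0.05, times a per-sample size factor uniform on [0.7, 1.4]. Defaults:
2000 genes, β1 = β2 = 3, 3 replicates; 80% null genes, 10% non-memory
responsive, 10% memory genes split 63/30/4/3 percent into
`[+/−]`/`[−/+]`/`[+/+]`/`[−/−]` — the class mix repeated-stress
transcriptomes show, with the inverted classes dominating. Effect sizes are
chosen for testability (the magnitudes of real salt-stress responses vary
per gene and are not modelled); a single seed feeds independent substreams
for counts, annotations, network and promoters.

TF families are assigned by drawing the number of family members among
memory genes binomially with success probability `multiplier × K/N` (K =
genome count, N = genes), so the expected within-memory frequency is
exactly multiplier × genome frequency; identities are sampled without
replacement from the unassigned pools, one family per gene. The default
family set totals 6% of the genome — the genome-wide TF fraction of plant
genomes — with WRKY (3×) and MYB (2×) enriched among memory genes, the
pattern reported for salt-stress memory. The interaction graph is
Erdős–Rényi (p = 0.05) over TF genes plus a planted clique (default K6) on
hub genes drawn from memory TFs. Promoters are 1-kb i.i.d. sequences at the
configured GC; each TF family gets a random width-8 consensus word, planted
once per true target at a recorded, non-overlapping offset on a random
strand.

What the generator does **not** emulate: read-level noise and mapping
artifacts, correlated gene modules, batch effects, length/GC biases,
isoform structure, dependent promoters (each is independent background),
and realistic motif degeneracy (planted instances are exact consensus
words). Passing recovery tests therefore demonstrates that the analysis
machinery is correct under the stated NB model, not that real-data
performance will match.

## Problem sizes and determinism

The test suite and acceptance script run the strong-effect condition at
2000 genes × 15 samples, enrichment ranking over 25–50 independent seeds,
hub recovery over 20 seeds on 60-node graphs, and motif recovery over
≈ 1000 planted instances — sizes at which every planted-truth rate is
estimated with small binomial error while the full suite completes in well
under a minute of compute per stage. All randomness flows from explicit
seeds; identical seeds give bit-identical outputs.

## Replay mode

Derived statistics of a published analysis — class shares, DEG reductions,
TF fractions, the Fisher p of the TF 2×2 table, target shares and
common-target composition — are pure arithmetic on printed count tables.
`saltmem.replay` recomputes them through the same code paths the pipeline
uses (`proportion`, `deg_reduction`, `fisher_2x2`), so printed summary
numbers can be verified without access to the underlying raw sequencing
data.

## Known limitations

* The Wald test's normal approximation is anticonservative at very low
  counts; the pseudocount mitigates but does not remove this.
* Median-of-ratios normalization assumes most genes unchanged; simulations
  with a majority of changed genes violate it (the generator's default 20%
  responsive fraction is safe).
* MCODE's published description leaves room for interpretation (fluff,
  seed handling after haircut); this implementation documents its choices
  above and exposes the parameters.
* The qPCR utility assumes amplification efficiency exactly 2 per cycle,
  as the 2^−ΔΔCt method does.
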