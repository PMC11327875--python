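# Methods

This note documents the models, conventions and numerical choices behind
`lncdisc`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Coordinates, classification and pairing

All coordinates are GTF-native: 1-based, inclusive. The overlap of
intervals [a, b] and [c, d] is `max(0, min(b,d) − max(a,c) + 1)`.

The lncRNA universe is defined at load time: genes on non-canonical
chromosomes are discarded (canonical default: 2L, 2R, 3L, 3R, 4, X, Y), and
non-coding genes qualify as lncRNAs only when their gene span strictly
exceeds 200 bp. Positional classification is mutually exclusive with
precedence genic exonic > genic intronic > intergenic, evaluated on the
lncRNA *gene span*, strand-agnostically: exon overlap of ≥ 1 bp (any
transcript of any PCG) wins; otherwise overlap with a PCG gene body means
intronic containment (PCG exons that overlapped would already have fired the
first rule); otherwise intergenic.

Pairing conventions, where the underlying definitions admit more than one
reading:

* *End-to-end distance* counts the bp strictly between gene spans, so
  abutting genes are at distance 0. An off-by-one alternative (counting one
  endpoint) would shift every distance by 1 and never change the chosen
  partner.
* *Most overlapping nucleotides* is measured on gene spans; exon-level
  overlap is used only for the exonic/intronic decision, matching the
  different granularities at which the two rules are stated.
* Ties (equal gap, or equal overlap) break toward the lexicographically
  smallest gene_id and are flagged `tie=true`; determinism matters more than
  the arbitrary choice.
* Sense/antisense and upstream/downstream sub-classes are deliberately not
  produced; the three-group scheme is strand-blind by design.

Classification uses per-chromosome interval trees over PCG exons and spans;
nearest-gap queries use sorted start/end arrays (downstream gap is strictly
increasing in partner start, so only minimal-start candidates can win). A
brute-force O(n²) scan reproduces both classification and pairing exactly on
1000 random layouts in the test suite.

## Expression operations

Replicates are collapsed by arithmetic mean per condition before any
thresholding. The expressed filter is inclusive: averaged TPM ≥ 1.
Tissue-specificity requires expression in ≥ 1 stage of exactly one tissue
and in no condition of any other tissue; the stage axis is symmetric.

For clustered summaries, genes expressed in no condition are dropped, each
gene's profile is standardized (z = (x − mean)/sd across conditions), and
"normalized into a −3 to 3 scale" is implemented as clipping at ±3 — an
affine rescale would destroy the z-score semantics of interior values.
Zero-variance genes get all-zero rows and are flagged rather than dropped.
Clustering is complete-linkage on Euclidean distances (the metric is a
parameter) over genes and over conditions; a flat k-cut labels gene
clusters. Heatmap columns default to replicate-averaged conditions.

## Profile categories and concordance

For an ordered triple of stage means, the category is *increasing* iff the
unique minimum is first and the unique maximum last, *peak* iff the unique
maximum is central, *valley* iff the unique minimum is central, *decreasing*
mirrored. With pairwise-distinct values exactly one rule fires (exhaustively
verified over all orderings). Real TPM triples are ties with probability
zero, but degenerate synthetic inputs need a deterministic outcome, so any
tie on the deciding extremum yields `ambiguous`, which propagates to an
*unrelated* pair call.

Concordant = equal categories; discordant = {increasing, decreasing} or
{peak, valley}; every cross combination, an ambiguous member, or a PCG
below 1 TPM in all conditions of the relevant tissue → unrelated.

Pairwise Pearson correlations are computed on log10(TPM + 0.1). The default
uses replicate-level columns (6 points for a 3-stage × 2-replicate tissue);
stage-averaged vectors are available by passing the averaged matrix instead.
Constant transformed vectors give NaN rather than an arbitrary value.

## Dual-criterion differential expression

At each time point, genes below 1 TPM in every sample are removed, then two
independent criteria are evaluated and intersected:

1. **TPM screen** — ratio of replicate-mean TPMs with a pseudocount of 0.1
   (mirroring the correlation transform), called when ≥ 1.7 or ≤ 1/1.7.
   The comparator is inclusive by default; a strict variant is exposed for
   the mutant-analysis phrasing.
2. **Count test** — a negative-binomial log-linear model per gene with
   log size-factor offsets, Wald z on the condition (or interaction)
   coefficient, two-sided normal p, BH adjustment within the time point,
   called when padj < 0.05 and |log2FC| ≥ log2 1.7.

Size factors are the median-of-ratios construction: per sample, the median
over all-positive genes of count/geometric-mean. Only factor *ratios* are
identifiable (rescaling one sample rescales the geometric-mean reference as
well); a pseudo-reference variant (counts + 1) covers matrices with no
all-positive gene.

### Dispersion estimation

The engine's one non-obvious component. Raw gene-wise method-of-moments
estimates (within-group variance of normalized counts vs mean) carry only
~4 residual degrees of freedom at 3+3 replicates, and plugging them directly
into the Wald variance roughly doubles the nominal type-I error — genes
whose variance happens to be underestimated get inflated z. Three
moment-derived steps stabilize the estimate without free tuning constants:

1. gene-wise MoM dispersion, pooled across design cells with df weights;
2. shrinkage of log-dispersion toward the ensemble mean with weight
   τ²/(τ² + c), where c = trigamma(df/2) approximates the sampling variance
   of a log variance on df degrees of freedom and τ² is the excess spread of
   the observed log estimates. With homogeneous true dispersion the weight
   collapses to 0 and all genes share the ensemble value; with strong
   heterogeneity most of the gene-wise signal is kept;
3. a reciprocal-bias (harmonic) correction at the post-shrinkage effective
   df: for a χ²-like variance estimate v on d degrees of freedom,
   E[1/v] = d/(d−2) · 1/σ², and the Wald variance uses exactly that
   reciprocal; d is recovered from the residual noise w²c.

Monte-Carlo behaviour at the package's simulated conditions (n = 3+3, means
100–1000): empirical type-I at nominal 0.05 is 0.05–0.065 under a
homogeneous-dispersion null and ≈ 0.06 under the generator's heterogeneous
null (dispersion log-uniform over [0.01, 0.5]); the BH-level global-null
dual-criterion call fraction is ≪ 0.05; and ≥ 90% of genes planted at fold
change 4 are recovered. Under extreme dispersion heterogeneity the marginal
raw-p error of any plug-in engine inflates for the highest-dispersion genes;
the FDR-level and dual-criterion calls remain controlled because those genes
rarely clear both thresholds. The engine intentionally omits mean-dispersion
trend fitting, LFC shrinkage, independent filtering and outlier refitting,
and is pluggable where exact replication against an external fitter is
wanted.

Interaction designs (intercept + genotype + condition + genotype:condition)
test the interaction coefficient; its standard error is roughly double the
two-group contrast's at equal replication, so power at 3 replicates per cell
is intrinsically modest (~0.65 at fold change 4 in simulation).

Non-converged fits are flagged, get NaN p-values, and are excluded from the
BH denominator. P-values are floored at 1e-300 to survive underflow.

## Alignment, duplication screen and ORFs

Scoring defaults: match +1, mismatch −1, gap open −2, gap extend −0.5 (a
gap of length L costs −2 − 0.5(L−1)). *Global* mode penalizes end gaps;
*glocal* mode frees end gaps against the longer sequence only, so a
contained duplicate aligns end-to-end, and identity is counted over aligned
columns after trimming the longer sequence's overhangs. Percent identity is
rounded half-up to one decimal for reporting; the raw fraction is retained.
The DP is validated against truly exhaustive alignment enumeration (short
sequences) and an independently coded affine-gap (Gotoh) DP (all {A,C}
pairs up to length 8).

The duplication screen aligns only pairs sharing ≥ 1 exact k-mer (k = 12
default). Two substitutions in a 214-bp copy leave a clean stretch ≥ 70 bp,
so planted duplicates always survive the prescreen; hits are filtered at
≥ 90% identity over ≥ 100 columns and sorted by identity, then length.

ORF search scans the three forward frames (reverse strand optional) for
ATG-to-stop frames under the standard genetic code; codons containing N
neither open nor close an ORF, and ORFs without an in-sequence stop are not
reported. The peptide length counts the initial methionine and excludes the
stop, so a 102-nt cassette (ATG + 32 codons + stop) yields 33 aa and
`end − start + 1 = 3 · (peptide_length + 1)`.

## Synthetic-data generator

One pseudo-random stream per artifact type (annotation, expression, counts,
sequences), spawned from the master seed, so regenerating one artifact never
perturbs another; identical seed + config gives byte-identical files.

* **Annotation** — non-overlapping PCGs with 1–5 exons (exons 150–600 bp,
  introns 500–1500 bp, inter-gene gaps 2–8 kb) across three chromosomes;
  monoexonic lncRNAs placed to realize a configurable exonic/intronic/
  intergenic mix (default 0.3/0.2/0.5). Truth records the planted class and
  the intended partner from a generator-side brute-force scan.
* **Development expression** — 3 tissues × 3 stages × 2 replicates. Each
  pair draws a relation (default 25/15/60% concordant/discordant/unrelated,
  in the neighbourhood of the proportions such experiments report); latent
  log10 profiles use a baseline of 0.5–1.5 and a stage step of 0.4–0.8, so
  categories survive the default multiplicative noise (sd 0.1 on log10 TPM)
  with ≥ 90% recovery. Concordant partners share the latent shape shifted to
  their own baseline; discordant partners get the mirrored shape; 10% of
  PCGs are pinned below 1 TPM everywhere to exercise the not-expressed →
  unrelated path.
* **Counts** — NB counts (variance μ + αμ²) with gene means log-uniform in
  [100, 1000] (moderately-to-well expressed genes), dispersions log-uniform
  in [0.01, 0.5], per-sample size factors 2^U(−0.5, 0.5), 3 replicates per
  group, and a 10% DE fraction at fold changes {1.7, 4} in random
  directions — per time point, or in the mutant × regeneration cell for the
  interaction design. TPM is derived from the counts through fixed per-gene
  lengths (uniform 500–5000 bp), so fold changes are consistent across both
  matrices.
* **Sequences** — a 214-bp query carrying exactly one 33-codon ORF
  (rejection-sampled so no longer ORF exists), embedded in a 361-bp target
  with 2 substitutions placed outside the ORF and ≥ 15 bp from the copy
  edges (an edge-adjacent substitution can let a gapped alignment tie with
  the intended ungapped containment); target flanks are rejection-sampled so
  no chimeric ORF outgrows the planted one. Plus plain random background
  sequences.

What the generator does *not* emulate: genomic sequence context under the
annotation (coordinates only), library-size realism, batch effects,
mean-dispersion trends, transcript isoforms, or read-level data. Passing
tests therefore demonstrate correctness of the pipeline's logic and
calibration under the stated stochastic models, not robustness to artifacts
real RNA-seq can contain (mapping bias, outliers, batch structure).

## Problem sizes

The test and acceptance runs use 2000-gene count matrices, 1000 expression
pairs, 1000 random annotations for the pairing oracle, and all {A,C} pairs
to length 8 for the alignment oracle — sizes chosen so every recovery and
calibration property is measured with useful precision while a full run
completes in well under a minute per stage.

## Known limitations

* The NB engine is a principled simplification; results will not numerically
  match DESeq2/edgeR gene-for-gene, though calls agree closely at strong
  effects. The FC filter is applied to the unshrunk Wald log2FC.
* Manual browser-track curation of exonic lncRNAs is replaced by an
  exclusion-list mechanism (genes stay in the full table, flagged, and leave
  the summaries).
* The duplication screen is within-set only (no database search, synteny or
  cross-species conservation).
* Whether the original analyses used replicate-level or stage-averaged
  vectors for the pair correlation is not stated in the underlying methods;
  replicate-level is the package default and both are exposed.
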