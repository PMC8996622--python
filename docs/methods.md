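# Methods

## Statistical model and procedure

All analyses operate on log expression `x = log10(TPM + 1)`.  Genes are kept
when `x >= 0.1` in every sample of the cohort entering a given analysis
("all individuals" is defined relative to that cohort); the expression
filter is applied before the technical-error filter.

**Whole-embryo variation.**  For two individuals the distance is the
population variance (divide by N) of the per-gene log differences,
`V = (1/N) Σ (y_j − ȳ)²`.  Mean-centring makes V invariant to global shifts
such as residual depth differences; the 1/N normalisation follows the
defining formula rather than the unbiased n−1 convention (the difference is
negligible at transcriptome scale and fidelity to the definition matters
more).  Stage stability is the mean V over sex-matched twin pairs;
intraspecies diversity the mean V over all sex-matched cross-population
pairs.  `1 − Spearman ρ` is available as an alternative distance; on
synthetic hourglass data the two distances rank stages with *distinct*
noise levels identically, while the mutual order of two stages simulated
with the same noise sd is exchangeable and not reproducible by any
statistic.

**Technical-error filter.**  Per gene, the one absolute difference per twin
pair is tested against the six pairwise absolute differences among the four
technical replicates with a one-sided Wilcoxon rank-sum test (H1: twin
differences stochastically greater), pass at p < 0.01 on raw p-values.  The
six technical differences enter the test individually (a rank-sum test
against their scalar average would be undefined); the average is still
reported as the per-gene technical-error summary.  The exact null
distribution is used when the smaller sample has ≤ 8 observations and the
pooled sample is tie-free; otherwise the mid-rank normal approximation with
continuity and tie corrections.  A caveat worth knowing: the six technical
differences are built from only four replicates and are therefore positively
correlated, which violates the independence assumption of the rank-sum null.
Under an exchangeable twin-noise = technical-noise null the realised pass
fraction at α = 0.01 is ≈ 0.04, not 0.01 (verified against a simulation with
hypothetically independent technical differences, which does calibrate at
≈ 0.009).  The filter is therefore anti-conservative by construction — it
admits more genes than its nominal level suggests — which is acceptable for
its screening purpose but should not be read as a calibrated test.  Power is
monotone in the biological:technical noise ratio.

**Stage-wise tests.**  Kruskal–Wallis (tie-corrected, χ² reference, p = 1
with a warning for fully degenerate input) followed by Steel–Dwass: for each
pair of groups the rank-sum statistic is computed on that pair alone,
standardized with tie correction, and `√2·|z|` is referred to the
studentized range distribution with k groups and infinite df.  The
asymptotic branch applies a 0.5 continuity correction to `|W − E[W]|`: at
the group sizes used here (10–25 values per stage) the discrete rank-sum
null has atoms of mass 0.03–0.05 at mid p, and the uncorrected continuous
approximation is anti-conservative by roughly half an atom; the correction
brings it within ~0.016 of a family-wise max-statistic permutation oracle
(mid-p convention).  A `method="permutation"` option computes the
family-wise p directly from the permutation distribution of the maximum
standardized statistic.

**Per-gene stability and the running-median correction.**  Raw variation is
the mean absolute pairwise difference.  Because variation depends
non-linearly on expression level, genes are sorted by mean expression (over
all individuals of the cohort; ties broken by gene id for determinism) and
the median raw variation of the ±250 neighbours (window 501) is subtracted.
Edge windows shrink symmetrically so both sides hold equal counts — the
first and last gene get singleton windows and corrected value 0.  Corrected
values may be negative; they are rank-compared across cohorts.  On data with
the planted monotone mean–variance trend the correction reduces
|ρ(variation, mean expression)| from > 0.5 to < 0.01.

**Orthology and interspecies variation.**  1:1 orthologs are reciprocal
best hits from tabular BLAST output: best = smallest e-value, ties broken by
larger bitscore then lexicographic subject id; hits pass at e-value < 1e−5.
(The threshold is sometimes printed with the inequality inverted in the
literature this follows; the literal `> 1e−5` reading is available behind
``literal_inequality=True`` but would discard all credible hits.)
Interspecies variation is the absolute difference of replicate-averaged
log expression per ortholog pair, corrected against the reference species'
mean expression.

**Pleiotropy, gene sets and enrichment.**  A gene is expressed in a context
(25 adult tissues, 16 developmental stages by default) when its
replicate-mean TPM ≥ 1; pleiotropy is the context count.  Developmental
genes carry GO:0032502 or any descendant (closure computed from a supplied
child→parent edge list, for determinism and offline use); constitutive
genes have replicate-mean log expression ≥ 0.1 at every stage.  Enrichment
of the 10% least-variable genes (floor of 0.1·n, ties at the cut broken by
gene id) against the remaining genes uses the hypergeometric upper tail
(one-sided Fisher), Benjamini–Hochberg q over all terms, and fold =
term-frequency ratio selected/background (∞ when the background frequency
is 0); the report keeps terms with fold strictly > 2 and flags q ≤ 0.01.

**Regulome.**  Coordinates are 0-based half-open; TSSs are 0-based points
(the minimal VCF writer converts to 1-based positions).  Each peak is linked
to the gene with the closest TSS (point-to-interval distance, equidistant
ties to the lexicographically smaller gene id) and retained iff strictly
more than half its length lies inside the union of the gene's distal
(±5000 bp) and proximal (−100..+50 bp, strand-aware; flipping strand mirrors
the window about the TSS exactly) regions.  Substitution counting clips the
retained peaks to the distal window, merges them, and sums carrier flags
over samples for substitutions inside (end coordinate excluded).  The TATA
scanner counts exact occurrences of TATAAAAA, TATAAATA, TATATAAA and
TATATATA at every offset plus occurrences of their reverse complements;
overlapping two-base-shifted matches and the two strands count separately,
so the palindromic TATATATA scores twice per site.

**Read-depth bias.**  Counts are subsampled per sample without replacement
(multivariate hypergeometric, matching random picking from a mapped-read
pool; a multinomial option exists and is indistinguishable at high depth),
converted to a TPM surrogate (proportion × 10⁶, no length correction since
synthetic genes carry no length), log-transformed, and summarised as mean
twin V per depth.  With identical latent profiles V reflects pure sampling
noise and decreases with depth.

## The synthetic-data generator

The generator plants structure on the log10(TPM+1) scale, where the
statistics operate.  Per gene: baseline `μ_j ~ Exponential(1)` (log10-TPM
units, median ≈ 0.7); noise multiplier `s_j ~ LogNormal(0, 0.5)`;
mean–variance coupling `g(μ) = 0.3 + exp(−μ)` (decreasing, convex,
flattening at high expression — the bias the running median must remove).
A twin sample at stage t is `x_j = μ_j + N(0, (sd_t · s_j · g(μ_j))²)`;
the default stage sds (0.20, 0.10, 0.10, 0.25) plant the hourglass over the
stages (early, phylo1, phylo2, hatch), and the default 20 twin pairs per
stage sits inside the 13–25 pairs of the emulated design.  Population B's
baseline adds `δ_j ~ N(0, (0.15 · s_j)²)`, drawn once per gene — the shared
multiplier s_j is what plants the stability–conservation correlation.
Technical replicates are four draws around one latent profile with flat
sd 0.05 (chosen below the mid-stage biological noise; the emulated study
does not report the empirical magnitude).  TPM is emitted as `10^x − 1` with
x floored at 0 so TPM ≥ 0; variance-recovery tests restrict themselves to
genes whose baseline is more than 5 noise sds above the floor.

GO-style labels plant one term at 0.25 frequency among the 10% of genes
with the smallest s_j and 0.05 elsewhere (5×), plus 20 stability-independent
decoy terms.  Tissue/stage contexts plant an expression mask whose
per-context probability decreases with the s_j rank; expressed replicates
draw TPM ≥ 1.5 and silent ones < 0.5, so the mask is exactly recoverable at
the TPM ≥ 1 rule.  The toy genome puts one TSS per gene at 20-kb spacing
with alternating strand, peaks at known offsets inside the distal window,
homozygous substitutions with 8 per-sample carrier flags, and 150-bp
proximal promoters built over {A, C, G} with planted motifs separated by CC
spacers — a T-free background means zero accidental motifs, making the
planted TATA count analytic (palindromic TATATATA scores 2, others 1) and
independent of the scanner that is later tested against it.

What the generator does *not* emulate: count-level noise (negative
binomial), gene lengths, sex-specific expression (sex is a matching label
only), correlated co-expression modules, and real GO topology.  Passing
tests therefore demonstrate that the statistics recover planted structure
of the assumed form, not that real RNA-seq noise is fully captured.

## Numerical and design choices

* RNG streams are derived from `(seed, stream-id, stage-index)` seed
  sequences, so μ_j and s_j are bit-identical across every operation of one
  config and each operation is independently reproducible.
* Gene sorts use mergesort with gene-id tie-breaks for full determinism.
* Degenerate inputs: all-tied rank-sum samples give p = 1; fully constant
  Kruskal–Wallis groups give p = 1 with a warning; constant profiles reject
  Spearman distance; constant feature columns are flagged undefined rather
  than silently dropped.
* Spearman no-correlation p uses the large-sample t approximation; at the
  minimum allowed 10 shared genes an exact permutation p (all 10!
  pairings, chunked) is computed instead.
* TPM matrices are not renormalised to sum to 10⁶ after the inverse
  transform; downstream statistics use the log matrix directly.
* Problem sizes in tests (2000–5000 genes, 20 pairs, 10–20 seeds, 10⁴
  permutations) were chosen so each property is measured well inside its
  Monte-Carlo error while the whole suite stays interactive.

## Known limitations

* The technical-error filter's nominal α overstates its stringency (see
  above); results depending on the *fraction* of filtered genes should use
  the measured, not nominal, level.
* The Steel–Dwass asymptotic p is an approximation; for small groups or
  ties near decision thresholds use `method="permutation"`.
* `assign_peaks` is quadratic per chromosome (vectorised over TSSs); it is
  meant for annotation-scale inputs (10⁴–10⁵ peaks), not base-pair scans.
* The interspecies workflow consumes precomputed BLAST tabular hits; it
  does not run alignments or select longest peptides.
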