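# Methods

## The experimental system being modeled

Three mitochondrial haplotypes (BRA, CAL, YEM) are introduced at exactly
1/3 each into replicate populations that share one of three outbred nuclear
backgrounds (Brazil, California, Yemen — each the native background of one
haplotype). Populations evolve under one of two stressful thermal regimes:
35°C for 36 generations or 23°C for 23 generations. The full design is
3 nuclear × 2 thermal × 2 maternal-Eve replicates × 2 technical replicates
= 24 lines; one Yemen/35°C line is lost, leaving the realized 23. End-point
haplotype frequencies are measured by sequencing pools of 100 individuals
and counting reads that map uniquely to one mitogenome; sex-specific
lifetime reproductive success (LRS, fertile eggs under competition) is
assayed at generations 3 and 33 in the warm regime.

## Synthetic-data generator

`mitosel.simulate` emulates this design layer by layer:

- **Selection + drift.** Haplotype frequencies follow the haploid selection
  recursion `p_i' = p_i W_i / Σ_j p_j W_j`, then drift by a multinomial
  resampling of `n_females` maternal lineages (mtDNA is maternally
  inherited, so drift acts on the female pool only). Default
  `n_females = 300`, half of the ~600 adults maintained per line; the
  realized effective maternal size of the original populations is unknown,
  so this is a free parameter. `deterministic_mode` bypasses all sampling
  and is the oracle used in exactness tests.
- **Planted fitness.** Per-(thermal, nuclear) fitness vectors default to
  CAL fittest and YEM least fit overall (per-generation gaps of roughly
  0.9–1% — the magnitude implied by the end-point frequency shifts this
  kind of experiment produces), with CAL and YEM relatively fitter at 35°C
  and BRA at 23°C, plus a small native-background (mitonuclear) bonus at
  35°C. Selection coefficients are constant; no frequency dependence.
- **Pool-seq.** Two-stage sampling: a multinomial pool of `pool_size = 100`
  individuals, then per-gene read totals Poisson-distributed around
  `total_reads / 13` (default `total_reads = 12,000`, matching ~60×
  effective mitogenome coverage from uniquely mapping zero-mismatch reads),
  allocated multinomially with probabilities ∝ pool fraction × per-gene
  bias factor. Both stages contribute variance; the pool stage dominates
  (SD ≈ √(pq/100) ≈ 0.05 per haplotype). Control samples are generated at
  the exactly known 1/3 composition with the pool stage skipped, mirroring
  controls pooled from pure lines in equal numbers.
- **Phenotypes.** Egg counts are log-normal; a mix line's mean log count is
  the composition-weighted mean of per-haplotype reproductive effects plus
  line, sex and generation terms (defaults: residual SD 0.35 on the log
  scale, line SD 0.08, 19 assays per sex × generation × line, matching the
  assay replication of the design). Female counts are halved into
  `adjusted_eggs` because female assays house two females against one focal
  male in male assays.
- **Mitogenomes.** `synthetic_mitogenomes` builds a 13-PCG genome (a few
  genes on the minus strand) and derives three haplotypes by planting
  verified synonymous/nonsynonymous substitutions unique to each haplotype,
  intergenic SNPs, and one single-base intergenic deletion. All planted
  counts are returned as ground truth.

What the generator does **not** emulate: linkage to nuclear variation,
heteroplasmy, age structure and overlapping generations, non-Poisson
sequencing artifacts (duplicates, strand bias), within-gene read
heterogeneity, or selection changing over time. Passing tests therefore
demonstrate correctness of the inference chain under its own statistical
assumptions, not robustness to every artifact of real sequencing data.

## Analysis stages and numerical choices

- **Bias filter.** Goodness-of-fit χ² (df 2) of observed haplotype counts
  against the known 1/3 expectation, per gene per control sample; BH-FDR
  within each control sample across the 13 genes; a gene is retained only
  if adjusted Q > α (default 0.05) in *every* control sample. The FDR
  scope (within-sample) is a package decision — the alternative (pooling
  all gene × sample tests) is nearly equivalent at these sizes. Genes with
  zero control reads are excluded and reported, never silently retained.
- **Frequencies.** Mean of per-gene read proportions (not pooled counts),
  renormalized to guard against floating-point drift; genes with zero reads
  in a sample are dropped for that sample with a warning. The mean
  per-gene-pair Pearson correlation across samples is reported as a
  consistency diagnostic.
- **Relative fitness.** The t-fold iterated recursion is solved exactly:
  `W_i ∝ (f_i(t)/f_i(0))^(1/t)`, normalized so `Σ_i f_i(0) W_i = 1`
  (initial mean fitness 1). This per-generation reading uses t and
  reproduces ~1% per-generation magnitudes; a one-step variant
  (`mode="one_step"`) is kept for sensitivity analysis. A haplotype at end
  frequency 0 gets W = 0 with a warning — a real outcome of drift, not an
  error. Forward-iterating the returned W reproduces the end point to
  1e-9 (tested).
- **Replicate-line tests.** Mean W per haplotype over lines with a
  bias-corrected (BC, not BCa) percentile bootstrap CI (lines resampled,
  default 9,999 replicates), one-sample t-tests of W = 1, Tukey HSD for
  pairwise haplotype contrasts, and a line-blocked one-way F as the overall
  test. Degenerate (zero-variance) inputs collapse CIs to the point and
  return p = 1 rather than NaN.
- **Compositional ANOVA.** PCA on the 3×3 correlation matrix of the W
  columns; the zero-sum row constraint makes the third eigenvalue
  numerically zero, so PC1+PC2 carry 100% of the variance. Sign
  convention: each component's largest-magnitude loading is positive.
  The between-subjects stratum of the repeated-measures ANOVA is computed
  on the per-line mean of the two PC responses; factors use sum-to-zero
  coding with Type III sums of squares because the realized 23-line design
  is unbalanced; error df = n_lines − 6 (17 for the full design). The
  within stratum (the PC1−PC2 contrast) is reported but non-focal. The
  mitochondrial-Eve replicate is accepted in the design table and ignored
  by default. The Type III engine is a QR-projection implementation so the
  permutation loop can refit thousands of times cheaply; it is verified
  against statsmodels' `anova_lm(typ=3)` to 1e-9 in the test suite.
- **Permutation inference.** Whole lines (the unit of replication) are
  reassigned to treatments unrestricted across both factors;
  `p_rand = (1 + #{F* ≥ F}) / (n_perm + 1)`. When the design admits fewer
  distinct assignments than `n_perm`, all are enumerated and the p-value is
  exact. Observed-F comparisons use a 1e-12 slack so exact ties count.
- **ΔW and PLS.** `ΔW = W33 − W3` per sex, with W the line's mean adjusted
  egg count divided by the CAL pure line's (replicate-averaged) mean at the
  same sex and generation. Both PLS blocks are mean-centered and scaled to
  unit variance (chosen for scale invariance; the loadings are then the
  first singular vectors of the standardized cross-covariance, PLS-SVD).
  `covariance_explained` is the first squared singular value over the sum
  of squared singular values. Bootstrap: lines resampled with replacement,
  replicates sign-flipped when their loading vector's dot product with the
  point estimate is negative (axis-reversal correction), SE = bootstrap SD,
  t = estimate/SE with df = n_lines − 1, BC percentile CIs; degenerate
  replicates are dropped and counted, with a warning above 10%.
- **Divergence.** Near-identity genomes are aligned by anchoring each
  sequence to the first via global affine-gap pairwise alignment and
  merging on reference coordinates (adequate at ~1% divergence; a
  `pre_aligned` path accepts an existing alignment). A gap-free column with
  ≥2 states is one SNP site (three-state columns count once); a maximal gap
  run in one row is one indel event. Coding SNPs are classified in codon
  context — all haplotypes' codons are read through the alignment, minus
  strands reverse-complemented — as synonymous or nonsynonymous under NCBI
  translation table 5 (invertebrate mitochondrial; the organisms force this
  choice), with premature stops flagged. π = differing / total aligned
  non-gap sites, over the whole alignment or PCGs only (both offered; which
  region a given published π used is often unstated). Coordinates are
  0-based half-open internally; GFF3 and 1-based-closed TSV annotations are
  converted on input.

## Reproducibility

One root seed drives everything: per-line streams are derived from
(seed, CRC32(line_id)), and every CLI entry point and the acceptance script
take `--seed`. Two runs with the same seed are byte-identical (tested).
The acceptance script uses 2,999-replicate bootstraps, 1,999 permutations
and 100 replicate experiments for the ranking-recovery rate — sizes chosen
to keep the whole run in seconds while leaving Monte-Carlo error well below
the effects being reported; the test suite uses similar scaled sizes per
test.

## Known limitations

- **Bootstrap PLS loading CIs are anti-conservative under weak or absent
  covariance.** The first-dimension loadings are unit-norm, so under a null
  link they cannot all be near zero, and sign-aligned bootstrap replicates
  correlate with the point estimate (resamples share ~63% of lines). In
  null simulations at n = 11 lines, ~1/3 of nominal-95% loading CIs exclude
  zero. Interpret loading CIs as uncertainty around the fitted direction,
  not as a calibrated test of "no association"; a permutation test of the
  first singular value would be the calibrated alternative.
- **Triple-ranking recovery is noise-limited at realistic effect sizes.**
  With per-generation fitness gaps of ~1% and drift on 300 maternal
  lineages over 23–36 generations, the per-line frequency SD is ≈ 0.16,
  hence a per-line W SD of ≈ 0.014; each pairwise mean-W gap across 23
  lines then has z ≈ 2, and the full CAL > BRA > YEM ordering is recovered
  in ~80% of simulated experiments, not essentially always. Larger
  effective maternal populations (or more lines) raise this quickly.
- The per-haplotype ANOVAs analyze three non-independent responses (the
  zero-sum constraint); they are descriptive companions to the
  compositional test, not independent confirmations.
- The anchor-based aligner assumes near-identical sequences; diverged or
  rearranged mitogenomes should be aligned externally and supplied via the
  pre-aligned path.
- No mixed-model treatment of the assay-level LRS data is provided; the
  package computes the group means feeding ΔW, which is all the PLS stage
  consumes.
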