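# Methods

## Pipeline

The analysis operates on a probes × samples matrix of strictly positive
linear-scale intensities and an annotation mapping each probe to a
probeset (exon) and transcript cluster (gene). Stages, in order:

1. **Quantile normalization** across samples. Every column is replaced
   by the across-sample mean of order statistics at its ranks; ties
   within a column receive the mean of the reference values they span
   (this makes the map well defined and idempotent up to floating-point
   rounding of the reference mean). A single-sample matrix is returned
   unchanged with a warning.
2. **Gene models.** Per transcript cluster, the log2 intensities
   (samples × probes) are fitted with the additive model
   `log2(PM_ij) = m + c_i + p_j + eps_ij` by Tukey median polish,
   sweeping rows (samples) first, then columns, until the largest
   absolute median removed in a sweep is ≤ `polish.tol` (default 1e-4
   log2 units) or `polish.max_iter` sweeps (default 10, the common RMA
   budget; pass `max_iter=50` where full convergence of the residual
   medians matters). Even-count medians are the mean of the two central
   values. The reconstruction `m + c_i + p_j + eps_ij` is exact to
   numerical precision regardless of convergence.
3. **FIRMA scores.** Exon k's score in sample i is the median of
   `eps_ij` over the probes of probeset k, in log2 residual units.
   This is order-equivalent to ratio-scale FIRMA output followed by a
   log2 transform; no scale standardization is applied because all
   downstream use is through dataset-wide percentiles. Scores are kept
   for every probeset with ≥1 probe present, including single-probe
   probesets.
4. **Aberrance thresholds.** Lower and upper percentiles (default 1st
   and 99th) of the *pooled* exon × sample score distribution, linear
   interpolation convention. Pooling over the dataset, rather than
   per-sample thresholds, ties every sample's calls to one common
   yardstick.
5. **Counts and TIN-estimates.** `skip_i = #{k: score(k,i) < lower}`,
   `incl_i = #{k: score(k,i) > upper}` (strict exceedance; values
   exactly at a threshold are not counted, so the flagged fraction never
   exceeds the nominal percentile under ties). The TIN-estimate is
   `T_i = log2(total_i / mean(total))` with the arithmetic mean, so a
   sample at exactly twice the average gets exactly +1.0 and the mean of
   `2^T` is exactly 1. Zero counts are replaced by 0.5 before ratios
   (logged). The alternative reading `rel_skip + rel_incl` is available
   as `tin.mode = "sum_components"`. The TIN-sample cutoff is
   `|T| ≥ 1.0`.
6. **Association.** Per-gene Pearson r against the TIN vector with the
   two-sided Student p from `t = r·sqrt((n−2)/(1−r²))`, n−2 df.
   Zero-variance genes are flagged degenerate and excluded from
   summaries; gene-set members missing from the expression matrix are
   reported, never silently dropped. No multiple-testing correction is
   applied anywhere — set-level inference rests entirely on the
   resampling nulls. Subgroup comparisons use the classic
   pooled-variance two-sample t-test; paired cohorts are scored as
   separate datasets first and their TIN-estimates correlated over
   complete pairs.
7. **Nulls.** Permutation null: B permutations of the TIN vector,
   statistic recomputed for the fixed gene set. Random-gene-set null: B
   uniform without-replacement draws of matched size from the full
   expression universe (focal genes included — the conservative choice),
   TIN vector fixed. Statistics: `pct_significant` (share of
   non-degenerate genes with p < alpha), `neg_pos_ratio` (∞ when no
   positive significant genes), `mean_abs_r`. Empirical p is the
   add-one estimator `(b+1)/(B+1)`, ties counting as extreme; with
   B = 1,000 its minimum is 1/1001 ≈ 0.001. Comparison is one-sided
   ("greater") by default and configurable. Permutations are drawn
   independently per replicate; duplicates are accepted.
8. **Multivariate.** PCA of samples by SVD of the gene-centered data
   (covariance, not correlation; signs fixed by the largest-|loading|
   rule). Hierarchical clustering of samples with Euclidean distance
   and complete linkage (scipy's implementation behind the module
   surface). The TIN separation score restricts to samples with
   `|T| ≥ cutoff` and, for every (high, low) pair, projects on the
   Fisher discriminant of the first two PC scores computed from the
   *other* samples; the score is the fraction of pairs where the high
   sample projects above the low one. Leaving the scored pair out keeps
   the null expectation at 0.5 (a resubstitution version is optimistic,
   ~0.6 at n = 40); 1.0 is perfect separation.
9. **Pooled ("pan-cancer") mode** subsamples `n_per_dataset` samples per
   dataset (per-dataset seeds derived from one root seed), concatenates
   the intensity columns, and recomputes normalization, FIRMA scores,
   thresholds and TIN-estimates across the pool — pooling re-scores, it
   does not concatenate per-dataset results. All bundles must share the
   annotation scheme.

Every stochastic step derives its seed from a single root seed recorded
in the report; reports regenerate bit-identically from config + inputs.

## Synthetic data generator

The generator emulates a post-normalization exon array with known
ground truth. One latent splicing capacity `z_i ~ N(0,1)` per sample
drives both sides of the association:

- splicing-factor genes: `a_gi = mu_g + lambda·z_i + N(0, sf_noise_sd)`;
- other genes: `a_gi = mu_g + N(0, 0.5)`;
- probe affinities `b_p ~ N(0, 0.5)` fixed per probe (pinnable to a
  separate `array_seed` so several datasets share one platform);
- `log2 intensity = a_gi + b_p + N(0, noise_sd)`, exported as `2^x`;
- planted events: `N_i = max(0, round(n0 · 2^(−beta·z_i)))` (or a
  Poisson draw with that mean with `count_model="poisson"`) distinct
  (gene, exon) pairs per sample, all probes of a chosen exon shifted by
  ±delta (inclusion with probability `event_inclusion_fraction`).

High capacity means high splicing-factor expression *and* few aberrant
events, so the planted association is inverse — the minimal mechanism
consistent with splicing-factor loss driving aberrant splicing. With
`beta = 0` the generator is a null model; the deterministic count rule
then produces constant planted counts, so null-calibration studies use
the Poisson option.

Key defaults, chosen once as the study conditions: 60 samples; 300
genes × 8 exons × 4 probes (exon arrays average four probes per
probeset); 40 splicing-factor genes; `beta = 1`; `n0 = 40` baseline
events (~2% of exon × sample cells, which keeps each tail of planted
events near the 1% threshold mass so measured counts track planted
counts); `delta = 3` log2 (comfortably beyond the ±2-ish thresholds
observed on real arrays); `noise_sd = 0.25`; `lambda = 1` with
`sf_noise_sd = 1` — gene-specific expression variation of the same
order as the shared loading, giving per-gene correlation strengths
around −0.6 rather than the unrealistic ≈ −1 of a noiseless loading
(near-collinear factor genes also degenerate the permutation null of
count statistics into an all-or-nothing distribution). Group effects
multiply `N_i` by `2^group_effect` for the affected group; pairing
labels consecutive samples.

What the generator does **not** emulate: CEL-level structure,
GC-content probe bias (replaced by an optional constant offset upstream,
default none), cross-hybridization, spatial artifacts, splicing modes
other than whole-exon shifts, and correlated probe noise. Passing tests
therefore validate the statistical machinery and its calibration, not
robustness to array-specific artifacts.

## Numerical and design notes

- Quantile convention: linear interpolation between order statistics
  throughout.
- Degenerate inputs: all-zero score pools warn and flag nothing (strict
  exceedance); all-zero counts refuse; zero-variance genes are
  excluded from summary denominators; zero pooled variance with unequal
  means in the t-test is a signalled error rather than ±∞.
- The empirical-p distribution of a *discrete* statistic
  (`pct_significant`) is conservative under ties (stochastically ≥
  uniform); uniformity on the grid holds for continuous statistics
  (`mean_abs_r`). The calibration suite checks exactly these two
  properties.
- Pooled fixtures must share array structure (`array_seed`): platforms
  re-drawn per dataset inject probe×dataset batch effects that make
  pooled TIN-estimates dataset-structured and can fabricate
  associations. Tissue-specific expression is emulated as mean-zero
  up/down gene patterns per dataset; uniform whole-set offsets distort
  pooled quantile normalization.
- Problem sizes in the test and analysis suite (20–100 samples, 60–300
  genes, B = 99–1,000, 60–150 replicates for calibration) were chosen
  to make every Monte-Carlo bound sharp at interactive runtimes.

## Known limitations

- Thresholds from small score pools (< 100/lower_percentile values)
  rest on extreme order statistics and are warned about.
- `neg_pos_ratio` is ∞ whenever no significant positive gene exists;
  rank-based comparisons handle this, means do not.
- The t-test is pooled-variance by design; no Welch option.
- Complete-linkage tie-breaking follows scipy's internal order; only
  merge heights, not tie order, are contractual.
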