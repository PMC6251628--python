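# Methods

This note documents the models, estimators and numerical choices behind
each module, the assumptions they make, and what the synthetic-data
generators do and do not emulate.

## Coverage-weighted methylation quantification

A CpG call is a pair (meth reads, total reads); its methylation fraction
x_i and weight w_i = total feed every downstream statistic. Feature-level
methylation is the coverage-weighted median: the smallest x (after
sorting) whose cumulative weight reaches half the total. The lower-median
convention makes the statistic deterministic and, for integer weights,
identical to the ordinary lower median of the weight-expanded sample —
which is how it is tested. Fixed 100-bp tiles use the coverage-weighted
mean instead of the median; the two summaries are deliberately different
because they serve different displays (robust per-feature value vs
global scatter of methylation change). Both require at least 2 CpGs at
≥ 5× coverage; anything less is reported as `insufficient_data`, never as
a number.

Inputs are assumed symmetric-CpG-merged (counts from both strands of a
CpG already summed at one coordinate), the common output convention of
RRBS callers.

## The weighted t-test and its variance estimate

Per region the CpGs at ≥ 5× form the sample in each condition. The test
statistic is Welch's t on coverage-weighted means. The variance of a
weighted mean is estimated as

    var(m) = s² / Σw,   s² = Σ w_i (x_i − m)² / (n − 1)

i.e. the weights are treated as inverse variances (the weighted-least-
squares reading). For binomial fractions with var(x_i) = p(1−p)/w_i each
term w_i(x_i − m)² has expectation p(1−p), so s² estimates p(1−p) and
var(m) estimates p(1−p)/Σw without bias — the estimator stays calibrated
no matter how dispersed the coverage is. Degrees of freedom are
Welch–Satterthwaite with n−1 per group. With equal weights everything
reduces exactly to the standard Welch test (asserted to 1e−9 in tests).

Two alternative variance estimators are exposed via `variance=` for
sensitivity analysis: the Kish effective-sample-size formulation
(n_eff = (Σw)²/Σw², which is conservative under varying weights because
its variance estimate inflates by n/n_eff) and a plain unweighted Welch
test. Degenerate regions (zero variance in both groups) yield p = 1 at
equal means and a flagged p = 0 otherwise.

Simulated calibration at the default study conditions (2,000 null
regions, 10 CpGs, ~30× negative-binomial coverage) is computed by the
test suite and the acceptance script, not quoted here.

## Multiple testing

Storey q-values: π0(λ) = #{p > λ}/(m(1−λ)) on λ ∈ {0.05, …, 0.95},
smoothed with a cubic spline and read off at λ = 0.95, clipped to (0, 1];
q = π0 × BH-adjusted p. The estimate falls back to π0 = 1 (plain
Benjamini–Hochberg) when m < 100 or the estimate is unstable (> 1 or
≤ 0). The λ grid is fixed for reproducibility.

## CGI detection

Thresholds: GC > 0.5, length > 200 bp, obs/exp = n_CpG·L/(n_C·n_G) > 0.6
(obs/exp defined as 0 when C or G is absent). The scan slides a 200-bp
window with 1-bp step, merges qualifying windows (gaps larger than one
window break regions), then trims each merged span 1 bp at a time —
dropping whichever end scores worse on the failing criterion — until the
reported region itself passes all three thresholds; spans that cannot
pass above the minimum length are dropped. Boundary resolution is
therefore one window (±200 bp), and the brute-force oracle used in tests
is the union of all qualifying substrings of the minimal admissible
length (201 bp): longer substrings can pass the thresholds only by
diluting island content across the boundary, so minimal-length substrings
define the boundary ground truth. Detection is strand-symmetric because
CG is its own reverse complement.

Shores are [start−2000, start) and [end, end+2000) clipped at chromosome
edges, with any overlap with islands subtracted. Promoters are
TSS ± 500 bp ("500 bp and 500 bp downstream" is read as symmetric 1 kb);
HCP means ≥ 1 bp overlap with an island. Coordinates are 0-based
half-open throughout; BED on disk.

## Chromatin state

Windows (1 kb H3K4me3 / 5 kb H3K27me3) are centred on the anchor
midpoint — deterministic for variable-length islands; an island-anchored
alternative would shift counts by at most half the island length. A read
counts if its 5′ position falls in the half-open window; fragment shift
is not modeled because inputs are position lists. λ is the mean window
count (the Poisson MLE over all windows); a trimmed-mean option exists
because enriched windows inflate the global mean — at the default 5%
enriched fraction the inflation (~25% at 6-fold enrichment) costs little
sensitivity, so the plain mean remains the default. p(k) = P(X ≥ k) is a
survival function; as a discrete statistic it is conservative, never
anti-conservative. `randomized=True` returns P(X > k) + U·P(X = k),
exactly Uniform(0,1) under the fitted model — the form used for
calibration audits; calling enrichment always uses the deterministic
p-values. States follow from the two enrichment flags alone.

Composite TSS profiles bin signal positions in ±5 kb (100-bp bins),
reflecting minus-strand anchors so negative bins are upstream; unstranded
anchors default to + with a warning.

## Epialleles, discordance, phase correlation

Epialleles are counted over complete reads only by default: partial
patterns would conflate coverage with diversity (deep amplicon data
covers all CpGs of the target; drop counts are reported). Encoding is
M=1, U=0; Pearson correlation on the binaries equals the phi coefficient.
Pairs involving a CpG with zero variance across reads are excluded and
counted. Distance bins default to 25-bp edges spanning the locus.
Discordance eligibility requires ≥ 4 covered CpGs (the convention of the
read-level discordance literature); a read is discordant iff its covered
states mix M and U.

## Susceptibility classifier

Feature table: per track, CGIs above that track's own 99th RPKM
percentile are dropped (literal reading of "filtered out"; a winsorizing
variant was considered and rejected to keep the filter testable), then
CGIs with starting methylation ≥ 0.2 are removed, then log(RPKM + 0.001)
and z-scoring over the retained set (filter first, then normalise, so the
z-columns have mean 0 / sd 1 over the set actually modeled). Natural log
by default; `log_base="log10"` available.

Random forest: 100 trees, class weights {neg: 1, pos: n_neg/n_pos}.
Gradient boosting: depth 10, 10 rounds, subsample 0.7, positive-class
weight n_neg/n_pos. Logistic regression (unpenalised), Gaussian naive
Bayes and a decision tree run at library defaults. Folds are stratified
(plain k-fold at ~20% prevalence would make fold-level PR estimates
unstable) and shared across all ablations so comparisons are paired.
"Recall at 5% FDR" is the largest recall on the pooled out-of-fold PR
curve with precision ≥ 0.95, 0 when never reached; AUC-PR is average
precision.

## Synthetic data: what it emulates, what it does not

All generators draw from one `numpy` Generator seeded explicitly; equal
seeds give byte-identical outputs, and planted truth is returned beside
the data, never written into it.

- **RRBS pairs.** Region baseline m ~ Beta(0.6, 4) — a low-methylation,
  CGI-like baseline (mean 0.13). Coverage is negative-binomial
  (mean 30, shape 5, truncated at 1 read) because RRBS coverage is
  overdispersed. Per CpG and condition an independent Gaussian offset
  (sd 0.02) perturbs m; independence between conditions keeps the two
  samples of a region independent, which is what a two-sample test
  assumes. DMR regions add the effect (default 0.3) to condition B,
  clipped to [0, 1]. 2,000 regions × 10 CpGs is the default problem
  size — large enough for stable rate estimates, small enough to run in
  seconds.
- **Amplicon reads.** Distributive accrual: each CpG independent with its
  site susceptibility (default: 50 CpGs spanning 0.02–0.54, the per-site
  range seen at a deeply sequenced CGI promoter amplicon). Processive
  accrual: a Poisson number of engagement events per molecule, each
  methylating a geometric run (mean 5 CpGs, uniform start, truncated at
  the edge), with the event rate targeting the mean susceptibility. A
  fixed per-molecule target count was rejected: conditioning on the
  total induces a negative long-range correlation that masks the run
  signal. Processive per-site marginals are approximate (edge truncation
  and run overlap pull them slightly below the nominal values).
- **ChIP windows.** Poisson background (λ = 10) with a 5% subpopulation
  at 6× — a sparse strongly-enriched mark.
- **Feature tables.** One latent openness variable drives H3K4me3 and
  DNase up and H3K27me3/starting methylation down, reproducing the
  observed correlation structure; density/GC/H3K36me3 depend on it only
  weakly. Susceptibility is logistic in the features, dominated by low
  H3K4me3, low DNase, high H3K27me3 and higher starting methylation;
  weights are overridable, which is how single-driver and no-signal
  tables for ablation tests are built.

None of the generators model bisulfite conversion error, mapping bias,
M-bias, PCR duplicates, strand asymmetry or spatial autocorrelation of
coverage. Passing tests therefore demonstrate correctness of the
statistics under their stated sampling assumptions, not robustness to
those artefacts in real libraries.

## Known limitations

- The phase-correlation decay statistic (Spearman of binned r vs
  distance) is noisy in the far tail where expected r is ~10⁻³; at
  50,000 reads its value fluctuates around −0.9.
- The trimming step of the CGI scan is greedy; for adversarial sequences
  the trimmed boundary can differ from the optimal trim by more than one
  window, though all reported islands always satisfy the thresholds.
- `call_dmrs` iterates regions in Python; it is comfortable at tens of
  thousands of regions but not genome-wide at single-CpG resolution.
- The hypergeometric overlap treats features as exchangeable units and
  ignores length/composition matching of the two sets.
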