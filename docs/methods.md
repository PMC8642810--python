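# Methods

This note documents the models and procedures implemented in `pedimmune`,
the defaults and why they were chosen, what the synthetic cohort does and
does not emulate, and the numerical decisions a maintainer should know.

## Normalization: TMM and FPKM

Between-sample scaling uses the trimmed mean of M-values. The reference
sample is the one whose 75th percentile of count proportions is closest
to the cohort mean of that percentile. For sample *j* against reference
*r*, over genes with positive counts in both, the log-ratio
M_g = log2((x_gj/N_j)/(x_gr/N_r)) and abundance
A_g = ½·log2((x_gj/N_j)·(x_gr/N_r)) are doubly trimmed — mid-rank-based,
default 30% per tail of M, 5% per tail of A — and the factor is 2 to the
mean of surviving M weighted by the inverse binomial variance
approximation w_g = [(N_j−x_gj)/(N_j x_gj) + (N_r−x_gr)/(N_r x_gr)]^(−1).
Factors are rescaled to geometric mean one so they are comparable across
runs. This is the published TMM recipe in its citable core; reference
implementations carry extra refinements (singleton-trimming guards,
alternative zero handling, weighting toggles) that are deliberately not
reproduced, so factors may differ in the third decimal from theirs on
pathological inputs.

FPKM uses the TMM-effective library size N_j·f_j — TMM scaling is
applied first and feeds through into FPKM: fpkm = x·10^9/(L·N·f). The log2
table adds a pseudocount of 1; downstream statistics are rank- or
threshold-based on raw FPKM, so this only affects reporting.

## ssGSEA

Per sample and gene set, genes are sorted by log2 FPKM descending (stable
sort; ties keep input gene order — FPKM ties are essentially confined to
zeros) and integer ranks G..1 are assigned down the sorted list. The
enrichment score accumulates, over every position, the difference between
the weighted in-set fraction (weights r^α, α default 0.75, the default of
the GenePattern projection module; the original publication used 0.25 —
both are exposed) and the unweighted out-of-set fraction. Scores are
rank-invariant: any strictly monotone transform of a sample's expression
leaves them unchanged, so ranking on log2 FPKM rather than FPKM is
presentational. Optional matrix-wide (max − min) normalization is off by
default: the downstream positive-fraction statistic thresholds at zero
and is unaffected by positive rescaling.

The positive-fraction summary is the percentage of samples per group with
ES strictly greater than zero; group medians use the usual middle-of-two
convention.

## Optimized Kaplan-Meier stratification

Candidate cutoffs are midpoints between consecutive distinct score
values for which both groups satisfy the admissibility bound
max(min_group_size = 5, ceil(min_group_fraction = 0.10 · n)); the bounds
guard degenerate splits and are configurable since the underlying
procedure leaves the scan range open. The two-group log-rank statistic
U²/V uses the hypergeometric variance with the (n_i − d_i)/(n_i − 1)
term and drops risk sets of size one; a degenerate comparison (V = 0)
scores zero. The returned cutoff maximizes χ²; ties break toward the
smallest cutoff (deterministic; favors the larger high-score group).

Because the cutoff is optimized, the nominal χ²(1) p at the optimum is
anti-conservative (in the null calibration below it rejects at ~40–45%
instead of 5%). Significance therefore comes from a permutation test:
scores are shuffled against the fixed (time, event) pairs — the natural
exchangeable null — the full scan is repeated per permutation, and
permutation_p = (1 + #{b : best χ²_b ≥ best χ²_obs})/(B + 1). The
add-one estimator keeps p valid and never zero; its discrete exact level
at α = 0.05 with B = 200 is 10/201 ≈ 0.0498. Everything is vectorized:
group membership across all cutoffs is a boolean matrix whose rows are
permuted per replicate, so one pass of cumulative sums and `reduceat`
evaluates the whole scan for hundreds of permutations at once; results
are bit-reproducible for a fixed seed.

When several signatures are scanned, permutation p-values are computed
per signature and a Benjamini-Hochberg column across signatures is
reported separately, keeping the per-signature and cross-signature
quantities both visible.

## TCR-beta repertoire statistics

Clonotypes are identified by CDR3 amino-acid sequence; duplicate rows
merge by summing counts (nucleotide-level convergence is collapsed).
Sequences containing non-amino-acid characters (stop codons, frameshift
markers) are dropped on read and tallied — a policy choice, since the
upstream assembler's filtering rules are not published.

Normalization reports cpm = 10^6·count/denominator and the intra-sample
fraction count/ΣTCR. The cpm denominator defaults to total sequenced
reads of the sample (natural for clonotypes recovered from RNA-seq),
with total TCR reads as the configurable fallback. Expansion calls use
the joint rule: cpm strictly above the pooled cohort 99th percentile
(pooled over all clones of all samples: one cohort-wide threshold, as
when every clone is plotted on common axes) and fraction strictly above
1%. Per-group
summaries count each patient once.

The overlap partition assigns each distinct cohort CDR3 to exactly one
of: `reference_shared` (present in any reference set — precedence),
`multi_tumor_private` (≥ 2 distinct patients, no reference hit; the
candidate tumor-associated public clones), or `private`. Length
distributions weight each distinct sequence once, not by read count.
Shannon entropy and clonality are auxiliary outputs.

## Differential expression and the antigen screen

The DE engine is intentionally minimal and fully enumerable. Dispersion
is estimated by moments on counts rescaled to the geometric-mean library
size: φ_g = max(0, (s² − x̄)/x̄²) with within-group pooled variance;
common mode takes the median over genes with mean scaled count > 1
(low-count genes carry almost no information about φ and only add
noise). The exact test conditions on the total of the two group sums,
which are NB with a shared success parameter under H0, giving a
closed-form split distribution (binomial at φ = 0); the two-sided p sums
all splits with probability ≤ the observed one (relative tie tolerance
1e-10). Totals ≤ 16384 are fully enumerated. Larger totals use the
log-concavity of the split mass — valid whenever both NB sizes n/φ ≥ 1 —
to locate the more-likely-than-observed window by bisection and sum only
the shorter of the window or its complement (recomputing the direct tail
sum when the complement route would cancel); outside the concave regime
(φ larger than a group size) enumeration proceeds in chunks. Fold
changes are log2((cpm_A + 0.5)/(cpm_B + 0.5)) on group-mean
counts-per-million; the prior damps low-abundance ratios.

The screen applies four criteria per cancer type: p ≤ 1e-5 (unadjusted
— the screen thresholds raw p at an extreme level; a BH column is
emitted for transparency), log2 FC ≥ 4, maximum over vital organs of the per-organ
median FPKM < 1, and median tumor FPKM ≥ 5. Testis and ovary are
excluded from the normal comparator, which is what lets tumor germline
antigens (the PRAME pattern: tumors plus germline tissues, silent
elsewhere) survive. Summaries use medians rather than means for robustness to outlier
samples (configurable). The vital
organ set defaults to heart, brain, cerebrum, cerebellum; only organs
present in the panel are evaluated, but heart and brain must be present.
A candidate must also belong to one of the screened categories
(cell-surface, transcription factor, tumor germline). Externally
computed DE tables can be fed to `screen_candidates` directly.

## Checkpoint-infiltrate association

Within each cancer type (≥ 4 samples), each checkpoint gene's log2 FPKM
is correlated with the per-sample CD8 enrichment score by Spearman rank
correlation with the t-approximation p (exact permutation p is
unnecessary at cohort sizes); BH adjustment is applied within type
across genes (the rule is evaluated per cancer type), and
significance requires rho > 0.3 and q < 0.05, both strict.

## Synthetic cohort

The generator emulates the statistical structure each stage assumes, at
desk scale, with exported ground truth:

* **Expression.** NB counts (dispersion φ = 0.2 by default, Poisson at
  φ = 0) with log-normal baseline expression parameterized on the FPKM
  scale and internally rescaled so realized FPKM tracks the configured
  values. Default cohort: three tumor types × 20 samples and an
  8-tissue normal panel (heart, brain, testis, ovary, lung, liver,
  kidney, muscle × 3) — a scaled-down version of a multi-type pediatric
  cohort with a ~150-sample normal panel. Per-sample depth averages
  3×10^6 with a 3-fold spread. A latent per-tumor immune factor
  N(0, 1) multiplies a 100-gene immune set by exp(factor); planted
  antigen genes (5 per type, 32-fold) are silent across normals, with a
  2-gene tumor-germline subset co-expressed in testis to exercise the
  comparator exclusion. Planted antigens are modeled as 10 kb
  transcripts at 0.4 FPKM baseline so that, after the 0.5-cpm fold-change
  prior, the planted 32-fold effect clears the 16-fold criterion with
  margin while vital-organ medians stay well below 1 FPKM — this is what
  makes the screen's planted-truth recovery exact by construction rather
  than probabilistic.
* **Survival.** Exponential times with hazard h0·exp(−β·factor)
  (β = 1 default: infiltration protective); exponential censoring whose
  rate is calibrated by bisection so the expected censoring fraction
  matches the target (20%). Exponential rather than Weibull keeps the
  censoring calibration closed-form.
* **Repertoires.** Background clone counts follow a deterministic Zipf
  rank-size law (top count 200, exponent 1, 50 clones/sample) with a
  fixed per-sample sequencing depth, so pooled cpm values tie by rank
  across samples and the top rank holds 2% of pooled clones: the pooled
  99th-percentile threshold equals the background maximum and no
  background clone exceeds it *strictly*. Planted expanded clones
  (5 cohort-wide) get counts forced above both criteria; planted public
  clones are injected into two patients each at low abundance and
  withheld from the healthy database; a configurable 10% of background
  sequences is mirrored into the healthy database. CDR3 lengths are
  clipped-normal around 14 within [6, 25], the typical human TRB-CDR3
  length profile (median 14); configurations whose top Zipf rank would hold ≤ 1% of pooled
  clones are rejected as infeasible for exact planting.

What passing tests on this cohort show — and what they do not: the
pipeline recovers planted structure exactly under the generator's
idealized conditions (independent genes, shared dispersion, tie-free
expansion margins, error-free CDR3 sequences). Real cohorts add
correlated genes, library-prep batch structure, dispersion
heterogeneity, assembler artifacts, and patient-level confounding; the
tests validate the statistics' implementations and calibration, not
robustness to those complications.

## Problem sizes and numerical choices

The test suite's simulation scales are chosen for tight Monte-Carlo
bands at interactive runtimes: 500 replicates × 200 permutations for
the null calibration of the optimized-KM procedure, 200 replicates for
cutoff recovery, 2000 genes for exact-test type-I calibration.
`scripts/acceptance.py` uses the generator's defaults (2000 genes, 60
tumors, 24 normals, 3000+ clonotypes) and completes in seconds.

Degenerate inputs are errors, not silent answers: constant scores,
all-censored cohorts, empty gene sets after intersection, zero library
sizes, unmapped samples. Ties are resolved deterministically everywhere
(stable sorts, smallest-cutoff tie-break, strict threshold
inequalities), so every result is bit-reproducible under a fixed seed.

## Known limitations

* The TMM implementation is the published recipe, not a line-for-line
  port of any reference implementation; factors can differ slightly on
  inputs with many zeros or tiny libraries.
* The DE engine replaces quantile-adjusted conditional likelihood and
  empirical-Bayes dispersion shrinkage with a moment/common estimator
  and a group-sum conditional exact test — adequate for screening at
  extreme thresholds (p ≤ 1e-5, 16-fold), not a general-purpose DE
  method at subtle effect sizes.
* Multivariable survival modeling (e.g. metastasis-adjusted Cox) is out
  of scope; the stratified output table is written so such models can be
  fitted elsewhere.
* No MHC-binding prediction, HLA typing, CDR3 assembly, or V(D)J
  segment analysis; clonotype tables are consumed as produced upstream.
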