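# Methods

This note documents the statistical procedures medipdiff implements, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the numerical conventions.

## Data model

Probe-level input is a complete matrix of normalized log2(MeDIP/input)
ratios, probes × samples, with a two-group design (canonical labels
`CPA` for the case group and `control`). Missing values are rejected at
load: the arrays this models are complete after upstream normalization,
and imputation is deliberately out of scope, as is any normalization of
raw intensities. Coordinates are 0-based half-open internally (BED
convention); human-facing reports use 1-based inclusive positions.
Promoter regions are defined in transcription orientation — 1000 bp
upstream to 250 bp downstream of the TSS — so minus-strand promoters
extend downstream in genome coordinates.

## Probe-level moderated t

The two-group comparison uses a pooled-variance (Student) linear model,
not Welch: the effect is the difference of group means of the log2
ratios (case − control), the residual variance is the pooled
within-group variance on n₁+n₂−2 df. Empirical-Bayes shrinkage follows
the standard scaled inverse-χ² hierarchy; the hyperparameters (d₀, s₀²)
are estimated by method of moments on log s²: with
e_g = log s²_g − ψ(d/2) + log(d/2),

* mean(e) estimates log s₀² + ψ(d₀/2) − log(d₀/2),
* var(e) − ψ′(d/2) estimates ψ′(d₀/2),

and d₀ is obtained by inverting the trigamma function with Newton
iteration (bisection-safeguarded, relative tolerance 1e-8). When the
observed dispersion of log s² does not exceed ψ′(d/2) — no evidence of
variance heterogeneity — d₀ = ∞ and s₀² is the arithmetic mean of the
variances; the statistic is then referred to a standard normal instead
of t(d₀+d). Variances at or below 1e-12 are treated as exactly zero and
excluded from prior estimation so degenerate synthetic probes cannot
poison the prior. The implementation reproduces Bioconductor limma's
`lmFit`+`eBayes` to ~1e-13 on a heterogeneous-variance fixture (frozen
as a test oracle). Plain empirical Bayes is implemented; limma's trend
and robust variants are not.

Probe calls require p ≤ `probe_p_threshold` (default 0.05,
intentionally uncorrected — the multiplicity control lives at the
promoter level) and |log2FC| ≥ `min_abs_log2fc` (default 0.25), both
inclusive.

## Promoter-level rank-sum aggregation

Each promoter is tested for enrichment of its probes' t-statistics at
either extreme of the array-wide distribution: a Wilcoxon rank-sum test
of the promoter's probes against **all other probes on the array**, one
sided per direction. The background choice (rest of array, rather than
a per-chromosome or matched background) is the natural reading of
"enriched relative to the array" and is fixed. The promoter p-value is
min(p_up, p_down) and BH is applied once to the pooled list; because
the two one-sided tests are complementary this is slightly anti-
conservative, so a Bonferroni-doubling alternative
(`direction_adjust="bonferroni"`) is available. Single-probe promoters
are allowed (the rank-sum is defined for n = 1). The final call
requires FDR ≤ 0.2 plus at least one same-direction probe call; a
stricter FDR ≤ 0.05 list is also reported.

The rank-sum p-value uses the exact null distribution when the combined
sample has at most 25 observations and no ties, and the normal
approximation with midranks, tie correction and continuity correction
otherwise. For the genome-scale promoter scan the approximation is
computed vectorised from a single global ranking (the combined sample is
the whole array for every promoter, so the tie correction is shared);
the vectorised path is tested to agree with the per-promoter scipy
computation to 1e-10 and with full enumeration on small arrays.

## Genomic clustering

*Chromosome overrepresentation* tests, per chromosome, the 2×2 table of
called/uncalled promoters on/off the chromosome with the hypergeometric
upper tail, BH-adjusted across chromosomes; −log10(FDR) gives the usual
bar heights. The enrichment unit here is the promoter.

*Window scan*: windows of `window_size` (default 500 kb) tile each
chromosome from coordinate 0 — a fixed partition, no sliding or offset
passes. The unit is the probe (assigned by interval midpoint), the test
the one-sided hypergeometric tail of the window's called-probe count per
direction, BH across all windows per direction. Enriched windows are
reported with the called gene promoters they contain.

*Distance correlation*: all intra-chromosomal probe pairs separated by
at most `max_correlation_distance` (default 10 Mb; midpoint distance)
contribute their log2FC pair to the bin of their separation
(`distance_bin_width`, default 500 kb). Per bin: Pearson r (streaming
sums), a 95% Fisher-z interval on the raw pair count, and a 95% null
envelope from `permutations` (default 200) within-chromosome value
shuffles, which preserve the marginal distribution and pair geometry
while destroying positional dependence. Pairs beyond a cap
(`pair_cap`) are uniformly subsampled with the seeded generator. Bins
with fewer than 10 pairs, or with numerically constant values, are
reported with undefined r. Two caveats are documented rather than
hidden: pairs sharing a probe are dependent, so the Fisher-z interval
(raw pair count) is anti-conservative; and the proper comparison
against the envelope is overlap of the interval with the band (as in
the standard correlogram display), since a 95% envelope leaves each
bin outside with 5% probability even under the null.

## CpG density

Normalized CpG density is observed/expected:
`(cpg/(L−1)) / ((c/L)(g/L))`. The dinucleotide denominator L−1 is the
count of dinucleotide positions; a plain-L variant is config-switchable
(`density_denominator="length"`) and differs by <1% for L ≥ 1 kb, so the
choice is immaterial at promoter scale. Densities are undefined (NaN,
excluded from contrasts with the exclusion counted) when a region has
no C or no G. Sequence counting is single-strand; CG is its own reverse
complement, so strand choice cannot change the CpG count. `N` bases are
excluded from base counts but kept in the length — conservative toward
undefined regions. Contrasts between call groups (up-vs-rest,
down-vs-rest, up-vs-down) reuse the two-sided rank-sum. CpG-island
*calling* (threshold rules) is out of scope; only the continuous
statistic is provided.

## Cohort statistics

Continuous variables printed as mean ± SD (n) per group are compared
with the pooled-variance two-sample t-test (df = n₁+n₂−2, matching the
printed df convention of such tables); binary variables with the
two-tailed Fisher exact test by the point-probability method (sum of
hypergeometric probabilities of tables no more likely than the observed
one, within a 1+1e-7 relative tolerance). The packaged reference table
reproduces the published cells t(18) = −0.81, t(17) = −1.06 and
two-tailed p = 0.019, 0.64, 0.10, 0.001. Three printed cells are *not*
recoverable from the printed inputs and are reported as computed, with
the discrepancy noted here rather than forced: the hyperactivity row
(printed p = 0.14; the printed counts 3/12 vs 4/8 give 0.36), the
anxiety row (printed 0.65; counts 1/12 vs 1/8 give 1.0), and the age
row's t (printed −0.26; the rounded summaries give −0.32).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
at the study's design points: two groups of 8 and 12, ~20 000 promoters
(default; tests use hundreds to thousands), a variable number of probes
tiling each −1000..+250 region (default 8–16, matching ~244 K probes on
~20 K promoters), i.i.d. Gaussian probe noise on the log2 scale
(default SD 0.25, chosen so single probes are unreliable and promoter
aggregation is genuinely needed), and a planted fraction (default 5%)
of promoters whose probes all receive a signed shift (magnitude ~
Normal(0.5, 0.15) by default, the middle of the fold-difference range
the original validation experiments targeted) in the case samples only.
Promoters are placed uniformly without overlap (sorted uniform starts
plus cumulative offsets, an exact uniform non-overlap construction);
CpG/C/G counts come from a two-component mixture (island-like vs
depleted) giving a realistic bimodal normalized-density range. Options:
`cluster_block_length` confines planted promoters to random genomic
blocks with one shared direction per contiguous neighbourhood (ground
truth for the window scan and correlogram), and
`cpg_density_link="directional"` makes planted hypermethylation
CpG-rich and hypomethylation CpG-poor with probability 0.9/0.1 about
the median density (ground truth for the density contrast). All
randomness flows from one seed through fixed per-stage child streams;
identical configs give byte-identical files.

What it does **not** emulate — so what green tests do and do not show:
no immunoprecipitation enrichment chemistry or CpG-coupling of the
MeDIP signal (values are generated directly as log2 ratios, the
abstraction level the analysis consumes), no dye bias, spatial array
artifacts, batch effects, probe-sequence effects, copy-number, or
heteroskedastic/correlated probe noise within promoters. Passing tests
therefore demonstrate correctness and calibration of the *statistics*
under their own assumptions, not robustness to array artifacts.

## Problem sizes and determinism

The test and acceptance simulations run at desk scale — 400–1000
promoters over 2–3 chromosomes of 10–20 Mb for calibration and
recovery, 20 chromosomes × 50 Mb with 400 kb probe spacing for the
correlogram — sizes chosen so every property is measurable in seconds
while keeping the relevant effect-to-noise ratios at the study's
values. Sparse probes in the correlogram simulation are deliberate:
dense tiling shrinks the permutation envelope (which scales with raw
pair count) without adding independent megabase blocks. The pipeline
runner fans a single seed out to per-stage sub-seeds and writes a
manifest with SHA-256 digests of all outputs; re-running with the same
inputs and seed reproduces the files byte-for-byte.
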