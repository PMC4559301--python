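# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `medipdmr`.

## Windowing, counting and QC

The genome is tiled into consecutive, non-overlapping fixed-width windows
(default 300 bp, the analysis unit throughout); a trailing sub-width
window is dropped so all windows share one width and the GLM needs no
per-window length offset.  Fragments are assigned to the window containing
their midpoint `floor((start+end)/2)`; the half-open BED convention makes
the boundary rule exact (midpoint 300 belongs to [300, 600)).  Fragment —
not read — counting is used: with paired 100 bp reads and 225–250 bp
fragments, the fragment is the natural sampling unit.

relH, the immunoprecipitation-efficiency QC, is the CpG-dinucleotide
density of the fragment footprints divided by the genome-wide density.
Overlapping fragments double-count deliberately: the score measures what
the library sampled, not which bases are covered.  Samples pass at
relH > 2.0, the working threshold for successful methyl-DNA pulldown
(input controls sit near 1).

The count filter keeps windows with more than `min_count` (default 5,
strict inequality) fragments in at least `ceil(min_fraction * n)` samples.
Full-quantile normalization replaces each sample column's order statistics
with the across-sample mean order-statistic vector; ties within a column
receive the average of their assigned quantile values, which preserves
column sums but means tied columns are equal only up to tie structure.

## The differential methylation model

Raw counts enter a negative-binomial GLM with log link,

    y_ws ~ NB(mu_ws, phi_w),  log mu_ws = o_s + x_s' beta_w,

with per-sample offsets `o_s = log(sum raw_s / sum normalized_s)` linking
the raw scale to the normalized one.  Fitting normalized values directly
would break the NB variance function; raw-counts-plus-offset keeps the
mean model equivalent while the dispersion stays interpretable.

The design is reference-coded: intercept, group (Hi vs Lo), gender, and
IP-batch.  A single-level factor is dropped with a warning; a covariate
aliased with the group (e.g. batch coinciding with group) raises — such a
design cannot separate the effects.

Dispersion is estimated by Cox–Reid adjusted profile likelihood:
`APL_w(phi) = loglik_w(beta_hat(phi), phi) - 0.5 log det(X' W X)`, the
determinant term correcting the bias from estimating `beta`.  The common
dispersion maximizes `sum_w APL_w` (grid over log phi in [1e-6, 5] with a
bounded refinement); the tagwise value maximizes
`APL_w + prior_df * mean_w APL_w`, a weighted-likelihood shrinkage toward
the common value with `prior_df = 10` windows' worth of prior information
(tunable; larger values collapse tagwise onto common).  Per-window maxima
are refined by quadratic interpolation on the log-phi grid.

GLMs are fitted by iteratively reweighted least squares batched across
windows (weights `mu/(1+phi*mu)`, linear predictor clipped at ±30,
at most 100 iterations, relative log-likelihood tolerance 1e-8).  The
group effect is tested by a likelihood-ratio test against the design
without the group column, with p from the chi-square(1) tail;
non-converging windows are flagged and given p = 1 rather than silently
trusted.  `log2fc = beta_group / ln 2`; direction "hypo" means a negative
log2fc (lower methylation signal in Hi).  Benjamini–Hochberg q-values are
computed by the step-up rule, and DMRs are annotated to the gene with the
nearest TSS (start for `+` genes, end for `-` genes; distance ties break
lexicographically on gene id).

The hypo/hyper composition of a DMR subset is tested with a two-sided
exact binomial test against a background hypo fraction (default 0.5, or
the hypo share of all tested windows).

## Interval spatial statistics

Two association statistics are computed between a query interval set
(e.g. DMRs) and a reference track (e.g. SINEs): the Jaccard measure
(intersection bases over union bases of the merged sets) and the
Kolmogorov–Smirnov statistic of the relative distances (query midpoint
position within its flanking reference-midpoint gap, uniform on [0, 0.5]
under independence).  The null repositions every query interval uniformly
within its own chromosome, preserving lengths and allowing overlaps — the
simplest null consistent with "permuting the intervals across the
genome".  Empirical p-values use the add-one rule `(r+1)/(n+1)`; the
Jaccard p is two-sided (doubled smaller tail), the KS p one-sided (larger
D means more different).  Each permutation's KS statistic is computed
against the pooled permutation distribution, itself included; at
n_perm ≥ 200 the resulting bias is negligible.  The analytic KS p against
Uniform(0, 0.5) is reported alongside; the permutation version is primary.

TFBS proximity enrichment expands the top hypo and top hyper DMRs
symmetrically around their midpoints (0 = the native window, then 1, 2,
5 kb), counts overlaps with each factor's merged peak set, and tests the
2×2 overlap table with a Pearson chi-square (1 df, no continuity
correction); 50 % representation is the expectation for equal-size sets.
Degenerate margins (e.g. peaks covering everything) return p = 1.

## CV saturation ("ceiling") analysis

Per window and group, CV = sample standard deviation / mean (n−1
denominator) of normalized counts; windows with non-positive means are
excluded and counted.  The saturation contrast is
`delta_w = CV_Hi(w) - CV_Lo(w)`: near the methylation ceiling
between-individual variance is compressed, so hypomethylated DMRs (Hi
moved off the ceiling) should show positive delta and hypermethylated
DMRs negative delta.  The primary test is a two-sided Mann–Whitney U
between the hypo and hyper delta sets — the one statistic that captures
both directions at once — with per-class Wilcoxon signed-rank tests
against zero reported alongside.  The Mann–Whitney implementation uses
full enumeration of group assignments (midranks for ties) when both
groups have ≤ 8 observations and the tie-corrected normal approximation
otherwise.

## Genetic confounding checks

SNPs are assigned to every DMR whose midpoint lies within `span/2`
(default 900 bp windows) of them.  Allele-class overrepresentation is the
observed / background frequency ratio of the 12 ordered ref/alt classes,
aggregated over the CpG-affecting set {C/T, G/A, T/C, A/G}; MeDIP's
preference for methylatable sequence makes a 3–4× aggregate ratio the
expected signature.  Per-SNP association uses allele-count 2×2 tables
(alt/ref × group) with Pearson chi-square, switching to Fisher's exact
test when any expected cell is below 5, and a Bonferroni line at
`alpha / n_tested` — a deliberate, conservative choice for the
genome-wide threshold.  The methylation-site effect of an allele is
classified from ref/alt alone (C→T and G→A lose a site, T→C and A→G gain
one); flanking-base context is ignored because it is not recoverable from
a genotype table, a documented simplification.  MAF–methylation
correlation is Pearson's r between (alt frequency in Hi − in Lo) and the
mapped DMR's log2fc, stratified by gain/loss × hypo/hyper, omitting
strata with fewer than 3 informative SNPs.

## Motif analysis

Discovery is ZOOPS (zero-or-one occurrence per sequence) EM against a
0-order background estimated from the input sequences (pseudocount 1 per
base, N excluded).  The E-step assigns occurrence posteriors over all
offsets on both strands plus the no-site event; the M-step re-estimates
the 4×w position probability matrix with pseudocount 0.25 and the
occurrence prior (clipped to [1e-3, 1−1e-3]).  Convergence is declared
when the log-likelihood-ratio gain falls below 1e-6 (relative) or after
200 iterations; the LLR trajectory is recorded and must be
non-decreasing.  Starting points matter more than restarts: 500 candidate
subsequence seeds are scored by how well a sharpened version of each
explains one site per sequence, and full EM runs from the best
`n_restarts` (default 10) of them.  Motif width defaults to 12 and is a
free parameter.

Scanning scores both strands with log2-odds sums.  Exact p-values come
from dynamic-programming convolution of the per-column score
distributions under the background after discretizing scores to 1000 bins;
the discretization error is bounded by half a bin width per column.
Benjamini–Hochberg q-values are computed over all scanned positions
pooled across sequences, and a sequence "contains" the motif at threshold
t when its best position has q ≤ t (0.05 and 0.1 are both reported; the
enrichment reconstruction uses 0.1, the more sensitive of the two).
Containment enrichment between hypo and hyper DMR sets is a 1-df
chi-square of the observed hypo/hyper split of containing sequences
against the expected hypo share.

Motif–motif similarity is the maximum over ungapped offsets (both
orientations, ≥ 4 overlapping columns) of the mean column-wise Pearson
correlation, with an empirical p from column-shuffled copies of the query
— a lighter-weight stand-in for a full motif-comparison null model.

## Clustering and disease classes

DMR profiles (rows) are median-centred Z-scores (subtract row median,
divide by row sd; zero-sd rows excluded).  Hierarchical clustering uses
Euclidean distance with average linkage (configurable; the linkage choice
is a genuinely open design point).  Cluster support follows the
multiscale bootstrap: at scales r ∈ {0.5, …, 1.4}, `n_boot` column
resamples of size `ceil(r·n)` are clustered and BP(r) is the fraction
containing the cluster; `qnorm(1−BP)` is regressed on `(sqrt r, 1/sqrt r)`
with delta-method weights, and AU = 1 − Φ(v − c) from the fitted signed
distance v and curvature c.  Clusters with AU ≥ 0.95 are flagged robust.
Degenerate BP profiles (all 1 or all 0 across scales) short-circuit to
AU = 1 or 0, as the regression carries no information there.  The default
`n_boot = 1000` per scale is a desk-scale setting; raise it (the study's
equivalent used 10,000) for publication-grade support values.

Disease-class profiles divide the number of distinct DMR genes annotated
to a class by the class's total gene count, with the user supplying the
gene→class map and class sizes; the fraction of DMR genes with any
annotation is reported alongside.

## The synthetic-data generator

`generate_genome` plants non-overlapping repeats (SINE/LINE/LTR/DNAt/
snRNA/Low, fixed class-typical lengths, densities as genome fractions)
and GC-rich CpG islands into an AT-biased random sequence; genes (2–8 kb,
random strand) are placed independently since real genes contain repeats.

`generate_counts` draws `y_ws ~ NB(mu_ws, phi)` with

    mu_ws = baseline_depth * depth_s * batch_s * g(CpG_w) * m_eff(w, s)
    m_eff = clip(m_w * 2^(beta_w * Hi_s) * eps_ws, 0, 1)

where `g(CpG_w) = 1 + CpG_w / median(CpG)` reproduces MeDIP's CpG-density
bias, `depth_s` and the five batch multipliers are log-normal(0, 0.1),
and the saturation level `m_w` is 0.97 in repeats, 0.70 in background and
0.05 in CpG islands (island status wins when both overlap).  `eps_ws` is
per-individual log-normal(0, `bio_sd`, default 0.3) biological
variability of the methylation level; its clipping at the ceiling is what
generates the CV saturation signature — with `bio_sd = 0` the counts are
exactly NB and carry essentially no ceiling signal, which is the setting
used wherever a property of the pure count model (calibration, dispersion
recovery) is being measured.  Hypo DMRs are planted in SINE windows
(excluding CpG-island windows, which would not survive the count filter)
and hyper DMRs in plain background windows; a +1 log2fc planted at
m = 0.7 saturates to an effective +0.51, an intended consequence of the
ceiling model.  The default effect size `dmr_log2fc = 1` is a free
parameter of the generator, not an estimate from data.

The sample sheet mirrors the target design at its default size: 24 + 24
with the study's gender split (16/13 F in Hi/Lo), five balanced IP
batches, and log-normal cortisol values strictly on either side of the
8.9 fmol/mg grouping threshold.

`generate_sequences_with_motifs` emits each planted DMR's window ± 300 bp
and overwrites a uniform-random stretch with a PWM draw (random strand)
with direction-specific probability (defaults 0.39 hypo / 0.07 hyper, the
containment rates the analysis should reproduce).

`generate_genotypes` places SNPs within ±450 bp of DMR midpoints.  The
background substitution-class frequencies give each CpG-affecting class
0.05 and each other class 0.1: a uniform 1/12 background cannot realize
an observed/background ratio above 3, so the non-uniform background is
what makes a planted factor f (default 3.5, valid up to 5) come out as an
aggregate ratio of exactly f.  Genotypes are Hardy–Weinberg draws with
MAF ~ U(0.05, 0.5), independent of group except for an optional
confounded subset given a strong frequency shift.

Everything is a pure function of the config seed (per-operation child
streams), so equal seeds give byte-identical FASTA/BED/TSV/VCF output.

What the generator does not emulate: mappability and GC artefacts of real
alignment, linkage disequilibrium between SNPs, sequence-driven repeat
families (planted repeats are compositionally plain), copy-number
variation, or cell-composition effects.  Passing tests therefore
demonstrate that the statistical machinery behaves as designed under the
assumed model, not that the biological conclusions of any particular
cohort are correct.

## Problem sizes and numerical defaults

Validation runs use roughly 5,000 windows × 48 samples for calibration
and recovery, 2,000 windows for dispersion recovery, 1,000 permutations
(199 in the repeated-null calibration sweep), 50 sequences × 900 bp for
motif recovery, 852 sequences for the containment reconstruction, and
500-SNP replicates for the genetics null — sizes chosen so each property
is measured with comfortable statistical margin on a single CPU.  Other
fixed numerics: IRLS tolerance 1e-8 (max 100 iterations), dispersion grid
36 log-spaced points with interpolation, scan discretization 1000 bins,
EM tolerance 1e-6 (max 200 iterations), AU scales 0.5–1.4 in steps of
0.1, minimum 100 bootstrap resamples per scale.
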