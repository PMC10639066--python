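# Methods

This note records the models, conventions and numerical choices behind
pausekit, and what the synthetic benchmark does and does not establish.

## Coordinates and quantification windows

All genomic intervals are 0-based half-open. For a gene on the plus strand
the TSS is `start` and the CPS is `end − 1`; minus-strand genes mirror
this. The promoter-proximal window is the 500 nt centred on the TSS (−250
to +250 in transcription coordinates) and the gene-body window runs from
+250 nt downstream of the TSS to 500 nt upstream of the CPS. A gene
therefore needs > 750 nt to have a non-empty body; shorter genes are
skipped with a log record rather than raising, since annotation sets
routinely contain short RNAs that simply cannot be quantified this way.
Counting is strand-matched only: antisense signal, including divergent
upstream transcription that falls inside the promoter window on the other
strand, is never added to a gene's counts. Overlapping genes are counted
independently (no masking); with the synthetic annotation genes are placed
disjoint, and on real data masking is a caller's policy decision, not a
quantification step.

## Pausing index

PI = (promoter count / 500) / (body count / body length). A pseudocount
(default ε = 0.5 reads, added to both windows before forming densities)
keeps the PI defined at zero-count windows; with ε = 0 the statistic is
exactly the density ratio and is invariant to rescaling both counts. PI is
computed on raw counts — it is a within-sample ratio, so sequencing depth
cancels — and the per-condition PI uses replicate-summed counts, which
stabilises low-count genes (a per-replicate-then-average mode is
available). ΔPI is the difference of treatment and time-matched control
PIs, so it is antisymmetric and depth-insensitive by construction.

## Active-gene filter

Model-based detection of transcription initiation (as done with trained
classifiers on run-on data) is replaced by a documented threshold rule: a
gene is active when its promoter-window counts summed over control
replicates reach `min_total` (default 20) and its body window is at least
`min_body_len` (default 500 nt). The rule is deterministic, configurable
and logged; it preserves the role of the filter — exclude untranscribed
annotation — without a model-weights dependency.

## Differential transcription

Size factors are median-of-ratios: per-gene geometric means over genes
observed in all samples form the reference, and each sample's factor is
its median count ratio to that reference. Note the known composition
effect: when a large asymmetric fraction of genes moves (e.g. 30% up),
the factors of the two groups separate slightly and estimated fold-changes
shrink by a few percent. This is inherent to the normalization and is left
in place; estimating factors jointly across all arms of a design (as the
pipeline does) dilutes it.

The test is an NB Wald test without shrinkage: log2FC is the log-ratio of
group means of normalized counts (pseudocount 0.5); the standard error
comes from the NB Fisher information,
Var(mean) = (1/n²) Σ_j (μ/s_j + α μ²); z = log2FC/se against a standard
normal, two-sided. Dispersion α is estimated from a mean-dispersion trend
α(μ) = a₀ + a₁/μ fitted by least squares to per-gene method-of-moments
estimates, clamped to [1e-8, 10]. A per-gene `max(MoM, trend)` mode
exists but is not the default: at two replicates the MoM estimate has ~2
degrees of freedom, and taking a per-gene max converts that sampling noise
into one-sided dispersion inflation that roughly halves power, while the
trend pools thousands of genes and tracks the true dispersion closely.
Measured on a 5000-gene 2-vs-2 null (α = 0.05), the type-I error at
nominal 0.05 is ≈ 0.05 for the trend mode and ≈ 0.04 for the max mode, so
calibration does not distinguish them; power does. All-zero genes are
reported with log2FC 0, p 1 and a flag. With one replicate per group only
the trend mode is meaningful and the fallback is logged.

BH adjustment is the standard step-up procedure with enforced
monotonicity; it is checked against a brute-force implementation.
Classification thresholds are inclusive exactly as stated: DTG
(gene-body Pol II) UP iff padj ≤ 0.05 and FC ≥ 1.25, DOWN iff FC ≤ 0.8;
DEG (steady-state RNA) at padj ≤ 0.001 and |log2FC| ≥ 1. Gene-length
boxplot summaries use type-7 (linear interpolation) quartiles with
whiskers at the most extreme points within 1.5·IQR.

## Metagene profiles

Each gene contributes its sense-strand per-nucleotide density oriented in
transcription direction. Panels: 10-nt bins over [−1000, +1000) around
the TSS (200 bins), the gene-body window split into 50 equal fractions
(mean density per fraction), and 10-nt bins over [−1000, +2000) around
the CPS (300 bins). The cross-gene summary is the unweighted mean; genes
shorter than `min_len` (default 3000 nt) are excluded so the fixed
TSS/CPS windows cannot swallow the scaled body. Tracks are divided by
their size factor before averaging, and replicate profiles are averaged
after profiling.

## Preranked enrichment

Genes are ranked by descending score with deterministic id tie-breaking.
The running sum adds |score|^p / Σ_hits |score|^p at members (p = 1 by
default; p = 0 gives the unweighted statistic) and subtracts 1/(N−Nh)
otherwise; ES is the maximum signed excursion, clipped to [−1, 1] against
float drift. Because a ranking of fold-changes has no sample labels to
permute, the null is random same-size gene sets (default 1000 draws,
shared across sets of equal size). NES divides ES by the mean |null ES|
of matching sign; nominal p is the same-sign null tail with a +1
correction; FDR q compares the null and observed NES tail fractions
within each sign pool, clipped to [0, 1]. Sets that collapse to the empty
set or the whole universe after restriction are skipped with a log
record. If every member score is exactly zero at p > 0 the hit weights
degenerate; the implementation falls back to equal hit weights for that
set.

## Bliss synergy and ΔΔCt

Readouts are normalized to the vehicle well: death-type assays
(cytotoxicity, apoptosis) use (x − vehicle)/(max_kill − vehicle) when a
max-kill reference exists, else the documented fallback
clip(x/vehicle − 1, 0, 1); viability uses 1 − clip(x/vehicle, 0, 1).
Replicates are averaged on the fraction scale before scoring. Per
combination cell, E = fA + fB − fA·fB and the score is 100 × (fAB − E);
the map reports every cell plus the maximum-scoring dose pair and the
matrix mean. The standard two-drug Bliss form is assumed throughout.
ΔΔCt follows the usual 2^−ΔΔCt with a reference gene and vehicle
condition.

## Synthetic generator

The generator emulates a multi-arm inhibitor experiment on cultured
cells: one chromosome, genes placed left-to-right with random gaps of at
least 2000 nt (so they stay disjoint even after ±1000 nt window
extension), strands assigned at random, lengths log-normal
(meanlog 8.6, sdlog 0.6, floor 1250 nt so the body window is ≥ 500 nt).
Per gene, a log-normal body density (sdlog 0.75 — the dynamic range of
active genes after filtering) and a log-normal true PI
(median 4, sdlog 0.5 — typical of paused metazoan promoters) define the
expected signals; the promoter-peak expectation is PI × body density ×
500 nt. Read counts per region are drawn NB(mean, α) and spread to
single-nucleotide positions: peak reads uniformly within a 40-nt pause
window at a per-gene offset drawn from +30..+60 nt downstream of the TSS,
body reads uniformly over [TSS+250, gene end). A Poisson background of
0.001 reads/nt per strand covers the genome so the active-gene filter has
something to reject. Depth is calibrated so the vehicle arm's expected
total equals `depth_per_sample`; treatment arms rescale the promoter and
body expectations of an affected gene subset. Affected sets are decided
by thresholding one per-gene uniform draw against `affected_fraction`,
so arms with equal fractions hit the same genes and a layered arm
(release + block) composes multipliers on that shared set.

The default NB dispersion is α = 0.01. Replicates here are same-passage
culture duplicates of the kind nascent-seq studies typically produce,
whose count reproducibility corresponds to genome-wide dispersions near
0.01; a prior power analysis of the 2-replicate, 2×10⁶-read design also
shows that the body fold-change of 1.5 used in the benchmark sits near
the information bound at α = 0.05, i.e. no calibrated test could detect
it reliably there, whereas α = 0.01 puts it comfortably inside.
The null-calibration benchmark deliberately keeps the harder α = 0.05.

What the generator does *not* model: mappability, batch effects,
spike-ins, UMIs/adapters, enhancer RNAs, overlapping genes, elongation
waves (treatment effects are stationary rescalings, not moving fronts).
Passing the recovery benchmark therefore shows that the statistics
recover region-level occupancy shifts under NB replicate noise — not that
the pipeline is robust to alignment artifacts or annotation errors in
real data.

## Benchmark scales

The recovery benchmark runs 2000 genes on a 40-Mb chromosome at 2×10⁶
reads per sample, 2 replicates × 4 arms, chosen to mirror the affected
fraction and effect sizes of a CDK12-inhibition-style design while
keeping a full run near ten seconds. The null calibration uses 5000
genes; oracle sweeps use 1000 random instances each; the exhaustive
enumeration check of the GSEA nominal p uses C(10,3) = 120 subsets.

## Known limitations

* The Wald test is asymptotic (normal, not t); at two replicates its
  honesty rests on the trended dispersion, which assumes dispersion is a
  smooth function of the mean.
* No fold-change shrinkage: low-count genes have noisy log2FC; the
  classification thresholds are applied to unshrunken estimates.
* Median-of-ratios composition bias under strongly asymmetric change
  (see above).
* GSEA FDR q is the tail-ratio estimator and can be conservative for
  small collections; nominal p resolution is 1/(nperm+1).
* The GTF converter reads only `gene` records with `gene_id`/`gene_name`
  attributes; it is a convenience, not a general GTF parser.
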