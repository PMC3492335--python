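# Methods

## Aberration calling

Each platform is reduced to per-gene binary indicators per sample over
six channels: gain, loss (copy number), hyper, hypo (methylation), over,
under (expression).

**Copy number.** Input is a segmented profile per sample (intervals with
mean log-ratio). A gene takes state *gain* when it overlaps any segment
with value ≥ 0.2 and *loss* when it overlaps any segment with value
≤ −0.2; high-level gain (0.6) and homozygous loss (−1.0) are thereby
merged into gain and loss. The gene-state thresholds are inclusive (a
segment exactly at 0.2 is a gain); the probe-level cuts below are
strict, matching how each convention is printed. A gene spanning both a
gained and a lost segment is listed in both states and flagged as a
conflict — the segment-level analogue of the probe inclusion rule — so
the choice is auditable rather than silent. Genes on chromosomes absent
from a sample's track are skipped with a warning by default
(configurable to an error) and drop out of the shared universe.

**Methylation and expression.** Probe values are compared to the mean of
the designated control samples: deltaBeta = β_case − mean(β_controls),
and similarly for vst-scale expression. The sources phrase both as a
"ratio", but both platforms are log-like scales where the printed
negative cuts (< −0.4, < −1) are only meaningful for a difference, so a
difference is what is computed. Calls are strict: deltaBeta > 0.4 →
hyper, < −0.4 → hypo; vst ratio > 1 → over, < −1 → under; a value
exactly at a cut is not called. Probes collapse to genes by inclusion
(logical OR per channel), so a gene with one hyper and one hypo probe
carries both channels.

**Shared universe.** Downstream stages operate on genes with ≥ 1 probe
on each of methylation and expression and full copy-number coverage,
autosomes 1–22 only. Sex chromosomes are rejected at read time rather
than filtered silently, so an input error cannot masquerade as
filtering.

Quantile normalization (for raw expression intensities) maps every
column onto the mean of the sorted columns, with rank-average
interpolation at ties.

## Integration and recurrence selection

With two channels per platform there are exactly 12 cross-platform
two-way and 8 three-way combinations. For every gene and combination the
recurrence count is the number of samples in which the gene carries all
channels simultaneously; a recurrence curve (genes with count ≥ k for
k = 1..n) summarizes each combination. Selection considers the four
expression-consistent pairs (gain+over, hypo+over, loss+under,
hyper+under) at count ≥ k, default k = 6 of 19 samples (> 30%); "six or
more" is implemented as integer count ≥ k, the percentage phrasing being
informative only. A gene is annotated with every qualifying combination,
not just the first found. The union rule then adds genes whose
over-expression co-occurs with either gain or hypo-methylation (or
under-expression with either loss or hyper-methylation) in a total of
≥ k samples, minus genes already selected — these are reported as
"additional", mirroring how alternative mechanisms for the same
expression change are counted toward one threshold.

## Dependency statistics

Per sample and channel pair (channels from different platforms), genes
are cross-tabulated into a 2×2 table (a, b, c, d) over the shared
universe. The odds ratio (a·d)/(b·c) uses the Haldane +0.5 correction
when any cell is zero (policy `none` reports an infinity flag instead).
Significance is a Pearson χ² test with 1 df, no continuity correction by
default (Yates available behind a flag, since the original convention is
unstated); a degenerate margin yields p = 1 with a flag. p-values are
corrected within each sample's family — the 12 combinations for the
two-way analysis, the strata × states for the conditional analysis —
because the results are presented per sample. Both Bonferroni and
Benjamini–Hochberg are implemented; BH is the default (it is what the
significance markings on the dependency heat maps use) and the method is
recorded in every output row.

The conditional analysis assigns each gene a three-state copy-number
label (gain / normal / loss, normal = neither channel) and expression
label (over / normal / under), then tests hyper-methylation against each
expression state within each CN stratum. Genes that cannot be placed in
a single state (a CN conflict, or both over and under via different
probes) are excluded from the partition and counted per sample in the
output; this keeps each stratum's tables summing exactly to the stratum
size. Empty strata and degenerate tables are flagged not-estimable.

## Copy-number frequency versus gene density

The per-sample segment tracks are re-partitioned at the union of all
breakpoints; each elementary segment carries the fraction of samples
whose covering segment is gained (value ≥ 0.2) or lost (≤ −0.2). The
test statistic is the mean track value inside gene-covered regions,
weighted by covered base pairs per segment; overlapping genes are
flattened to a union of covered bases first so dense loci are not
double-counted. Because it is unstated whether the original weighting
was by base pairs or by segments, a segment-weighted variant (unweighted
mean over segments overlapping any gene) is available behind a flag. The
null hypothesis shuffles segment values uniformly among the fixed
segment positions; the Monte Carlo p-value uses the add-one estimator
p = (1 + #{permuted ≥ observed}) / (n_perm + 1) (≤ for the loss test,
whose alternative is "lower than expected"), so p is never 0 and a
zero-exceedance run at the default 1,000 permutations reports
p ≈ 0.001. Per-arm tests restrict both segments and genes to one arm,
with an independent child seed per arm spawned from the master seed;
arms with < 2 segments are flagged. The arm family is whatever arms
carry genes in the annotation, so an acrocentric-style genome (no p-arm
genes on some chromosomes) simply yields a smaller family — nothing is
hard-coded.

## Differential testing

Methylation is tested on M = log2(β/(1−β)), with β clamped to
[ε, 1−ε] (ε = 1e−6) so the transform stays finite; M is strictly
increasing in β, so deltaBeta-based calls and ΔM agree in sign.
Expression is tested on its vst-like scale directly. Per probe, a
two-sample t-test compares cases to controls — pooled variance by
default because the control group is tiny (n = 2 in the emulated
design) and per-probe variance is unstable; Welch and a minimum-variance
floor are available. These are plain t-tests rather than the moderated
empirical-Bayes variant used by array-analysis toolchains; moderation is
that toolchain's internal machinery and is deliberately out of scope
here. A probe passes when the BH-adjusted p < 0.05 and the absolute
mean difference exceeds the platform cut: 6 on the M scale, 0.5 on the
vst scale. The methylation cut is read as |ΔM| > 6 (the sources are
ambiguous between "M-value > 6" and "fold change > 6"; only the
mean-difference reading uses both groups). Genes collapse by inclusion:
a gene passes if any probe passes.

## Clustering

Sample distance is d(i, j) = 1 − ρ_Spearman(i, j) — not 1 − |ρ| or
(1 − ρ)/2; the transform is recorded in output metadata and
configurable since the original choice is unstated — or Euclidean for
the selected-gene expression heat map path. Linkage is complete
(farthest neighbour), which guarantees monotone merge heights.
Dendrograms serialize to Newick with branch lengths equal to
merge-height differences; k-cuts use the maxclust criterion.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions the pipeline targets: 19 case samples, 2 controls, 22
autosomes. The genome is tiled (default 20 tiles of 1 Mb per
chromosome); a latent Gamma(2, 1) density field per tile drives gene
placement (default 100 genes per chromosome — a deliberately scaled-down
genome of 2,200 genes standing in for the ~12k-gene shared universe of a
real three-platform panel) and, when `density_bias` > 0, tilts
background gain placement toward dense tiles and loss placement away
from them. The centromere sits at a fixed fraction (0.4) of each
chromosome, aligned to a tile boundary; arms matter only for the
per-arm tests, not for any biology.

Copy number: each tile is independently gained (rate 0.2 per case
sample), lost (0.1) or normal; segment values are the state level
(±0.5) plus N(0, 0.05) noise, so planted events clear the ±0.2 cuts by
many noise SDs. Methylation: probe β values are the logistic transform
of a latent normal (gene baseline N(−1.2, 0.6) on the logit scale,
probe offsets N(0, 0.2), noise N(0, 0.3)); planting shifts the latent
by ±3.5, i.e. a deltaBeta of ≈ 0.65 at the typical baseline, and
planted-hypo genes start from a high baseline so the downward shift is
visible. The logistic-latent construction keeps β strictly inside
(0, 1) and makes the ±0.4 deltaBeta cut meaningful at both ends of the
range. Expression: probe baseline N(7, 1) plus a linear-additive
deterministic shift 0.5·(CN state) − 0.5·(methylation shift in beta
units) + (±2.0 for planted over/under) plus N(0, 0.3) noise — the
simplest coupling that reproduces the expected sign structure
(gain→over, loss→under, hyper→under). Each platform draws from its own
RNG stream spawned from the master seed, so enlarging one platform
never perturbs the others.

Planted combinations force their channels jointly in a random subset of
case samples; tiles carrying CN-planted genes have background events
cleared so the planted truth is exact. The ground truth records, for
every gene and sample, the thresholded *deterministic* effect
components — with all noise scales at zero the call matrix equals the
ground truth exactly, which the tests assert. An unsatisfiable
configuration (planted effects that cannot clear the calling thresholds
by 2 noise SDs) raises at generation time.

The `SimulationConfig.null()` preset (no planting, no density bias, no
coupling) raises the methylation/expression noise scales (1.0 / 0.8
latent units) so every channel produces calls at workable marginal
rates; calibration studies then see non-degenerate contingency margins,
which the χ² asymptotics need.

What the generator does *not* emulate: array noise physics (spatial
artefacts, dye/bead effects, detection p-values), SNP-level allele
structure, focal amplicons narrower than a tile, correlated methylation
blocks, and chromothripsis-like rearrangement. Passing tests therefore
demonstrate the correctness and calibration of the analysis logic under
a faithful structural model of the three-platform design — not
performance on any particular real array dataset, whose headline gene
counts depend on platform annotations and preprocessing not reproduced
here.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full design at 2,200
genes × 19 samples for recovery, dependency and density-power
experiments; calibration studies use 200 replicates of a 6-chromosome ×
40-gene null genome with 99 permutations per replicate (the add-one
estimator's p-grid of 1/100 steps keeps the discreteness bias an order
of magnitude below the KS critical value at 200 replicates). Exhaustive
oracle comparisons sweep all 2×2 tables up to n = 10 and all value
permutations of 6-segment tracks. Ties at calling thresholds are
resolved by the strict/inclusive semantics stated above; merge ties in
clustering follow scipy's deterministic ordering; all Monte Carlo paths
take explicit seeds and spawn child streams, never global state.
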