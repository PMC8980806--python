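# Methods

This note documents the models, conventions and numerical choices behind
`cnvpop`, and what the synthetic benchmarks do and do not demonstrate.

## Coordinates and data model

All internal coordinates are 0-based half-open (the BED convention).
Region strings printed for humans (`chr1:50500-51499`) are 1-based fully
closed, so a printed region of length 1000 reads `50500-51499`; the
`onebased` dialect converts on input/output. Abutting half-open intervals
(`end == start`) do **not** overlap — overlap everywhere in the package
means ≥ 1 shared base.

A panel is described by a sample sheet (`sample_id`, `breed`,
`group ∈ {wild, domestic}`); each breed belongs to exactly one group. The
default panel mirrors a 51-bird design: 4 wild red jungle fowl (RJF) and
six domestic breeds (XH, LXG, YOU, SILK ×9, RW, WL ×6, others ×8).

## Read-depth caller

Depth is consumed as 1-kb windows with raw depth, GC fraction and masked
fraction. A window is usable when `masked_fraction ≤ 0.5`.

**GC normalization.** `norm_i = raw_i · m̂ / f(gc_i)` where `f` is a LOESS
fit (span 0.3) of depth against GC, with a deterministic binned-median
alternative (bins of 0.01) for exact reproducibility, and `m̂` a robust
global depth mean. The fitting set excludes candidate CNV windows *before*
fitting: a window is kept only if its 5-window rolling raw depth stays
within 30 % (or 3 robust sds of the ratio, if larger) of a wide 201-window
rolling median. The wide median tracks the slowly varying GC baseline
while a CNV shifts the local ratio by ~50 % per copy, so the exclusion
needs no GC model of its own. This ordering matters: excluding by residual
from a fitted curve is self-masking — a long CNV that dominates a sparse GC
stratum bends the curve far enough to normalize itself away. A second pass
removes CNVs whose wide-median baseline was itself contaminated (two events
within the baseline span) and refits. The final fitting set is exported as
a `fit_used` flag; all null statistics downstream are estimated on it.

**Depth statistics.** The genome-wide mean/sd are obtained by iterative
sigma trimming that centres each pass on the median with a MAD-derived
scale (factor 1.4826) and drops windows beyond 3 scales, then reports the
plain moments of the final set. The robust centre is essential: when CNVs
cover a double-digit percentage of a small genome, a mean/sd-seeded trim
converges to the mixture, not to the diploid mode.

**Segmentation.** Usable 1-kb windows are aggregated into sliding 5-kb
windows (five consecutive usable windows, stepping one window) over the
unmasked sequence budget, so masked blocks shorten runs rather than shift
the grid. A duplication (deletion) core is declared wherever at least 6 of
7 consecutive sliding windows lie above mean + 4 sd (below mean − 4 sd);
heptads sharing windows merge, and the core spans the first to the last
exceeding window. The 5-kb statistics are estimated only on sliding
windows entirely composed of `fit_used` windows — a robust trim over all
sliding windows is still contaminated enough at 10x to hide heterozygous
events.

**Refinement and copy number.** Core boundaries extend outward through
contiguous usable 1-kb windows beyond mean ± 2 sd (same direction) and
shrink past non-qualifying edge windows; a call whose interior retains no
qualifying window is dropped. Copy number is
`2 · mean(norm over interior 1-kb windows) / genome mean`, reported as a
continuous value (integer rounding is left to consumers). Overlapping
refined calls of one direction are unioned. Calls whose estimated CN
contradicts their direction (a "duplication" at CN ≤ 2) are discarded.

Expected operating point (asserted by the tests): on a 10 Mb genome at 10x
with dispersion 0.05, sensitivity and precision ≥ 0.9 and CN mean absolute
error ≤ 0.2 for planted events of 10–100 kb with |ΔCN| ≥ 1; fewer than one
false call per 10 Mb on CNV-free genomes (average over 20 simulations).
Boundary precision is a few windows for strong events; heterozygous events
(|ΔCN| = 1) have intrinsically fuzzy edges at this coverage because a ±2 sd
window test is only ~2 sigma from the diploid mean.

## Deletion consensus

Deletions shorter than 50 bp are removed (half-open length equals the
printed inclusive length). Within each sample, deletions from up to four
callers chain by single linkage under ≥ 1 bp overlap — consistent with the
CNVR rule — and a cluster is retained only when it unites **≥ 2 distinct
callers**; two calls from one caller are not support. The consensus
interval is the union span of the cluster (the downstream CNVR merge
unions regardless, making this low-impact). A reciprocal-overlap linkage
(`min_reciprocal`) is exposed for stricter matching. Consensus deletions
take their copy number from the read-depth caller's window track when
available.

In the end-to-end pipeline the read-depth caller's deletion set serves as
the fourth caller alongside three simulated callers, matching the study
layout in which the duplication-aware read-depth method also contributes a
(small) deletion set.

## CNVR construction and frequency spectrum

CNVRs are the connected components of the ≥ 1 bp overlap graph over all
samples' calls, regardless of type — equivalently the clusters of a plane
sweep. Classes: all-DEL → *deletion*, all-DUP → *duplication*, mixed →
*complex*. Presence is binary per sample; frequency is carriers / all
samples (the panel denominator, not per-population). Categories:
singleton (exactly one carrier, any panel size), low (> 1 carrier,
frequency < 20 %), medium (20 % ≤ f ≤ 80 %; both printed boundaries
assigned inward), high (80 % < f < 100 %), common (every sample). These
partition the CNVR set by construction. Singletons are removed before
annotation-facing summaries.

## Population statistics

**PCA** operates on the column-centred binary presence matrix via full SVD
without variance scaling (0/1 cells are already commensurate), with a
deterministic sign convention (largest-magnitude loading per component made
positive).

**Vst** for one window and two populations:
`(σ²_T − (n₁σ²₁ + n₂σ²₂)/(n₁+n₂)) / σ²_T`, with all variances computed by
the population (divide-by-n) estimator. This convention makes Vst exactly
0 for identically distributed groups, provably confines it to [0, 1], and
gives 0.8 on the hand-checkable case [2,2,3,3] vs [4,4,5,5]. The
sample-variance (n−1) estimator is available via `ddof=1` for comparison
but can leave the unit interval. Zero pooled variance leaves Vst
undefined; undefined windows are excluded from quantiles and scans rather
than set to 0, to avoid diluting them. A float guard clips −1e−16-type
excursions into [0, 1].

**Domestication scan**: Vst of wild vs all domestic samples pooled, per
1-kb window of the copy-number matrix (windows restricted to CNVRs); the
threshold is the (1 − top_fraction) quantile of defined values (default top
1 %), ties at the threshold included; qualifying windows merge into
candidate regions. **Breed-specificity scan**: for each domestic breed,
Vst against each of the other six populations (five domestic + wild); a
window qualifies only if *all six* values exceed 0.4 (windows with any
undefined comparison are conservatively excluded); contiguous qualifying
windows merge into regions. Whether the rule applies to single windows or
merged runs was an open choice; merged runs are reported, with the
per-window table retained.

The planted-scan benchmark sets differentiated loci to ~0.6 % of the CNVR
window budget. That choice reflects the regime the top-1 % scan is built
for — differentiated loci being a small minority of the CNV landscape — and
is a precondition for the quantile threshold to sit below the
differentiated windows' Vst rather than inside it.

## Annotation and expression

Gene annotation is strand-agnostic full-span overlap (≥ 1 bp) against gene
models from GFF3 or BED, via an interval tree whose results are
property-tested against a brute-force all-pairs oracle.

The differential-expression table is an input (or simulated); the package
applies `padj < 0.01` and a direction-symmetric fold-change filter
`max(FC, 1/FC) > 1.5`, then correlates per-breed mean copy number (mean
over a gene's overlapping CN windows, then over each breed's samples) with
per-breed mean expression. Significance is the two-sided p < 0.05 of the
Pearson t transform with n − 2 df — at n = 5 breeds this is numerically
|r| > 0.878, so a hard |r| cut-off is deliberately not used. The number of
breeds entering the correlation is configurable; n = 5 (wild + four breeds
with transcriptomes) is the reference configuration.

## Synthetic data: what it emulates, and what it does not

The generator works at window resolution. Sequenced bases per 1-kb window
are negative-binomial with mean `depth · (cn/2) · g(gc) · 1000` and
variance `m + d·m²`; `d = 0.05` by default (window CV ≈ 22 % at 10x,
matching overdispersed short-read data), `d = 0` degenerates to Poisson
for analytic checks. The GC response `g` is a symmetric quadratic bump
peaking at GC 0.5 with max/min ratio `1 + strength` (default 1.3); any
unimodal curve would serve, since the normalizer must remove it, not model
it. Masked regions are kb-aligned 10–100 kb blocks (repeat clusters and
deserts) totalling 10 % by default; the GC track is an autocorrelated
smooth profile clipped to [0.3, 0.7].

Planted CNVs carry per-breed carrier frequencies: *common* (fixed
everywhere, duplications), *domestication-differentiated* (fixed in wild,
absent in domestic: wild CN ≈ 4 vs domestic 2), *breed-specific* (0.95 in
one breed, 0 elsewhere), and *neutral* — one shared ancestral frequency per
CNV with small per-breed Gaussian drift (sd 0.05). Fully independent
per-breed neutral frequencies would plant genuine breed differentiation,
contradicting the label and the scans' specificity checks.
Differentiated and breed-specific CNVs are centred on gene models by
default so annotation and expression stages have guaranteed substrate.
Carrier status is drawn once per sample per CNV from a stream keyed by
(seed, sample id), so depth evidence, caller call sets and expression
dosage all agree, and adding a sample never reshuffles another's genotype.

Simulated callers see only the carried deletions: each is reported with
probability 1 − FNR if long enough, with Gaussian endpoint jitter; false
positives arrive as a Poisson shower of random 0.2–5 kb intervals. The
four default profiles order the callers the way read-depth, segmentation,
read-pair and split-read methods order in practice (fewest to most calls);
the true error rates of real callers are unknowable here, so these are
qualitative.

Expression for dosage-linked genes is constructed by orthogonalizing the
noise against the breed dosage vector, so the realized Pearson r equals
the requested `dosage_r` exactly (±1 with zero noise as the degenerate
cases); the default −0.9 places dosage-driven genes in the
strong-correlation regime where significance at five breeds is attainable.

What passing these benchmarks does **not** show: robustness to alignment
artefacts, mappability structure beyond a boolean mask, GC curves that are
not unimodal, related individuals, sex chromosomes, or read-level effects
(none of which are modelled). Absolute performance numbers are properties
of the simulation's noise model at the stated sizes, not of any real
dataset.

## Problem sizes and determinism

Benchmarks run on single-chromosome genomes of 2–10 Mb with the 51-sample
panel: large enough for ≥ 4,000 usable 1-kb windows per sample (stable
LOESS and trimmed statistics) while keeping the full suite around two
minutes on one CPU. The end-to-end pipeline is a pure function of
(config, seed): one master seed expands into per-stage, per-sample,
per-caller streams through stable CRC32 tags, and a repeated run is
byte-identical.

## Known limitations

* Heterozygous-event boundaries at 10x are accurate only to a few kb; the
  ±2 sd refinement is a per-window test with no joint segmentation.
* Copy numbers above ~8 saturate the trimmed-statistics separation slowly;
  very-high-copy repeat arrays (CN in the hundreds) are out of scope.
* The consensus treats caller calls as independent evidence; correlated
  errors between real callers (shared alignment) would inflate support.
* CNVR frequency uses the whole-panel denominator; per-population
  frequencies are not computed.
* The expression stage consumes a precomputed DE table; no count-level
  model is fitted here.
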