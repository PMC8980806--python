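# cnvpop

Copy-number-variation (CNV) landscape analysis for multi-breed whole-genome
resequencing panels, built around the study design used for chicken
domestication genomics: a handful of wild red jungle fowl plus several
domestic breeds, sequenced at ~10x, analysed for duplications and deletions
whose frequencies differentiate wild from domestic populations or single
breeds from all others.

The package implements the full chain as a tested, reusable library plus a
thin CLI:

* **read-depth CNV caller** — LOESS GC-bias normalization, robust genome-wide
  depth statistics, duplication/deletion cores wherever at least **6 of 7
  consecutive 5-kb windows (1-kb steps)** exceed mean ± 4 sd, boundary
  refinement with 1-kb windows at mean ± 2 sd, and absolute copy number
  `CN = 2 · norm_depth / genome_mean`;
* **multi-caller deletion consensus** — deletions < 50 bp removed, calls
  from four callers single-linkage clustered by ≥ 1 bp overlap within each
  sample, clusters kept only with **support from ≥ 2 distinct callers**;
* **CNVR construction** — calls from all samples merged into copy-number
  variation regions (CNVRs) by ≥ 1 bp overlap; classes *deletion* /
  *duplication* / *complex*; per-sample presence/absence matrix; frequency
  spectrum (singleton, < 20 %, 20–80 %, 80–99 %, common);
* **population statistics** — presence/absence PCA, and per-window

  ```
  Vst = ( σ²_T − (n₁·σ²₁ + n₂·σ²₂) / (n₁ + n₂) ) / σ²_T
  ```

  computed with population (divide-by-n) variances over 1-kb window copy
  numbers; a wild-vs-domestic scan keeping the top 1 % of Vst values, and a
  breed-specificity scan requiring **all six pairwise Vst > 0.4**;
* **gene annotation** by ≥ 1 bp overlap with gene models (GFF3/BED);
* **expression correlation** — differential-expression filters
  (adjusted p < 0.01, fold change beyond 1.5x either direction) and Pearson
  correlation of per-breed mean copy number with per-breed mean expression
  (at n = 5 breeds, p < 0.05 corresponds to |r| > 0.878);
* **synthetic-data module** — genome layout with repeat masking and a smooth
  GC profile, CNVs planted at controlled per-breed frequencies (neutral,
  universal, wild/domestic-differentiated, breed-specific), per-sample
  negative-binomial window depth with GC bias, per-caller deletion call sets
  with boundary jitter / false negatives / false positives, and expression
  tables with a tunable dosage correlation — everything carries ground truth
  for end-to-end scoring.

Real sequencing data are not required anywhere: the synthetic module
generates every input format the pipeline consumes, and the tests verify
recovery of the planted truth.

## Worked example

The CNVR merge rule on three per-sample deletions (coordinates printed
1-based, fully closed):

```bash
$ cnvpop worked-example
chr1:50500-52199
chr1:53000-53999
```

Sample 1 carries a deletion chr1:50500-51499 and sample 2 chr1:50600-52199;
they overlap by ≥ 1 bp and merge into chr1:50500-52199, carried by samples
1 and 2 but not sample 3, whose deletion chr1:53000-53999 stands alone.

The Vst statistic on a hand-checkable window:

```python
>>> from cnvpop.popgen import vst
>>> r = vst([2, 2, 3, 3], [4, 4, 5, 5])
>>> r.vst, r.sigma2_T, r.sigma2_1
(0.8, 1.25, 0.25)
```

Both groups have within-variance 0.25 and the pooled variance is 1.25, so
Vst = (1.25 − 0.25) / 1.25 = 0.8 — strong but not complete differentiation.

A full synthetic run (51 birds, 3 Mb genome, 20 planted CNVs):

```python
from cnvpop.config import RunConfig, GenomeParams
from cnvpop.simulate import CnvDesign
from cnvpop.pipeline import run_all

cfg = RunConfig(
    seed=1,
    genome=GenomeParams(chrom_len=3_000_000, masked_fraction=0.08, n_genes=60),
    design=CnvDesign(n_neutral=10, n_common=2, n_domestication=2,
                     n_breed_specific=1, length_range=(10_000, 30_000)),
)
report = run_all(cfg, outdir="out")
```

prints (abridged) a report such as

```
"n_truth_cnvs": 20,        "n_cnvrs": 22,
"freq_spectrum": {"singleton": 2, "low": 9, "medium": 9, "high": 0, "common": 2},
"n_domestication_windows": 5,
"n_significant_correlations": 2, "n_negative_significant": 2,
"rd_sensitivity": 0.9919,  "rd_precision": 1.0,
"consensus_sensitivity": 1.0, "consensus_precision": 0.9802
```

i.e. the read-depth caller recovers 99 % of carried events with no false
calls, the 4-caller consensus is 98 % precise, the 20 planted CNVs yield 22
CNVRs (long events can split at masked gaps), and both dosage-correlated
genes come out significant with the planted negative correlation sign.
Every stage also writes its TSV/BED outputs under `out/`.

The same stages are exposed as subcommands (`cnvpop simulate`,
`call-depth`, `consensus`, `build-cnvr`, `pca`, `vst-scan`, `breed-scan`,
`annotate`, `correlate`, `run-all`) for file-based use.

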