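# asearray

Analysis of **allele-specific expression (ASE)** measured on two-color
GoldenGate-style allelic bead arrays — and a synthetic-data generator that
makes every step of that analysis testable against known ground truth.

On these arrays each coding SNP is interrogated by ~30 replicate beads whose
red (Cy5) and green (Cy3) channels report the two alleles. For genomic DNA
the log-ratio `M = log2(Cy5/Cy3)` clusters by genotype (AA, AB, BB); for cDNA
from a heterozygous individual, a shift of M away from the heterozygote
baseline indicates preferential expression of one allele. Getting from raw
beads to trustworthy ASE calls requires a chain of preprocessing decisions —
local background subtraction, array-level QC, within-array normalization of
the two channels, and filtering of probes that do not respond to the alleles
at all — and this package implements that chain together with the machinery
to measure what each decision buys.

## What is inside

- **`asearray.simulate`** — generators for the three study designs with
  recorded truth: gDNA *mixture titrations* (pooling two genotyped
  individuals creates known allelic imbalances at every discordant SNP),
  *dye-swap* control experiments with injected intensity-dependent dye bias,
  and gDNA/cDNA *cohorts* containing non-responding and silenced probes.
- **`asearray.summarize`** — bead-level to per-SNP summarization: per-bead
  `log2R`, `log2G`, `M`, `A = (log2R + log2G)/2`, independent outlier
  removal per quantity (beyond 3 raw MADs from the median), optional local
  background subtraction.
- **`asearray.qc`** — failed-hybridization flagging by channel IQR ≤ 1 and
  within-array quantile normalization of the two channels.
- **`asearray.linear_models`** — SNP-wise OLS across replicate arrays
  (`y_i = X β_i + e_i`), contrasts `α_i = Cᵀβ_i` against the 50:50 baseline,
  empirical-Bayes variance shrinkage with moderated *t* and log-odds (*B*)
  statistics, and dye-effect (intercept) estimation for dye-swap designs.
- **`asearray.roc`** — truth sets from genotype pairs and tie-aware ROC/AUC
  evaluation of SNP rankings.
- **`asearray.filtering`** — per-SNP regression of cDNA on gDNA log-ratios
  over homozygotes (≥3 AA and ≥3 BB), intensity-threshold filtering of
  non-responders, and the interpolation-based heterozygote ASE caller.
- **`asearray.pipeline` / `asearray` CLI** — end-to-end orchestration
  (`simulate`, `summarize`, `qc`, `normalize`, `fit`, `benchmark`,
  `dyeswap`, `filter`, `call`) with deterministic, seed-driven runs.

## Worked example

`examples/mixture_benchmark.py` pools two simulated individuals' gDNA at
proportions 50:50 … 100:0 in triplicate, fits SNP-wise models, contrasts
each mixture against 50:50, and scores the log-odds ranking against the
built-in truth:

```
truth set: 489 true positives, 295 true negatives, 16 excluded (missing genotypes)

AUC by mixture (rows) and preprocessing condition (columns):
condition           bg+nonorm  bg+norm  nobg+nonorm  nobg+norm
contrast
mix_056_vs_mix_050      0.908    0.926        0.870      0.882
mix_060_vs_mix_050      0.993    0.989        0.986      0.980
mix_067_vs_mix_050      0.999    0.999        0.999      0.999
mix_100_vs_mix_050      1.000    1.000        1.000      1.000
```

Two findings are visible at a glance: detection power falls as the pools
approach 50:50 (a 56:44 pool is only a ~1.3-fold imbalance, the hardest to
separate from noise), and the background-corrected conditions (`bg`) beat
their uncorrected counterparts at the subtle mixtures. The other examples
walk the dye-swap analysis (`dye_swap_correction.py`), the bead-level
summarization and QC path (`bead_summarization.py`), and cohort
non-responder filtering plus ASE calling
(`cohort_filtering_and_calling.py`).

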