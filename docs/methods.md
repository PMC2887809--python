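# Methods

This note records the statistical model, the generative model behind the
synthetic experiments, the numerical conventions, and the design choices
made where more than one reasonable option existed.

## The analysis model

### Summarization

Each (array, SNP) pair carries ~30 replicate beads. Four per-bead
quantities are formed — `log2R`, `log2G`, `M = log2R − log2G`,
`A = (log2R + log2G)/2` — and each is summarized by the mean of the beads
surviving a single-pass outlier rule: drop beads more than `k = 3` MADs
from the median of that quantity. Two conventions matter and are exposed as
options:

- **Raw MAD.** The MAD is the plain median absolute deviation, *without*
  the 1.4826 normal-consistency constant (for normal noise, 3 raw MADs ≈
  2.02 σ, so a few percent of clean beads are trimmed). The constant
  changes which beads are outliers; `scaled_mad=True` switches it on.
- **Per-quantity removal.** The four quantities are screened
  independently: a bead can be an outlier in M yet contribute to A. As a
  consequence `mean_M` is *not* `mean_logR − mean_logG`; the summaries are
  averages of per-bead values, deliberately.

The outlier pass is not iterated. Local background subtraction, when
requested, is `fg' = max(fg − bg, floor)` per bead and channel with
`floor = 1` intensity unit, so logarithms stay defined while ordering is
preserved.

### Array QC

Failed hybridizations show compressed signal in both channels. An array is
flagged when the IQR (75th − 25th percentile, linear interpolation) of its
per-SNP `mean_logR` *or* `mean_logG` summaries is ≤ 1 log2 unit. Flagged
arrays are excluded before normalization and before any model fitting. The
IQR is computed on per-SNP summaries, not on raw beads.

### Within-array quantile normalization

The two channels of one array are forced onto a common distribution whose
quantiles are the means of the two sorted channel vectors; each value is
replaced by the target value at its rank, and tied values within a channel
receive the mean target value over their tied ranks. With tie-free inputs
(the generic case for continuous intensities) the sorted normalized
channels are identical multisets and the operation is idempotent; the tie
rule trades exact multiset equality for a deterministic, order-independent
treatment of ties. M and A are recomputed from the normalized channels.
gDNA and cDNA arrays have very different signal distributions and are
always normalized separately, never pooled.

### SNP-wise linear models and moderation

For SNP *i*, the log-ratios across the N retained arrays of one material
follow `y_i = X β_i + e_i`, `Var(e_i) = σ_i² I`, fitted by OLS per SNP with
row-wise deletion of missing arrays (SNPs whose missingness makes X rank
deficient are skipped). Two designs are built in: one coefficient per
mixture, and intercept + swap-sign column for dye-swap data (the intercept
is the dye effect; the ±1 column carries the true allelic signal, which
flips sign when the dyes swap).

Contrasts `α_i = Cᵀβ_i` compare each mixture with the 50:50 pool. This
baseline subtraction cancels SNP-specific offsets — probe affinity
asymmetry, genotype effects, any dye bias constant across arrays — which
would otherwise shift the null away from 0.

Residual variances are shrunk toward a shared prior: the hyperparameters
`(d₀, s₀²)` are estimated by moment-matching the log sample variances to a
scaled-F sampling model (closed-form digamma/trigamma matching, with a
Newton trigamma inverse), the posterior variance is
`s̃_i² = (d₀ s₀² + d_i σ̂_i²)/(d₀ + d_i)`, and the moderated
`t̃ = α̂/(u s̃_i)` has `d₀ + d_i` degrees of freedom. When the moment
estimate of d₀ diverges (no excess spread among the variances) it is capped
at 10⁷. The log-odds score *B* assumes a configurable prior proportion of
truly imbalanced SNPs (default 0.01) and an effect-variance ratio estimated
from the upper tail of the |t̃| distribution, clipped to a coefficient-sd
window of (0.1, 4) log2 units scaled by the median residual variance. One
test pins the whole procedure — t̃, B, d₀, s₀² — to the R reference
implementation (limma) at 1e-8 on a shared fixture. Tests are two-sided;
no multiple-testing correction is applied inside the module because the
benchmarks rank SNPs rather than thresholding them.

### Truth sets and ROC

In a two-individual mixture, discordant genotypes (AA:BB, AA:AB, …) imply a
real allelic imbalance at every unbalanced proportion (true positives);
concordant genotypes are unaffected by mixing (true negatives); SNPs with a
missing (NN) call are excluded. ROC curves sweep the unique scores
descending with tied scores grouped (diagonal segments); the AUC is the
trapezoid area and equals the tie-aware Mann-Whitney probability, which a
property test asserts against an independent rank-based oracle. Direction
of imbalance is not part of the truth, so rankings use two-sided evidence.
The x-axis emitted is 1 − specificity, labelled `fpr`.

### Non-responder filtering and the interpolation caller

Per SNP, the per-individual average cDNA log-ratio is regressed on the
gDNA log-ratio over homozygous individuals only, requiring ≥ 3 AA and ≥ 3
BB so slope and intercept are reasonably estimated. Responding probes have
slopes well above zero that rise with average intensity; non-specific
probes sit near zero slope at low intensity, so a mean-A cutoff removes
most of them. When no cutoff is supplied, one is suggested from the binned
slope-versus-intensity curve: the lower edge of the first intensity decile
whose mean slope reaches half the brightest decile's mean slope. The
fraction is exposed because the appropriate stringency is a study-level
choice.

The heterozygote caller summarizes, per SNP, the AA and BB populations of
both materials by center and spread (robust: median and 1.4826-scaled MAD,
so ±2 MADs is commensurate with ±2 SDs; or moments), then fits three
regression lines *across* SNPs: cDNA center on gDNA center, cDNA upper
bound on gDNA *lower* bound, and cDNA lower bound on gDNA *upper* bound —
crossing the bounds widens the band conservatively. A heterozygous sample
is called `above`/`below` when its observed cDNA log-ratio escapes the band
interpolated at its own gDNA log-ratio. The per-SNP homozygote regression
(filtering) and this global interpolation (calling) are deliberately
separate operations: they answer different questions. With multiple probe
panels, lines should be fitted per panel.

## The synthetic-data generator

The generator is the package's instrument for turning qualitative claims
into tests; its defaults define the simulated study conditions.

**Signal model.** For allele-A fraction θ (diploid dosage mapping AA = 1,
AB = 0.5, BB = 0 over the pooled individuals), a SNP with brightness `S`
emits allele signals `θ·S·2^{κ/2}` and `(1−θ)·S·2^{−κ/2}` into the red and
green channels respectively, plus a per-SNP non-specific floor; each bead
multiplies its channels by `2^{ε}`, `ε ~ N(0, noise_sd)`, and adds local
background. The noise-free, background-free log-ratio is therefore
`log2(θ/(1−θ)) + κ`. Carrying allele A in the red channel makes M increase
with the allele-A fraction; the assignment is a labeling convention with no
downstream consequence (all tests are two-sided and the ROC uses
|evidence|).

Component by component:

- **Probe brightness** `S`: log-normal across SNPs (log2 SD 1.0) around
  4000 (gDNA) or 600 (cDNA) intensity units — cDNA arrays are dimmer, as on
  the real platform, and the spread produces the A-value range the
  intensity analyses need.
- **Probe affinity asymmetry** `κ ~ N(0, 0.7²)` log2 units: allele-specific
  amplification efficiency, constant per SNP. It shifts every baseline away
  from 0 (motivating the 50:50 contrast), sign-flips under dye swap like
  any true allelic signal, and gives the channel distributions the
  continuous spread real arrays show.
- **Non-specific floor**: allele-independent cross-hybridization signal,
  log-normal across SNPs (median 80, log2 SD 0.8), present in both
  channels. It attenuates log-ratios of dim probes and is *not* part of
  the recorded local background — background subtraction cannot remove it,
  matching how the dimmest-pixel estimate behaves on images.
- **Local background**: additive per bead and channel, N(250, 100²)
  clipped at 0. The large SD is spatial (scanner gradients, regional
  artifacts); the recorded background estimate tracks it with only
  pixel-level error (SD 15), which is exactly why subtracting it helps:
  correction removes a real, locally-estimable noise component while
  uncorrected data both attenuates the signal and inherits the spatial
  variability.
- **Bead noise**: multiplicative, log2 SD 0.35 per channel — chosen so
  that with 30 beads and 3 replicate arrays the 56:44 mixture is hard but
  above-random, the regime of interest.
- **Outlier beads**: at rate 0.01, a bead's red channel is displaced by a
  log2 offset sized in multiples (default 5) of the bead population's raw
  MAD, with random sign and enough headroom that the displacement exceeds
  the nominal MAD count.
- **Failed arrays**: listed arrays have their log2 intensities compressed
  toward the array median by a factor 0.08, so the channel IQR of the
  summaries collapses below the QC threshold — scale compression rather
  than dropout, making the IQR the detecting statistic.
- **Dye bias**: added to the whole red channel (signal and background) as
  `2^{intercept + slope·A₀}` with A₀ the SNP's noise-free average log
  intensity. Multiplying the entire channel reflects a dye/scanner gain
  effect and makes the dye-swap intercept recover the injected bias
  exactly in the noise-free limit. The benchmarks inject slope 0.2 with
  intercept −1.5: dim probes lean toward Cy3 (negative), bright probes
  toward Cy5, and the pre-normalization effects are systematically
  positive — the pattern the dye-swap analysis is designed to expose.
- **Mixture series**: defaults to the 17 symmetric proportions
  {0, 5, 9, 17, 33, 36, 40, 44, 50, 56, 60, 64, 67, 83, 91, 95, 100}% of
  individual 1, hybridized in triplicate; benchmarks typically use the
  informative subset {50, 56, 60, 67, 100}%.
- **Genotypes**: independent Hardy-Weinberg draws per individual at the
  configured allele frequency (0.5), giving ~62% discordant pairs — close
  to the truth-set proportions of a real mixture experiment; an option
  forces full discordance. NN calls are assigned at rate 0.01 and resolved
  to a hidden true genotype for signal generation while remaining missing
  in the observed table.
- **Cohorts** are emitted at summary level (per-SNP means with
  SE-of-the-mean noise): the filtering analyses consume summaries only,
  and bead-level detail would add runtime without adding information.
  cDNA responders scale with a log-normal expression level (log2 SD 1.0;
  the distribution is configurable because real expression distributions
  are study-specific); non-responders emit only the floor; silenced SNPs
  express a single allele in heterozygotes.

**Randomness** is split per array from the master seed (and a separate
per-SNP stream for probe-level draws), so adding arrays does not perturb
existing ones and identical configurations are byte-identical.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: spatial structure within an array (the
background model is marginal, not image-based), PCR competition between
pooled templates, copy-number variation distorting the genotype clusters,
probe cross-reactivity correlated between SNPs, and scanner saturation.
The mixture design itself is optimistic about cDNA performance: pooled
gDNA offers a constant template amount per SNP, whereas cDNA template
varies with expression.

## Numerical conventions and degenerate inputs

- Log base 2 throughout; intensities at or below 0 after background
  subtraction are clamped to `floor = 1` before logging.
- IQR uses linear-interpolation percentiles (affects flagging only within
  ~0.01 of the threshold).
- `remove_outliers` with MAD = 0 keeps only values exactly at the median.
- Zero residual df: coefficients are kept, the residual scale is undefined
  and the SNP is excluded from moderation with a warning. All residual
  variances zero (exactly collinear data) is a degenerate prior and raises.
- A mixture that loses all its arrays to QC is skipped with a warning; the
  50:50 baseline cannot be skipped (error).
- Contrast matrices with an all-zero column (zero-variance contrast) are
  rejected.
- `expected_fold_change` raises at the pure 0:100/100:0 endpoints rather
  than returning a sentinel infinity.

## Problem sizes used by the shipped benchmarks

The acceptance script and the end-to-end tests run 1,300-SNP titrations
(triplicate, five proportions) over 6–10 seeds, a 2,000-SNP dye-swap with
8 arrays, 5,000 null SNPs for test calibration, and a 30-individual,
1,000-SNP cohort — sizes chosen to keep Monte-Carlo error well below the
effects being asserted while a full run stays around a minute.

## Known limitations

- The B-statistic's assumed non-null proportion (0.01) is conventional,
  not estimated; rankings are insensitive to it but the absolute log-odds
  scale is not.
- The interpolation caller inherits the global-regression assumption that
  one line family fits all SNPs; probe-affinity offsets push some
  heterozygotes outside the band without true ASE, so its raw calls are
  best treated as candidates to be screened by the slope/intensity filter.
- Quantile normalization couples SNPs within an array: with strongly
  discrete genotype compositions it can compress dim probes' log-ratios.
  The benchmarks quantify (rather than hide) this: normalization helps
  when dye bias is present and is roughly neutral otherwise.
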