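# Methods

## The assay and the unit of analysis

A STARR-seq MPRA places each candidate regulatory sequence in the 3'-UTR of
a reporter driven by a minimal promoter, so an active enhancer transcribes
itself.  After AAV delivery, two library types are sequenced per biological
replicate: viral genomic **DNA** (delivered copy number) and reporter
**RNA** (transcription), plus one previral plasmid **library** sample and
optionally a high-cycle technical RNA replicate.  The unit of analysis is
the amplicon (~900 bp candidate); inputs are an amplicon × sample matrix of
raw de-duplicated read counts, a sample sheet, and an amplicon catalog with
group labels, GC fraction, and an enhancer-ascertainment flag.

## Normalization and inclusion filters

Counts are converted to proportions per sample as `p = (c + 1) / (T + 1)`
with `T` the sample total; the single pseudocount (added to numerator and
denominator) prevents division by zero and means proportions need not sum
to 1.  Two exclusion rules then apply, each logged separately so the
attrition is auditable: minimum raw count across DNA replicates < 200, or
mean proportion across DNA replicates < 2⁻¹⁵.  An amplicon is removed if
either fires.  The mean-proportion rule is evaluated on the DNA replicates
(not the previral library sample), which participates only in QC
correlations; the two readings differ by one flag.

## Ratiometric activity

Per replicate, ratio = RNA proportion / DNA proportion, where proportions
are computed after adding a stabilizer (default 1000) to every raw count.
The stabilizer damps ratios where counts are low (a count of ~1000 is
shrunk toward 1 by about half).  It is applied to counts *before*
proportion conversion; applying it on another scale would be a different
statistic.  An amplicon is ratiometric-active when the replicate mean ratio
exceeds 1.5 **and** the replicate sample s.d. is below the mean — the s.d.
clause rejects calls driven by a single replicate.  Technical replicates
are excluded from every summary; DNA and RNA samples are paired by
replicate id.

## Background-regression model

Enhancer activity is excess RNA relative to what delivery and composition
predict.  The background is modeled by OLS:

    log2(mean RNA proportion) = b0 + b1 * log2(mean DNA proportion) + b2 * GC + e

`b1` near 1 captures basal transcription proportional to copy number; `b2`
absorbs residual GC dependence (GC bias enters at cloning and library
prep).  The training set is the middle 80 % of amplicons ranked by mean
ratiometric activity — `floor(0.10 n)` removed from each extreme, ties
broken by amplicon id — so presumptive actives and dropouts do not distort
the background.  With n = 308 this retains 248.  Residual normality is
checked by a Kolmogorov–Smirnov test on standardized training residuals.

The fitted model is applied to **all** retained amplicons; residuals are
Z-scaled using the mean and s.d. of the full scored set (not the training
set), and the one-tailed p-value is the upper standard-normal tail.  Only
excess RNA is called; strongly negative residuals are reported but carry no
interpretation here.

### Empirical tail-area FDR

q-values are computed from the Z scores against an empirical null:
the non-positive scores are mirrored and a half-normal scale
`sigma = sqrt(mean(z_neg^2))` estimated from them, then

    q(z_i) = min(1, pi0 * n * S_null(z_i) / #{j : z_j >= z_i})

with `S_null(z) = 1 − Φ(z / sigma)`, `pi0 = 1` (conservative), and monotone
non-increasing enforcement in z (cumulative minimum).  This is a compact
tail-area estimator in the spirit of the fdrtool family; exact numerical
equality with that tool is not claimed.  If fewer than two non-positive
scores exist the scale falls back to the full root-mean-square.

### Supporting tests

* Wilcoxon rank-sum (one-tailed, RNA greater) of per-replicate DNA vs RNA
  proportions, per amplicon.  For combined n ≤ 12 the p-value is computed by
  exact enumeration of all rank assignments using midranks, so ties are
  handled exactly; above that, the normal approximation with continuity and
  tie correction.  A one-sided Hodges–Lehmann lower confidence bound for
  the location shift is reported; "shift bound > 0" is the confidence-based
  call criterion.  BH step-up correction across amplicons.
* One-way ANOVA of mean activity across amplicon groups.
* Fisher 2×2 (one-tailed, sample odds ratio a·d/b·c) for
  enhancer-ascertainment enrichment among call sets.

## Annotation enrichment

Annotation interval sets are merged with reduce semantics (book-ended
intervals fuse) before intersecting; an amplicon overlaps a mark when they
share at least one base (0-based half-open everywhere).  Significance is a
one-tailed permutation test: the null redraws `|significant|` amplicons
without replacement from the **library background** — resampling amplicon
identities, not genomic positions — which conditions on the library's own
selection bias.  The Monte-Carlo p uses the add-one estimator
`(#{null ≥ observed} + 1)/(n_perm + 1)`, never zero, with 20,000
resamplings by default and a fixed seed.  On small backgrounds the
estimator agrees with the exact hypergeometric tail to Monte-Carlo error.
Complementary covariate analyses: adding the overlap flag to the background
GLM and comparing `BIC = n ln(RSS/n) + k ln(n)` (k counts coefficients plus
the error variance, consistently between models), and the point-biserial
(Pearson) correlation of the flag with the Z-scaled residuals.

## Allele-level summaries

Long-format allele counts (one row per SNP/sample/base, as produced by
readcount extractors; per-read mapping/base-quality filters are upstream)
pass a mean-base-quality filter (default 25) and a within-sample
allele-frequency floor (default 0.01); SNPs whose surviving alleles number
exactly two are kept.  Reference-allele frequencies are pooled within
sample kind; SNPs with pooled-DNA minor allele frequency above 0.1 are
comparison-eligible, and the DNA–RNA reference-AF Pearson correlation is
reported over them.  No allelic significance test is offered: typical MPRA
depths lack power for moderate allelic differences, so the module reports
frequencies and correlations only.

## Synthetic data generator

The generator emulates the study conditions the analysis assumes, with
defaults chosen once as realistic for this assay class:

| parameter | default | meaning |
|---|---|---|
| n_amplicons | 308 | library size after QC in the emulated design |
| n_dna_reps / n_rna_reps | 4 / 4 | biological replicates (plus 1 library sample and 1 technical RNA replicate) |
| depth_dna / depth_rna | 2×10⁶ | expected reads per sample (~6,500 per amplicon) |
| log_abundance_sd | 1.2 (log2) | amplicon-specific cloning abundance spread; gives DNA replicate correlations ≈ 0.87 at the default dispersion, matching the strong DNA replicate agreement such assays show |
| gc_law | Beta(8, 8) | amplicon GC fractions, mean 0.5, s.d. ≈ 0.12 |
| gc_bias_coeff | 2.5 | log2 representation change per unit GC (cloning PCR bias); representation–GC correlation ≈ 0.25 |
| basal_slope | 0.9 | log2 RNA per log2 DNA (basal transcription near proportionality) |
| rna_gc_coeff | 1.0 | residual GC dependence of RNA beyond copy number (RT/capture efficiency); significant-but-small relative to the DNA term, as observed in such assays |
| frac_active / effect_law | 0.1 / fixed 4.0 | spiked multiplicative enhancer effects |
| dispersion | 0.1 | negative-binomial overdispersion (Poisson at 0) |
| dropout_rate | 0.1 | per-replicate RNA dropout probability, lowest abundance decile only |

Expected DNA/library proportions are
`∝ 2^(gc_bias_coeff·gc + abundance)`; expected RNA proportions
`∝ DNA^basal_slope × 2^(rna_gc_coeff·gc) × effect`; counts are
gamma-Poisson.  The explicit RNA-side GC term is what the background
model's GC coefficient estimates, making GC-recovery checks well-posed:
without it, GC would enter RNA only through DNA and the model's true GC
coefficient would be 0.  Annotation marks cover actives with probability
`p_active` (default 0.8) and inactives with `p_inactive` (0.2); allele
counts are binomial with frequencies shared between DNA and RNA (the
null).  All stages draw from independent streams of a single seed and are
bit-reproducible.

**What the generator does not emulate:** read-level artifacts (alignment,
PCR duplicates), amplicon-specific sequence effects beyond GC,
transduction mosaicism beyond scalar dropout, correlated effects across
neighboring amplicons, and the effect-size distribution of any real
dataset — simulator defaults are set for test power, not fidelity to a
particular experiment.  Passing recovery tests therefore demonstrates the
statistical machinery, not performance on real tissue data.

## Calibration and known limitations

* **Null calibration.** On null simulations (n = 2000, 4+4 replicates,
  dispersion 0.1) the fraction of model p-values below 0.05 is ≈ 0.045–0.05.
  Dropout only fattens the *left* residual tail; calls are one-sided, so
  right-tail calibration survives the default dropout.
* **Trim-selection attenuation.** Ranking by ratiometric activity to pick
  the training set selects partly on the same RNA noise that forms the
  model residuals.  When the ratio ranking is noise-dominated (a pure null
  library), this truncation induces a negative GC–residual correlation in
  the training set and attenuates the fitted GC coefficient by roughly a
  third; with a realistic spiked fraction the ranking is signal-driven and
  the attenuation shrinks to ~10 %.  This is a property of the
  trim-then-fit procedure itself, worth remembering when interpreting
  covariate coefficients on weakly structured libraries.
* **Filter interaction with recovery.** The DNA-count filter removes
  low-abundance amplicons regardless of activity; recovery rates are
  measured among retained actives, since filtered amplicons are outside
  the callable set by design.
* **Problem sizes.** Calibration and recovery checks use n = 2000
  amplicons; permutation agreement uses 4,000 resamplings per instance on
  backgrounds up to 12; the pipeline examples use 200–308 amplicons.  These
  sizes give stable Monte-Carlo behavior while keeping the whole suite in
  seconds.
* **Degenerate inputs.** Constant or collinear predictors raise
  `DegenerateDesignError`; constant vectors raise errors in correlation and
  point-biserial computations; empty or misaligned matrices are rejected at
  validation.  Ties in training-set ranking break by amplicon id;
  amplicons with identical counts receive identical scores.
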