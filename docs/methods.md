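# Methods

This note documents the statistical models implemented in `divescan`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical and design decisions a maintainer would
want recorded.

## Drift model and the synthetic-data generator

`simulate_panel` draws, per SNP, an ancestral frequency `p0` (default
Uniform(0.05, 0.95); a Beta law is available for spectra concentrated near
fixation) and one Balding–Nichols step per population branch: the daughter
frequency is `Beta(p0(1−F)/F, (1−p0)(1−F)/F)`, which has mean `p0` and
variance `F·p0(1−p0)` and keeps frequencies strictly inside (0, 1) without
clipping. Frequencies already at 0 or 1 are treated as absorbing. The
Gaussian model used by the scan is therefore an *approximation* of the
generating process, which is exactly the situation the scan faces on real
data.

Defaults define the emulated study system:

- three populations, focal `JEJ` (island-like), sister `KOR`
  (mainland-like), outgroup `CHS`, with branch drift
  `F = (0.004, 0.004, 0.02)`. Matched focal/sister drift of 0.004 yields a
  realized focal–sister Weir–Cockerham F_ST of ≈ 0.004, the observed scale
  of differentiation between such recently separated groups, and the larger
  outgroup value emulates a deeper split;
- diploid sample sizes `(57, 84, 50)`, matching a small phenotyped island
  cohort plus somewhat larger comparison panels;
- synthetic coordinates: 3 kb spacing, one chromosome per 100,000 SNPs, so
  positional window rules operate on realistic SNP densities;
- mutation rate `μ = 1.25e-8` per site per generation (used only by the
  diversity-based Ne estimate) and a generation time of 27 years.

Two selection mechanisms are available:

- **variance boost** (`n_selected`, `selection_boost`): selected loci use
  `F_focal × boost` on the focal branch. The Beta parametrization requires
  `F_focal × boost < 1`; larger values are rejected as degenerate.
- **sweep footprint** (`SweepSpec`): the focal frequency at a chosen SNP is
  pinned to a target (default 0.07 → 0.33, the allele-frequency contrast
  typical of a strong recent sweep), and flanking SNPs receive a decaying
  fraction (0.55/0.40/0.30 over three SNPs per side) of the same
  displacement. This emulates the *positional* footprint of hitchhiking.
  Genotypes remain unlinked: without some flank signal a swept singleton
  would always be discarded by the window-support rule, which requires a
  second outlier within ±100 kb, so the footprint is what makes the peak
  rules exercisable in simulation. The decay weights were fixed once from a
  pre-registered power analysis of the peak pipeline and are configurable.

Genotypes are Binomial(2, p) per individual; phenotypes are
`intercept + β·dosage + Σ effect·covariate + N(0, σ²)` with covariates
(age, height, weight, dive duration) drawn from Gaussian laws calibrated to
an elderly female diving cohort (age 65 ± 8 y, height 158 ± 6 cm, weight
60 ± 9 kg, dive duration 30 ± 8 s) and defaults β = −10 phenotype units per
allele, σ = 8 — the scale of a diastolic-blood-pressure effect.

Injected artifacts carry ground truth for QC testing: allele flips recode a
designated sample subset as `2 − g` at sites fixed in the realized sample
(the fixed-difference signature of allele-coding errors between merged
panels), and related pairs overwrite one sample with a Mendelian resample of
another (one allele copied from the template, one drawn from the population
frequency — a parent–offspring pair with K0 ≈ 0).

What the generator does **not** emulate: linkage disequilibrium and
recombination (SNPs are independent given the frequencies), sequencing and
imputation error, phasing, admixture and migration, and ascertainment of the
SNP set. Passing tests therefore demonstrate correctness of the statistics
under drift + binomial sampling, not robustness to LD or data artifacts
beyond the two injected classes.

## Selection scan

With outgroup-rooted contrasts `y` and per-SNP scale `s = p̄(1−p̄)`
(unweighted across-population mean `p̄`), the genome-wide covariance is
`C = mean(y yᵀ/s)` over SNPs where every population is called and `s > 0`,
projected onto the PSD cone if sampling noise produces a negative
eigenvalue. Binomial sampling noise is not subtracted: `C` is the covariance
of *observed* contrasts, which is also what the per-SNP test sees.

The alternative replaces `c_ff` by `γ·c_ff` (focal diagonal entry only) and
maximises the Gaussian log-likelihood over `log γ ∈ [0, log 10⁶]` with
bounded scalar minimisation (tolerance 1e-8). A derivative test at the
boundary detects `γ̂ = 1` analytically, so the majority of null SNPs skip
the optimiser. For diagonal `C` the profile likelihood has the closed form
`LLR = z − 1 − ln z` for `z = y_f²/(s·c_ff) > 1`, else 0; the test suite
verifies the numeric optimiser against this form to 1e-6. A ridge
(`1e-9 × mean diagonal`) is added only when `cond(C) > 1e10`, so
well-conditioned models are evaluated exactly.

### The null mass at zero

Asymptotic boundary theory for a one-parameter LRT predicts a 50:50 mixture
of a point mass at zero and χ²₁. That asymptotic argument assumes the
unconstrained estimator of γ is approximately Gaussian around 1, which
requires many observations *per test*. Here each SNP contributes a single
draw: under the Gaussian null the unconstrained MLE of γ is itself a χ²₁
variable, so

    P(LLR = 0) = P(χ²₁ ≤ 1) = 0.683,

not 0.5. Simulation under the full Balding–Nichols + binomial generating
process reproduces this exactly (68% of null SNPs at zero, and slightly more
when the frequency spectrum is discrete or concentrated near fixation). Real
scans of this type show the same behaviour — zero fractions well above one
half. The calibration machinery is insensitive to this because it uses the
99th percentile, far outside the zero mass; the mixture p-values inherit the
conservative 0.5 weight, which makes candidate p-values slightly
conservative rather than anticonservative.

### Calibration

The lowest half of the statistics is discarded (every discarded value ≤
every retained value; when more than half the scan is zero the retained half
still contains zeros, and the zero fraction is reported alongside λ).
`λ = P99(retained)/P99(χ²₁)` by default; a variant computes the percentile
over all statistics (`basis="all"`). All statistics are divided by λ and
p-values assigned as `p = 1` at `LLR = 0`, else `0.5·S_χ²₁(LLR/λ)` — so `p`
is nonincreasing in LLR and equals 1 exactly on the zero class.

## Peak selection

Order-fixed pipeline: (1) outliers are SNPs with `LLR ≥` the empirical 99%
quantile (zeros included in the quantile base; "≥" membership makes ties
deterministic); (2) window support: an outlier needs ≥ 1 other outlier
within ±100,000 bp inclusive; (3) local maximum: an outlier survives only if
it strictly exceeds every other outlier in its window, with exact ties
resolved toward the lower position; (4) single-linkage chaining within 1 Mb
collapses wide peaks (low-recombination regions such as centromeres can
yield multi-megabase signal runs; the chain distance is configurable and an
explicit exclusion list can replace it); (5) top-n peaks (default 10) by
representative LLR, ties broken by chromosome then position. Gene
annotation attaches every gene interval (1-based inclusive, GFF3
convention) overlapping a candidate's representative SNP.

## Association

OLS of the untransformed phenotype on allele dosage plus age, height,
weight, dive duration, optionally age², and the first 10 PCs of the
analysed samples' standardized genotype matrix (dosages mean-imputed,
centred by 2p̂, scaled by √(2p̂(1−p̂))). Complete-case analysis; the genotype
coefficient is reported in phenotype units per alternate allele with a
two-sided t-test on residual degrees of freedom. Rank-deficient designs fail
loudly, naming the collinear column. Family-wise control is Bonferroni,
`α/m` over the m candidates; a within-population re-test is available to
check whether an association is driven by between-population frequency
differences. Diagnostics: median-based genomic-control λ on a p-value
collection, and pooled-variance (default) or Welch unpaired t-tests for
group comparisons. The age² covariate (not age¹) is used for the nonlinear
age term, the convention of blood-pressure GWAS. No medication-use
covariate exists in the model, mirroring the data limitation of the study
design this emulates.

## QC

- **ExcHet**: one-sided exact test against heterozygote excess using the
  exact conditional (Levene–Haldane) distribution of the heterozygote count
  given allele counts, computed in log space; sites with `p ≤ 1e-6` are
  removed. `p = 1` whenever no heterozygotes are observed.
- **MAF**: minor-allele frequency across all samples jointly; default
  threshold 1%.
- **Allele flips**: variants where one panel is fixed for REF and the other
  for ALT (tolerance ε, default exact fixation) are flagged as apparent
  fixed differences; with biologically plausible drift these arise only
  from allele-coding errors.
- **Relatedness**: K0 (probability of sharing zero alleles IBD) estimated by
  the method of moments: observed opposite-homozygote (IBS0) count divided
  by its expectation for an unrelated HWE pair, `Σ 2p²(1−p)²`, truncated to
  [0, 1]. Duplicates and parent–offspring pairs give K0 ≈ 0; unrelated pairs
  ≈ 1. Pruning iteratively flags pairs on the configured side of the 0.75
  threshold and removes the later sample of each flagged pair until no pair
  is flagged. The comparator direction is configurable because published
  usage of "K0 > 0.75" as a *relatedness* criterion inverts the
  conventional semantics (high K0 = unrelated); the default here flags low
  K0. The estimator needs enough informative sites: with ~30 expected IBS0
  events (a 1,000-SNP panel) its coefficient of variation is ~18% and the
  0.75 threshold is not separable from noise; ≥ 10,000 SNPs is the
  recommended scale, and pairs with < 100 overlapping calls are rejected.
- Filter order in the pipeline: biallelic → ExcHet → merge/flip removal →
  MAF.

## Population-genetic statistics

- **F_ST**: Weir & Cockerham (1984) two-population variance components
  (a, b, c) with the multi-SNP estimate as the ratio of averages
  `Σa / Σ(a+b+c)`, never the average of per-SNP ratios; monomorphic input is
  flagged undefined rather than returned as 0.
- **π**: per site `2p̂(1−p̂)·2n/(2n−1)` (the unbiased estimator, equal to the
  mean pairwise haplotype difference computed without replacement), summed
  per window and divided by window length; windows are 1-based inclusive,
  converted to 0-based half-open only at BED export. `Ne = π/(4μ)`.
  Per-chromosome Ne estimates are combined by unweighted mean.
- **PCA**: eigendecomposition of the sample covariance of standardized
  dosages; monomorphic variants dropped, missing calls mean-imputed. Scores
  are orthogonal across axes and defined up to sign.

## Numerical and testing notes

- All generators are pure functions of (parameters, seed); every stochastic
  test is seeded and every expected value in the suite was computed from an
  independent oracle (exact-fraction enumeration for ExcHet, hand-evaluated
  variance components for F_ST, closed-form profile likelihood for the
  scan, normal equations for OLS, brute-force interval/window enumeration
  for peak rules).
- Problem sizes used by the test suite and the acceptance script — 20,000
  SNPs for null-scan summaries, 50,000 for F_ST recovery, 2,000-SNP panels
  for 160 two-stage replicates — were chosen as the smallest sizes at which
  the Monte-Carlo error is comfortably inside the asserted tolerances.
- Known limitations: no LD-aware clumping (candidates from one sweep are
  deduplicated positionally, not by correlation); the K0 estimator is a
  desk-scale approximation to likelihood-based relatedness inference from
  genotype likelihoods; the scan's Gaussian model is used outside its
  asymptotic regime at per-SNP resolution (see the null-mass discussion
  above); and the generator's no-LD assumption means power estimates for
  the peak rules depend on the sweep-footprint parametrization.
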