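# Methods

This note documents the models behind `chronotx`, the defaults that matter,
what the synthetic generator does and does not emulate, and the numerical
choices made where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Temporal discretization

Death times are stored as integer minutes since midnight; sub-minute inputs
are truncated toward zero. The fixed clock intervals — day [08:00, 17:00),
night [21:00, 05:00), twilight otherwise — partition the 24-h circle into
540 + 480 + 420 minutes. Both intervals are half-open exactly as written, so
17:00 is twilight and 05:00 is twilight while 04:59 is night. No
sunrise/sunset or geography-aware daylight model is attempted: the fixed
intervals are the operative rule, chosen once to keep day and night
unambiguous across the year. Seasons are taken verbatim from metadata —
with only a season of death on record there is no date to infer them from.

## Synthetic cohort generator

The generator emulates a 932-donor postmortem cohort: death times uniform on
[0, 1440) minutes, seasons multinomial with probabilities proportional to
(190, 221, 282, 239) for spring/summer/fall/winter, two-thirds male, ages
normal around 55 y (SD 12, clipped 21–80), BMI normal around 27 (SD 4.5),
postmortem interval uniform 1–24 h. Uniform death times slightly overweight
twilight relative to a real cohort but exercise every boundary of the label
intervals, which is the point of the fixture.

Counts for gene g in sample s are negative binomial with mean
μ_gs = L_s · 2^{η_gs} / Z and variance μ + φμ² (dispersion φ = 0.1 by
default; φ = 0 falls back to Poisson). The log2 mean is additive:

* baseline: uniform on [3, 9] log2 units;
* `daynight` genes (5%): amplitude · cos(2π(t − phase)/24), amplitude
  uniform on [0.5, 1.5] log2, phase uniform on [0, 24) h — the amplitude
  floor of 0.5 matches the effect scale at which the sensitive threshold is
  meant to operate, and uniform phases deliberately include peaks at
  twilight, where a day-night contrast has little power;
* `seasonal` genes (5%): a ±amplitude offset (uniform [0.5, 1.5]) in one
  uniformly chosen target season;
* `covariate_only` genes (5%): a ±0.3 log2 effect per SD of one covariate
  (sex as a binary offset) — temporal nulls that stress the covariate
  adjustment;
* the rest are nulls.

Library sizes are uniform on [1, 2] × 10⁶; gene lengths log-normal with
median 2 kb (σ_log = 0.6), present solely to exercise the TPM path. Missing
donor × tissue combinations are simulated by Bernoulli thinning with a
per-tissue sampling probability. Every output is a deterministic function of
the config seed (independent substreams per stage).

What the generator does **not** emulate: postmortem RNA-degradation
programs, isoform-aware quantification (one length per gene, whereas real
TPMs are transcript-aware), batch or ancestry structure, donor-level
correlation across tissues, and non-uniform death-time distributions.
Passing tests therefore demonstrate the statistical machinery under a clean
additive model, not robustness to those real-data artifacts.

## Expression filtering

TPM divides counts by gene length and rescales each sample to 10⁶; an
all-zero sample yields an all-zero column with a warning. The recurring
eligibility rule keeps genes with median TPM ≥ 1 over the contrast samples,
with the even-count median taken as the midpoint mean so a gene at exactly
1.0 is kept. Day-night analyses filter on the day+night samples only;
seasonal analyses filter on all samples — the two filters legitimately
differ, which is why the expressed-gene universes of the two analyses need
not coincide.

## Differential model

TMM scaling factors are computed natively: the reference sample is the one
whose upper-quartile of library-scaled counts is closest to the mean
upper-quartile; per sample, M-values are trimmed 30% on each side and
A-values 5%, and the surviving M-values averaged with inverse
asymptotic-variance weights; factors are rescaled to geometric mean 1. The
precision-weight stage uses log2 CPM with a +0.5 count offset and +1 library
offset, a lowess trend (span 0.5) of √(residual SD) against mean log2 count,
and weights equal to the trend value at each observation's fitted log-count
raised to the −4th power. These three constants follow the published
defaults of the upstream normalization/weighting chain and are recorded here
as configuration. The empirical-Bayes prior (d₀, s₀²) is estimated by
moment-matching the log residual variances against a scaled-F model
(trigamma inversion by Newton iteration); d₀ = ∞ (fully pooled) and d₀ = 0
(no moderation) are supported as explicit limits. The test suite pins this
implementation against `edgeR::calcNormFactors` and the
`voom`/`lmFit`/`eBayes` chain run through Rscript on a small fixture;
agreement is at machine precision for TMM and within ~10⁻⁴ relative on
p-values for the moderated fit.

Covariates enter as stated by the design: age, BMI and postmortem interval
as linear numeric terms; season (day-night runs) or day/night/twilight
(seasonal runs) as treatment-coded factors with the alphabetically first
level as reference; sex as a male indicator, dropped for sex-specific
tissues. The reported log2FC is the group coefficient itself (day = 1, or
target season = 1), so positive always means "up in day" / "up in the target
season". Rank-deficient designs abort with the aliased columns named. Each
tissue is analyzed independently; one sample per donor per tissue is
assumed, and no surrogate-variable or random-effect modelling is attempted.

## Window scan

Twelve pairs [i, i+6) vs [i+12, i+18) hours (mod 24), i = 0..11, hourly
steps. Each pair reuses the day-night model with the temporal grouping
replaced by the arc indicator; season stays a covariate, and the expression
filter is computed once from the whole tissue (one filter, twelve tests).
Per gene the twelve nominal p-values are BH-adjusted; circadian-like means
any pair with adjusted p ≤ 0.05 and |log2FC| ≥ 0.1. Note an index subtlety:
the arcs of pair i reappear with groups swapped only at i+12, which is
outside the 0..11 range — all twelve pairs are therefore arc-distinct
contrasts. Pairs with fewer than two samples in either arc are skipped and
recorded. Ties in the best-pair selection break toward the smaller nominal
p.

## Lomb–Scargle scan

The variance-normalized floating-mean periodogram is evaluated on a period
grid of [20, 28] h at 0.1-h resolution (both configurable) — the standard
defaults for hour-resolved circadian scans. The peak-power p-value is the
single-frequency beta tail (1 − z)^((N−3)/2) combined with the Baluev (2008)
aliasing-free bound for the scanned band,
FAP = 1 − (1 − p₁)e^(−τ) with τ = γ·W·√z·(1 − z)^((N−4)/2) and
W = Δf·√(4π·Var(t)); with death times spanning a single 24-h clock the band
contains roughly one independent frequency and the correction is small but
keeps the white-noise exceedance rate at the nominal level (checked by
simulation in the test suite). An exact permutation p-value is available
when the approximation is unwanted. Constant series get power 0 and p = 1.
Peak phases of rhythmic genes missed by the day-night contrast are binned
into day / night / twilight / "within 1 hour of the twilight", the last
taking precedence within 60 min (strict) of any twilight-interval edge.

## Aggregation and exact tests

Direction profiles take the sign of log2FC for sensitive calls only. Three
exact two-sided binomial tests per gene (all / non-brain / brain scopes, the
two-sided p summing all outcomes no more probable than the observed one)
define high-confidence membership at p ≤ 0.05 in any scope; the per-scope
direction is the majority sign, so a gene can carry opposite directions in
brain and non-brain scopes and contribute two directional calls but one
unique gene. Brain tissues default to GTEx-style names beginning "Brain",
overridable by a tissue-class table. The consistency-ratio test uses the
literal strict rule (day fraction < 0.25 or > 0.75): note the resulting
chance probability is *not* monotone in the number of tissues (k = 4 gives
0.125 but k = 5 gives 0.375, because 1/5 < 0.25), a sawtooth the tests pin
against enumeration. Seasonal high-confidence sets are built per season with
the identical construction. "Strongly seasonal" entries are sensitive calls
with |log2FC| ≥ 1 (at least two-fold), boundary inclusive.

## Resampling nulls

Label permutations shuffle the full day/night/twilight vector (or the
binarized season-of-interest vector) with the label multiset preserved
exactly, *before* any filtering: each permutation repeats twilight removal,
the median-TPM filter and the moderated fit from scratch. The study-scale
default is 1,000 permutations per tissue; tests run scaled down.

The marker randomization redistributes each cell type's observed up- and
down-instance totals uniformly over the region × season cells, rejecting
draws that put both signs in one cell (the observed tables never mix signs
within a cell, and the null conservatively preserves that). The empirical p
is the fraction of draws with a count ≥ observed, with no +1 correction,
Bonferroni-corrected by the number of cell tests (260 at study scale:
13 regions × 4 seasons × 5 cell types) and row tests (20: 4 × 5). Because
the redistribution mechanics are not uniquely determined by a verbal
description, the instance-level assignment with rejection is the default and
an alternative cell-level sign assignment is available
(`scheme="cell_sign"`); a tiny-grid exhaustive enumeration is the
correctness anchor for the default. Rejection sampling is vectorized and
bounded; pathological tables that would drive the acceptance probability to
zero raise rather than loop.

## Cross-species concordance

Evidence from another species is either a direction or a peak phase; phases
map to day/night through the *human* clock intervals (no species-specific
light schedule is modelled — a documented convention, since no mapping rule
is uniquely implied), and twilight phases exclude the pair with the reason
recorded so pair counts stay auditable. Only pairs significant in both
species are classified. Concordance is the exact one-sided binomial tail
P(X ≥ k), X ~ Binomial(n, 0.5), in the requested direction. Set overlaps use
the Simpson coefficient |A∩B|/min(|A|,|B|) and the one-sided hypergeometric
tail. A generic two-sample proportion test (χ² without continuity
correction) is provided for set-vs-genome rate comparisons.

## Numerical choices and degenerate inputs

* BH adjustment is the standard step-up procedure; ties and p = 1 are
  allowed; the window scan's per-gene BH is a vectorized row-wise
  implementation tested against statsmodels.
* Binomial, hypergeometric and χ² tails come from scipy; every exact test
  is pinned against brute-force enumeration for totals ≤ 12.
* Weighted least squares is batched (per-gene p × p solves); contrast
  variances are clamped away from zero; lowess trend predictions are floored
  at 10⁻⁴ before the −4th power.
* Samples with zero totals, empty sample subsets, absent seasons, fewer
  than two samples per group, rank-deficient designs, non-positive gene
  lengths, mixed-sign marker cells and out-of-range times all raise
  informative errors; all-zero TPM columns and all-constant periodogram
  series degrade gracefully instead.

## Problem sizes

The test suite exercises the pipeline at 2,000 genes and 300–932 donors per
tissue, 5–10 seeds per stochastic claim, 15–20 label permutations, and 10⁴–10⁵
marker randomizations — sizes at which every statistical property under test
(calibration, sensitivity, localization, Monte-Carlo agreement with
enumeration) is already stable, while the full-scale defaults (1,000
permutations, 10⁶ randomizations) remain the configured study-scale values.

## Known limitations

* The day-night contrast has intrinsically low power for cosine effects
  peaking near 06:45 or 18:45, where day- and night-window means coincide;
  the window scan and periodogram stages exist precisely to catch those.
* Twilight cohort fractions differ between a uniform-time synthetic cohort
  (420/1440 ≈ 29%) and any real cohort with structured death times.
* The analytic periodogram p-value is an approximation; the permutation
  option is exact but slow.
* Cross-species phase binning through human clock intervals is a
  convention, not an inference; reported exclusions let users audit it.
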