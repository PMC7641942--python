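# Methods

## The risk score and its conventions

The score is additive on the log-odds scale: for individual *j*,
`GRS_j = Σ_i d_ij w_i / (2 n_j)` with `w_i = log10(OR_i)` and `n_j` the
number of non-missing SNPs. Two conventions are fixed deliberately:

* **Missingness** defaults to *reduce-denominator*: a missing SNP leaves both
  numerator and denominator, so the score stays a per-allele mean and remains
  comparable across missingness patterns. A *drop-individual(max_missing)*
  policy is available for analyses that prefer a fixed panel.
* **Classification is strict**: `high` means `GRS > threshold`; a score
  exactly at the threshold is `low`. The same strictness applies to antibody
  cut-offs, keeping control false-positive rates at or below their nominal
  1%/5%.

Negative weights (OR < 1) are accepted; the non-negativity bound on scores
then no longer holds, and the analytic sensitivity calculation (below)
refuses such tables.

Published 30-SNP panels for type 1 diabetes sometimes add an HLA DR/DQ
interaction term to the additive sum. The implementation is purely additive;
an interaction term can be supplied as an extra pseudo-SNP row in the weight
table (its "dosage" column then encodes carriage of the genotype
combination), which is why no separate code path exists for it.

VCF ingestion reads GT only, matches sites by ID, requires biallelic sites at
scored SNPs, and resolves allele orientation against the weight table. Under
`flip-unambiguous` a site matching only after base complementing is accepted
unless the SNP is A/T or C/G, where a strand flip is undetectable — those
always raise rather than guess.

## Threshold calibration and the excess estimator

Quantiles everywhere (centile threshold, medians, IQRs) use linear
interpolation between order statistics — numpy's default "type 7" convention
— pinned by sort-oracle tests. The threshold is the 95th centile of a
user-supplied control reference; reference size is data, not a constant, and
a warning fires when an extreme centile is estimated from under 20 scores.

`estimate_excess` reports both the real-valued expectation `α·n_tested` and
its half-to-even rounding; the headline excess is computed from the rounded
expectation to match how such tables are reported, with the unrounded value
alongside. A negative raw excess is reported as 0 with a flag. The p-value
is the exact binomial upper tail summed in log space, so counts deep in the
tail (observing 63 of 166 at α = 0.05 is a ~1e-38 event) do not underflow; a
directional chi-square alternative exists behind an option. The Wilson-score
interval for the high fraction is shifted by α and rescaled to the cohort
denominator, floored at zero.

The estimator is deliberately a lower bound: with true polygenic fraction π
and case exceedance sensitivity *s*, the expected excess fraction over the
tested set is `π(s − α)`, which is below π whenever *s* < 1. The test suite
verifies this identity against the analytic *s* (below).

## Comparison statistics

Fisher's exact test, Mann–Whitney U and Kruskal–Wallis are implemented
directly because their conventions are part of the contract:

* Fisher is two-sided by the probability-mass rule — sum all tables with the
  observed margins whose hypergeometric probability is ≤ the observed
  table's, with a 1 + 1e-7 relative tolerance against floating-point ties —
  computed in log space.
* Mann–Whitney uses midranks; p is exact (enumerated null distribution of U
  via the classic counting recurrence) when `n·m ≤ 400` and the pooled data
  are tie-free, otherwise normal with tie and continuity corrections. Exact
  mode refuses ties and falls back with a log message.
* Kruskal–Wallis applies the standard tie correction and a chi-square
  reference with k−1 df.

SciPy's versions serve as independent cross-checks in the tests, never as
the implementation. Raw two-sided p-values are reported with no
multiple-testing correction (the analysis this mirrors applied none; this is
stated in the report, and a Bonferroni helper exists for users who want it).
Significance is flagged at p < 0.05.

## Birthweight standardisation

z = (birthweight − mean(sex, week)) / sd(sex, week), with mean and sd
linearly interpolated between tabulated weeks and **no extrapolation**
outside the table. The mean/sd parameterisation (not LMS skew-adjusted
curves) is used. The regression of z on age at diagnosis is ordinary least
squares with the two-sided slope t-test (n−2 df). The packaged growth
reference is synthetic — a smooth term-anchored fetal weight curve with
sd ≈ 8.5% of mean + 120 g — adequate for tests and examples only.

## The synthetic cohort generator

The generator emulates the referral-series structure, not any real dataset:

* **Genotypes.** Controls: `dosage ~ Binomial(2, f_i)` (Hardy–Weinberg).
  Cases: `P(g) ∝ C(2,g) f_i^g (1−f_i)^{2−g} OR_i^g`, the logistic tilt that
  reproduces each configured odds ratio exactly in expectation. SNPs are in
  linkage equilibrium — a known departure from real panels, where HLA SNPs
  are correlated, so simulated score distributions are smoother and
  unimodal-per-class.
* **Mixture.** `round(π · n_cohort)` polygenic cases, remainder
  monogenic-like; defaults mirror the study shape (m = 30, n_cohort = 166,
  reference n = 4862, π = 0.33), with comparison groups of 164 confirmed
  monogenic and 152 later-onset type 1 diabetes individuals.
* **Antibodies.** Healthy log10 titres are Normal(0, 0.5); each analyte's
  cut-off is the analytic healthy 99th percentile, so ~1% of negatives are
  incidentally positive by construction. Class positivity probabilities
  default to polygenic ≈ (GADA 0.27, IA2A 0.16, ZnT8A 0.12, IAA 0.82) and
  monogenic ≈ (0.02, 0.04, 0.01, 0.39) — the observed proportions in
  early-onset autoimmune vs monogenic series.
* **C-peptide.** Log-normal per class (polygenic median 1.2 pmol/l, σ = 1.2,
  putting ~three quarters below the 3 pmol/l detection limit; monogenic
  median 60 pmol/l, σ = 1.3); written with `"<3"` censoring tokens.
* **Birthweight.** `z ~ Normal(μ_class + β·age_weeks, σ)` with polygenic
  μ = −2.4, β = 0.08/week, σ = 1.1 and monogenic μ = −1.6, β = 0.02, σ = 1.1,
  back-transformed to grams through the growth reference. With the polygenic
  age distribution this gives regressions with r² around 0.2.
* **Ages.** Scaled Beta distributions on (0, 26] weeks — monogenic presents
  earlier (Beta(1.3, 2.5)) than polygenic (Beta(2.5, 1.6)); the 6–24-month
  group is uniform on 26–104 weeks.

The packaged 30-SNP table is synthetic: three large HLA-like effects
(OR 8.0, 5.8, 4.2) and a tail of modest loci (1.08–2.4), frequencies
0.10–0.70. Its score scale (control mean ≈ 0.09, 95th centile ≈ 0.12)
intentionally differs from any published score — the threshold is always
recalibrated from the supplied reference, never hard-coded.

**Analytic sensitivity.** `exceedance_sensitivity` convolves the per-SNP
dosage-weight distributions on a 2^17-point grid (valid because simulated
SNPs are independent); accumulated grid rounding is ≲ 3·10⁻⁶ on the score
scale, negligible against the Monte-Carlo tolerances it is compared with.

What passing tests on this generator do **not** show: robustness to LD,
population stratification, assay drift between laboratories, or real
referral-bias structure. The generator answers "does the machinery recover
what it should when its assumptions hold", nothing more.

## Pipeline conventions

Stages run score → classify → excess → biomarkers → clinical → statistics.
Input groups are exactly `monogenic_NDM`, `unknown`, `T1D_6_24m`; others are
rejected, and the `unknown_high_GRS`/`unknown_low_GRS` split is always
derived from the threshold, never supplied. All inputs are validated before
any output is written. The JSON report isolates its timestamp under `meta`,
so re-runs on identical inputs produce an identical `report` object.
Percentages are rounded half-away-from-zero via `proportion_report`, the
only formatting-time arithmetic in the rendered report.

Problem sizes used in the automated checks — 200 replicates of n = 1000 for
null calibration, up to 100 cohorts of n = 5000 for mixture recovery, 30
SNPs throughout — were chosen to keep Monte-Carlo standard errors well below
the effect sizes being verified.

## Known limitations

* Linkage equilibrium and additivity in the generator (no HLA interaction,
  no LD), as above.
* The excess estimator assumes the monogenic class carries exactly the
  reference score distribution; ancestry mismatch between cohort and
  reference would bias it (the sensitivity analysis that addresses this in
  practice — re-running within one ancestry — is the user's responsibility).
* No imputation, no indel/multiallelic scoring, no strand inference from
  allele frequencies.
* Exact Mann–Whitney p-values are unavailable under ties (midrank/normal
  fallback is used), and the Fisher two-sided definition is the
  probability-mass rule — other software may differ in the third decimal.
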