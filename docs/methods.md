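# Methods

## The analysis model

The package implements a stratified genome-wide interaction meta-analysis
for quantitative traits measured in many studies. Individuals are split
into four disjoint strata — men ≤ 50 y, men > 50 y, women ≤ 50 y,
women > 50 y — and every study contributes, per stratum, marker-level
summary statistics from an additive linear regression of the
inverse-normal-transformed trait on allele dosage. All downstream
inference works on these summaries; no individual-level data cross the
module boundary (a miniature individual-level simulator exists solely to
validate the transformation and regression contract).

The stages are:

1. **Harmonisation and QC.** Marker identifiers are rewritten to
   `chromosome:position` so genome-wide imputed panels and targeted-chip
   panels overlap; alleles are aligned to a consortium-wide orientation
   (swap = beta sign flip and EAF mirror). Filters remove monomorphic
   markers, markers with minor-allele count ≤ 3 (MAF·N ≤ 3), imputed
   markers below the software-specific quality floor (MACH r² < 0.3,
   BIMBAM dosage-variance ratio < 0.3, IMPUTE info < 0.4, PLINK
   info < 0.8) and genotyped markers with call rate < 95 % or
   Hardy–Weinberg exact P < 10⁻⁵.
2. **Genomic control.** Per study-stratum,
   λ = median((β/SE)²)/0.4549 is estimated from all markers (or from a
   designated null subset for targeted-chip panels), clamped at 1, and
   SEs are scaled by √λ with P-values recomputed from β/SE. P-values are
   recomputed from z throughout the pipeline so rounding in uploads never
   propagates.
3. **Fixed-effect pooling.** Inverse-variance weights (w = 1/SE²) pool
   estimates across studies within stratum, then across the stratum
   hierarchy (two sexes, two age groups, overall). IVW pooling is
   associative, so hierarchy order is irrelevant; the tests assert this
   to machine precision. After pooling, markers are kept only if
   available in at least half of the maximum sample size in *every*
   stratum and mappable to a position.
4. **Joint test.** A 4-df chi-square, the sum of squared pooled stratum
   z-scores, tests the main effect in the presence of interaction.
   Strata are disjoint samples, so the statistic treats them as
   independent; possible between-stratum covariance from shared study
   infrastructure is ignored (a deliberate simplification — see
   Limitations).
5. **Interaction statistics.** Two-way differences use
   t = (β_a − β_b)/√(SE_a² + SE_b² − 2 r SE_a SE_b), with r the
   genome-wide Spearman rank correlation between the two groups' effect
   estimates, estimated once per trait on the complete-marker set and
   applied as a constant. The same statistic serves external-group
   comparisons where r reflects overlapping samples. The three-way
   statistic is the age-difference of sex-differences divided by the
   plain root-sum of the four squared SEs; it carries no correlation
   terms, an asymmetry kept intentionally because the three-way contrast
   is defined directly on the four disjoint strata. Markers missing any
   stratum are excluded from all three tests rather than partially
   imputed.
6. **Screens.** Six interaction screens (three tests × with/without the
   a-priori filter P_overall < 10⁻⁵) control FDR at 5 % by
   Benjamini–Hochberg over each screen's own tested set — the filter is
   applied *before* the step-up, so the multiplicity burden is the
   filtered count. Two main-effect screens (overall and joint) use the
   fixed 5×10⁻⁸ genome-wide threshold. Discoveries are clumped into loci
   greedily by physical distance (< 500 kb of the current lead, strict
   inequality, ties on P broken by lower position); novelty is assessed
   against a user-supplied known-locus table, none bundled.

## Correlation adjustment: what it does and does not fix

The r-term in the two-way denominator calibrates the test when the two
group estimates are correlated *as estimators* — overlapping samples, or
any mechanism inducing correlated errors. The calibration suite verifies
exactly this: on 10⁵ null markers whose group estimates share error
correlation ρ = 0.12, the adjusted test holds its size at α ∈ {0.05,
10⁻³} and the unadjusted test is conservative. When the genome-wide
correlation instead arises purely from shared *true* polygenic effects in
disjoint samples, those shared effects cancel in the difference and the
adjustment is slightly anti-conservative; with r ≈ 0.05–0.12 and
SE-dominated estimates the size distortion is second-order. The package
follows the published convention (estimate r genome-wide, subtract), and
the synthetic generator can reproduce either mechanism.

## Analytic power

A scenario fixes the four true stratum effects (SD units), the allele
frequency and the per-stratum n; each stratum estimate has closed-form
SE = 1/√(2·MAF·(1−MAF)·n) for a unit-variance trait, and every screen
statistic is a linear (or quadratic, for the joint test) function of the
four independent estimates. Two-way and three-way powers are shifted
normal tails; with the a-priori filter the power is the bivariate-normal
probability that |Z_overall| passes the filter quantile and |Z_diff|
passes the test quantile, with their correlation derived from the IVW
weights (zero for equal strata, by orthogonality of the contrasts).
Union power over several screens is Monte-Carlo (default 10⁵ replicates,
seeded), since all statistics are deterministic functions of the same
four estimates. Analytic and Monte-Carlo powers agree within ±0.01 in
the tests.

Effect sizes convert to explained variance via R² = 2·MAF·(1−MAF)·β²
(unit-variance phenotype). The preset scenarios use four equal strata of
75 000 (N = 300 000), MAF 0.5 and the anchor effect β = 0.033
(R² ≈ 0.037 %), the conventional medium body-size effect. The published
power percentages for these scenarios depend on an unprinted significance
level, so the package treats them as ordering/magnitude anchors, not
numeric targets: α is an explicit parameter defaulting to 10⁻⁵ for
filtered screens and 5×10⁻⁸ for unfiltered ones (matching the
multiplicity each faces), and the acceptance checks assert the ordering
opposite-direction two-way > pure two-way > 3-strata > 1-stratum with
the 1-stratum power below 10 % and the opposite-direction power above
95 %, which holds across that whole α range. Note that the *unfiltered*
three-way statistic cannot separate the 1-stratum from the 3-strata
shape (identical noncentrality ±β/√(ΣSE²)); the separation — and the
different required sample sizes at 80 % power — comes entirely from the
a-priori filter, which the 3-strata shape passes (strong overall effect)
and the 1-stratum shape mostly fails.

## Downstream statistics

Per-SNP explained variance from a P-value and sample size uses
z = Φ⁻¹(P/2) (log-space quantile near the underflow limit), main term
z²/(z²+N), and the small-sample correction −(1−r²)/N solved in closed
form from the linear self-consistency r²(1−1/N) = z²/(z²+N) − 1/N,
floored at zero; the uncorrected main term is also exposed. Group sums
clump by overall P (< 500 kb), score each lead SNP with the *group's* P
and N, and attach a nonparametric bootstrap SE over loci (the
group-difference significance is likewise bootstrap-based — a choice of
this package, since no test is standard for that comparison).

Direction/enrichment tests are exact one-sided binomial upper tails
P(X ≥ k). For look-up enrichment the null success probability is
0.025 = 0.05 (nominal significance) × ½ (direction), with the success
definition "P < 0.05 with the hypothesised sign".

## Synthetic data

The summary-level generator mirrors the consortium structure: a marker
map over 22 chromosomes (default 1 Mb spacing so each marker is its own
locus), MAFs uniform on a configurable range, a study roster with
per-stratum sample sizes, panel type (targeted-chip studies emit a fixed
random subset of the map, shared across chip studies), imputation
software, ascertainment and self-report flags, and a target inflation
factor. Estimates are drawn Normal(true effect, SE(MAF, n)) with the
sampling noise scaled by √λ (so reported SEs stay honest and z-scores
carry the inflation); EAFs get binomial noise at 2n draws; quality
fields are drawn above the QC floors so generated data pass QC cleanly.
True effects are planted single-marker scenarios plus an optional
polygenic background whose 4×4 covariance is the Kronecker product of a
sex-block and an age-block correlation (ρ_sex, ρ_age), the mechanism
that induces genome-wide between-group effect correlations in disjoint
samples. All randomness flows from one master seed keyed by
(study, stratum), making every table bit-reproducible.

What the generator does *not* emulate: linkage disequilibrium between
markers (clumping tests are position-only), allele-frequency drift
between studies, phenotype measurement error beyond the unit-variance
convention, and X-chromosome markers. Passing tests therefore certify
the statistical machinery, not robustness to LD-induced redundancy or
cross-study frequency mismatch.

The end-to-end recovery configuration plants 20 women-only loci with
R² between 0.02 % and 0.08 % (the realistic range for sex-specific
body-shape effects) plus one opposite-direction locus, across six
studies totalling 150 000 individuals per stratum — sample sizes chosen
so that the weakest planted locus has a reasonable chance of passing the
a-priori filter, which is the binding constraint; the marker count
(5 000) and study count are kept miniature since neither affects the
per-marker operating characteristics. MAF is fixed at 0.5 in this preset
so the R²↔β conversion is exact.

## Bundled reference tables

`stratinteract.datasets` ships the printed group-specific association
results for 15 age-dependent BMI loci and 44 sex-dependent WHR_adjBMI
loci from a large published interaction meta-analysis, plus the look-up
enrichment counts. These drive recomputation checks: back-deriving group
SEs as |β|/z(P) and re-applying the difference test with the reported
genome-wide correlations (r_age = 0.123 for the BMI table,
r_sex = 0.047 for the WHR_adjBMI table) reproduces the printed
interaction P-values up to the 2-significant-figure rounding of the
inputs — all 15 age loci within a factor of 2; for the sex table, rows
whose printed beta is 0.000 cannot pin down the SE (the ratio 0/z is
uninformative), so the reconstruction falls back on the partner group's
SE scaled by √(N ratio) and the acceptance check additionally propagates
printed-precision intervals. The pattern classifier (opposite iff both
groups nominally significant with discordant signs, otherwise labelled
by the larger |β|, ties to women/younger) reproduces the published
28 stronger-in-women / 5 stronger-in-men / 11 opposite partition and the
11-of-15 stronger-in-younger count.

## Numerical choices

- λ clamped at 1: deflation is never "corrected upward", standard
  consortium practice.
- Duplicate markers within a study-stratum: keep highest imputation
  quality, then lowest input row index.
- Strand-ambiguous (A/T, C/G) markers are retained and flagged; against
  a reference with EAFs they are orientation-checked by |ΔEAF| < 0.2.
- Clump window comparisons are strict (< window); two markers exactly a
  window apart form separate loci.
- BH q-values enforce monotonicity by reverse cumulative minimum;
  significance is q < level.
- `required_n` bisects on total n at 1 000-person resolution with the
  scenario shape (relative stratum sizes and effects) held fixed.
- Degenerate difference-test inputs (|r| → 1 with equal SEs) raise with
  the offending indices rather than returning infinities.

## Limitations

- Fixed-effect pooling only; cross-study heterogeneity is assumed
  absent, not modelled (no Cochran's Q, no random effects).
- Only study-stratum-level genomic control is applied; no second,
  meta-level correction.
- The joint test ignores between-stratum covariance; with disjoint
  samples this is exact, with related individuals across strata it is
  approximate.
- Distance-only clumping can merge distinct signals in gene-dense
  regions and split long-range LD; no r²-based clumping.
- The explained-variance formula is a per-SNP approximation; summing
  over clumped leads ignores residual correlation between loci.
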