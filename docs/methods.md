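# Methods

`polyqmod` implements a candidate-SNP modifier analysis of age at onset
(AAO) in seven polyglutamine diseases (HD and SCA1/2/3/6/7/17), together
with a synthetic-cohort generator that reproduces the statistical structure
the analysis assumes. This note records the models, the defaults and why
they were chosen, the numerical decisions, and what the synthetic data can
and cannot show.

## Onset model and residual AAO

Within each disease, AAO is modelled log-linearly in the expanded CAG
repeat length:

    ln(AAO) = A + B·CAG + ε,   ε ~ N(0, σ²)

fitted by ordinary least squares per disease (`fit_onset_model`), with a
two-sided t-test on the slope B. The fitted curve yields an expected onset
per subject, and the residual is the modifier-analysis phenotype.

Two residual scales are exposed because the construction is genuinely
ambiguous between conventions:

* **years** (default): `AAO − exp(A + B·CAG)` — the literal "expected
  onset age subtracted from observed age". No log-normal bias correction
  (e.g. +σ²/2) is applied to the back-transform; the expectation is a plain
  plug-in value.
* **log**: `ln(AAO) − (A + B·CAG)` — the residual of the regression itself
  (the convention of the HD onset-modifier GWAS this analysis replicates).

The two scales are rank-concordant (Spearman ρ > 0.99) when the repeat
spread is cohort-realistic (CAG SD of ~5 around the disease mean). They
decouple noticeably (ρ ≈ 0.93) when CAG spans the full pathogenic range
uniformly, because the years-scale residual is the log-scale residual
amplified by `exp(A + B·CAG)`, which varies over an order of magnitude
across such a range. All headline analyses run on the years scale.

A per-disease sex effect on the residual is tested (OLS on a male
indicator) and reported, but never adjusted for: the study design treats
sex as a verified non-covariate.

## Per-SNP association

For each SNP and each of eight disease groups (HD+SCAs, HD, all SCAs,
SCA1, SCA2, SCA3, SCA6, SCA7 — SCA17 is too small to stand alone and
enters only the pooled groups), residual AAO is regressed on the
effect-allele dosage (0/1/2), intercept + dosage only, solved in closed
form from the normal equations. Missing calls are dropped pairwise per
SNP, so each SNP keeps the sample its assay success rate allows. Dosage
counts the **prior table's effect allele**, not the sample minor allele:
effect directions and score weights are defined relative to the reference
study's alleles, which need not be the minor allele in a new cohort.

Each test yields the usual two-sided p-value and a directional one-sided
p-value aligned with the reference study's effect direction d ∈ {+1, −1}:

    p_one = p_two/2        if sign(β) = d
    p_one = 1 − p_two/2    otherwise
    p_one = 1/2            if β = 0 exactly (continuity)

Monomorphic-in-group SNPs and groups below 10 complete observations are
marked not-computable and excluded from combination rather than imputed.

## QC

The only default filter is the exact Hardy–Weinberg test at p < 0.001
(strict inequality), computed on the whole pooled cohort — a guard against
stratification and assay artefacts. The test enumerates every heterozygote
count attainable given the observed allele counts and sums the conditional
probabilities of configurations no more probable than the observed one
(no mid-p correction), in log space via log-gamma so large cohorts are
safe. Call rate and folded MAF are reported per SNP; an optional
minimum-call-rate filter exists but defaults to off, since assay success
rates are reported rather than filtered on.

## Combining dependent p-values (Brown's method)

Fisher's statistic X = −2·Σ ln pᵢ is χ²(2k) only for independent tests;
LD between panel SNPs correlates the statistics and makes Fisher
anti-conservative. Brown's method moment-matches the null of X with a
scaled chi-square c·χ²_f from E[X] = 2k and
Var[X] = 4k + 2·Σ_{i<j} δ_ij, where δ_ij = cov(−2 ln pᵢ, −2 ln pⱼ).

The covariance is mapped from the correlation ρ of the underlying test
statistics by the Kost–McDermott cubic

    δ(ρ) = 3.263·ρ + 0.710·ρ² + 0.027·ρ³

evaluated **at the signed correlation**. The even-power term keeps its
sign: the true covariance is not an odd function of ρ (at ρ = −1 it is
4 − 2π²/3 ≈ −2.58, not −4), and an odd-symmetric reflection of the
positive branch overstates negative covariance by up to 55%, which in our
calibration experiments inflated type-I error to 0.10 at α = 0.05. The
signed cubic tracks a 6×10⁶-draw Monte-Carlo covariance on both branches
to < 0.003.

Statistic correlations are taken as ρ_ij = d_i·d_j·r_ij for the one-sided
flavor (aligning each statistic with its prior direction; proxy SNPs in a
block share a direction, so within-block ρ is positive in realistic use)
and r_ij² mapped through δ for the two-sided flavor. r is the Pearson
correlation of dosage columns over pairwise-complete subjects; entries
with fewer than 10 complete pairs are treated as zero covariance with a
warning (conservative toward Fisher). A seeded Monte-Carlo estimate of δ
(10⁵ draws from the multivariate-normal null) is available as a
cross-check on the polynomial (`cov_method="montecarlo"`).

Numerical guards: k = 1 returns the input p unchanged; Var[X] is floored
at 2·E[X]·10⁻⁶ against pathological δ sums; p-values are clipped into
(0, 1].

**Accuracy of the scaled chi-square.** With identity LD the method reduces
to Fisher exactly (tested to 10⁻¹²). Against exact-null simulation, the
tail probability is accurate to within ~2×10⁻⁴ in the combination's
operating regime — per-test evidence near the 0.05 level with small panels
or strong dependence — which is where the oracle-agreement test operates.
Outside that regime (mild significance, or weak correlation across many
tests, e.g. k = 22 at ρ = 0.3) the moment-matching approximation deviates
from the exact tail by ~0.5–2×10⁻³. This is inherent to Brown's
two-moment approximation, not to the δ map: replacing the polynomial δ by
a high-precision Monte-Carlo δ does not remove it. Empirical type-I error
at α = 0.05 under blocked-LD nulls stays within [0.03, 0.07] throughout.

## Multiplicity

Single-SNP results are judged against two Bonferroni tiers — 0.05/(22·8)
= 2.84×10⁻⁴ across all SNPs and groups, and 0.05/22 = 2.27×10⁻³ within a
group — and the primary (combined) analysis against 0.05/8 across the
eight disease groups. The group-level correction is conservative because
the pooled groups overlap their constituent diseases.

## Sensitivity analyses

Each group's one-sided combination is recomputed after (a) removing the
high-LD proxy SNPs (all pairs with r² > 0.8; one representative of each
pair retained) and (b) removing the single most significant SNP, reporting
the change in −log₁₀(p). These mirror the checks that a multi-SNP signal
is not an LD echo or a single-SNP artefact.

## Polygenic onset score

S = Σ_s w_s·dosage_s, with w_s the reference study's effect size in years
of onset shift per effect allele (negative = earlier onset). Missing
dosages contribute their SNP's mean (2 × panel allele frequency) — the
standard mean-imputation convention — with the imputed count reported.
Subjects are binned into empirical score quartiles over the whole analyzed
pool (stable sort, sizes differing by ≤ 1), residual AAO is summarized per
quartile, and the variance explained is the R² of OLS of residual on S.

## Synthetic cohorts

The generator is first-class, tested code. Defaults mirror the
seven-disease study structure: cohort sizes (445/177/294/397/69/73
subjects; SCA17 simulated at 50 so its own onset law is estimable, though
it still enters only pooled groups), per-disease onset-law coefficients
(A, B), and CAG ranges. Choices the study conditions do not pin down:

* **σ(ln AAO) = 0.2** for every disease. No residual SD is reported; 0.2
  puts repeat length at ~50–70% of ln-AAO variance in the larger simulated
  groups, matching the range the field reports for these diseases.
* **CAG uniform within range** rather than matched to the observed means:
  the spread maximizes identifiability of (A, B) in tests. The cost is the
  years/log concordance caveat above.
* **LD at the dosage level** via a Gaussian copula on the two allele
  draws; no haplotype phase, no meiotic/somatic instability, no repeat
  interruptions. The default panel carries one three-SNP proxy block
  (latent allele correlation 0.995 → realized dosage r² ≈ 0.85–0.9 at MAF
  0.3; the latent value sits above the dosage-scale target because
  thresholding attenuates correlation) among otherwise independent SNPs
  with MAFs spread over [0.1, 0.5].
* **Missingness 2–5.8%** per SNP, evenly spread (assay success
  94.2–98%).
* **Modifier effects on the years scale**: AAO = exp(A + B·CAG + ε) +
  Σ effect·dosage, floored at 1 year (floored subjects are counted and
  reported). This makes simulated truth directly comparable to score
  weights quoted in years. A missing dosage contributes its SNP mean to
  the effect term so assay dropout does not shrink true effects.
* **Score calibration**: `calibrate_effects` rescales an effect pattern so
  var(S)/(var(S) + var(residual)) hits a target (e.g. the ~1% reported for
  the real score), measuring the baseline residual variance from a null
  pilot cohort and assuming independent SNPs for var(S).

All randomness derives from one integer seed via named substreams, so
stages can be regenerated independently and runs are bit-reproducible.

What passing tests on these cohorts do **not** show: robustness to
population stratification beyond the HWE guard, to relatedness, to
repeat-tract interruptions, to non-log-linear onset laws, or to
ascertainment patterns of real clinic cohorts. The generator's LD is
block-equicorrelated, not a realistic haplotype map.

## Experiment sizes

The validation experiments (shared by the test suite and
`scripts/acceptance.py`) use: 2,000 replicates × 2,000 subjects × 12 SNPs
for combination calibration; 10⁶ draws per exact-null oracle case; 500
replicates at n = 445 for onset-law recovery; 200 replicates for the
directionality and score-calibration experiments, the latter on a
~4,000-subject pool so the sampling SD of a 1% R² (~0.003) is small
against its acceptance band. The whole suite runs in about a minute on
one CPU.

## Known limitations

* Brown's two-moment approximation degrades in the weak-dependence,
  many-test, mild-significance regime (see above); a permutation or full
  Monte-Carlo combination would be exact but is deliberately out of scope.
* The years-scale residual inherits heteroscedasticity from the
  back-transform (variance grows with expected onset); the log scale is
  provided where that matters.
* Real prior tables (effect directions and weights per SNP) must be
  assembled by the user from the reference GWAS; the package ships no
  curated panel, and the synthetic priors are labelled as such.
* Strand-ambiguous (A/T, C/G) assays cannot be harmonized and fail
  loudly; the synthetic panel avoids them by construction.
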