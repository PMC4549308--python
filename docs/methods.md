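# Methods note

## Estimand and estimator

The causal parameter is α in the structural equation `y = αx + η`, with
`x` the centered natural-log 25OHD level and `y` the log-odds of MS. All
instrument effects are oriented to the 25OHD-*decreasing* allele, so the
package's α is the log-odds of disease per unit *decrease* of log 25OHD
and all four packaged βᵢ are positive. Per-variant Wald ratios
`αᵢ = βᵢ/γᵢ` are pooled by inverse-variance weighting. The per-variant
variance is the first-order expression `vᵢ = (s(βᵢ)/γᵢ)²`: uncertainty
in γᵢ is deliberately excluded from the weights (the standard
summary-statistic convention; consequences below). Fixed-effects pooling
is implemented as, and tested against, the zero-intercept weighted
least-squares regression of βᵢ on γᵢ with weights `1/s(βᵢ)²`; the two
are algebraically identical.

Random effects use the DerSimonian–Laird moment estimator
`τ² = max(0, (Q − df)/C)`, `C = Σwᵢ − Σwᵢ²/Σwᵢ`, with re-weighting
`wᵢ* = 1/(vᵢ + τ²)`. Heterogeneity is reported as Cochran's Q and
Higgins I² with the test-based confidence interval on ln H:
`se(ln H) = (ln Q − ln df) / (2(√(2Q) − √(2df−1)))` for `Q > df`, the
large-sample alternative otherwise, back-transformed and truncated to
[0, 100). This interval — not the Q-profile interval — reproduces the
published 0–88% bound for the four-SNP analysis. With exactly two
instruments the interval is computed but flagged `unstable`; it cannot
be estimated reliably at df = 1.

## Standard-error derivation from printed summaries

Outcome log-odds SEs are derived canonically from the printed confidence
interval, `s(β) = (ln hi − ln lo)/(2·1.959964)`, assuming a Wald
interval symmetric on the log scale. Derivation from the p-value
(`s(β) = |β|/z(p)`) is an explicit opt-in
(`OutcomeAssociation(se_derivation="p")`). On the packaged table the two
derivations agree within 12% (printed-value rounding); the CI route is
canonical because it reproduces the published heterogeneity statistics.

## The two σ calibrations

The source tables never print the SD of log 25OHD, and they are mutually
inconsistent about it. The threshold-equivalence table is exactly
consistent with σ = ln(36.86/25) = 0.38829 (`SIGMA_THRESH`), while the
odds-ratio tables are jointly consistent with σ ≈ 0.517
(`SIGMA_OR = 0.51738`, calibrated once by solving
`exp(α̂·σ) = 2.02` on the full four-SNP fixed-effects fit). The package
does not resolve this: σ is a required configuration scalar, both
calibrations ship as documented constants, and the forest output
footnotes the discrepancy. Threshold back-transformations
(`sd_equivalent_level`) use `SIGMA_THRESH`; per-SD odds ratios that are
compared with published values use `SIGMA_OR`.

## Sensitivity analyses

Named exclusions re-run the identical pipeline on the reduced instrument
set: dropping rs12785878 (*DHCR7*, the variant associated with ancestry)
and dropping rs2282679 (*GC*, the variant with a plausible direct route
to disease through the vitamin D binding protein). Pathway stratification
splits the panel into synthesis (*DHCR7*, *CYP2R1*) and metabolism
(*GC*, *CYP24A1*) strata; labels are data (a fixture column), not
inferred. Leave-one-out generalizes the named exclusions to all n
single-omission reruns. Both fixed and random models are reported for
every plan.

## Individual-level validation statistics

Residualization regresses log 25OHD on sex, age, age², BMI and season
(four categories; the first level is the reference) by OLS; all strength
statistics use these "multiply adjusted" residuals. Instrument strength
follows the two-stage convention — residualize, then a single-predictor
regression with an n−2 denominator — so F equals the squared slope
t-statistic exactly. An optional `covariate_df` recomputes F with the
residualization degrees of freedom also removed (the joint-regression
convention); the gap between the two is one plausible source of the
published tension between F = 49.7 and r² = 2.44% at n = 2,347, which
the simple identity `F = (n−2)r²/(1−r²)` does not satisfy.

The trend across allele-count groups is Cuzick's rank test with group
scores equal to the counts (the likely referent of a "non-parametric
trend test" in this literature); a Monte-Carlo permutation p-value is
available as an option, and with two groups the statistic reduces
exactly to the normal approximation of the Wilcoxon rank-sum test.
Pairwise LD is the squared sample correlation of dosage columns
(composite LD), invariant to allele relabeling. The population-
stratification screen is the Cochran–Armitage trend test of dosage
against a binary non-European label (verified against R's
`prop.trend.test`); a 2×3 genotype chi-square is available as an option.
Hardy–Weinberg checks use the 1-df goodness-of-fit chi-square.

## Synthetic-data generator

The generator emulates the two-sample design: an exposure cohort
(default n = 2,347) and an independent case-control outcome study
(default 14,498 cases / 24,091 controls), with disjoint seed streams
spawned from one master seed so the two-sample separation is exact.
Genotypes are two independent allele draws per SNP (Hardy–Weinberg),
with the packaged panel's frequencies and effects as defaults. The
biomarker is

    log x = μ + Σᵢ (−γᵢ)(dᵢ − E dᵢ) + covariate terms + λₓU + ε ,

with every contribution centered so μ is the marginal mean, and the
residual SD solved exactly from the variance budget
`σ² = genetic + covariate + confounder + residual` (truncated-normal
moments are computed analytically, not sampled; an infeasible budget
raises with the full breakdown). Disease is drawn from
`logit⁻¹(κ − α·z + Σδᵢdᵢ + λ_yU)` with `z` the standardized log
biomarker, so `alpha_true` is directly the log-odds per 1-SD decrease
and comparable to the MR estimand. Individuals are sampled from a
synthetic superpopulation until the case and control targets are met.

Choices the sources do not determine, made once:

- **Baseline risk.** κ defaults to logit(0.05). A 5% superpopulation
  prevalence keeps per-allele logistic odds ratios nearly collapsible
  (marginalizing over the residual liability barely attenuates them)
  while the case target is reachable from a ≈300k-person pool per
  replicate. MS's true rarity (~0.1%) is not emulated; prevalence
  affects only the non-collapsibility attenuation, which is small at 5%.
- **Covariate distributions and effects.** Age ~ N(62, 13²) truncated to
  [25, 95], BMI ~ N(27, 4.5²) truncated at 12, 69% female, season
  uniform — ageing-cohort-like but arbitrary, all configurable. True
  covariate effects default to small values (season ±0.04, sex 0.02,
  BMI −0.004/unit, age 5·10⁻⁴/year, age² 0) so the covariate share of
  biomarker variance is <1% and the allele score explains ≈2.4% of the
  adjusted variance, matching the published instrument strength; with
  Table-style inputs the per-SNP F-statistics then center near their
  published values (≈20/19/15/3.5 vs printed 18.8/18.3/13.4/3.1).
- **Pleiotropy demonstrations** attach the direct effect δ to
  rs12785878 (*DHCR7*), the panel's highest-precision instrument, where
  a fixed δ = 0.15 per allele produces the clearest leave-one-out
  signal.

What the generator does **not** emulate: linkage disequilibrium between
SNPs (draws are independent), genotyping error and missingness, age-of-
onset/survival structure, assay batch effects, and realistic MS
prevalence. Tests passing on synthetic data therefore validate the
estimator algebra, calibration under the stated model, and the
diagnostics' power — not robustness to real-data artifacts.

## Numerical choices

- Normal quantile for 95% intervals: 1.959963984540054 (not 1.96).
- I² truncated at 0; its CI truncated to [0, 100); τ² truncated at 0.
- p-values are two-sided standard-normal, no small-p clamping (values
  below double precision are floored at the smallest subnormal only
  where a probability type requires p > 0).
- Missing optional TSV fields are ".", never zero; cohort tables use
  listwise deletion with a logged count.
- Dosage-aggregated binomial GLM for per-SNP case-control fits (exactly
  the individual-level logistic MLE, since dosage takes three values);
  separation is detected and the SNP dropped with a warning.
- Degenerate inputs raise: zero-width CIs, γ = 0 instruments,
  monomorphic SNPs, single-group trend tests, n < 2 random-effects
  pools, exclusions that empty the instrument set.

## Known limitations

- **Weak-instrument undercoverage (NOME violation).** Because vᵢ
  excludes the uncertainty in γᵢ, the omitted variance term is
  `α²·s(γᵢ)²/γᵢ² = α²/Fᵢ` per instrument. At the study's instrument
  strengths (F ≈ 3–20) and a causal effect as large as α = 0.70 per SD,
  that term rivals vᵢ itself: the fixed-effects CI then covers the truth
  in roughly three-quarters of simulated replicates rather than 95%, the
  Wald ratios acquire genuine extra dispersion (part of the observed
  I²), and leave-one-out diagnostics lose some sharpness. Near the null
  the test is exactly calibrated (the omitted term scales with α²), so
  type-I error is unaffected. This is a property of the method being
  reproduced, faithfully retained, not corrected; `HarmonizedInstrument`
  carries the exposure SE so users can assess the magnitude via
  `α²/F`.
- Ratio-estimator nonlinearity biases the mean recovered α slightly
  toward zero at these instrument strengths (≈−0.05 per SD at α = 0.70
  in the recovery study); this sits well within the documented recovery
  tolerance.
- No strand/palindrome logic: the four packaged SNPs are fixed and
  unambiguous; allele frequencies refer to the decreasing allele as
  printed. Proxy SNPs are metadata only (perfect-LD substitutes); no LD
  imputation is performed.
- The I² confidence interval at two instruments is reported but
  unreliable by construction (flagged).
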