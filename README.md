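# vitdmr

Two-sample Mendelian randomization (MR) of genetically lowered
25-hydroxyvitamin D (25OHD) on multiple sclerosis (MS) risk, built as a
tested, reusable Python package. It is aimed at genetic epidemiologists
who want to reproduce, stress-test, or extend the classic four-SNP
vitamin D / MS instrumental-variable analysis from summary statistics,
and at methodologists who need a fully seeded synthetic two-sample
generator with known truth.

## The model

Let `x` be centered natural-log 25OHD and `y` the log-odds of MS, related
by the structural equation `y = αx + η`, where `η` absorbs confounding.
For each genetic variant *i* with per-allele effect `γᵢ` on `x` (oriented
to the 25OHD-*decreasing* allele) and per-allele log-odds `βᵢ` on `y`
with standard error `s(βᵢ)`, the Wald ratio and its first-order variance
are

    αᵢ = βᵢ / γᵢ ,    vᵢ = (s(βᵢ) / γᵢ)² ,    wᵢ = 1 / vᵢ .

The inverse-variance-weighted (IVW) fixed-effects estimate is
`α̂ = Σwᵢαᵢ / Σwᵢ` with `s(α̂) = (Σwᵢ)^(-1/2)` — identical to the
zero-intercept weighted regression of `βᵢ` on `γᵢ` with weights
`1/s(βᵢ)²`, which is how the core estimator is implemented
(`IVWEstimator`, a scikit-learn regressor). Heterogeneity is quantified
by Cochran's `Q = Σwᵢ(αᵢ − α̂)²` on `n−1` df, Higgins
`I² = 100·max(0, (Q−df)/Q)` with a test-based ln-H confidence interval,
and the DerSimonian–Laird `τ²` used for random-effects re-weighting.
Estimates are reported as the odds ratio per one standard deviation (SD)
decrease of log 25OHD, `exp(α̂·σ)`.

Alongside the estimator stack the package ships: harmonization and TSV
I/O for summary-statistic instruments, Bonferroni screening, sensitivity
reruns (named exclusions, synthesis/metabolism pathway strata,
leave-one-out), individual-level instrument validation (allele-count
score, covariate residualization, F-statistics, Cuzick rank trend test,
pairwise LD r², Hardy–Weinberg check, Cochran–Armitage ancestry screen),
clinical-threshold back-transformation, and a seeded generator of
genotype–biomarker–disease cohorts with optional pleiotropy, confounding
and population stratification.

## Worked example

The packaged instrument table (`vitdmr/data/camos_imsgc_table1.tsv`)
carries the four vitamin D SNPs — rs10741657 (*CYP2R1*), rs12785878
(*DHCR7*), rs2282679 (*GC*), rs6013897 (*CYP24A1*) — with their
per-allele effects on log 25OHD and their MS odds ratios.

```python
import vitdmr as v

records = v.load_fixture()
results = v.run_mr(records, sigma_logx=v.SIGMA_OR)
fixed = results["fixed"]
print(f"OR per 1-SD decrease: {fixed.or_per_sd:.2f} "
      f"({fixed.or_ci_low:.2f}-{fixed.or_ci_high:.2f})")
print(f"p = {fixed.pooled.p:.3g}, I2 = {fixed.pooled.het.i2:.1f}% "
      f"({fixed.pooled.het.i2_ci_low:.0f}-{fixed.pooled.het.i2_ci_high:.0f}%)")
```

prints

```
OR per 1-SD decrease: 2.02 (1.66-2.46)
p = 2.81e-12, I2 = 63.6% (0-88%)
```

i.e. each genetically determined 1-SD decrease in log 25OHD roughly
doubles the odds of MS, with moderate between-instrument heterogeneity
(I² ≈ 64%, a wide interval at only four instruments). The same pipeline
from the shell, including sensitivity reruns and the clinical
equivalence table:

```bash
vitdmr run --out results/
vitdmr equivalence            # 50 nmol/l -> 73.7, 75 -> 110.6 nmol/l
vitdmr simulate --seed 4      # synthetic end-to-end run vs known truth
```

`express_per_sd` exposes σ (the SD of log 25OHD) as configuration
because the published tables imply two inconsistent calibrations:
`SIGMA_OR = 0.51738` reproduces the headline odds ratios, while
`SIGMA_THRESH = 0.38829` reproduces the threshold equivalences. See
`docs/methods.md` for the details and for what the synthetic generator
does and does not emulate.

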