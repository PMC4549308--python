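"""Seeded generator of genotype-biomarker-disease cohorts and two-sample
summary datasets.

The generator emulates the two-sample design the MR analysis assumes: an
exposure cohort (CaMos-like, default n = 2,347) in which four biallelic
SNPs additively lower natural-log 25OHD alongside sex, age, age^2, BMI
and season effects, and an independent case-control outcome study
(IMSGC-like, default 14,498 cases / 24,091 controls) in which disease
liability follows a logistic model in the standardized log biomarker.
Optional knobs break the MR assumptions on purpose: per-SNP direct
effects on disease (pleiotropy), a latent confounder entering both the
biomarker and the liability, and a two-subpopulation stratification with
shifted allele frequencies and baseline risk.

The marginal variance of log 25OHD is a fixed budget: the residual noise
SD is solved from ``sigma_logx^2`` minus the exact genetic, covariate
and confounder contributions (exact truncated-normal moments, no
sampling), so the simulated biomarker SD matches ``sigma_logx`` by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats

from .cohort_validation import SEASONS, Cohort, residualize_exposure
from .instruments import (
    ExposureAssociation,
    InstrumentRecord,
    OutcomeAssociation,
)

__all__ = [
    "SNPSpec",
    "CovariateModel",
    "CovariateEffects",
    "StratParams",
    "SimulationParams",
    "TwoSampleDataset",
    "DEFAULT_SNPS",
    "simulate_cohort",
    "summarize_exposure_gwas",
    "summarize_outcome_gwas",
    "make_two_sample_dataset",
]


@dataclass(frozen=True)
class SNPSpec:
    """One simulated biallelic SNP, oriented to the 25OHD-decreasing allele."""

    rsid: str
    freq: float                 # frequency of the decreasing allele
    gamma_decrease: float       # log-25OHD decrease per allele copy (>= 0)
    pathway: str = "unknown"
    locus: str = ""
    chromosome: int = 1
    allele: str = "A"

    def __post_init__(self) -> None:
        if not 0.0 < self.freq < 1.0:
            raise ValueError(f"{self.rsid}: frequency must be in (0,1)")
        if self.gamma_decrease < 0.0:
            raise ValueError(f"{self.rsid}: gamma_decrease must be >= 0")


#: The four-SNP vitamin D instrument panel (frequencies and per-allele
#: log-25OHD effects of the packaged instrument table).
DEFAULT_SNPS = (
    SNPSpec("rs10741657", 0.62, 0.052, "synthesis", "CYP2R1", 11, "C"),
    SNPSpec("rs12785878", 0.27, 0.056, "synthesis", "DHCR7", 11, "G"),
    SNPSpec("rs2282679", 0.30, 0.047, "metabolism", "GC", 4, "C"),
    SNPSpec("rs6013897", 0.19, 0.027, "metabolism", "CYP24A1", 20, "A"),
)


@lru_cache(maxsize=32)
def _tn_moments(
    mean: float, sd: float, lower: float, upper: float
) -> tuple[float, float, float, float]:
    """First four non-central moments of a truncated normal (cached)."""
    lo, hi = (lower - mean) / sd, (upper - mean) / sd if np.isfinite(upper) else np.inf
    tn = stats.truncnorm(lo, hi, loc=mean, scale=sd)
    return tuple(float(tn.moment(k)) for k in (1, 2, 3, 4))


@dataclass(frozen=True)
class CovariateModel:
    """Sampling distributions for the non-genetic covariates.

    Ageing-cohort-like defaults; the source analyses do not publish
    covariate distributions, so these are explicit package choices.
    """

    age_mean: float = 62.0
    age_sd: float = 13.0
    age_range: tuple[float, float] = (25.0, 95.0)
    bmi_mean: float = 27.0
    bmi_sd: float = 4.5
    bmi_min: float = 12.0
    p_female: float = 0.69


@dataclass(frozen=True)
class CovariateEffects:
    """True covariate effects on log 25OHD (log units).

    ``season`` maps each season to its additive effect; defaults are
    deliberately small so the instruments explain roughly the share of
    adjusted biomarker variance seen in real exposure cohorts (~2.4%).
    """

    sex: float = 0.02
    age: float = 5e-4
    age2: float = 0.0
    bmi: float = -0.004
    season: tuple[float, float, float, float] = (0.04, 0.0, -0.04, 0.0)

    def season_map(self) -> dict[str, float]:
        return dict(zip(SEASONS, self.season))


@dataclass(frozen=True)
class StratParams:
    """Two-subpopulation stratification: a fraction of individuals with
    shifted allele frequencies and a baseline-risk offset."""

    subpop_fraction: float
    freq_offsets: dict[str, float] = field(default_factory=dict)
    kappa_offset: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.subpop_fraction < 1.0:
            raise ValueError("subpop_fraction must be in (0,1)")


@dataclass(frozen=True)
class SimulationParams:
    """Full generative specification for the two-sample design.

    ``alpha_true`` is the log-odds of disease per 1-SD *decrease* of log
    25OHD, directly comparable to the MR estimand; ``kappa`` is the
    baseline log-odds in the outcome superpopulation.
    """

    n_exposure: int = 2347
    n_cases: int = 14498
    n_controls: int = 24091
    snps: tuple[SNPSpec, ...] = DEFAULT_SNPS
    sigma_logx: float = 0.38829
    mu_logx: float = float(np.log(60.0))
    covariate_effects: CovariateEffects = CovariateEffects()
    covariate_model: CovariateModel = CovariateModel()
    alpha_true: float = 0.70
    kappa: float = float(np.log(0.05 / 0.95))
    pleiotropy_delta: dict[str, float] = field(default_factory=dict)
    confounder_lambda_x: float = 0.0
    confounder_lambda_y: float = 0.0
    strat: Optional[StratParams] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_logx <= 0.0:
            raise ValueError("sigma_logx must be > 0")
        unknown = set(self.pleiotropy_delta) - {s.rsid for s in self.snps}
        if unknown:
            raise ValueError(f"pleiotropy_delta for unknown SNPs: {sorted(unknown)}")
        self.residual_sd()  # fail fast on an infeasible variance budget

    # -- exact moments for the variance budget --------------------------------

    def _age_var(self) -> float:
        m = self.covariate_model
        c1, c2 = self.covariate_effects.age, self.covariate_effects.age2
        m1, m2, m3, m4 = _tn_moments(m.age_mean, m.age_sd, *m.age_range)
        mean = c1 * m1 + c2 * m2
        second = c1**2 * m2 + 2 * c1 * c2 * m3 + c2**2 * m4
        return float(second - mean**2)

    def _bmi_var(self) -> float:
        m = self.covariate_model
        m1, m2, _, _ = _tn_moments(m.bmi_mean, m.bmi_sd, m.bmi_min, np.inf)
        return float(self.covariate_effects.bmi**2 * (m2 - m1**2))

    def _season_var(self) -> float:
        effects = np.array(self.covariate_effects.season, float)
        return float(np.mean(effects**2) - np.mean(effects) ** 2)

    def _sex_var(self) -> float:
        p = self.covariate_model.p_female
        return float(self.covariate_effects.sex**2 * p * (1 - p))

    def _snp_freqs(self, snp: SNPSpec) -> tuple[float, float, float]:
        """(main freq, subpop freq, subpop fraction) for one SNP."""
        if self.strat is None:
            return snp.freq, snp.freq, 0.0
        offset = self.strat.freq_offsets.get(snp.rsid, 0.0)
        f2 = float(np.clip(snp.freq + offset, 1e-6, 1 - 1e-6))
        return snp.freq, f2, self.strat.subpop_fraction

    def _dosage_moments(self, snp: SNPSpec) -> tuple[float, float]:
        """Mean and variance of the dosage under the (mixture) HWE model."""
        f1, f2, pi = self._snp_freqs(snp)
        mean = 2 * ((1 - pi) * f1 + pi * f2)
        second = (1 - pi) * (2 * f1 * (1 - f1) + (2 * f1) ** 2) + pi * (
            2 * f2 * (1 - f2) + (2 * f2) ** 2
        )
        return mean, second - mean**2

    def _genetic_var(self) -> float:
        return float(
            sum(
                snp.gamma_decrease**2 * self._dosage_moments(snp)[1]
                for snp in self.snps
            )
        )

    def variance_budget(self) -> dict[str, float]:
        """Exact decomposition of var(log 25OHD) under the generator."""
        genetic = self._genetic_var()
        covariate = (
            self._age_var() + self._bmi_var() + self._season_var() + self._sex_var()
        )
        confounder = self.confounder_lambda_x**2
        residual = self.sigma_logx**2 - genetic - covariate - confounder
        return {
            "genetic": genetic,
            "covariate": covariate,
            "confounder": confounder,
            "residual": residual,
        }

    def residual_sd(self) -> float:
        budget = self.variance_budget()
        if budget["residual"] < 0.0:
            raise ValueError(
                "infeasible variance budget: genetic + covariate + confounder "
                f"variance exceeds sigma_logx^2 = {self.sigma_logx**2:.6g}; "
                f"budget = {budget}"
            )
        return float(np.sqrt(budget["residual"]))


@dataclass(frozen=True)
class TwoSampleDataset:
    """Instrument records estimated from two independent simulated cohorts,
    with the generating truth retained for recovery tests."""

    instruments: tuple[InstrumentRecord, ...]
    truth: SimulationParams


def _role_rng(params: SimulationParams, role: str) -> np.random.Generator:
    roles = {"exposure": 0, "outcome": 1}
    if role not in roles:
        raise ValueError(f"role must be 'exposure' or 'outcome', got {role!r}")
    return np.random.default_rng(
        np.random.SeedSequence(params.seed, spawn_key=(roles[role],))
    )


def _truncated_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float,
    lower: float, upper: float,
) -> np.ndarray:
    """Inverse-CDF sampling; exact and loop-free."""
    a = special.ndtr((lower - mean) / sd)
    b = special.ndtr((upper - mean) / sd) if np.isfinite(upper) else 1.0
    return mean + sd * special.ndtri(rng.uniform(a, b, size=n))


def _draw_block(
    params: SimulationParams, rng: np.random.Generator, n: int
) -> dict[str, np.ndarray]:
    """One block of individuals: genotypes, covariates, U, log biomarker."""
    cm = params.covariate_model
    ce = params.covariate_effects
    subpop = (
        rng.random(n) < params.strat.subpop_fraction
        if params.strat is not None
        else np.zeros(n, bool)
    )
    dosages = {}
    logx = np.full(n, params.mu_logx)
    for snp in params.snps:
        f1, f2, _ = params._snp_freqs(snp)
        freqs = np.where(subpop, f2, f1)
        d = rng.binomial(2, freqs)
        dosages[snp.rsid] = d
        logx += -snp.gamma_decrease * (d - params._dosage_moments(snp)[0])

    sex = (rng.random(n) < cm.p_female).astype(int)
    age = _truncated_normal(rng, n, cm.age_mean, cm.age_sd, *cm.age_range)
    bmi = _truncated_normal(rng, n, cm.bmi_mean, cm.bmi_sd, cm.bmi_min, np.inf)
    season_idx = rng.integers(0, 4, size=n)
    season = np.asarray(SEASONS)[season_idx]
    u = rng.standard_normal(n)

    # centered contributions keep E[log x] = mu exactly
    age_m1, age_m2, _, _ = _tn_moments(cm.age_mean, cm.age_sd, *cm.age_range)
    bmi_m1, _, _, _ = _tn_moments(cm.bmi_mean, cm.bmi_sd, cm.bmi_min, np.inf)
    season_effects = np.array(ce.season, float)
    logx = (
        logx
        + ce.sex * (sex - cm.p_female)
        + ce.age * (age - age_m1)
        + ce.age2 * (age**2 - age_m2)
        + ce.bmi * (bmi - bmi_m1)
        + (season_effects[season_idx] - season_effects.mean())
        + params.confounder_lambda_x * u
        + params.residual_sd() * rng.standard_normal(n)
    )
    return {
        "dosages": dosages, "sex": sex, "age": age, "bmi": bmi,
        "season": season, "u": u, "logx": logx, "subpop": subpop,
    }


def _disease_probability(
    params: SimulationParams, block: dict[str, np.ndarray]
) -> np.ndarray:
    z_x = (block["logx"] - params.mu_logx) / params.sigma_logx
    eta = params.kappa - params.alpha_true * z_x
    eta = eta + params.confounder_lambda_y * block["u"]
    for rsid, delta in params.pleiotropy_delta.items():
        eta = eta + delta * block["dosages"][rsid]
    if params.strat is not None:
        eta = eta + params.strat.kappa_offset * block["subpop"]
    return special.expit(eta)


def _block_to_cohort(
    params: SimulationParams,
    block: dict[str, np.ndarray],
    disease: Optional[np.ndarray],
) -> Cohort:
    return Cohort(
        dosages=pd.DataFrame(block["dosages"]),
        log_biomarker=block["logx"],
        sex=block["sex"],
        age=block["age"],
        bmi=block["bmi"],
        season=block["season"],
        disease=disease,
        ancestry_non_european=block["subpop"].astype(int)
        if params.strat is not None
        else None,
        decreasing_oriented=True,
    )


def simulate_cohort(params: SimulationParams, role: str = "exposure") -> Cohort:
    """Simulate one cohort; reproducible given (params, seed, role).

    The exposure and outcome roles consume disjoint seed streams derived
    from the master seed, so the two-sample separation is exact: no
    random draw is shared between the cohorts.  The outcome role samples
    individuals from a synthetic superpopulation until the requested
    case and control counts are reached.
    """
    rng = _role_rng(params, role)
    if role == "exposure":
        block = _draw_block(params, rng, params.n_exposure)
        return _block_to_cohort(params, block, disease=None)

    prevalence = float(special.expit(params.kappa))
    prevalence = min(max(prevalence, 1e-3), 1 - 1e-3)
    target = max(params.n_cases / prevalence, params.n_controls / (1 - prevalence))
    batch = int(target * 1.15) + 1000
    case_blocks: list[dict[str, np.ndarray]] = []
    control_blocks: list[dict[str, np.ndarray]] = []
    n_case = n_control = 0
    for _ in range(200):
        block = _draw_block(params, rng, batch)
        disease = rng.random(batch) < _disease_probability(params, block)
        for mask, blocks, have, need in (
            (disease, case_blocks, n_case, params.n_cases),
            (~disease, control_blocks, n_control, params.n_controls),
        ):
            take = min(int(mask.sum()), need - have)
            if take > 0:
                idx = np.flatnonzero(mask)[:take]
                blocks.append({
                    key: (
                        {r: v[idx] for r, v in val.items()}
                        if key == "dosages"
                        else val[idx]
                    )
                    for key, val in block.items()
                })
        n_case = sum(len(b["logx"]) for b in case_blocks)
        n_control = sum(len(b["logx"]) for b in control_blocks)
        if n_case >= params.n_cases and n_control >= params.n_controls:
            break
        batch = max(batch // 4, 10000)
    else:
        raise RuntimeError(
            "could not reach the requested case/control counts; "
            "check kappa and the liability model"
        )

    def _concat(blocks: list[dict[str, np.ndarray]]) -> dict[str, np.ndarray]:
        return {
            key: (
                {
                    r: np.concatenate([b["dosages"][r] for b in blocks])
                    for r in blocks[0]["dosages"]
                }
                if key == "dosages"
                else np.concatenate([b[key] for b in blocks])
            )
            for key in blocks[0]
        }

    cases, controls = _concat(case_blocks), _concat(control_blocks)
    merged = {
        key: (
            {r: np.concatenate([cases["dosages"][r], controls["dosages"][r]])
             for r in cases["dosages"]}
            if key == "dosages"
            else np.concatenate([cases[key], controls[key]])
        )
        for key in cases
    }
    disease = np.concatenate(
        [np.ones(params.n_cases, int), np.zeros(params.n_controls, int)]
    )
    return _block_to_cohort(params, merged, disease=disease)


def summarize_exposure_gwas(cohort: Cohort) -> pd.DataFrame:
    """Per-SNP additive effect on the multiply adjusted log biomarker.

    The biomarker is residualized on the covariates once, then each SNP
    is tested in a single-SNP linear regression; the reported gamma_hat
    is signed per decreasing-allele copy (negative under the generator's
    truth).  Monomorphic SNPs are dropped with a warning.
    """
    import warnings

    residuals = residualize_exposure(cohort)
    rows = {}
    for rsid in cohort.snps:
        dosage = cohort.dosages[rsid].to_numpy(float)
        if np.var(dosage) == 0.0:
            warnings.warn(f"monomorphic SNP {rsid} dropped from exposure GWAS")
            continue
        fit = sm.OLS(residuals, sm.add_constant(dosage)).fit()
        rows[rsid] = {
            "gamma_hat": float(fit.params[1]),
            "se": float(fit.bse[1]),
            "p": float(fit.pvalues[1]),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def summarize_outcome_gwas(cohort: Cohort, ci_level: float = 0.95) -> pd.DataFrame:
    """Per-SNP logistic regression of disease on dosage with Wald CI.

    Dosage takes three values, so the per-SNP fit is run on genotype-
    aggregated case/control counts (exactly the individual-level MLE).
    SNPs with separation (unbounded estimates) are dropped with a warning.
    """
    import warnings

    if cohort.disease is None:
        raise ValueError("outcome GWAS needs a cohort with disease status")
    y = np.asarray(cohort.disease)
    if y.min() == y.max():
        raise ValueError("need both cases and controls")
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    rows = {}
    for rsid in cohort.snps:
        dosage = cohort.dosages[rsid].to_numpy()
        levels = np.unique(dosage)
        cases = np.array([(y[dosage == g] == 1).sum() for g in levels], float)
        totals = np.array([(dosage == g).sum() for g in levels], float)
        if np.any(cases == 0) or np.any(cases == totals) or levels.size < 2:
            warnings.warn(f"separation for SNP {rsid}: dropped from outcome GWAS")
            continue
        endog = np.column_stack([cases, totals - cases])
        exog = sm.add_constant(levels.astype(float))
        fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        beta, se = float(fit.params[1]), float(fit.bse[1])
        if not np.isfinite(beta) or not np.isfinite(se) or se > 30.0:
            warnings.warn(f"separation for SNP {rsid}: dropped from outcome GWAS")
            continue
        p = float(2.0 * stats.norm.sf(abs(beta / se)))
        rows[rsid] = {
            "or": float(np.exp(beta)),
            "ci_low": float(np.exp(beta - z * se)),
            "ci_high": float(np.exp(beta + z * se)),
            "p": max(p, 5e-324),
            "log_odds": beta,
            "se": se,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def make_two_sample_dataset(params: SimulationParams) -> TwoSampleDataset:
    """Simulate both cohorts and assemble summary-statistic instruments.

    Exposure statistics come only from the exposure cohort and outcome
    statistics only from the case-control study; the generating truth is
    attached for parameter-recovery tests.
    """
    exposure_cohort = simulate_cohort(params, "exposure")
    outcome_cohort = simulate_cohort(params, "outcome")
    exposure = summarize_exposure_gwas(exposure_cohort)
    outcome = summarize_outcome_gwas(outcome_cohort)
    records = []
    for snp in params.snps:
        if snp.rsid not in exposure.index or snp.rsid not in outcome.index:
            continue
        e = exposure.loc[snp.rsid]
        o = outcome.loc[snp.rsid]
        records.append(
            InstrumentRecord(
                rsid=snp.rsid,
                locus=snp.locus or snp.rsid,
                chromosome=snp.chromosome,
                exposure_decreasing_allele=snp.allele,
                exposure=ExposureAssociation(
                    effect_per_allele=float(e["gamma_hat"]),
                    allele_freq=snp.freq,
                    se=float(e["se"]),
                    p_discovery=min(max(float(e["p"]), 5e-324), 1.0),
                ),
                outcome=OutcomeAssociation(
                    odds_ratio=float(o["or"]),
                    ci_low=float(o["ci_low"]),
                    ci_high=float(o["ci_high"]),
                    p_value=min(float(o["p"]), 1.0),
                    source_study="synthetic-case-control",
                ),
                pathway=snp.pathway,
            )
        )
    return TwoSampleDataset(instruments=tuple(records), truth=params)


def with_seed(params: SimulationParams, seed: int) -> SimulationParams:
    """Convenience: the same generative specification under another seed."""
    return replace(params, seed=seed)
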