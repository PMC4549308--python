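"""Individual-level instrument validation for a genotyped biomarker cohort.

Implements the checks run on an exposure cohort before its SNPs are
trusted as instruments: the unweighted count of 25OHD-decreasing alleles
(allele score), covariate residualization of the log biomarker,
instrument-strength F-statistics (joint score and per SNP), a Cuzick
rank trend test of the adjusted biomarker across allele counts, pairwise
linkage-disequilibrium r-squared, a Hardy-Weinberg goodness-of-fit
check, and a Cochran-Armitage test of each SNP against non-European
ancestry (population-stratification screen).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "Cohort",
    "ScoreRegressionResult",
    "TrendTestResult",
    "SEASONS",
    "allele_count_score",
    "residualize_exposure",
    "instrument_strength",
    "per_snp_strength",
    "trend_test",
    "pairwise_r2",
    "ancestry_association",
    "hwe_check",
]

#: Season of biomarker measurement: summer = July-September, autumn =
#: October-December, winter = January-March, spring = April-June.
SEASONS = ("summer", "autumn", "winter", "spring")


@dataclass
class Cohort:
    """Individual-level genotypes, covariates and log biomarker.

    ``dosages`` counts copies of the 25OHD-*decreasing* allele (0/1/2)
    per SNP; ``decreasing_oriented`` records that orientation and must be
    True before score construction.  ``disease`` and
    ``ancestry_non_european`` are optional binary columns (case-control
    cohorts and stratification screens).
    """

    dosages: pd.DataFrame
    log_biomarker: np.ndarray
    sex: np.ndarray
    age: np.ndarray
    bmi: np.ndarray
    season: np.ndarray
    disease: Optional[np.ndarray] = None
    ancestry_non_european: Optional[np.ndarray] = None
    decreasing_oriented: bool = True

    def __post_init__(self) -> None:
        n = len(self.log_biomarker)
        if self.dosages.shape[0] != n or self.dosages.shape[1] < 1:
            raise ValueError("dosages must be n x m with m >= 1")
        if self.dosages.isna().any().any():
            raise ValueError("missing dosages are not allowed")
        if not self.dosages.isin([0, 1, 2]).all().all():
            raise ValueError("dosages must be allele counts in {0, 1, 2}")
        for name in ("sex", "age", "bmi", "season"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"covariate {name!r} length mismatch")
        bad = set(np.unique(self.season)) - set(SEASONS)
        if bad:
            raise ValueError(f"unknown season levels: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.log_biomarker)

    @property
    def snps(self) -> list[str]:
        return list(self.dosages.columns)

    def to_frame(self) -> pd.DataFrame:
        """Flat table with the documented TSV schema."""
        frame = pd.DataFrame({"id": np.arange(self.n)})
        for snp in self.snps:
            frame[f"g_{snp}"] = self.dosages[snp].to_numpy()
        frame["sex"] = self.sex
        frame["age"] = self.age
        frame["bmi"] = self.bmi
        frame["season"] = self.season
        frame["log25ohd"] = self.log_biomarker
        if self.disease is not None:
            frame["disease"] = self.disease
        if self.ancestry_non_european is not None:
            frame["non_european"] = self.ancestry_non_european
        return frame

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Cohort":
        """Read a cohort table; rows with missing values are dropped (logged)."""
        frame = pd.read_csv(path, sep="\t", na_values=".")
        complete = frame.dropna(
            subset=[c for c in frame.columns if c not in ("disease", "non_european")]
        )
        dropped = len(frame) - len(complete)
        if dropped:
            warnings.warn(f"listwise deletion dropped {dropped} incomplete rows")
        snp_cols = [c for c in complete.columns if c.startswith("g_")]
        if not snp_cols:
            raise ValueError("no genotype columns (expected g_<rsid>)")
        return cls(
            dosages=complete[snp_cols]
            .rename(columns=lambda c: c[2:])
            .astype(int)
            .reset_index(drop=True),
            log_biomarker=complete["log25ohd"].to_numpy(float),
            sex=complete["sex"].to_numpy(int),
            age=complete["age"].to_numpy(float),
            bmi=complete["bmi"].to_numpy(float),
            season=complete["season"].to_numpy(str),
            disease=complete["disease"].to_numpy(int)
            if "disease" in complete and complete["disease"].notna().all()
            else None,
            ancestry_non_european=complete["non_european"].to_numpy(int)
            if "non_european" in complete and complete["non_european"].notna().all()
            else None,
        )


@dataclass(frozen=True)
class ScoreRegressionResult:
    """Single-predictor regression summary: slope, F = t^2, r^2, p."""

    slope: float
    f_statistic: float
    r2: float
    p: float
    n: int
    df_resid: int
    f_covariate_adjusted: Optional[float] = None


@dataclass(frozen=True)
class TrendTestResult:
    """Cuzick rank trend statistic across ordered allele-count groups."""

    z: float
    p: float
    group_means: tuple[float, ...]
    group_counts: tuple[int, ...] = ()


def allele_count_score(cohort: Cohort) -> np.ndarray:
    """Per-individual count of 25OHD-decreasing alleles across all SNPs."""
    if not cohort.decreasing_oriented:
        raise ValueError(
            "dosages are not oriented to the 25OHD-decreasing allele"
        )
    return cohort.dosages.to_numpy().sum(axis=1)


def _covariate_design(cohort: Cohort) -> np.ndarray:
    season_dummies = [
        (cohort.season == level).astype(float) for level in SEASONS[1:]
    ]  # first level is the reference
    design = np.column_stack(
        [cohort.sex, cohort.age, cohort.age**2, cohort.bmi, *season_dummies]
    )
    return sm.add_constant(design, has_constant="add")


def residualize_exposure(cohort: Cohort) -> np.ndarray:
    """OLS residuals of log 25OHD on sex, age, age^2, BMI and season.

    These "multiply adjusted" values are the quantity all downstream
    strength statistics are computed on; their mean is zero by
    construction.
    """
    design = _covariate_design(cohort)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear covariates: design matrix is rank-deficient")
    return np.asarray(sm.OLS(cohort.log_biomarker, design).fit().resid)


def _simple_regression(
    y: np.ndarray, x: np.ndarray, covariate_df: int = 0
) -> ScoreRegressionResult:
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if y.shape != x.shape:
        raise ValueError("response and predictor lengths differ")
    if np.var(x) == 0.0:
        raise ValueError("constant predictor: regression undefined")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    t = fit.tvalues[1]
    adjusted = None
    if covariate_df:
        # same sums of squares, denominator df shrunk by the covariates
        # consumed during residualization (the joint-regression convention)
        df_adj = len(y) - 2 - covariate_df
        if df_adj <= 0:
            raise ValueError("covariate_df leaves no residual degrees of freedom")
        adjusted = float(fit.rsquared / (1.0 - fit.rsquared) * df_adj)
    return ScoreRegressionResult(
        slope=float(fit.params[1]),
        f_statistic=float(t**2),
        r2=float(fit.rsquared),
        p=float(fit.pvalues[1]),
        n=len(y),
        df_resid=int(fit.df_resid),
        f_covariate_adjusted=adjusted,
    )


def instrument_strength(
    residuals: np.ndarray, score: np.ndarray, covariate_df: int = 0
) -> ScoreRegressionResult:
    """Strength of the allele score for the adjusted log biomarker.

    Two-stage convention: residualize first, then regress the residuals
    on the score with an n-2 denominator; ``covariate_df`` optionally
    reports the F recomputed with the residualization degrees of freedom
    also removed (the joint-regression convention).
    """
    return _simple_regression(residuals, score, covariate_df)


def per_snp_strength(
    residuals: np.ndarray, dosage: np.ndarray, covariate_df: int = 0
) -> ScoreRegressionResult:
    """As ``instrument_strength`` for a single SNP dosage column."""
    dosage = np.asarray(dosage)
    if np.var(dosage) == 0.0:
        raise ValueError("monomorphic SNP: strength regression undefined")
    return _simple_regression(residuals, dosage, covariate_df)


def trend_test(
    residuals: np.ndarray,
    score: np.ndarray,
    method: str = "normal",
    n_permutations: int = 10000,
    rng: Optional[np.random.Generator] = None,
) -> TrendTestResult:
    """Cuzick rank trend test across ordered allele-count groups.

    Group scores equal the allele counts.  The statistic is
    T = sum_i l_{g(i)} R_i on the midranks R_i, standardized by its
    permutation mean and variance; the p-value is two-sided normal (or
    an exact Monte-Carlo permutation p with ``method="permutation"``).
    With two groups the statistic reduces to the normal approximation of
    the Wilcoxon rank-sum test.
    """
    residuals = np.asarray(residuals, float)
    score = np.asarray(score)
    levels, inverse = np.unique(score, return_inverse=True)
    if levels.size < 2:
        raise ValueError("trend test needs >= 2 distinct score values")
    n = residuals.size
    ranks = stats.rankdata(residuals)
    l_obs = levels[inverse].astype(float)
    t_stat = float(np.sum(l_obs * ranks))
    counts = np.bincount(inverse)
    sum_l = float(np.sum(counts * levels))
    sum_l2 = float(np.sum(counts * levels.astype(float) ** 2))
    e_t = 0.5 * (n + 1) * sum_l
    var_t = (n + 1) / 12.0 * (n * sum_l2 - sum_l**2)
    z = (t_stat - e_t) / np.sqrt(var_t)
    if method == "normal":
        p = float(2.0 * stats.norm.sf(abs(z)))
    elif method == "permutation":
        rng = rng or np.random.default_rng()
        perm = np.array([
            np.sum(l_obs * rng.permutation(ranks)) for _ in range(n_permutations)
        ])
        p = float(
            (np.sum(np.abs(perm - e_t) >= abs(t_stat - e_t)) + 1)
            / (n_permutations + 1)
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    group_means = tuple(
        float(residuals[inverse == g].mean()) for g in range(levels.size)
    )
    return TrendTestResult(
        z=float(z), p=p, group_means=group_means,
        group_counts=tuple(int(c) for c in counts),
    )


def pairwise_r2(dosages: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Squared sample correlation between dosage columns (composite LD).

    Symmetric with unit diagonal; invariant to allele relabeling (the
    reflection d -> 2 - d flips the correlation's sign only).
    """
    if isinstance(dosages, pd.DataFrame):
        names = list(dosages.columns)
        mat = dosages.to_numpy(float)
    else:
        mat = np.asarray(dosages, float)
        names = [str(j) for j in range(mat.shape[1])]
    if mat.shape[1] < 2:
        raise ValueError("need >= 2 SNPs for pairwise LD")
    variances = mat.var(axis=0)
    for name, var in zip(names, variances):
        if var == 0.0:
            raise ValueError(f"monomorphic SNP {name}: r^2 undefined")
    return np.corrcoef(mat, rowvar=False) ** 2


def ancestry_association(
    dosage: np.ndarray,
    non_european: np.ndarray,
    method: str = "trend",
) -> tuple[float, float]:
    """Association of a SNP dosage with a binary ancestry label.

    ``method="trend"`` is the Cochran-Armitage trend test (score test of
    the group proportion across the ordered genotypes, two-sided normal
    p); ``method="chi2"`` is the 2x3 genotype-table chi-square.
    """
    dosage = np.asarray(dosage)
    group = np.asarray(non_european)
    if group.min() == group.max():
        raise ValueError("both ancestry groups must be non-empty")
    if method == "chi2":
        table = pd.crosstab(group, dosage).to_numpy()
        chi2, p, _, _ = stats.chi2_contingency(table)
        return float(chi2), float(p)
    if method != "trend":
        raise ValueError(f"unknown method {method!r}")
    n = dosage.size
    p_bar = group.mean()
    s = dosage.astype(float)
    t_stat = float(np.sum(s * (group - p_bar)))
    var_t = p_bar * (1 - p_bar) * (np.sum(s**2) - np.sum(s) ** 2 / n)
    if var_t <= 0.0:
        raise ValueError("monomorphic SNP: trend test undefined")
    z = t_stat / np.sqrt(var_t)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def hwe_check(dosage: np.ndarray) -> float:
    """1-df chi-square goodness of fit to Hardy-Weinberg proportions."""
    dosage = np.asarray(dosage)
    n = dosage.size
    if n < 30:
        raise ValueError("Hardy-Weinberg check needs n >= 30")
    observed = np.array([(dosage == g).sum() for g in (0, 1, 2)], float)
    freq = (observed[1] + 2 * observed[2]) / (2 * n)
    if freq in (0.0, 1.0):
        warnings.warn("monomorphic SNP: Hardy-Weinberg trivially satisfied")
        return 1.0
    expected = n * np.array([(1 - freq) ** 2, 2 * freq * (1 - freq), freq**2])
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))
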