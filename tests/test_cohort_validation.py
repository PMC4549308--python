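"""Allele score, residualization, strength statistics, trend test, LD, HWE,
and the population-stratification screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vitdmr.cohort_validation import (
    Cohort,
    SEASONS,
    allele_count_score,
    ancestry_association,
    hwe_check,
    instrument_strength,
    pairwise_r2,
    per_snp_strength,
    residualize_exposure,
    trend_test,
)
from vitdmr.synthetic_data import CovariateEffects, SimulationParams, simulate_cohort


def _toy_cohort(dosages: dict, logx: np.ndarray, rng=None) -> Cohort:
    n = len(logx)
    rng = rng or np.random.default_rng(5)
    return Cohort(
        dosages=pd.DataFrame(dosages),
        log_biomarker=np.asarray(logx, float),
        sex=rng.integers(0, 2, n),
        age=rng.uniform(30, 80, n),
        bmi=rng.uniform(20, 35, n),
        season=np.asarray(SEASONS)[rng.integers(0, 4, n)],
    )


class TestAlleleCountScore:
    def test_counts_decreasing_alleles(self):
        cohort = _toy_cohort(
            {"a": [0, 2, 1], "b": [0, 2, 1], "c": [0, 1, 2], "d": [0, 1, 0]},
            np.zeros(3),
        )
        assert allele_count_score(cohort).tolist() == [0, 6, 4]

    def test_single_snp_homozygote(self):
        cohort = _toy_cohort({"a": [2]}, np.zeros(1))
        assert allele_count_score(cohort).tolist() == [2]

    def test_requires_orientation_metadata(self):
        cohort = _toy_cohort({"a": [0, 1]}, np.zeros(2))
        cohort.decreasing_oriented = False
        with pytest.raises(ValueError, match="orient"):
            allele_count_score(cohort)


class TestResidualize:
    def test_constant_biomarker_gives_zero_residuals(self):
        rng = np.random.default_rng(0)
        cohort = _toy_cohort({"a": rng.integers(0, 3, 40)}, np.full(40, 4.0), rng)
        assert np.allclose(residualize_exposure(cohort), 0.0, atol=1e-10)

    def test_residual_mean_is_zero(self):
        params = SimulationParams(seed=3, n_exposure=500)
        cohort = simulate_cohort(params, "exposure")
        resid = residualize_exposure(cohort)
        assert abs(resid.mean()) < 1e-10

    def test_null_covariates_leave_variance_untouched(self):
        zeroed = CovariateEffects(sex=0, age=0, age2=0, bmi=0, season=(0, 0, 0, 0))
        ratios = []
        for seed in range(30):
            params = SimulationParams(
                seed=seed, n_exposure=1000, covariate_effects=zeroed
            )
            cohort = simulate_cohort(params, "exposure")
            resid = residualize_exposure(cohort)
            ratios.append(resid.var() / cohort.log_biomarker.var())
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.02)

    def test_season_effect_is_removed(self):
        """A +0.2 summer shift leaves <5% of season-attributable variance."""
        strong = CovariateEffects(season=(0.2, 0.0, 0.0, 0.0))

        def season_var(values, season):
            grand = values.mean()
            return sum(
                (values[season == s].mean() - grand) ** 2 * np.mean(season == s)
                for s in SEASONS
            )

        before, after = [], []
        for seed in range(200):
            params = SimulationParams(
                seed=seed, n_exposure=400, covariate_effects=strong
            )
            cohort = simulate_cohort(params, "exposure")
            resid = residualize_exposure(cohort)
            before.append(season_var(cohort.log_biomarker, cohort.season))
            after.append(season_var(resid, cohort.season))
        assert np.mean(after) <= 0.05 * np.mean(before)

    def test_collinear_covariates_rejected(self):
        cohort = _toy_cohort({"a": [0, 1, 2, 1, 0, 2]}, np.arange(6.0))
        cohort.age = np.full(6, 50.0)  # age and age^2 now both constant
        with pytest.raises(ValueError, match="rank"):
            residualize_exposure(cohort)


class TestInstrumentStrength:
    def test_f_equals_squared_t_statistic(self, rng):
        import statsmodels.api as sm

        score = rng.integers(0, 9, 300)
        resid = -0.03 * score + rng.normal(0, 0.4, 300)
        result = instrument_strength(resid, score)
        fit = sm.OLS(resid, sm.add_constant(score.astype(float))).fit()
        assert result.f_statistic == pytest.approx(fit.tvalues[1] ** 2, rel=1e-12)
        assert result.r2 == pytest.approx(fit.rsquared, rel=1e-12)
        assert result.p == pytest.approx(fit.pvalues[1], rel=1e-12)

    def test_perfectly_linear_residuals_give_unit_r2(self):
        score = np.array([0, 1, 2, 3, 4, 5])
        result = instrument_strength(0.1 * score, score)
        assert result.r2 == pytest.approx(1.0)

    def test_constant_score_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            instrument_strength(np.arange(5.0), np.ones(5))

    def test_covariate_adjusted_f_uses_reduced_df(self, rng):
        score = rng.integers(0, 9, 300)
        resid = -0.03 * score + rng.normal(0, 0.4, 300)
        result = instrument_strength(resid, score, covariate_df=7)
        expected = result.r2 / (1 - result.r2) * (300 - 2 - 7)
        assert result.f_covariate_adjusted == pytest.approx(expected, rel=1e-12)
        assert result.f_covariate_adjusted < result.f_statistic

    def test_monomorphic_snp_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            per_snp_strength(np.arange(5.0), np.full(5, 2))


class TestTrendTest:
    def test_two_groups_reduce_to_rank_sum(self, rng):
        x0 = rng.normal(0.0, 1.0, 40)
        x1 = rng.normal(0.5, 1.0, 55)
        resid = np.concatenate([x0, x1])
        score = np.concatenate([np.zeros(40, int), np.ones(55, int)])
        trend = trend_test(resid, score)
        ranksum = stats.ranksums(x1, x0)
        assert trend.z**2 == pytest.approx(ranksum.statistic**2, rel=1e-9)

    def test_detects_negative_trend(self, rng):
        score = rng.integers(0, 7, 2000)
        resid = -0.05 * score + rng.normal(0, 0.3, 2000)
        trend = trend_test(resid, score)
        assert trend.z < -3
        assert trend.p < 1e-3
        assert len(trend.group_means) == len(np.unique(score))

    def test_permutation_p_agrees_with_normal_p(self, rng):
        score = rng.integers(0, 5, 120)
        resid = -0.1 * score + rng.normal(0, 0.5, 120)
        normal = trend_test(resid, score)
        perm = trend_test(
            resid, score, method="permutation", n_permutations=4000,
            rng=np.random.default_rng(7),
        )
        assert perm.p == pytest.approx(normal.p, abs=0.02)

    def test_type_i_error_calibrated(self, rng):
        rejections = 0
        reps = 1000
        for _ in range(reps):
            score = rng.integers(0, 7, 80)
            resid = rng.normal(0, 1, 80)
            rejections += trend_test(resid, score).p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            trend_test(np.arange(5.0), np.ones(5, int))


class TestPairwiseR2:
    def test_duplicated_column_has_unit_ld(self, rng):
        d = rng.binomial(2, 0.3, 200)
        r2 = pairwise_r2(pd.DataFrame({"a": d, "b": d}))
        assert r2[0, 1] == pytest.approx(1.0)

    def test_symmetric_with_unit_diagonal(self, rng):
        frame = pd.DataFrame(
            {f"s{j}": rng.binomial(2, 0.4, 500) for j in range(4)}
        )
        r2 = pairwise_r2(frame)
        assert np.allclose(r2, r2.T)
        assert np.allclose(np.diag(r2), 1.0)

    def test_invariant_to_allele_reflection(self, rng):
        frame = pd.DataFrame(
            {"a": rng.binomial(2, 0.3, 300), "b": rng.binomial(2, 0.6, 300)}
        )
        reflected = frame.copy()
        reflected["b"] = 2 - reflected["b"]
        assert pairwise_r2(frame)[0, 1] == pytest.approx(
            pairwise_r2(reflected)[0, 1], rel=1e-12
        )

    def test_complete_positive_association_gives_one(self):
        # haplotype construction: both SNPs share the same allele draws
        rng = np.random.default_rng(2)
        hap1, hap2 = rng.random(400) < 0.5, rng.random(400) < 0.5
        d = (hap1.astype(int) + hap2.astype(int))
        r2 = pairwise_r2(np.column_stack([d, d]))
        assert r2[0, 1] == pytest.approx(1.0)

    def test_monomorphic_column_named_in_error(self, rng):
        frame = pd.DataFrame({"ok": rng.binomial(2, 0.5, 100), "mono": 0})
        with pytest.raises(ValueError, match="mono"):
            pairwise_r2(frame)


class TestAncestryAssociation:
    def test_matches_r_prop_trend_test(self):
        # frozen oracle: R stats::prop.trend.test(c(5,9,10), c(50,30,20))
        # X-squared = 13.37719298, p = 0.000254702641
        dosage = np.repeat([0, 1, 2], [50, 30, 20])
        group = np.concatenate([
            np.repeat([1, 0], [5, 45]),
            np.repeat([1, 0], [9, 21]),
            np.repeat([1, 0], [10, 10]),
        ])
        z, p = ancestry_association(dosage, group)
        assert z**2 == pytest.approx(13.37719298, rel=1e-9)
        assert p == pytest.approx(0.000254702641, rel=1e-6)

    def test_frequency_gap_grows_significant_with_n(self, rng):
        p_values = []
        for n in (200, 2000, 20000):
            group = (rng.random(n) < 0.5).astype(int)
            freq = np.where(group == 1, 0.45, 0.25)
            dosage = rng.binomial(2, freq)
            p_values.append(ancestry_association(dosage, group)[1])
        assert p_values[2] < p_values[0]
        assert p_values[2] < 1e-10

    def test_type_i_error_calibrated(self, rng):
        rejections = 0
        reps = 2000
        for _ in range(reps):
            group = (rng.random(300) < 0.1).astype(int)
            if group.sum() == 0:
                continue
            dosage = rng.binomial(2, 0.3, 300)
            rejections += ancestry_association(dosage, group)[1] < 0.05
        assert 0.035 <= rejections / reps <= 0.065

    def test_chi2_variant_available(self, rng):
        dosage = rng.binomial(2, 0.3, 500)
        group = (rng.random(500) < 0.3).astype(int)
        chi2, p = ancestry_association(dosage, group, method="chi2")
        assert chi2 >= 0 and 0 <= p <= 1

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ancestry_association(np.array([0, 1, 2]), np.zeros(3, int))


class TestHweCheck:
    def test_equilibrium_counts_not_rejected(self):
        # genotype counts (49, 42, 9) at f ~ 0.3: close to HWE proportions
        dosage = np.repeat([0, 1, 2], [49, 42, 9])
        assert hwe_check(dosage) > 0.05

    def test_maximal_disequilibrium_rejected(self):
        dosage = np.repeat([0, 2], [50, 50])  # no heterozygotes at f = 0.5
        assert hwe_check(dosage) < 1e-10

    def test_matches_scipy_chisquare_oracle(self):
        dosage = np.repeat([0, 1, 2], [60, 30, 10])
        n = 100
        f = (30 + 2 * 10) / 200
        expected = n * np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
        chi2 = ((np.array([60, 30, 10]) - expected) ** 2 / expected).sum()
        assert hwe_check(dosage) == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-12)

    def test_monomorphic_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="monomorphic"):
            assert hwe_check(np.zeros(50, int)) == 1.0

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 30"):
            hwe_check(np.array([0, 1, 2]))

    def test_simulated_genotypes_have_uniform_p(self):
        """Generator output under HWE: p-values pass a KS uniformity check."""
        p_values = []
        for seed in range(400):
            params = SimulationParams(seed=seed, n_exposure=500)
            cohort = simulate_cohort(params, "exposure")
            p_values.append(hwe_check(cohort.dosages["rs10741657"].to_numpy()))
        assert stats.kstest(p_values, "uniform").pvalue > 0.01


class TestCohortIO:
    def test_tsv_round_trip(self, tmp_path):
        params = SimulationParams(seed=9, n_exposure=120)
        cohort = simulate_cohort(params, "exposure")
        path = tmp_path / "cohort.tsv"
        cohort.to_tsv(path)
        back = Cohort.from_tsv(path)
        assert back.n == cohort.n
        assert back.snps == cohort.snps
        assert np.allclose(back.log_biomarker, cohort.log_biomarker)
        assert (back.dosages.to_numpy() == cohort.dosages.to_numpy()).all()

    def test_incomplete_rows_dropped_with_warning(self, tmp_path):
        params = SimulationParams(seed=9, n_exposure=50)
        cohort = simulate_cohort(params, "exposure")
        frame = cohort.to_frame()
        frame.loc[0, "bmi"] = np.nan
        path = tmp_path / "cohort.tsv"
        frame.to_csv(path, sep="\t", index=False)
        with pytest.warns(UserWarning, match="listwise"):
            back = Cohort.from_tsv(path)
        assert back.n == 49

    def test_bad_dosage_rejected(self):
        with pytest.raises(ValueError, match="allele counts"):
            _toy_cohort({"a": [0, 3]}, np.zeros(2))
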