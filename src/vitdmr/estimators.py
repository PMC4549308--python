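"""Scikit-learn-style estimator for inverse-variance-weighted pooling.

The IVW fixed-effects meta-analytic estimate of the causal slope is
identical to the zero-intercept weighted least-squares regression of the
per-SNP outcome effects (beta) on the exposure effects (gamma) with
weights 1/s(beta)^2, so the pooling step is exposed here as a regressor
that composes with sklearn pipelines and model selection.  Fitting with
``X = gamma`` and ``sample_weight = 1 / se_beta**2`` yields the pooled
causal slope ``alpha_``; fitting with ``X = 1`` and per-estimate inverse
variances as weights reduces to plain inverse-variance meta-analysis.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = ["IVWEstimator", "i2_from_q", "i2_confidence_interval"]


def i2_from_q(q: float, df: int) -> float:
    """Higgins I-squared (percent) from Cochran's Q, truncated at zero."""
    if df < 1 or q <= 0.0:
        return 0.0
    return max(0.0, (q - df) / q) * 100.0


def i2_confidence_interval(
    q: float, df: int, level: float = 0.95
) -> tuple[float, float]:
    """Test-based confidence interval for I-squared on the ln-H scale.

    Uses se(ln H) = (ln Q - ln df) / (2 (sqrt(2Q) - sqrt(2 df - 1))) when
    Q > df, and the large-sample alternative sqrt((1 - 1/(3 (df-1)^2)) /
    (2 (df - 1))) otherwise; the interval for H is back-transformed to
    I^2 = 100 (H^2 - 1)/H^2 and truncated to [0, 100).  With df = 1 and
    Q <= df no SE is defined and (0, nan) is returned; callers flag the
    two-estimate case as unstable regardless.
    """
    if df < 1:
        return (float("nan"), float("nan"))
    if q > df:
        se_ln_h = 0.5 * (np.log(q) - np.log(df)) / (
            np.sqrt(2.0 * q) - np.sqrt(2.0 * df - 1.0)
        )
    elif df >= 2:
        se_ln_h = np.sqrt((1.0 - 1.0 / (3.0 * (df - 1.0) ** 2)) / (2.0 * (df - 1.0)))
    else:
        return (0.0, float("nan"))
    ln_h = 0.5 * np.log(max(q / df, 1.0))
    z = stats.norm.ppf(0.5 + level / 2.0)

    def to_i2(ln_h_bound: float) -> float:
        h2 = np.exp(2.0 * ln_h_bound)
        return float(np.clip((h2 - 1.0) / h2 * 100.0, 0.0, 100.0 - 1e-12))

    return to_i2(ln_h - z * se_ln_h), to_i2(ln_h + z * se_ln_h)


class IVWEstimator(RegressorMixin, BaseEstimator):
    """Inverse-variance-weighted causal-slope estimator (fixed or random).

    Parameters
    ----------
    effects : {"fixed", "random"}
        "fixed" pools with weights equal to the reciprocal per-estimate
        variances; "random" adds a DerSimonian-Laird between-instrument
        variance tau^2 (truncated at zero) to every variance before
        re-weighting.
    ci_level : float
        Confidence level used for the I-squared interval.

    Attributes (after ``fit``)
    --------------------------
    alpha_, coef_ : pooled slope (log-odds of disease per unit decrease
        of log 25OHD when fitted on harmonized instruments).
    se_, zvalue_, pvalue_ : Wald inference on the pooled slope.
    q_, df_, i2_, i2_ci_, tau2_ : Cochran heterogeneity statistics of the
        per-estimate Wald ratios around the fixed-effects pool.
    wald_alphas_, wald_variances_ : the per-instrument ratio estimates
        and their first-order variances.

    Notes
    -----
    The per-estimate variance is the first-order expression
    ``v_i = s(beta_i)^2 / gamma_i^2``; uncertainty in gamma never enters
    the weights, mirroring the summary-statistic two-sample convention.
    Heterogeneity (``q_`` and friends) is always computed around the
    fixed-effects pool, also under ``effects="random"``.
    """

    def __init__(self, effects: str = "fixed", ci_level: float = 0.95):
        self.effects = effects
        self.ci_level = ci_level

    def fit(self, X, y, sample_weight=None):
        if self.effects not in ("fixed", "random"):
            raise ValueError(f"effects must be 'fixed' or 'random', got {self.effects!r}")
        X, y = validate_data(self, X, y, ensure_min_samples=1)
        if X.shape[1] != 1:
            raise ValueError("IVWEstimator expects a single exposure-effect column")
        x = X[:, 0].astype(float)
        if np.any(x == 0.0):
            raise ValueError("zero exposure effect: Wald ratio undefined")
        if sample_weight is None:
            sample_weight = np.ones_like(x)
        sample_weight = np.asarray(sample_weight, dtype=float)
        if sample_weight.shape != x.shape or np.any(sample_weight <= 0.0):
            raise ValueError("sample_weight must be positive, one per estimate")
        n = x.size
        if self.effects == "random" and n < 2:
            raise ValueError(
                "random-effects pooling needs >= 2 estimates; use effects='fixed'"
            )

        alphas = y / x                      # per-SNP Wald ratios
        variances = 1.0 / (sample_weight * x**2)
        w = 1.0 / variances
        alpha_fe = float(np.sum(w * alphas) / np.sum(w))
        se_fe = float(np.sum(w) ** -0.5)

        df = n - 1
        if df >= 1:
            q = float(np.sum(w * (alphas - alpha_fe) ** 2))
            c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
            tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
            i2 = i2_from_q(q, df)
            i2_ci = i2_confidence_interval(q, df, self.ci_level)
        else:
            q, tau2, i2, i2_ci = float("nan"), float("nan"), float("nan"), (
                float("nan"), float("nan"))

        if self.effects == "random":
            w_star = 1.0 / (variances + tau2)
            alpha = float(np.sum(w_star * alphas) / np.sum(w_star))
            se = float(np.sum(w_star) ** -0.5)
        else:
            alpha, se = alpha_fe, se_fe

        self.alpha_ = alpha
        self.coef_ = np.array([alpha])
        self.intercept_ = 0.0
        self.se_ = se
        self.zvalue_ = alpha / se
        self.pvalue_ = float(2.0 * stats.norm.sf(abs(self.zvalue_)))
        self.fixed_alpha_ = alpha_fe
        self.fixed_se_ = se_fe
        self.q_ = q
        self.df_ = df
        self.i2_ = i2
        self.i2_ci_ = i2_ci
        self.tau2_ = tau2
        self.wald_alphas_ = alphas
        self.wald_variances_ = variances
        self.n_instruments_ = n
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return X[:, 0] * self.alpha_

    def confint(self, level: float = 0.95) -> tuple[float, float]:
        """Wald confidence interval for the pooled slope."""
        check_is_fitted(self)
        z = stats.norm.ppf(0.5 + level / 2.0)
        return self.alpha_ - z * self.se_, self.alpha_ + z * self.se_
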