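"""Core Mendelian-randomization estimators and per-SD scaling.

The structural model is ``y = alpha * x + eta`` with ``x`` the (centered,
scaled) natural-log 25OHD level and ``y`` the log-odds of multiple
sclerosis.  Each variant contributes a Wald ratio ``alpha_i = beta_i /
gamma_i`` with first-order variance ``v_i = (s(beta_i) / gamma_i)^2``;
ratios are pooled by inverse-variance weighting (fixed effects) or by
DerSimonian-Laird re-weighting (random effects), with Cochran's Q and
Higgins I-squared quantifying between-instrument heterogeneity.

Because the instruments are oriented to 25OHD-*decreasing* alleles, the
pooled ``alpha`` is the log-odds of disease per unit decrease of log
25OHD; ``express_per_sd`` rescales it to the more interpretable odds
ratio per one standard deviation of log 25OHD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .estimators import IVWEstimator, i2_confidence_interval, i2_from_q
from .instruments import HarmonizedInstrument, InstrumentRecord, harmonize

__all__ = [
    "WaldEstimate",
    "HeterogeneityStats",
    "PooledEstimate",
    "MRResult",
    "ClinicalThreshold",
    "wald_ratio",
    "pool_fixed",
    "pool_random",
    "cochran_q",
    "express_per_sd",
    "sd_equivalent_level",
    "calibrate_sigma",
    "run_mr",
    "SIGMA_THRESH",
    "SIGMA_OR",
    "CALIBRATION_OR_PER_SD",
    "DEFAULT_THRESHOLDS",
]

#: SD of natural-log 25OHD implied by the published clinical-threshold
#: equivalences (a 1-SD increase maps 25 nmol/l to 36.86 nmol/l):
#: ln(36.86 / 25).  Used for threshold back-transformation.
SIGMA_THRESH = 0.38829

#: Headline fixed-effects odds ratio per 1-SD decrease reported for this
#: four-instrument panel; used only to calibrate SIGMA_OR.
CALIBRATION_OR_PER_SD = 2.02

#: SD of natural-log 25OHD calibrated once so that the four-instrument
#: fixed-effects OR per SD on the packaged table equals the published
#: headline value for the same panel (ln(2.02) / 1.358966).  The source
#: analyses never print the cohort SD directly, and the two published
#: calibrations are mutually inconsistent; both are therefore exposed as
#: configuration rather than resolved.
SIGMA_OR = 0.51738

_Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class WaldEstimate:
    """Per-SNP causal estimate alpha_i = beta_i / gamma_i with variance."""

    rsid: str
    alpha: float
    variance: float
    weight: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.variance <= 0.0:
            raise ValueError(f"{self.rsid}: variance must be > 0")
        if self.weight is None:
            object.__setattr__(self, "weight", 1.0 / self.variance)
        if not math.isclose(self.weight * self.variance, 1.0, rel_tol=1e-9):
            raise ValueError(f"{self.rsid}: weight must equal 1/variance")


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q, Higgins I-squared (percent) with CI, and DL tau^2.

    ``defined`` is False for fewer than two instruments (df = 0), in
    which case the remaining fields are NaN.  ``unstable`` flags the
    two-instrument case, where the I-squared interval cannot be reliably
    estimated.
    """

    q: float
    df: int
    i2: float
    i2_ci_low: float
    i2_ci_high: float
    tau2: float
    unstable: bool = False

    @property
    def defined(self) -> bool:
        return self.df >= 1

    @classmethod
    def undefined(cls) -> "HeterogeneityStats":
        nan = float("nan")
        return cls(q=nan, df=0, i2=nan, i2_ci_low=nan, i2_ci_high=nan, tau2=nan)


@dataclass(frozen=True)
class PooledEstimate:
    """Pooled causal log-odds per unit decrease of log 25OHD."""

    model: str                    # "fixed" or "random"
    alpha: float
    se: float
    z: float
    p: float
    het: HeterogeneityStats
    n: int


@dataclass(frozen=True)
class MRResult:
    """Pooled estimate expressed as OR per 1-SD decrease of log 25OHD."""

    pooled: PooledEstimate
    sigma_logx: float
    or_per_sd: float
    or_ci_low: float
    or_ci_high: float
    instruments: tuple[WaldEstimate, ...] = ()


@dataclass(frozen=True)
class ClinicalThreshold:
    """A clinically relevant 25OHD level in nmol/l (e.g. insufficiency)."""

    label: str
    level: float

    def __post_init__(self) -> None:
        if self.level <= 0.0:
            raise ValueError("threshold level must be > 0 nmol/l")


#: Deficiency / insufficiency / sufficiency cut-points in nmol/l.
DEFAULT_THRESHOLDS = (
    ClinicalThreshold("vitamin D deficient", 25.0),
    ClinicalThreshold("vitamin D insufficient", 50.0),
    ClinicalThreshold("vitamin D sufficient", 75.0),
)


def wald_ratio(inst: HarmonizedInstrument) -> WaldEstimate:
    """Single-variant causal estimate: alpha = beta / gamma, v = (se/gamma)^2."""
    alpha = inst.beta / inst.gamma_decrease
    variance = (inst.se_beta / inst.gamma_decrease) ** 2
    return WaldEstimate(rsid=inst.rsid, alpha=alpha, variance=variance)


def _fit(estimates: Sequence[WaldEstimate], effects: str) -> IVWEstimator:
    x = np.ones((len(estimates), 1))
    y = np.array([e.alpha for e in estimates])
    w = np.array([e.weight for e in estimates])
    return IVWEstimator(effects=effects).fit(x, y, sample_weight=w)


def cochran_q(
    estimates: Sequence[WaldEstimate], pooled_alpha: float
) -> HeterogeneityStats:
    """Heterogeneity of Wald ratios around a pooled value.

    Q = sum w_i (alpha_i - pooled)^2 on n-1 df; I^2 = 100 max(0, (Q-df)/Q);
    tau^2 is the DerSimonian-Laird moment estimator truncated at zero.
    """
    n = len(estimates)
    if n < 2:
        return HeterogeneityStats.undefined()
    w = np.array([e.weight for e in estimates])
    a = np.array([e.alpha for e in estimates])
    q = float(np.sum(w * (a - pooled_alpha) ** 2))
    df = n - 1
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    lo, hi = i2_confidence_interval(q, df)
    return HeterogeneityStats(
        q=q, df=df, i2=i2_from_q(q, df), i2_ci_low=lo, i2_ci_high=hi,
        tau2=tau2, unstable=(n == 2),
    )


def pool_fixed(estimates: Sequence[WaldEstimate]) -> PooledEstimate:
    """Inverse-variance-weighted fixed-effects pool of Wald ratios."""
    if len(estimates) == 0:
        raise ValueError("cannot pool an empty list of estimates")
    est = _fit(estimates, "fixed")
    return PooledEstimate(
        model="fixed", alpha=est.alpha_, se=est.se_, z=est.zvalue_,
        p=est.pvalue_, het=cochran_q(estimates, est.alpha_), n=len(estimates),
    )


def pool_random(estimates: Sequence[WaldEstimate]) -> PooledEstimate:
    """DerSimonian-Laird random-effects pool (weights 1/(v_i + tau^2))."""
    if len(estimates) < 2:
        raise ValueError(
            "random-effects pooling needs >= 2 instruments; use pool_fixed"
        )
    est = _fit(estimates, "random")
    return PooledEstimate(
        model="random", alpha=est.alpha_, se=est.se_, z=est.zvalue_,
        p=est.pvalue_, het=cochran_q(estimates, est.fixed_alpha_),
        n=len(estimates),
    )


def express_per_sd(
    pooled: PooledEstimate,
    sigma_logx: float,
    instruments: Sequence[WaldEstimate] = (),
) -> MRResult:
    """Rescale a pooled per-unit estimate to an OR per 1-SD decrease.

    z and p are invariant under the rescaling (the slope and its SE are
    multiplied by the same sigma).
    """
    if sigma_logx <= 0.0:
        raise ValueError(f"sigma_logx must be > 0, got {sigma_logx}")
    alpha_sd = pooled.alpha * sigma_logx
    se_sd = pooled.se * sigma_logx
    return MRResult(
        pooled=pooled,
        sigma_logx=sigma_logx,
        or_per_sd=float(np.exp(alpha_sd)),
        or_ci_low=float(np.exp(alpha_sd - _Z975 * se_sd)),
        or_ci_high=float(np.exp(alpha_sd + _Z975 * se_sd)),
        instruments=tuple(instruments),
    )


def sd_equivalent_level(threshold: ClinicalThreshold, sigma_logx: float) -> float:
    """25OHD level (nmol/l) one log-SD above a clinical threshold.

    exp(ln(level) + sigma): e.g. with sigma = 0.38829, the 50 nmol/l
    insufficiency cut-point maps to 73.7 nmol/l.
    """
    if sigma_logx < 0.0:
        raise ValueError("sigma_logx must be non-negative")
    return float(np.exp(np.log(threshold.level) + sigma_logx))


def calibrate_sigma(alpha_per_unit: float, target_or_per_sd: float) -> float:
    """Solve exp(alpha * sigma) = target OR for the log-25OHD SD."""
    if alpha_per_unit == 0.0:
        raise ValueError("cannot calibrate sigma against a null pooled estimate")
    return float(np.log(target_or_per_sd) / alpha_per_unit)


def run_mr(
    records: Sequence[InstrumentRecord],
    sigma_logx: float = SIGMA_OR,
) -> dict[str, Optional[MRResult]]:
    """Full pipeline: harmonize, Wald ratios, pool both models, scale.

    Returns ``{"fixed": MRResult, "random": MRResult | None}``; the
    random-effects entry is None with a single instrument.
    """
    if len(records) == 0:
        raise ValueError("no instruments supplied")
    estimates = []
    for record in records:
        try:
            estimates.append(wald_ratio(harmonize(record)))
        except ValueError as exc:
            raise ValueError(f"instrument {record.rsid}: {exc}") from exc
    fixed = express_per_sd(pool_fixed(estimates), sigma_logx, estimates)
    random = (
        express_per_sd(pool_random(estimates), sigma_logx, estimates)
        if len(estimates) >= 2
        else None
    )
    return {"fixed": fixed, "random": random}
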