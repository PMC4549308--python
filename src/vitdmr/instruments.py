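"""Summary-statistic instruments: data model, TSV I/O, and harmonization.

An *instrument* is a SNP robustly associated with circulating
25-hydroxyvitamin D (25OHD, analyzed on the natural-log scale) whose
association with multiple sclerosis is taken from an independent
case-control study.  Each record carries the per-allele effect on
log-25OHD (gamma) and the outcome odds ratio with its confidence
interval, from which the log-odds beta and its standard error are
derived.

Orientation convention: all harmonized effects are expressed per copy of
the 25OHD-*decreasing* allele, so gamma_decrease > 0 is the magnitude of
the log-25OHD decrease per allele copy and beta is the log-odds of
disease per copy of the same allele.  The downstream causal estimand is
then the log-odds of disease per unit *decrease* in log 25OHD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExposureAssociation",
    "OutcomeAssociation",
    "InstrumentRecord",
    "HarmonizedInstrument",
    "beta_from_or_ci",
    "se_from_p",
    "harmonize",
    "bonferroni_screen",
    "read_instrument_table",
    "fixture_path",
    "load_fixture",
    "PATHWAY_BY_LOCUS",
]

#: Gene-to-pathway assignment: DHCR7 (7-dehydrocholesterol supply) and
#: CYP2R1 (hepatic 25-hydroxylation) act in 25OHD synthesis; GC (the
#: vitamin D binding protein) and CYP24A1 (24-hydroxylase inactivation)
#: act in 25OHD transport/metabolism.
PATHWAY_BY_LOCUS = {
    "DHCR7": "synthesis",
    "CYP2R1": "synthesis",
    "GC": "metabolism",
    "CYP24A1": "metabolism",
}

_VALID_ALLELES = frozenset("ACGT")

_COLUMNS = [
    "rsid", "locus", "chromosome", "decreasing_allele", "allele_freq",
    "gamma", "gamma_se", "p_exposure", "f_statistic", "or_outcome",
    "ci_low", "ci_high", "p_outcome", "source_study", "proxy_rsid",
    "proxy_r2", "pathway",
]


def beta_from_or_ci(
    odds_ratio: float, lo: float, hi: float, level: float = 0.95
) -> tuple[float, float]:
    """Convert an odds ratio and its confidence interval to log-odds and SE.

    The SE is ``(ln hi - ln lo) / (2 z)`` with ``z`` the standard-normal
    quantile at ``(1 + level) / 2``; this assumes the interval is a Wald
    interval symmetric on the log scale.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    if not (0.0 < lo <= odds_ratio <= hi):
        raise ValueError(
            f"require 0 < lo <= or <= hi, got lo={lo}, or={odds_ratio}, hi={hi}"
        )
    if lo == hi:
        raise ValueError("zero-width confidence interval: SE would be 0")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.log(odds_ratio)), float((np.log(hi) - np.log(lo)) / (2.0 * z))


def se_from_p(log_odds: float, p: float) -> float:
    """Recover the standard error of a log-odds from its two-sided p-value.

    Inverts ``p = 2 * Phi(-|log_odds| / se)``.  Useful when the printed
    confidence interval is more coarsely rounded than the p-value.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0,1) for SE recovery, got {p}")
    if log_odds == 0.0:
        raise ValueError("log-odds of 0 with p < 1 is inconsistent")
    z = stats.norm.isf(p / 2.0)
    if z <= 0.0 or not np.isfinite(z):
        raise ValueError(f"p = {p} yields a non-positive normal quantile")
    return float(abs(log_odds) / z)


@dataclass(frozen=True)
class ExposureAssociation:
    """Per-allele association of a SNP with natural-log 25OHD (gamma)."""

    effect_per_allele: float
    allele_freq: float
    se: Optional[float] = None
    p_discovery: Optional[float] = None
    f_statistic: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.allele_freq < 1.0:
            raise ValueError(
                f"frequency out of (0,1): allele_freq={self.allele_freq}"
            )
        if self.se is not None and self.se <= 0.0:
            raise ValueError(f"exposure SE must be > 0, got {self.se}")
        if self.p_discovery is not None and not 0.0 < self.p_discovery <= 1.0:
            raise ValueError(f"p_discovery out of (0,1]: {self.p_discovery}")
        if self.f_statistic is not None and self.f_statistic < 0.0:
            raise ValueError(f"F-statistic must be >= 0, got {self.f_statistic}")


@dataclass(frozen=True)
class OutcomeAssociation:
    """Case-control association of a SNP with disease, as OR plus CI.

    ``log_odds`` (beta) and ``se_log_odds`` (s(beta)) are derived fields;
    ``se_derivation`` records whether the SE came from the CI (canonical)
    or from the p-value (opt-in alternative).
    """

    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    source_study: str = ""
    ci_level: float = 0.95
    log_odds: float = field(init=False)
    se_log_odds: float = field(init=False)
    se_derivation: str = "ci"

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p_value out of (0,1]: {self.p_value}")
        log_odds, se_ci = beta_from_or_ci(
            self.odds_ratio, self.ci_low, self.ci_high, self.ci_level
        )
        if self.se_derivation == "ci":
            se = se_ci
        elif self.se_derivation == "p":
            se = se_from_p(log_odds, self.p_value)
        else:
            raise ValueError(f"unknown se_derivation {self.se_derivation!r}")
        object.__setattr__(self, "log_odds", log_odds)
        object.__setattr__(self, "se_log_odds", se)


@dataclass(frozen=True)
class InstrumentRecord:
    """One SNP's exposure and outcome associations plus provenance."""

    rsid: str
    locus: str
    chromosome: int
    exposure_decreasing_allele: str
    exposure: ExposureAssociation
    outcome: OutcomeAssociation
    pathway: str = "unknown"
    proxy_rsid: Optional[str] = None
    proxy_r2: Optional[float] = None

    def __post_init__(self) -> None:
        if not 1 <= self.chromosome <= 22:
            raise ValueError(f"{self.rsid}: chromosome must be 1-22")
        if self.exposure_decreasing_allele not in _VALID_ALLELES:
            raise ValueError(
                f"{self.rsid}: allele must be one of A,C,G,T, "
                f"got {self.exposure_decreasing_allele!r}"
            )
        if self.pathway not in ("synthesis", "metabolism", "unknown"):
            raise ValueError(f"{self.rsid}: unknown pathway {self.pathway!r}")
        if self.proxy_rsid is not None and self.proxy_r2 is None:
            raise ValueError(f"{self.rsid}: proxy_rsid given without proxy_r2")
        if self.proxy_r2 is not None and not 0.0 <= self.proxy_r2 <= 1.0:
            raise ValueError(f"{self.rsid}: proxy_r2 out of [0,1]")


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Instrument oriented to the 25OHD-decreasing allele.

    ``flipped`` records whether the orientation step re-signed the input
    effects (i.e. the stated allele was the 25OHD-increasing one).
    """

    rsid: str
    gamma_decrease: float
    beta: float
    se_beta: float
    pathway: str = "unknown"
    flipped: bool = False

    def __post_init__(self) -> None:
        if self.gamma_decrease <= 0.0:
            raise ValueError(f"{self.rsid}: gamma_decrease must be > 0")
        if self.se_beta <= 0.0:
            raise ValueError(f"{self.rsid}: se_beta must be > 0")


def harmonize(record: InstrumentRecord) -> HarmonizedInstrument:
    """Orient a record so effects are per copy of the 25OHD-decreasing allele.

    If the stated allele lowers 25OHD (negative ``effect_per_allele``)
    the magnitudes pass through; if it raises 25OHD, both gamma and beta
    are re-signed in lockstep so the pair still refers to one allele.
    """
    gamma = record.exposure.effect_per_allele
    if gamma == 0.0:
        raise ValueError(f"{record.rsid}: null instrument (gamma = 0)")
    if gamma < 0.0:
        gamma_decrease, beta, flipped = -gamma, record.outcome.log_odds, False
    else:
        gamma_decrease, beta, flipped = gamma, -record.outcome.log_odds, True
    return HarmonizedInstrument(
        rsid=record.rsid,
        gamma_decrease=gamma_decrease,
        beta=beta,
        se_beta=record.outcome.se_log_odds,
        pathway=record.pathway,
        flipped=flipped,
    )


def bonferroni_screen(
    records: Sequence[InstrumentRecord], fwer: float = 0.05
) -> tuple[float, list[str]]:
    """Family-wise screen of outcome associations at ``fwer / n``.

    Returns the per-test threshold and the rsids whose outcome p-value is
    at or below it (input order preserved; the comparison is inclusive).
    """
    if len(records) == 0:
        raise ValueError("no instruments to screen")
    if not 0.0 < fwer < 1.0:
        raise ValueError(f"fwer must be in (0,1), got {fwer}")
    threshold = fwer / len(records)
    passing = [r.rsid for r in records if r.outcome.p_value <= threshold]
    return threshold, passing


def _parse(value: str, kind, row: int, col: str, optional: bool = False):
    if value is None or (isinstance(value, str) and value.strip() in (".", "")):
        if optional:
            return None
        raise ValueError(f"row {row}, column {col!r}: missing required value")
    try:
        return kind(value)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"row {row}, column {col!r}: {exc}") from exc


def read_instrument_table(path: str | Path) -> list[InstrumentRecord]:
    """Read a tab-separated instrument table into records.

    The dialect is UTF-8 TSV with ``.`` for missing optional values and
    scientific notation accepted for p-values.  Column names must match
    the documented schema exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    records: list[InstrumentRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row = dict(zip(frame.columns, row))
        rsid = _parse(row["rsid"], str, i, "rsid")
        if rsid in seen:
            raise ValueError(f"row {i}: duplicate rsid {rsid!r}")
        seen.add(rsid)
        try:
            exposure = ExposureAssociation(
                effect_per_allele=_parse(row["gamma"], float, i, "gamma"),
                allele_freq=_parse(row["allele_freq"], float, i, "allele_freq"),
                se=_parse(row["gamma_se"], float, i, "gamma_se", optional=True),
                p_discovery=_parse(row["p_exposure"], float, i, "p_exposure",
                                   optional=True),
                f_statistic=_parse(row["f_statistic"], float, i, "f_statistic",
                                   optional=True),
            )
            outcome = OutcomeAssociation(
                odds_ratio=_parse(row["or_outcome"], float, i, "or_outcome"),
                ci_low=_parse(row["ci_low"], float, i, "ci_low"),
                ci_high=_parse(row["ci_high"], float, i, "ci_high"),
                p_value=_parse(row["p_outcome"], float, i, "p_outcome"),
                source_study=row["source_study"],
            )
            record = InstrumentRecord(
                rsid=rsid,
                locus=row["locus"],
                chromosome=_parse(row["chromosome"], int, i, "chromosome"),
                exposure_decreasing_allele=row["decreasing_allele"],
                exposure=exposure,
                outcome=outcome,
                pathway=_parse(row["pathway"], str, i, "pathway", optional=True)
                or "unknown",
                proxy_rsid=_parse(row["proxy_rsid"], str, i, "proxy_rsid",
                                  optional=True),
                proxy_r2=_parse(row["proxy_r2"], float, i, "proxy_r2",
                                optional=True),
            )
        except ValueError as exc:
            if str(exc).startswith("row "):
                raise
            raise ValueError(f"row {i} ({rsid}): {exc}") from exc
        records.append(record)
    return records


def fixture_path() -> Path:
    """Path to the packaged four-SNP vitamin D / MS instrument table."""
    return Path(resources.files("vitdmr").joinpath("data/camos_imsgc_table1.tsv"))


def load_fixture() -> list[InstrumentRecord]:
    """Load the packaged four-SNP instrument table."""
    return read_instrument_table(fixture_path())
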