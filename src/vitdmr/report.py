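"""Result tabulation: tidy TSV frames and text forest tables."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import InstrumentRecord
from .mr_core import MRResult

__all__ = ["results_frame", "forest_table", "equivalence_frame"]

_RESULT_COLUMNS = [
    "analysis", "model", "n_snps", "alpha", "se", "z", "p", "q", "df",
    "i2", "i2_lo", "i2_hi", "tau2", "sigma", "or_per_sd", "or_lo", "or_hi",
]

_Z975 = stats.norm.ppf(0.975)


def _result_row(analysis: str, result: MRResult) -> dict:
    pooled, het = result.pooled, result.pooled.het
    return {
        "analysis": analysis,
        "model": pooled.model,
        "n_snps": pooled.n,
        "alpha": pooled.alpha,
        "se": pooled.se,
        "z": pooled.z,
        "p": pooled.p,
        "q": het.q,
        "df": het.df,
        "i2": het.i2,
        "i2_lo": het.i2_ci_low,
        "i2_hi": het.i2_ci_high,
        "tau2": het.tau2,
        "sigma": result.sigma_logx,
        "or_per_sd": result.or_per_sd,
        "or_lo": result.or_ci_low,
        "or_hi": result.or_ci_high,
    }


def results_frame(
    analyses: Sequence[tuple[str, dict[str, Optional[MRResult]]]],
) -> pd.DataFrame:
    """One row per (analysis, model), in the documented column order."""
    rows = []
    for name, pair in analyses:
        for model in ("fixed", "random"):
            if pair.get(model) is not None:
                rows.append(_result_row(name, pair[model]))
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def forest_table(
    records: Sequence[InstrumentRecord],
    result: MRResult,
    footnote: Optional[str] = None,
) -> str:
    """Aligned text forest table: per-SNP OR per 1-SD decrease plus pool.

    Rows keep the input (locus) order; ORs are rounded to two decimals
    for display only.
    """
    sigma = result.sigma_logx
    by_rsid = {w.rsid: w for w in result.instruments}
    lines = []
    header = f"{'locus':<10} {'rsid':<12} {'OR/SD':>6} {'95% CI':>14} {'weight %':>9}"
    lines.append(header)
    lines.append("-" * len(header))
    total_w = sum(w.weight for w in result.instruments) or float("nan")
    for record in records:
        w = by_rsid.get(record.rsid)
        if w is None:
            continue
        or_sd = np.exp(w.alpha * sigma)
        lo = np.exp((w.alpha - _Z975 * np.sqrt(w.variance)) * sigma)
        hi = np.exp((w.alpha + _Z975 * np.sqrt(w.variance)) * sigma)
        lines.append(
            f"{record.locus:<10} {record.rsid:<12} {or_sd:>6.2f} "
            f"({lo:>5.2f}-{hi:>5.2f}) {100 * w.weight / total_w:>8.1f}%"
        )
    lines.append("-" * len(header))
    lines.append(
        f"{'pooled':<10} {result.pooled.model:<12} {result.or_per_sd:>6.2f} "
        f"({result.or_ci_low:>5.2f}-{result.or_ci_high:>5.2f}) {100.0:>8.1f}%"
    )
    if footnote:
        lines.append("")
        lines.append(footnote)
    return "\n".join(lines) + "\n"


def equivalence_frame(rows: Sequence[tuple[str, float, float]]) -> pd.DataFrame:
    """Clinical-threshold equivalence table (label, nmol/l, 1-SD level)."""
    return pd.DataFrame(
        rows, columns=["threshold", "level_nmol_l", "plus_one_sd_nmol_l"]
    )
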