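"""Sensitivity reruns: named exclusions, pathway strata, leave-one-out.

MR assumptions (no pleiotropy, no population stratification) cannot be
verified directly, so the analysis is repeated on instrument subsets:
dropping the variant associated with ancestry (DHCR7), dropping the
variant with a plausible pleiotropic route (GC), splitting by biological
pathway (synthesis vs metabolism), and omitting each variant in turn.
A pleiotropic instrument reveals itself when its omission moves the
pooled estimate far more than any other omission does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .instruments import InstrumentRecord
from .mr_core import MRResult, SIGMA_OR, run_mr

__all__ = [
    "SensitivityPlan",
    "exclude_and_rerun",
    "stratify_by_pathway",
    "leave_one_out",
]


@dataclass(frozen=True)
class SensitivityPlan:
    """A named rerun: instruments to drop and/or a pathway split."""

    name: str
    excluded_rsids: frozenset[str] = field(default_factory=frozenset)
    stratify: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "excluded_rsids", frozenset(self.excluded_rsids))


def exclude_and_rerun(
    records: Sequence[InstrumentRecord],
    excluded_rsids: Iterable[str],
    sigma_logx: float = SIGMA_OR,
) -> dict[str, Optional[MRResult]]:
    """Re-run the MR analysis without the named instruments."""
    excluded = set(excluded_rsids)
    available = {r.rsid for r in records}
    unknown = excluded - available
    if unknown:
        raise ValueError(f"excluded rsids not in instrument set: {sorted(unknown)}")
    kept = [r for r in records if r.rsid not in excluded]
    if not kept:
        raise ValueError("exclusion removes every instrument")
    return run_mr(kept, sigma_logx)


def stratify_by_pathway(
    records: Sequence[InstrumentRecord],
    sigma_logx: float = SIGMA_OR,
) -> dict[str, dict[str, Optional[MRResult]]]:
    """Independent MR per pathway stratum (synthesis vs metabolism).

    Every instrument must carry a pathway label; strata of two SNPs have
    their heterogeneity interval flagged unstable by the core.
    """
    unlabeled = [r.rsid for r in records if r.pathway == "unknown"]
    if unlabeled:
        raise ValueError(f"instruments without pathway label: {unlabeled}")
    strata: dict[str, list[InstrumentRecord]] = {}
    for record in records:
        strata.setdefault(record.pathway, []).append(record)
    return {
        pathway: run_mr(members, sigma_logx)
        for pathway, members in strata.items()
    }


def leave_one_out(
    records: Sequence[InstrumentRecord],
    sigma_logx: float = SIGMA_OR,
) -> list[tuple[str, dict[str, Optional[MRResult]]]]:
    """Fixed/random rerun omitting each instrument in turn (n rows)."""
    if len(records) < 2:
        raise ValueError("leave-one-out needs >= 2 instruments")
    return [
        (record.rsid, exclude_and_rerun(records, {record.rsid}, sigma_logx))
        for record in records
    ]
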