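"""Analysis configuration: defaults, YAML/JSON loading, validation."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .mr_core import DEFAULT_THRESHOLDS, SIGMA_OR, SIGMA_THRESH, ClinicalThreshold
from .sensitivity import SensitivityPlan

__all__ = ["AnalysisConfig", "DEFAULT_PLANS"]

#: The canonical sensitivity reruns: drop the ancestry-associated DHCR7
#: variant, drop the potentially pleiotropic GC variant, and split the
#: panel by biological pathway.
DEFAULT_PLANS = (
    SensitivityPlan("excl_DHCR7", frozenset({"rs12785878"})),
    SensitivityPlan("excl_GC", frozenset({"rs2282679"})),
    SensitivityPlan("pathway_strata", frozenset(), stratify=True),
)


@dataclass
class AnalysisConfig:
    """Configuration for the summary-statistic MR pipeline.

    ``sigma_logx`` scales pooled per-unit estimates to the per-SD odds
    ratio; ``sigma_thresh`` is used for the clinical-threshold
    equivalence table.  Two documented calibrations ship as defaults
    because the source tables are mutually inconsistent about the SD of
    log 25OHD (see the methods note).
    """

    instrument_path: Optional[Path] = None     # None -> packaged fixture
    sigma_logx: float = SIGMA_OR
    sigma_thresh: float = SIGMA_THRESH
    fwer: float = 0.05
    plans: Sequence[SensitivityPlan] = DEFAULT_PLANS
    thresholds: Sequence[ClinicalThreshold] = DEFAULT_THRESHOLDS
    output_dir: Path = Path("results")
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.sigma_logx <= 0 or self.sigma_thresh <= 0:
            raise ValueError("sigma values must be > 0")
        if not 0 < self.fwer < 1:
            raise ValueError("fwer must be in (0,1)")
        if self.instrument_path is not None:
            self.instrument_path = Path(self.instrument_path)
        self.output_dir = Path(self.output_dir)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        raw = dict(raw)
        if "plans" in raw:
            raw["plans"] = tuple(
                SensitivityPlan(
                    name=p["name"],
                    excluded_rsids=frozenset(p.get("excluded_rsids", ())),
                    stratify=bool(p.get("stratify", False)),
                )
                for p in raw["plans"]
            )
        if "thresholds" in raw:
            raw["thresholds"] = tuple(
                ClinicalThreshold(t["label"], float(t["level"]))
                for t in raw["thresholds"]
            )
        return cls(**raw)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load YAML or JSON configuration (by extension)."""
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(raw or {})

    def to_dict(self) -> dict:
        raw = asdict(self)
        raw["instrument_path"] = (
            str(self.instrument_path) if self.instrument_path else None
        )
        raw["output_dir"] = str(self.output_dir)
        raw["plans"] = [
            {
                "name": p.name,
                "excluded_rsids": sorted(p.excluded_rsids),
                "stratify": p.stratify,
            }
            for p in self.plans
        ]
        raw["thresholds"] = [
            {"label": t.label, "level": t.level} for t in self.thresholds
        ]
        return raw
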