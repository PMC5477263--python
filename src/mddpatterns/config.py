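"""Pipeline configuration: every threshold of the line-of-therapy algorithm.

All windows and thresholds used anywhere in the pipeline live here, with the
study's published values as defaults, so that sensitivity analyses only ever
touch a config object. Dates are handled on an integer day grid throughout
(days since 1970-01-01, half-open intervals); CSVs carry ISO-8601 dates.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field

# Drug-class vocabulary. Antidepressant (AD) classes vs the atypical
# antipsychotic (AAP) class; anything else is ignored by the regimen engine.
AD_CLASSES = frozenset({"SSRI", "SNRI", "TCA", "other_ad"})
AAP_CLASS = "aap"
MDD_DX_PREFIXES = ("296.2", "296.3")
SCHIZOPHRENIA_PREFIX = "295."
# Mental-health-related: any ICD-9 diagnosis with integer prefix 290..319.
MENTAL_HEALTH_RANGE = (290, 319)

SETTINGS = ("inpatient", "er", "outpatient", "other")

PLAN_TYPES = ("PPO", "HMO/POS-cap", "POS/EPO", "comprehensive", "CDHP/HDHP", "unknown")
REGIONS = ("west", "south", "north_east", "north_central", "unknown")

# ILLUSTRATIVE medical-care CPI table (index points by calendar year). CPI
# values are external facts supplied by the user in real analyses; this table
# is shipped only so the pipeline runs end-to-end and is clearly synthetic —
# a smooth ~4%/year trend, not official BLS numbers.
ILLUSTRATIVE_CPI_MEDICAL = {
    2003: 297.1, 2004: 310.1, 2005: 323.2, 2006: 336.2, 2007: 351.1,
    2008: 364.1, 2009: 375.6, 2010: 388.4, 2011: 400.3, 2012: 414.9,
    2013: 425.1, 2014: 435.3,
}


class PipelineConfig(BaseModel):
    """All tunable thresholds, in days unless noted.

    Defaults are the published study constants; every rule in the engine and
    the selection flowchart reads its threshold from here.
    """

    gap_days: int = Field(42, gt=0, description="supply gap defining discontinuation / episode split")
    escalation_factor: float = Field(1.5, gt=1.0, description="daily-dose ratio defining escalation")
    titration_days: int = Field(21, ge=0, description="per-line window where escalation is ignored as titration")
    switch_window_days: int = Field(42, gt=0, description="max gap for a new regimen to count as a switch (inclusive)")
    monotherapy_window_days: int = Field(30, ge=0, description="post-index window that must be free of a 2nd AD/AAP")
    dx_pair_window_days: int = Field(183, gt=0, description="'6-month' window for the two qualifying MDD claims")
    dx_to_index_window_days: int = Field(30, ge=0, description="index fill must fall within this many days after an MDD dx")
    pre_enrollment_days: int = Field(365, gt=0, description="continuous enrollment required before index")
    post_enrollment_days: int = Field(730, gt=0, description="continuous enrollment required after index")
    enrollment_gap_tolerance_days: int = Field(0, ge=0, description="allowed gap between enrollment spans")
    adequacy_days: int = Field(42, gt=0, description="minimum line duration for adequate treatment")
    max_changes: int = Field(4, gt=0, description="treatment changes followed per patient (fourth line terminal)")
    cohort_report_cutoff: float = Field(0.05, ge=0, le=1, description="cohorts below this share are flagged not-analyzed")
    min_adult_age: int = Field(18, ge=0)
    stockpiling: bool = Field(True, description="carry leftover days supply forward on early refills")
    stockpile_cap_days: int = Field(90, ge=0, description="max leftover supply carried forward")
    escalation_vs_index_dose: bool = Field(
        False, description="compare escalation to the line's starting dose instead of the immediately prior dose"
    )
    distinct_day_mode: bool = Field(
        False, description="count a multi-setting calendar day once instead of once per setting"
    )
    cpi_medical: dict[int, float] = Field(default_factory=lambda: dict(ILLUSTRATIVE_CPI_MEDICAL))
    cpi_target_year: int = 2014

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Stable hash of the full configuration, for run manifests."""
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def is_mdd_code(code: str) -> bool:
    return code.startswith(MDD_DX_PREFIXES)


def is_schizophrenia_code(code: str) -> bool:
    return code.startswith(SCHIZOPHRENIA_PREFIX) or (
        len(code) >= 3 and code[:3] == "295"
    )


def is_mental_health_code(code: str) -> bool:
    """True for any ICD-9 code whose integer part lies in 290..319."""
    head = code.split(".")[0]
    if not head.isdigit():
        return False
    lo, hi = MENTAL_HEALTH_RANGE
    return lo <= int(head) <= hi
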