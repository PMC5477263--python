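"""Study-population selection: the inclusion/exclusion flowchart.

Inclusion requires, in flowchart order: an antidepressant fill (the first one
ever is the index date), two MDD-coded claims (ICD-9 296.2x/296.3x) within a
six-month window, an MDD claim on or up to 30 days before the index fill,
age >= 18 at index, continuous enrollment >= 12 months before and >= 24 months
after index, antidepressant monotherapy during the first 30 days after index
(no second AD ingredient, no atypical antipsychotic), and no schizophrenia
claim (ICD-9 295.xx) at any time. The attrition table counts patients
surviving each step.

Tables arrive as pandas DataFrames on the integer day grid (see ``io``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd

from .config import (
    AAP_CLASS,
    AD_CLASSES,
    PipelineConfig,
    is_mdd_code,
    is_schizophrenia_code,
)
from .io import year_of_day

logger = logging.getLogger(__name__)

CRITERIA = (
    "has_ad_fill",
    "mdd_dx_pair",
    "index_within_30d_of_dx",
    "adult_at_index",
    "continuous_enrollment",
    "monotherapy_30d",
    "no_schizophrenia",
)


@dataclass(frozen=True)
class SelectionResult:
    patient_id: str
    index_date: int | None
    index_ingredient: str | None
    index_class: str | None
    included: bool
    first_failed_criterion: str | None


def _dx_dates(med: pd.DataFrame, code_pred) -> list[int]:
    """Service start dates of claims carrying a matching diagnosis code."""
    dates = []
    for r in med.itertuples():
        codes = str(r.dx_codes).split(";") if r.dx_codes else []
        ok = False
        for c in codes:
            c = c.strip()
            if not c:
                continue
            if not c[0].isdigit():
                warnings.warn(f"malformed ICD-9 code {c!r} skipped", stacklevel=2)
                continue
            if code_pred(c):
                ok = True
        if ok:
            dates.append(int(r.service_start_date))
    return sorted(dates)


def qualify_mdd(dx_dates: list[int], window_days: int = 183) -> int | None:
    """Date of the first claim of the earliest MDD pair within the window.

    ``dx_dates`` are sorted dates of MDD-coded claims; a qualifying pair is
    two claims at most ``window_days`` apart (two distinct claims; same-day
    pairs qualify only if two claims exist that day).
    """
    for a, b in zip(dx_dates, dx_dates[1:]):
        if b - a <= window_days:
            return a
    return None


def find_index(pharm: pd.DataFrame) -> tuple[int, str, str] | None:
    """(index_date, ingredient, class) of the first-ever antidepressant fill."""
    ad = pharm[pharm["drug_class"].isin(AD_CLASSES)]
    if ad.empty:
        return None
    first = ad.sort_values(["fill_date", "ingredient"]).iloc[0]
    return int(first["fill_date"]), str(first["ingredient"]), str(first["drug_class"])


def check_index_proximity(mdd_dates: list[int], index_date: int, window_days: int = 30) -> bool:
    """An MDD dx claim must fall within [index - window, index]."""
    return any(index_date - window_days <= d <= index_date for d in mdd_dates)


def check_windows(
    spans: pd.DataFrame,
    index_date: int,
    age_at_index: int,
    cfg: PipelineConfig,
) -> tuple[bool, bool]:
    """(adult, continuously_enrolled) for the required pre/post windows.

    Enrollment must cover [index - pre, index + post] as a gapless union of
    spans (end dates inclusive; gaps above the configured tolerance break
    continuity).
    """
    adult = age_at_index >= cfg.min_adult_age
    need_start = index_date - cfg.pre_enrollment_days
    need_end = index_date + cfg.post_enrollment_days
    covered_to = None
    for r in spans.sort_values("start_date").itertuples():
        s, e = int(r.start_date), int(r.end_date)
        if covered_to is None:
            if s <= need_start <= e:
                covered_to = e
        else:
            if s - covered_to <= 1 + cfg.enrollment_gap_tolerance_days:
                covered_to = max(covered_to, e)
            elif covered_to >= need_end:
                break
    enrolled = covered_to is not None and covered_to >= need_end
    return adult, enrolled


def check_monotherapy(
    pharm: pd.DataFrame,
    index_date: int,
    index_ingredient: str,
    window_days: int = 30,
) -> bool:
    """No different-AD or AAP fill within [index, index + window] (inclusive)."""
    win = pharm[(pharm["fill_date"] >= index_date) & (pharm["fill_date"] <= index_date + window_days)]
    for r in win.itertuples():
        if r.drug_class == AAP_CLASS:
            return False
        if r.drug_class in AD_CLASSES and str(r.ingredient) != index_ingredient:
            return False
    return True


def apply_selection(
    enrollment: pd.DataFrame,
    pharmacy: pd.DataFrame,
    medical: pd.DataFrame,
    cfg: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full flowchart; return (selection table, attrition table).

    The selection table has one row per patient with the index information,
    study window and, when excluded, the first failed criterion; the attrition
    table counts patients surviving each successive step.
    """
    cfg = cfg or PipelineConfig()
    patients = sorted(
        set(enrollment["patient_id"]) | set(pharmacy["patient_id"]) | set(medical["patient_id"])
    )
    enr_by = dict(tuple(enrollment.groupby("patient_id", sort=False))) if len(enrollment) else {}
    pharm_by = dict(tuple(pharmacy.groupby("patient_id", sort=False))) if len(pharmacy) else {}
    med_by = dict(tuple(medical.groupby("patient_id", sort=False))) if len(medical) else {}
    empty_pharm = pharmacy.iloc[0:0]
    empty_med = medical.iloc[0:0]
    empty_enr = enrollment.iloc[0:0]

    demo = (
        enrollment.drop_duplicates("patient_id").set_index("patient_id")
        if len(enrollment)
        else pd.DataFrame()
    )

    rows = []
    surviving = {c: 0 for c in CRITERIA}
    for pid in patients:
        pharm = pharm_by.get(pid, empty_pharm)
        med = med_by.get(pid, empty_med)
        spans = enr_by.get(pid, empty_enr)
        mdd_dates = _dx_dates(med, is_mdd_code)
        schiz_dates = _dx_dates(med, is_schizophrenia_code)

        failed = None
        index_date = index_ing = index_cls = None
        idx = find_index(pharm)
        if idx is None:
            failed = "has_ad_fill"
        else:
            index_date, index_ing, index_cls = idx
        if failed is None and qualify_mdd(mdd_dates, cfg.dx_pair_window_days) is None:
            failed = "mdd_dx_pair"
        if failed is None and not check_index_proximity(mdd_dates, index_date, cfg.dx_to_index_window_days):
            failed = "index_within_30d_of_dx"
        if failed is None:
            birth_year = int(demo.loc[pid, "birth_year"]) if pid in demo.index else 0
            # age from birth year only (claims carry no full DOB)
            age = year_of_day(index_date) - birth_year
            adult, enrolled = check_windows(spans, index_date, age, cfg)
            if not adult:
                failed = "adult_at_index"
            elif not enrolled:
                failed = "continuous_enrollment"
        if failed is None and not check_monotherapy(pharm, index_date, index_ing, cfg.monotherapy_window_days):
            failed = "monotherapy_30d"
        if failed is None and schiz_dates:
            failed = "no_schizophrenia"

        # study period = index to end of continuous enrollment after index
        study_end = None
        if index_date is not None and len(spans):
            covered_to = None
            for r in spans.sort_values("start_date").itertuples():
                s, e = int(r.start_date), int(r.end_date)
                if covered_to is None:
                    if s <= index_date <= e:
                        covered_to = e
                elif s - covered_to <= 1 + cfg.enrollment_gap_tolerance_days:
                    covered_to = max(covered_to, e)
                else:
                    break
            study_end = covered_to + 1 if covered_to is not None else None  # half-open

        ok = failed is None
        for c in CRITERIA:
            if failed == c:
                break
            surviving[c] += 1
        rows.append(
            {
                "patient_id": pid,
                "index_date": index_date,
                "index_ingredient": index_ing,
                "index_class": index_cls,
                "study_end": study_end,
                "included": ok,
                "first_failed_criterion": failed,
            }
        )
        logger.debug("patient %s: %s", pid, "included" if ok else f"failed {failed}")

    selection = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "index_date", "index_ingredient", "index_class",
            "study_end", "included", "first_failed_criterion",
        ],
    )
    attrition = pd.DataFrame(
        {
            "criterion": list(CRITERIA),
            "n_surviving": [surviving[c] for c in CRITERIA],
        }
    )
    attrition.insert(0, "step", range(1, len(CRITERIA) + 1))
    n_in = int(selection["included"].sum()) if len(selection) else 0
    logger.info("selection: %d of %d patients included", n_in, len(patients))
    return selection, attrition
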