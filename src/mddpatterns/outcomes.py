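"""Baseline characteristics, HCRU and cost aggregation.

Implements the descriptive outcome measures of the study design:

* the Charlson comorbidity index in its Quan ICD-9-CM adaptation, with the
  weighted max-rules for liver disease, diabetes and malignancy;
* days with medical visits — inpatient days (length of stay) plus, per
  non-inpatient setting, distinct calendar days with at least one claim —
  and the share of those days that are mental-health-related (any ICD-9
  diagnosis 290–319 on the day/setting);
* per-patient-per-year (PPPY) normalization by individual follow-up, using a
  365.25-day year, with follow-up running from the index date to the end of
  continuous enrollment;
* healthcare costs inflated to a target year with a medical-component CPI
  table, split into medical vs pharmacy, with mental-health medical and
  MDD-related pharmacy (antidepressant + atypical antipsychotic) shares.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd

from .config import (
    AAP_CLASS,
    AD_CLASSES,
    PipelineConfig,
    SETTINGS,
    is_mental_health_code,
)
from .io import year_of_day

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class CCIFlags:
    """Dichotomous comorbidity indicators entering the Quan-CCI score."""

    mi: bool = False
    chf: bool = False
    pvd: bool = False
    cerebrovascular: bool = False
    dementia: bool = False
    chronic_pulmonary: bool = False
    rheumatologic: bool = False
    peptic_ulcer: bool = False
    mild_liver: bool = False
    moderate_severe_liver: bool = False
    mild_diabetes: bool = False
    chronic_diabetes: bool = False
    hemiplegia: bool = False
    renal: bool = False
    malignancy: bool = False
    metastatic_solid_tumor: bool = False
    aids: bool = False


def cci_score(flags: CCIFlags) -> int:
    """Quan-CCI score: unit weights plus the published max/weight rules.

    score = sum(MI, CHF, PVD, cerebrovascular, dementia, chronic pulmonary,
    rheumatologic, peptic ulcer) + max(mild liver, 3*moderate/severe liver)
    + max(mild diabetes, 2*chronic diabetes) + 2*hemiplegia + 2*renal
    + max(2*malignancy, 6*metastatic solid tumor) + 6*AIDS.
    """
    s = sum(
        int(getattr(flags, f))
        for f in (
            "mi", "chf", "pvd", "cerebrovascular", "dementia",
            "chronic_pulmonary", "rheumatologic", "peptic_ulcer",
        )
    )
    s += max(int(flags.mild_liver), 3 * int(flags.moderate_severe_liver))
    s += max(int(flags.mild_diabetes), 2 * int(flags.chronic_diabetes))
    s += 2 * int(flags.hemiplegia)
    s += 2 * int(flags.renal)
    s += max(2 * int(flags.malignancy), 6 * int(flags.metastatic_solid_tumor))
    s += 6 * int(flags.aids)
    return s


# Quan et al. (2005) ICD-9-CM coding algorithm, as 3- to 5-digit prefixes.
# Standard published lists (abbreviated to prefix granularity); the score
# formula above is what the analysis depends on.
QUAN_ICD9_PREFIXES: dict[str, tuple[str, ...]] = {
    "mi": ("410", "412"),
    "chf": ("398.91", "402.01", "402.11", "402.91", "404.01", "404.03",
            "404.11", "404.13", "404.91", "404.93", "425.4", "425.5",
            "425.6", "425.7", "425.8", "425.9", "428"),
    "pvd": ("093.0", "437.3", "440", "441", "443.1", "443.2", "443.8",
            "443.9", "447.1", "557.1", "557.9", "V43.4"),
    "cerebrovascular": ("362.34", "430", "431", "432", "433", "434", "435",
                        "436", "437", "438"),
    "dementia": ("290", "294.1", "331.2"),
    "chronic_pulmonary": ("416.8", "416.9", "490", "491", "492", "493",
                          "494", "495", "496", "500", "501", "502", "503",
                          "504", "505", "506.4", "508.1", "508.8"),
    "rheumatologic": ("446.5", "710.0", "710.1", "710.2", "710.3", "710.4",
                      "714.0", "714.1", "714.2", "714.8", "725"),
    "peptic_ulcer": ("531", "532", "533", "534"),
    "mild_liver": ("070.22", "070.23", "070.32", "070.33", "070.44",
                   "070.54", "070.6", "070.9", "570", "571.0", "571.2",
                   "571.3", "571.4", "571.5", "571.6", "571.8", "571.9",
                   "573.3", "573.4", "573.8", "573.9", "V42.7"),
    "moderate_severe_liver": ("456.0", "456.1", "456.2", "572.2", "572.3",
                              "572.4", "572.8"),
    "mild_diabetes": ("250.0", "250.1", "250.2", "250.3", "250.8", "250.9"),
    "chronic_diabetes": ("250.4", "250.5", "250.6", "250.7"),
    "hemiplegia": ("334.1", "342", "343", "344.0", "344.1", "344.2",
                   "344.3", "344.4", "344.5", "344.6", "344.9"),
    "renal": ("403.01", "403.11", "403.91", "404.02", "404.03", "404.12",
              "404.13", "404.92", "404.93", "582", "583.0", "583.1",
              "583.2", "583.4", "583.6", "583.7", "585", "586", "588.0",
              "V42.0", "V45.1", "V56"),
    "malignancy": tuple(str(c) for c in range(140, 173)) + tuple(
        str(c) for c in range(174, 196)
    ) + ("200", "201", "202", "203", "204", "205", "206", "207", "208", "238.6"),
    "metastatic_solid_tumor": ("196", "197", "198", "199"),
    "aids": ("042", "043", "044"),
}


def cci_flags_from_codes(codes: list[str]) -> CCIFlags:
    """Map a patient's ICD-9 codes to comorbidity flags by prefix match."""
    hits = {}
    for name, prefixes in QUAN_ICD9_PREFIXES.items():
        hits[name] = any(c.startswith(p) for c in codes for p in prefixes)
    return CCIFlags(**hits)


def _claim_is_mh(dx_codes: str) -> bool:
    return any(is_mental_health_code(c.strip()) for c in str(dx_codes).split(";") if c.strip())


def visit_days(
    medical: pd.DataFrame,
    window_start: int,
    window_end: int,
    *,
    distinct_day_mode: bool = False,
) -> dict:
    """Days with medical visits by setting within ``[window_start, window_end)``.

    Inpatient claims contribute their in-window length of stay; each other
    setting contributes its count of distinct calendar days with a claim. The
    default total sums over settings (a day with both an ER and an outpatient
    claim counts twice); ``distinct_day_mode`` instead counts distinct
    calendar days across the non-inpatient settings once.

    Returns per-setting day counts, the total, and the mental-health-related
    fraction of those day units (a unit is mental-health-related if any of
    its claims carries an ICD-9 diagnosis in 290-319).
    """
    days: dict[str, float] = {s: 0 for s in SETTINGS}
    mh_units = 0
    total_units = 0

    med = medical[
        (medical["service_start_date"] < window_end)
        & (medical["service_end_date"] >= window_start)
    ]
    inpat = med[med["setting"] == "inpatient"]
    for r in inpat.itertuples():
        s = max(int(r.service_start_date), window_start)
        e = min(int(r.service_end_date) + 1, window_end)  # end date inclusive
        n = max(0, e - s)
        days["inpatient"] += n
        total_units += n
        if _claim_is_mh(r.dx_codes):
            mh_units += n

    other = med[med["setting"] != "inpatient"]
    if distinct_day_mode:
        seen: dict[int, bool] = {}
        per_setting: dict[str, set[int]] = {s: set() for s in SETTINGS if s != "inpatient"}
        for r in other.itertuples():
            d = int(r.service_start_date)
            if not window_start <= d < window_end:
                continue
            per_setting[str(r.setting)].add(d)
            seen[d] = seen.get(d, False) or _claim_is_mh(r.dx_codes)
        for s, dd in per_setting.items():
            days[s] = len(dd)
        total_units += len(seen)
        mh_units += sum(seen.values())
    else:
        groups: dict[tuple[str, int], bool] = {}
        for r in other.itertuples():
            d = int(r.service_start_date)
            if not window_start <= d < window_end:
                continue
            key = (str(r.setting), d)
            groups[key] = groups.get(key, False) or _claim_is_mh(r.dx_codes)
        for (setting, _d), is_mh in groups.items():
            days[setting] += 1
            total_units += 1
            mh_units += int(is_mh)

    total = total_units
    return {
        "days_by_setting": days,
        "total_days": total,
        "mental_health_share": (mh_units / total) if total else 0.0,
    }


def pppy(value: float, follow_up_days: int, *, minimum_days: int = 730) -> float:
    """Annualize a per-patient quantity: value * 365.25 / follow-up days."""
    if follow_up_days < minimum_days:
        raise ValueError(
            f"follow-up of {follow_up_days} days is below the {minimum_days}-day study minimum"
        )
    return value * DAYS_PER_YEAR / follow_up_days


def inflate_to_target(
    amount: float,
    service_year: int,
    cpi: dict[int, float],
    target_year: int = 2014,
) -> float:
    """CPI-adjust a cost to target-year dollars: amount * cpi[t]/cpi[y]."""
    if service_year not in cpi or target_year not in cpi:
        raise KeyError(f"CPI table does not cover year {service_year} and/or {target_year}")
    return amount * cpi[target_year] / cpi[service_year]


def patient_hcru_costs(
    medical: pd.DataFrame,
    pharmacy: pd.DataFrame,
    window_start: int,
    window_end: int,
    cfg: PipelineConfig,
) -> dict:
    """Per-patient raw (not annualized) HCRU and inflated cost aggregates."""
    vd = visit_days(
        medical, window_start, window_end, distinct_day_mode=cfg.distinct_day_mode
    )
    med = medical[
        (medical["service_start_date"] >= window_start)
        & (medical["service_start_date"] < window_end)
    ]
    medical_cost = 0.0
    mh_medical_cost = 0.0
    for r in med.itertuples():
        c = inflate_to_target(
            float(r.paid_amount), year_of_day(int(r.service_start_date)),
            cfg.cpi_medical, cfg.cpi_target_year,
        )
        medical_cost += c
        if _claim_is_mh(r.dx_codes):
            mh_medical_cost += c
    pharm = pharmacy[
        (pharmacy["fill_date"] >= window_start) & (pharmacy["fill_date"] < window_end)
    ]
    pharmacy_cost = 0.0
    mdd_pharmacy_cost = 0.0
    for r in pharm.itertuples():
        c = inflate_to_target(
            float(r.paid_amount), year_of_day(int(r.fill_date)),
            cfg.cpi_medical, cfg.cpi_target_year,
        )
        pharmacy_cost += c
        if r.drug_class in AD_CLASSES or r.drug_class == AAP_CLASS:
            mdd_pharmacy_cost += c
    return {
        **vd,
        "medical_cost": medical_cost,
        "mh_medical_cost": mh_medical_cost,
        "pharmacy_cost": pharmacy_cost,
        "mdd_pharmacy_cost": mdd_pharmacy_cost,
        "total_cost": medical_cost + pharmacy_cost,
    }


def group_summary(per_patient: pd.DataFrame, label: str) -> dict:
    """Mean/median PPPY HCRU and cost summary for one cohort or pattern.

    ``per_patient`` needs columns total_days, total_cost, medical_cost,
    pharmacy_cost, mh_medical_cost, mdd_pharmacy_cost, mh_day_units,
    follow_up_days; every column is annualized per patient before averaging.
    """
    if per_patient.empty:
        return {"label": label, "n": 0}
    f = per_patient["follow_up_days"]
    days_pppy = per_patient["total_days"] * DAYS_PER_YEAR / f
    cost_pppy = per_patient["total_cost"] * DAYS_PER_YEAR / f
    med_pppy = per_patient["medical_cost"] * DAYS_PER_YEAR / f
    pharm_pppy = per_patient["pharmacy_cost"] * DAYS_PER_YEAR / f
    tot_days = per_patient["total_days"].sum()
    tot_cost = per_patient["total_cost"].sum()
    return {
        "label": label,
        "n": int(len(per_patient)),
        "mean_days_with_visits_pppy": float(days_pppy.mean()),
        "median_days_with_visits_pppy": float(days_pppy.median()),
        "mental_health_day_share": float(
            per_patient["mh_day_units"].sum() / tot_days if tot_days else 0.0
        ),
        "mean_total_cost_pppy": float(cost_pppy.mean()),
        "median_total_cost_pppy": float(cost_pppy.median()),
        "mean_medical_cost_pppy": float(med_pppy.mean()),
        "mean_pharmacy_cost_pppy": float(pharm_pppy.mean()),
        "mental_health_medical_cost_share": float(
            per_patient["mh_medical_cost"].sum() / tot_cost if tot_cost else 0.0
        ),
        "mdd_pharmacy_cost_share": float(
            per_patient["mdd_pharmacy_cost"].sum() / tot_cost if tot_cost else 0.0
        ),
    }


def cohort_outcomes(
    selected: pd.DataFrame,
    subsample: pd.DataFrame,
    medical: pd.DataFrame,
    pharmacy: pd.DataFrame,
    freq: pd.DataFrame,
    cfg: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Study-period HCRU/cost summaries at cohort and top-pattern level.

    Only cohorts at or above the reporting cutoff (the <5% rule) are
    summarized, mirroring the a-priori analysis restriction.
    """
    cfg = cfg or PipelineConfig()
    sel = selected.set_index("patient_id")
    med_by = dict(tuple(medical.groupby("patient_id", sort=False))) if len(medical) else {}
    pharm_by = dict(tuple(pharmacy.groupby("patient_id", sort=False))) if len(pharmacy) else {}
    empty_med = medical.iloc[0:0]
    empty_pharm = pharmacy.iloc[0:0]

    rows = []
    for r in subsample.itertuples():
        pid = r.patient_id
        start = int(sel.loc[pid, "index_date"])
        end = int(sel.loc[pid, "study_end"])
        agg = patient_hcru_costs(
            med_by.get(pid, empty_med), pharm_by.get(pid, empty_pharm), start, end, cfg
        )
        rows.append(
            {
                "patient_id": pid,
                "cohort": r.cohort,
                "pattern": r.pattern,
                "follow_up_days": end - start,
                "total_days": agg["total_days"],
                "mh_day_units": agg["total_days"] * agg["mental_health_share"],
                "medical_cost": agg["medical_cost"],
                "pharmacy_cost": agg["pharmacy_cost"],
                "mh_medical_cost": agg["mh_medical_cost"],
                "mdd_pharmacy_cost": agg["mdd_pharmacy_cost"],
                "total_cost": agg["total_cost"],
                **{f"days_{s}": agg["days_by_setting"][s] for s in SETTINGS},
            }
        )
    per_patient = pd.DataFrame(rows)

    analyzed = freq[(freq["row_type"] == "cohort") & freq["analyzed"]]["cohort"].tolist()
    cohort_rows = []
    pattern_rows = []
    for cohort in analyzed:
        grp = per_patient[per_patient["cohort"] == cohort] if len(per_patient) else per_patient
        cohort_rows.append({"cohort": cohort, **group_summary(grp, cohort)})
        top = freq[(freq["cohort"] == cohort) & (freq["row_type"] == "pattern")]["label"]
        for pat in top:
            sub = grp[grp["pattern"] == pat]
            pattern_rows.append({"cohort": cohort, "pattern": pat, **group_summary(sub, pat)})
    return pd.DataFrame(cohort_rows), pd.DataFrame(pattern_rows)


def baseline_profile(
    selected: pd.DataFrame,
    enrollment: pd.DataFrame,
    medical: pd.DataFrame,
    pharmacy: pd.DataFrame,
    cfg: PipelineConfig | None = None,
) -> dict:
    """Baseline (12 months pre-index) characterization of included patients.

    Returns age/sex/region/plan/Medicare distributions, the index-AD class
    mix, per-setting baseline visit counts, visits to a mental-health
    professional, baseline total costs (inflated), and the Quan-CCI.
    """
    cfg = cfg or PipelineConfig()
    inc = selected[selected["included"]]
    demo = enrollment.drop_duplicates("patient_id").set_index("patient_id")
    med_by = dict(tuple(medical.groupby("patient_id", sort=False))) if len(medical) else {}
    pharm_by = dict(tuple(pharmacy.groupby("patient_id", sort=False))) if len(pharmacy) else {}
    empty_med = medical.iloc[0:0]
    empty_pharm = pharmacy.iloc[0:0]

    ages, ccis, costs, mh_visits = [], [], [], []
    setting_counts: dict[str, list[int]] = {s: [] for s in SETTINGS}
    sex_counts: dict[str, int] = {}
    region_counts: dict[str, int] = {}
    plan_counts: dict[str, int] = {}
    class_counts: dict[str, int] = {}
    medicare = 0
    for r in inc.itertuples():
        pid = r.patient_id
        idx = int(r.index_date)
        b0, b1 = idx - cfg.pre_enrollment_days, idx
        d = demo.loc[pid]
        ages.append(year_of_day(idx) - int(d["birth_year"]))
        sex_counts[str(d["sex"])] = sex_counts.get(str(d["sex"]), 0) + 1
        region_counts[str(d["region"])] = region_counts.get(str(d["region"]), 0) + 1
        plan_counts[str(d["plan_type"])] = plan_counts.get(str(d["plan_type"]), 0) + 1
        medicare += int(bool(d["medicare_flag"]))
        class_counts[str(r.index_class)] = class_counts.get(str(r.index_class), 0) + 1

        med = med_by.get(pid, empty_med)
        base = med[(med["service_start_date"] >= b0) & (med["service_start_date"] < b1)]
        for s in SETTINGS:
            setting_counts[s].append(int((base["setting"] == s).sum()))
        mh_visits.append(int(base["provider_mental_health_flag"].sum()))
        codes = [
            c.strip()
            for dx in base["dx_codes"]
            for c in str(dx).split(";")
            if c.strip()
        ]
        ccis.append(cci_score(cci_flags_from_codes(codes)))

        cost = sum(
            inflate_to_target(float(x.paid_amount), year_of_day(int(x.service_start_date)),
                              cfg.cpi_medical, cfg.cpi_target_year)
            for x in base.itertuples()
        )
        pharm = pharm_by.get(pid, empty_pharm)
        pbase = pharm[(pharm["fill_date"] >= b0) & (pharm["fill_date"] < b1)]
        cost += sum(
            inflate_to_target(float(x.paid_amount), year_of_day(int(x.fill_date)),
                              cfg.cpi_medical, cfg.cpi_target_year)
            for x in pbase.itertuples()
        )
        costs.append(cost)

    n = len(inc)

    def dist(counts: dict[str, int]) -> dict[str, dict]:
        return {
            k: {"n": v, "percent": round(100 * v / n, 1) if n else 0.0}
            for k, v in sorted(counts.items())
        }

    return {
        "n": n,
        "age_mean": float(np.mean(ages)) if ages else 0.0,
        "age_median": float(np.median(ages)) if ages else 0.0,
        "sex": dist(sex_counts),
        "region": dist(region_counts),
        "plan_type": dist(plan_counts),
        "medicare": {"n": medicare, "percent": round(100 * medicare / n, 1) if n else 0.0},
        "index_class": dist(class_counts),
        "cci_mean": float(np.mean(ccis)) if ccis else 0.0,
        "cci_median": float(np.median(ccis)) if ccis else 0.0,
        "baseline_visits_mean": {
            s: float(np.mean(v)) if v else 0.0 for s, v in setting_counts.items()
        },
        "mh_professional_visits_mean": float(np.mean(mh_visits)) if mh_visits else 0.0,
        "baseline_total_cost_mean": float(np.mean(costs)) if costs else 0.0,
        "baseline_total_cost_median": float(np.median(costs)) if costs else 0.0,
    }
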