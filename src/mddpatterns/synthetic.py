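"""Synthetic claims generator with scripted, labelled treatment trajectories.

Real administrative claims are proprietary, so every downstream stage is
exercised on synthetic tables whose treatment content is *scripted*: a
:class:`TrajectoryScript` states the exact sequence of treatment changes a
patient realizes (with day offsets and parameters), and the generator emits
pharmacy fills that satisfy the change definitions by construction —
back-to-back fills on a day grid, supply ending exactly where a script says a
regimen ends. The intended cohort, pattern string and change dates go into a
ground-truth table against which the line-of-therapy engine is verified.

Visit and cost processes are stochastic but seeded: Poisson visit counts per
care setting, lognormal claim amounts (right-skewed, as claims costs are),
and a configurable share of mental-health-coded diagnoses. Calendar time
spans 2003–2014 so the CPI adjustment is exercised.

Negative-control flags produce patients that violate exactly one selection
criterion each, for attrition testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import PLAN_TYPES, REGIONS, PipelineConfig
from .io import from_day, to_day, year_of_day
from .patterns import SEP, TOKEN
from .regimen import (
    AUGMENTATION,
    COMBINATION,
    DISCONTINUATION,
    DOSE_ESCALATION,
    PERSISTENCE,
    REMAINED_UNTREATED,
    RESUMPTION,
    SWITCH,
    SWITCH_DROP,
)

CHANGE_TYPES = (
    DISCONTINUATION, DOSE_ESCALATION, SWITCH, COMBINATION, AUGMENTATION,
    SWITCH_DROP, RESUMPTION,
)


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    drug_class: str
    strength_mg: float
    brand: bool = False


DEFAULT_CATALOG: tuple[CatalogEntry, ...] = (
    CatalogEntry("sertraline", "SSRI", 50.0),
    CatalogEntry("fluoxetine", "SSRI", 20.0),
    CatalogEntry("citalopram", "SSRI", 20.0),
    CatalogEntry("escitalopram", "SSRI", 10.0, brand=True),
    CatalogEntry("paroxetine", "SSRI", 20.0),
    CatalogEntry("venlafaxine", "SNRI", 75.0),
    CatalogEntry("duloxetine", "SNRI", 30.0, brand=True),
    CatalogEntry("amitriptyline", "TCA", 25.0),
    CatalogEntry("nortriptyline", "TCA", 25.0),
    CatalogEntry("bupropion", "other_ad", 150.0),
    CatalogEntry("mirtazapine", "other_ad", 15.0),
    CatalogEntry("trazodone", "other_ad", 50.0),
    CatalogEntry("aripiprazole", "aap", 5.0, brand=True),
    CatalogEntry("quetiapine", "aap", 100.0),
    CatalogEntry("olanzapine", "aap", 5.0),
    CatalogEntry("risperidone", "aap", 1.0),
    CatalogEntry("atorvastatin", "other", 20.0),
    CatalogEntry("lisinopril", "other", 10.0),
)
_CATALOG_BY_NAME = {c.name: c for c in DEFAULT_CATALOG}

# mental-health (290-319) codes that are neither MDD nor schizophrenia, so
# random visits never interfere with selection controls
_MH_CODES = ("300.00", "311", "309.0", "300.4")
_NON_MH_CODES = ("401.9", "272.4", "724.2", "466.0", "780.79")
_COMORBIDITY_CODES = ("250.00", "428.0", "496", "571.5")


class ScriptError(ValueError):
    """A trajectory script violates its invariants (offending step named)."""


@dataclass(frozen=True)
class Step:
    """One scripted treatment change.

    ``day_offset`` counts from the current line's start. ``params`` by type:
    dose_escalation: factor (>=1.5); switch: ingredient, gap (0..42), dose;
    combination/augmentation: ingredient, dose; switch_drop: drop (ingredient)
    or ingredient+dose to add; resumption: ingredient, dose (day_offset is the
    untreated gap, >= 42). Discontinuation needs no params.
    """

    change_type: str
    day_offset: int
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TrajectoryScript:
    """A patient's scripted trajectory plus demographics."""

    patient_id: str
    index_day: int  # absolute day number of the index fill
    steps: tuple[Step, ...] = ()
    index_ingredient: str = "sertraline"
    index_dose_mg: float = 50.0
    index_offset_days: int = 400  # enrollment starts this many days before index
    post_days: int = 1095  # enrollment/study days after index
    age_at_index: int = 42
    sex: str = "F"
    region: str = "south"
    plan_type: str = "PPO"
    medicare: bool = False
    control: str | None = None  # negative-control flag, see CONTROLS

    def validate(self) -> None:
        if self.index_offset_days < 365:
            raise ScriptError(f"{self.patient_id}: index_offset_days must be >= 365")
        if self.post_days < 730 and self.control not in ("short_enrollment",):
            raise ScriptError(f"{self.patient_id}: post_days must be >= 730")
        prev_type = None
        for i, st in enumerate(self.steps):
            where = f"{self.patient_id} step {i} ({st.change_type})"
            if st.change_type not in CHANGE_TYPES:
                raise ScriptError(f"{where}: unknown change type")
            if i >= 4:
                raise ScriptError(f"{where}: at most 4 change steps (fourth line is terminal)")
            if st.day_offset <= 0:
                raise ScriptError(f"{where}: day_offset must be positive")
            if st.change_type == DOSE_ESCALATION:
                if st.day_offset <= 21:
                    raise ScriptError(f"{where}: escalation must occur after day 21 of the line")
                if st.params.get("factor", 1.5) < 1.5:
                    raise ScriptError(f"{where}: escalation factor must be >= 1.5")
            if st.change_type == RESUMPTION:
                if prev_type != DISCONTINUATION:
                    raise ScriptError(f"{where}: resumption must follow a discontinuation")
                if st.day_offset < 42:
                    raise ScriptError(f"{where}: resumption gap must be >= 42 days")
            if prev_type == DISCONTINUATION and st.change_type != RESUMPTION:
                raise ScriptError(f"{where}: only resumption may follow a discontinuation")
            if st.change_type == SWITCH and not 0 <= st.params.get("gap", 14) <= 42:
                raise ScriptError(f"{where}: switch gap must be within 0..42 days")
            prev_type = st.change_type


CONTROLS = (
    "no_ad", "single_dx", "dx_far_from_index", "underage",
    "short_enrollment", "monotherapy", "schizophrenia",
)
# criterion each control must fail, in flowchart vocabulary
CONTROL_FAILS = {
    "no_ad": "has_ad_fill",
    "single_dx": "mdd_dx_pair",
    "dx_far_from_index": "index_within_30d_of_dx",
    "underage": "adult_at_index",
    "short_enrollment": "continuous_enrollment",
    "monotherapy": "monotherapy_30d",
    "schizophrenia": "no_schizophrenia",
}


@dataclass(frozen=True)
class VisitCostConfig:
    """Stochastic visit/cost process parameters (events per year, 2014-ish USD)."""

    inpatient_rate: float = 0.2
    er_rate: float = 0.4
    outpatient_rate: float = 12.0
    other_rate: float = 1.5
    mental_health_dx_probability: float = 0.3
    comorbidity_probability: float = 0.05
    mh_provider_probability: float = 0.5
    other_rx_rate: float = 2.0
    # lognormal (mu, sigma) of claim paid amounts per setting
    cost_params: dict = field(
        default_factory=lambda: {
            "inpatient": (8.5, 0.7),
            "er": (6.2, 0.6),
            "outpatient": (4.9, 0.8),
            "other": (4.0, 0.8),
        }
    )
    rx_cost_params: dict = field(
        default_factory=lambda: {
            "SSRI": (3.6, 0.5), "SNRI": (4.2, 0.5), "TCA": (3.0, 0.5),
            "other_ad": (3.7, 0.5), "aap": (5.3, 0.5), "other": (3.3, 0.5),
        }
    )

    def validate(self) -> None:
        for r in (self.inpatient_rate, self.er_rate, self.outpatient_rate,
                  self.other_rate, self.other_rx_rate):
            if r < 0:
                raise ValueError("visit rates must be >= 0")
        for p in (self.mental_health_dx_probability, self.comorbidity_probability,
                  self.mh_provider_probability):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# script compilation: scripted changes -> supply segments -> fills + truth
# ---------------------------------------------------------------------------

def _line_duration(change_type: str, event_day: int, line_start: int, supply_end: int) -> int:
    if change_type == SWITCH:
        return supply_end - line_start
    return event_day - line_start


def compile_script(script: TrajectoryScript) -> tuple[list[dict], dict]:
    """Realize a script as supply segments plus its ground-truth record.

    Returns (segments, truth): segments are dicts with ingredient, class,
    dose, start, end (absolute days, half-open); truth carries the cohort,
    canonical pattern string, change days and per-line adequacy.
    """
    script.validate()
    idx = script.index_day
    study_end = idx + script.post_days

    segments: list[dict] = []
    open_segs: dict[str, dict] = {}  # ingredient -> open segment

    def open_component(ingredient: str, dose: float, start: int) -> None:
        entry = _CATALOG_BY_NAME[ingredient]
        seg = {
            "ingredient": ingredient,
            "drug_class": entry.drug_class,
            "dose": dose,
            "start": start,
            "end": None,
        }
        segments.append(seg)
        open_segs[ingredient] = seg

    def close_component(ingredient: str, end: int) -> None:
        seg = open_segs.pop(ingredient)
        seg["end"] = end

    def close_all(end: int) -> None:
        for ing in list(open_segs):
            close_component(ing, end)

    if script.control != "no_ad":
        open_component(script.index_ingredient, script.index_dose_mg, idx)

    line_start = idx
    truth_events: list[dict] = []
    terminal: str | None = PERSISTENCE if script.control != "no_ad" else None
    last_regimen: set[str] = set()

    def _is_ad(ing: str) -> bool:
        return _CATALOG_BY_NAME[ing].drug_class in ("SSRI", "SNRI", "TCA", "other_ad")

    for i, st in enumerate(script.steps):
        where = f"{script.patient_id} step {i}"
        day = line_start + st.day_offset
        if st.change_type == DOSE_ESCALATION:
            ing = st.params.get("ingredient", next(iter(open_segs)))
            if ing not in open_segs:
                raise ScriptError(f"{where}: {ing} not active")
            factor = st.params.get("factor", 1.5)
            dose = open_segs[ing]["dose"] * factor
            close_component(ing, day)
            open_component(ing, dose, day)
            event_day, supply_end = day, day
        elif st.change_type in (COMBINATION, AUGMENTATION):
            ing = st.params["ingredient"]
            want_aap = st.change_type == AUGMENTATION
            if ing in open_segs:
                raise ScriptError(f"{where}: {ing} already active")
            if _is_ad(ing) == want_aap:
                raise ScriptError(f"{where}: wrong drug class for {st.change_type}")
            if len(open_segs) != 1 or not all(_is_ad(a) for a in open_segs):
                raise ScriptError(f"{where}: add-on requires an AD-monotherapy line")
            open_component(ing, st.params.get("dose", _CATALOG_BY_NAME[ing].strength_mg), day)
            event_day, supply_end = day, day
        elif st.change_type == SWITCH_DROP:
            if len(open_segs) < 2:
                raise ScriptError(f"{where}: switch/drop requires a multi-component regimen")
            if "drop" in st.params:
                drop = st.params["drop"]
                if drop not in open_segs:
                    raise ScriptError(f"{where}: cannot drop inactive {drop!r}")
                close_component(drop, day)
            else:
                ing = st.params["ingredient"]
                if ing in open_segs:
                    raise ScriptError(f"{where}: {ing} already active")
                open_component(ing, st.params.get("dose", _CATALOG_BY_NAME[ing].strength_mg), day)
            event_day, supply_end = day, day
        elif st.change_type == DISCONTINUATION:
            last_regimen = set(open_segs)
            close_all(day)
            event_day, supply_end = day, day
            terminal = REMAINED_UNTREATED
        elif st.change_type == RESUMPTION:
            # line_start is the discontinuation day; day_offset is the gap
            ing = st.params.get("ingredient", script.index_ingredient)
            if st.day_offset == 42 and {ing} != last_regimen:
                raise ScriptError(f"{where}: a different regimen at a 42-day gap is a switch")
            dose = st.params.get("dose", _CATALOG_BY_NAME[ing].strength_mg)
            open_component(ing, dose, day)
            event_day, supply_end = day, day
            terminal = PERSISTENCE
        elif st.change_type == SWITCH:
            gap = st.params.get("gap", 14)
            ing = st.params["ingredient"]
            if {ing} == set(open_segs):
                raise ScriptError(f"{where}: switch target equals the current regimen")
            close_all(day)
            new_start = day + gap
            open_component(ing, st.params.get("dose", _CATALOG_BY_NAME[ing].strength_mg), new_start)
            event_day, supply_end = new_start, day
        else:  # pragma: no cover - guarded by validate()
            raise ScriptError(f"{where}: unsupported type")

        dur = _line_duration(st.change_type, event_day, line_start, supply_end)
        truth_events.append(
            {
                "change_type": st.change_type,
                "event_day": event_day,
                "line_start": line_start,
                "duration": dur,
                "adequate": dur >= 42,
            }
        )
        line_start = event_day

    if len(truth_events) == 4:
        terminal = None
    if terminal == REMAINED_UNTREATED and study_end - truth_events[-1]["event_day"] < 42:
        raise ScriptError(
            f"{script.patient_id}: final discontinuation needs >= 42 untreated days before study end"
        )
    close_all(study_end)

    tokens = [TOKEN[e["change_type"]] for e in truth_events]
    if terminal is not None:
        tokens.append(TOKEN[terminal])
    cohort = truth_events[0]["change_type"] if truth_events else PERSISTENCE
    if script.control is not None:
        cohort, pattern = "", ""
    else:
        pattern = SEP.join(tokens) if tokens else TOKEN[PERSISTENCE]

    truth = {
        "patient_id": script.patient_id,
        "cohort": cohort,
        "pattern": pattern,
        "index_date": idx,
        "change_dates": ";".join(from_day(e["event_day"]).isoformat() for e in truth_events),
        "change_days": ";".join(str(e["event_day"]) for e in truth_events),
        "n_changes": len(truth_events),
        "all_lines_adequate": all(e["adequate"] for e in truth_events),
        "control": script.control or "",
        "expected_failure": CONTROL_FAILS.get(script.control, ""),
    }
    return segments, truth


def _segments_to_fills(
    segments: list[dict], rng: np.random.Generator, rx_cost: dict, fill_days: int = 30
) -> list[dict]:
    """Chop supply segments into back-to-back fills (last fill truncated)."""
    fills = []
    for seg in segments:
        entry = _CATALOG_BY_NAME[seg["ingredient"]]
        d = seg["start"]
        while d < seg["end"]:
            supply = min(fill_days, seg["end"] - d)
            mu, sigma = rx_cost[entry.drug_class]
            fills.append(
                {
                    "fill_date": d,
                    "ingredient": entry.name,
                    "drug_class": entry.drug_class,
                    "brand_generic": "brand" if entry.brand else "generic",
                    "strength_mg": entry.strength_mg,
                    "quantity": seg["dose"] * supply / entry.strength_mg,
                    "days_supply": supply,
                    "paid_amount": round(float(rng.lognormal(mu, sigma)), 2),
                }
            )
            d += supply
    return fills


def generate_mdd_diagnoses(script: TrajectoryScript, rng: np.random.Generator) -> list[dict]:
    """Diagnosis claims establishing (or deliberately failing) MDD selection."""
    idx = script.index_day
    code = "296.30" if rng.random() < 0.5 else "296.20"
    rows = []

    def dx(day: int, codes: str) -> dict:
        return {
            "service_start_date": day,
            "service_end_date": day,
            "setting": "outpatient",
            "dx_codes": codes,
            "paid_amount": round(float(rng.lognormal(4.9, 0.5)), 2),
            "provider_mental_health_flag": True,
        }

    if script.control == "single_dx":
        rows.append(dx(idx, code))
    elif script.control == "dx_far_from_index":
        rows.append(dx(idx - 120, code))
        rows.append(dx(idx - 60, code))
    else:
        rows.append(dx(idx - 30, code))
        rows.append(dx(idx, code))
    if script.control == "schizophrenia":
        rows.append(dx(idx + 60, "295.00"))
    return rows


def _random_visits(
    script: TrajectoryScript, cfg: VisitCostConfig, rng: np.random.Generator
) -> list[dict]:
    start = script.index_day - script.index_offset_days
    end = script.index_day + script.post_days
    years = (end - start) / 365.25
    rows = []
    for setting, rate in (
        ("inpatient", cfg.inpatient_rate), ("er", cfg.er_rate),
        ("outpatient", cfg.outpatient_rate), ("other", cfg.other_rate),
    ):
        n = rng.poisson(rate * years)
        days = sorted(int(d) for d in rng.integers(start, end, size=n))
        for d in days:
            is_mh = rng.random() < cfg.mental_health_dx_probability
            if is_mh:
                codes = str(rng.choice(_MH_CODES))
            elif rng.random() < cfg.comorbidity_probability:
                codes = str(rng.choice(_COMORBIDITY_CODES))
            else:
                codes = str(rng.choice(_NON_MH_CODES))
            los = 1 + int(rng.poisson(2.0)) if setting == "inpatient" else 1
            mu, sigma = cfg.cost_params[setting]
            rows.append(
                {
                    "service_start_date": d,
                    "service_end_date": min(d + los - 1, end - 1),
                    "setting": setting,
                    "dx_codes": codes,
                    "paid_amount": round(float(rng.lognormal(mu, sigma)), 2),
                    "provider_mental_health_flag": bool(
                        is_mh and setting == "outpatient" and rng.random() < cfg.mh_provider_probability
                    ),
                }
            )
    return rows


def _other_rx(
    script: TrajectoryScript, cfg: VisitCostConfig, rng: np.random.Generator
) -> list[dict]:
    start = script.index_day - script.index_offset_days
    end = script.index_day + script.post_days
    n = rng.poisson(cfg.other_rx_rate * (end - start) / 365.25)
    rows = []
    mu, sigma = cfg.rx_cost_params["other"]
    for d in sorted(int(x) for x in rng.integers(start, end, size=n)):
        entry = _CATALOG_BY_NAME[str(rng.choice(["atorvastatin", "lisinopril"]))]
        rows.append(
            {
                "fill_date": d,
                "ingredient": entry.name,
                "drug_class": "other",
                "brand_generic": "generic",
                "strength_mg": entry.strength_mg,
                "quantity": 30.0,
                "days_supply": 30,
                "paid_amount": round(float(rng.lognormal(mu, sigma)), 2),
            }
        )
    return rows


def generate_population(
    scripts: list[TrajectoryScript],
    visit_cfg: VisitCostConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Emit (enrollment, pharmacy, medical, ground-truth) day-grid tables.

    Deterministic for a fixed (scripts, config, seed); each patient draws
    from an independent child generator so scripts can be reordered without
    changing any patient's claims.
    """
    visit_cfg = visit_cfg or VisitCostConfig()
    visit_cfg.validate()
    for s in scripts:
        s.validate()

    enr_rows, pharm_rows, med_rows, truth_rows = [], [], [], []
    for i, script in enumerate(sorted(scripts, key=lambda s: s.patient_id)):
        rng = np.random.default_rng([seed, i])
        idx = script.index_day
        if script.control == "short_enrollment":
            enr_start = idx - 100
        else:
            enr_start = idx - script.index_offset_days
        enr_end = idx + script.post_days - 1  # inclusive
        age = 17 if script.control == "underage" else script.age_at_index
        enr_rows.append(
            {
                "patient_id": script.patient_id,
                "start_date": enr_start,
                "end_date": enr_end,
                "plan_type": script.plan_type,
                "medicare_flag": script.medicare,
                "birth_year": year_of_day(idx) - age,
                "sex": script.sex,
                "region": script.region,
            }
        )

        segments, truth = compile_script(script)
        fills = _segments_to_fills(segments, rng, visit_cfg.rx_cost_params)
        if script.control == "monotherapy":
            other_ad = "fluoxetine" if script.index_ingredient != "fluoxetine" else "citalopram"
            entry = _CATALOG_BY_NAME[other_ad]
            fills.append(
                {
                    "fill_date": idx + 10,
                    "ingredient": entry.name,
                    "drug_class": entry.drug_class,
                    "brand_generic": "generic",
                    "strength_mg": entry.strength_mg,
                    "quantity": 7.0,
                    "days_supply": 7,
                    "paid_amount": 12.5,
                }
            )
        fills.extend(_other_rx(script, visit_cfg, rng))
        for f in fills:
            pharm_rows.append({"patient_id": script.patient_id, **f})

        for m in generate_mdd_diagnoses(script, rng) + _random_visits(script, visit_cfg, rng):
            med_rows.append({"patient_id": script.patient_id, **m})
        truth_rows.append(truth)

    enrollment = pd.DataFrame(enr_rows)
    pharmacy = pd.DataFrame(pharm_rows).sort_values(
        ["patient_id", "fill_date", "ingredient"], kind="stable"
    ).reset_index(drop=True)
    medical = pd.DataFrame(med_rows).sort_values(
        ["patient_id", "service_start_date", "setting"], kind="stable"
    ).reset_index(drop=True)
    truth = pd.DataFrame(truth_rows)
    return enrollment, pharmacy, medical, truth


# ---------------------------------------------------------------------------
# scenario builder: populations with a configured cohort/pattern mix
# ---------------------------------------------------------------------------

# cohort mix of the calibrated scenario: the published analysis sub-sample
# proportions (counts 10358/7879/1390/732/588/141 of 21088)
CALIBRATED_COHORT_MIX = {
    DISCONTINUATION: 10358 / 21088,
    DOSE_ESCALATION: 7879 / 21088,
    SWITCH: 1390 / 21088,
    PERSISTENCE: 732 / 21088,
    COMBINATION: 588 / 21088,
    AUGMENTATION: 141 / 21088,
}

_ADS = [c.name for c in DEFAULT_CATALOG if c.drug_class in ("SSRI", "SNRI", "TCA", "other_ad")]
_AAPS = [c.name for c in DEFAULT_CATALOG if c.drug_class == "aap"]
# index class mix close to the published baseline (SSRI-dominated)
_INDEX_CHOICES = (
    ["sertraline", "fluoxetine", "citalopram", "escitalopram", "paroxetine"],
    ["venlafaxine", "duloxetine"],
    ["amitriptyline"],
    ["bupropion", "mirtazapine", "trazodone"],
)
_INDEX_CLASS_P = (0.695, 0.108, 0.010, 0.187)


def _disc_day(rng: np.random.Generator, median_days: int = 161) -> int:
    """Line duration before a discontinuation: lognormal, median 23 weeks.

    Capped at 600 days to keep trajectories inside the follow-up window; the
    cap is far above the median, so the median is unaffected.
    """
    return max(43, min(600, int(round(median_days * float(np.exp(rng.normal(0.0, 0.5)))))))


def _steps_horizon(steps: tuple[Step, ...]) -> int:
    """Day offset of the last scripted event relative to the index date."""
    t = 0
    for st in steps:
        t += st.day_offset
        if st.change_type == SWITCH:
            t += st.params.get("gap", 14)
    return t


def _pick_other(rng: np.random.Generator, pool: list[str], *exclude: str) -> str:
    choices = [p for p in pool if p not in exclude]
    return str(rng.choice(choices))


def make_scenario(
    n_patients: int,
    seed: int = 0,
    cohort_mix: dict[str, float] | None = None,
    inadequate_fraction: float = 0.0,
) -> list[TrajectoryScript]:
    """Scripts for a population with the configured first-change mix.

    Each patient's cohort is drawn from ``cohort_mix`` (default: the
    calibrated mix above); within a cohort, a concrete pattern and its
    timing are drawn from a small menu mirroring the common observed
    patterns. ``inadequate_fraction`` forces that share of patients to an
    inadequate (sub-42-day) first line, for sub-sample restriction tests.
    """
    mix = cohort_mix or CALIBRATED_COHORT_MIX
    cohorts = list(mix)
    probs = np.array([mix[c] for c in cohorts], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    scripts = []
    for i in range(n_patients):
        pid = f"P{i:05d}"
        grp = int(rng.choice(len(cohorts), p=probs))
        cohort = cohorts[grp]
        cls = int(rng.choice(len(_INDEX_CHOICES), p=np.array(_INDEX_CLASS_P) / sum(_INDEX_CLASS_P)))
        index_ing = str(rng.choice(_INDEX_CHOICES[cls]))
        dose = _CATALOG_BY_NAME[index_ing].strength_mg
        index_day = to_day("2004-01-01") + int(rng.integers(0, 7 * 365))
        post = int(rng.integers(760, 1400))
        steps = _pattern_steps(cohort, index_ing, rng, post)
        if inadequate_fraction and rng.random() < inadequate_fraction and steps:
            first = steps[0]
            # day 31..41: past the monotherapy window, below the adequacy bar
            if first.change_type in (DISCONTINUATION, COMBINATION, AUGMENTATION, SWITCH):
                steps = (replace(first, day_offset=int(rng.integers(31, 42))),) + steps[1:]
        post = max(post, _steps_horizon(steps) + 60)
        scripts.append(
            TrajectoryScript(
                patient_id=pid,
                index_day=index_day,
                steps=steps,
                index_ingredient=index_ing,
                index_dose_mg=dose,
                index_offset_days=int(rng.integers(365, 500)),
                post_days=post,
                age_at_index=int(rng.integers(18, 80)),
                sex="F" if rng.random() < 0.611 else "M",
                region=str(rng.choice(REGIONS[:4])),
                plan_type=str(rng.choice(PLAN_TYPES[:5])),
                medicare=bool(rng.random() < 0.071),
            )
        )
    return scripts


def _pattern_steps(
    cohort: str, index_ing: str, rng: np.random.Generator, post_days: int
) -> tuple[Step, ...]:
    """Draw a concrete adequate-duration pattern for one cohort."""
    d1 = _disc_day(rng)
    gap = int(rng.integers(43, 120))
    dur = lambda: int(rng.integers(43, 200))  # noqa: E731 - terse sampler
    if cohort == PERSISTENCE:
        return ()
    if cohort == DISCONTINUATION:
        u = rng.random()
        if u < 0.47:  # disc -> remained untreated
            return (Step(DISCONTINUATION, d1),)
        if u < 0.70:  # disc -> resume -> disc -> resume
            return (
                Step(DISCONTINUATION, d1),
                Step(RESUMPTION, gap, {"ingredient": index_ing}),
                Step(DISCONTINUATION, dur()),
                Step(RESUMPTION, int(rng.integers(43, 120)), {"ingredient": index_ing}),
            )
        if u < 0.85:  # disc -> resume -> disc -> untreated
            return (
                Step(DISCONTINUATION, d1),
                Step(RESUMPTION, gap, {"ingredient": index_ing}),
                Step(DISCONTINUATION, dur()),
            )
        return (  # other: disc -> resume -> persist
            Step(DISCONTINUATION, d1),
            Step(RESUMPTION, gap, {"ingredient": index_ing}),
        )
    if cohort == DOSE_ESCALATION:
        e1 = Step(DOSE_ESCALATION, int(rng.integers(43, 150)))
        u = rng.random()
        if u < 0.25:  # esc -> disc -> untreated
            return (e1, Step(DISCONTINUATION, dur()))
        if u < 0.50:  # esc -> disc -> resume -> disc
            return (
                e1,
                Step(DISCONTINUATION, dur()),
                Step(RESUMPTION, gap, {"ingredient": index_ing}),
                Step(DISCONTINUATION, dur()),
            )
        if u < 0.65:  # esc -> persistence
            return (e1,)
        return (e1, Step(DOSE_ESCALATION, int(rng.integers(43, 150))))  # other
    if cohort == SWITCH:
        new = _pick_other(rng, _ADS, index_ing)
        s1 = Step(SWITCH, d1, {"ingredient": new, "gap": int(rng.integers(0, 43))})
        u = rng.random()
        if u < 0.25:  # switch -> disc -> untreated
            return (s1, Step(DISCONTINUATION, dur()))
        if u < 0.50:  # switch -> disc -> resume -> disc
            return (
                s1,
                Step(DISCONTINUATION, dur()),
                Step(RESUMPTION, gap, {"ingredient": new}),
                Step(DISCONTINUATION, dur()),
            )
        if u < 0.75:  # switch -> esc -> disc -> resume
            return (
                s1,
                Step(DOSE_ESCALATION, int(rng.integers(43, 150))),
                Step(DISCONTINUATION, dur()),
                Step(RESUMPTION, gap, {"ingredient": new}),
            )
        return (s1,)  # other: switch -> persistence
    if cohort == COMBINATION:
        second = _pick_other(rng, _ADS, index_ing)
        c1 = Step(COMBINATION, int(rng.integers(43, 180)), {"ingredient": second})
        u = rng.random()
        if u < 0.35:  # combo -> switch/drop -> disc -> resume
            return (
                c1,
                Step(SWITCH_DROP, dur(), {"drop": second}),
                Step(DISCONTINUATION, dur()),
                Step(RESUMPTION, gap, {"ingredient": index_ing}),
            )
        if u < 0.60:  # combo -> esc -> switch/drop -> combo
            third = _pick_other(rng, _ADS, index_ing, second)
            return (
                c1,
                Step(DOSE_ESCALATION, int(rng.integers(43, 150)), {"ingredient": index_ing}),
                Step(SWITCH_DROP, dur(), {"drop": second}),
                Step(COMBINATION, dur(), {"ingredient": third}),
            )
        return (c1, Step(SWITCH_DROP, dur(), {"drop": index_ing}))  # other
    if cohort == AUGMENTATION:
        aap = str(rng.choice(_AAPS))
        a1 = Step(AUGMENTATION, int(rng.integers(43, 180)), {"ingredient": aap})
        u = rng.random()
        if u < 0.4:  # aug -> switch/drop -> disc -> resume
            return (
                a1,
                Step(SWITCH_DROP, dur(), {"drop": aap}),
                Step(DISCONTINUATION, dur()),
                Step(RESUMPTION, gap, {"ingredient": index_ing}),
            )
        if u < 0.7:  # aug -> persistence
            return (a1,)
        return (a1, Step(SWITCH_DROP, dur(), {"drop": index_ing}))  # other
    raise ValueError(f"unknown cohort {cohort!r}")


def make_negative_controls(index_day: int | None = None) -> list[TrajectoryScript]:
    """One patient per selection criterion, each violating exactly that one."""
    idx = index_day if index_day is not None else to_day("2006-06-15")
    return [
        TrajectoryScript(
            patient_id=f"NC_{c}",
            index_day=idx,
            steps=(),
            control=c,
            post_days=1095 if c != "short_enrollment" else 1095,
        )
        for c in CONTROLS
    ]
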