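"""Line-of-therapy engine: exposure episodes, change detection, line assembly.

The engine turns a patient's antidepressant (AD) and atypical-antipsychotic
(AAP) fills into a sequence of treatment-change events, following the claims
conventions of gap-based persistence analysis:

* A *drug regimen* is identified by its set of active ingredients, except that
  all atypical antipsychotics count as one interchangeable component ("AAP"):
  a change from one AAP molecule to another is not a regimen change, and a
  brand/generic change of the same ingredient is not one either.
* Fills of one component merge into an **exposure episode** while the gap
  between the end of supply and the next fill is shorter than ``gap_days``
  (42 by default); a gap of ``gap_days`` or more splits episodes.
* The first qualifying change ends a line of therapy; the six change types
  are discontinuation, dose escalation, switch, combination, augmentation,
  and — in multi-component lines — switch/drop; resumption re-opens therapy
  after a discontinuation. Up to ``max_changes`` (4) changes are followed.

Two implementations are provided: the interval-algebra engine
(:func:`build_lines`) used by the pipeline, and a brute-force day-by-day
simulation (:func:`day_grid_oracle`) that applies the same definitions
literally on a calendar grid and serves as an independent cross-check.

All dates are integers on a day grid; intervals are half-open ``[start, end)``
so that supply end = fill date + days supply.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .config import AAP_CLASS, AD_CLASSES, PipelineConfig

_EPS = 1e-9

# Regimen pseudo-key for the interchangeable atypical-antipsychotic component.
AAP_KEY = "AAP"

# change types
DISCONTINUATION = "discontinuation"
DOSE_ESCALATION = "dose_escalation"
SWITCH = "switch"
COMBINATION = "combination"
AUGMENTATION = "augmentation"
SWITCH_DROP = "switch_drop"
RESUMPTION = "resumption"
PERSISTENCE = "persistence"
REMAINED_UNTREATED = "remained_untreated"

# same-day tie-break: add-on family before escalation before regimen-end events
_PRIORITY = {COMBINATION: 0, AUGMENTATION: 0, SWITCH_DROP: 0, DOSE_ESCALATION: 1, SWITCH: 2, DISCONTINUATION: 2}


@dataclass(frozen=True)
class Fill:
    """One pharmacy fill on the day grid."""

    fill_date: int
    ingredient: str
    drug_class: str
    strength_mg: float
    quantity: float
    days_supply: int
    brand: bool = False


@dataclass
class ExposureEpisode:
    """A continuous supply interval of one regimen component.

    Dose segments cover the supplied portions only (bridged gaps carry no
    segment) and are kept per actual molecule — dose comparisons are only
    meaningful within one ingredient, even though all AAP molecules share a
    single regimen component. ``dose_segments`` is the flattened, ordered
    view across molecules.
    """

    key: str
    start: int
    supply_end: int
    segments_by_molecule: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)

    @property
    def dose_segments(self) -> list[tuple[int, int, float]]:
        return sorted(seg for segs in self.segments_by_molecule.values() for seg in segs)


@dataclass(frozen=True)
class TreatmentChangeEvent:
    patient_id: str
    line_index: int
    change_type: str
    event_date: int
    line_start_date: int
    line_duration_days: int
    adequate: bool


@dataclass(frozen=True)
class PatientLines:
    """build_lines output: ordered change events plus the terminal state."""

    patient_id: str
    events: tuple[TreatmentChangeEvent, ...]
    terminal: str | None  # persistence / remained_untreated / None when truncated at max_changes


def daily_dose(strength_mg: float, quantity: float, days_supply: int) -> float:
    """mg/day implied by one fill: strength x quantity / days supply."""
    if strength_mg <= 0 or quantity <= 0 or days_supply <= 0:
        raise ValueError("strength, quantity and days supply must be positive")
    return strength_mg * quantity / days_supply


def regimen_key(ingredient: str, drug_class: str) -> str | None:
    """Regimen-identity key for a fill; None for classes the engine ignores."""
    if drug_class in AD_CLASSES:
        return ingredient
    if drug_class == AAP_CLASS:
        return AAP_KEY
    return None


def _coverage(fills: Sequence[Fill], stockpiling: bool, cap: int) -> list[tuple[int, int, float]]:
    """Map one ingredient's fills to (start, end, dose) coverage intervals.

    With stockpiling, an early refill's coverage is deferred until the current
    supply runs out, carrying at most ``cap`` leftover days forward.
    """
    out: list[tuple[int, int, float]] = []
    next_free: int | None = None
    for f in sorted(fills, key=lambda f: f.fill_date):
        start = f.fill_date
        if stockpiling and next_free is not None:
            start = max(f.fill_date, min(next_free, f.fill_date + cap))
        end = start + f.days_supply
        out.append((start, end, daily_dose(f.strength_mg, f.quantity, f.days_supply)))
        next_free = end if next_free is None else max(next_free, end)
    return out


def _merge_episodes(intervals: Iterable[tuple[int, int]], gap_days: int) -> list[tuple[int, int]]:
    """Merge coverage intervals into episodes; a gap >= gap_days splits."""
    eps: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if eps and s - eps[-1][1] < gap_days:
            eps[-1] = (eps[-1][0], max(eps[-1][1], e))
        else:
            eps.append((s, e))
    return eps


def _dose_segments(intervals: Sequence[tuple[int, int, float]]) -> list[tuple[int, int, float]]:
    """Boundary sweep: total daily dose over covered days, equal doses merged."""
    points = sorted({p for s, e, _ in intervals for p in (s, e)})
    segs: list[tuple[int, int, float]] = []
    for a, b in zip(points, points[1:]):
        dose = sum(d for s, e, d in intervals if s <= a and b <= e)
        if dose <= _EPS:
            continue
        if segs and segs[-1][1] == a and abs(segs[-1][2] - dose) <= _EPS:
            segs[-1] = (segs[-1][0], b, segs[-1][2])
        else:
            segs.append((a, b, dose))
    return segs


def build_episodes(
    fills: Sequence[Fill],
    *,
    stockpiling: bool = True,
    stockpile_cap_days: int = 90,
    gap_days: int = 42,
) -> list[ExposureEpisode]:
    """Build exposure episodes for one patient, keyed by regimen component.

    Fills of classes outside AD/AAP are ignored. All AAP molecules share the
    pseudo-component ``AAP`` (interchangeability rule); episode coverage is
    the union of their per-molecule coverage, while dose segments remain at
    molecule level and are attached to the episode they fall in.
    """
    by_key: dict[str, list[Fill]] = {}
    for f in fills:
        key = regimen_key(f.ingredient, f.drug_class)
        if key is not None:
            by_key.setdefault(key, []).append(f)

    episodes: list[ExposureEpisode] = []
    for key, key_fills in by_key.items():
        # stockpiling operates per actual molecule
        cov: list[tuple[int, int, float]] = []
        by_mol: dict[str, list[Fill]] = {}
        for f in key_fills:
            by_mol.setdefault(f.ingredient, []).append(f)
        mol_cov = {
            mol: _coverage(fl, stockpiling, stockpile_cap_days) for mol, fl in by_mol.items()
        }
        for c in mol_cov.values():
            cov.extend(c)
        for ep_start, ep_end in _merge_episodes([(s, e) for s, e, _ in cov], gap_days):
            ep = ExposureEpisode(key=key, start=ep_start, supply_end=ep_end)
            # molecule-level dose segments falling inside this episode
            for mol, c in mol_cov.items():
                inside = [(s, e, d) for s, e, d in c if ep_start <= s < ep_end]
                segs = _dose_segments(inside)
                if segs:
                    ep.segments_by_molecule[mol] = segs
            episodes.append(ep)
    episodes.sort(key=lambda e: (e.start, e.key))
    return episodes


# ---------------------------------------------------------------------------
# individual change detectors (single source of truth for the line scanner)
# ---------------------------------------------------------------------------

def detect_discontinuation(
    regimen_supply_end: int,
    next_initiation: int | None,
    study_end: int,
    *,
    gap_days: int = 42,
    switch_window_days: int = 42,
    same_regimen: bool = False,
) -> int | None:
    """Date of a discontinuation event at a regimen's supply end, or None.

    Fires when the untreated gap after supply end reaches ``gap_days`` with no
    *different* regimen initiated inside the switch window (that is a switch).
    Re-initiation of the same regimen after the split threshold counts as a
    discontinuation (followed by resumption).
    """
    if next_initiation is None:
        return regimen_supply_end if study_end - regimen_supply_end >= gap_days else None
    gap = next_initiation - regimen_supply_end
    if gap <= switch_window_days and not same_regimen:
        return None  # classified as switch
    if gap >= gap_days:
        return regimen_supply_end
    return None


def detect_switch(
    regimen_supply_end: int,
    next_initiation: int | None,
    old_regimen: frozenset[str],
    new_regimen: frozenset[str],
    *,
    switch_window_days: int = 42,
) -> int | None:
    """Date of a switch event (the new regimen's start), or None.

    A switch is the initiation of a different regimen within the switch window
    (inclusive) of the prior regimen's supply end; the comparison is at active-
    ingredient level with all AAPs interchangeable, so brand/generic and
    AAP-to-AAP transitions never qualify.
    """
    if next_initiation is None:
        return None
    if next_initiation - regimen_supply_end > switch_window_days:
        return None
    if new_regimen == old_regimen:
        return None
    return next_initiation


def detect_dose_escalation(
    segments: Sequence[tuple[int, int, float]],
    line_start: int,
    *,
    factor: float = 1.5,
    titration_days: int = 21,
    vs_index_dose: bool = False,
) -> int | None:
    """First qualifying dose-escalation date within a line, or None.

    A boundary qualifies when the new total daily dose is >= ``factor`` times
    the reference dose and the boundary falls after the line's titration
    window. The reference is the immediately prior covered segment's dose, or
    the line's starting dose when ``vs_index_dose`` is set.
    """
    ref: float | None = None
    prior: float | None = None
    for s, e, dose in segments:
        if e <= line_start:
            prior = dose
            continue
        if ref is None:
            # segment in force at (or first after) line start defines the
            # line's baseline dose; its own onset is never an event
            ref = dose
            prior = dose
            continue
        base = ref if vs_index_dose else prior
        if s > line_start + titration_days and base is not None and dose >= factor * base - _EPS:
            return s
        prior = dose
    return None


def detect_addon(
    regimen: frozenset[str],
    new_key: str,
    start: int,
    regimen_supply_end: int,
) -> str | None:
    """Classify a component starting while the line's regimen is active.

    Monotherapy AD line: a second AD is a combination, an AAP an augmentation.
    Multi-component lines treat any regimen change as switch/drop.
    """
    if new_key in regimen or start >= regimen_supply_end:
        return None
    if len(regimen) == 1 and AAP_KEY not in regimen:
        return AUGMENTATION if new_key == AAP_KEY else COMBINATION
    return SWITCH_DROP


def detect_resumption(
    prior_supply_end: int,
    next_fill: int | None,
    *,
    switch_window_days: int = 42,
    same_regimen: bool = False,
) -> int | None:
    """First (re)initiation after a discontinuation gap, or None."""
    if next_fill is None:
        return None
    gap = next_fill - prior_supply_end
    if gap > switch_window_days or same_regimen:
        return next_fill
    return None


# ---------------------------------------------------------------------------
# line assembly
# ---------------------------------------------------------------------------

def _active_keys(episodes: Sequence[ExposureEpisode], date: int) -> frozenset[str]:
    return frozenset(ep.key for ep in episodes if ep.start <= date < ep.supply_end)


def build_lines(
    patient_id: str,
    fills: Sequence[Fill],
    index_date: int,
    study_end: int,
    cfg: PipelineConfig | None = None,
) -> PatientLines:
    """Assemble treatment-change events through the fourth line of therapy.

    Scans each line's regimen for the earliest qualifying change (same-day
    ties broken add-on > escalation > regimen-end events), emits the event,
    and restarts the line at the event date until ``max_changes`` events have
    fired or the study period ends without a change (persistence, or
    "remained untreated" after a final discontinuation).
    """
    cfg = cfg or PipelineConfig()
    episodes = build_episodes(
        fills,
        stockpiling=cfg.stockpiling,
        stockpile_cap_days=cfg.stockpile_cap_days,
        gap_days=cfg.gap_days,
    )
    events: list[TreatmentChangeEvent] = []
    line_start = index_date
    terminal: str | None = None

    def emit(change: str, date: int, start: int, duration: int) -> None:
        events.append(
            TreatmentChangeEvent(
                patient_id=patient_id,
                line_index=len(events) + 1,
                change_type=change,
                event_date=date,
                line_start_date=start,
                line_duration_days=duration,
                adequate=duration >= cfg.adequacy_days,
            )
        )

    while len(events) < cfg.max_changes:
        regimen_eps = {ep.key: ep for ep in episodes if ep.start <= line_start < ep.supply_end}
        if not regimen_eps:
            terminal = REMAINED_UNTREATED
            break
        regimen = frozenset(regimen_eps)
        reg_end = max(ep.supply_end for ep in regimen_eps.values())

        candidates: list[tuple[int, int, str]] = []  # (date, priority, type)

        # add-ons / regimen additions: first episode of a non-regimen key
        # starting inside the active regimen
        for key in {ep.key for ep in episodes} - regimen:
            starts = [ep.start for ep in episodes if ep.key == key and ep.start >= line_start]
            if starts:
                s = min(starts)
                ctype = detect_addon(regimen, key, s, reg_end)
                if ctype is not None:
                    candidates.append((s, _PRIORITY[ctype], ctype))

        # component drop in a multi-component regimen while another continues
        if len(regimen_eps) >= 2:
            for key, ep in regimen_eps.items():
                if ep.supply_end < reg_end and any(
                    o.start <= ep.supply_end < o.supply_end
                    for k, o in regimen_eps.items()
                    if k != key
                ):
                    candidates.append((ep.supply_end, _PRIORITY[SWITCH_DROP], SWITCH_DROP))

        # dose escalation on any molecule of the active regimen (dose
        # comparisons never cross molecules, even inside the AAP component)
        for ep in regimen_eps.values():
            for segs in ep.segments_by_molecule.values():
                b = detect_dose_escalation(
                    [seg for seg in segs if seg[0] < reg_end],
                    line_start,
                    factor=cfg.escalation_factor,
                    titration_days=cfg.titration_days,
                    vs_index_dose=cfg.escalation_vs_index_dose,
                )
                if b is not None and b < reg_end:
                    candidates.append((b, _PRIORITY[DOSE_ESCALATION], DOSE_ESCALATION))

        candidates = [c for c in candidates if c[0] < reg_end]

        if candidates:
            date, _, ctype = min(candidates)
            emit(ctype, date, line_start, date - line_start)
            line_start = date
            continue

        # regimen end: switch vs discontinuation (vs nothing) at reg_end
        future_starts = [ep.start for ep in episodes if ep.start >= reg_end]
        nxt = min(future_starts) if future_starts else None
        new_regimen = _active_keys(episodes, nxt) if nxt is not None else frozenset()
        same = new_regimen == regimen
        sw = detect_switch(reg_end, nxt, regimen, new_regimen, switch_window_days=cfg.switch_window_days)
        if sw is not None:
            emit(SWITCH, sw, line_start, reg_end - line_start)
            line_start = sw
            continue
        disc = detect_discontinuation(
            reg_end, nxt, study_end,
            gap_days=cfg.gap_days, switch_window_days=cfg.switch_window_days, same_regimen=same,
        )
        if disc is not None:
            emit(DISCONTINUATION, disc, line_start, disc - line_start)
            res = detect_resumption(
                disc, nxt, switch_window_days=cfg.switch_window_days, same_regimen=same
            )
            if res is None:
                terminal = REMAINED_UNTREATED
                break
            if len(events) >= cfg.max_changes:
                break
            emit(RESUMPTION, res, disc, res - disc)
            line_start = res
            continue
        # supply runs (or nearly runs) to study end without a change
        terminal = PERSISTENCE
        break
    else:
        terminal = None  # truncated after max_changes

    if len(events) == cfg.max_changes:
        terminal = None
    return PatientLines(patient_id=patient_id, events=tuple(events), terminal=terminal)


# ---------------------------------------------------------------------------
# brute-force day-grid oracle
# ---------------------------------------------------------------------------

def day_grid_oracle(
    patient_id: str,
    fills: Sequence[Fill],
    index_date: int,
    study_end: int,
    cfg: PipelineConfig | None = None,
) -> PatientLines:
    """Day-by-day simulation of the change definitions, for cross-checking.

    Expands supply onto per-day arrays and walks the calendar one day at a
    time, re-deriving bridged exposure runs, dose changes, and gap lengths
    literally. Intended for small inputs; must agree with :func:`build_lines`.
    """
    cfg = cfg or PipelineConfig()
    horizon = study_end - index_date
    if horizon <= 0:
        return PatientLines(patient_id, (), PERSISTENCE)

    # per-molecule daily dose arrays (0 = unsupplied); day i = index_date + i
    mols: dict[str, list[float]] = {}
    mol_key: dict[str, str] = {}
    for f in sorted(fills, key=lambda f: f.fill_date):
        key = regimen_key(f.ingredient, f.drug_class)
        if key is None:
            continue
        mol_key[f.ingredient] = key
        mols.setdefault(f.ingredient, [0.0] * horizon)
    next_free: dict[str, int] = {}
    for f in sorted(fills, key=lambda f: f.fill_date):
        if f.ingredient not in mols:
            continue
        begin = f.fill_date
        if cfg.stockpiling and f.ingredient in next_free:
            begin = max(f.fill_date, min(next_free[f.ingredient], f.fill_date + cfg.stockpile_cap_days))
        dose = daily_dose(f.strength_mg, f.quantity, f.days_supply)
        for d in range(begin, begin + f.days_supply):
            i = d - index_date
            if 0 <= i < horizon:
                mols[f.ingredient][i] += dose
        end = begin + f.days_supply
        next_free[f.ingredient] = max(next_free.get(f.ingredient, end), end)

    keys = sorted(set(mol_key.values()))
    covered: dict[str, list[bool]] = {
        k: [any(mols[m][i] > _EPS for m in mols if mol_key[m] == k) for i in range(horizon)]
        for k in keys
    }

    # bridged activity: gaps shorter than gap_days between covered runs stay active
    active: dict[str, list[bool]] = {}
    for k, cov in covered.items():
        act = list(cov)
        runs: list[tuple[int, int]] = []
        i = 0
        while i < horizon:
            if cov[i]:
                j = i
                while j < horizon and cov[j]:
                    j += 1
                runs.append((i, j))
                i = j
            else:
                i += 1
        for (s1, e1), (s2, e2) in zip(runs, runs[1:]):
            if s2 - e1 < cfg.gap_days:
                for d in range(e1, s2):
                    act[d] = True
        active[k] = act

    def active_at(day: int) -> frozenset[str]:
        i = day - index_date
        if not 0 <= i < horizon:
            return frozenset()
        return frozenset(k for k in keys if active[k][i])

    def run_end(key: str, day: int) -> int:
        i = day - index_date
        while i < horizon and active[key][i]:
            i += 1
        return index_date + i

    events: list[TreatmentChangeEvent] = []
    terminal: str | None = None
    line_start = index_date

    def emit(change: str, date: int, start: int, duration: int) -> None:
        events.append(
            TreatmentChangeEvent(patient_id, len(events) + 1, change, date, start, duration, duration >= cfg.adequacy_days)
        )

    while len(events) < cfg.max_changes:
        regimen = active_at(line_start)
        if not regimen:
            terminal = REMAINED_UNTREATED
            break
        ends = {k: run_end(k, line_start) for k in regimen}
        reg_end = max(ends.values())

        # escalation reference doses at line start (per molecule of the regimen)
        cur: dict[str, float | None] = {}
        for m in mols:
            if mol_key[m] in regimen:
                i0 = line_start - index_date
                cur[m] = mols[m][i0] if 0 <= i0 < horizon and mols[m][i0] > _EPS else None
        ref = dict(cur)

        found: tuple[int, int, str] | None = None
        for day in range(line_start, min(reg_end, study_end)):
            i = day - index_date
            day_cands: list[tuple[int, str]] = []
            # new component starting today while regimen active
            for k in keys:
                if k in regimen:
                    continue
                if active[k][i] and (i == 0 or not active[k][i - 1]):
                    if len(regimen) == 1 and AAP_KEY not in regimen:
                        day_cands.append((_PRIORITY[COMBINATION], AUGMENTATION if k == AAP_KEY else COMBINATION))
                    else:
                        day_cands.append((_PRIORITY[SWITCH_DROP], SWITCH_DROP))
            # component drop while another continues
            if len(regimen) >= 2:
                for k in regimen:
                    if ends[k] == day and any(active[k2][i] for k2 in regimen if k2 != k):
                        day_cands.append((_PRIORITY[SWITCH_DROP], SWITCH_DROP))
            # dose change today
            for m, base in list(cur.items()):
                dose = mols[m][i]
                if dose <= _EPS:
                    continue  # bridged gap: prior dose persists
                if base is None:
                    cur[m] = dose
                    if ref[m] is None:
                        ref[m] = dose
                    continue
                if abs(dose - base) > _EPS:
                    cmp = ref[m] if cfg.escalation_vs_index_dose else base
                    if day > line_start + cfg.titration_days and cmp is not None and dose >= cfg.escalation_factor * cmp - _EPS:
                        day_cands.append((_PRIORITY[DOSE_ESCALATION], DOSE_ESCALATION))
                    cur[m] = dose
            if day_cands:
                prio, ctype = min(day_cands)
                found = (day, prio, ctype)
                break

        if found is not None:
            date, _, ctype = found
            emit(ctype, date, line_start, date - line_start)
            line_start = date
            continue

        # regimen end at reg_end: look for the next initiation day
        nxt = None
        for day in range(reg_end, study_end):
            i = day - index_date
            if any(active[k][i] and (i == 0 or not active[k][i - 1]) for k in keys):
                nxt = day
                break
        new_regimen = active_at(nxt) if nxt is not None else frozenset()
        same = new_regimen == regimen
        if nxt is not None and nxt - reg_end <= cfg.switch_window_days and not same:
            emit(SWITCH, nxt, line_start, reg_end - line_start)
            line_start = nxt
            continue
        if (nxt is None and study_end - reg_end >= cfg.gap_days) or (
            nxt is not None and nxt - reg_end >= cfg.gap_days
        ):
            emit(DISCONTINUATION, reg_end, line_start, reg_end - line_start)
            if nxt is None:
                terminal = REMAINED_UNTREATED
                break
            if len(events) >= cfg.max_changes:
                break
            emit(RESUMPTION, nxt, reg_end, nxt - reg_end)
            line_start = nxt
            continue
        terminal = PERSISTENCE
        break

    if len(events) == cfg.max_changes:
        terminal = None
    return PatientLines(patient_id, tuple(events), terminal)


# ---------------------------------------------------------------------------
# table-level driver
# ---------------------------------------------------------------------------

def fills_from_frame(pharm: pd.DataFrame) -> list[Fill]:
    return [
        Fill(
            fill_date=int(r.fill_date),
            ingredient=str(r.ingredient),
            drug_class=str(r.drug_class),
            strength_mg=float(r.strength_mg),
            quantity=float(r.quantity),
            days_supply=int(r.days_supply),
            brand=bool(getattr(r, "brand_generic", "generic") == "brand"),
        )
        for r in pharm.itertuples()
    ]


def classify_patients(
    pharmacy: pd.DataFrame,
    selected: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    engine=build_lines,
) -> tuple[pd.DataFrame, dict[str, PatientLines]]:
    """Run the line engine for every selected patient.

    ``pharmacy`` must carry integer day-grid ``fill_date``; ``selected`` needs
    ``patient_id``, ``index_date`` and ``study_end`` columns. Returns an
    events table (one row per change) and the per-patient PatientLines.
    """
    cfg = cfg or PipelineConfig()
    rows = []
    lines: dict[str, PatientLines] = {}
    pharm_by_pid = dict(tuple(pharmacy.groupby("patient_id", sort=False)))
    for r in selected.itertuples():
        pid = str(r.patient_id)
        sub = pharm_by_pid.get(pid)
        fills = fills_from_frame(sub) if sub is not None else []
        pl = engine(pid, fills, int(r.index_date), int(r.study_end), cfg)
        lines[pid] = pl
        for ev in pl.events:
            rows.append(
                {
                    "patient_id": pid,
                    "line_index": ev.line_index,
                    "change_type": ev.change_type,
                    "event_date": ev.event_date,
                    "line_start_date": ev.line_start_date,
                    "line_duration_days": ev.line_duration_days,
                    "adequate": ev.adequate,
                }
            )
    events = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "line_index", "change_type", "event_date",
            "line_start_date", "line_duration_days", "adequate",
        ],
    )
    return events, lines
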