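"""Cohort assignment, pattern strings, sub-sample restriction, frequencies.

Cohorts are defined by the *first* treatment change following first-line
initiation (persistence when no change occurs through the study period).
Pattern strings list the changes through the fourth line of therapy, joined
by " → ", with a terminal "Persistence" or "Remained Untreated" token when
fewer than four changes are observed. The analysis sub-sample keeps patients
whose every observed line was adequate (>= 42 days by default); frequency
tables report per-cohort counts and the top patterns as percentages of that
sub-sample, rounded half-up to one decimal.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .config import PipelineConfig
from .regimen import (
    AUGMENTATION,
    COMBINATION,
    DISCONTINUATION,
    DOSE_ESCALATION,
    PERSISTENCE,
    PatientLines,
    REMAINED_UNTREATED,
    RESUMPTION,
    SWITCH,
    SWITCH_DROP,
)

TOKEN = {
    DISCONTINUATION: "Discontinuation",
    DOSE_ESCALATION: "Escalation",
    SWITCH: "Switch",
    COMBINATION: "Combination",
    AUGMENTATION: "Augmentation",
    SWITCH_DROP: "Switch/Drop",
    RESUMPTION: "Resumption",
    PERSISTENCE: "Persistence",
    REMAINED_UNTREATED: "Remained Untreated",
}
SEP = " → "

COHORTS = (DISCONTINUATION, DOSE_ESCALATION, SWITCH, PERSISTENCE, COMBINATION, AUGMENTATION)


def assign_cohort(lines: PatientLines) -> str:
    """Cohort label = type of the first treatment change (persistence if none)."""
    if not lines.events:
        if lines.terminal is None:
            raise ValueError(f"patient {lines.patient_id}: no events and no terminal state")
        return PERSISTENCE if lines.terminal == PERSISTENCE else DISCONTINUATION
    first = lines.events[0].change_type
    if first not in COHORTS:
        raise ValueError(f"patient {lines.patient_id}: first change {first!r} cannot open a pattern")
    return first


def pattern_string(lines: PatientLines) -> str:
    """Canonical " → "-joined change sequence with terminal token."""
    toks = [TOKEN[e.change_type] for e in lines.events]
    if lines.terminal is not None:
        toks.append(TOKEN[lines.terminal])
    return SEP.join(toks)


def patient_patterns(
    all_lines: dict[str, PatientLines],
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """One row per patient: cohort, pattern string, adequacy, sub-sample flag."""
    cfg = cfg or PipelineConfig()
    rows = []
    for pid, pl in all_lines.items():
        adequate = all(e.adequate for e in pl.events)
        rows.append(
            {
                "patient_id": pid,
                "cohort": assign_cohort(pl),
                "pattern": pattern_string(pl),
                "n_changes": len(pl.events),
                "all_lines_adequate": adequate,
                "in_analysis_subsample": adequate,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "cohort", "pattern", "n_changes", "all_lines_adequate", "in_analysis_subsample"],
    )


def restrict_subsample(patterns: pd.DataFrame) -> pd.DataFrame:
    """Keep patients with adequate treatment duration in every observed line."""
    return patterns[patterns["in_analysis_subsample"]].reset_index(drop=True)


def percent(count: int, total: int) -> float:
    """Share of total as a percentage, rounded half-up to one decimal."""
    if total == 0:
        return 0.0
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def frequency_table(
    subsample: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    top_n: int = 3,
) -> pd.DataFrame:
    """Cohort and top-pattern frequency table over the analysis sub-sample.

    Rows: one per cohort (count, percent of sub-sample, analyzed flag per the
    <5% cutoff) followed by its ``top_n`` most common patterns and an
    "other patterns" remainder. Persistence has a single pattern by definition
    and gets no pattern breakdown.
    """
    cfg = cfg or PipelineConfig()
    total = len(subsample)
    rows = []
    for cohort in COHORTS:
        grp = subsample[subsample["cohort"] == cohort]
        n = len(grp)
        share = n / total if total else 0.0
        analyzed = share >= cfg.cohort_report_cutoff
        rows.append(
            {
                "cohort": cohort,
                "label": TOKEN[cohort],
                "row_type": "cohort",
                "count": n,
                "percent": percent(n, total),
                "analyzed": analyzed,
            }
        )
        if cohort == PERSISTENCE:
            continue
        counts = grp["pattern"].value_counts()
        top = counts.head(top_n)
        for pat, c in top.items():
            rows.append(
                {
                    "cohort": cohort,
                    "label": pat,
                    "row_type": "pattern",
                    "count": int(c),
                    "percent": percent(int(c), total),
                    "analyzed": analyzed,
                }
            )
        other = n - int(top.sum())
        rows.append(
            {
                "cohort": cohort,
                "label": "other patterns",
                "row_type": "other",
                "count": other,
                "percent": percent(other, total),
                "analyzed": analyzed,
            }
        )
    out = pd.DataFrame(rows, columns=["cohort", "label", "row_type", "count", "percent", "analyzed"])
    out.attrs["subsample_total"] = total
    return out


def time_to_discontinuation(
    events: pd.DataFrame,
    selected: pd.DataFrame,
    subsample: pd.DataFrame,
) -> pd.Series:
    """Weeks from index date to the first-line discontinuation, per patient.

    Restricted to discontinuation-cohort members of the sub-sample; the
    cohort median is ``.median()`` of the returned series.
    """
    cohort_ids = set(subsample.loc[subsample["cohort"] == DISCONTINUATION, "patient_id"])
    first = events[(events["line_index"] == 1) & (events["change_type"] == DISCONTINUATION)]
    first = first[first["patient_id"].isin(cohort_ids)]
    idx = selected.set_index("patient_id")["index_date"]
    weeks = (first.set_index("patient_id")["event_date"] - idx).dropna() / 7.0
    weeks.name = "weeks_to_discontinuation"
    return weeks
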