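"""End-to-end orchestration: simulate -> select -> classify -> patterns -> outcomes.

Each stage reads and writes the documented CSV tables, so any stage can be
re-run from its inputs alone; ``run_pipeline`` wires them together and writes
a JSON run manifest (config hash, seed, row counts) for reproducibility.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .io import write_claims_csv
from .outcomes import baseline_profile, cohort_outcomes
from .patterns import (
    frequency_table,
    patient_patterns,
    restrict_subsample,
    time_to_discontinuation,
)
from .regimen import classify_patients
from .selection import apply_selection
from .synthetic import VisitCostConfig, generate_population, make_scenario

logger = logging.getLogger(__name__)


def run_pipeline(
    cfg: PipelineConfig,
    out_dir: str | Path,
    *,
    enrollment: pd.DataFrame | None = None,
    pharmacy: pd.DataFrame | None = None,
    medical: pd.DataFrame | None = None,
    simulate_n: int | None = None,
    seed: int = 0,
    visit_cfg: VisitCostConfig | None = None,
) -> dict:
    """Run the full analysis; returns the report bundle as a dict.

    Either pass the three claims tables (day-grid DataFrames) or set
    ``simulate_n`` to generate a calibrated synthetic population first.
    Writes attrition, events, pattern, frequency, HCRU/cost and baseline
    outputs plus ``manifest.json`` under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = None
    if simulate_n is not None:
        scripts = make_scenario(simulate_n, seed=seed)
        enrollment, pharmacy, medical, truth = generate_population(
            scripts, visit_cfg or VisitCostConfig(), seed=seed
        )
        write_claims_csv(enrollment, out / "enrollment.csv", "enrollment")
        write_claims_csv(pharmacy, out / "pharmacy.csv", "pharmacy")
        write_claims_csv(medical, out / "medical.csv", "medical")
        write_claims_csv(truth, out / "ground_truth.csv", "truth")
    if enrollment is None or pharmacy is None or medical is None:
        raise ValueError("either provide all three claims tables or set simulate_n")

    selection, attrition = apply_selection(enrollment, pharmacy, medical, cfg)
    logger.info("attrition:\n%s", attrition.to_string(index=False))
    selected = selection[selection["included"]].reset_index(drop=True)
    selection.to_csv(out / "selection.csv", index=False)
    attrition.to_csv(out / "attrition.csv", index=False)

    events, lines = classify_patients(pharmacy, selected, cfg)
    events.to_csv(out / "events.csv", index=False)
    patterns = patient_patterns(lines, cfg)
    patterns.to_csv(out / "patterns.csv", index=False)
    subsample = restrict_subsample(patterns)
    if subsample.empty:
        logger.warning("analysis sub-sample is empty; downstream outputs will be empty")
    freq = frequency_table(subsample, cfg)
    freq.to_csv(out / "frequency_table.csv", index=False)

    weeks = time_to_discontinuation(events, selected, subsample)
    cohort_hcru, pattern_hcru = cohort_outcomes(
        selected, subsample, medical, pharmacy, freq, cfg
    )
    cohort_hcru.to_csv(out / "cohort_outcomes.csv", index=False)
    pattern_hcru.to_csv(out / "pattern_outcomes.csv", index=False)
    baseline = baseline_profile(selection, enrollment, medical, pharmacy, cfg)
    with open(out / "baseline.json", "w") as fh:
        json.dump(baseline, fh, indent=2)

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": seed,
        "rows": {
            "enrollment": int(len(enrollment)),
            "pharmacy": int(len(pharmacy)),
            "medical": int(len(medical)),
            "selected": int(len(selected)),
            "events": int(len(events)),
            "subsample": int(len(subsample)),
        },
        "median_weeks_to_discontinuation": float(weeks.median()) if len(weeks) else None,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "selection": selection,
        "attrition": attrition,
        "events": events,
        "patterns": patterns,
        "subsample": subsample,
        "frequency": freq,
        "weeks_to_discontinuation": weeks,
        "cohort_outcomes": cohort_hcru,
        "pattern_outcomes": pattern_hcru,
        "baseline": baseline,
        "manifest": manifest,
        "truth": truth,
    }
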