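import pandas as pd
import pytest

from mddpatterns.config import PipelineConfig
from mddpatterns.patterns import patient_patterns
from mddpatterns.regimen import classify_patients
from mddpatterns.selection import apply_selection
from mddpatterns.synthetic import VisitCostConfig, generate_population, make_scenario

SCENARIO_SEED = 11
SCENARIO_N = 600


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def calibrated_population():
    """A calibrated scripted population with its claims tables and truth."""
    scripts = make_scenario(SCENARIO_N, seed=SCENARIO_SEED)
    enr, pharm, med, truth = generate_population(scripts, VisitCostConfig(), seed=SCENARIO_SEED)
    return {"scripts": scripts, "enrollment": enr, "pharmacy": pharm, "medical": med, "truth": truth}


@pytest.fixture(scope="session")
def classified(calibrated_population, cfg):
    """Selection + engine output for the calibrated population."""
    pop = calibrated_population
    selection, attrition = apply_selection(pop["enrollment"], pop["pharmacy"], pop["medical"], cfg)
    selected = selection[selection["included"]].reset_index(drop=True)
    events, lines = classify_patients(pop["pharmacy"], selected, cfg)
    patterns = patient_patterns(lines, cfg)
    return {
        "selection": selection,
        "attrition": attrition,
        "selected": selected,
        "events": events,
        "lines": lines,
        "patterns": patterns,
    }


def merge_with_truth(patterns: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    return patterns.merge(truth, on="patient_id", suffixes=("_engine", "_truth"))
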