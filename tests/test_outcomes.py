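"""CCI scoring, visit-day counting, PPPY and cost aggregation."""

import numpy as np
import pandas as pd
import pytest

from mddpatterns.config import PipelineConfig
from mddpatterns.io import to_day
from mddpatterns.outcomes import (
    DAYS_PER_YEAR,
    CCIFlags,
    cci_flags_from_codes,
    cci_score,
    group_summary,
    inflate_to_target,
    patient_hcru_costs,
    pppy,
    visit_days,
)


class TestCCI:
    def test_all_false_scores_zero(self):
        assert cci_score(CCIFlags()) == 0

    def test_liver_max_rule(self):
        assert cci_score(CCIFlags(mild_liver=True, moderate_severe_liver=True)) == 3
        assert cci_score(CCIFlags(mild_liver=True)) == 1

    def test_diabetes_max_rule(self):
        assert cci_score(CCIFlags(mild_diabetes=True, chronic_diabetes=True)) == 2

    def test_malignancy_max_and_aids(self):
        assert cci_score(CCIFlags(malignancy=True, metastatic_solid_tumor=True, aids=True)) == 12

    def test_double_weights(self):
        assert cci_score(CCIFlags(hemiplegia=True, renal=True)) == 4

    def test_full_formula(self):
        flags = CCIFlags(**{f: True for f in CCIFlags.__dataclass_fields__})
        # 8 unit conditions + 3 (liver) + 2 (diabetes) + 2 + 2 + 6 (metastatic) + 6 (AIDS)
        assert cci_score(flags) == 8 + 3 + 2 + 2 + 2 + 6 + 6

    def test_flags_from_codes(self):
        flags = cci_flags_from_codes(["410.1", "250.41", "571.5", "196.9"])
        assert flags.mi and flags.chronic_diabetes and flags.mild_liver
        assert flags.metastatic_solid_tumor and not flags.aids


def _med(rows):
    return pd.DataFrame(
        rows,
        columns=["patient_id", "service_start_date", "service_end_date", "setting",
                 "dx_codes", "paid_amount", "provider_mental_health_flag"],
    )


class TestVisitDays:
    def test_inpatient_stay_plus_outpatient_days(self):
        med = _med([
            ("p", 10, 12, "inpatient", "300.4", 100.0, False),  # 3-day stay
            ("p", 20, 20, "outpatient", "401.9", 50.0, False),
            ("p", 30, 30, "outpatient", "401.9", 50.0, False),
        ])
        out = visit_days(med, 0, 100)
        assert out["total_days"] == 5
        assert out["days_by_setting"]["inpatient"] == 3
        assert out["days_by_setting"]["outpatient"] == 2

    def test_same_day_two_settings_counts_per_setting(self):
        med = _med([
            ("p", 20, 20, "outpatient", "401.9", 50.0, False),
            ("p", 20, 20, "er", "401.9", 200.0, False),
        ])
        assert visit_days(med, 0, 100)["total_days"] == 2
        assert visit_days(med, 0, 100, distinct_day_mode=True)["total_days"] == 1

    def test_mental_health_day_classification(self):
        med = _med([
            ("p", 20, 20, "outpatient", "300.4", 50.0, False),   # anxiety: MH
            ("p", 30, 30, "outpatient", "401.9", 50.0, False),   # hypertension: not
        ])
        out = visit_days(med, 0, 100)
        assert out["mental_health_share"] == pytest.approx(0.5)

    def test_same_setting_same_day_counts_once(self):
        med = _med([
            ("p", 20, 20, "outpatient", "401.9", 50.0, False),
            ("p", 20, 20, "outpatient", "300.4", 60.0, False),
        ])
        out = visit_days(med, 0, 100)
        assert out["total_days"] == 1
        assert out["mental_health_share"] == 1.0  # any MH claim flags the day

    def test_inpatient_truncated_to_window(self):
        med = _med([("p", 95, 110, "inpatient", "401.9", 100.0, False)])
        assert visit_days(med, 0, 100)["total_days"] == 5  # days 95..99


class TestPPPY:
    def test_known_value(self):
        assert pppy(58, 1461) == pytest.approx(14.5)

    def test_zero_events(self):
        assert pppy(0, 900) == 0.0

    def test_scale_invariance(self):
        assert pppy(10, 730) == pytest.approx(pppy(20, 1460))

    def test_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            pppy(5, 729)


class TestInflation:
    CPI = PipelineConfig().cpi_medical

    def test_target_year_identity(self):
        assert inflate_to_target(100.0, 2014, self.CPI) == pytest.approx(100.0)

    def test_ratio(self):
        cpi = {2010: 388.0, 2014: 446.0}
        assert inflate_to_target(100.0, 2010, cpi) == pytest.approx(100.0 * 446 / 388)

    def test_factor_monotone_for_monotone_table(self):
        factors = [inflate_to_target(1.0, y, self.CPI) for y in sorted(self.CPI)]
        assert all(a >= b for a, b in zip(factors, factors[1:]))

    def test_missing_year_errors(self):
        with pytest.raises(KeyError):
            inflate_to_target(100.0, 1999, self.CPI)


class TestCosts:
    def _cfg(self):
        return PipelineConfig()

    def test_single_mh_claim_two_years(self):
        start = to_day("2014-01-01")
        med = _med([("p", start + 10, start + 10, "outpatient", "311", 100.0, True)])
        pharm = pd.DataFrame(columns=["patient_id", "fill_date", "drug_class", "paid_amount"])
        agg = patient_hcru_costs(med, pharm, start, start + 730, self._cfg())
        assert agg["total_cost"] == pytest.approx(100.0)
        assert agg["mh_medical_cost"] == pytest.approx(100.0)
        assert pppy(agg["total_cost"], 730) == pytest.approx(50.0, abs=0.1)

    def test_mdd_pharmacy_share(self):
        start = to_day("2014-01-01")
        med = _med([])
        pharm = pd.DataFrame(
            [
                {"patient_id": "p", "fill_date": start + 5, "drug_class": "SSRI", "paid_amount": 30.0},
                {"patient_id": "p", "fill_date": start + 6, "drug_class": "other", "paid_amount": 20.0},
            ]
        )
        agg = patient_hcru_costs(med, pharm, start, start + 730, self._cfg())
        assert agg["pharmacy_cost"] == pytest.approx(50.0)
        assert agg["mdd_pharmacy_cost"] / agg["pharmacy_cost"] == pytest.approx(0.6)

    def test_total_is_medical_plus_pharmacy(self):
        rng = np.random.default_rng(3)
        start = to_day("2013-01-01")
        med = _med([
            ("p", start + int(rng.integers(0, 700)), start + int(rng.integers(0, 700)),
             "outpatient", "401.9", float(rng.lognormal(4, 1)), False)
            for _ in range(20)
        ])
        med["service_end_date"] = med["service_start_date"]
        pharm = pd.DataFrame(
            [
                {"patient_id": "p", "fill_date": start + int(rng.integers(0, 700)),
                 "drug_class": "SSRI", "paid_amount": float(rng.lognormal(3, 0.5))}
                for _ in range(10)
            ]
        )
        agg = patient_hcru_costs(med, pharm, start, start + 730, self._cfg())
        assert agg["total_cost"] == pytest.approx(agg["medical_cost"] + agg["pharmacy_cost"])
        assert 0 <= agg["mh_medical_cost"] <= agg["medical_cost"]
        assert 0 <= agg["mdd_pharmacy_cost"] <= agg["pharmacy_cost"]


class TestGroupSummary:
    def test_matches_per_patient_brute_force(self):
        rng = np.random.default_rng(9)
        n = 40
        df = pd.DataFrame(
            {
                "total_days": rng.integers(0, 120, n),
                "total_cost": rng.lognormal(8, 1, n),
                "medical_cost": 0.0,
                "pharmacy_cost": 0.0,
                "mh_medical_cost": 0.0,
                "mdd_pharmacy_cost": 0.0,
                "mh_day_units": rng.integers(0, 40, n),
                "follow_up_days": rng.integers(730, 2000, n),
            }
        )
        df["medical_cost"] = df["total_cost"] * 0.7
        df["pharmacy_cost"] = df["total_cost"] * 0.3
        out = group_summary(df, "g")
        brute_days = np.array(
            [r.total_days * DAYS_PER_YEAR / r.follow_up_days for r in df.itertuples()]
        )
        brute_cost = np.array(
            [r.total_cost * DAYS_PER_YEAR / r.follow_up_days for r in df.itertuples()]
        )
        assert out["mean_days_with_visits_pppy"] == pytest.approx(brute_days.mean())
        assert out["median_days_with_visits_pppy"] == pytest.approx(np.median(brute_days))
        assert out["mean_total_cost_pppy"] == pytest.approx(brute_cost.mean())
        assert out["median_total_cost_pppy"] == pytest.approx(np.median(brute_cost))

    def test_empty_group(self):
        out = group_summary(pd.DataFrame(), "empty")
        assert out == {"label": "empty", "n": 0}
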