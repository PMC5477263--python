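"""Unit and property tests for the line-of-therapy engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mddpatterns.config import PipelineConfig
from mddpatterns.regimen import (
    AUGMENTATION,
    COMBINATION,
    DISCONTINUATION,
    DOSE_ESCALATION,
    PERSISTENCE,
    REMAINED_UNTREATED,
    RESUMPTION,
    SWITCH,
    SWITCH_DROP,
    Fill,
    build_episodes,
    build_lines,
    daily_dose,
    day_grid_oracle,
    detect_addon,
    detect_discontinuation,
    detect_dose_escalation,
    detect_resumption,
    detect_switch,
)

STUDY_END = 1200


def ad(day, supply=30, ingredient="sertraline", dose=50.0, strength=50.0, brand=False):
    return Fill(day, ingredient, "SSRI", strength, dose * supply / strength, supply, brand)


def aap(day, supply=30, ingredient="quetiapine", dose=100.0, strength=100.0):
    return Fill(day, ingredient, "aap", strength, dose * supply / strength, supply)


def run(fills, **cfg_kw):
    return build_lines("p", fills, 0, STUDY_END, PipelineConfig(**cfg_kw))


def seq(result):
    return [e.change_type for e in result.events]


@pytest.mark.parametrize(
    "strength,qty,days,expected",
    [(20.0, 30, 30, 20.0), (10.0, 60, 30, 20.0), (20.0, 45, 30, 30.0)],
)
def test_daily_dose_arithmetic(strength, qty, days, expected):
    assert daily_dose(strength, qty, days) == pytest.approx(expected)


def test_daily_dose_rejects_nonpositive_fields():
    with pytest.raises(ValueError):
        daily_dose(0.0, 30, 30)
    with pytest.raises(ValueError):
        daily_dose(20.0, 30, 0)


class TestEpisodes:
    def test_back_to_back_fills_merge(self):
        eps = build_episodes([ad(0), ad(30)])
        assert len(eps) == 1
        assert (eps[0].start, eps[0].supply_end) == (0, 60)

    def test_gap_at_least_42_splits(self):
        eps = build_episodes([ad(0), ad(100)])  # gap 70
        assert [(e.start, e.supply_end) for e in eps] == [(0, 30), (100, 130)]

    def test_gap_41_bridges(self):
        eps = build_episodes([ad(0), ad(71)])  # gap 41
        assert len(eps) == 1
        assert eps[0].supply_end == 101

    def test_stockpiling_defers_early_refill(self):
        # refill at day 20 while 10 days remain: coverage shifts to day 30
        eps = build_episodes([ad(0), ad(20)], stockpiling=True)
        assert eps[0].supply_end == 60
        # without stockpiling the doses overlap instead
        eps2 = build_episodes([ad(0), ad(20)], stockpiling=False)
        assert eps2[0].supply_end == 50
        assert max(d for _, _, d in eps2[0].dose_segments) == pytest.approx(100.0)

    def test_aap_molecules_share_one_component(self):
        eps = build_episodes([aap(0, ingredient="quetiapine"), aap(30, ingredient="olanzapine", strength=5.0, dose=5.0)])
        assert len(eps) == 1 and eps[0].key == "AAP"
        assert set(eps[0].segments_by_molecule) == {"quetiapine", "olanzapine"}


class TestChangeBoundaries:
    """Day-grid boundary behaviour of each change definition."""

    def test_discontinuation_gap_42_fires_41_does_not(self):
        # supply [0, 60); next same-drug fill after a 42-day gap
        disc = run([ad(0, 60), ad(102)])
        assert seq(disc)[:2] == [DISCONTINUATION, RESUMPTION]
        assert disc.events[0].event_date == 60
        cont = run([ad(0, 60), ad(101, 1099)])  # gap 41 bridges
        assert seq(cont) == []
        assert cont.terminal == PERSISTENCE

    def test_final_gap_to_study_end(self):
        disc = run([ad(0, 60)])
        assert seq(disc) == [DISCONTINUATION]
        assert disc.terminal == REMAINED_UNTREATED
        near_end = build_lines("p", [ad(0, 60)], 0, 90, PipelineConfig())  # only 30 untreated days
        assert near_end.terminal == PERSISTENCE

    def test_escalation_50pct_fires_49pct_does_not(self):
        base = [ad(0, 30, dose=100.0)]
        esc = run(base + [ad(30, 30, dose=150.0)])
        assert seq(esc)[0] == DOSE_ESCALATION
        no = run(base + [ad(30, 30, dose=149.0)])
        assert DOSE_ESCALATION not in seq(no)

    def test_escalation_titration_window_day_21_vs_22(self):
        fills = [ad(0, 21, dose=100.0), ad(21, 30, dose=200.0)]
        assert DOSE_ESCALATION not in seq(run(fills))  # boundary at day 21: titration
        fills = [ad(0, 22, dose=100.0), ad(22, 30, dose=200.0)]
        out = run(fills)
        assert seq(out)[0] == DOSE_ESCALATION
        assert out.events[0].event_date == 22

    def test_switch_window_day_42_vs_43(self):
        sw = run([ad(0, 60), ad(102, ingredient="fluoxetine", strength=20.0, dose=20.0)])
        assert seq(sw)[0] == SWITCH
        assert sw.events[0].line_duration_days == 60
        far = run([ad(0, 60), ad(103, ingredient="fluoxetine", strength=20.0, dose=20.0)])
        assert seq(far)[:2] == [DISCONTINUATION, RESUMPTION]

    def test_dose_decrease_is_never_an_event(self):
        out = run([ad(0, 30, dose=100.0), ad(30, 1170, dose=50.0)])
        assert seq(out) == []


class TestRegimenIdentity:
    def test_brand_generic_same_ingredient_is_continuation(self):
        out = run([
            ad(0, 60, ingredient="escitalopram", strength=10.0, dose=10.0, brand=True),
            ad(70, 1130, ingredient="escitalopram", strength=10.0, dose=10.0, brand=False),
        ])
        assert seq(out) == []

    def test_aap_to_aap_is_not_a_switch(self):
        fills = [
            ad(0, 1200),
            aap(10, 50, ingredient="quetiapine"),
            aap(70, 1130, ingredient="olanzapine", strength=5.0, dose=5.0),
        ]
        out = run(fills)
        assert seq(out) == [AUGMENTATION]

    def test_switch_to_different_ingredient(self):
        out = run([ad(0, 60), ad(90, 1110, ingredient="fluoxetine", strength=20.0, dose=20.0)])
        assert seq(out) == [SWITCH]
        assert out.events[0].event_date == 90


class TestAddOnsAndDrops:
    def test_combination_requires_overlap(self):
        overlap = run([ad(0, 1200), ad(50, 1150, ingredient="bupropion", strength=150.0, dose=150.0)])
        assert seq(overlap) == [COMBINATION]
        assert overlap.events[0].event_date == 50
        no_overlap = run([ad(0, 40), ad(50, 1150, ingredient="bupropion", strength=150.0, dose=150.0)])
        assert COMBINATION not in seq(no_overlap)
        assert seq(no_overlap)[0] == SWITCH

    def test_augmentation_on_aap_overlap(self):
        out = run([ad(0, 1200), aap(50, 1150)])
        assert seq(out) == [AUGMENTATION]

    def test_dropping_one_combination_component_is_switch_drop(self):
        fills = [ad(0, 1200), ad(50, 100, ingredient="bupropion", strength=150.0, dose=150.0)]
        out = run(fills)
        assert seq(out) == [COMBINATION, SWITCH_DROP]
        assert out.events[1].event_date == 150  # bupropion supply end

    def test_resumption_after_untreated_gap(self):
        out = run([ad(0, 60), ad(130, 1070)])
        assert seq(out) == [DISCONTINUATION, RESUMPTION]
        assert out.events[1].event_date == 130
        assert out.events[1].adequate  # gap lines are adequate by construction


class TestDetectors:
    def test_detect_discontinuation_cases(self):
        assert detect_discontinuation(60, 130, STUDY_END) == 60  # gap 70
        assert detect_discontinuation(60, None, 90) is None  # runs to study end
        assert detect_discontinuation(60, 90, STUDY_END) is None  # switch handles gap 30

    def test_detect_switch_cases(self):
        a, b = frozenset({"a"}), frozenset({"b"})
        assert detect_switch(60, 90, a, b) == 90
        assert detect_switch(60, 103, a, b) is None  # beyond the window
        assert detect_switch(60, 90, a, a) is None  # same regimen

    def test_detect_addon_classification(self):
        mono = frozenset({"sertraline"})
        assert detect_addon(mono, "bupropion", 50, 100) == COMBINATION
        assert detect_addon(mono, "AAP", 50, 100) == AUGMENTATION
        combo = frozenset({"sertraline", "bupropion"})
        assert detect_addon(combo, "AAP", 50, 100) == SWITCH_DROP
        assert detect_addon(mono, "bupropion", 100, 100) is None  # no overlap

    def test_detect_resumption_cases(self):
        assert detect_resumption(60, 130) == 130
        assert detect_resumption(60, None) is None
        assert detect_resumption(60, 90) is None  # switch/continuation path

    def test_detect_escalation_prior_vs_index_reference(self):
        segs = [(0, 30, 20.0), (30, 60, 25.0), (60, 90, 40.0)]
        # vs immediately prior: 40 >= 1.5*25 fires at 60
        assert detect_dose_escalation(segs, 0) == 60
        # vs the line's starting dose: 25 < 30, 40 >= 30 still fires at 60
        assert detect_dose_escalation(segs, 0, vs_index_dose=True) == 60
        # a 2x jump inside titration is ignored, later repeat fires
        segs = [(0, 14, 20.0), (14, 40, 40.0)]
        assert detect_dose_escalation(segs, 0) is None


class TestLinesAssembly:
    def test_persistence_terminal(self):
        out = run([ad(0, STUDY_END)])
        assert out.events == ()
        assert out.terminal == PERSISTENCE

    def test_four_changes_truncate(self):
        fills = [ad(0, 60), ad(130, 60), ad(260, 60), ad(400, 800)]
        out = run(fills)
        assert seq(out) == [DISCONTINUATION, RESUMPTION, DISCONTINUATION, RESUMPTION]
        assert out.terminal is None

    def test_escalation_then_discontinuation_pattern(self):
        fills = [ad(0, 30, dose=50.0), ad(30, 60, dose=100.0)]
        out = run(fills)
        assert seq(out) == [DOSE_ESCALATION, DISCONTINUATION]
        assert out.terminal == REMAINED_UNTREATED
        assert out.events[1].line_start_date == 30

    def test_line_duration_and_adequacy(self):
        out = run([ad(0, 41), ad(50, 1150, ingredient="fluoxetine", strength=20.0, dose=20.0)])
        ev = out.events[0]
        assert ev.change_type == SWITCH
        assert ev.line_duration_days == 41
        assert not ev.adequate


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

fill_strategy = st.lists(
    st.tuples(st.integers(0, 400), st.integers(7, 90)), min_size=1, max_size=8
).map(lambda specs: [ad(max(0, d if i else 0), s) for i, (d, s) in enumerate(specs)])


@settings(max_examples=200, derandomize=True, deadline=None)
@given(fill_strategy)
def test_episodes_partition_fills(fills):
    """Episodes of one ingredient are disjoint and cover every fill date."""
    eps = build_episodes(fills)
    spans = sorted((e.start, e.supply_end) for e in eps)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 + 42 <= s2  # disjoint with at least the splitting gap
    for f in fills:
        assert sum(e.start <= f.fill_date < e.supply_end for e in eps) == 1


@settings(max_examples=100, derandomize=True, deadline=None)
@given(fill_strategy, st.integers(43, 90))
def test_gap_threshold_monotonicity(fills, bigger_gap):
    """Raising the discontinuation gap never increases discontinuations."""
    base = build_lines("p", fills, 0, 600, PipelineConfig())
    wide = build_lines(
        "p", fills, 0, 600, PipelineConfig(gap_days=bigger_gap, switch_window_days=bigger_gap)
    )
    n = sum(e.change_type == DISCONTINUATION for e in base.events)
    m = sum(e.change_type == DISCONTINUATION for e in wide.events)
    assert m <= n


def _random_history(rng):
    cat = [
        ("sertraline", "SSRI", 50.0), ("fluoxetine", "SSRI", 20.0),
        ("venlafaxine", "SNRI", 75.0), ("bupropion", "other_ad", 150.0),
        ("quetiapine", "aap", 100.0), ("aripiprazole", "aap", 5.0),
    ]
    fills = []
    for i in range(int(rng.integers(1, 12))):
        name, cls, strength = cat[int(rng.integers(0, 4 if i == 0 else len(cat)))]
        day = 0 if i == 0 else int(rng.integers(0, 800))
        fills.append(Fill(day, name, cls, strength, float(rng.integers(10, 120)), int(rng.integers(7, 91))))
    return fills


def test_escalation_factor_monotonicity():
    """Raising the escalation factor never increases escalation events."""
    rng = np.random.default_rng(5)
    for _ in range(150):
        fills = _random_history(rng)
        n = {}
        for factor in (1.5, 2.0, 3.0):
            out = build_lines("p", fills, 0, 1100, PipelineConfig(escalation_factor=factor))
            n[factor] = sum(e.change_type == DOSE_ESCALATION for e in out.events)
        assert n[3.0] <= n[2.0] <= n[1.5]


def test_oracle_agrees_on_random_histories():
    """Interval engine and day-grid oracle agree event-for-event."""
    rng = np.random.default_rng(17)
    for _ in range(250):
        fills = _random_history(rng)
        assert build_lines("p", fills, 0, 1100) == day_grid_oracle("p", fills, 0, 1100)


def test_oracle_single_fill_discontinuation():
    out = day_grid_oracle("p", [ad(0, 30)], 0, STUDY_END)
    assert seq(out) == [DISCONTINUATION]
    assert out.events[0].event_date == 30  # first unsupplied day
    assert out.terminal == REMAINED_UNTREATED
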