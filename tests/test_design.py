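"""Workload categories, startup/monitor selection, plans and consolidation."""

import pytest

from bracketqc.design import (
    Category,
    NOT_CONTROLLABLE,
    PLAN_CATALOGUE,
    WorkloadProfile,
    categorize_workload,
    consolidate,
    design_monitor,
    design_plan,
    design_startup,
)
from bracketqc.enuf import max_run_size
from bracketqc.power import critical_shift, rejection_probability


@pytest.mark.parametrize(
    "workload, run_size, category",
    [
        (200, 50, "C"),  # the worked example: 200 samples/day -> category C
        (400, 100, "A"),
        (49, 13, "D"),
        (48, 12, "E"),
        (1, 1, "E"),
        (301, 76, "A"),
        (5000, 1250, "A"),  # capped: QC at least every 100 samples
    ],
)
def test_categorize_workload(workload, run_size, category):
    prof = categorize_workload(workload)
    assert prof.run_size == run_size
    assert prof.category == Category(category)


def test_categorize_workload_rejects_nonpositive():
    with pytest.raises(ValueError):
        categorize_workload(0)


def test_startup_band_overrides():
    prof = categorize_workload(200)
    # sigma >= 6: the unified simple single rule
    assert design_startup(6.2, prof).name == "1_2.5s N1"
    # 4 <= sigma < 5: the multirule, regardless of run size
    assert design_startup(4.4, prof).name == "MR N4"
    assert design_startup(4.4, categorize_workload(400)).name == "MR N4"
    # sigma < 4: not controllable
    with pytest.raises(ValueError, match="sigma"):
        design_startup(3.2, prof)


def test_startup_sigma_5_worked_example():
    """At sigma 5 / 200 samples a single 2-SD-limit control reaches Ped >= 0.9."""
    rule = design_startup(5.0, categorize_workload(200))
    assert rule.name == "1_2s N1"
    assert rejection_probability(rule, critical_shift(5.0)) == pytest.approx(0.9115, abs=5e-5)


def test_startup_escalates_when_workload_exceeds_run_bound():
    # at 400 samples/day the 2-SD rule's allowed run (381) falls short;
    # the four-measurement 3-SD rule is the simplest compliant choice
    rule = design_startup(5.0, categorize_workload(400))
    assert rule.name == "1_3s N4"
    assert max_run_size(rule, 5.0) >= 400


def test_monitor_selection():
    prof_c = categorize_workload(200)
    assert design_monitor(5.0, prof_c).name == "1_3s N1"
    # category E at sigma 6: the simplest wide-limit rule already qualifies
    assert design_monitor(6.0, categorize_workload(48)).name == "1_3s N1"
    with pytest.raises(ValueError):
        design_monitor(3.5, prof_c)


def test_monitor_never_returns_the_2sd_rule():
    for sigma in (4.0, 4.5, 5.0, 5.5, 6.0, 6.5):
        for cat in "ABCDE":
            rule = design_monitor(sigma, WorkloadProfile.from_category(cat))
            assert rule.name != "1_2s N1"


@pytest.mark.parametrize(
    "sigma, workload, plan_id",
    [
        (6.2, 100, 1),  # category D at high sigma -> plan 1
        (4.2, 200, 6),  # MR N4 startup with an N-matched monitor
    ],
)
def test_design_plan_catalogued_outcomes(sigma, workload, plan_id):
    a = design_plan("x", "a", sigma, categorize_workload(workload))
    assert a.is_controllable
    assert a.plan.plan_id == plan_id


def test_design_plan_sentinel_below_sigma_4():
    a = design_plan("x", "a", 3.2, categorize_workload(200))
    assert a.plan == NOT_CONTROLLABLE
    assert not a.is_controllable


def test_design_plan_is_deterministic():
    prof = categorize_workload(120)
    first = design_plan("x", "a", 5.3, prof)
    again = design_plan("x", "a", 5.3, prof)
    assert first == again


def test_every_designed_plan_meets_its_criteria():
    """Sweep sigma x category: Ped >= 0.9 at startup, Pfr <= 0.05 at monitor,
    Max E(Nuf) <= 1 at the run size for both stages, and at the daily
    workload for nomogram-constrained startups (sigma >= 5)."""
    for sigma in (4.0, 4.5, 5.0, 5.5, 6.0, 6.5):
        delta = critical_shift(sigma)
        for cat in "ABCDE":
            prof = WorkloadProfile.from_category(cat)
            a = design_plan("x", "a", sigma, prof)
            assert a.is_controllable
            startup, monitor = a.plan.startup, a.plan.monitor
            assert rejection_probability(startup, delta, n_events=200_000) >= 0.9
            assert rejection_probability(monitor, 0.0, n_events=200_000) <= 0.05
            assert max_run_size(monitor, sigma) >= prof.run_size
            assert max_run_size(startup, sigma) >= prof.run_size
            if sigma >= 5.0:
                assert max_run_size(startup, sigma) >= prof.daily_workload


def test_consolidation_reproduces_the_implemented_plans(plan_assignments):
    """The reference assignments consolidate to the implemented configuration:
    general plans (3,2,3,2,3,3), two distinct general plans, four
    individualized plans covering ten parameters on twelve pairs."""
    from bracketqc.reference_data import ANALYZERS, load_implemented_consolidation

    expected = load_implemented_consolidation()
    general = {}
    indiv_pairs = []
    for analyzer in ANALYZERS:
        res = consolidate(plan_assignments, analyzer)
        general[analyzer] = res.general_plan.plan_id
        indiv_pairs += [(analyzer, p, plan.plan_id) for p, plan in res.individualized]
    assert [general[a] for a in ANALYZERS] == [3, 2, 3, 2, 3, 3]
    exp_general = expected.groupby("analyzer")["general_plan_id"].first().to_dict()
    assert general == exp_general
    exp_pairs = {
        (r.analyzer, r.parameter, int(r.individualized_plan_id))
        for r in expected.dropna(subset=["parameter"]).itertuples(index=False)
    }
    assert set(indiv_pairs) == exp_pairs
    assert len(indiv_pairs) == 12
    assert len({p for _, p, _ in indiv_pairs}) == 10
    assert len({pid for _, _, pid in indiv_pairs}) == 4
    assert len(set(general.values())) == 2


def test_consolidation_uncovered_and_degenerate_cases(plan_assignments):
    res = consolidate(plan_assignments, "Alinity_c1")
    assert sorted(res.uncovered) == ["LD", "Magnesium", "Sodium"]
    # a single-parameter analyzer with plan 1 consolidates to plan 1, nothing individualized
    from bracketqc.design import PlanAssignment

    single = [PlanAssignment("only", "Z", 6.5, Category.D, PLAN_CATALOGUE[1])]
    res = consolidate(single, "Z")
    assert res.general_plan.plan_id == 1
    assert res.individualized == []


def test_consolidation_warns_when_nothing_is_controllable():
    from bracketqc.design import PlanAssignment

    bad = [PlanAssignment("p", "Z", 3.0, Category.C, NOT_CONTROLLABLE)]
    with pytest.warns(UserWarning, match="no controllable"):
        res = consolidate(bad, "Z")
    assert res.general_plan is None and res.uncovered == ["p"]
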