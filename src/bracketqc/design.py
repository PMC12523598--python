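"""Multistage (startup/monitor) QC plan design and cross-analyzer consolidation.

The run size between QC events is a quarter of the daily workload, binned
into categories A (100), B (75), C (50), D (25), E (12) — the smallest class
whose capacity covers the run size, capped to A above 100.

Plan selection follows a sigma-band framework:

* sigma >= 6: startup is the unified 1_2.5s N1 choice (a 3-SD single rule
  would also suffice below ~350 samples/day, but one rule is standardized);
* 5 <= sigma < 6: the simplest startup rule achieving Ped >= 0.9 at the
  critical shift whose Max E(Nuf) <= 1 run-size bound covers the daily
  workload;
* 4 <= sigma < 5: the MR N4 multirule, regardless of the desired run size —
  no simpler rule reaches the required error detection;
* sigma < 4: no startup rule achieves Ped >= 0.9; the procedure is not
  controllable and analytical improvement is required.

The monitor stage takes the simplest rule (wide limits first, 1_2s N1
excluded for its ~5% false-rejection rate) with Pfr <= 0.05 whose run-size
bound covers the run size.  Consolidation keeps, per analyzer, the most
demanding "simple" plan (startup with at most two single-rule measurements)
as the general plan; N4-startup plans stay individualized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

from .enuf import max_run_size
from .power import critical_shift, rejection_probability
from .rules import RULES, QCRule

__all__ = [
    "Category",
    "WorkloadProfile",
    "MultistagePlan",
    "PLAN_CATALOGUE",
    "PlanAssignment",
    "ConsolidationResult",
    "categorize_workload",
    "design_startup",
    "design_monitor",
    "design_plan",
    "consolidate",
]

PED_THRESHOLD = 0.9
PFR_THRESHOLD = 0.05
MIN_CONTROLLABLE_SIGMA = 4.0

#: run-size capacity of each workload category
CATEGORY_CAPACITY = {"E": 12, "D": 25, "C": 50, "B": 75, "A": 100}


class Category(str, Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"

    @property
    def capacity(self) -> int:
        return CATEGORY_CAPACITY[self.value]


@dataclass(frozen=True)
class WorkloadProfile:
    """Daily workload, derived run size and run-size category."""

    daily_workload: int
    run_size: int
    category: Category

    @classmethod
    def from_category(cls, category: Category | str) -> "WorkloadProfile":
        """Nominal profile at a category's capacity (workload = 4x capacity)."""
        cat = Category(category)
        return cls(daily_workload=4 * cat.capacity, run_size=cat.capacity, category=cat)


def categorize_workload(daily_workload: int) -> WorkloadProfile:
    """Run size = ceil(workload / 4), binned to the smallest covering category.

    Run sizes above 100 are capped to category A (QC at least every 100
    samples).
    """
    if daily_workload < 1:
        raise ValueError("daily_workload must be >= 1")
    run_size = math.ceil(daily_workload / 4)
    for cat in ("E", "D", "C", "B", "A"):
        if run_size <= CATEGORY_CAPACITY[cat]:
            return WorkloadProfile(daily_workload, run_size, Category(cat))
    return WorkloadProfile(daily_workload, run_size, Category.A)


@dataclass(frozen=True)
class MultistagePlan:
    """A startup/monitor rule pair, optionally carrying its catalogue id."""

    startup: QCRule
    monitor: QCRule
    plan_id: int | None = None

    @property
    def label(self) -> str:
        pid = f"plan {self.plan_id}: " if self.plan_id is not None else ""
        return f"{pid}{self.startup.name} / {self.monitor.name}"


#: the seven catalogued startup/monitor plans
PLAN_CATALOGUE: dict[int, MultistagePlan] = {
    1: MultistagePlan(RULES["1_2.5s N1"], RULES["1_3s N1"], 1),
    2: MultistagePlan(RULES["1_3s N2"], RULES["1_3s N1"], 2),
    3: MultistagePlan(RULES["1_2s N1"], RULES["1_3s N1"], 3),
    4: MultistagePlan(RULES["MR N4"], RULES["1_3s N2"], 4),
    5: MultistagePlan(RULES["1_3s N4"], RULES["1_2.5s N1"], 5),
    6: MultistagePlan(RULES["MR N4"], RULES["1_3s N4"], 6),
    7: MultistagePlan(RULES["1_3s N4"], RULES["1_3s N1"], 7),
}

_CATALOGUE_BY_RULES = {
    (p.startup.name, p.monitor.name): pid for pid, p in PLAN_CATALOGUE.items()
}

#: plans whose startup uses at most two single-rule measurements; these can be
#: run as an analyzer-wide general plan.  Demand order (most demanding startup
#: first) established by Ped dominance over sigma in [4.9, 6].
SIMPLE_PLAN_DEMAND_ORDER = (3, 2, 1)

#: startup candidates for the nomogram-constrained 5-6 sigma band, simplest
#: first (single rules by fewest measurements, then multirule)
STARTUP_CANDIDATES = ("1_2.5s N1", "1_3s N1", "1_2s N1", "1_3s N2", "1_3s N4", "MR N4")

#: monitor candidates, wide limits first (minimizing Pfr); 1_2s N1 excluded
MONITOR_CANDIDATES = ("1_3s N1", "1_2.5s N1", "1_3s N2", "1_3s N4", "MR N4")


class NotControllable(ValueError):
    """No startup rule achieves Ped >= 0.9 (sigma < 4)."""


def design_startup(
    sigma: float,
    workload: WorkloadProfile,
    candidates=STARTUP_CANDIDATES,
    *,
    ped_threshold: float = PED_THRESHOLD,
    criterion: float = 1.0,
    seed: int | None = None,
) -> QCRule:
    """Select the startup rule for a procedure of the given sigma.

    Sigma-band overrides apply first (>= 6 -> 1_2.5s N1; [4, 5) -> MR N4);
    in the [5, 6) band the simplest candidate with Ped >= 0.9 at the
    critical shift and a Max E(Nuf) run bound covering the daily workload
    wins.
    """
    if sigma < MIN_CONTROLLABLE_SIGMA:
        raise NotControllable(f"sigma {sigma} < 4: no startup rule reaches Ped >= 0.9")
    kw = {} if seed is None else {"seed": seed}
    if sigma >= 6.0:
        return RULES["1_2.5s N1"]
    if sigma < 5.0:
        return RULES["MR N4"]
    delta = critical_shift(sigma)
    for name in candidates:
        rule = RULES[name]
        if rejection_probability(rule, delta, **kw) < ped_threshold:
            continue
        if max_run_size(rule, sigma, criterion=criterion, **kw) >= workload.daily_workload:
            return rule
    raise NotControllable(
        f"no startup candidate covers a daily workload of {workload.daily_workload} at sigma {sigma}"
    )


def design_monitor(
    sigma: float,
    workload: WorkloadProfile,
    candidates=MONITOR_CANDIDATES,
    *,
    pfr_threshold: float = PFR_THRESHOLD,
    criterion: float = 1.0,
    seed: int | None = None,
) -> QCRule:
    """Select the monitor rule: simplest with Pfr <= 0.05 covering the run size."""
    if sigma < MIN_CONTROLLABLE_SIGMA:
        raise NotControllable(f"sigma {sigma} < 4: procedure not controllable")
    kw = {} if seed is None else {"seed": seed}
    for name in candidates:
        if name == "1_2s N1":  # excluded: Pfr about 0.05 compromises routine efficiency
            continue
        rule = RULES[name]
        if rejection_probability(rule, 0.0, **kw) > pfr_threshold:
            continue
        if max_run_size(rule, sigma, criterion=criterion, **kw) >= workload.run_size:
            return rule
    raise NotControllable(
        f"no monitor candidate covers a run size of {workload.run_size} at sigma {sigma}"
    )


#: sentinel plan states
NOT_CONTROLLABLE = "not_controllable"
NOT_AVAILABLE = "not_available"


@dataclass(frozen=True)
class PlanAssignment:
    """A parameter/analyzer's designed plan, or a sentinel.

    ``plan`` is a :class:`MultistagePlan`, or the string sentinel
    ``"not_controllable"`` (sigma < 4) / ``"not_available"`` (procedure not
    on this analyzer).
    """

    parameter: str
    analyzer: str
    sigma: float | None
    category: Category | None
    plan: MultistagePlan | str

    @property
    def is_controllable(self) -> bool:
        return isinstance(self.plan, MultistagePlan)


def design_plan(
    parameter: str,
    analyzer: str,
    sigma: float,
    workload: WorkloadProfile,
    *,
    seed: int | None = None,
) -> PlanAssignment:
    """Design the multistage plan for one parameter on one analyzer.

    A sigma below 4 yields the ``not_controllable`` sentinel rather than an
    error.  When the startup/monitor pair matches a catalogued plan its id is
    attached.
    """
    if sigma < MIN_CONTROLLABLE_SIGMA:
        return PlanAssignment(parameter, analyzer, sigma, workload.category, NOT_CONTROLLABLE)
    startup = design_startup(sigma, workload, seed=seed)
    monitor = design_monitor(sigma, workload, seed=seed)
    pid = _CATALOGUE_BY_RULES.get((startup.name, monitor.name))
    return PlanAssignment(
        parameter, analyzer, sigma, workload.category, MultistagePlan(startup, monitor, pid)
    )


@dataclass
class ConsolidationResult:
    """Per-analyzer general plan plus the individualized N4-startup plans."""

    analyzer: str
    general_plan: MultistagePlan | None
    individualized: list[tuple[str, MultistagePlan]] = field(default_factory=list)
    uncovered: list[str] = field(default_factory=list)
    general_parameters: list[str] = field(default_factory=list)


def _is_simple(plan: MultistagePlan) -> bool:
    """Simple = startup is a single rule with at most 2 measurements."""
    return (not plan.startup.is_multirule) and plan.startup.n_per_event <= 2


def consolidate(assignments, analyzer: str) -> ConsolidationResult:
    """Consolidate one analyzer's assignments into general + individualized plans.

    The general plan is the most demanding *simple* plan present (demand
    order: 1_2s N1 startup > 1_3s N2 startup > 1_2.5s N1 startup); it covers
    every parameter whose own plan is simple.  Plans with a 4-measurement
    startup (multirule or 1_3s N4) remain individualized.  Parameters with
    sigma < 4 are listed as uncovered.
    """
    assignments = [a for a in assignments if a.analyzer == analyzer]
    result = ConsolidationResult(analyzer, None)
    simple_present: set[int] = set()
    for a in assignments:
        if a.plan == NOT_AVAILABLE:
            continue
        if a.plan == NOT_CONTROLLABLE:
            result.uncovered.append(a.parameter)
            continue
        if _is_simple(a.plan):
            result.general_parameters.append(a.parameter)
            if a.plan.plan_id is not None:
                simple_present.add(a.plan.plan_id)
        else:
            result.individualized.append((a.parameter, a.plan))
    if not result.general_parameters and not result.individualized:
        import warnings

        warnings.warn(f"{analyzer}: no controllable parameters to consolidate", stacklevel=2)
        return result
    for pid in SIMPLE_PLAN_DEMAND_ORDER:
        if pid in simple_present:
            result.general_plan = PLAN_CATALOGUE[pid]
            break
    result.individualized.sort(key=lambda t: (t[1].plan_id or 99, t[0]))
    return result
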