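"""Reference laboratory dataset bundled with the package.

A transcription of the published multi-analyzer core-laboratory study this
design procedure was validated on: 35 biochemistry parameters across four
Alinity c and two Cobas Pro analyzers, with per-parameter mean sigma values,
the seven-plan startup/monitor catalogue, the per-parameter plan and
run-size-category assignments, and the consolidated (general +
individualized) plans actually implemented.

Transcription conventions:

* sigma values reported as ">= 6" are encoded as exactly ``6.0`` with
  ``censored_ge6 = True`` — a conservative lower bound for downstream rule
  selection (the raw computed sigma is not recoverable);
* ``status = "sigma_below_4"`` marks parameters reported without a plan
  ("-"): no startup rule achieves Ped >= 0.9 below sigma 4;
* ``status = "not_available"`` marks parameters not offered on an analyzer;
  such rows are skipped in all aggregations.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .design import PLAN_CATALOGUE, MultistagePlan, NOT_AVAILABLE, NOT_CONTROLLABLE, PlanAssignment, Category

__all__ = [
    "load_sigma_table",
    "load_plan_catalogue",
    "load_plan_assignments",
    "load_implemented_consolidation",
    "assignments_from_table",
    "ANALYZERS",
]

ANALYZERS = (
    "Alinity_c1",
    "Alinity_c2",
    "Alinity_c3",
    "Alinity_c4",
    "Cobas_Pro_1",
    "Cobas_Pro_2",
)


def _read(name: str) -> pd.DataFrame:
    with resources.files("bracketqc.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_sigma_table(platform: str = "all") -> pd.DataFrame:
    """Mean sigma per parameter and analyzer.

    ``platform`` is ``"alinity"``, ``"cobas"`` or ``"all"``.  Rows where the
    procedure is not offered have ``available = False`` and a missing sigma.
    """
    frames = []
    if platform in ("alinity", "all"):
        frames.append(_read("alinity_sigma.csv"))
    if platform in ("cobas", "all"):
        frames.append(_read("cobas_sigma.csv"))
    if not frames:
        raise ValueError(f"unknown platform {platform!r}")
    return pd.concat(frames, ignore_index=True)


def load_plan_catalogue() -> pd.DataFrame:
    """The seven catalogued startup/monitor plan definitions."""
    return _read("qc_plan_catalogue.csv")


def load_plan_assignments(platform: str = "all") -> pd.DataFrame:
    """Per-parameter plan id and run-size category on each analyzer."""
    frames = []
    if platform in ("alinity", "all"):
        frames.append(_read("alinity_plan_assignments.csv"))
    if platform in ("cobas", "all"):
        frames.append(_read("cobas_plan_assignments.csv"))
    if not frames:
        raise ValueError(f"unknown platform {platform!r}")
    df = pd.concat(frames, ignore_index=True)
    df["plan_id"] = df["plan_id"].astype("Int64")
    return df


def load_implemented_consolidation() -> pd.DataFrame:
    """The general plan per analyzer and the individualized plan/parameter pairs."""
    df = _read("implemented_consolidation.csv")
    df["individualized_plan_id"] = df["individualized_plan_id"].astype("Int64")
    return df


def assignments_from_table(df: pd.DataFrame) -> list[PlanAssignment]:
    """Convert an assignment table into :class:`PlanAssignment` records.

    Sigma is not carried by the table; sentinel rows map to the
    ``not_controllable`` / ``not_available`` plan states.
    """
    out: list[PlanAssignment] = []
    for row in df.itertuples(index=False):
        if row.status == "not_available":
            plan: MultistagePlan | str = NOT_AVAILABLE
            cat = None
        elif row.status == "sigma_below_4":
            plan = NOT_CONTROLLABLE
            cat = Category(row.category)
        else:
            plan = PLAN_CATALOGUE[int(row.plan_id)]
            cat = Category(row.category)
        out.append(PlanAssignment(row.parameter, row.analyzer, None, cat, plan))
    return out
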