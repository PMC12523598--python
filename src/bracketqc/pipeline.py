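"""End-to-end pipeline: IQC summaries -> sigma -> plans -> consolidation -> report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import (
    NOT_CONTROLLABLE,
    PlanAssignment,
    categorize_workload,
    consolidate,
    design_plan,
)
from .enuf import build_nomogram
from .io import (
    RunConfig,
    read_iqc_stats,
    read_tea_specs,
    read_workloads,
    validate_inputs,
    write_json,
)
from .rules import RULES
from .sigma import ControlLevelStats, PerformanceSpec, SourceTier, select_tea

__all__ = ["PipelineResult", "sigma_report", "run_pipeline"]

log = logging.getLogger("bracketqc.pipeline")


def sigma_report(iqc: pd.DataFrame, tea: pd.DataFrame) -> pd.DataFrame:
    """Per parameter/analyzer sigma assessment from IQC summaries and TEa specs.

    Multiple TEa rows per parameter are treated as candidate specifications;
    the most demanding one yielding acceptable performance is selected.
    """
    rows = []
    for (param, analyzer), grp in iqc.groupby(["parameter", "analyzer"], sort=True):
        levels = [
            ControlLevelStats(
                level_id=str(r.level_id),
                target_value=float(r.target_value),
                observed_mean=float(r.observed_mean),
                cv_pct=float(r.cv_pct),
                n_obs=int(r.n_obs),
                is_low_concentration=bool(r.is_low_concentration),
            )
            for r in grp.itertuples(index=False)
        ]
        cand_rows = tea[tea["parameter"] == param]
        if cand_rows.empty:
            raise ValueError(f"no TEa specification for parameter {param!r}")
        candidates = [
            PerformanceSpec(float(r.tea_pct), SourceTier(r.source_tier))
            for r in cand_rows.itertuples(index=False)
        ]
        spec, assessment = select_tea(candidates, levels)
        rows.append(
            {
                "parameter": param,
                "analyzer": analyzer,
                "tea_pct": spec.tea_pct,
                "tea_source": spec.source_tier.value,
                "mean_sigma": assessment.mean_sigma,
                "min_sigma": min(s for _, s in assessment.per_level_sigma),
                "acceptable": assessment.acceptable,
                "low_level_exception_used": assessment.low_level_exception_used,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    sigma_report: pd.DataFrame
    assignments: list[PlanAssignment]
    assignment_table: pd.DataFrame
    consolidations: dict
    nomogram: "object"
    summary: dict
    outputs: dict[str, str] = field(default_factory=dict)


def _assignment_table(assignments) -> pd.DataFrame:
    rows = []
    for a in assignments:
        plan_id = a.plan.plan_id if a.is_controllable else None
        rows.append(
            {
                "parameter": a.parameter,
                "analyzer": a.analyzer,
                "sigma": a.sigma,
                "category": a.category.value if a.category else None,
                "plan_id": plan_id,
                "startup": a.plan.startup.name if a.is_controllable else None,
                "monitor": a.plan.monitor.name if a.is_controllable else None,
                "status": "assigned" if a.is_controllable else a.plan,
            }
        )
    df = pd.DataFrame(rows)
    df["plan_id"] = df["plan_id"].astype("Int64")
    return df


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full design procedure and write the report bundle.

    Stages: validate inputs, sigma assessment with TEa selection, per
    parameter/analyzer plan design (run size = a quarter of the daily
    workload), per-analyzer consolidation, nomogram recomputation, and a
    human-readable summary.  Deterministic given ``config.seed``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    iqc = read_iqc_stats(config.iqc_path)
    tea = read_tea_specs(config.tea_path)
    workloads = read_workloads(config.workload_path)
    report = validate_inputs(iqc, tea, workloads)
    report.raise_if_failed()
    log.info("stage=validate ok rows_iqc=%d rows_tea=%d", len(iqc), len(tea))

    sigmas = sigma_report(iqc, tea)
    log.info("stage=sigma parameters=%d", len(sigmas))

    wl = workloads.set_index(["parameter", "analyzer"])["daily_workload"]
    assignments = []
    for r in sigmas.itertuples(index=False):
        try:
            daily = int(wl.loc[(r.parameter, r.analyzer)])
        except KeyError as exc:
            raise ValueError(f"no workload for {r.parameter}/{r.analyzer}") from exc
        profile = categorize_workload(daily)
        sigma_val = r.mean_sigma if r.acceptable else min(r.mean_sigma, r.min_sigma)
        assignments.append(
            design_plan(r.parameter, r.analyzer, sigma_val, profile, seed=config.seed)
        )
    table = _assignment_table(assignments)
    log.info(
        "stage=design assigned=%d not_controllable=%d",
        int((table["status"] == "assigned").sum()),
        int((table["status"] == NOT_CONTROLLABLE).sum()),
    )

    consolidations = {
        an: consolidate(assignments, an) for an in sorted(table["analyzer"].unique())
    }

    nomogram = build_nomogram(
        list(RULES.values()),
        np.arange(4.0, 6.51, 0.5),
        criterion=config.enuf_criterion,
        seed=config.seed,
    )

    bands = pd.cut(
        sigmas["mean_sigma"],
        bins=[-np.inf, 4, 5, 6, np.inf],
        labels=["<4", "4-5", "5-6", ">=6"],
        right=False,
    )
    band_counts = (
        pd.crosstab(sigmas["analyzer"], bands).reindex(columns=["<4", "4-5", "5-6", ">=6"])
        .fillna(0)
        .astype(int)
    )
    general_plans = {
        an: (c.general_plan.plan_id if c.general_plan else None)
        for an, c in consolidations.items()
    }
    indiv_pairs = [
        (an, param, plan.plan_id)
        for an, c in consolidations.items()
        for param, plan in c.individualized
    ]
    summary = {
        "n_parameter_analyzer": len(table),
        "n_assigned": int((table["status"] == "assigned").sum()),
        "n_not_controllable": int((table["status"] == NOT_CONTROLLABLE).sum()),
        "plan_usage": {
            int(k): int(v) for k, v in table["plan_id"].value_counts().sort_index().items()
        },
        "general_plans": general_plans,
        "n_distinct_general_plans": len({p for p in general_plans.values() if p is not None}),
        "individualized": indiv_pairs,
        "n_distinct_individualized_plans": len({p for _, _, p in indiv_pairs if p is not None}),
        "n_individualized_parameters": len({param for _, param, _ in indiv_pairs}),
        "sigma_band_counts": {an: band_counts.loc[an].to_dict() for an in band_counts.index},
    }

    outputs = {}
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = {
        "enuf_criterion": config.enuf_criterion,
        "ped_threshold": config.ped_threshold,
        "pfr_threshold": config.pfr_threshold,
    }
    sigmas.to_csv(out / "sigma_report.csv", index=False)
    table.to_csv(out / "plan_assignments.csv", index=False)
    nomogram.table.to_csv(out / "nomogram.csv", index=False)
    write_json(
        {
            an: {
                "general_plan": general_plans[an],
                "individualized": [
                    {"parameter": p, "plan_id": plan.plan_id}
                    for p, plan in consolidations[an].individualized
                ],
                "uncovered": consolidations[an].uncovered,
            }
            for an in consolidations
        },
        out / "consolidation.json",
        seed=config.seed,
        thresholds=thresholds,
    )
    write_json(summary, out / "summary.json", seed=config.seed, thresholds=thresholds)
    with open(out / "summary.txt", "w", encoding="utf-8") as fh:
        fh.write("Sigma-band counts per analyzer\n")
        fh.write(band_counts.to_string())
        fh.write("\n\nGeneral plan per analyzer\n")
        for an, pid in general_plans.items():
            fh.write(f"  {an}: plan {pid}\n")
        fh.write("\nIndividualized plans\n")
        for an, param, pid in indiv_pairs:
            fh.write(f"  {an}: plan {pid} ({param})\n")
    outputs = {
        "sigma_report": str(out / "sigma_report.csv"),
        "plan_assignments": str(out / "plan_assignments.csv"),
        "nomogram": str(out / "nomogram.csv"),
        "consolidation": str(out / "consolidation.json"),
        "summary": str(out / "summary.json"),
        "summary_txt": str(out / "summary.txt"),
    }
    log.info("stage=report outputs=%s", sorted(outputs))
    return PipelineResult(sigmas, assignments, table, consolidations, nomogram, summary, outputs)
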