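"""Input validation, file formats and run configuration.

All tables are comma-delimited UTF-8 CSV with a mandatory header and "."
decimal separator.  JSON outputs carry a ``schema_version`` field plus the
seeds and thresholds used, so every result is traceable to its inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

__all__ = [
    "RunConfig",
    "ValidationIssue",
    "ValidationReport",
    "validate_inputs",
    "read_iqc_stats",
    "read_tea_specs",
    "read_workloads",
    "write_json",
]

SCHEMA_VERSION = "1.0"

IQC_COLUMNS = (
    "parameter",
    "analyzer",
    "level_id",
    "target_value",
    "observed_mean",
    "cv_pct",
    "n_obs",
    "is_low_concentration",
)
TEA_COLUMNS = ("parameter", "tea_pct", "source_tier")
WORKLOAD_COLUMNS = ("parameter", "analyzer", "daily_workload")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    iqc_path: str
    tea_path: str
    workload_path: str
    out_dir: str = "bracketqc_out"
    enuf_criterion: float = 1.0
    ped_threshold: float = 0.9
    pfr_threshold: float = 0.05
    mc_events: int = 1_000_000
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.ped_threshold < 1) or not (0 < self.pfr_threshold < 1):
            raise ValueError("ped/pfr thresholds must lie in (0, 1)")
        if self.enuf_criterion <= 0:
            raise ValueError("enuf_criterion must be > 0")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from a YAML (or JSON) mapping file."""
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass(frozen=True)
class ValidationIssue:
    table: str
    row: int | None
    key: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, table: str, row, key: str, message: str) -> None:
        self.issues.append(ValidationIssue(table, row, key, message))

    def raise_if_failed(self) -> None:
        if not self.ok:
            lines = "\n".join(
                f"  [{i.table}] row {i.row} ({i.key}): {i.message}" for i in self.issues
            )
            raise ValueError(f"input validation failed with {len(self.issues)} issue(s):\n{lines}")


def _check_columns(df: pd.DataFrame, cols, table: str, report: ValidationReport) -> bool:
    missing = [c for c in cols if c not in df.columns]
    for c in missing:
        report.add(table, None, c, "missing required column")
    return not missing


def validate_inputs(
    iqc: pd.DataFrame, tea: pd.DataFrame, workloads: pd.DataFrame
) -> ValidationReport:
    """Schema and sanity checks; all row-level problems are collected.

    Percent-unit guards reject values that look like absolute units (CV >=
    50%, TEa >= 100%) and the usual domain constraints (positive targets and
    CVs, positive workloads, unique (parameter, analyzer, level) keys).
    """
    report = ValidationReport()
    if _check_columns(iqc, IQC_COLUMNS, "iqc_stats", report):
        for idx, row in iqc.iterrows():
            key = f"{row['parameter']}/{row['analyzer']}/{row['level_id']}"
            if not row["target_value"] > 0:
                report.add("iqc_stats", idx, key, f"target_value must be > 0, got {row['target_value']}")
            if not row["cv_pct"] > 0:
                report.add("iqc_stats", idx, key, f"cv_pct must be > 0, got {row['cv_pct']}")
            elif row["cv_pct"] >= 50:
                report.add("iqc_stats", idx, key, f"cv_pct {row['cv_pct']} >= 50: not a percent?")
            if row["n_obs"] < 0:
                report.add("iqc_stats", idx, key, "n_obs must be >= 0")
        dup = iqc.duplicated(subset=["parameter", "analyzer", "level_id"], keep=False)
        for idx in iqc.index[dup]:
            row = iqc.loc[idx]
            report.add(
                "iqc_stats",
                idx,
                f"{row['parameter']}/{row['analyzer']}/{row['level_id']}",
                "duplicate (parameter, analyzer, level_id) key",
            )
    if _check_columns(tea, TEA_COLUMNS, "tea_specs", report):
        for idx, row in tea.iterrows():
            if not row["tea_pct"] > 0:
                report.add("tea_specs", idx, row["parameter"], "tea_pct must be > 0")
            elif row["tea_pct"] >= 100:
                report.add("tea_specs", idx, row["parameter"], f"tea_pct {row['tea_pct']} >= 100: not a percent?")
    if _check_columns(workloads, WORKLOAD_COLUMNS, "workloads", report):
        for idx, row in workloads.iterrows():
            if not row["daily_workload"] >= 1:
                report.add(
                    "workloads",
                    idx,
                    f"{row['parameter']}/{row['analyzer']}",
                    "daily_workload must be >= 1",
                )
    return report


def read_iqc_stats(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_tea_specs(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_workloads(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj, path, *, seed=None, thresholds=None) -> None:
    """Write a JSON result with schema version and traceability metadata."""
    payload = {"schema_version": SCHEMA_VERSION}
    if seed is not None:
        payload["seed"] = seed
    if thresholds:
        payload["thresholds"] = thresholds
    payload["result"] = obj
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if hasattr(o, "__dataclass_fields__"):
        return asdict(o)
    return str(o)
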