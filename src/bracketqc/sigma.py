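"""Sigma metrics for IQC performance summaries.

For each control level the systematic error (bias) is

    SE% = (observed mean - target) / target * 100

and the sigma metric, against an allowable total error TEa (percent), is

    sigma = (TEa - |SE|) / CV

with CV the imprecision in percent.  The bias enters as a magnitude: a
negative bias consumes the error budget exactly as a positive one does (the
signed value is retained for reporting).  Levels are aggregated to an
unweighted mean sigma per parameter/analyzer; the procedure is acceptable
when every level reaches sigma >= 4, with an allowance down to sigma >= 3
for levels flagged as low-concentration, where performance is structurally
poorer and no concentration-dependent quality specification exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "ControlLevelStats",
    "PerformanceSpec",
    "SourceTier",
    "SigmaAssessment",
    "systematic_error_pct",
    "sigma_metric",
    "assess_analyzer_sigma",
    "select_tea",
]

ACCEPTABLE_SIGMA = 4.0
LOW_LEVEL_SIGMA = 3.0


class SourceTier(str, Enum):
    """Provenance tier of an allowable-total-error specification."""

    biological_variation = "biological_variation"
    state_of_the_art = "state_of_the_art"
    other = "other"


@dataclass(frozen=True)
class ControlLevelStats:
    """IQC summary for one control level on one analyzer."""

    level_id: str
    target_value: float
    observed_mean: float
    cv_pct: float
    n_obs: int = 0
    is_low_concentration: bool = False

    def __post_init__(self) -> None:
        if self.target_value <= 0:
            raise ValueError(f"level {self.level_id}: target_value must be > 0")
        if self.cv_pct <= 0:
            raise ValueError(f"level {self.level_id}: cv_pct must be > 0")
        if self.n_obs < 0:
            raise ValueError(f"level {self.level_id}: n_obs must be >= 0")

    @property
    def se_pct(self) -> float:
        return systematic_error_pct(self.observed_mean, self.target_value)


@dataclass(frozen=True)
class PerformanceSpec:
    """An allowable total error specification, in percent."""

    tea_pct: float
    source_tier: SourceTier = SourceTier.other

    def __post_init__(self) -> None:
        if self.tea_pct <= 0:
            raise ValueError("tea_pct must be > 0")


@dataclass(frozen=True)
class SigmaAssessment:
    """Per-level sigmas and acceptability for one parameter/analyzer."""

    per_level_sigma: tuple[tuple[str, float], ...]
    mean_sigma: float
    all_levels_acceptable: bool
    low_level_exception_used: bool
    acceptable: bool
    spec: PerformanceSpec | None = field(default=None, compare=False)


def systematic_error_pct(observed_mean: float, target_value: float) -> float:
    """Signed bias in percent of the target value."""
    if target_value == 0:
        raise ValueError("target_value must be nonzero")
    return (observed_mean - target_value) / target_value * 100.0


def sigma_metric(tea_pct: float, se_pct: float, cv_pct: float) -> float:
    """Sigma metric (TEa - |SE|) / CV, all inputs in percent.

    May be negative when the bias alone exceeds the allowable total error.
    """
    if cv_pct <= 0:
        raise ValueError("cv_pct must be > 0")
    return (tea_pct - abs(se_pct)) / cv_pct


def assess_analyzer_sigma(levels, spec: PerformanceSpec) -> SigmaAssessment:
    """Assess all control levels of a parameter on one analyzer.

    Acceptable iff every level's sigma >= 4, or every non-low level >= 4 and
    every low-concentration level >= 3 (exception flagged).
    """
    levels = list(levels)
    if not levels:
        raise ValueError("at least one control level is required")
    sigmas = [
        (lv.level_id, sigma_metric(spec.tea_pct, lv.se_pct, lv.cv_pct)) for lv in levels
    ]
    values = [s for _, s in sigmas]
    all_ok = all(s >= ACCEPTABLE_SIGMA for s in values)
    exception_used = False
    if all_ok:
        acceptable = True
    else:
        acceptable = True
        for lv, (_, s) in zip(levels, sigmas):
            if s >= ACCEPTABLE_SIGMA:
                continue
            if lv.is_low_concentration and s >= LOW_LEVEL_SIGMA:
                exception_used = True
            else:
                acceptable = False
    return SigmaAssessment(
        per_level_sigma=tuple(sigmas),
        mean_sigma=sum(values) / len(values),
        all_levels_acceptable=all_ok,
        low_level_exception_used=exception_used and acceptable,
        acceptable=acceptable,
        spec=spec,
    )


def select_tea(candidates, levels) -> tuple[PerformanceSpec, SigmaAssessment]:
    """Select the most demanding TEa giving acceptable performance.

    Candidates are scanned from the smallest ``tea_pct`` upward (the order
    passed in is irrelevant); the first spec whose assessment is acceptable
    wins.  If none qualifies, the largest TEa is returned with its
    (unacceptable) assessment so callers can report the shortfall.
    """
    candidates = sorted(candidates, key=lambda c: c.tea_pct)
    if not candidates:
        raise ValueError("candidate TEa list must be non-empty")
    last = None
    for spec in candidates:
        assessment = assess_analyzer_sigma(levels, spec)
        if assessment.acceptable:
            return spec, assessment
        last = (spec, assessment)
    return last
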