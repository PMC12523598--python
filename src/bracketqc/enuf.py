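"""Expected number of unreliable final results between QC events.

Under bracketed reporting, patient results are withheld until the next QC
event passes; a rejection triggers correction of the pending run.  If a
persistent systematic shift Delta (SD units) begins at a uniformly
distributed point within an inter-QC interval of ``n`` patient samples, the
expected number of *released* results exceeding the allowable total error is

    E(Nuf)(Delta) = dpE(sigma, Delta) * n * ( q/2 + q**2 / Ped )

where ``dpE = 1 - Phi(sigma - Delta) + Phi(-sigma - Delta)`` is the defect
rate, ``Ped`` is the rule's rejection probability at Delta and ``q = 1 -
Ped``.  The ``q/2`` term is the onset run (half a run of shifted results,
released only if its closing event passes); the geometric term counts full
runs released before the first detection.  Max E(Nuf) is the maximum over
Delta, and the maximum allowed run size is the largest ``n`` keeping
Max E(Nuf) at or below the risk criterion (default 1.0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .power import DEFAULT_MC_SEED, critical_shift
from .rules import QCRule, reject_mask

__all__ = [
    "defect_rate",
    "expected_nuf",
    "ENufProfile",
    "max_enuf",
    "max_run_size",
    "NomogramTable",
    "build_nomogram",
]

#: Monte-Carlo events per grid point for multirule power interpolation
MR_TABLE_EVENTS = 200_000
MR_TABLE_STEP = 0.05
DEFAULT_GRID_STEP = 0.01
MAX_ENUF_TOL = 1e-4


def defect_rate(sigma: float, shift) -> np.ndarray | float:
    """Probability that a patient result's total error exceeds the TEa.

    With the assay's error ~ N(shift, 1) in SD units and the quality
    requirement at ``sigma`` SD: ``1 - Phi(sigma - shift) + Phi(-sigma -
    shift)``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    shift_arr = np.asarray(shift, dtype=float)
    if np.any(shift_arr < 0):
        raise ValueError("shift must be non-negative")
    out = norm.sf(sigma - shift_arr) + norm.cdf(-sigma - shift_arr)
    return float(out) if np.isscalar(shift) or shift_arr.ndim == 0 else out


@lru_cache(maxsize=64)
def _mr_ped_table(
    rule_key: tuple, upper: float, step: float, n_events: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Tabulated MC power of a multirule on [0, upper], common random numbers."""
    rule = QCRule(*rule_key[:2], subrules=rule_key[2])
    grid = np.arange(0.0, upper + step, step)
    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal((n_events, rule.n_per_event))
    ped = np.array([np.mean(reject_mask(rule, z0 + d)) for d in grid])
    # power of a threshold multirule is non-decreasing in the shift; enforce
    # on the MC table so interpolation inherits monotonicity
    return grid, np.maximum.accumulate(ped)


def _ped_fn(rule: QCRule, upper: float, seed: int):
    """Vectorized Ped(Delta) for a rule; closed form or interpolated MC."""
    if not rule.is_multirule:
        k, n = rule.limit, rule.n_per_event

        def ped(delta):
            p = norm.sf(k - np.asarray(delta, dtype=float)) + norm.cdf(
                -k - np.asarray(delta, dtype=float)
            )
            return 1.0 - (1.0 - p) ** n

        return ped
    key = (rule.rule_id, rule.n_per_event, rule.subrules)
    # fixed master range so the MC table is built once and shared across sigmas
    master_upper = max(12.0, math.ceil(upper))
    grid, table = _mr_ped_table(key, master_upper, MR_TABLE_STEP, MR_TABLE_EVENTS, seed)

    def ped(delta):
        return np.interp(np.asarray(delta, dtype=float), grid, table)

    return ped


def _per_patient_enuf(dp, ped):
    """E(Nuf) per patient sample in the run: dpE * (q/2 + q^2/Ped)."""
    ped = np.asarray(ped, dtype=float)
    q = 1.0 - ped
    with np.errstate(divide="ignore", invalid="ignore"):
        val = dp * (q / 2.0 + np.where(ped > 0, q * q / np.where(ped > 0, ped, 1.0), np.inf))
    return val


def expected_nuf(
    rule: QCRule,
    sigma: float,
    run_size: int,
    shift: float,
    *,
    seed: int = DEFAULT_MC_SEED,
) -> float:
    """Expected unreliable final results for one error episode at shift Delta.

    Returns ``inf`` when the rule cannot detect the shift (Ped = 0).
    """
    if run_size < 1:
        raise ValueError("run_size must be >= 1")
    ped = float(_ped_fn(rule, max(shift, sigma + 5.0), seed)(shift))
    dp = defect_rate(sigma, shift)
    if ped <= 0.0:
        return math.inf if dp > 0 else 0.0
    return float(run_size * _per_patient_enuf(dp, ped))


@dataclass
class ENufProfile:
    """E(Nuf) as a function of the shift, and its maximum."""

    rule: QCRule
    sigma: float
    run_size: int
    shift_grid: np.ndarray
    enuf_by_shift: np.ndarray
    max_enuf: float
    argmax_shift: float
    metadata: dict = field(default_factory=dict)


def max_enuf(
    rule: QCRule,
    sigma: float,
    run_size: int,
    *,
    grid_step: float = DEFAULT_GRID_STEP,
    seed: int = DEFAULT_MC_SEED,
) -> ENufProfile:
    """Maximize E(Nuf) over the shift magnitude.

    Grid search on ``[0, sigma + 5]`` (default step 0.01 SD) with bounded
    local refinement for closed-form rules; the objective is smooth and in
    practice unimodal.  For the MC-tabulated multirule the grid value is
    reported directly (refinement below the MC noise is meaningless).
    """
    if run_size < 1:
        raise ValueError("run_size must be >= 1")
    upper = sigma + 5.0
    ped = _ped_fn(rule, upper, seed)
    grid = np.arange(0.0, upper + grid_step, grid_step)
    vals = run_size * _per_patient_enuf(defect_rate(sigma, grid), ped(grid))
    vals = np.nan_to_num(vals, nan=0.0, posinf=np.inf)
    i = int(np.argmax(vals))
    best_x, best_v = float(grid[i]), float(vals[i])
    if not rule.is_multirule and np.isfinite(best_v) and 0 < i < grid.size - 1:
        res = minimize_scalar(
            lambda d: -run_size * float(_per_patient_enuf(defect_rate(sigma, d), ped(d))),
            bounds=(grid[i - 1], grid[i + 1]),
            method="bounded",
            options={"xatol": MAX_ENUF_TOL},
        )
        if -res.fun > best_v:
            best_x, best_v = float(res.x), float(-res.fun)
    return ENufProfile(
        rule,
        sigma,
        run_size,
        grid,
        vals,
        best_v,
        best_x,
        metadata={
            "grid_step": grid_step,
            "seed": seed,
            "convention": "uniform-onset half-run exposure, bracketed release",
        },
    )


def max_run_size(
    rule: QCRule,
    sigma: float,
    *,
    criterion: float = 1.0,
    grid_step: float = DEFAULT_GRID_STEP,
    seed: int = DEFAULT_MC_SEED,
) -> int:
    """Largest run size keeping Max E(Nuf) at or below the criterion.

    E(Nuf) is linear in the run size, so ``n_max = floor(criterion /
    max_per_patient)``; 0 means even a single sample between QC events
    violates the bound.
    """
    if criterion <= 0:
        raise ValueError("criterion must be positive")
    return _max_run_size_cached(rule, float(sigma), float(criterion), float(grid_step), int(seed))


@lru_cache(maxsize=4096)
def _max_run_size_cached(
    rule: QCRule, sigma: float, criterion: float, grid_step: float, seed: int
) -> int:
    profile = max_enuf(rule, sigma, 1, grid_step=grid_step, seed=seed)
    if profile.max_enuf == 0.0:
        return np.iinfo(np.int64).max
    if not np.isfinite(profile.max_enuf):
        return 0
    return int(math.floor(criterion / profile.max_enuf))


@dataclass
class NomogramTable:
    """Maximum allowed run size on a (sigma, rule) grid at a risk criterion."""

    table: "object"  # pandas.DataFrame: sigma, rule_id, n_per_event, max_run_size
    criterion: float
    metadata: dict = field(default_factory=dict)

    def run_size(self, rule_name: str, sigma: float) -> int:
        df = self.table
        row = df[(df["rule"] == rule_name) & (np.isclose(df["sigma"], sigma))]
        if row.empty:
            raise KeyError(f"({rule_name}, sigma={sigma}) not on the nomogram grid")
        return int(row["max_run_size"].iloc[0])


def build_nomogram(
    rules,
    sigma_grid,
    *,
    criterion: float = 1.0,
    grid_step: float = DEFAULT_GRID_STEP,
    seed: int = DEFAULT_MC_SEED,
) -> NomogramTable:
    """Recompute the sigma-metric run-size nomogram for a set of rules.

    One row per (rule, sigma): the maximum run size with Max E(Nuf) <=
    ``criterion``.  Run size is non-decreasing in sigma for a fixed rule.
    """
    import pandas as pd

    rules = list(rules)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if not rules or sigma_grid.size == 0:
        raise ValueError("rules and sigma grid must be non-empty")
    rows = []
    for rule in rules:
        for s in sigma_grid:
            rows.append(
                {
                    "rule": rule.name,
                    "rule_id": rule.rule_id,
                    "n_per_event": rule.n_per_event,
                    "sigma": float(s),
                    "max_run_size": max_run_size(
                        rule, float(s), criterion=criterion, grid_step=grid_step, seed=seed
                    ),
                }
            )
    meta = {
        "criterion": criterion,
        "grid_step": grid_step,
        "seed": seed,
        "enuf_convention": "uniform-onset half-run exposure, bracketed release",
    }
    return NomogramTable(pd.DataFrame(rows), criterion, meta)
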