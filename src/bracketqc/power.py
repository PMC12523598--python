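"""Power functions of control rules.

The power function of a rule is the probability that one QC event rejects,
as a function of a persistent systematic shift Delta (in assay-SD units)
affecting every control observation.  Controls are modeled as independent
Gaussian with unit SD and mean Delta.

Single ``1_ks`` rules have the closed form

    p(Delta)  = 1 - Phi(k - Delta) + Phi(-k - Delta)      (one observation)
    Ped(Delta) = 1 - (1 - p)**N                           (event of N)

The MR multirule has no convenient closed form; its power is estimated by
seeded Monte Carlo over simulated events, with the standard error reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .rules import QCRule, reject_mask

__all__ = [
    "critical_shift",
    "rejection_probability",
    "rejection_probability_mc",
    "false_rejection_probability",
    "PowerCurve",
    "power_curve",
]

#: z-quantile at which 5% of results exceed the allowable total error
DEFECT_QUANTILE = 1.65

DEFAULT_MC_EVENTS = 10**6
DEFAULT_MC_SEED = 20230901


def critical_shift(sigma: float) -> float:
    """Critical systematic error for a procedure of the given sigma metric.

    The shift (in SD units) that drives the defect rate — the fraction of
    patient results exceeding the allowable total error — to 5%:
    ``Delta_crit = sigma - 1.65``.

    Raises
    ------
    ValueError
        If ``sigma <= 1.65``: no controllable critical shift exists (the
        procedure produces >= 5% defective results even in control).
    """
    if sigma <= DEFECT_QUANTILE:
        raise ValueError(
            f"sigma {sigma} <= {DEFECT_QUANTILE}: procedure not controllable "
            "(defect rate is at least 5% with no shift)"
        )
    return sigma - DEFECT_QUANTILE


def _single_rule_p(limit: float, shift) -> np.ndarray:
    shift = np.asarray(shift, dtype=float)
    return norm.sf(limit - shift) + norm.cdf(-limit - shift)


def rejection_probability(
    rule: QCRule,
    shift: float,
    *,
    n_events: int = DEFAULT_MC_EVENTS,
    seed: int = DEFAULT_MC_SEED,
) -> float:
    """Probability that one QC event rejects under a systematic shift.

    Closed form for single rules; seeded Monte Carlo (``n_events`` simulated
    events) for the MR multirule.  ``shift`` must be >= 0.
    """
    if shift < 0:
        raise ValueError("shift must be non-negative")
    if not rule.is_multirule:
        p = float(_single_rule_p(rule.limit, shift))
        return 1.0 - (1.0 - p) ** rule.n_per_event
    est, _ = rejection_probability_mc(rule, shift, n_events=n_events, seed=seed)
    return est


def rejection_probability_mc(
    rule: QCRule,
    shift: float,
    *,
    n_events: int = DEFAULT_MC_EVENTS,
    seed: int = DEFAULT_MC_SEED,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the event rejection probability, with its SE.

    Works for any rule (used as the independent cross-check of the closed
    forms).  Reproducible: the seed fully determines the draw.
    """
    if shift < 0:
        raise ValueError("shift must be non-negative")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_events, rule.n_per_event)) + shift
    rej = reject_mask(rule, z)
    p = float(np.mean(rej))
    se = math.sqrt(max(p * (1.0 - p), 1e-300) / n_events)
    return p, se


def false_rejection_probability(rule: QCRule, **kw) -> float:
    """Pfr: rejection probability with no systematic error (shift = 0)."""
    return rejection_probability(rule, 0.0, **kw)


@dataclass
class PowerCurve:
    """Rejection probability of a rule over a grid of shifts.

    Attributes
    ----------
    shift_grid:
        Systematic-error magnitudes in SD units, ascending.
    ped:
        Rejection probability at each shift.
    pfr:
        Rejection probability at zero shift (equals ``ped`` where the grid
        contains 0).
    se_of_ped:
        Monte-Carlo standard errors (zeros for closed-form entries).
    """

    rule: QCRule
    shift_grid: np.ndarray
    ped: np.ndarray
    pfr: float
    se_of_ped: np.ndarray
    metadata: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "shift": self.shift_grid,
                "ped": self.ped,
                "se_of_ped": self.se_of_ped,
                "method": self.metadata.get("method", "closed_form"),
            }
        )


def power_curve(
    rule: QCRule,
    shift_grid,
    *,
    n_events: int = DEFAULT_MC_EVENTS,
    seed: int = DEFAULT_MC_SEED,
) -> PowerCurve:
    """Compute a rule's power function over an ascending non-negative grid."""
    grid = np.asarray(shift_grid, dtype=float)
    if grid.size == 0 or np.any(grid < 0):
        raise ValueError("shift grid must be non-empty and non-negative")
    if np.any(np.diff(grid) < 0):
        raise ValueError("shift grid must be ascending")
    if not rule.is_multirule:
        p = _single_rule_p(rule.limit, grid)
        ped = 1.0 - (1.0 - p) ** rule.n_per_event
        se = np.zeros_like(ped)
        meta = {"method": "closed_form"}
    else:
        # common random numbers across the grid: smooth, reproducible curve
        rng = np.random.default_rng(seed)
        z0 = rng.standard_normal((n_events, rule.n_per_event))
        ped = np.empty(grid.size)
        se = np.empty(grid.size)
        for i, d in enumerate(grid):
            rej = reject_mask(rule, z0 + d)
            ped[i] = np.mean(rej)
            se[i] = math.sqrt(max(ped[i] * (1 - ped[i]), 1e-300) / n_events)
        meta = {"method": "monte_carlo", "n_events": n_events, "seed": seed}
    pfr = float(ped[0]) if grid[0] == 0.0 else rejection_probability(rule, 0.0, n_events=n_events, seed=seed)
    return PowerCurve(rule, grid, np.asarray(ped, dtype=float), pfr, se, meta)
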