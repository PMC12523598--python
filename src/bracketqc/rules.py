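"""Westgard control rules and their evaluation on QC events.

A QC event is a set of N standardized control deviations (z-values, in units
of the assay SD).  Single rules ``1_ks`` reject when any observation falls at
or beyond ``k`` SD from target.  The multirule ``MR`` combines the classic
1_3s / 2_2s / R_4s / 4_1s criteria within a single event of four control
measurements; no memory is carried across events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QCRule",
    "RuleDecision",
    "RULES",
    "parse_rule",
    "evaluate_event",
    "reject_mask",
]

#: subrules making up the MR multirule, in evaluation order
MR_SUBRULES = ("1_3s", "2_2s", "R_4s", "4_1s")

#: z-limit of each single rule, in SD units
SINGLE_RULE_LIMITS = {"1_2s": 2.0, "1_2.5s": 2.5, "1_3s": 3.0}


@dataclass(frozen=True)
class QCRule:
    """A control rule applied to one QC event of ``n_per_event`` measurements.

    Parameters
    ----------
    rule_id:
        ``"1_2s"``, ``"1_2.5s"``, ``"1_3s"`` for single rules, or ``"MR"``
        for the 1_3s/2_2s/R_4s/4_1s multirule.
    n_per_event:
        Number of control measurements per QC event (1, 2 or 4).  ``MR``
        requires 4.
    """

    rule_id: str
    n_per_event: int
    subrules: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_per_event not in (1, 2, 4):
            raise ValueError(f"n_per_event must be 1, 2 or 4, got {self.n_per_event}")
        if self.rule_id == "MR":
            if self.n_per_event != 4:
                raise ValueError("MR multirule requires 4 control measurements per event")
            if not self.subrules:
                object.__setattr__(self, "subrules", MR_SUBRULES)
        elif self.rule_id in SINGLE_RULE_LIMITS:
            if self.subrules:
                raise ValueError("single rules take no subrules")
        else:
            raise ValueError(f"unknown rule_id {self.rule_id!r}")

    @property
    def is_multirule(self) -> bool:
        return self.rule_id == "MR"

    @property
    def limit(self) -> float:
        """Rejection limit in SD units (single rules only)."""
        if self.is_multirule:
            raise AttributeError("MR multirule has no single limit")
        return SINGLE_RULE_LIMITS[self.rule_id]

    @property
    def name(self) -> str:
        return f"{self.rule_id} N{self.n_per_event}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


#: the rule set used throughout the multistage designs
RULES: dict[str, QCRule] = {
    r.name: r
    for r in (
        QCRule("1_2s", 1),
        QCRule("1_2.5s", 1),
        QCRule("1_3s", 1),
        QCRule("1_3s", 2),
        QCRule("1_3s", 4),
        QCRule("MR", 4),
    )
}


def parse_rule(name: str) -> QCRule:
    """Parse a rule name such as ``"1_3s N2"`` or ``"MR N4"``."""
    key = " ".join(name.split())
    if key in RULES:
        return RULES[key]
    try:
        rule_id, n_part = key.rsplit(" ", 1)
        return QCRule(rule_id, int(n_part.lstrip("N")))
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"cannot parse rule name {name!r}") from exc


@dataclass(frozen=True)
class RuleDecision:
    reject: bool
    triggered: tuple[str, ...]


def _subrule_fires(subrule: str, z: np.ndarray) -> bool:
    # |z| = limit counts as a rejection throughout (fixed boundary convention)
    if subrule == "1_3s":
        return bool(np.any(np.abs(z) >= 3.0))
    if subrule == "2_2s":
        return bool(np.sum(z >= 2.0) >= 2 or np.sum(z <= -2.0) >= 2)
    if subrule == "R_4s":
        return bool(z.max() - z.min() >= 4.0)
    if subrule == "4_1s":
        return bool(np.all(z >= 1.0) or np.all(z <= -1.0))
    raise ValueError(f"unknown subrule {subrule!r}")


def evaluate_event(rule: QCRule, z_values) -> RuleDecision:
    """Evaluate one QC event against a rule.

    Parameters
    ----------
    rule:
        The control rule.
    z_values:
        Sequence of standardized control deviations; its length must equal
        ``rule.n_per_event``.

    Returns
    -------
    RuleDecision
        ``reject`` and the labels of the triggered (sub)rules.
    """
    z = np.asarray(z_values, dtype=float)
    if z.ndim != 1 or z.size != rule.n_per_event:
        raise ValueError(
            f"event has {z.size} observations, rule {rule.name} expects {rule.n_per_event}"
        )
    if rule.is_multirule:
        triggered = tuple(s for s in rule.subrules if _subrule_fires(s, z))
        return RuleDecision(bool(triggered), triggered)
    if np.any(np.abs(z) >= rule.limit):
        return RuleDecision(True, (rule.rule_id,))
    return RuleDecision(False, ())


def reject_mask(rule: QCRule, z_matrix: np.ndarray) -> np.ndarray:
    """Vectorized rejection decision for many events at once.

    ``z_matrix`` has shape (n_events, n_per_event); returns a boolean mask of
    shape (n_events,).  Used by the Monte-Carlo power and patient-flow
    simulators; agrees with :func:`evaluate_event` row by row.
    """
    z = np.asarray(z_matrix, dtype=float)
    if z.ndim != 2 or z.shape[1] != rule.n_per_event:
        raise ValueError(f"expected shape (n, {rule.n_per_event}), got {z.shape}")
    if not rule.is_multirule:
        return np.any(np.abs(z) >= rule.limit, axis=1)
    rej = np.zeros(z.shape[0], dtype=bool)
    if "1_3s" in rule.subrules:
        rej |= np.any(np.abs(z) >= 3.0, axis=1)
    if "2_2s" in rule.subrules:
        rej |= (np.sum(z >= 2.0, axis=1) >= 2) | (np.sum(z <= -2.0, axis=1) >= 2)
    if "R_4s" in rule.subrules:
        rej |= (z.max(axis=1) - z.min(axis=1)) >= 4.0
    if "4_1s" in rule.subrules:
        rej |= np.all(z >= 1.0, axis=1) | np.all(z <= -1.0, axis=1)
    return rej
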