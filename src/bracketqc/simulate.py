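"""Synthetic IQC streams, laboratory fixtures, and the bracketed patient-flow simulator.

The simulator is the empirical counterpart of the analytic E(Nuf) model: it
plays out error episodes in a bracketed laboratory — a persistent systematic
shift arises at a uniform point within an inter-QC interval, QC events are
evaluated with the actual control rule on simulated control measurements,
runs are released only when their closing event passes, and released patient
results exceeding the allowable total error are counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .enuf import defect_rate
from .rules import QCRule, reject_mask
from .sigma import sigma_metric

__all__ = [
    "SimulationConfig",
    "PatientFlowResult",
    "generate_iqc_stream",
    "simulate_bracketed_flow",
    "LabFixture",
    "generate_lab_fixture",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated assay and error episode.

    All error terms are Gaussian.  ``cv_pct``/``bias_pct``/``tea_pct`` are in
    percent of the target concentration; ``shift_sd`` is the persistent
    systematic shift in assay-SD units; ``run_size`` the number of patient
    samples between QC events; ``n_runs`` the number of simulated error
    episodes.  The seed fully determines every draw.
    """

    cv_pct: float = 2.0
    bias_pct: float = 0.0
    tea_pct: float = 10.0
    shift_sd: float = 0.0
    onset: int | str = "uniform"
    run_size: int = 50
    n_runs: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_pct <= 0:
            raise ValueError("cv_pct must be > 0")
        if self.run_size < 1:
            raise ValueError("run_size must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    @property
    def sigma(self) -> float:
        """Sigma metric implied by the configured TEa, bias and CV."""
        return sigma_metric(self.tea_pct, self.bias_pct, self.cv_pct)


def generate_iqc_stream(
    config: SimulationConfig, n_events: int, n_per_event: int
) -> np.ndarray:
    """Simulate standardized IQC deviations for a sequence of QC events.

    Returns an array of shape (n_events, n_per_event): z = bias/CV + shift
    (from the onset event onward) + N(0, 1).  ``config.onset`` is the index
    of the first shifted event (``"uniform"`` puts the shift on from the
    start, matching a stream observed entirely under the shift).
    """
    if n_events < 1 or n_per_event < 1:
        raise ValueError("n_events and n_per_event must be >= 1")
    rng = np.random.default_rng(config.seed)
    z = rng.standard_normal((n_events, n_per_event))
    z += config.bias_pct / config.cv_pct
    onset = 0 if config.onset == "uniform" else int(config.onset)
    z[onset:] += config.shift_sd
    return z


@dataclass
class PatientFlowResult:
    """Empirical Nuf statistics over simulated error episodes."""

    episodes: int
    mean_nuf: float
    se_of_mean: float
    detection_event_histogram: dict[int, int] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def simulate_bracketed_flow(
    rule: QCRule,
    config: SimulationConfig,
    *,
    max_events: int = 10_000,
) -> PatientFlowResult:
    """Count unreliable final results per error episode under bracketed QC.

    Each episode: a persistent shift of ``config.shift_sd`` SD starts at a
    uniform point within one inter-QC interval of ``run_size`` samples (so
    the expected shifted exposure of the onset run is ``run_size / 2``).
    QC events are simulated as ``n_per_event`` control draws N(shift, 1) and
    evaluated with the actual rule; every run is released only if its
    closing event passes, and a rejection ends the episode (the pending run
    is corrected).  Released results are unreliable when their total error
    exceeds the TEa, i.e. with the defect probability of a N(shift, 1) error
    against limits at ``sigma`` SD; counts per run are drawn from the exact
    binomial law of that exceedance.

    The sample mean of the per-episode counts estimates E(Nuf); ``max_events``
    caps pathological never-detected episodes (their remaining runs are
    truncated, which biases the estimate only when Ped is near 0).
    """
    sigma = config.sigma
    if config.shift_sd < 0:
        raise ValueError("shift_sd must be non-negative")
    rng = np.random.default_rng(config.seed)
    n = config.run_size
    n_ep = config.n_runs
    dp = float(defect_rate(sigma, config.shift_sd))

    # shifted exposure of the onset run: uniform onset over the interval,
    # discretized to 0..n inclusive so the expectation is exactly n/2
    if config.onset == "uniform":
        exposure = rng.integers(0, n + 1, size=n_ep)
    else:
        exposure = np.full(n_ep, n - int(config.onset), dtype=int)

    nuf = np.zeros(n_ep, dtype=np.int64)
    detected_at = np.zeros(n_ep, dtype=np.int64)  # QC event index of detection, 1-based
    active = np.arange(n_ep)
    event_idx = 0
    while active.size and event_idx < max_events:
        event_idx += 1
        z = rng.standard_normal((active.size, rule.n_per_event)) + config.shift_sd
        rejected = reject_mask(rule, z)
        passed = active[~rejected]
        if passed.size:
            released = exposure[passed] if event_idx == 1 else np.full(passed.size, n)
            nuf[passed] += rng.binomial(released, dp)
        detected_at[active[rejected]] = event_idx
        active = passed
    detected_at[active] = 0  # never detected within the cap

    mean = float(np.mean(nuf))
    se = float(np.std(nuf, ddof=1) / math.sqrt(n_ep)) if n_ep > 1 else float("nan")
    hist_vals, hist_counts = np.unique(detected_at, return_counts=True)
    return PatientFlowResult(
        episodes=n_ep,
        mean_nuf=mean,
        se_of_mean=se,
        detection_event_histogram={int(k): int(v) for k, v in zip(hist_vals, hist_counts)},
        metadata={
            "rule": rule.name,
            "sigma": sigma,
            "shift_sd": config.shift_sd,
            "run_size": n,
            "seed": config.seed,
            "defect_rate": dp,
        },
    )


@dataclass
class LabFixture:
    """A synthetic laboratory input bundle (IQC stats, TEa specs, workloads)."""

    iqc_stats: pd.DataFrame
    tea_specs: pd.DataFrame
    workloads: pd.DataFrame
    targets: pd.DataFrame  # drawn per parameter/analyzer sigma targets
    seed: int

    def write(self, outdir) -> dict[str, str]:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("iqc_stats", self.iqc_stats),
            ("tea_specs", self.tea_specs),
            ("workloads", self.workloads),
            ("sigma_targets", self.targets),
        ):
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = str(p)
        return paths


#: typical analyte scale and TEa used when drawing synthetic assays
_FIXTURE_TEA_CHOICES = (5.0, 6.0, 8.0, 10.0, 12.0, 15.0)


def generate_lab_fixture(
    seed: int,
    n_analyzers: int = 4,
    n_parameters: int = 20,
    sigma_distribution=None,
    workload_distribution=None,
    *,
    n_obs: int = 180,
    summary_mode: str = "exact",
) -> LabFixture:
    """Generate a consistent synthetic laboratory input bundle.

    Each parameter is offered on 1 to ``n_analyzers`` analyzers with its own
    sigma target per analyzer; two control levels per procedure.  The emitted
    CV is back-solved from the drawn sigma, TEa and bias — ``sigma = (TEa -
    |SE|) / CV`` — so recomputing sigma from the bundle reproduces the target
    exactly (``summary_mode="exact"``) or within sampling error when the
    summary statistics are instead estimated from a simulated IQC stream of
    ``n_obs`` daily results (``summary_mode="simulated"``, about six months
    of daily IQC).

    ``sigma_distribution(rng) -> float`` and ``workload_distribution(rng) ->
    int`` may override the defaults: a sigma mix spanning < 4 to >= 6 (15%
    below 4, 25% 4-5, 35% 5-6, 25% >= 6, mirroring a routine biochemistry
    menu) and daily workloads log-uniform between 30 and 450 samples.
    """
    if summary_mode not in ("exact", "simulated"):
        raise ValueError("summary_mode must be 'exact' or 'simulated'")
    rng = np.random.default_rng(seed)

    def default_sigma(r):
        band = r.choice(4, p=[0.15, 0.25, 0.35, 0.25])
        lo, hi = [(3.0, 4.0), (4.0, 5.0), (5.0, 6.0), (6.0, 7.5)][band]
        return float(r.uniform(lo, hi))

    def default_workload(r):
        return int(round(float(np.exp(r.uniform(np.log(30), np.log(450))))))

    sigma_draw = sigma_distribution or default_sigma
    workload_draw = workload_distribution or default_workload

    analyzers = [f"Analyzer_{i + 1}" for i in range(n_analyzers)]
    iqc_rows, tea_rows, wl_rows, target_rows = [], [], [], []
    for j in range(n_parameters):
        param = f"param_{j + 1:02d}"
        tea = float(rng.choice(_FIXTURE_TEA_CHOICES))
        tea_rows.append({"parameter": param, "tea_pct": tea, "source_tier": "biological_variation"})
        n_avail = int(rng.integers(1, n_analyzers + 1))
        offered = list(rng.choice(analyzers, size=n_avail, replace=False))
        for an in sorted(offered):
            sigma_target = sigma_draw(rng)
            wl_rows.append(
                {"parameter": param, "analyzer": an, "daily_workload": workload_draw(rng)}
            )
            target_rows.append({"parameter": param, "analyzer": an, "sigma_target": sigma_target})
            for lvl, level_id in enumerate(("L1", "L2")):
                target_value = float(rng.uniform(1.0, 200.0) * (lvl + 1))
                bias = float(rng.uniform(-0.2, 0.2) * tea)  # bias within 20% of budget
                cv = (tea - abs(bias)) / sigma_target
                if summary_mode == "exact":
                    observed_mean = target_value * (1 + bias / 100.0)
                    cv_pct = cv
                else:
                    draws = rng.normal(
                        target_value * (1 + bias / 100.0),
                        target_value * cv / 100.0,
                        size=n_obs,
                    )
                    observed_mean = float(np.mean(draws))
                    cv_pct = float(np.std(draws, ddof=1) / np.mean(draws) * 100.0)
                iqc_rows.append(
                    {
                        "parameter": param,
                        "analyzer": an,
                        "level_id": level_id,
                        "target_value": target_value,
                        "observed_mean": observed_mean,
                        "cv_pct": cv_pct,
                        "n_obs": n_obs,
                        "is_low_concentration": lvl == 0 and sigma_target < 4.5,
                    }
                )
    return LabFixture(
        iqc_stats=pd.DataFrame(iqc_rows),
        tea_specs=pd.DataFrame(tea_rows),
        workloads=pd.DataFrame(wl_rows),
        targets=pd.DataFrame(target_rows),
        seed=seed,
    )
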