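# bracketqc

Risk-based multistage statistical quality-control (SQC) design for highly
automated clinical laboratories operating in continuous mode with bracketed
reporting — patient results are withheld until the next internal QC (IQC)
event passes, and a rejection triggers correction of the pending run.

`bracketqc` is for laboratory statisticians and clinical-chemistry
specialists who need to turn routine IQC performance summaries into
defensible, analyzer-spanning QC plans: which Westgard rule to run at
startup, which to run during the day, how many patient samples may sit
between QC events, and how to consolidate dozens of per-parameter designs
into a handful of manageable plans.

## The model

**Sigma metric.** For each control level, with the allowable total error
TEa, the bias SE = (mean − target)/target × 100 and the imprecision CV (all
in percent):

    σ = (TEa − |SE|) / CV

The most demanding TEa giving acceptable performance (σ ≥ 4 on every level,
with σ ≥ 3 tolerated on low-concentration levels) is selected, and levels
are averaged to a mean σ per parameter and analyzer.

**Rule power.** Control observations are modeled as independent N(Δ, 1) in
assay-SD units under a persistent systematic shift Δ. A single rule 1_ks
rejects an event of N controls with probability 1 − (1 − p)^N, where
p = 1 − Φ(k − Δ) + Φ(−k − Δ); the 1_3s/2_2s/R_4s/4_1s multirule (MR N4) is
evaluated by seeded Monte Carlo. The critical shift of a σ-metric procedure
is Δ_c = σ − 1.65, the error that drives the patient-result defect rate to
5%.

**Run-size risk bound.** With defect rate dpE(σ, Δ) = 1 − Φ(σ − Δ) +
Φ(−σ − Δ) and q = 1 − Ped(Δ), the expected number of unreliable *final*
(released) results per error episode in a bracket of n samples is

    E(Nuf) = dpE · n · ( q/2 + q²/Ped )

Maximizing over Δ gives Max E(Nuf); the largest n with Max E(Nuf) ≤ 1 is
the allowed run size, tabulated over (rule, σ) as a run-size nomogram.

**Multistage design.** The startup rule must detect the critical shift with
Ped ≥ 0.9 (σ ≥ 6 → 1_2.5s N1; 5 ≤ σ < 6 → simplest rule whose allowed run
covers the daily workload; 4 ≤ σ < 5 → MR N4; σ < 4 → not controllable).
The monitor rule is the simplest with Pfr ≤ 0.05 (1_2s N1 excluded) whose
allowed run covers the run size (= workload/4, categories A–E). Per
analyzer, the most demanding "simple" plan becomes the general plan; plans
with four-measurement startups stay individualized.

## Worked example

A parameter with mean σ = 5.0 and 200 samples/day:

```python
from bracketqc import (categorize_workload, design_plan, critical_shift,
                       rejection_probability, max_enuf, max_run_size)

profile = categorize_workload(200)
plan = design_plan("CRP", "analyzer-1", 5.0, profile).plan
ped = rejection_probability(plan.startup, critical_shift(5.0))
pfr = rejection_probability(plan.monitor, 0.0)
print(profile.run_size, profile.category.value, plan.label)
print(f"startup Ped {ped:.4f}, monitor Pfr {pfr:.4f}")
print(max_run_size(plan.startup, 5.0), max_run_size(plan.monitor, 5.0))
print(f"{max_enuf(plan.monitor, 5.0, profile.run_size).max_enuf:.3f}")
```

prints

```
50 C plan 3: 1_2s N1 / 1_3s N1
startup Ped 0.9115, monitor Pfr 0.0027
381 51
0.975
```

The daily workload of 200 lands in category C (QC every 50 samples). The
2-SD single rule detects the critical shift (3.35 SD) with probability
0.9115 ≥ 0.9 and its risk bound allows 381 samples/day ≥ 200, so it anchors
the startup; the 3-SD single rule keeps false rejections at 0.27% ≤ 5% and
its allowed run of 51 covers the bracket of 50, where the worst-case
expected number of released unreliable results stays at 0.975 ≤ 1.

The package also ships a transcribed reference dataset from a published
six-analyzer core-laboratory implementation (35 biochemistry parameters):
`bracketqc.reference_data` exposes the sigma tables, the seven-plan
catalogue, the per-parameter assignments, and the consolidated
configuration that the `consolidate` algorithm reproduces exactly.

A CLI wraps the library:

```sh
bracketqc sigma --iqc iqc.csv --tea tea.csv --out out/
bracketqc run --iqc iqc.csv --tea tea.csv --workloads wl.csv --out out/
bracketqc nomogram --out out/          # run-size nomogram CSV + plot
bracketqc simulate --rule "1_2.5s N1" --sigma 6 --shift 4 --run-size 250
```

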