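# Methods

## Scope and model

`bracketqc` implements a risk-based design procedure for statistical QC in
continuous-mode laboratories with bracketed reporting. Its inputs are
per-control-level IQC summaries (target, observed mean, CV%), allowable
total error (TEa) specifications, and daily workloads; its outputs are
per-parameter sigma assessments, startup/monitor rule pairs, run-size
bounds, and per-analyzer consolidated plans.

All analytical error is modeled as Gaussian in assay-SD units. A persistent
systematic shift of magnitude Δ displaces both control and patient results;
imprecision is stable. These are the standard assumptions of power-function
and Max E(Nuf) SQC models; real assays violate them during lot changes,
calibration drift and autocorrelated instrument drift, none of which are
modeled here.

## Sigma assessment

Per level, σ = (TEa − |SE|)/CV with SE = (mean − target)/target × 100. The
bias enters as a magnitude: a negative bias consumes the total-error budget
exactly as a positive one, so sign must not inflate σ (the signed SE is kept
for reports). The mean σ per parameter/analyzer is the unweighted arithmetic
mean across levels — no weighting is defensible without level-specific
patient mixes. Acceptability requires σ ≥ 4 on every level, relaxed to σ ≥ 3
on levels flagged low-concentration, where performance is structurally
poorer and concentration-dependent specifications are unavailable. The
low-concentration flag is an input, not inferred: no numeric cutoff
generalizes across analytes. TEa candidates are scanned from the most
demanding (smallest) upward and the first acceptable one is selected; when
none qualifies the widest is returned flagged unacceptable. In the pipeline,
an unacceptable assessment is carried into plan design as the minimum
per-level sigma so that a sub-4 level yields the `not_controllable`
sentinel rather than being averaged away.

## Rule power

Single rules have the closed form p = 1 − Φ(k − Δ) + Φ(−k − Δ) per control,
1 − (1 − p)^N per event. Observations within an event are independent with
a common shift; no correlation structure between materials/levels is
assumed. A |z| exactly at the limit counts as a rejection — a measure-zero
convention fixed for bit-reproducibility. Multirule counting rules (2_2s,
4_1s) apply within a single QC event only; no memory crosses events,
matching the four-measurements-per-event definition of MR N4.

MR N4 power is estimated by seeded Monte Carlo (default 10⁶ events for point
queries, with the standard error reported). Inside the E(Nuf) maximization,
MR power is tabulated once on a Δ-grid of step 0.05 over [0, 12] with
2×10⁵ events per point using common random numbers, monotonized (power of a
threshold multirule is non-decreasing in Δ) and linearly interpolated; the
table's MC error (~0.001) dominates the interpolation error, and building it
once keeps nomogram construction tractable.

The critical shift Δ_c = σ − 1.65 is the systematic error at which 5% of
patient results exceed TEa; σ ≤ 1.65 is flagged uncontrollable.

## E(Nuf) convention

The expected number of unreliable final results per error episode is

    E(Nuf)(Δ) = dpE(σ, Δ) · n · ( q/2 + q²/Ped ),   q = 1 − Ped(Δ)

derived from: error onset uniform within an inter-QC interval (expected
shifted exposure of the onset run = n/2); a run's results become final only
when its closing QC event passes; a rejection corrects the pending run and
ends the episode; full runs released before first detection follow a
geometric law. Published Max E(Nuf) analyses do not fix a single accounting
(onset exposure n/2 vs (n−1)/2, treatment of the detected run), so this
convention is declared once, implemented behind `expected_nuf`, and
validated against an independent discrete-event simulator
(`simulate_bracketed_flow`) that plays out QC events with the actual rule
and counts released TEa-exceedances: the two agree within Monte-Carlo error
across a (rule × σ × Δ) grid. Note that at Δ = 0 the formula counts the
~1/Pfr in-control runs released before a false rejection; the in-control
*defect* contribution is negligible (dpE < 10⁻⁶ for σ ≥ 5.5) and the
zero-shift point never drives the maximum.

Maximization over Δ uses a grid on [0, σ + 5] with step 0.01 SD plus bounded
local refinement (tolerance 10⁻⁴) for closed-form rules; for the
MC-interpolated multirule the grid value is reported directly, refinement
below the MC noise being meaningless. E(Nuf) is linear in n, so the maximum
run size is floor(criterion / max-per-patient-E(Nuf)). The risk criterion is
the closed bound Max E(Nuf) ≤ 1.0.

## Plan design

Run size = ceil(workload/4) — fractional patients are meaningless and
rounding up is conservative — binned to categories A (100), B (75), C (50),
D (25), E (12), the smallest class covering the run size, capped to A.

Startup (error detection at start of reporting): sigma bands with half-open
edges [4,5), [5,6), [6,∞). At σ ≥ 6 the unified 1_2.5s N1 choice is applied
(a 3-SD rule would suffice below ~350 samples/day, but one standardized rule
is operationally simpler). In [5,6) the candidate list (single rules by
fewest measurements first, then MR N4) is scanned for Ped ≥ 0.9 at Δ_c *and*
a run bound covering the daily workload; when only a category is known the
nominal workload 4 × category capacity is used. In [4,5) the MR N4 multirule
is prescribed regardless of run size — no simpler rule reaches Ped ≥ 0.9
(MR N4 itself achieves 0.947 at σ = 4) — which means the Max E(Nuf) ≤ 1
bound at the *daily workload* is only guaranteed up to MR N4's own limit
(n = 226 at σ = 4.0); it always holds at the run size (category cap 100).
Below 4, no rule reaches Ped ≥ 0.9 and the `not_controllable` sentinel is
emitted.

Monitor (low false rejection during the day): candidates scanned wide limits
first (1_3s N1, 1_2.5s N1, 1_3s N2, 1_3s N4, MR N4), excluding 1_2s N1 whose
Pfr of 0.0455 would cost ~5% of QC events; the first with Pfr ≤ 0.05 and a
run bound covering the run size wins. Designed pairs usually match one of
the seven catalogued plans; pairs outside the catalogue keep a null plan id.

Consolidation: per analyzer, "simple" plans (startup with ≤ 2 single-rule
measurements, catalogue ids 1–3) are replaceable by the most demanding one
present, with demand order 1_2s N1 > 1_3s N2 > 1_2.5s N1 startup (validated
by Ped dominance over σ ∈ [4.9, 6]); N4-startup plans (ids 4–7) remain
individualized; sub-4-sigma parameters are listed uncovered. This fixed
ordering operationalizes "keep the plan covering the most parameters" in a
falsifiable way and reproduces the reference dataset's implemented
configuration exactly.

## Synthetic data

`generate_iqc_stream` emits standardized control deviations z = bias/CV +
shift + N(0,1). `generate_lab_fixture` draws a laboratory (parameters ×
analyzers, sigma mix 15% < 4, 25% 4–5, 35% 5–6, 25% ≥ 6, mirroring a routine
biochemistry menu; workloads log-uniform 30–450/day; two control levels) and
back-solves CV = (TEa − |SE|)/σ so sigma recovery through the sigma module
is exact to 10⁻⁹, or estimates summaries from a simulated stream of
n_obs = 180 daily IQC results (≈ six months), recovering sigma within
sampling error. The patient-flow simulator simulates one error onset per
episode (onset exposure uniform on {0..n}, expectation exactly n/2),
evaluates QC events by drawing control values and applying the actual rule,
and draws released defect counts from the exact binomial exceedance law of
N(Δ,1) against ±σ — distributionally identical to drawing each patient
result. Steady-state in-control stretches are not part of an episode; their
defect contribution is reported separately by the defect rate.

What passing tests show: the closed forms, the maximization, the design
logic and the consolidation are internally consistent and reproduce the
reference implementation's configuration. What they do not show: performance
on real IQC data with drifting bias, lot changes, non-Gaussian tails, or
correlated multi-level controls.

## Problem sizes and determinism

Unit and acceptance tests use 10⁵–2×10⁵ Monte-Carlo events for power checks
and 4×10⁴–2×10⁵ episodes for simulator/analytic agreement (4-SE bands),
sizes at which the whole suite runs in about a minute on one core. All
randomness flows through `numpy.random.default_rng` seeds carried in
configs and function arguments; reruns with equal seeds are byte-identical.
Known numerical choices: ≥-6 censored sigmas are encoded as exactly 6.0
(conservative lower bound); rejection at the limit counts as rejection;
Max E(Nuf) criterion is the closed bound ≤ 1.0.
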