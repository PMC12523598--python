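"""Synthetic IQC streams, lab fixtures, and simulator-vs-closed-form agreement."""

import numpy as np
import pytest

from bracketqc.enuf import expected_nuf
from bracketqc.pipeline import sigma_report
from bracketqc.rules import RULES
from bracketqc.simulate import (
    SimulationConfig,
    generate_iqc_stream,
    generate_lab_fixture,
    simulate_bracketed_flow,
)


def flow_config(sigma, shift, run_size, n_runs, seed):
    """Zero-bias assay with CV 1%: sigma equals TEa numerically."""
    return SimulationConfig(
        cv_pct=1.0,
        bias_pct=0.0,
        tea_pct=sigma,
        shift_sd=shift,
        run_size=run_size,
        n_runs=n_runs,
        seed=seed,
    )


def test_iqc_stream_mean_and_determinism():
    cfg = SimulationConfig(cv_pct=2.0, bias_pct=0.0, tea_pct=10.0, shift_sd=0.0, seed=11)
    z = generate_iqc_stream(cfg, 100_000, 1)
    assert abs(z.mean()) < 4 / np.sqrt(z.size)

    shifted = SimulationConfig(cv_pct=2.0, bias_pct=0.0, tea_pct=10.0, shift_sd=2.0, seed=11)
    z2 = generate_iqc_stream(shifted, 100_000, 1)
    assert z2.mean() == pytest.approx(2.0, abs=4 / np.sqrt(z2.size))

    # bias enters as bias/CV in SD units
    biased = SimulationConfig(cv_pct=2.0, bias_pct=1.0, tea_pct=10.0, seed=11)
    zb = generate_iqc_stream(biased, 100_000, 2)
    assert zb.mean() == pytest.approx(0.5, abs=4 / np.sqrt(zb.size))

    again = generate_iqc_stream(cfg, 100_000, 1)
    np.testing.assert_array_equal(z, again)


def test_simulator_limit_cases():
    # overwhelming shift with a tight four-measurement rule: onset run always caught
    res = simulate_bracketed_flow(RULES["1_3s N4"], flow_config(6.0, 15.0, 100, 2000, 3))
    assert res.mean_nuf == 0.0
    assert res.detection_event_histogram.get(1, 0) == 2000
    # no shift, high sigma: essentially no defective results are ever released
    res0 = simulate_bracketed_flow(RULES["1_3s N1"], flow_config(5.5, 0.0, 50, 200, 3))
    assert res0.mean_nuf < 0.01


def test_simulator_reproducible_by_seed():
    cfg = flow_config(5.0, 3.0, 50, 5000, 42)
    a = simulate_bracketed_flow(RULES["1_2.5s N1"], cfg)
    b = simulate_bracketed_flow(RULES["1_2.5s N1"], cfg)
    assert a.mean_nuf == b.mean_nuf
    assert a.detection_event_histogram == b.detection_event_histogram


def test_simulator_matches_closed_form_reference_point():
    """1_2.5s N1, sigma 6, n=250, shift 4: empirical E(Nuf) within 4 SE of 0.217."""
    rule = RULES["1_2.5s N1"]
    res = simulate_bracketed_flow(rule, flow_config(6.0, 4.0, 250, 200_000, 19))
    closed = expected_nuf(rule, 6.0, 250, 4.0)
    assert closed == pytest.approx(0.217, abs=0.001)
    assert abs(res.mean_nuf - closed) < 4 * res.se_of_mean


@pytest.mark.parametrize("rule_name", ["1_3s N1", "1_2.5s N1", "MR N4"])
@pytest.mark.parametrize("sigma", [4.5, 5.0, 6.0])
@pytest.mark.parametrize("shift", [2.0, 3.0, 4.0, 5.0])
def test_simulator_agrees_with_analytic_enuf_grid(rule_name, sigma, shift):
    """Bracketed patient-flow oracle vs analytic model across rule x sigma x shift."""
    rule = RULES[rule_name]
    n = 50
    res = simulate_bracketed_flow(rule, flow_config(sigma, shift, n, 40_000, 101))
    analytic = expected_nuf(rule, sigma, n, shift)
    se = max(res.se_of_mean, 2e-4)  # guard: tiny-E(Nuf) cells have near-zero SE
    assert abs(res.mean_nuf - analytic) < 4 * se


def test_lab_fixture_sigma_recovery_exact():
    """Back-solved CVs reproduce the drawn sigma targets through the sigma module."""
    fx = generate_lab_fixture(seed=123, n_analyzers=3, n_parameters=12)
    report = sigma_report(fx.iqc_stats, fx.tea_specs)
    merged = report.merge(fx.targets, on=["parameter", "analyzer"])
    assert len(merged) == len(fx.targets)
    np.testing.assert_allclose(merged["mean_sigma"], merged["sigma_target"], atol=1e-9)


def test_lab_fixture_sigma_recovery_from_simulated_streams():
    """Summaries estimated from n_obs=180 simulated IQC results recover sigma
    within sampling error (CV estimate SE ~ CV/sqrt(2(n-1)))."""
    fx = generate_lab_fixture(seed=7, n_analyzers=2, n_parameters=10, summary_mode="simulated")
    report = sigma_report(fx.iqc_stats, fx.tea_specs)
    merged = report.merge(fx.targets, on=["parameter", "analyzer"])
    # sigma = (TEa - |SE|)/CV: a 4-SE band on the CV translates to ~4/sqrt(358) ~ 21%
    rel_err = np.abs(merged["mean_sigma"] - merged["sigma_target"]) / merged["sigma_target"]
    assert (rel_err < 0.25).all()
    assert rel_err.median() < 0.08


def test_lab_fixture_deterministic_and_writable(tmp_path):
    a = generate_lab_fixture(seed=5, n_parameters=6)
    b = generate_lab_fixture(seed=5, n_parameters=6)
    for attr in ("iqc_stats", "tea_specs", "workloads", "targets"):
        assert getattr(a, attr).equals(getattr(b, attr))
    paths = a.write(tmp_path)
    assert set(paths) == {"iqc_stats", "tea_specs", "workloads", "sigma_targets"}
    import pandas as pd

    round_tripped = pd.read_csv(paths["iqc_stats"])
    assert len(round_tripped) == len(a.iqc_stats)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(cv_pct=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(run_size=0)
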