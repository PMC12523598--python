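"""E(Nuf) model: defect rate, closed form, maximization, run sizes, nomogram."""

import numpy as np
import pytest
from scipy.stats import norm

from bracketqc.enuf import (
    build_nomogram,
    defect_rate,
    expected_nuf,
    max_enuf,
    max_run_size,
)
from bracketqc.power import critical_shift, rejection_probability
from bracketqc.rules import RULES


def test_defect_rate_normal_tail_values():
    assert defect_rate(6.0, 0.0) == pytest.approx(2 * norm.sf(6.0), rel=1e-9)
    assert defect_rate(6.0, 0.0) == pytest.approx(2.0e-9, rel=0.02)
    # at shift = sigma, half of all results exceed the budget
    assert defect_rate(6.0, 6.0) == pytest.approx(0.5 + norm.cdf(-12.0), rel=1e-12)
    assert defect_rate(5.0, 4.0) == pytest.approx(norm.sf(1.0) + norm.cdf(-9.0), rel=1e-12)
    assert defect_rate(5.0, 4.0) == pytest.approx(0.1587, abs=5e-5)


def test_defect_rate_increases_with_shift_decreases_with_sigma():
    shifts = np.linspace(0, 8, 50)
    assert np.all(np.diff(defect_rate(5.0, shifts)) > 0)
    assert defect_rate(6.0, 2.0) < defect_rate(4.0, 2.0)


def test_expected_nuf_hand_computed_value():
    """1_2.5s N1, sigma 6, n = 250, shift 4: dpE*n*(q/2 + q^2/Ped) ~ 0.217."""
    rule = RULES["1_2.5s N1"]
    dp = 2.2750131948179195e-02  # 1 - Phi(2)
    ped = norm.cdf(1.5) + norm.sf(6.5)
    q = 1 - ped
    expected = dp * 250 * (q / 2 + q * q / ped)
    assert expected_nuf(rule, 6.0, 250, 4.0) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(0.217, abs=0.001)


def test_expected_nuf_limit_cases():
    # a certain-detection rule yields zero released unreliable results
    huge_shift = 20.0
    rule = RULES["1_3s N4"]
    assert rejection_probability(rule, huge_shift) == pytest.approx(1.0)
    assert expected_nuf(rule, 6.0, 100, huge_shift) == pytest.approx(0.0, abs=1e-12)


def test_in_control_results_are_essentially_reliable():
    """At sigma >= 5.5 with no shift, the defect rate is < 1e-6, so the
    zero-shift point contributes negligibly to Max E(Nuf) even though many
    in-control runs are released between false rejections."""
    n = 1000
    assert defect_rate(5.5, 0.0) * n < 1e-3
    rule = RULES["1_3s N1"]
    at_zero = expected_nuf(rule, 5.5, n, 0.0)
    assert at_zero < 0.01 * max_enuf(rule, 5.5, n).max_enuf


def test_max_enuf_linear_in_run_size():
    rule = RULES["1_2.5s N1"]
    m1 = max_enuf(rule, 5.5, 100).max_enuf
    m2 = max_enuf(rule, 5.5, 200).max_enuf
    assert m2 == pytest.approx(2 * m1, rel=1e-9)


def test_max_enuf_dominates_value_at_critical_shift():
    rule = RULES["1_3s N1"]
    prof = max_enuf(rule, 5.0, 50)
    assert prof.max_enuf >= expected_nuf(rule, 5.0, 50, critical_shift(5.0))
    assert prof.max_enuf >= prof.enuf_by_shift.max() - 1e-12


def test_max_enuf_argmax_location_vs_coarse_scan():
    """Independent coarse scan brackets the argmax for 1_3s N1 at sigma 6."""
    rule = RULES["1_3s N1"]
    coarse = np.arange(0.0, 11.0, 0.1)
    vals = [expected_nuf(rule, 6.0, 100, d) for d in coarse]
    coarse_argmax = coarse[int(np.argmax(vals))]
    prof = max_enuf(rule, 6.0, 100)
    assert abs(prof.argmax_shift - coarse_argmax) <= 0.1
    assert 4.2 <= prof.argmax_shift <= 4.5


def test_max_run_size_scaling_and_dominance():
    rule = RULES["1_3s N1"]
    n1 = max_run_size(rule, 5.0, criterion=1.0)
    n2 = max_run_size(rule, 5.0, criterion=2.0)
    assert n1 <= n2 <= 2 * n1 + 1  # doubling the criterion doubles n (up to flooring)
    # more control measurements detect better, allowing longer runs
    assert max_run_size(RULES["1_3s N4"], 5.0) >= max_run_size(RULES["1_3s N1"], 5.0)
    # and run size grows with sigma
    sizes = [max_run_size(rule, s) for s in (4.0, 4.5, 5.0, 5.5, 6.0)]
    assert sizes == sorted(sizes)
    assert sizes[0] < sizes[-1]


def test_nomogram_round_trip_and_monotonicity():
    rules = [RULES["1_2.5s N1"], RULES["1_3s N1"], RULES["1_3s N2"]]
    sigma_grid = np.arange(4.0, 6.01, 0.5)
    nomo = build_nomogram(rules, sigma_grid)
    for rule in rules:
        sizes = [nomo.run_size(rule.name, s) for s in sigma_grid]
        assert sizes == sorted(sizes)
        # definitional round trip at a mid-grid point
        n = nomo.run_size(rule.name, 5.0)
        assert max_enuf(rule, 5.0, n).max_enuf <= 1.0 + 1e-9
        assert max_enuf(rule, 5.0, n + 1).max_enuf > 1.0


def test_nomogram_admits_the_worked_example_at_sigma_5():
    """A sigma-5 procedure admits a startup rule with Ped >= 0.9 and run >= 200."""
    rule = RULES["1_2s N1"]
    assert rejection_probability(rule, critical_shift(5.0)) >= 0.9
    assert max_run_size(rule, 5.0) >= 200


def test_unbounded_and_zero_run_sizes():
    # sigma 2 with a weak rule: even one patient between QC events is too risky
    assert max_run_size(RULES["1_3s N1"], 2.0) == 0


def test_expected_nuf_input_validation():
    with pytest.raises(ValueError):
        expected_nuf(RULES["1_3s N1"], 5.0, 0, 1.0)
    with pytest.raises(ValueError):
        defect_rate(-1.0, 1.0)
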