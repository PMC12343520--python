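"""Closed-form checks, cross-library oracles and algebraic invariants for
the four disproportionality statistics and the joint signal rule."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from faersig.config import SignalThresholds
from faersig.contingency import ContingencyTable
from faersig.errors import EvaluationError, UndefinedStatisticError
from faersig.stats import (
    BCPNNPriors,
    SignalStatistics,
    bcpnn_stat,
    chi2_stat,
    compute_statistics,
    ebgm_stat,
    evaluate_signal,
    prr_stat,
    ror_stat,
    round_half_up,
)

cells = st.integers(min_value=1, max_value=10_000)


def table(a, b, c, d):
    return ContingencyTable(a, b, c, d, drug="t")


class TestClosedForms:
    def test_independence_table_is_null_for_all_four(self):
        t = table(100, 900, 900, 8100)
        assert ror_stat(t)[0] == pytest.approx(1.0)
        assert prr_stat(t)[0] == pytest.approx(1.0)
        assert ebgm_stat(t)[0] == pytest.approx(1.0)
        assert bcpnn_stat(t)[0] == 0.0

    def test_direct_evaluations(self):
        t = table(10, 10, 10, 1000)
        assert ror_stat(t)[0] == pytest.approx(100.0)
        assert prr_stat(t)[0] == pytest.approx(50.5)
        assert ebgm_stat(t)[0] == pytest.approx(25.75)

    def test_unit_table(self):
        t = table(1, 1, 1, 1)
        ror, lo, hi = ror_stat(t)
        assert ror == pytest.approx(1.0) and lo < 1.0 < hi
        assert prr_stat(t)[0] == pytest.approx(1.0)

    def test_ror_against_log_odds_oracle(self):
        """Independent log-odds + Wald computation (statsmodels Table2x2)."""
        sm = pytest.importorskip("statsmodels.api")
        t = table(20, 80, 80, 820)
        # statsmodels lays the 2x2 out as [[a, c], [b, d]] for the same OR
        oracle = sm.stats.Table2x2(np.array([[20, 80], [80, 820]]))
        ror, lo, hi = ror_stat(t)
        assert ror == pytest.approx(oracle.oddsratio, rel=1e-12)
        olo, ohi = oracle.oddsratio_confint(0.05)
        assert lo == pytest.approx(olo, rel=1e-3)
        assert hi == pytest.approx(ohi, rel=1e-3)


class TestBCPNN:
    def test_high_precision_oracle_values(self):
        """Frozen symbolic evaluation of the closed forms on (5,95,95,9805)
        with the default priors (computed independently with exact rational
        arithmetic)."""
        ic, eic, vic, ic025 = bcpnn_stat(table(5, 95, 95, 9805))
        assert ic == pytest.approx(math.log2(5), abs=1e-12)
        assert eic == pytest.approx(1.57082714095488233, abs=1e-10)
        assert vic == pytest.approx(0.387567197491134295, abs=1e-10)
        assert ic025 == pytest.approx(0.325729237188059190, abs=1e-10)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=200, derandomize=True)
    def test_vic_positive_and_ic025_identity(self, a, b, c, d):
        ic, eic, vic, ic025 = bcpnn_stat(table(a, b, c, d))
        assert vic > 0
        assert ic025 == pytest.approx(eic - 2 * math.sqrt(vic))

    def test_invalid_priors_rejected(self):
        with pytest.raises(ValueError):
            BCPNNPriors(alpha=0.0)


class TestAlgebraicIdentities:
    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=300, derandomize=True)
    def test_ebgm_equals_two_to_the_ic(self, a, b, c, d):
        t = table(a, b, c, d)
        assert ebgm_stat(t)[0] == pytest.approx(2.0 ** bcpnn_stat(t)[0], rel=1e-12)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=300, derandomize=True)
    def test_ordering_identity(self, a, b, c, d):
        """sign(ROR-PRR) = sign(PRR-EBGM) = sign(ad-bc)."""
        t = table(a, b, c, d)
        ror, prr, ebgm = ror_stat(t)[0], prr_stat(t)[0], ebgm_stat(t)[0]
        sign = np.sign(a * d - b * c)
        assert np.sign(np.round(ror - prr, 14)) == sign
        assert np.sign(np.round(prr - ebgm, 14)) == sign

    def test_independence_scaling_leaves_null_values(self):
        for k in (1, 3, 17):
            t = table(10 * k, 90 * k, 90 * k, 810 * k)
            assert ror_stat(t)[0] == pytest.approx(1.0)
            assert prr_stat(t)[0] == pytest.approx(1.0)
            assert ebgm_stat(t)[0] == pytest.approx(1.0)
            assert bcpnn_stat(t)[0] == pytest.approx(0.0)


class TestChi2:
    def test_unit_table_clamps_to_zero(self):
        assert chi2_stat(table(1, 1, 1, 1)) == 0.0

    def test_matches_scipy_yates(self):
        t = table(10, 10, 10, 1000)
        expected = chi2_contingency(
            np.array([[10, 10], [10, 1000]]), correction=True
        ).statistic
        assert chi2_stat(t) == pytest.approx(expected, rel=1e-12)

    def test_uncorrected_matches_scipy_and_limit(self):
        t = table(5000, 4000, 4000, 5000)
        uncorrected = chi2_stat(t, yates=False)
        expected = chi2_contingency(
            np.array([[5000, 4000], [4000, 5000]]), correction=False
        ).statistic
        assert uncorrected == pytest.approx(expected, rel=1e-12)
        # correction is negligible on a large balanced table
        assert abs(chi2_stat(t) - uncorrected) / uncorrected < 0.01


class TestUndefinedAndContinuity:
    def test_prr_with_zero_c_is_undefined(self):
        with pytest.raises(UndefinedStatisticError, match="c"):
            prr_stat(table(5, 10, 0, 100))

    def test_ror_zero_cell_without_correction_names_cell(self):
        with pytest.raises(UndefinedStatisticError, match="cell b"):
            ror_stat(table(5, 0, 10, 100), continuity=False)

    def test_haldane_correction_applied_and_flagged(self):
        t = table(5, 0, 10, 100)
        ror, lo, hi = ror_stat(t, continuity=True)
        assert ror == pytest.approx((5.5 * 100.5) / (0.5 * 10.5))
        s = compute_statistics(t)
        assert s.continuity_corrected
        # PRR needs no correction here (only c = 0 leaves it undefined)
        assert s.prr == pytest.approx(11.0)
        assert compute_statistics(table(5, 10, 0, 100)).prr is None

    def test_ebgm05_onesided_variant_is_larger(self):
        t = table(30, 70, 70, 830)
        _, low_two, _ = ebgm_stat(t)
        _, low_one, _ = ebgm_stat(t, onesided_05=True)
        assert low_one > low_two


class TestEvaluateSignal:
    def _stats(self, a=3, ror=6.03, ror_lo=1.5, prr=5.56, prr_lo=1.4,
               ic025=0.95, ebgm05=2.06):
        return SignalStatistics(
            drug="x", a=a, ror=ror, ror_ci_low=ror_lo, ror_ci_high=ror * 2,
            prr=prr, prr_ci_low=prr_lo, prr_ci_high=prr * 2,
            ic025=ic025, ebgm05=ebgm05,
        )

    def test_weakest_tabulated_signal_is_joint_positive(self):
        # the a=3 row: ROR 6.03, PRR 5.56, IC025 0.95, EBGM05 2.06
        decision = evaluate_signal(self._stats())
        assert decision.joint_positive
        assert all([decision.ror_positive, decision.prr_positive,
                    decision.bcpnn_positive, decision.ebgm_positive])

    def test_minimum_count_gate_beats_huge_ror(self):
        decision = evaluate_signal(self._stats(a=2, ror=1000.0))
        assert not decision.ror_positive and not decision.joint_positive

    def test_ic025_boundary_is_strict(self):
        assert not evaluate_signal(self._stats(ic025=0.0)).bcpnn_positive

    def test_ebgm05_boundary_is_strict(self):
        assert not evaluate_signal(self._stats(ebgm05=2.0)).ebgm_positive

    @pytest.mark.parametrize("combo", range(16))
    def test_joint_rule_is_conjunction_over_all_combinations(self, combo):
        """Exhaust the 16 pass/fail patterns: joint <=> all four positive."""
        want = [(combo >> i) & 1 == 1 for i in range(4)]
        s = self._stats(
            ror=6.0 if want[0] else 2.0,
            prr=5.0 if want[1] else 1.5,
            ic025=0.9 if want[2] else -0.1,
            ebgm05=2.5 if want[3] else 1.1,
        )
        decision = evaluate_signal(s)
        assert [decision.ror_positive, decision.prr_positive,
                decision.bcpnn_positive, decision.ebgm_positive] == want
        assert decision.joint_positive == all(want)

    def test_missing_statistic_raises_with_gap_listed(self):
        with pytest.raises(EvaluationError, match="ic025"):
            evaluate_signal(self._stats() and SignalStatistics(drug="x", a=5))

    def test_custom_thresholds_respected(self):
        loose = SignalThresholds(ror_min=1.5, ebgm05_min=1.0)
        s = self._stats(ror=2.0, ebgm05=1.2)
        assert evaluate_signal(s, loose).joint_positive


def test_round_half_up_matches_reporting_convention():
    assert round_half_up(31.435, 2) == 31.44
    assert round_half_up(2.345, 2) == 2.35
    assert round_half_up(1.005, 2) == 1.01
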