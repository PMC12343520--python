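"""Time-to-onset extraction rules, quantile summaries and Weibull recovery."""

from __future__ import annotations

import datetime as dt
import math

import numpy as np
import pytest
from scipy import stats as sps

from faersig.contingency import NEURALGIA
from faersig.io import clean_and_join, find_quarters
from faersig.mapping import DrugDictionary, map_to_generic
from faersig.synthetic import generate_dataset
from faersig.tto import (
    TTORecord,
    classify_onset_pattern,
    extract_tto,
    summarize_drug_tto,
    summarize_tto,
    weibull_fit,
)

from conftest import make_case, small_config


def _case(event, start, drug="dx", reactions=("Neuralgia",)):
    return make_case(
        drugs=[drug], reactions=list(reactions), event_dt=event,
        starts={drug: start} if start else {},
    )


class TestExtractTTO:
    def test_two_day_interval(self):
        records, excl = extract_tto(
            [_case(dt.date(2020, 1, 3), dt.date(2020, 1, 1))], "dx", NEURALGIA
        )
        assert [r.onset_days for r in records] == [2]
        assert sum(excl.values()) == 0

    def test_event_before_start_excluded_as_negative(self):
        records, excl = extract_tto(
            [_case(dt.date(2019, 12, 31), dt.date(2020, 1, 1))], "dx", NEURALGIA
        )
        assert not records and excl["negative_interval"] == 1

    def test_missing_dates_tallied(self):
        records, excl = extract_tto(
            [_case(None, dt.date(2020, 1, 1)), _case(dt.date(2020, 1, 5), None)],
            "dx", NEURALGIA,
        )
        assert not records
        assert excl["missing_event_dt"] == 1 and excl["missing_start_dt"] == 1

    def test_non_case_and_unexposed_reports_ignored(self):
        records, excl = extract_tto(
            [
                _case(dt.date(2020, 1, 3), dt.date(2020, 1, 1), reactions=("Nausea",)),
                _case(dt.date(2020, 1, 3), dt.date(2020, 1, 1), drug="other"),
            ],
            "dx", NEURALGIA,
        )
        assert not records and sum(excl.values()) == 0

    def test_earliest_start_used_for_multi_therapy_rows(self):
        case = make_case(drugs=["dx"], reactions=["Neuralgia"], event_dt=dt.date(2020, 2, 1))
        case.drugs[0].start_dt = dt.date(2020, 1, 20)
        case.drugs.append(
            type(case.drugs[0])("dx", "C", 2, dt.date(2020, 1, 10), "20200110")
        )
        records, _ = extract_tto([case], "dx", NEURALGIA)
        assert records[0].onset_days == 22

    def test_extracted_intervals_equal_planted_ground_truth(self, tmp_path):
        """With no benign date missingness, extracted intervals match the
        generator's emitted intervals exactly, case by case."""
        rates = dict(small_config().missing_field_rates)
        rates.update({"event_dt": 0.0, "start_dt": 0.0, "event_dt_partial": 0.0})
        config = small_config(seed=17, n_reports=3000, missing_field_rates=rates)
        _, truth = generate_dataset(config, tmp_path)
        cases, _ = clean_and_join(find_quarters(tmp_path))
        mapped, _, _ = map_to_generic(
            cases, DrugDictionary.from_tsv(tmp_path / "drug_dictionary.tsv")
        )
        for drug in truth.signal_drugs:
            records, _ = extract_tto(mapped, drug, NEURALGIA)
            got = {r.caseid: r.onset_days for r in records}
            planted = truth.planted_tto[drug]
            for cid, onset in planted.items():
                if cid in got:
                    assert got[cid] == onset
            # cleaning removes only error-injected reports, nothing else
            lost = set(planted) - set(got)
            injected = set().union(*truth.error_caseids.values())
            assert lost <= injected
            # any extra extraction is a case whose event was driven by a
            # co-planted stronger signal drug on the same report
            others = set().union(
                *(truth.planted_tto[d] for d in truth.signal_drugs if d != drug)
            )
            assert set(got) - set(planted) <= others


class TestSummarizeTTO:
    def test_simple_median(self):
        assert summarize_tto([1, 2, 3])[0] == 2

    def test_interpolated_quartiles_hand_oracle(self):
        # sorted [1,1,2,4,5]: positions 0..4; q25 at 1.0 -> 1, q75 at 3.0 -> 4
        assert summarize_tto([1, 1, 2, 4, 5]) == (2.0, 1.0, 4.0)
        # sorted [1,2,3,4]: q25 at 0.75 -> 1.75, median 2.5, q75 3.25
        assert summarize_tto([1, 2, 3, 4]) == (2.5, 1.75, 3.25)

    def test_single_value_degenerate(self):
        assert summarize_tto([TTORecord("d", "c", 7)]) == (7.0, 7.0, 7.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            summarize_tto([])


class TestWeibullFit:
    def test_recovers_exponential_shape(self):
        rng = np.random.default_rng(2)
        x = sps.weibull_min.rvs(1.0, scale=10.0, size=10_000, random_state=rng)
        fit = weibull_fit(x)
        # asymptotic SD of the shape MLE is ~0.78 k / sqrt(n)
        assert abs(fit.shape - 1.0) < 3 * 0.78 / math.sqrt(10_000)
        assert fit.scale == pytest.approx(10.0, rel=0.05)
        assert classify_onset_pattern(fit) == "random"

    def test_recovers_late_onset_shape(self):
        rng = np.random.default_rng(3)
        x = sps.weibull_min.rvs(2.0, scale=30.0, size=10_000, random_state=rng)
        fit = weibull_fit(x)
        assert abs(fit.shape - 2.0) < 3 * 0.78 * 2.0 / math.sqrt(10_000)
        assert classify_onset_pattern(fit) == "late"

    def test_agrees_with_scipy_mle_oracle(self):
        rng = np.random.default_rng(4)
        x = sps.weibull_min.rvs(0.7, scale=15.0, size=500, random_state=rng)
        fit = weibull_fit(x)
        shape_ref, loc, scale_ref = sps.weibull_min.fit(x, floc=0)
        assert fit.shape == pytest.approx(shape_ref, rel=1e-4)
        assert fit.scale == pytest.approx(scale_ref, rel=1e-4)

    def test_identical_values_fail_gracefully(self):
        fit = weibull_fit([5.0] * 20)
        assert not fit.converged and math.isnan(fit.shape)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        x = sps.weibull_min.rvs(1.5, scale=8.0, size=2000, random_state=rng)
        f1, f2 = weibull_fit(x), weibull_fit(7.0 * x)
        assert f2.shape == pytest.approx(f1.shape, rel=1e-9)
        assert f2.scale == pytest.approx(7.0 * f1.scale, rel=1e-9)

    def test_zero_shift_and_min_n(self):
        fit = weibull_fit([0, 1, 2, 3, 4, 5, 6, 7, 8, 9])
        assert fit.zeros_shifted == 1 and fit.converged
        with pytest.raises(ValueError):
            weibull_fit([1, 2, 3], min_n=10)


class TestSummarizeDrugTTO:
    def test_exclusion_conservation(self, small_pipeline):
        cases = small_pipeline.cases
        from faersig.contingency import is_case

        for drug in ("signalfast", "signalslow"):
            summary = summarize_drug_tto(cases, drug, NEURALGIA)
            candidates = sum(
                1 for c in cases if drug in c.drug_names() and is_case(c, NEURALGIA)
            )
            assert summary.n_used + sum(summary.n_excluded.values()) == candidates

    def test_planted_pattern_recovered(self, small_pipeline):
        late = summarize_drug_tto(small_pipeline.cases, "signalslow", NEURALGIA)
        assert late.onset_pattern == "late"  # planted shape 2.0
        assert late.iqr_low <= late.median_days <= late.iqr_high

    def test_no_records_suppresses_summary(self):
        summary = summarize_drug_tto([], "ghost", NEURALGIA)
        assert summary.n_used == 0 and summary.median_days is None
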