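"""Time-to-onset computation, segmentation, Weibull fits, classification."""

import math

import numpy as np
import pytest

from faerspv.casestore import CaseReport, DrugUse
from faerspv.dates import PartialDate
from faerspv.tto import (
    DEGENERATE,
    EARLY,
    MISSING,
    MISSING_SEGMENT,
    NEGATIVE,
    PARTIAL,
    RANDOM,
    VALID,
    WEAROUT,
    OnsetRecord,
    classify_failure,
    classify_shape_ci,
    compute_tto,
    fit_weibull,
    segment_tto,
    summarize_tto,
)


def _case(event, start):
    case = CaseReport(caseid="1", primaryid="11", fda_dt=None, event_dt=event)
    case.drugs = [DrugUse("X", {"PS"}, start_dt=start)]
    return case


class TestComputeTTO:
    def test_plain_interval(self):
        rec = compute_tto(_case(PartialDate(2020, 1, 20),
                                PartialDate(2020, 1, 1)), "X")
        assert rec.status == VALID and rec.tto_days == 19

    def test_same_day_onset_is_valid(self):
        rec = compute_tto(_case(PartialDate(2020, 1, 1),
                                PartialDate(2020, 1, 1)), "X")
        assert rec.status == VALID and rec.tto_days == 0

    def test_negative_interval_flagged(self):
        rec = compute_tto(_case(PartialDate(2020, 1, 20),
                                PartialDate(2020, 2, 1)), "X")
        assert rec.status == NEGATIVE and rec.tto_days is None

    def test_missing_event_date(self):
        rec = compute_tto(_case(None, PartialDate(2020, 1, 1)), "X")
        assert rec.status == MISSING

    def test_partial_date_excluded_from_arithmetic(self):
        rec = compute_tto(_case(PartialDate(2020, 3), PartialDate(2020, 1, 1)),
                          "X")
        assert rec.status == PARTIAL

    def test_earliest_start_of_that_drug_used(self):
        case = _case(PartialDate(2020, 6, 1), PartialDate(2020, 5, 1))
        case.drugs.append(DrugUse("X", {"SS"}, start_dt=PartialDate(2020, 1, 1)))
        rec = compute_tto(case, "X")
        assert rec.tto_days == (PartialDate(2020, 6, 1).to_date()
                                - PartialDate(2020, 1, 1).to_date()).days


class TestSegmentation:
    def _recs(self, days):
        return [OnsetRecord(str(i), "X", VALID, d) for i, d in enumerate(days)]

    @pytest.mark.parametrize("day, label", [
        (0, "0-30d"), (30, "0-30d"), (31, "31-60d"), (60, "31-60d"),
        (90, "61-90d"), (120, "91-120d"), (150, "121-150d"),
        (180, "151-180d"), (360, "181-360d"), (361, ">360d"), (5000, ">360d"),
    ])
    def test_inclusive_boundaries(self, day, label):
        seg = segment_tto(self._recs([day]))
        assert seg.counts[label] == 1

    def test_missing_and_negative_pooled(self):
        records = self._recs([10]) + [
            OnsetRecord("a", "X", NEGATIVE), OnsetRecord("b", "X", MISSING),
            OnsetRecord("c", "X", PARTIAL)]
        seg = segment_tto(records)
        assert seg.counts[MISSING_SEGMENT] == 3
        assert sum(seg.counts.values()) == 4

    def test_every_record_in_exactly_one_bin(self):
        rng = np.random.default_rng(0)
        days = rng.integers(0, 800, size=500)
        seg = segment_tto(self._recs(days))
        assert sum(seg.counts.values()) == 500

    def test_all_missing(self):
        seg = segment_tto([OnsetRecord("a", "X", MISSING)] * 3)
        assert seg.counts[MISSING_SEGMENT] == 3


class TestSummary:
    def test_single_value(self):
        s = summarize_tto([OnsetRecord("1", "X", VALID, 19)])
        assert (s.median, s.q1, s.q3) == (19, 19, 19)

    def test_order_statistics(self):
        recs = [OnsetRecord(str(i), "X", VALID, d)
                for i, d in enumerate([0, 3, 19, 108, 14610])]
        s = summarize_tto(recs)
        assert (s.median, s.q1, s.q3) == (19, 3, 108)
        assert (s.min, s.max) == (0, 14610)

    def test_invalid_records_excluded(self):
        recs = [OnsetRecord("1", "X", VALID, 10),
                OnsetRecord("2", "X", NEGATIVE)]
        s = summarize_tto(recs)
        assert s.n == 1 and s.n_missing == 1 and s.mean == 10

    def test_no_valid_records(self):
        s = summarize_tto([OnsetRecord("1", "X", MISSING)])
        assert s.n == 0 and math.isnan(s.median)


class TestFitWeibull:
    def test_insufficient_data_raises(self):
        with pytest.raises(ValueError, match="insufficient"):
            fit_weibull([1.0, 2.0])

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            fit_weibull([1.0, -2.0, 3.0])

    def test_identical_values_degenerate(self):
        fit = fit_weibull([5.0] * 10)
        assert not fit.converged and fit.failure_type == DEGENERATE

    def test_grid_search_oracle_regression(self):
        """MLE of {1,2,3,4,10} frozen from an independent coarse-to-fine
        grid search over (scale, shape) maximizing the log-likelihood."""
        fit = fit_weibull([1, 2, 3, 4, 10])
        assert fit.scale == pytest.approx(4.40637, rel=2e-4)
        assert fit.shape == pytest.approx(1.36441, rel=2e-4)
        assert fit.converged

    def test_parameter_recovery_large_sample(self):
        rng = np.random.default_rng(7)
        x = 122.0 * rng.weibull(0.59, size=10_000)
        fit = fit_weibull(x)
        assert fit.shape == pytest.approx(0.59, rel=0.05)
        assert fit.scale == pytest.approx(122.0, rel=0.05)

    def test_exponential_shape_ci_contains_one(self):
        rng = np.random.default_rng(0)
        x = rng.exponential(30.0, size=5000)
        fit = fit_weibull(x)
        assert fit.shape_low < 1.0 < fit.shape_high
        assert classify_failure(fit) == RANDOM

    def test_scale_equivariance_shape_invariance(self):
        rng = np.random.default_rng(3)
        x = 50.0 * rng.weibull(0.7, size=400) + 0.01
        f1 = fit_weibull(x)
        f2 = fit_weibull(7.0 * x)
        assert f2.scale == pytest.approx(7.0 * f1.scale, rel=1e-3)
        assert f2.shape == pytest.approx(f1.shape, rel=1e-3)

    def test_zero_days_substituted_for_fitting_only(self):
        fit = fit_weibull([0, 1, 2, 3, 4, 10])
        assert fit.converged  # would fail outright with a literal zero

    def test_agrees_with_lifelines(self):
        """Cross-check point estimates and shape CI against lifelines'
        Weibull fitter (an independent MLE implementation)."""
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(21)
        x = 40.0 * rng.weibull(1.3, size=300) + 0.01
        fit = fit_weibull(x)
        wf = lifelines.WeibullFitter().fit(x)
        assert fit.scale == pytest.approx(wf.lambda_, rel=1e-3)
        assert fit.shape == pytest.approx(wf.rho_, rel=1e-3)

    def test_recovery_and_coverage_over_replicates(self):
        """200 replicates at n = 100, scale 50, shape 0.7: median relative
        bias of both estimates < 5% and shape-CI coverage >= 90%."""
        rng = np.random.default_rng(2024)
        scale_err, shape_err, covered = [], [], 0
        for _ in range(200):
            x = 50.0 * rng.weibull(0.7, size=100)
            fit = fit_weibull(x)
            assert fit.converged
            scale_err.append(fit.scale / 50.0 - 1.0)
            shape_err.append(fit.shape / 0.7 - 1.0)
            covered += fit.shape_low <= 0.7 <= fit.shape_high
        assert abs(np.median(scale_err)) < 0.05
        assert abs(np.median(shape_err)) < 0.05
        assert covered / 200 >= 0.90


class TestClassifyFailure:
    @pytest.mark.parametrize("low, high, expected", [
        (0.50, 0.69, EARLY),    # decreasing hazard
        (0.81, 1.22, RANDOM),   # constant hazard
        (1.06, 1.68, WEAROUT),  # increasing hazard
        (0.97, 1.62, RANDOM),
        (0.999, 1.001, RANDOM),
    ])
    def test_shape_ci_rule(self, low, high, expected):
        assert classify_shape_ci(low, high) == expected
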