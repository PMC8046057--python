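"""Control reference bands, classification, and cohort reporting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from dentct.cohort import (
    CohortTable,
    ReferenceInterval,
    classify_within_limits,
    cohort_report,
    fold_change,
    percent_change,
    reference_interval,
)


def toy_table(shift=0.0):
    rows = []
    rng = np.random.default_rng(0)
    for metric, base in (("density", 1200.0), ("thickness", 0.2)):
        for i in range(4):
            rows.append(dict(patient=f"c{i}", tooth=f"c{i}_{metric[0]}",
                             group="control", metric=metric,
                             value=base * (1 + rng.normal(0, 0.01))))
        for i in range(3):
            rows.append(dict(patient=f"x{i}", tooth=f"x{i}_{metric[0]}",
                             group="case", metric=metric,
                             value=base * (1 + shift + rng.normal(0, 0.01))))
    return CohortTable.from_records(rows)


class TestReferenceInterval:
    def test_all_equal_values_give_point_interval(self):
        iv = reference_interval([3.0, 3.0, 3.0])
        assert iv.ci_low == iv.mean == iv.ci_high == 3.0

    def test_closed_form_t_interval(self):
        iv = reference_interval([1.0, 2.0, 3.0])
        half = stats.t.ppf(0.975, 2) * 1.0 / np.sqrt(3)
        assert iv.mean == 2.0
        assert iv.ci_low == pytest.approx(2.0 - half, abs=1e-10)
        assert iv.ci_high == pytest.approx(2.0 + half, abs=1e-10)

    def test_widening_sd_widens_interval(self):
        narrow = reference_interval([10.0, 10.5, 9.5])
        wide = reference_interval([10.0, 12.0, 8.0])
        assert (wide.ci_high - wide.ci_low) > (narrow.ci_high - narrow.ci_low)

    def test_sd_band_mode_uses_normal_quantile(self):
        vals = [8.0, 10.0, 12.0, 10.0]
        iv = reference_interval(vals, mode="sd_band")
        sd = np.std(vals, ddof=1)
        assert iv.ci_high - iv.mean == pytest.approx(1.959963985 * sd, rel=1e-6)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            reference_interval([1.0])


class TestClassification:
    def interval(self):
        return ReferenceInterval(metric="m", n=5, mean=10.0, sd=1.0,
                                 ci_low=9.0, ci_high=11.0)

    def test_boundary_value_is_within(self):
        assert classify_within_limits(9.0, self.interval()) == "within"
        assert classify_within_limits(11.0, self.interval()) == "within"

    def test_below_and_above(self):
        assert classify_within_limits(8.999, self.interval()) == "below"
        assert classify_within_limits(11.001, self.interval()) == "above"

    @given(st.floats(-100, 100))
    def test_pure_function(self, v):
        iv = self.interval()
        assert classify_within_limits(v, iv) == classify_within_limits(v, iv)

    def test_injected_downshift_classified_below(self):
        table = toy_table(shift=-0.20)
        report, _ = cohort_report(table, make_plots=False)
        dens = report[report.metric == "density"]
        assert (dens.classification == "below").all()


class TestEffectSizes:
    def test_fold_change_equal_means(self):
        assert fold_change(5.0, 5.0) == 1.0

    def test_fold_change_585(self):
        assert fold_change(58.5, 0.1) == pytest.approx(585.0)

    def test_fold_change_zero_control_guidance(self):
        with pytest.raises(ValueError, match="absolute difference"):
            fold_change(1.0, 0.0)

    def test_percent_change_minus_10(self):
        assert percent_change(1080.0, 1200.0) == pytest.approx(-10.0)

    def test_percent_change_identical_is_zero(self):
        assert percent_change(7.0, 7.0) == 0.0

    @given(st.floats(-1e4, 1e4), st.floats(0.01, 1e4))
    def test_percent_change_matches_spreadsheet_formula(self, case, ctrl):
        assert percent_change(case, ctrl) == pytest.approx(
            100 * (case - ctrl) / ctrl, rel=1e-12
        )


class TestCohortTable:
    def test_duplicate_tooth_metric_rejected(self):
        rows = [dict(patient="p", tooth="t1", group="case", metric="m", value=1.0)] * 2
        with pytest.raises(ValueError, match="one value"):
            CohortTable.from_records(rows)

    def test_unknown_group_rejected(self):
        rows = [dict(patient="p", tooth="t1", group="weird", metric="m", value=1.0)]
        with pytest.raises(ValueError, match="group"):
            CohortTable.from_records(rows)


class TestReport:
    def test_report_shape_metrics_times_cases(self):
        table = toy_table()
        report, summary = cohort_report(table, make_plots=False)
        assert len(report) == 2 * 3  # 2 metrics x 3 case teeth
        assert len(summary) == 2
        assert set(summary.columns) >= {"control_mean", "ci_low", "ci_high",
                                        "fold_change", "percent_change"}

    def test_classifications_consistent_with_classify(self):
        table = toy_table(shift=-0.05)
        report, _ = cohort_report(table, make_plots=False)
        for _, row in report.iterrows():
            iv = ReferenceInterval(metric=row.metric, n=4, mean=row.control_mean,
                                   sd=1.0, ci_low=row.ci_low, ci_high=row.ci_high)
            assert row.classification == classify_within_limits(row.value, iv)

    def test_missing_group_skips_metric_with_warning(self):
        rows = [dict(patient="p", tooth=f"t{i}", group="control",
                     metric="lonely", value=float(i)) for i in range(3)]
        table = CohortTable.from_records(rows)
        with pytest.warns(UserWarning, match="skipped"):
            report, summary = cohort_report(table, make_plots=False)
        assert report.empty and summary.empty

    def test_regenerated_report_byte_identical(self, tmp_path):
        table = toy_table()
        d1, d2 = tmp_path / "a", tmp_path / "b"
        cohort_report(table, out_dir=d1)
        cohort_report(table, out_dir=d2)
        for name in ("report.csv", "summary.csv", "density.png"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_per_patient_aggregation_averages_teeth(self):
        rows = []
        for i in range(3):
            rows.append(dict(patient="c", tooth=f"ct{i}", group="control",
                             metric="m", value=10.0 + i))
        rows.append(dict(patient="x", tooth="x1", group="case", metric="m", value=8.0))
        rows.append(dict(patient="x", tooth="x2", group="case", metric="m", value=12.0))
        table = CohortTable.from_records(rows)
        report, _ = cohort_report(table, make_plots=False, aggregate="per_patient")
        assert len(report) == 1
        assert report.value.iloc[0] == pytest.approx(10.0)
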