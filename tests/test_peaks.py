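"""Peak processing: retention indices, aggregation, filters, normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tnscreen.peaks import (
    AlkaneCalibration,
    MetaboliteMatrix,
    ProcessingError,
    aggregate_derivatives,
    blank_filter,
    label_unknown,
    match_unknowns,
    median_normalize,
    normalize_by_od_is,
    normalize_matrix,
    process_peak_tables,
    reproducibility_filter,
    reproducibility_fraction,
    retention_index,
    two_step_median_normalize,
)

CAL = AlkaneCalibration(
    carbons=(10, 13, 14, 17, 18, 36),
    retention_times=(5.0, 9.5, 11.0, 15.0, 16.2, 40.0),
)


class TestRetentionIndex:
    def test_exact_at_alkane_nodes(self):
        assert retention_index(15.0, CAL) == pytest.approx(1700.0)
        assert retention_index(5.0, CAL) == pytest.approx(1000.0)

    def test_linear_midpoint(self):
        assert retention_index((15.0 + 16.2) / 2, CAL) == pytest.approx(1750.0)

    def test_fractional_position_closed_form(self):
        # 40% of the way from C13 to C14: RI = 100 * (13 + 0.4) = 1340
        rt = 9.5 + 0.4 * (11.0 - 9.5)
        assert retention_index(rt, CAL) == pytest.approx(1340.0)

    def test_outside_range_errors_unless_extrapolating(self):
        with pytest.raises(ProcessingError):
            retention_index(4.0, CAL)
        # linear extension of the first segment: slope 300/4.5 RI units per min
        assert retention_index(4.0, CAL, extrapolate=True) == pytest.approx(
            1000.0 - 1.0 * 300.0 / 4.5
        )

    @settings(derandomize=True, max_examples=200)
    @given(data=st.data())
    def test_monotone_in_retention_time(self, data):
        rts = sorted(
            data.draw(
                st.lists(
                    st.floats(1.0, 60.0, allow_nan=False), min_size=3, max_size=8,
                    unique=True,
                )
            )
        )
        carbons = tuple(range(10, 10 + len(rts)))
        cal = AlkaneCalibration(carbons, tuple(rts))
        q = sorted(
            data.draw(
                st.lists(st.floats(rts[0], rts[-1], allow_nan=False), min_size=2,
                         max_size=6)
            )
        )
        ris = [retention_index(x, cal) for x in q]
        assert all(a <= b + 1e-9 for a, b in zip(ris, ris[1:]))


class TestUnknownLabels:
    @pytest.mark.parametrize(
        "ri,expected",
        [(1705.4, "NA_1705.4"), (1375.4, "NA_1375.4"), (1000, "NA_1000.0")],
    )
    def test_label_format(self, ri, expected):
        assert label_unknown(ri) == expected

    def test_unknowns_matched_across_samples_within_tolerance(self):
        peaks = pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s1", "s2"],
                "label": ["", "", "", "", ""],
                "retention_index": [1705.3, 1705.5, 1705.4, 1380.0, 1380.4],
                "area": [1.0, 2.0, 3.0, 4.0, 5.0],
            }
        )
        out = match_unknowns(peaks, ri_tolerance=2.0)
        labels = set(out["label"])
        assert labels == {"NA_1705.4", "NA_1380.2"}


def _matrix(values, sample_types, experiments=None, od=None, index=None):
    n = len(sample_types)
    cols = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "sample_type": sample_types,
            "mutant_id": ["" for _ in range(n)],
            "experiment_id": experiments or ["E1"] * n,
            "od": od if od is not None else [1.0] * n,
        },
        index=pd.Index(cols, name="sample_id"),
    )
    vals = pd.DataFrame(values, columns=cols)
    if index is not None:
        vals.index = index
    return MetaboliteMatrix(vals, meta)


class TestBlankFilter:
    def test_metabolite_near_blank_level_dropped(self):
        mm = _matrix(
            [[100.0, 100.0, 90.0], [500.0, 500.0, 10.0]],
            ["wildtype", "wildtype", "blank"],
            index=["contam", "real"],
        )
        out = blank_filter(mm, min_sample_to_blank_ratio=3)
        assert list(out.values.index) == ["real"]
        assert out.samples_of_type("blank") == []

    def test_metabolite_absent_from_blanks_kept(self):
        mm = _matrix(
            [[100.0, 100.0, np.nan]],
            ["wildtype", "wildtype", "blank"],
            index=["real"],
        )
        out = blank_filter(mm)
        assert list(out.values.index) == ["real"]

    def test_no_blanks_pass_through_with_warning(self):
        mm = _matrix([[1.0, 2.0]], ["wildtype", "wildtype"], index=["x"])
        with pytest.warns(UserWarning, match="blank"):
            out = blank_filter(mm)
        assert out.values.shape == (1, 2)


class TestAggregation:
    def test_derivative_areas_sum_to_metabolite(self):
        peaks = pd.DataFrame(
            {
                "sample_id": ["s1", "s1", "s1"],
                "label": ["glutamate_2TMS", "glutamate_3TMS", "alanine_2TMS"],
                "retention_index": [1620.0, 1640.0, 1100.0],
                "area": [100.0, 200.0, 50.0],
            }
        )
        dmap = {"glutamate_2TMS": "glutamate", "glutamate_3TMS": "glutamate",
                "alanine_2TMS": "alanine"}
        wide = aggregate_derivatives(peaks, dmap)
        assert wide.at["glutamate", "s1"] == pytest.approx(300.0)
        assert wide.at["alanine", "s1"] == pytest.approx(50.0)

    def test_generator_conservation(self, small_study):
        """Summed derivative areas reproduce the generator's true abundances."""
        bundle = small_study["bundle"]
        peaks = bundle.peaks[bundle.peaks["label"] != "ribitol"]
        wide = aggregate_derivatives(peaks, bundle.derivative_map)
        shared = [m for m in wide.index if m in bundle.abundances.index]
        got = wide.loc[shared]
        want = bundle.abundances.loc[shared, got.columns]
        mask = got.notna() & want.notna()
        np.testing.assert_allclose(
            got.values[mask.values], want.values[mask.values], rtol=1e-9
        )


class TestNormalization:
    def test_scalar_arithmetic(self):
        assert normalize_by_od_is(1000.0, 2.0, 500.0) == pytest.approx(1.0)
        assert normalize_by_od_is(0.0, 2.0, 500.0) == 0.0
        with pytest.raises(ProcessingError):
            normalize_by_od_is(1.0, 0.0, 500.0)

    def test_internal_standard_row_excluded(self):
        mm = _matrix(
            [[1000.0, 2000.0], [500.0, 500.0]],
            ["wildtype", "wildtype"],
            od=[2.0, 2.0],
            index=["met", "ribitol"],
        )
        out = normalize_matrix(mm)
        assert "ribitol" not in out.values.index
        assert out.values.at["met", "s0"] == pytest.approx(1.0)
        assert out.values.at["met", "s1"] == pytest.approx(2.0)
        assert out.meta["internal_standard_area"].tolist() == [500.0, 500.0]

    def test_bad_sample_named_in_error(self):
        mm = _matrix(
            [[1.0, 1.0], [500.0, np.nan]],
            ["wildtype", "wildtype"],
            index=["met", "ribitol"],
        )
        with pytest.raises(ProcessingError, match="s1"):
            normalize_matrix(mm)


class TestReproducibility:
    def test_fraction_counts_quantified(self):
        assert reproducibility_fraction([1.0, 2.0, 3.0]) == 1.0
        assert reproducibility_fraction([1.0, np.nan, 3.0]) == pytest.approx(2 / 3)
        vals = [1.0] * 38 + [np.nan, 0.0]
        assert reproducibility_fraction(vals) == pytest.approx(0.95)

    def test_threshold_is_strictly_below(self):
        # 4 of 5 = 0.8 exactly: kept under threshold 0.8 ("under 80%" is strict)
        vals = np.array([[1.0, 1.0, 1.0, 1.0, np.nan]])
        mm = _matrix(vals, ["wildtype"] * 5, index=["met"])
        out = reproducibility_filter(mm, threshold=0.8, scope="per_experiment")
        assert "met" in out.values.index
        out = reproducibility_filter(mm, threshold=0.8, scope="global")
        assert "met" in out.values.index

    def test_per_experiment_removes_only_failing_experiment(self):
        vals = np.array([
            [np.nan, np.nan, 1.0, 1.0, 1.0, 1.0],  # 1/3 in E1, 3/3 in E2
            [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
        ])
        mm = _matrix(
            vals,
            ["wildtype"] * 6,
            experiments=["E1"] * 3 + ["E2"] * 3,
            index=["flaky", "solid"],
        )
        out = reproducibility_filter(mm, threshold=0.8, scope="per_experiment")
        assert out.values.loc["flaky", ["s0", "s1", "s2"]].isna().all()
        assert out.values.loc["flaky", ["s3", "s4", "s5"]].notna().all()
        assert out.values.loc["solid"].notna().all()

    def test_global_scope_drops_row_everywhere(self):
        vals = np.array([[1.0, np.nan, np.nan, 1.0], [1.0, 1.0, 1.0, 1.0]])
        mm = _matrix(vals, ["wildtype"] * 4, index=["low", "high"])
        out = reproducibility_filter(mm, threshold=0.95, scope="global")
        assert list(out.values.index) == ["high"]


class TestMedianNormalize:
    def test_constant_matrix_becomes_ones(self):
        df = pd.DataFrame(np.full((3, 4), 7.0))
        out = two_step_median_normalize(df)
        np.testing.assert_allclose(out.values, 1.0)

    def test_two_by_two_worked_example(self):
        df = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]])
        out = two_step_median_normalize(df)
        # step 1 row medians (1.5, 3.5); step 2 column medians (16/21, 26/21)
        expected = np.array([[0.875, 14.0 / 13.0], [1.125, 12.0 / 13.0]])
        np.testing.assert_allclose(out.values, expected, rtol=1e-12)

    def test_column_median_is_one(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.lognormal(size=(17, 9)))
        out = two_step_median_normalize(df)
        np.testing.assert_allclose(out.median(axis=0).values, 1.0, atol=1e-12)

    def test_missing_preserved_and_ignored(self):
        df = pd.DataFrame([[1.0, np.nan, 2.0], [2.0, 4.0, 6.0]])
        out = two_step_median_normalize(df)
        assert np.isnan(out.iat[0, 1])
        assert out.notna().sum().sum() == 5

    def test_all_missing_sample_errors(self):
        df = pd.DataFrame([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ProcessingError, match="samples"):
            two_step_median_normalize(df)

    def test_per_experiment_scope_leaves_filtered_rows_missing(self):
        vals = np.array([
            [np.nan, np.nan, 1.0, 2.0],
            [1.0, 2.0, 3.0, 4.0],
        ])
        mm = _matrix(
            vals, ["wildtype"] * 4, experiments=["E1", "E1", "E2", "E2"],
            index=["partial", "full"],
        )
        out = median_normalize(mm, scope="per_experiment")
        assert out.values.loc["partial", ["s0", "s1"]].isna().all()
        assert out.values.loc["partial", ["s2", "s3"]].notna().all()


class TestFullChain:
    def test_scale_invariance_per_sample(self, small_study):
        """Multiplying every peak of one sample by a constant changes nothing.

        The constant cancels through the internal standard and the
        sample-specific median, so the final normalized column is identical.
        """
        bundle = small_study["bundle"]
        base = process_peak_tables(
            bundle.peaks, bundle.sample_meta, bundle.derivative_map
        ).matrix
        target = base.values.columns[0]
        peaks = bundle.peaks.copy()
        sel = peaks["sample_id"] == target
        peaks.loc[sel, "area"] *= 10.0
        scaled = process_peak_tables(
            peaks, bundle.sample_meta, bundle.derivative_map
        ).matrix
        pd.testing.assert_frame_equal(base.values, scaled.values, rtol=1e-9)

    def test_funnel_counts_are_consistent(self, small_matrix):
        for name, before, after in small_matrix.funnel:
            assert after <= before
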