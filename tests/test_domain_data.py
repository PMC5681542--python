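"""Cohort ingestion, the difference transform, and atlas adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cephbn as cb
from cephbn.errors import CohortValidationError, CoverageError, FormatError

FEATURES = cb.FEATURES


def _row(pid="P1", treated=0, growth=0, age_t1=8.0, age_t2=15.0, **values):
    row = {"id": pid, "treated": treated, "growth": growth,
           "age_t1": age_t1, "age_t2": age_t2}
    for f in FEATURES:
        row[f"{f}_t1"] = values.get(f"{f}_t1", 10.0)
        row[f"{f}_t2"] = values.get(f"{f}_t2", 12.0)
    return row


def _write(tmp_path, rows, drop=None):
    frame = pd.DataFrame(rows)
    if drop:
        frame = frame.drop(columns=[drop])
    path = tmp_path / "cohort.csv"
    frame.to_csv(path, index=False)
    return path


class TestReadCohort:
    def test_well_formed_rows_ingested(self, tmp_path):
        path = _write(tmp_path, [_row("P1"), _row("P2"), _row("P3")])
        cohort = cb.read_cohort(path)
        assert len(cohort) == 3
        assert [r.patient_id for r in cohort.records] == ["P1", "P2", "P3"]

    def test_missing_column_names_the_column(self, tmp_path):
        path = _write(tmp_path, [_row()], drop="CoGo_t1")
        with pytest.raises(FormatError, match="CoGo_t1"):
            cb.read_cohort(path)

    def test_equal_ages_rejected_with_patient_id(self, tmp_path):
        path = _write(tmp_path, [_row("P1"), _row("P9", age_t1=9, age_t2=9)])
        with pytest.raises(CohortValidationError, match="P9"):
            cb.read_cohort(path)

    def test_growth_missing_allowed_only_for_treated(self, tmp_path):
        ok = _write(tmp_path, [_row("P1", treated=1, growth=None)])
        assert cb.read_cohort(ok).records[0].growth is None
        bad = _write(tmp_path, [_row("P2", treated=0, growth=None)])
        with pytest.raises(CohortValidationError, match="P2"):
            cb.read_cohort(bad)

    def test_duplicate_ids_rejected_unless_first_last(self, tmp_path):
        rows = [_row("P1", age_t1=6, age_t2=9, CoA_t2=90.0),
                _row("P1", age_t1=9, age_t2=14, CoA_t1=90.0, CoA_t2=95.0)]
        path = _write(tmp_path, rows)
        with pytest.raises(CohortValidationError):
            cb.read_cohort(path)
        cohort = cb.read_cohort(path, visits="first_last")
        rec = cohort.records[0]
        assert (rec.age_t1, rec.age_t2) == (6, 14)
        assert rec.values_t2["CoA"] == 95.0

    def test_dialect_maps_column_names(self, tmp_path):
        frame = pd.DataFrame([_row()]).rename(columns={"id": "patient"})
        path = tmp_path / "c.csv"
        frame.to_csv(path, index=False)
        assert len(cb.read_cohort(path, dialect={"patient": "id"})) == 1

    def test_write_read_roundtrip(self, tmp_path, fixture_cohort):
        path = tmp_path / "out.csv"
        cb.write_cohort(fixture_cohort, path)
        again = cb.read_cohort(path)
        assert len(again) == len(fixture_cohort)
        a, b = fixture_cohort.records[0], again.records[0]
        assert a.values_t1 == pytest.approx(b.values_t1)


class TestComputeDifferences:
    def test_direct_arithmetic(self):
        rec = cb.PatientRecord(
            "P1", 0, 1, 8.0, 15.0,
            {**{f: 10.0 for f in FEATURES}, "CoA": 85.0, "ANB": 3.0},
            {**{f: 12.0 for f in FEATURES}, "CoA": 99.0, "ANB": 3.0},
        )
        table = cb.compute_differences(cb.Cohort((rec,)))
        row = table.frame.iloc[0]
        assert row["dT"] == 7.0
        assert row["dCoA"] == 14.0
        assert row["dANB"] == 0.0  # identical at both visits

    def test_shape_contract(self, fixture_cohort, rate_table):
        assert len(rate_table) == len(fixture_cohort)
        assert rate_table.columns == list(cb.DELTA_COLUMNS)

    def test_permutation_equivariance(self, fixture_cohort):
        reversed_cohort = cb.Cohort(tuple(reversed(fixture_cohort.records)))
        fwd = cb.compute_differences(fixture_cohort).frame
        rev = cb.compute_differences(reversed_cohort).frame
        pd.testing.assert_frame_equal(fwd.sort_index(), rev.sort_index())

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(
        st.tuples(st.floats(-50, 50, allow_nan=False),
                  st.floats(-50, 50, allow_nan=False)),
        min_size=6, max_size=6))
    def test_visit2_rebuilds_exactly(self, pairs):
        v1 = {f: a for f, (a, _) in zip(FEATURES, pairs)}
        v2 = {f: b for f, (_, b) in zip(FEATURES, pairs)}
        rec = cb.PatientRecord("P1", 0, 0, 7.0, 12.5, v1, v2)
        row = cb.compute_differences(cb.Cohort((rec,))).frame.iloc[0]
        for f in FEATURES:
            assert v1[f] + row[f"d{f}"] == pytest.approx(v2[f], abs=1e-12)


class TestAdjustByReference:
    def _reference(self, offset=0.0, slope=0.0):
        ages = np.array([4.0, 20.0])
        return cb.ReferenceTable(
            {f: (ages, offset + slope * ages) for f in FEATURES})

    def test_zero_reference_is_identity(self, fixture_cohort):
        adjusted = cb.adjust_by_reference(fixture_cohort, self._reference(0.0))
        assert adjusted.provenance == "adjusted"
        for a, b in zip(adjusted.records, fixture_cohort.records):
            assert a.values_t1 == pytest.approx(b.values_t1)

    def test_self_subtraction_yields_zero(self):
        rec = cb.PatientRecord("P1", 0, 0, 8.0, 10.0,
                               {f: 5.0 for f in FEATURES},
                               {f: 5.0 for f in FEATURES})
        ref = cb.ReferenceTable(
            {f: (np.array([4.0, 20.0]), np.array([5.0, 5.0])) for f in FEATURES})
        adjusted = cb.adjust_by_reference(cb.Cohort((rec,)), ref)
        assert all(v == 0.0 for v in adjusted.records[0].values_t1.values())

    def test_linear_interpolation_midpoint(self):
        ref = cb.ReferenceTable({
            f: (np.array([8.0, 10.0]), np.array([4.0, 6.0])) for f in FEATURES})
        rec = cb.PatientRecord("P1", 0, 0, 9.0, 10.0,
                               {f: 5.0 for f in FEATURES},
                               {f: 6.0 for f in FEATURES})
        adjusted = cb.adjust_by_reference(cb.Cohort((rec,)), ref)
        assert adjusted.records[0].values_t1["ANB"] == pytest.approx(0.0)

    def test_out_of_range_age_names_patient(self):
        ref = cb.ReferenceTable({
            f: (np.array([8.0, 10.0]), np.array([4.0, 6.0])) for f in FEATURES})
        rec = cb.PatientRecord("P7", 0, 0, 8.5, 12.0,
                               {f: 5.0 for f in FEATURES},
                               {f: 6.0 for f in FEATURES})
        with pytest.raises(CoverageError, match="P7"):
            cb.adjust_by_reference(cb.Cohort((rec,)), ref)

    def test_adjustment_commutes_with_differences(self, fixture_cohort):
        """adjust -> diff equals diff -> subtracting interpolated reference
        differences, to floating-point accuracy."""
        ref = self._reference(offset=1.0, slope=0.8)
        left = cb.compute_differences(
            cb.adjust_by_reference(fixture_cohort, ref)).frame
        right = cb.compute_differences(fixture_cohort).frame.copy()
        for rec in fixture_cohort.records:
            for f in FEATURES:
                delta_ref = (ref.lookup(f, rec.age_t2) - ref.lookup(f, rec.age_t1))
                right.loc[rec.patient_id, f"d{f}"] -= delta_ref
        assert np.allclose(left.to_numpy(), right.to_numpy(),
                           atol=1e-9, equal_nan=True)

    def test_reference_csv_roundtrip(self, tmp_path):
        ref = cb.synthetic_reference(seed=5)
        path = tmp_path / "ref.csv"
        ref.write(path)
        again = cb.ReferenceTable.read(path)
        assert again.lookup("CoA", 9.3) == pytest.approx(ref.lookup("CoA", 9.3))
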