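"""Encounter-history data model, .inp/CSV I/O and standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mscmr.data import (
    Dataset,
    EncounterHistory,
    InpParseError,
    StudyCalendar,
    filter_missing_mass,
    read_inp,
    read_year_covariates,
    standardize,
    write_inp,
)

from conftest import random_dataset

CAL10 = StudyCalendar(2003, 10)


class TestInpParsing:
    def test_fledgling_line_maps_fields(self, tmp_path):
        p = tmp_path / "x.inp"
        p.write_text("1011000000 1 1 3.40;\n")
        ds = read_inp(p, CAL10)
        (h,) = ds.histories
        assert h.mark_occasion == 1
        assert h.is_fledgling
        assert h.fledging_mass_kg == pytest.approx(3.40)
        assert h.detections == (1, 0, 1, 1, 0, 0, 0, 0, 0, 0)

    def test_adult_line_first_one_rule(self, tmp_path):
        p = tmp_path / "x.inp"
        p.write_text("0000100000 1 0;\n")
        ds = read_inp(p, CAL10)
        (h,) = ds.histories
        assert h.mark_occasion == 5
        assert not h.is_fledgling
        assert h.fledging_mass_kg is None

    @pytest.mark.parametrize(
        "line, msg",
        [
            ("101100000 1 1 3.40;", "length"),
            ("10a1000000 1 1 3.40;", "non-binary"),
            ("1011000000 1 2 3.40;", "group"),
            ("0000100000 1 0 3.1;", "mass"),
        ],
    )
    def test_malformed_lines_name_line_number(self, tmp_path, line, msg):
        p = tmp_path / "x.inp"
        p.write_text("1000000000 1 0;\n" + line + "\n")
        with pytest.raises(InpParseError, match="line 2"):
            read_inp(p, CAL10)
        with pytest.raises(InpParseError, match=msg):
            read_inp(p, CAL10)

    def test_round_trip_random_datasets(self, tmp_path):
        rng = np.random.default_rng(0)
        for rep in range(10):
            ds = random_dataset(rng, T=7, n=100)
            p = tmp_path / f"rt{rep}.inp"
            write_inp(ds, p)
            back = read_inp(p, ds.calendar)
            assert back == ds

    def test_write_read_write_idempotent(self, tmp_path):
        ds = random_dataset(np.random.default_rng(3), T=6, n=50)
        p1, p2 = tmp_path / "a.inp", tmp_path / "b.inp"
        write_inp(ds, p1)
        write_inp(read_inp(p1, ds.calendar), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_dataset_writes_empty_file(self, tmp_path):
        ds = Dataset(calendar=CAL10, histories=[])
        p = tmp_path / "e.inp"
        write_inp(ds, p)
        assert p.read_text() == ""
        assert read_inp(p, CAL10).histories == []


class TestHistoryValidation:
    def test_detection_before_marking_rejected(self):
        with pytest.raises(ValueError):
            EncounterHistory("x", 3, "adult", (1, 0, 1, 0))

    def test_marking_must_be_detected(self):
        with pytest.raises(ValueError):
            EncounterHistory("x", 2, "adult", (0, 0, 1, 0))

    def test_duplicate_ids_rejected(self):
        h = EncounterHistory("x", 1, "adult", (1, 0))
        with pytest.raises(ValueError, match="duplicate"):
            Dataset(calendar=StudyCalendar(2003, 2), histories=[h, h])


class TestStandardize:
    def test_symmetric_example(self):
        s = standardize([1.0, 2.0, 3.0])
        assert s.center == 2.0
        assert s.scale == 1.0
        assert s.z == (-1.0, 0.0, 1.0)

    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=20).filter(
            lambda v: np.std(v, ddof=1) > 1e-6
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_zero_mean_unit_sd(self, values):
        z = np.asarray(standardize(values).z)
        assert abs(z.mean()) < 1e-10
        assert abs(z.std(ddof=1) - 1) < 1e-10

    def test_destandardize_round_trip(self):
        rng = np.random.default_rng(1)
        x = rng.normal(3.0, 0.5, 40)
        s = standardize(x)
        assert np.allclose(s.destandardize(np.asarray(s.z)), x, atol=1e-12)

    @given(
        st.floats(-10, 10),
        st.floats(0.1, 10),
    )
    @settings(max_examples=30, deadline=None)
    def test_affine_invariance(self, a, b):
        x = np.array([0.3, 1.7, -2.2, 4.0, 0.9])
        assert np.allclose(standardize(a + b * x).z, standardize(x).z, atol=1e-8)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            standardize([5.0, 5.0, 5.0])
        with pytest.raises(ValueError):
            standardize([1.0])


class TestYearCovariates:
    def _write(self, tmp_path, df):
        p = tmp_path / "cov.csv"
        df.to_csv(p, index=False)
        return p

    def _full_frame(self, shuffle=False):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "season": list(range(2003, 2013)),
                "pred_pressure": rng.integers(10, 60, 10),
                "lsst_lag0": rng.normal(size=10),
                "lsst_lag1": rng.normal(size=10),
                "enso_lag2": rng.normal(size=10),
                "enso_lag3": rng.normal(size=10),
                "sam_lag0": rng.normal(size=10),
                "sam_lag1": rng.normal(size=10),
                "gateway_days": [150, 140, 160, 120, 0, 130, 50, 180, 170, 150],
                "mean_fledging_mass": rng.normal(3.28, 0.1, 10),
            }
        )
        if shuffle:
            df = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        return df

    def test_full_table_and_sorting(self, tmp_path):
        ordered = read_year_covariates(self._write(tmp_path, self._full_frame()), CAL10)
        shuffled = read_year_covariates(
            self._write(tmp_path, self._full_frame(shuffle=True)), CAL10
        )
        assert ordered.missing == ()
        pd.testing.assert_frame_equal(ordered.table, shuffled.table)
        assert ordered.values("gateway_days")[4] == 0

    def test_missing_column_flagged(self, tmp_path):
        df = self._full_frame().drop(columns=["sam_lag1"])
        tab = read_year_covariates(self._write(tmp_path, df), CAL10)
        assert "sam_lag1" in tab.missing
        with pytest.raises(KeyError):
            tab.values("sam_lag1")

    def test_row_count_mismatch(self, tmp_path):
        df = self._full_frame().iloc[:8]
        with pytest.raises(InpParseError, match="rows"):
            read_year_covariates(self._write(tmp_path, df), CAL10)

    def test_non_numeric_cell(self, tmp_path):
        df = self._full_frame()
        df["lsst_lag0"] = df["lsst_lag0"].astype(object)
        df.loc[3, "lsst_lag0"] = "oops"
        with pytest.raises(InpParseError, match="non-numeric"):
            read_year_covariates(self._write(tmp_path, df), CAL10)


class TestFilterMissingMass:
    def _mixed(self, n_missing):
        T = 4
        cal = StudyCalendar(2003, T)
        hs = []
        for i in range(20):
            mass = None if i < n_missing else 3.3
            hs.append(
                EncounterHistory(f"f{i}", 1, "fledgling", (1, 0, 1, 0), mass)
            )
        for i in range(5):
            hs.append(EncounterHistory(f"ad{i}", 2, "adult", (0, 1, 1, 0)))
        return Dataset(calendar=cal, histories=hs)

    def test_no_missing_removes_none(self):
        ds, removed = filter_missing_mass(self._mixed(0))
        assert removed == 0
        assert len(ds) == 25

    def test_masked_masses_counted(self):
        ds, removed = filter_missing_mass(self._mixed(11))
        assert removed == 11
        assert len(ds.fledglings) == 9
        assert len(ds.adults) == 5

    def test_retained_histories_untouched(self):
        before = self._mixed(3)
        after, _ = filter_missing_mass(before)
        kept_ids = {h.animal_id for h in after.histories}
        for h in before.histories:
            if h.animal_id in kept_ids:
                assert h in after.histories
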