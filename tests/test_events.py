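"""Event-table parsing, BLQ flagging, exclusion filters and round-trips."""

import numpy as np
import pandas as pd
import pytest

from pkpdkit.cohort import CohortSpec, simulate_pk_dataset
from pkpdkit.events import (
    ConsistencyError,
    EventTable,
    ParseError,
    apply_exclusions,
    concat_tables,
    read_event_table,
    write_event_table,
)

HEADER = "ID,TIME,AMT,DV,DVID,EVID,MDV,FOOD,OCC,SEX,AGE,WEIGHT,EGFR,COMPLIANCE"


def _write(tmp_path, rows, name="d.csv"):
    path = tmp_path / name
    path.write_text("\n".join([HEADER] + rows) + "\n")
    return path


def _row(sid, time, amt, dv, dvid=1, evid=0, mdv=0, cov="male,60,84,89,1.0"):
    return f"{sid},{time},{amt},{dv},{dvid},{evid},{mdv},0,1,{cov}"


class TestReadEventTable:
    def test_small_fixture_parses(self, tmp_path):
        path = _write(tmp_path, [
            _row("A", 0, 180, ".", evid=1, mdv=1),
            _row("A", 1, ".", 2.5),
            _row("A", 4, ".", 5.0),
        ])
        table = read_event_table(path, lloq=0.01)
        assert len(table.records) == 3
        assert table.n_subjects == 1
        assert len(table.observations) == 2
        assert table.covariates.loc["A", "sex"] == "male"

    def test_blq_flag_set_below_lloq(self, tmp_path):
        path = _write(tmp_path, [
            _row("A", 0, 180, ".", evid=1, mdv=1),
            _row("A", 1, ".", 0.005),
            _row("A", 2, ".", 0.5),
        ])
        table = read_event_table(path, lloq=0.01)
        obs = table.observations.sort_values("TIME")
        assert obs["BLQ"].tolist() == [1, 0]

    def test_empty_file_gives_empty_table(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        table = read_event_table(path)
        assert len(table.records) == 0

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(HEADER + "\nA,0,180\n")
        with pytest.raises(ParseError, match="line 2"):
            read_event_table(path)

    def test_non_numeric_dv_rejected(self, tmp_path):
        path = _write(tmp_path, [_row("A", 1, ".", "oops")])
        with pytest.raises(ParseError):
            read_event_table(path)

    def test_round_trip(self, tmp_path, pk_base):
        spec = CohortSpec(n_subjects=6, duration_days=2, design="serial", seed=3)
        table, _ = simulate_pk_dataset(spec, pk_base)
        out = tmp_path / "rt.csv"
        write_event_table(table, out)
        table2 = read_event_table(out, lloq=table.lloq)
        pd.testing.assert_frame_equal(
            table.records.reset_index(drop=True), table2.records.reset_index(drop=True),
            check_dtype=False,
        )
        got = table2.covariates[table.covariates.columns]
        for col in table.covariates.columns:
            a, b = table.covariates[col], got[col]
            if a.dtype.kind in "fi":
                assert np.allclose(a.astype(float), b.astype(float), equal_nan=True)
            else:
                assert (a.astype(str) == b.astype(str)).all()


class TestApplyExclusions:
    def _table(self):
        rec = pd.DataFrame(
            [
                # subject A: 1 dose, 10 observations, 2 post-dose BLQ, 1 pre-dose
                ["A", -1.0, np.nan, 0.5, 1, 0, 0, 0, 0, 1],
                ["A", 0.0, 180.0, np.nan, 1, 1, 1, 0, 0, 1],
            ]
            + [["A", float(t), np.nan, 1.0, 1, 0, 0, 0, 0, 1] for t in range(1, 8)]
            + [
                ["A", 8.0, np.nan, 0.005, 1, 0, 0, 1, 0, 1],
                ["A", 9.0, np.nan, 0.003, 1, 0, 0, 1, 0, 1],
            ],
            columns=["ID", "TIME", "AMT", "DV", "DVID", "EVID", "MDV", "BLQ", "FOOD", "OCC"],
        )
        rec["TIME"] = rec["TIME"] + 1.0  # keep times non-negative
        rec = rec.sort_values(["ID", "TIME"]).reset_index(drop=True)
        rec["dv_kind"] = "pk"
        cov = pd.DataFrame({"compliance": [1.0]}, index=pd.Index(["A"], name="ID"))
        return EventTable(rec, cov, lloq=0.01)

    def test_hand_counted_fractions(self):
        table = self._table()
        out, rep = apply_exclusions(table, 0.8)
        assert rep.n_input_observations == 10
        assert rep.n_blq_excluded == 2
        assert rep.n_predose_pk_excluded == 1
        assert len(out.observations) == 7
        assert rep.blq_fraction_of_all == pytest.approx(0.2)
        assert rep.n_predose_pk_excluded / rep.n_input_observations == pytest.approx(0.1)
        # both BLQ denominators exposed
        assert rep.blq_fraction_of_postdose == pytest.approx(2 / 9)

    def test_noncompliant_subject_fully_removed(self):
        table = self._table()
        table.covariates.loc["A", "compliance"] = 0.75
        out, rep = apply_exclusions(table, 0.8)
        assert len(out.records) == 0
        assert rep.n_noncompliant_subjects == 1
        assert rep.n_noncompliant_records == rep.n_input_records

    def test_noop_when_clean(self, serial_table):
        table, _ = serial_table
        clean = EventTable(
            table.records[table.records["BLQ"] == 0].reset_index(drop=True),
            table.covariates, table.lloq,
        )
        out, rep = apply_exclusions(clean, 0.8)
        assert len(out.records) == len(clean.records)
        assert rep.n_excluded == 0

    def test_idempotent_and_conserving(self, serial_table):
        table, _ = serial_table
        once, rep1 = apply_exclusions(table, 0.8)
        twice, rep2 = apply_exclusions(once, 0.8)
        pd.testing.assert_frame_equal(once.records, twice.records)
        assert rep2.n_excluded == 0
        assert rep1.n_retained_records + rep1.n_excluded == rep1.n_input_records

    def test_predose_ldl_retained(self):
        rec = pd.DataFrame(
            [
                ["A", 0.0, np.nan, 140.0, 2, 0, 0, 0, 0, 1],   # baseline LDL, pre-dose
                ["A", 1.0, 180.0, np.nan, 1, 1, 1, 0, 0, 1],
                ["A", 2.0, np.nan, 3.0, 1, 0, 0, 0, 0, 1],
            ],
            columns=["ID", "TIME", "AMT", "DV", "DVID", "EVID", "MDV", "BLQ", "FOOD", "OCC"],
        )
        rec["dv_kind"] = rec["DVID"].map({1: "pk", 2: "ldl"})
        cov = pd.DataFrame({"compliance": [1.0]}, index=pd.Index(["A"], name="ID"))
        out, rep = apply_exclusions(EventTable(rec, cov, 0.01), 0.8)
        assert (out.records["dv_kind"] == "ldl").sum() == 1
        assert rep.n_predose_pk_excluded == 0

    def test_bad_threshold_rejected(self, serial_table):
        with pytest.raises(ValueError):
            apply_exclusions(serial_table[0], 0.0)


def test_concat_rejects_duplicate_ids(serial_table):
    table, _ = serial_table
    with pytest.raises(ConsistencyError):
        concat_tables([table, table])


def test_validate_catches_unsorted_times(serial_table):
    table, _ = serial_table
    bad = table.copy()
    bad.records = bad.records.iloc[::-1].reset_index(drop=True)
    with pytest.raises(ConsistencyError):
        bad.validate()
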