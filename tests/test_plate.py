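import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbgrowth import (
    Plate,
    WellResult,
    aggregate_replicates,
    cglutamicum_like,
    deviation_percent,
    process_plate,
    read_plate_table,
    simulate_plate,
    write_plate_csv,
    write_results,
)


@pytest.fixture(scope="module")
def small_plate_csv(tmp_path_factory):
    path = tmp_path_factory.mktemp("plates") / "plate3.csv"
    wells, _, _ = simulate_plate(3, seed=3)
    wells = [w.__class__(well_id=w.well_id, time=w.time[:100],
                         backscatter=w.backscatter[:100]) for w in wells]
    write_plate_csv(wells, path)
    return path, wells


class TestReadPlateTable:
    def test_wide_csv_round_trip(self, small_plate_csv):
        path, wells = small_plate_csv
        plate = read_plate_table(path, "wide_csv")
        assert len(plate) == 3
        assert [w.well_id for w in plate.wells] == [w.well_id for w in wells]
        for got, exp in zip(plate.wells, wells):
            np.testing.assert_allclose(got.backscatter, exp.backscatter,
                                       rtol=1e-12)
            assert len(got) == 100

    def test_time_unit_minutes_converted_to_hours(self, tmp_path):
        path = tmp_path / "minutes.csv"
        pd.DataFrame({"time_h": [0, 9, 18, 27, 36],
                      "A01": [10, 10, 11, 13, 17.0]}).to_csv(path, index=False)
        plate = read_plate_table(path, "wide_csv", {"time_unit": "min"})
        assert plate.wells[0].time[1] == pytest.approx(0.15)

    def test_biolector_xlsx_dialect(self, tmp_path, small_plate_csv):
        _, wells = small_plate_csv
        path = tmp_path / "plate.xlsx"
        df = pd.DataFrame({"t [h]": wells[0].time})
        for w in wells:
            df[w.well_id] = w.backscatter
        df.to_excel(path, sheet_name="backscatter", index=False)
        plate = read_plate_table(path, "biolector_xlsx",
                                 {"sheet": "backscatter",
                                  "time_column": "t [h]",
                                  "wells": [wells[0].well_id]})
        assert len(plate) == 1
        np.testing.assert_allclose(plate.wells[0].backscatter,
                                   wells[0].backscatter)

    def test_hard_errors_name_the_defect(self, tmp_path):
        p1 = tmp_path / "notime.csv"
        pd.DataFrame({"A01": np.arange(10.0)}).to_csv(p1, index=False)
        with pytest.raises(ValueError, match="time column"):
            read_plate_table(p1, "wide_csv")
        p2 = tmp_path / "short.csv"
        pd.DataFrame({"time_h": [0, 1], "A01": [1.0, 2.0]}).to_csv(
            p2, index=False)
        with pytest.raises(ValueError, match="4 rows"):
            read_plate_table(p2, "wide_csv")
        with pytest.raises(FileNotFoundError):
            read_plate_table(tmp_path / "missing.csv", "wide_csv")

    def test_unparseable_row_truncates_well_with_warning(self, tmp_path):
        path = tmp_path / "bad.csv"
        df = pd.DataFrame({"time_h": np.arange(8) * 0.15,
                           "A01": ["10", "10", "10", "10", "11", "oops",
                                   "13", "14"]})
        df.to_csv(path, index=False)
        with pytest.warns(UserWarning, match="truncating"):
            plate = read_plate_table(path, "wide_csv")
        assert len(plate.wells[0]) == 5


@pytest.fixture(scope="module")
def plate48():
    spec = cglutamicum_like()
    wells, truth, groups = simulate_plate(
        48, lambda i: spec, seed=11, groups=[f"g{i}" for i in range(3)])
    return Plate(wells=wells, groups=groups), truth


class TestProcessPlate:
    def test_all_growers_converge_and_replicates_agree(self, plate48):
        plate, truth = plate48
        results = process_plate(plate, loq=4.0)
        assert len(results) == 48
        assert all(r.status == "ok" for r in results)
        mus = np.array([r.mu for r in results])
        # every well within 10% of the shared true rate
        assert np.all(np.abs(mus - 0.46) / 0.46 < 0.10)
        # replicate scatter no larger than the CI half-width scale
        halfwidths = [(r.ci95[1] - r.ci95[0]) / 2 for r in results]
        assert np.std(mus) <= np.mean(halfwidths)

    def test_blank_medium_well_flagged_not_fatal(self):
        wells, _, groups = simulate_plate(3, seed=4, n_blank_wells=1)
        results = process_plate(Plate(wells=wells, groups=groups), loq=4.0)
        by_status = {r.well_id: r.status for r in results}
        assert list(by_status.values()).count("ok") == 3
        assert list(by_status.values()).count("no_growth") == 1

    def test_serial_and_parallel_runs_are_byte_identical(self, plate48,
                                                         tmp_path):
        plate, _ = plate48
        paths = []
        for jobs in (1, 4):
            res = process_plate(plate, loq=4.0, n_jobs=jobs)
            summ = aggregate_replicates(res, plate.groups)
            rp = tmp_path / f"results_{jobs}.csv"
            sp = tmp_path / f"summary_{jobs}.csv"
            write_results(res, summ, rp, sp)
            paths.append((rp.read_bytes(), sp.read_bytes()))
        assert paths[0] == paths[1]

    def test_results_independent_of_well_order(self):
        wells, _, _ = simulate_plate(6, seed=9)
        fwd = process_plate(Plate(wells=wells), loq=4.0)
        rev = process_plate(Plate(wells=wells[::-1]), loq=4.0)
        assert {r.well_id: r.mu for r in fwd} == {r.well_id: r.mu for r in rev}


class TestAggregation:
    def make_results(self, mus, strain="s"):
        return [WellResult(well_id=f"A{i:02d}", strain=strain, status="ok",
                           mu=mu) for i, mu in enumerate(mus)]

    def test_replicate_mean_rounds_to_presented_value(self):
        s = aggregate_replicates(self.make_results([0.601, 0.615, 0.617]))[0]
        assert s.mu_mean == pytest.approx(0.611, abs=1e-12)
        assert f"{s.mu_mean:.2f}" == "0.61"

    def test_duplicate_mean(self):
        s = aggregate_replicates(self.make_results([0.455, 0.456]))[0]
        assert s.mu_mean == pytest.approx(0.4555)
        assert f"{s.mu_mean:.2f}" == "0.46"

    def test_single_replicate_and_failed_group(self):
        ok = self.make_results([0.30])
        failed = [WellResult(well_id="B01", strain="t",
                             status="no_exponential_phase")]
        summaries = {s.strain: s for s in aggregate_replicates(ok + failed)}
        assert summaries["s"].mu_mean == 0.30
        assert summaries["t"].status == "no_converged_replicates"
        assert summaries["t"].n_replicates == 0


class TestDeviationPercent:
    def test_printed_examples(self):
        assert deviation_percent(0.30, 0.30) == 0.0
        assert deviation_percent(0.30, 0.32) == pytest.approx(6.25)

    @given(st.floats(0.01, 10))
    @settings(max_examples=30, deadline=None)
    def test_scale_free(self, x):
        assert deviation_percent(1.1 * x, x) == pytest.approx(10.0)

    def test_requires_positive_literature_rate(self):
        with pytest.raises(ValueError):
            deviation_percent(0.3, 0.0)


class TestWriteResults:
    def test_round_trip_preserves_stored_precision(self, tmp_path):
        wells, _, groups = simulate_plate(3, seed=6)
        res = process_plate(Plate(wells=wells, groups=groups), loq=4.0)
        summ = aggregate_replicates(res, groups)
        rp, sp = tmp_path / "r.csv", tmp_path / "s.csv"
        write_results(res, summ, rp, sp)
        back = pd.read_csv(rp)
        assert list(back.columns)[:4] == ["well_id", "strain", "status",
                                          "mu_h-1"]
        for r, (_, row) in zip(res, back.iterrows()):
            assert float(f"{r.mu:.6g}") == row["mu_h-1"]

    def test_all_failed_wells_still_write_rows(self, tmp_path):
        res = [WellResult(well_id="A01", strain="s", status="no_growth")]
        write_results(res, [], tmp_path / "r.csv", tmp_path / "s.csv")
        back = pd.read_csv(tmp_path / "r.csv")
        assert len(back) == 1
        assert back.loc[0, "status"] == "no_growth"
        summary = pd.read_csv(tmp_path / "s.csv")
        assert len(summary) == 0
        assert "mu_mean" in summary.columns
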