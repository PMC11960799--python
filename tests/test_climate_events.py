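"""Event detection against worked examples and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from arcex import climate_events as ce
from arcex.synthetic_data import ClimateSimConfig, simulate_climate

from conftest import constant_threshold, make_cube


def brute_force_warming_days(cube, thr_values, strict=True):
    """Independent per-day condition check: winter AND tmax > threshold."""
    time = pd.DatetimeIndex(cube.time.values)
    winter = np.isin(time.month, (10, 11, 12, 1, 2, 3))
    out = set()
    tas = cube.tasmax.values
    for t in range(len(time)):
        if not winter[t]:
            continue
        for iy in range(cube.sizes["lat"]):
            for ix in range(cube.sizes["lon"]):
                v, c = tas[t, iy, ix], thr_values[iy, ix]
                if np.isfinite(v) and np.isfinite(c) and (
                    v > c if strict else v >= c
                ):
                    out.add((t, iy, ix))
    return out


def brute_force_ros_days(cube):
    """Independent four-condition day check (without the refreeze rule)."""
    time = pd.DatetimeIndex(cube.time.values)
    winter = np.isin(time.month, (10, 11, 12, 1, 2, 3))
    tas, rain, swe = cube.tasmax.values, cube.pr.values, cube.swe.values
    out = set()
    for t in range(len(time)):
        if not winter[t]:
            continue
        for iy in range(cube.sizes["lat"]):
            for ix in range(cube.sizes["lon"]):
                if (
                    rain[t, iy, ix] >= 3.0
                    and swe[t, iy, ix] >= 3.0
                    and tas[t, iy, ix] > 1.0
                ):
                    out.add((t, iy, ix))
    return out


def segment(days_for_cell):
    """Split sorted day indices into consecutive runs (oracle)."""
    runs, cur = [], []
    for d in days_for_cell:
        if cur and d == cur[-1] + 1:
            cur.append(d)
        else:
            if cur:
                runs.append(cur)
            cur = [d]
    if cur:
        runs.append(cur)
    return runs


class TestAggregateGrid:
    def test_constant_field_unchanged(self):
        cube = make_cube(
            np.full((5, 4, 4), 2.0), lats=np.arange(4) * 0.25 + 70.125,
            lons=np.arange(4) * 0.25 + 20.125,
        )
        agg = ce.aggregate_grid(cube, 1.0)
        assert agg.sizes["lat"] == agg.sizes["lon"] == 1
        assert np.allclose(agg.tasmax.values, 2.0)

    def test_mean_of_member_cells(self):
        field = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        cube = make_cube(field, lats=[70.25, 70.75], lons=[20.25, 20.75])
        agg = ce.aggregate_grid(cube, 1.0)
        assert float(agg.tasmax.values.squeeze()) == pytest.approx(2.5)

    def test_matches_block_mean_oracle(self):
        rng = np.random.default_rng(0)
        field = rng.normal(size=(3, 8, 8))
        cube = make_cube(
            field, lats=np.arange(8) * 0.25 + 70.125,
            lons=np.arange(8) * 0.25 + 20.125,
        )
        agg = ce.aggregate_grid(cube, 1.0)
        oracle = field.reshape(3, 2, 4, 2, 4).mean(axis=(2, 4))
        assert np.allclose(agg.tasmax.values, oracle)

    def test_non_divisible_resolution_rejected(self):
        cube = make_cube(
            np.zeros((2, 3, 3)), lats=[70.1, 70.5, 70.9], lons=[20.1, 20.5, 20.9]
        )
        with pytest.raises(ValueError):
            ce.aggregate_grid(cube, 1.0)


class TestWinterSeasons:
    def test_single_season_definition(self):
        time = pd.date_range("1950-10-01", "1951-03-31")
        labels = ce.winter_season_labels(time)
        assert (labels == 1951).all()
        assert len(time) == 182

    def test_summer_days_excluded(self):
        assert ce.winter_season_labels(pd.DatetimeIndex(["1950-07-15"]))[0] == -1

    def test_matches_month_mask_oracle_over_decades(self):
        time = pd.date_range("1950-01-01", "1979-12-31")
        labels = ce.winter_season_labels(time)
        oracle_winter = np.isin(time.month, (10, 11, 12, 1, 2, 3))
        assert ((labels > 0) == oracle_winter).all()
        oracle_label = np.where(
            time.month >= 10, time.year + 1, time.year
        )
        assert (labels[labels > 0] == oracle_label[oracle_winter]).all()

    def test_winter_days_flags_incomplete_boundary_seasons(self, sim_cube):
        wd = ce.winter_days(sim_cube)
        # first winter (Jan-Mar of start year) lacks its Oct-Dec part
        assert not wd.iloc[0]["complete"]
        assert wd.iloc[1:-1]["complete"].all()
        assert set(wd[wd["complete"]]["n_days"]) <= {182, 183}


class TestThreshold:
    def test_constant_series_threshold_is_the_constant(self):
        cube = make_cube(np.full(900, 5.0), start="1950-01-01")
        thr = ce.compute_threshold(cube, baseline=(1950, 1952))
        assert float(thr.values.values.squeeze()) == pytest.approx(5.0)

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(4)
        n = 1100
        vals = rng.permutation(np.linspace(-20, 10, n))
        cube = make_cube(vals, start="1950-01-01")
        thr = ce.compute_threshold(cube, baseline=(1950, 1952))
        time = pd.DatetimeIndex(cube.time.values)
        labels = ce.winter_season_labels(time)
        pool = np.sort(vals[(labels >= 1951) & (labels <= 1952)])
        # linear interpolation between order statistics
        h = (len(pool) - 1) * 0.99
        lo = int(np.floor(h))
        oracle = pool[lo] + (h - lo) * (pool[lo + 1] - pool[lo])
        assert float(thr.values.values.squeeze()) == pytest.approx(oracle, abs=1e-10)

    def test_cells_are_independent(self):
        a = np.full((900, 1, 2), 0.0)
        a[:, 0, 1] = 8.0
        cube = make_cube(a, start="1950-01-01", lons=[20.5, 21.5])
        thr = ce.compute_threshold(cube, baseline=(1950, 1952))
        assert np.allclose(thr.values.values, [[0.0, 8.0]])


class TestWarmingDetection:
    def test_worked_intensity_example(self):
        # two consecutive winter days at 5 then 7 degC over a 3 degC cut-off
        tas = np.full(10, -10.0)
        tas[3], tas[4] = 5.0, 7.0
        cube = make_cube(tas)
        events = ce.detect_warming_events(cube, constant_threshold(cube, 3.0))
        assert len(events) == 1
        ev = events[0]
        assert ev.length == 2
        assert ev.intensity == pytest.approx((5 - 3) * 1 + (7 - 3) * 2)  # = 10
        assert ev.max_temp == pytest.approx(7.0)

    def test_all_days_below_threshold_yield_no_events(self):
        cube = make_cube(np.full(30, -5.0))
        assert ce.detect_warming_events(cube, constant_threshold(cube, 3.0)) == []

    def test_segmentation_matches_run_length_oracle(self, sim_cube):
        thr = ce.compute_threshold(sim_cube, baseline=(1950, 1960))
        events = ce.detect_warming_events(sim_cube, thr)
        day_oracle = brute_force_warming_days(sim_cube, thr.values.values)
        detected_days = set()
        time = pd.DatetimeIndex(sim_cube.time.values)
        t_index = {ts: i for i, ts in enumerate(time)}
        lat_i = {v: i for i, v in enumerate(sim_cube.lat.values)}
        lon_i = {v: i for i, v in enumerate(sim_cube.lon.values)}
        for ev in events:
            start = t_index[ev.start]
            for k in range(ev.length):
                detected_days.add((start + k, lat_i[ev.lat], lon_i[ev.lon]))
        assert detected_days == day_oracle
        # event count equals the oracle's run segmentation per cell
        by_cell = {}
        for t, iy, ix in sorted(day_oracle):
            by_cell.setdefault((iy, ix), []).append(t)
        n_runs = sum(len(segment(days)) for days in by_cell.values())
        assert len(events) == n_runs

    def test_single_day_event_intensity_equals_exceedance(self):
        tas = np.full(10, -10.0)
        tas[5] = 4.5
        cube = make_cube(tas)
        (ev,) = ce.detect_warming_events(cube, constant_threshold(cube, 3.0))
        assert ev.intensity == pytest.approx(1.5)

    def test_higher_threshold_never_detects_more_days(self, sim_cube):
        t97 = ce.compute_threshold(sim_cube, (1950, 1960), percentile=97)
        t99 = ce.compute_threshold(sim_cube, (1950, 1960), percentile=99)
        n97 = sum(e.length for e in ce.detect_warming_events(sim_cube, t97))
        n99 = sum(e.length for e in ce.detect_warming_events(sim_cube, t99))
        assert n99 <= n97

    def test_missing_data_breaks_runs(self):
        tas = np.full(10, 5.0)
        tas[4] = np.nan
        cube = make_cube(tas)
        events = ce.detect_warming_events(cube, constant_threshold(cube, 3.0))
        assert [e.length for e in events] == [4, 5]

    def test_deleting_summer_days_changes_nothing(self, sim_cube):
        thr = ce.compute_threshold(sim_cube, baseline=(1950, 1960))
        full = ce.detect_warming_events(sim_cube, thr)
        time = pd.DatetimeIndex(sim_cube.time.values)
        winter_only = sim_cube.isel(time=ce.winter_season_labels(time) > 0)
        trimmed = ce.detect_warming_events(winter_only, thr)
        assert len(full) == len(trimmed)
        for a, b in zip(full, trimmed):
            assert a.start == b.start and a.length == b.length
            assert a.intensity == pytest.approx(b.intensity)


class TestRosDetection:
    def test_worked_intensity_example(self):
        tas = np.full(10, -5.0)
        tas[3], tas[4] = 2.0, 2.0
        rain = np.zeros(10)
        rain[3], rain[4] = 5.0, 7.0
        cube = make_cube(tas, pr=rain, swe=np.full(10, 10.0))
        events, diag = ce.detect_ros_events(cube)
        assert len(events) == 1
        assert events[0].intensity == pytest.approx(5 * 1 + 7 * 2)  # = 19
        assert diag == {"truncated_at_record_end": 0, "failed_refreeze": 0}

    def test_refreeze_criterion_rejects_warm_aftermath(self):
        tas = np.full(10, -5.0)
        tas[3] = 2.0
        tas[4:7] = 2.0  # 3 following days warm: no refreeze
        rain = np.zeros(10)
        rain[3] = 5.0
        cube = make_cube(tas, pr=rain, swe=np.full(10, 10.0))
        events, diag = ce.detect_ros_events(cube)
        assert events == []
        assert diag["failed_refreeze"] == 1

    def test_event_too_close_to_record_end_is_discarded(self):
        tas = np.full(5, -5.0)
        tas[-1] = 2.0
        rain = np.zeros(5)
        rain[-1] = 5.0
        cube = make_cube(tas, pr=rain, swe=np.full(5, 10.0))
        events, diag = ce.detect_ros_events(cube)
        assert events == []
        assert diag["truncated_at_record_end"] == 1

    def test_each_condition_is_necessary(self):
        base_tas = np.full(10, -5.0)
        base_rain, base_swe = np.zeros(10), np.full(10, 10.0)

        def detect(tas3=2.0, rain3=5.0, swe3=10.0):
            tas, rain, swe = base_tas.copy(), base_rain.copy(), base_swe.copy()
            tas[3], rain[3], swe[3] = tas3, rain3, swe3
            cube = make_cube(tas, pr=rain, swe=swe)
            return ce.detect_ros_events(cube)[0]

        assert len(detect()) == 1
        assert detect(rain3=2.9) == []  # rain below 3 mm
        assert detect(swe3=2.9) == []  # snowpack below 3 mm SWE
        assert detect(tas3=1.0) == []  # tmax not above 1 degC
        # thresholds are inclusive for rain and snow
        assert len(detect(rain3=3.0, swe3=3.0)) == 1

    def test_day_set_matches_four_condition_oracle(self, sim_cube):
        events, _ = ce.detect_ros_events(sim_cube)
        oracle_days = brute_force_ros_days(sim_cube)
        # every detected day must qualify under the independent check
        time = pd.DatetimeIndex(sim_cube.time.values)
        t_index = {ts: i for i, ts in enumerate(time)}
        lat_i = {v: i for i, v in enumerate(sim_cube.lat.values)}
        lon_i = {v: i for i, v in enumerate(sim_cube.lon.values)}
        detected = set()
        for ev in events:
            s = t_index[ev.start]
            for k in range(ev.length):
                detected.add((s + k, lat_i[ev.lat], lon_i[ev.lon]))
        assert detected <= oracle_days
        # days in the oracle but not detected must fail only refreeze/truncation
        tas = sim_cube.tasmax.values
        for t, iy, ix in oracle_days - detected:
            run = next(
                r
                for days in [sorted(
                    d for (d, y, x) in oracle_days if (y, x) == (iy, ix)
                )]
                for r in segment(days)
                if t in r
            )
            end = run[-1] + 1
            truncated = end + 3 > tas.shape[0]
            assert truncated or tas[end : end + 3, iy, ix].mean() >= 0.0


class TestSummariesAndEmergence:
    def test_cumulative_exceedance_is_sum_of_event_series(self):
        tas = np.full(20, -10.0)
        tas[3], tas[4] = 5.0, 7.0  # event with exceedances (2, 4)
        cube = make_cube(tas)
        thr = constant_threshold(cube, 3.0)
        events = ce.detect_warming_events(cube, thr)
        summ = ce.annual_summaries(events, ce.winter_days(cube), cube)
        row = summ[(summ["type"] == "warming") & (summ["n_events"] > 0)]
        assert row["total"].iloc[0] == pytest.approx(6.0)

    def test_empty_season_yields_zero_summary(self):
        cube = make_cube(np.full(20, -10.0))
        summ = ce.annual_summaries([], ce.winter_days(cube), cube)
        assert (summ["n_events"] == 0).all()
        assert (summ["total"] == 0).all()

    def test_summaries_match_flat_recomputation(self, sim_cube):
        thr = ce.compute_threshold(sim_cube, baseline=(1950, 1960))
        events = ce.detect_warming_events(sim_cube, thr)
        summ = ce.annual_summaries(events, ce.winter_days(sim_cube), sim_cube)
        summ = summ[summ["type"] == "warming"]
        # conservation: total exceedance over all seasons equals event sum
        assert summ["total"].sum() == pytest.approx(
            sum(ev.series.sum() for ev in events)
        )
        # spot-check one populated cell-season against direct aggregation
        ev = max(events, key=lambda e: e.length)
        group = [
            e
            for e in events
            if (e.lat, e.lon, e.season) == (ev.lat, ev.lon, ev.season)
        ]
        row = summ[
            (summ["cell_lat"] == ev.lat)
            & (summ["cell_lon"] == ev.lon)
            & (summ["season"] == ev.season)
        ].iloc[0]
        assert row["n_events"] == len(group)
        assert row["total"] == pytest.approx(sum(e.series.sum() for e in group))
        assert row["mean_length"] == pytest.approx(
            np.mean([e.length for e in group])
        )
        assert row["mean_intensity"] == pytest.approx(
            np.mean([e.intensity for e in group])
        )

    def test_emergence_flags_match_planted_pattern(self):
        rows = []
        # cell A: events only late; cell B: both; cell C: only early
        for lat, early, late in ((70.5, 0, 2), (71.5, 1, 1), (72.5, 3, 0)):
            rows.append((lat, 20.5, 1955, "rain-on-snow", early))
            rows.append((lat, 20.5, 1995, "rain-on-snow", late))
        summaries = pd.DataFrame(
            rows, columns=["cell_lat", "cell_lon", "season", "type", "n_events"]
        )
        flags = ce.emergence_flags(summaries, (1950, 1980), (1990, 2020))
        got = dict(zip(flags["cell_lat"], flags["flag"]))
        assert got == {70.5: "new", 71.5: "both-periods", 72.5: "vanished"}
        props = flags.attrs["proportions"]
        assert props["new"] == pytest.approx(1 / 3)

    def test_overlapping_periods_rejected(self):
        summaries = pd.DataFrame(
            columns=["cell_lat", "cell_lon", "season", "type", "n_events"]
        )
        with pytest.raises(ValueError, match="disjoint"):
            ce.emergence_flags(summaries, (1950, 1995), (1990, 2020))


def test_detection_is_cell_local(sim_cube):
    """Permuting cells permutes events correspondingly."""
    thr = ce.compute_threshold(sim_cube, baseline=(1950, 1960))
    events = ce.detect_warming_events(sim_cube, thr)
    flipped = sim_cube.isel(lat=slice(None, None, -1))
    thr_f = ce.compute_threshold(flipped, baseline=(1950, 1960))
    events_f = ce.detect_warming_events(flipped, thr_f)
    key = lambda e: (e.lat, e.lon, e.start, e.length, round(e.intensity, 9))
    assert sorted(map(key, events)) == sorted(map(key, events_f))
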