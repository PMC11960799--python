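"""Detection of extreme winter warming and rain-on-snow events.

Operates on daily gridded cubes (xarray Datasets with ``tasmax`` in °C,
``pr`` and ``prsn`` in mm/day, ``swe`` in mm SWE on dims
``(time, lat, lon)``).  The Arctic winter season is October–March; the
winter spanning Oct of year Y−1 through Mar of year Y is labelled Y, so
each season's days are contiguous in time.

An extreme winter warming event is a maximal run of consecutive winter
days in one cell whose daily maximum temperature exceeds that cell's
baseline 99th-percentile winter threshold.  A rain-on-snow event is a run
of winter days with ≥ 3 mm rain, ≥ 3 mm SWE snowpack and tmax > 1 °C,
retained only when the mean of the three daily maxima after the run is
below 0 °C (a refreeze, which is what forms the ice crust).  Event
intensity is the day-weighted sum of the event's own series — exceedance
for warming, rainfall for rain-on-snow — with 1-based day indices, so
sustained late-event conditions weigh more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "WINTER_MONTHS",
    "RosCriteria",
    "BaselineThreshold",
    "ExtremeEvent",
    "aggregate_grid",
    "winter_season_labels",
    "winter_days",
    "compute_threshold",
    "detect_warming_events",
    "detect_ros_events",
    "annual_summaries",
    "emergence_flags",
    "events_to_frame",
]

WINTER_MONTHS = (10, 11, 12, 1, 2, 3)


@dataclass(frozen=True)
class RosCriteria:
    """Thresholds of the four-part rain-on-snow day definition.

    A day qualifies when rain and snowpack meet their thresholds
    (inclusive by default; both comparisons switchable to strict) and
    tmax strictly exceeds ``temp_c``.  A candidate run is kept only if
    the mean tmax of the ``refreeze_days`` days after it is < 0 °C.
    """

    rain_mm: float = 3.0
    snow_mm: float = 3.0
    temp_c: float = 1.0
    refreeze_days: int = 3
    strict_rain: bool = False
    strict_snow: bool = False


@dataclass
class BaselineThreshold:
    """Per-cell percentile threshold of winter daily maximum temperature."""

    values: xr.DataArray  # (lat, lon), °C; NaN where no baseline data
    period: tuple[int, int]
    percentile: float
    interpolation: str = "linear"


@dataclass
class ExtremeEvent:
    """One maximal run of qualifying days in one grid cell."""

    lat: float
    lon: float
    event_type: str  # "warming" | "rain-on-snow"
    start: pd.Timestamp
    length: int
    #: per-day exceedance (°C, warming) or rainfall (mm, rain-on-snow)
    series: np.ndarray
    max_temp: float
    season: int
    intensity: float = field(init=False)

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.length != len(self.series):
            raise ValueError("length does not match series")
        self.intensity = float(
            np.sum(self.series * np.arange(1, self.length + 1))
        )


def aggregate_grid(
    cube: xr.Dataset,
    cell_size: float,
    reductions: dict[str, str] | None = None,
) -> xr.Dataset:
    """Block-aggregate a cube to a coarser regular grid.

    Each coarse cell's daily value is the unweighted mean of its member
    fine cells (per-variable reduction overridable, e.g. ``{"tasmax":
    "max"}``).  ``cell_size`` must be an integer multiple of the source
    spacing and divide the grid extent evenly.
    """
    src = float(cube.lat[1] - cube.lat[0]) if cube.sizes["lat"] > 1 else float(
        cube.attrs.get("cell_size_deg", cell_size)
    )
    factor = cell_size / src
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"target cell size {cell_size} is not an integer multiple of the "
            f"source spacing {src}"
        )
    factor = int(round(factor))
    if cube.sizes["lat"] % factor or cube.sizes["lon"] % factor:
        raise ValueError("grid extent is not divisible by the target cell size")
    reductions = reductions or {}
    out = {}
    for name, da in cube.data_vars.items():
        coarse = da.coarsen(lat=factor, lon=factor, boundary="exact")
        how = reductions.get(name, "mean")
        out[name] = getattr(coarse, how)()
    agg = xr.Dataset(out, attrs=dict(cube.attrs))
    agg.attrs["cell_size_deg"] = cell_size
    return agg


def winter_season_labels(time: pd.DatetimeIndex) -> np.ndarray:
    """Season label per day: Oct(Y−1)–Mar(Y) → Y; Apr–Sep → −1."""
    time = pd.DatetimeIndex(time)
    month = time.month.to_numpy()
    year = time.year.to_numpy()
    labels = np.where(month >= 10, year + 1, np.where(month <= 3, year, -1))
    return labels.astype(int)


def winter_days(cube: xr.Dataset) -> pd.DataFrame:
    """Partition the cube's calendar into winter seasons.

    Returns one row per season with its label, first/last member day,
    number of days, and a completeness flag (a complete Oct–Mar season
    has 182 days, or 183 when it contains Feb 29).
    """
    time = pd.DatetimeIndex(cube.time.values)
    labels = winter_season_labels(time)
    rows = []
    for label in np.unique(labels[labels > 0]):
        days = time[labels == label]
        expected_start = pd.Timestamp(year=label - 1, month=10, day=1)
        expected_end = pd.Timestamp(year=label, month=3, day=31)
        rows.append(
            {
                "season": int(label),
                "first_day": days[0],
                "last_day": days[-1],
                "n_days": len(days),
                "complete": bool(
                    days[0] == expected_start and days[-1] == expected_end
                ),
            }
        )
    return pd.DataFrame(rows)


def _winter_mask(time: pd.DatetimeIndex) -> np.ndarray:
    return winter_season_labels(time) > 0


def compute_threshold(
    cube: xr.Dataset,
    baseline: tuple[int, int] = (1950, 1980),
    percentile: float = 99.0,
) -> BaselineThreshold:
    """Per-cell percentile of winter daily maximum temperature.

    Pools every winter day of the complete seasons labelled
    ``baseline[0]+1 .. baseline[1]`` (i.e. the winters fully contained in
    the baseline period) and takes the per-cell percentile with linear
    interpolation between order statistics.  Cells with no valid baseline
    data get a NaN threshold, which downstream detection treats as
    "never exceeded".
    """
    time = pd.DatetimeIndex(cube.time.values)
    labels = winter_season_labels(time)
    lo, hi = baseline
    in_baseline = (labels >= lo + 1) & (labels <= hi)
    if not in_baseline.any():
        raise ValueError(f"no complete baseline winters in {baseline}")
    tas = cube["tasmax"].isel(time=in_baseline)
    with np.errstate(invalid="ignore"):
        thr = tas.quantile(percentile / 100.0, dim="time", method="linear")
    thr = thr.drop_vars("quantile")
    return BaselineThreshold(
        values=thr, period=baseline, percentile=percentile
    )


def _day_numbers(time: pd.DatetimeIndex) -> np.ndarray:
    return (time.asi8 // 86_400_000_000_000).astype(np.int64)


def _runs_of(mask_1d: np.ndarray, daynum: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of qualifying *consecutive calendar days*.

    Runs break wherever the calendar gap between successive qualifying
    entries exceeds one day, so a cube with out-of-season days removed
    segments identically to the full cube.
    """
    idx = np.flatnonzero(mask_1d)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(daynum[idx]) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return [(int(s), int(e) + 1) for s, e in zip(starts, ends)]


def detect_warming_events(
    cube: xr.Dataset,
    thresholds: BaselineThreshold,
    strict: bool = True,
) -> list[ExtremeEvent]:
    """Detect extreme winter warming events.

    A day qualifies iff it is a winter day and its tmax exceeds the cell
    threshold (strictly by default).  Maximal runs of consecutive
    qualifying days in one cell form one event; the per-day exceedance is
    tmax − threshold.  Days with missing tmax never qualify, so gaps
    break runs.
    """
    time = pd.DatetimeIndex(cube.time.values)
    labels = winter_season_labels(time)
    winter = labels > 0
    tas = cube["tasmax"].transpose("time", "lat", "lon").values
    thr = thresholds.values.transpose("lat", "lon").values
    with np.errstate(invalid="ignore"):
        exceeds = tas > thr if strict else tas >= thr
    qual = exceeds & winter[:, None, None] & np.isfinite(tas)
    daynum = _day_numbers(time)
    lats = cube.lat.values
    lons = cube.lon.values
    events: list[ExtremeEvent] = []
    for iy in range(len(lats)):
        for ix in range(len(lons)):
            for s, e in _runs_of(qual[:, iy, ix], daynum):
                series = tas[s:e, iy, ix] - thr[iy, ix]
                events.append(
                    ExtremeEvent(
                        lat=float(lats[iy]),
                        lon=float(lons[ix]),
                        event_type="warming",
                        start=time[s],
                        length=e - s,
                        series=series,
                        max_temp=float(tas[s:e, iy, ix].max()),
                        season=int(labels[s]),
                    )
                )
    return events


def detect_ros_events(
    cube: xr.Dataset,
    criteria: RosCriteria = RosCriteria(),
) -> tuple[list[ExtremeEvent], dict]:
    """Detect rain-on-snow events under the four-part criteria.

    Runs of qualifying days are candidates; each is retained iff the mean
    of the ``refreeze_days`` daily maxima following its last day is below
    0 °C.  Candidates too close to the end of the record for the
    refreeze check are discarded and counted in the diagnostics, as are
    candidates failing the refreeze criterion.  The refreeze lookahead
    deliberately may use April days for events ending in late March: the
    criterion tests physical refreeze, not season membership.
    """
    time = pd.DatetimeIndex(cube.time.values)
    labels = winter_season_labels(time)
    winter = labels > 0
    tas = cube["tasmax"].transpose("time", "lat", "lon").values
    rain = cube["pr"].transpose("time", "lat", "lon").values
    swe = cube["swe"].transpose("time", "lat", "lon").values
    c = criteria
    with np.errstate(invalid="ignore"):
        rain_ok = rain > c.rain_mm if c.strict_rain else rain >= c.rain_mm
        snow_ok = swe > c.snow_mm if c.strict_snow else swe >= c.snow_mm
        temp_ok = tas > c.temp_c
    finite = np.isfinite(tas) & np.isfinite(rain) & np.isfinite(swe)
    qual = rain_ok & snow_ok & temp_ok & winter[:, None, None] & finite
    daynum = _day_numbers(time)
    nt = len(time)
    lats, lons = cube.lat.values, cube.lon.values
    events: list[ExtremeEvent] = []
    diagnostics = {"truncated_at_record_end": 0, "failed_refreeze": 0}
    for iy in range(len(lats)):
        for ix in range(len(lons)):
            for s, e in _runs_of(qual[:, iy, ix], daynum):
                if (
                    e + c.refreeze_days > nt
                    or daynum[e + c.refreeze_days - 1] - daynum[e - 1]
                    != c.refreeze_days
                ):
                    # not enough consecutive calendar days after the run
                    diagnostics["truncated_at_record_end"] += 1
                    continue
                follow = tas[e : e + c.refreeze_days, iy, ix]
                if not np.isfinite(follow).all() or follow.mean() >= 0.0:
                    diagnostics["failed_refreeze"] += 1
                    continue
                events.append(
                    ExtremeEvent(
                        lat=float(lats[iy]),
                        lon=float(lons[ix]),
                        event_type="rain-on-snow",
                        start=time[s],
                        length=e - s,
                        series=rain[s:e, iy, ix],
                        max_temp=float(tas[s:e, iy, ix].max()),
                        season=int(labels[s]),
                    )
                )
    return events, diagnostics


def events_to_frame(events: list[ExtremeEvent]) -> pd.DataFrame:
    """Tidy one-row-per-event table (series summarised by its sum)."""
    cols = [
        "cell_lat",
        "cell_lon",
        "season",
        "type",
        "start_date",
        "length",
        "max_temp",
        "intensity",
        "series_total",
    ]
    rows = [
        (
            ev.lat,
            ev.lon,
            ev.season,
            ev.event_type,
            ev.start,
            ev.length,
            ev.max_temp,
            ev.intensity,
            float(ev.series.sum()),
        )
        for ev in events
    ]
    return pd.DataFrame(rows, columns=cols)


def annual_summaries(
    events: list[ExtremeEvent],
    seasons: pd.DataFrame,
    cube: xr.Dataset,
) -> pd.DataFrame:
    """Per cell, season and event type: counts, totals and means.

    ``total`` is the cumulative warming exceedance (°C) for warming
    events — the sum of the daily tmax−threshold differences over all of
    the cell-season's events — and total rain-on-snow rainfall (mm) for
    rain-on-snow events.  Every (cell, season, type) combination present
    in the cube appears, with zeros where no events occurred.
    """
    lats = cube.lat.values
    lons = cube.lon.values
    season_labels = seasons["season"].tolist()
    index = pd.MultiIndex.from_product(
        [lats, lons, season_labels, ["warming", "rain-on-snow"]],
        names=["cell_lat", "cell_lon", "season", "type"],
    )
    out = pd.DataFrame(
        0.0,
        index=index,
        columns=["n_events", "total", "mean_length", "mean_intensity", "max_temp"],
    )
    out["max_temp"] = np.nan
    grouped: dict[tuple, list[ExtremeEvent]] = {}
    for ev in events:
        grouped.setdefault((ev.lat, ev.lon, ev.season, ev.event_type), []).append(ev)
    for key, evs in grouped.items():
        if key not in out.index:
            continue
        out.loc[key, "n_events"] = len(evs)
        out.loc[key, "total"] = float(sum(ev.series.sum() for ev in evs))
        out.loc[key, "mean_length"] = float(np.mean([ev.length for ev in evs]))
        out.loc[key, "mean_intensity"] = float(
            np.mean([ev.intensity for ev in evs])
        )
        out.loc[key, "max_temp"] = float(max(ev.max_temp for ev in evs))
    return out.reset_index()


def emergence_flags(
    summaries: pd.DataFrame,
    period_a: tuple[int, int],
    period_b: tuple[int, int],
    event_type: str = "rain-on-snow",
) -> pd.DataFrame:
    """Classify cells by event presence in two disjoint periods.

    "new" = events in B but none in A (the rain-on-snow emergence
    pattern); "vanished" = the reverse; "both-periods" / "neither"
    otherwise.  Periods are season-label ranges, inclusive.  The returned
    frame carries the per-flag proportions over cells in ``attrs``.
    """
    if not (period_a[1] < period_b[0] or period_b[1] < period_a[0]):
        raise ValueError("periods must be disjoint")
    sub = summaries[summaries["type"] == event_type]

    def _counts(period):
        m = (sub["season"] >= period[0]) & (sub["season"] <= period[1])
        return (
            sub[m].groupby(["cell_lat", "cell_lon"])["n_events"].sum()
        )

    in_a = _counts(period_a)
    in_b = _counts(period_b)
    cells = in_a.index.union(in_b.index)
    in_a = in_a.reindex(cells, fill_value=0)
    in_b = in_b.reindex(cells, fill_value=0)
    flag = np.select(
        [
            (in_a == 0) & (in_b > 0),
            (in_a > 0) & (in_b == 0),
            (in_a > 0) & (in_b > 0),
        ],
        ["new", "vanished", "both-periods"],
        default="neither",
    )
    out = pd.DataFrame(
        {"events_a": in_a.values, "events_b": in_b.values, "flag": flag},
        index=cells,
    ).reset_index()
    n = len(out)
    out.attrs["proportions"] = {
        k: float((out["flag"] == k).sum()) / n if n else 0.0
        for k in ("new", "vanished", "both-periods", "neither")
    }
    return out
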