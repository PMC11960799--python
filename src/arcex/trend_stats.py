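"""Temporal trends, period comparisons and spatial autocorrelation.

Trends in event characteristics are estimated with the Theil–Sen slope
(median of all pairwise slopes), with significance from the Mann–Kendall
test — the standard nonparametric companion.  Period contrasts use
paired t-tests with grid cells as the pairing unit.  Spatial
autocorrelation of the gridded change fields is assessed with a Mantel
permutation test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .climate_events import winter_season_labels

__all__ = [
    "RegionBox",
    "REGIONS",
    "TrendResult",
    "PeriodComparison",
    "MantelResult",
    "theil_sen",
    "paired_period_test",
    "mantel_test",
    "precip_trends",
]


@dataclass(frozen=True)
class RegionBox:
    """Axis-aligned lat/lon box used as an area of special interest."""

    name: str
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def contains(self, lat, lon):
        return (
            (lat >= self.lat_min)
            & (lat <= self.lat_max)
            & (lon >= self.lon_min)
            & (lon <= self.lon_max)
        )

    def subset(self, cube: xr.Dataset) -> xr.Dataset:
        return cube.sel(
            lat=slice(self.lat_min, self.lat_max),
            lon=slice(self.lon_min, self.lon_max),
        )


#: Approximate boxes for the four areas of special interest.
REGIONS = {
    "northern_alaska": RegionBox("northern_alaska", 66.0, 72.0, -166.0, -140.0),
    "northern_fennoscandia": RegionBox(
        "northern_fennoscandia", 68.0, 71.5, 18.0, 31.0
    ),
    "svalbard": RegionBox("svalbard", 76.0, 81.0, 10.0, 34.0),
    "yamal": RegionBox("yamal", 66.0, 73.0, 66.0, 82.0),
}


@dataclass
class TrendResult:
    variable: str
    region: str
    slope: float  # variable units per season
    intercept: float
    p_value: float
    n_seasons: int
    method: str


@dataclass
class PeriodComparison:
    region: str
    variable: str
    period_a: tuple[int, int]
    period_b: tuple[int, int]
    mean_a: float
    mean_b: float
    mean_difference: float  # B − A, variable units
    t_statistic: float
    p_value: float
    n_cells: int


@dataclass
class MantelResult:
    r: float
    p_value: float
    permutations: int


def theil_sen(
    x: np.ndarray,
    y: np.ndarray,
    variable: str = "y",
    region: str = "all",
    method: str = "theil-sen",
) -> TrendResult:
    """Robust trend of ``y`` against ``x`` (typically season labels).

    Theil–Sen slope = median of all pairwise slopes (y_j − y_i)/(x_j −
    x_i) over i < j with distinct x; intercept = median(y − slope·x).
    The p-value is from the Mann–Kendall test (Kendall's tau of y
    against x, tie-corrected).  ``method="ols"`` switches to ordinary
    least squares with its t-test p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 finite observations")
    if np.ptp(x) == 0:
        raise ValueError("all x values identical; slope undefined")
    if method == "ols":
        fit = stats.linregress(x, y)
        return TrendResult(
            variable, region, float(fit.slope), float(fit.intercept),
            float(fit.pvalue), len(x), "ols",
        )
    slope = float(stats.theilslopes(y, x).slope)
    intercept = float(np.median(y - slope * x))
    if np.ptp(y) == 0:
        p = 1.0  # constant series: no trend evidence
    else:
        p = float(stats.kendalltau(x, y).pvalue)
    return TrendResult(variable, region, slope, intercept, p, len(x), "theil-sen")


def paired_period_test(
    summaries: pd.DataFrame,
    period_a: tuple[int, int],
    period_b: tuple[int, int],
    variable: str = "total",
    event_type: str | None = None,
    region: RegionBox | None = None,
) -> PeriodComparison:
    """Paired t-test of per-cell period means between two periods.

    Each grid cell contributes one pair: its mean of ``variable`` over
    the seasons of period A and of period B (cells must have data in
    both).  The reported mean difference is B − A in variable units.
    """
    sub = summaries
    if event_type is not None:
        sub = sub[sub["type"] == event_type]
    if region is not None:
        sub = sub[region.contains(sub["cell_lat"], sub["cell_lon"])]

    def _cell_means(period):
        m = (sub["season"] >= period[0]) & (sub["season"] <= period[1])
        return sub[m].groupby(["cell_lat", "cell_lon"])[variable].mean()

    a = _cell_means(period_a)
    b = _cell_means(period_b)
    cells = a.index.intersection(b.index)
    a, b = a.loc[cells].dropna(), b.loc[cells].dropna()
    cells = a.index.intersection(b.index)
    a, b = a.loc[cells], b.loc[cells]
    if len(cells) < 2:
        raise ValueError("need at least 2 cells with data in both periods")
    diff = b.values - a.values
    if np.allclose(diff, diff[0]) and np.isclose(diff[0], 0.0):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(b.values, a.values)
    return PeriodComparison(
        region=region.name if region else "all",
        variable=variable,
        period_a=period_a,
        period_b=period_b,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        mean_difference=float(diff.mean()),
        t_statistic=float(t),
        p_value=float(p),
        n_cells=len(cells),
    )


def _mantel_r(d1: np.ndarray, d2: np.ndarray, iu) -> float:
    return float(stats.pearsonr(d1[iu], d2[iu]).statistic)


def mantel_test(
    dist1: np.ndarray,
    dist2: np.ndarray,
    permutations: int = 999,
    seed: int | None = 0,
    alternative: str = "greater",
    exhaustive: bool = False,
) -> MantelResult:
    """Mantel permutation test of correlation between two distance matrices.

    r is the Pearson correlation of the upper-triangle entries; the
    p-value is the one-sided (``greater``) permutation tail proportion
    over simultaneous row/column permutations of the second matrix, with
    the +1 correction so p ≥ 1/(B+1).  ``exhaustive=True`` enumerates all
    n! permutations (small n only), in which case the p-value is the
    exact tail proportion without correction.
    """
    d1 = np.asarray(dist1, dtype=float)
    d2 = np.asarray(dist2, dtype=float)
    n = d1.shape[0]
    for d in (d1, d2):
        if d.shape != (n, n):
            raise ValueError("matrices must be square and of equal order")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrices must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrices must have zero diagonal")
    iu = np.triu_indices(n, k=1)
    if np.ptp(d1[iu]) == 0 or np.ptp(d2[iu]) == 0:
        raise ValueError("constant distance matrix: correlation undefined")
    r_obs = _mantel_r(d1, d2, iu)

    def _tail(r_perm: float) -> bool:
        if alternative == "greater":
            return r_perm >= r_obs
        if alternative == "less":
            return r_perm <= r_obs
        return abs(r_perm) >= abs(r_obs)

    if exhaustive:
        count = total = 0
        for perm in itertools.permutations(range(n)):
            p = np.asarray(perm)
            count += _tail(_mantel_r(d1, d2[np.ix_(p, p)], iu))
            total += 1
        return MantelResult(r=r_obs, p_value=count / total, permutations=total)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        p = rng.permutation(n)
        count += _tail(_mantel_r(d1, d2[np.ix_(p, p)], iu))
    p_value = (count + 1) / (permutations + 1)
    return MantelResult(r=r_obs, p_value=p_value, permutations=permutations)


def precip_trends(
    cube: xr.Dataset,
    region: RegionBox | None = None,
    method: str = "theil-sen",
    complete_only: bool = True,
) -> tuple[dict[str, TrendResult], dict]:
    """Trends in winter rainfall, snowfall and the rain:snow ratio.

    For each winter season the per-cell winter totals of ``pr`` and
    ``prsn`` are averaged over the region's cells ("average total winter
    rainfall/snowfall"); the ratio series is their quotient.  Seasons
    whose snowfall total is 0 are dropped from the ratio trend, with the
    dropped count reported in the diagnostics.
    """
    sub = region.subset(cube) if region is not None else cube
    time = pd.DatetimeIndex(sub.time.values)
    labels = winter_season_labels(time)
    season_ids = np.unique(labels[labels > 0])
    if complete_only:
        from .climate_events import winter_days

        wd = winter_days(sub)
        season_ids = wd[wd["complete"]]["season"].to_numpy()
    if len(season_ids) < 3:
        raise ValueError("region must span at least 3 complete winters")
    rain_tot, snow_tot = [], []
    for sid in season_ids:
        sel = labels == sid
        rain_tot.append(float(sub["pr"].isel(time=sel).sum("time").mean()))
        snow_tot.append(float(sub["prsn"].isel(time=sel).sum("time").mean()))
    rain_tot = np.asarray(rain_tot)
    snow_tot = np.asarray(snow_tot)
    x = season_ids.astype(float)
    name = region.name if region else "all"
    results = {
        "winter_rainfall": theil_sen(x, rain_tot, "winter_rainfall", name, method),
        "winter_snowfall": theil_sen(x, snow_tot, "winter_snowfall", name, method),
    }
    ok = snow_tot > 0
    diagnostics = {"ratio_seasons_dropped": int((~ok).sum())}
    if ok.sum() >= 3:
        results["rain_snow_ratio"] = theil_sen(
            x[ok], rain_tot[ok] / snow_tot[ok], "rain_snow_ratio", name, method
        )
    return results, diagnostics
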