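"""Standardized mean differences with heteroscedastic variances (SMDH).

The effect size used throughout is the standardized mean difference that
allows the two groups' population variances to differ, a Hedges-type d
standardized by s' = sqrt((s_c² + s_r²)/2):

    d  = J(m) · (mean_r − mean_c) / s',           m = n_c + n_r − 2
    J(m) = Γ(m/2) / ( sqrt(m/2) · Γ((m−1)/2) )    (small-sample bias factor)
    var(d) = d²·(s_c⁴/(n_c−1) + s_r⁴/(n_r−1)) / (8 s'⁴)
             + (s_c²/(n_c−1) + s_r²/(n_r−1)) / s'²

This module also harmonizes the fitness direction of effects (an
increase in, say, winter mortality is a fitness loss, so such effects
are sign-flipped), derives control/response groups from observational
annual series using a regional percentile threshold, and removes gross
outliers by standardized residual under a random-effects overall model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "GroupSummary",
    "DEFAULT_DIRECTION_FLAGS",
    "smdh",
    "smdh_table",
    "harmonize_direction",
    "derive_groups_from_series",
    "remove_outliers",
]


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one group (n years or replicates)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("group n must be >= 2")
        if self.sd < 0:
            raise ValueError("SD must be >= 0")


#: response variable name -> direction flag (+1 keeps the sign, −1 flips
#: it because an *increase* harms fitness).  Editable / extendable.
DEFAULT_DIRECTION_FLAGS = {
    "mortality": -1,
    "winter_mortality": -1,
    "shoot_mortality": -1,
    "dig_time": -1,
    "abundance": 1,
    "flower_abundance": 1,
    "psii_activity": 1,
    "photosynthetic_rate": 1,
    "body_mass": 1,
    "shoot_growth": 1,
    "calf_at_heel": 1,
    "reproductive_success": 1,
}


def _bias_correction(m: float) -> float:
    """Exact small-sample factor J(m); ~ 1 − 3/(4m − 1)."""
    if m <= 1:
        raise ValueError("need n_c + n_r - 2 > 1 for the bias correction")
    return math.exp(
        special.gammaln(m / 2.0)
        - math.log(math.sqrt(m / 2.0))
        - special.gammaln((m - 1.0) / 2.0)
    )


def smdh(control: GroupSummary, response: GroupSummary) -> tuple[float, float]:
    """SMDH point estimate (response − control) and its sampling variance."""
    s2 = (control.sd**2 + response.sd**2) / 2.0
    if s2 == 0:
        raise ValueError("both group SDs are zero: effect undefined")
    sp = math.sqrt(s2)
    m = control.n + response.n - 2
    d = _bias_correction(m) * (response.mean - control.mean) / sp
    var = (
        d**2
        * (control.sd**4 / (control.n - 1) + response.sd**4 / (response.n - 1))
        / (8.0 * s2**2)
        + (control.sd**2 / (control.n - 1) + response.sd**2 / (response.n - 1))
        / s2
    )
    return d, var


def smdh_table(table: pd.DataFrame) -> pd.DataFrame:
    """Vectorized SMDH over a group-summary table.

    Expects columns ``n_control, mean_control, sd_control, n_response,
    mean_response, sd_response``; returns a copy with ``smdh`` and
    ``variance`` columns appended.
    """
    t = table.copy()
    nc = t["n_control"].to_numpy(dtype=float)
    nr = t["n_response"].to_numpy(dtype=float)
    if (nc < 2).any() or (nr < 2).any():
        raise ValueError("all group sample sizes must be >= 2")
    sc = t["sd_control"].to_numpy(dtype=float)
    sr = t["sd_response"].to_numpy(dtype=float)
    s2 = (sc**2 + sr**2) / 2.0
    if (s2 == 0).any():
        raise ValueError("records with both SDs zero: effect undefined")
    m = nc + nr - 2
    j = np.exp(
        special.gammaln(m / 2.0)
        - np.log(np.sqrt(m / 2.0))
        - special.gammaln((m - 1.0) / 2.0)
    )
    d = j * (t["mean_response"].to_numpy() - t["mean_control"].to_numpy()) / np.sqrt(s2)
    var = (
        d**2 * (sc**4 / (nc - 1) + sr**4 / (nr - 1)) / (8.0 * s2**2)
        + (sc**2 / (nc - 1) + sr**2 / (nr - 1)) / s2
    )
    t["smdh"] = d
    t["variance"] = var
    return t


def harmonize_direction(
    table: pd.DataFrame,
    flags: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align effect signs so that negative always means a fitness loss.

    Requires an ``smdh`` column and either a ``direction`` column of ±1
    flags or a ``response_variable`` column resolved through ``flags``.
    Records whose variable has no known flag are quarantined (returned
    separately), never silently passed through.  Re-applying to an
    already-harmonized table raises; the marker is a real column so the
    guard survives CSV round trips.
    """
    if table.attrs.get("direction_applied") or (
        "direction_applied" in table.columns
        and bool(table["direction_applied"].any())
    ):
        raise ValueError("direction flags already applied to this table")
    t = table.copy()
    if "direction" in t.columns:
        dir_flags = t["direction"].to_numpy()
        unknown = ~np.isin(dir_flags, (1, -1))
    else:
        lookup = DEFAULT_DIRECTION_FLAGS if flags is None else flags
        dir_flags = np.array(
            [lookup.get(v, 0) for v in t["response_variable"]], dtype=int
        )
        unknown = dir_flags == 0
    quarantined = t[unknown].copy()
    t = t[~unknown].copy()
    t["smdh"] = t["smdh"].to_numpy() * dir_flags[~unknown]
    t["direction"] = dir_flags[~unknown]
    t["direction_applied"] = True
    t.attrs["direction_applied"] = True
    return t, quarantined


def derive_groups_from_series(
    values: pd.Series,
    extreme_years: list[int] | None = None,
    env_series: pd.Series | None = None,
    threshold: float | None = None,
) -> tuple[GroupSummary, GroupSummary, dict]:
    """Split an annual observational series into control/response groups.

    ``values`` is the fitness-related variable indexed by year.  If
    ``extreme_years`` is given (the study states them), those years are
    the response group and the year immediately preceding each extreme
    year is its control.  Otherwise a year is classed extreme when
    ``env_series`` (the study's environmental variable, indexed by year)
    exceeds ``threshold`` — typically the regional baseline 99th
    percentile obtained from :func:`regional_percentile_threshold`.  An
    extreme year is kept only if the preceding year is available to serve
    as its control and is not itself extreme; a year may serve as control
    for at most one extreme year (conflicts are logged and dropped).

    Returns ``(control, response, diagnostics)`` with group means/SDs and
    n = number of years per role.
    """
    values = values.dropna()
    years = set(values.index.astype(int))
    if extreme_years is None:
        if env_series is None or threshold is None:
            raise ValueError(
                "either extreme_years or (env_series, threshold) is required"
            )
        env_series = env_series.dropna()
        extreme_years = sorted(
            int(y) for y, v in env_series.items() if v > threshold
        )
    extreme_set = set(int(y) for y in extreme_years)
    diagnostics = {"dropped_no_control": [], "dropped_control_conflict": []}
    controls, responses = [], []
    used_controls: set[int] = set()
    for y in sorted(extreme_set):
        if y not in years:
            continue
        prev = y - 1
        if prev not in years or prev in extreme_set:
            diagnostics["dropped_no_control"].append(y)
            continue
        if prev in used_controls:
            diagnostics["dropped_control_conflict"].append(y)
            continue
        used_controls.add(prev)
        responses.append(float(values.loc[y]))
        controls.append(float(values.loc[prev]))
    if len(controls) < 2 or len(responses) < 2:
        raise ValueError(
            "fewer than 2 assignable years per role; no record can be derived"
        )
    control = GroupSummary(
        n=len(controls), mean=float(np.mean(controls)), sd=float(np.std(controls, ddof=1))
    )
    response = GroupSummary(
        n=len(responses),
        mean=float(np.mean(responses)),
        sd=float(np.std(responses, ddof=1)),
    )
    return control, response, diagnostics


def regional_percentile_threshold(
    cube,
    site_lat: float,
    site_lon: float,
    variable: str = "tasmax",
    baseline: tuple[int, int] = (1950, 1980),
    box_deg: float = 5.0,
    percentile: float = 99.0,
) -> float:
    """Baseline percentile of a variable in a box around a study site.

    Pools all winter-day values of ``variable`` in the ``box_deg`` ×
    ``box_deg`` region centred on the site over the baseline winters and
    returns the requested percentile (linear interpolation).
    """
    from .climate_events import winter_season_labels

    half = box_deg / 2.0
    sub = cube.sel(
        lat=slice(site_lat - half, site_lat + half),
        lon=slice(site_lon - half, site_lon + half),
    )
    if sub.sizes["lat"] == 0 or sub.sizes["lon"] == 0:
        raise ValueError("site box contains no grid cells")
    labels = winter_season_labels(pd.DatetimeIndex(sub.time.values))
    mask = (labels >= baseline[0] + 1) & (labels <= baseline[1])
    vals = sub[variable].isel(time=mask).values.ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no baseline winter data in the site box")
    return float(np.percentile(vals, percentile, method="linear"))


def _reml_tau2_overall(y: np.ndarray, v: np.ndarray) -> float:
    """REML between-effect variance of the intercept-only model."""

    def neg_restricted_ll(log_tau2: float) -> float:
        tau2 = math.exp(log_tau2)
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        return 0.5 * (
            np.sum(np.log(v + tau2))
            + math.log(np.sum(w))
            + np.sum(w * (y - mu) ** 2)
        )

    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(-30.0, 10.0), method="bounded",
        options={"xatol": 1e-10},
    )
    tau2 = math.exp(res.x)
    return 0.0 if tau2 < 1e-9 else tau2


def remove_outliers(
    table: pd.DataFrame,
    threshold: float = 3.0,
    method: str = "random",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop effects whose |standardized residual| exceeds ``threshold``.

    Residuals are taken from an overall-mean meta-analytic model in a
    single pass (no refit-and-repeat): with ``method="random"`` the
    residual is (y − μ̂)/sqrt(v_i + τ̂²) with τ̂² the REML between-effect
    variance; ``method="common"`` sets τ̂² = 0.  Requires ``smdh`` and
    ``variance`` columns.  Returns ``(kept, removed)``.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 records to assess outliers")
    y = table["smdh"].to_numpy(dtype=float)
    v = table["variance"].to_numpy(dtype=float)
    if (v <= 0).any():
        raise ValueError("sampling variances must be > 0")
    tau2 = _reml_tau2_overall(y, v) if method == "random" else 0.0
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    resid = (y - mu) / np.sqrt(v + tau2)
    keep = np.abs(resid) <= threshold
    kept = table[keep].copy()
    removed = table[~keep].copy()
    removed["standardized_residual"] = resid[~keep]
    kept.attrs.update(table.attrs)
    kept.attrs["outliers_removed"] = int((~keep).sum())
    return kept, removed
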