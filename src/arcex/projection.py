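"""Spatial projection of pooled biotic effects onto climate change maps.

Multiplies the per-cell change in an extreme-event metric between two
periods (cumulative winter warming exceedance in °C, or total
rain-on-snow in mm) by the corresponding statistically significant
pooled effect size, yielding a map of the *relative magnitude* of
projected biotic impact.  Projection is refused outright for effects
whose confidence interval includes zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .trend_stats import RegionBox

__all__ = ["PooledEffect", "NonSignificantEffectError", "project", "coverage_gap"]


@dataclass(frozen=True)
class PooledEffect:
    """A pooled effect size (SMD scale) with its 95% CI."""

    value: float
    ci_low: float
    ci_high: float
    event_type: str = ""

    @property
    def significant(self) -> bool:
        return self.ci_low > 0.0 or self.ci_high < 0.0


class NonSignificantEffectError(ValueError):
    """Raised when projecting a pooled effect whose CI spans zero."""


def project(change: xr.DataArray, effect: PooledEffect) -> xr.DataArray:
    """Per-cell projected impact = change x pooled effect size.

    ``change`` is the period difference of an event metric per cell (its
    units are kept in metadata); the output is unitless-SMD x metric
    units, to be read as relative magnitude only.  Cells with missing
    change stay missing.
    """
    if not effect.significant:
        raise NonSignificantEffectError(
            f"pooled effect {effect.value:.3f} "
            f"[{effect.ci_low:.3f}, {effect.ci_high:.3f}] includes zero; "
            "projection refused"
        )
    impact = change * effect.value
    impact = impact.rename("projected_impact")
    impact.attrs.update(
        {
            "effect_value": effect.value,
            "effect_ci": (effect.ci_low, effect.ci_high),
            "event_type": effect.event_type,
            "change_units": change.attrs.get("units", ""),
            "interpretation": "relative magnitude only, not a measurement",
        }
    )
    return impact


def coverage_gap(
    impact: xr.DataArray,
    study_locations: pd.DataFrame,
    regions: dict[str, RegionBox],
) -> pd.DataFrame:
    """Rank regions by projected impact against local research effort.

    ``study_locations`` needs ``lat``/``lon`` columns (one row per
    study).  For every region box the mean absolute projected impact
    over its cells and the number of studies inside are reported, sorted
    by impact descending — the top rows with zero studies are the
    coverage gaps.
    """
    rows = []
    for name, box in regions.items():
        sub = impact.sel(
            lat=slice(box.lat_min, box.lat_max),
            lon=slice(box.lon_min, box.lon_max),
        )
        vals = sub.values
        mean_abs = float(np.nanmean(np.abs(vals))) if vals.size else np.nan
        if len(study_locations):
            inside = box.contains(
                study_locations["lat"].to_numpy(),
                study_locations["lon"].to_numpy(),
            )
            n_studies = int(np.sum(inside))
        else:
            n_studies = 0
        rows.append(
            {"region": name, "mean_abs_impact": mean_abs, "n_studies": n_studies}
        )
    out = pd.DataFrame(rows).sort_values(
        "mean_abs_impact", ascending=False, ignore_index=True
    )
    return out
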