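import numpy as np
import pandas as pd
import pytest
import xarray as xr


def make_cube(
    tasmax,
    pr=None,
    swe=None,
    prsn=None,
    start="1990-12-01",
    lats=(70.5,),
    lons=(20.5,),
):
    """One-variable-at-a-time cube builder for hand-made scenarios.

    ``tasmax`` may be 1-D (single cell) or (time, lat, lon).
    """
    tasmax = np.asarray(tasmax, dtype=float)
    if tasmax.ndim == 1:
        tasmax = tasmax[:, None, None]
    nt = tasmax.shape[0]
    time = pd.date_range(start, periods=nt, freq="D")

    def _field(x, fill):
        if x is None:
            return np.full_like(tasmax, fill)
        x = np.asarray(x, dtype=float)
        return x[:, None, None] if x.ndim == 1 else x

    ds = xr.Dataset(
        {
            "tasmax": (("time", "lat", "lon"), tasmax),
            "pr": (("time", "lat", "lon"), _field(pr, 0.0)),
            "prsn": (("time", "lat", "lon"), _field(prsn, 0.0)),
            "swe": (("time", "lat", "lon"), _field(swe, 0.0)),
        },
        coords={"time": time, "lat": list(lats), "lon": list(lons)},
    )
    return ds


def constant_threshold(cube, value):
    from arcex.climate_events import BaselineThreshold

    da = xr.DataArray(
        np.full((cube.sizes["lat"], cube.sizes["lon"]), float(value)),
        coords={"lat": cube.lat, "lon": cube.lon},
        dims=("lat", "lon"),
    )
    return BaselineThreshold(values=da, period=(1950, 1980), percentile=99.0)


@pytest.fixture(scope="session")
def sim_cube():
    """A 15-year 4x4 simulated cube shared by read-only tests."""
    from arcex.synthetic_data import ClimateSimConfig, simulate_climate

    cfg = ClimateSimConfig(year_start=1950, year_end=1964, seed=101)
    return simulate_climate(cfg)


@pytest.fixture(scope="session")
def meta_table():
    """A simulated effect-size table run through the SMDH pipeline."""
    from arcex import effect_sizes as es
    from arcex.synthetic_data import MetaSimConfig, simulate_effect_sizes

    cfg = MetaSimConfig(seed=11, n_studies=12, effects_per_study=5, n_species=15)
    table, newick, truth = simulate_effect_sizes(cfg)
    table = es.smdh_table(table)
    table, _ = es.harmonize_direction(table)
    return table, newick, truth
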