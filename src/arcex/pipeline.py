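"""End-to-end pipeline driver: simulate/read -> detect -> trends -> meta -> project.

A :class:`PipelineConfig` (loadable from YAML) fixes the periods,
thresholds, regions and seeds; :func:`run_pipeline` executes every stage,
writes each stage's artifact under the output directory and returns a
manifest.  All outputs carry the config hash and seed, and a rerun with
the same config reproduces them exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate_events, effect_sizes, io, meta_model, projection, synthetic_data, trend_stats

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    output_dir: str = "arcex_output"
    climate_path: str | None = None  # None -> simulate
    effects_path: str | None = None  # None -> simulate
    tree_path: str | None = None
    baseline_period: tuple[int, int] = (1950, 1980)
    modern_period: tuple[int, int] = (1990, 2020)
    percentile: float = 99.0
    ros: climate_events.RosCriteria = field(
        default_factory=climate_events.RosCriteria
    )
    regions: dict = field(default_factory=lambda: dict(trend_stats.REGIONS))
    # the demo simulation spans the full baseline..modern study window
    climate_sim: synthetic_data.ClimateSimConfig = field(
        default_factory=lambda: synthetic_data.ClimateSimConfig(
            year_start=1950, year_end=2020
        )
    )
    meta_sim: synthetic_data.MetaSimConfig = field(
        default_factory=synthetic_data.MetaSimConfig
    )
    seed: int = 0

    def validate(self, cube=None) -> None:
        a, b = self.baseline_period, self.modern_period
        if not (a[1] < b[0] or b[1] < a[0]):
            raise ValueError("baseline and modern periods must be disjoint")
        if cube is not None:
            years = pd.DatetimeIndex(cube.time.values).year
            lo, hi = int(years.min()), int(years.max())
            for p in (a, b):
                if p[0] < lo or p[1] > hi + 1:
                    raise ValueError(
                        f"period {p} lies outside the cube span {lo}-{hi}"
                    )

    def hash(self) -> str:
        payload = asdict(self)
        payload.pop("output_dir")  # where results land is not part of *what* ran
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig()
    for key, val in raw.items():
        if key == "ros":
            cfg.ros = climate_events.RosCriteria(**val)
        elif key == "climate_sim":
            cfg.climate_sim = synthetic_data.ClimateSimConfig(**val)
        elif key == "meta_sim":
            cfg.meta_sim = synthetic_data.MetaSimConfig(**val)
        elif key == "regions":
            cfg.regions = {
                name: trend_stats.RegionBox(name, **box) for name, box in val.items()
            }
        elif key in ("baseline_period", "modern_period"):
            setattr(cfg, key, tuple(val))
        elif hasattr(cfg, key):
            setattr(cfg, key, val)
        else:
            raise ValueError(f"unknown config key {key!r}")
    return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; return a manifest of written artifacts."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.hash(), "seed": config.seed, "stages": {}}

    # wall-clock per stage lives outside the stage records so that rerun
    # manifests stay comparable on their scientific content
    manifest["timings_seconds"] = {}
    t_last = time.perf_counter()

    def _stage(name):
        nonlocal t_last
        now = time.perf_counter()
        if manifest["stages"]:
            prev = next(reversed(manifest["stages"]))
            manifest["timings_seconds"][prev] = round(now - t_last, 3)
        t_last = now
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    try:
        # --- climate input -------------------------------------------------
        st = _stage("climate")
        if config.climate_path:
            cube = io.read_climate(config.climate_path)
            st["source"] = str(config.climate_path)
        else:
            cube = synthetic_data.simulate_climate(config.climate_sim)
            st["source"] = "simulated"
            st["path"] = str(io.write_climate(cube, out / "climate.nc"))
        config.validate(cube)

        # --- detection -----------------------------------------------------
        st = _stage("detect")
        thr = climate_events.compute_threshold(
            cube, config.baseline_period, config.percentile
        )
        warming = climate_events.detect_warming_events(cube, thr)
        ros, ros_diag = climate_events.detect_ros_events(cube, config.ros)
        seasons = climate_events.winter_days(cube)
        summaries = climate_events.annual_summaries(warming + ros, seasons, cube)
        st["n_warming_events"] = len(warming)
        st["n_ros_events"] = len(ros)
        st["ros_diagnostics"] = ros_diag
        st["events_path"] = str(io.write_events(warming + ros, out / "events.csv"))
        summaries.to_csv(out / "summaries.csv", index=False)
        st["summaries_path"] = str(out / "summaries.csv")

        # --- trends and period comparisons ----------------------------------
        st = _stage("trends")
        trend_rows = []
        complete = seasons[seasons["complete"]]["season"]
        for region_name, box in {**{"all": None}, **config.regions}.items():
            sub = summaries
            if box is not None:
                sub = sub[box.contains(sub["cell_lat"], sub["cell_lon"])]
            if not len(sub):
                continue
            for ev_type in ("warming", "rain-on-snow"):
                per_season = (
                    sub[(sub["type"] == ev_type) & sub["season"].isin(complete)]
                    .groupby("season")[["total", "n_events", "mean_length", "mean_intensity"]]
                    .mean()
                )
                if len(per_season) < 3:
                    continue
                for var in per_season.columns:
                    try:
                        tr = trend_stats.theil_sen(
                            per_season.index.to_numpy(float),
                            per_season[var].to_numpy(float),
                            variable=f"{ev_type}:{var}",
                            region=region_name,
                        )
                    except ValueError:
                        continue
                    trend_rows.append(
                        {
                            "region": tr.region,
                            "variable": tr.variable,
                            "slope": tr.slope,
                            "p": tr.p_value,
                            "n": tr.n_seasons,
                        }
                    )
        trends = pd.DataFrame(trend_rows)
        trends.to_csv(out / "trends.csv", index=False)
        st["path"] = str(out / "trends.csv")

        comparisons = {}
        for ev_type, var in (("warming", "total"), ("rain-on-snow", "total")):
            try:
                comparisons[ev_type] = trend_stats.paired_period_test(
                    summaries,
                    config.baseline_period,
                    config.modern_period,
                    variable=var,
                    event_type=ev_type,
                )
            except ValueError as exc:
                st[f"comparison_skipped_{ev_type}"] = str(exc)
        st["period_comparisons"] = {
            k: asdict(v) for k, v in comparisons.items()
        }

        # --- effect sizes ----------------------------------------------------
        st = _stage("effects")
        if config.effects_path:
            table = pd.read_csv(config.effects_path)
            newick = Path(config.tree_path).read_text() if config.tree_path else None
            st["source"] = str(config.effects_path)
        else:
            table, newick, _truth = synthetic_data.simulate_effect_sizes(
                config.meta_sim
            )
            st["source"] = "simulated"
        table = effect_sizes.smdh_table(table)
        table, quarantined = effect_sizes.harmonize_direction(table)
        table, removed = effect_sizes.remove_outliers(table)
        table.to_csv(out / "effect_sizes.csv", index=False)
        st["path"] = str(out / "effect_sizes.csv")
        st["n_effects"] = len(table)
        st["n_quarantined"] = len(quarantined)
        st["n_outliers_removed"] = len(removed)
        if newick:
            (out / "tree.nwk").write_text(newick)
            st["tree_path"] = str(out / "tree.nwk")

        # --- meta-analysis ---------------------------------------------------
        st = _stage("meta")
        species = sorted(table["species"].unique())
        A = meta_model.tree_to_correlation(newick, species, seed=config.seed)
        null_fit = meta_model.fit(table, A=A, seed=config.seed)
        event_fit = meta_model.moderator_test(
            table, "event_type", A=A, seed=config.seed
        )
        st["null_path"] = str(io.write_fit(null_fit, out / "fit_null.json"))
        st["event_path"] = str(io.write_fit(event_fit, out / "fit_event_type.json"))
        st["overall_effect"] = null_fit.estimate
        st["i2_total"] = null_fit.i2_total

        # --- projection ------------------------------------------------------
        st = _stage("projection")
        pooled = {}
        for _, row in event_fit.coefficients.iterrows():
            ev = row["name"].split(":", 1)[1]
            pooled[ev] = projection.PooledEffect(
                row["estimate"], row["ci_low"], row["ci_high"], event_type=ev
            )
        for ev_type in ("warming", "rain-on-snow"):
            if ev_type not in pooled:
                continue
            change = _change_map(
                summaries, ev_type, config.baseline_period, config.modern_period, cube
            )
            try:
                impact = projection.project(change, pooled[ev_type])
            except projection.NonSignificantEffectError as exc:
                st[f"refused_{ev_type}"] = str(exc)
                continue
            fname = out / f"impact_{ev_type.replace('-', '_')}.nc"
            impact.to_netcdf(fname)
            st[f"impact_path_{ev_type}"] = str(fname)
        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = list(manifest["stages"])[-1] if manifest["stages"] else None
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _change_map(summaries, event_type, period_a, period_b, cube):
    """Per-cell (modern mean − baseline mean) of the event metric."""
    sub = summaries[summaries["type"] == event_type]

    def _mean(period):
        m = (sub["season"] >= period[0]) & (sub["season"] <= period[1])
        return sub[m].groupby(["cell_lat", "cell_lon"])["total"].mean()

    diff = (_mean(period_b) - _mean(period_a)).reset_index()
    pivot = diff.pivot(index="cell_lat", columns="cell_lon", values="total")
    import xarray as xr

    da = xr.DataArray(
        pivot.values,
        coords={"lat": pivot.index.values, "lon": pivot.columns.values},
        dims=("lat", "lon"),
        name="change",
        attrs={"units": "degC" if event_type == "warming" else "mm"},
    )
    return da
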