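"""End-to-end orchestration: simulate -> process -> model -> report.

``run`` executes the whole analysis as a fixed sequence of stages, writing
every intermediate table to a stage-numbered subdirectory plus a JSON
manifest of per-stage row counts, so a season-long run can be audited
filter by filter.  Identical configuration and seed give identical outputs.

Stages
------
1. synthetic inputs (hourly weather, hourly activity, GPS fixes)
2. solar table (sunrise/sunset, covering the study window plus one day)
3. activity summaries (hourly on biological days; daily means)
4. weather aggregation and model-table joins
5. heatwave detection and the heatwave model table
6. GPS filtering and daily movement metrics
7. model fits and effect contrasts
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accel, heatwave, models, movement, simulate, solartime, weather

__all__ = ["RunConfig", "load_config", "run"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run."""

    seed: int = 1
    n_animals: int = 3
    start: str = "2019-06-01"
    end: str = "2019-08-31"
    site_lat: float = 50.0
    site_lon: float = 14.8
    tz_offset: float = 2.0
    heatwave_threshold_c: float = 24.0
    heatwave_min_hours: int = 23
    coverage_threshold: float = 0.8
    min_hours_per_day: int = 20
    gap_cap_min: float = 120.0
    basis_k: int = 8
    basis_k_tensor: int = 5
    fit_models: bool = True
    # day-level heatwave injections for the synthetic weather: list of
    # [start_day_index, length_days, boost_c]
    heatwave_injection: list = field(default_factory=lambda: [[20, 3, 7.0], [55, 2, 7.0]])

    def __post_init__(self) -> None:
        y0 = pd.Timestamp(self.start).year
        y1 = pd.Timestamp(self.end).year
        if y0 != y1:
            raise ValueError("study window must lie within one calendar year")

    def sim_config(self) -> simulate.SimConfig:
        tp = simulate.TempParams(heatwave_injection=[tuple(x) for x in self.heatwave_injection])
        return simulate.SimConfig(
            seed=self.seed,
            n_animals=self.n_animals,
            start=self.start,
            end=self.end,
            site_lat=self.site_lat,
            site_lon=self.site_lon,
            tz_offset=self.tz_offset,
            temp=tp,
        )


def load_config(path) -> RunConfig:
    """Load a RunConfig from a flat key-value YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _write(df: pd.DataFrame, path: Path) -> int:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return len(df)


def run(config: RunConfig, out_dir) -> dict:
    """Execute all stages; return the manifest (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": dataclasses.asdict(config), "stages": {}}

    def stage(name, counts):
        manifest["stages"][name] = counts
        log.info("stage %s: %s", name, counts)

    try:
        # 1 -- synthetic inputs
        sim = config.sim_config()
        wx = simulate.gen_weather(sim)
        act = simulate.gen_hourly_vedba(sim, wx)
        gps = simulate.gen_gps(sim)
        stage(
            "1_simulate",
            {
                "weather_hours": _write(wx, out / "1_simulate" / "weather.csv"),
                "activity_hours": _write(act, out / "1_simulate" / "hourly_vedba.csv"),
                "gps_fixes": _write(gps, out / "1_simulate" / "gps.csv"),
            },
        )

        # 2 -- solar table padded one day each side: pre-dawn hours of the first
        # date belong to the previous biological day, and the last hours need a
        # following sunrise
        start_minus = (pd.Timestamp(config.start) - pd.Timedelta(days=1)).date()
        end_plus = (pd.Timestamp(config.end) + pd.Timedelta(days=1)).date()
        solar = solartime.solar_table(
            config.site_lat, config.site_lon, start_minus, end_plus, config.tz_offset
        )
        stage("2_solar", {"days": _write(solar, out / "2_solar" / "solar.csv")})

        # 3 -- activity on biological days
        hourly = accel.hourly_from_simulated(act, solar)
        daily = accel.daily_summary(hourly, min_hours=config.min_hours_per_day)
        daily_ok = daily[daily["included"]]
        stage(
            "3_activity",
            {
                "hourly_rows": _write(hourly, out / "3_activity" / "hourly.csv"),
                "daily_rows": _write(daily, out / "3_activity" / "daily.csv"),
                "daily_included": int(len(daily_ok)),
            },
        )

        # 4 -- weather aggregation and joins
        dwx = weather.daily_weather(wx, solar)
        wx_h = wx.copy()
        wx_h["precip_presence"] = weather.precip_binary(wx_h["precip"].to_numpy())
        gam1_table = weather.join_weather(hourly[hourly["complete"]], wx_h, on=["t_hour"])
        gam2_table = weather.join_weather(daily_ok, dwx, on=["bio_day"])
        stage(
            "4_weather",
            {
                "daily_weather": _write(dwx, out / "4_weather" / "daily_weather.csv"),
                "gam1_rows": _write(gam1_table, out / "4_weather" / "gam1_table.csv"),
                "gam2_rows": _write(gam2_table, out / "4_weather" / "gam2_table.csv"),
            },
        )

        # 5 -- heatwaves
        waves = heatwave.detect_heatwaves(
            dwx, threshold_c=config.heatwave_threshold_c, min_hours=config.heatwave_min_hours
        )
        hw_df = pd.DataFrame(
            [(w.start_day, w.end_day, w.length_days) for w in waves],
            columns=["start_day", "end_day", "length_days"],
        )
        hw_table = heatwave.heatwave_table(waves, dwx, daily_ok)
        stage(
            "5_heatwaves",
            {
                "heatwaves": _write(hw_df, out / "5_heatwaves" / "heatwaves.csv"),
                "heatwave_table_rows": _write(hw_table, out / "5_heatwaves" / "heatwave_table.csv"),
            },
        )

        # 6 -- movement
        gps_ok = movement.filter_dop(gps)
        moved = movement.daily_metrics(gps_ok, solar, gap_cap_min=config.gap_cap_min)
        move_table = weather.join_weather(moved, dwx, on=["bio_day"])
        move_table["doy"] = pd.to_datetime(move_table["bio_day"]).dt.dayofyear
        stage(
            "6_movement",
            {
                "fixes_in": int(len(gps)),
                "fixes_kept": _write(gps_ok, out / "6_movement" / "gps_filtered.csv"),
                "daily_movement": _write(moved, out / "6_movement" / "daily_movement.csv"),
                "movement_model_rows": _write(move_table, out / "6_movement" / "movement_table.csv"),
            },
        )

        # 7 -- models
        if config.fit_models:
            mdir = out / "7_models"
            mdir.mkdir(parents=True, exist_ok=True)
            gam1 = models.fit_gam_hourly(
                gam1_table, k=config.basis_k, k_tensor=config.basis_k_tensor
            )
            gam2 = models.fit_gam_seasonal(
                gam2_table, k=config.basis_k, k_tensor=config.basis_k_tensor
            )
            contrasts = {
                "night_day_elevation_pct": models.night_day_elevation(gam1),
                "sunset_increase_pct_15C_dry": models.percent_change(
                    gam1, (16, 17, 18), (20, 21, 22), temp=15.0, precip=0
                ),
                "sunset_increase_pct_30C_dry": models.percent_change(
                    gam1, (16, 17, 18), (20, 21, 22), temp=30.0, precip=0
                ),
            }
            reports = [gam1.summary(), "", gam2.summary(), ""]
            counts = {"gam1_n": gam1.n, "gam2_n": gam2.n}
            for resp in ("distance_m", "max_nsd_m2", "mean_speed_ms"):
                fit = models.fit_gam_seasonal(
                    move_table, response=resp, k=config.basis_k, k_tensor=config.basis_k_tensor
                )
                reports += [fit.summary(), ""]
                counts[f"move_{resp}_n"] = fit.n
            try:
                lmm = models.fit_lmm_heatwave(hw_table)
            except ValueError as exc:
                counts["lmm_skipped"] = str(exc)
                log.warning("heatwave LMM skipped: %s", exc)
            else:
                reports += [lmm.summary(), ""]
                lmm.coef.to_csv(mdir / "lmm_coefficients.csv")
                counts["lmm_n"] = lmm.n
            (mdir / "fit_report.txt").write_text("\n".join(reports))
            (mdir / "contrasts.json").write_text(json.dumps(contrasts, indent=2))
            curves = pd.concat(
                [
                    models.temp_response_curve(gam1, precip=0).assign(precip=0),
                    models.temp_response_curve(gam1, precip=1).assign(precip=1),
                ]
            )
            curves.to_csv(mdir / "gam1_temp_response.csv", index=False)
            manifest["contrasts"] = {k: float(np.round(v, 4)) for k, v in contrasts.items()}
            stage("7_models", counts)
    except Exception as exc:  # noqa: BLE001 -- re-raise with stage context
        done = list(manifest["stages"])
        raise RuntimeError(f"pipeline failed after stages {done}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
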