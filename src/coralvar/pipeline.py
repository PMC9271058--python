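"""End-to-end orchestration: simulate -> carbonate -> variability -> rates ->
mixed models -> model selection -> report.

The pipeline consumes plain CSV tables (logger series, bottle samples,
specimen tables), produces CSV/JSON artifacts and a single manifest with
content hashes so a rerun on unchanged inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .carbonate import WaterSample, depth_to_pressure, solve_ph_from_ta_dic
from .inference import (
    ENV_PREDICTORS,
    exhaustive_subset_selection,
    fit_repeated_lmm,
    posthoc_contrasts,
    residual_diagnostics,
    shallow_native_spec,
    transplant_spec,
)
from .rates import (
    ARAGONITE_DENSITY,
    GeometryRecord,
    IncubationRecord,
    WeighingRecord,
    calcification_rate,
    cone_surface_area,
    dry_mass_from_buoyant,
    relative_calcification,
    respiration_rate,
)
from .variability import (
    DEFAULT_SEASONS,
    SeasonCalendar,
    TemperatureSeries,
    diurnal_anomalies,
    variability_metric,
    window_summaries,
)

__all__ = [
    "RunConfig",
    "carbonate_table",
    "variability_table",
    "compute_rate_table",
    "station_season_table",
    "run_pipeline",
    "validate_inputs",
]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_dir: Path
    output_dir: Path
    calendar: SeasonCalendar = DEFAULT_SEASONS
    metric: str = "mean_daily_sd"
    criterion: str = "aicc"
    contrast_adjust: str = "tukey"
    deep_stations: frozenset[str] = frozenset({"Ed"})
    aragonite_density: float = ARAGONITE_DENSITY
    seed: int = 0

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def _write_json(obj: dict, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ----------------------------------------------------------------------
# stage: carbonate


def carbonate_table(water_samples: pd.DataFrame) -> pd.DataFrame:
    """Resolve the CO2 system for every bottle row of the water-sample table.

    Input columns: station_id, season, depth_m, temp_C, salinity,
    ta_umol_kg, dic_umol_kg, po4_umol_kg, sioh4_umol_kg (extra columns pass
    through).  Adds ph_total, pco2_uatm, hco3_umol_kg, co3_umol_kg and
    omega_arag.
    """
    out = water_samples.copy()
    results = []
    for row in out.itertuples():
        sample = WaterSample(
            station_id=str(row.station_id),
            season=str(row.season),
            temperature=float(row.temp_C),
            salinity=float(row.salinity),
            pressure=depth_to_pressure(float(row.depth_m)),
            ta=float(row.ta_umol_kg),
            dic=float(row.dic_umol_kg),
            phosphate=float(getattr(row, "po4_umol_kg", 0.0)),
            silicate=float(getattr(row, "sioh4_umol_kg", 0.0)),
        )
        st = solve_ph_from_ta_dic(sample)
        results.append((st.ph_total, st.pco2, st.hco3, st.co3, st.omega_arag))
    out[["ph_total", "pco2_uatm", "hco3_umol_kg", "co3_umol_kg", "omega_arag"]] = (
        pd.DataFrame(results, index=out.index)
    )
    return out


# ----------------------------------------------------------------------
# stage: variability


def _series_from_frame(group: pd.DataFrame) -> TemperatureSeries:
    return TemperatureSeries(
        station_id=str(group["station_id"].iloc[0]),
        depth=float(group["depth_m"].iloc[0]),
        timestamps=pd.DatetimeIndex(pd.to_datetime(group["timestamp"])),
        values=group["temp_C"].to_numpy(dtype=float),
    )


def variability_table(
    temperatures: pd.DataFrame,
    calendar: SeasonCalendar = DEFAULT_SEASONS,
    metric: str = "mean_daily_sd",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-station seasonal + annual variability stats and window summaries.

    Input columns: station_id, depth_m, timestamp (ISO-8601), temp_C.
    Returns ``(variability, summaries)``.
    """
    var_rows, summary_frames = [], []
    for station, group in temperatures.groupby("station_id", sort=True):
        series = _series_from_frame(group)
        anom = diurnal_anomalies(series)
        temps = series.to_frame()["temp_C"]
        spans = list(calendar.windows) + [
            (
                "annual",
                str(series.timestamps.min()),
                str(series.timestamps.max() + pd.Timedelta(minutes=1)),
            )
        ]
        for label, start, end in spans:
            try:
                stat = variability_metric(
                    anom,
                    window=(pd.Timestamp(start), pd.Timestamp(end)),
                    metric=metric,
                    station_id=str(station),
                    window_label=label,
                    temperatures=temps,
                )
            except ValueError:
                warnings.warn(
                    f"station {station}: window {label} outside series span",
                    stacklevel=2,
                )
                continue
            var_rows.append(
                {
                    "station_id": stat.station_id,
                    "window": stat.window,
                    "mean_temp_C": stat.mean_temperature,
                    "temp_variability_C": stat.variability,
                    "metric_name": stat.metric_name,
                    "n_days": stat.n_days,
                }
            )
        summary_frames.append(window_summaries(series, calendar))
    return pd.DataFrame(var_rows), pd.concat(summary_frames, ignore_index=True)


# ----------------------------------------------------------------------
# stage: rates


def _season_of(day: pd.Timestamp, calendar: SeasonCalendar) -> str | None:
    for label, start, end in calendar.windows:
        if pd.Timestamp(start) <= day < pd.Timestamp(end):
            return label
    return None


def compute_rate_table(
    specimens: pd.DataFrame,
    weighings: pd.DataFrame,
    geometry: pd.DataFrame,
    incubations: pd.DataFrame,
    calendar: SeasonCalendar = DEFAULT_SEASONS,
    deep_stations: frozenset[str] = frozenset({"Ed"}),
    aragonite_density: float = ARAGONITE_DENSITY,
) -> tuple[pd.DataFrame, dict]:
    """Per specimen x season calcification and respiration from raw tables.

    Growth periods are consecutive weighing pairs; the period's season is
    the calendar window containing its midpoint.  The normalising area is
    the cup (frustum) area from calliper geometry under the area policy:
    shallow corals use the final (most accurate, end-of-study) record for
    every period, deep corals the most recent record at or before the
    period start (their calyx grew substantially within the year).
    Respiration subtracts the station-season control-vial blank.  Returns
    ``(rates, qc_report)``.
    """
    spec_idx = specimens.set_index("specimen_id")
    weighings = weighings.assign(date=pd.to_datetime(weighings["date"]))
    geometry = geometry.assign(date=pd.to_datetime(geometry["date"]))

    controls: dict[tuple[str, str], list[IncubationRecord]] = {}
    coral_incubations: dict[tuple[str, str], IncubationRecord] = {}
    for row in incubations.itertuples():
        rec = IncubationRecord(
            specimen_id=None if int(row.control) else str(row.specimen_id),
            o2_start=float(row.o2_start_umol_l),
            o2_end=float(row.o2_end_umol_l),
            vial_volume=float(row.vial_volume_l),
            duration=float(row.duration_h),
            bath_temperature=float(row.bath_temp_C),
        )
        key = (str(row.station), str(row.season))
        if rec.is_control:
            controls.setdefault(key, []).append(rec)
        else:
            coral_incubations[(str(row.specimen_id), str(row.season))] = rec

    rows = []
    qc = {"n_specimens": 0, "negative_respiration": [], "missing_incubation": []}
    for specimen_id, wgroup in weighings.groupby("specimen_id", sort=True):
        if specimen_id not in spec_idx.index:
            raise KeyError(f"weighing references unknown specimen {specimen_id!r}")
        station = str(spec_idx.loc[specimen_id, "deployment_station"])
        deep = station in deep_stations
        qc["n_specimens"] += 1

        wgroup = wgroup.sort_values("date")
        wrecs = [
            WeighingRecord(
                specimen_id=str(specimen_id),
                date=r.date.date(),
                buoyant_mass=float(r.buoyant_mass_g),
                bath_temperature=float(r.bath_temp_C),
                bath_salinity=float(r.bath_salinity),
            )
            for r in wgroup.itertuples()
        ]
        dry = [dry_mass_from_buoyant(w, aragonite_density) for w in wrecs]

        ggroup = geometry[geometry["specimen_id"] == specimen_id].sort_values("date")
        if ggroup.empty:
            raise KeyError(f"no geometry for specimen {specimen_id!r}")

        def area_for(period_start: pd.Timestamp) -> float:
            if deep:
                eligible = ggroup[ggroup["date"] <= period_start]
                grow = eligible.iloc[-1] if not eligible.empty else ggroup.iloc[0]
            else:
                grow = ggroup.iloc[-1]
            rec = GeometryRecord(
                specimen_id=str(specimen_id),
                date=grow["date"].date(),
                oral_diameter=float(grow["oral_diameter_mm"]),
                basal_diameter=float(grow["basal_diameter_mm"]),
                height=float(grow["height_mm"]),
                tissue_fraction=float(grow["tissue_fraction"]),
            )
            return cone_surface_area(rec)

        for k in range(len(wrecs) - 1):
            start, end = wrecs[k].date, wrecs[k + 1].date
            days = (pd.Timestamp(end) - pd.Timestamp(start)).days
            mid = pd.Timestamp(start) + (pd.Timestamp(end) - pd.Timestamp(start)) / 2
            season = _season_of(mid, calendar)
            if season is None:
                continue
            area = area_for(pd.Timestamp(start))
            g = calcification_rate(dry[k], dry[k + 1], days, area)
            g_rel = relative_calcification(dry[k], dry[k + 1], days)

            resp = None
            flagged = False
            inc = coral_incubations.get((str(specimen_id), season))
            if inc is None:
                qc["missing_incubation"].append(f"{specimen_id}/{season}")
            else:
                ctrl = controls.get((station, season), [])
                resp, flagged = respiration_rate(inc, ctrl, area)
                if flagged:
                    qc["negative_respiration"].append(f"{specimen_id}/{season}")

            rows.append(
                {
                    "specimen_id": str(specimen_id),
                    "station": station,
                    "origin_station": str(spec_idx.loc[specimen_id, "origin_station"]),
                    "transplant": str(
                        spec_idx.loc[specimen_id, "transplant_status"]
                    ),
                    "season": season,
                    "calcification_g": g,
                    "calcification_rel": g_rel,
                    "respiration": resp,
                    "respiration_flagged": int(flagged),
                    "surface_area_cm2": area,
                    "growth_days": days,
                }
            )
    rates = pd.DataFrame(rows)
    qc["n_rate_rows"] = int(len(rates))
    return rates, qc


# ----------------------------------------------------------------------
# stage: join for the selection layer


def station_season_table(
    rates: pd.DataFrame,
    variability: pd.DataFrame,
    carbonate: pd.DataFrame,
) -> pd.DataFrame:
    """Station x season table joining mean rates with the six predictors.

    The response is the mean calcification over all corals (native and
    novel pooled) deployed at the station; predictors are the seasonal mean
    temperature and variability plus the bottle-derived pH_T, Omega_arag,
    salinity and oxygen.
    """
    mean_rates = (
        rates.groupby(["station", "season"], sort=True)["calcification_g"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "calcification_g", "count": "n_corals"})
    )
    var = variability[variability["window"] != "annual"][
        ["station_id", "window", "mean_temp_C", "temp_variability_C"]
    ].rename(columns={"station_id": "station", "window": "season"})
    carb_cols = ["station_id", "season", "ph_total", "omega_arag", "salinity"]
    if "oxygen_umol_kg" in carbonate.columns:
        carb_cols.append("oxygen_umol_kg")
    carb = carbonate[carb_cols].rename(columns={"station_id": "station"})
    out = mean_rates.merge(var, on=["station", "season"], how="left").merge(
        carb, on=["station", "season"], how="left"
    )
    return out


# ----------------------------------------------------------------------
# validation


_SCHEMAS = {
    "specimens.csv": ["specimen_id", "origin_station", "deployment_station", "transplant_status"],
    "weighings.csv": ["specimen_id", "date", "buoyant_mass_g", "bath_temp_C", "bath_salinity"],
    "geometry.csv": ["specimen_id", "date", "oral_diameter_mm", "basal_diameter_mm", "height_mm", "tissue_fraction"],
    "incubations.csv": ["specimen_id", "station", "season", "control", "o2_start_umol_l", "o2_end_umol_l", "vial_volume_l", "duration_h"],
    "temperatures.csv": ["station_id", "depth_m", "timestamp", "temp_C"],
    "water_samples.csv": ["station_id", "season", "depth_m", "temp_C", "salinity", "ta_umol_kg", "dic_umol_kg"],
}

_RANGES = {
    ("temperatures.csv", "temp_C"): (-2.0, 40.0),
    ("water_samples.csv", "temp_C"): (-2.0, 40.0),
    ("water_samples.csv", "salinity"): (0.0, 45.0),
    ("water_samples.csv", "ta_umol_kg"): (1.0, 5000.0),
    ("water_samples.csv", "dic_umol_kg"): (1.0, 5000.0),
    ("weighings.csv", "buoyant_mass_g"): (0.0, 1000.0),
    ("incubations.csv", "o2_start_umol_l"): (0.0, 600.0),
    ("incubations.csv", "o2_end_umol_l"): (0.0, 600.0),
}


def validate_inputs(input_dir: Path, strict: bool = False) -> dict:
    """Schema, range and referential-integrity checks on the input tables.

    Violations are reported, not raised, unless ``strict``.
    """
    input_dir = Path(input_dir)
    violations: list[str] = []
    tables: dict[str, pd.DataFrame] = {}
    for name, columns in _SCHEMAS.items():
        path = input_dir / name
        if not path.exists():
            violations.append(f"{name}: file missing")
            continue
        df = pd.read_csv(path)
        tables[name] = df
        for col in columns:
            if col not in df.columns:
                violations.append(f"{name}: missing column {col}")
        for (fname, col), (lo, hi) in _RANGES.items():
            if fname != name or col not in df.columns:
                continue
            bad = df[(df[col] < lo) | (df[col] > hi)]
            for i in bad.index:
                violations.append(
                    f"{name}: row {int(i)}: {col}={df.loc[i, col]!r} outside [{lo}, {hi}]"
                )
    if "specimens.csv" in tables:
        known = set(tables["specimens.csv"]["specimen_id"].astype(str))
        for name in ("weighings.csv", "geometry.csv"):
            if name not in tables:
                continue
            ids = tables[name]["specimen_id"].astype(str)
            for i, sid in ids.items():
                if sid not in known:
                    violations.append(f"{name}: row {int(i)}: unknown specimen_id {sid!r}")
        if "incubations.csv" in tables:
            inc = tables["incubations.csv"]
            corals = inc[inc["control"] == 0]
            for i, sid in corals["specimen_id"].astype(str).items():
                if sid not in known:
                    violations.append(
                        f"incubations.csv: row {int(i)}: unknown specimen_id {sid!r}"
                    )
    report = {"n_violations": len(violations), "violations": violations}
    if strict and violations:
        raise ValueError(f"input validation failed with {len(violations)} violations")
    return report


# ----------------------------------------------------------------------
# full run


def _lmm_report(rates: pd.DataFrame, adjust: str) -> dict:
    """Both canonical mixed models with contrasts, as a JSON-ready dict."""
    report: dict = {}
    for spec in (shallow_native_spec(), transplant_spec()):
        try:
            res = fit_repeated_lmm(rates, spec)
        except (ValueError, RuntimeError) as exc:
            report[spec.label] = {"error": str(exc)}
            continue
        contrasts = {}
        for factor in sorted({f for t in spec.fixed_terms for f in t.split(":")}):
            table = posthoc_contrasts(res, factor, adjust=adjust)
            contrasts[factor] = table.drop(columns=["factor"]).to_dict("records")
        diag = residual_diagnostics(
            np.asarray(res._fit.resid), response=res._data[spec.response].to_numpy()
        )
        report[spec.label] = {
            "fixed_effects": res.fixed_effects.reset_index(names="coefficient").to_dict(
                "records"
            ),
            "term_tests": res.term_tests.reset_index().to_dict("records"),
            "variance_components": {
                "specimen": res.group_variance,
                "residual": res.residual_variance,
            },
            "n_obs": res.n_obs,
            "n_specimens": res.n_groups,
            "contrasts": contrasts,
            "diagnostics": diag,
        }
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write all artifacts plus the hash manifest.

    Expects the six input CSVs in ``config.input_dir``; writes carbonate,
    variability, summary and rate CSVs, the mixed-model report, the
    63-row model-selection table, diagnostics and ``manifest.json`` into
    ``config.output_dir``.  Returns the manifest dict.
    """
    ind, outd = config.input_dir, config.output_dir
    outd.mkdir(parents=True, exist_ok=True)

    water = pd.read_csv(ind / "water_samples.csv")
    temps = pd.read_csv(ind / "temperatures.csv")
    specimens = pd.read_csv(ind / "specimens.csv")
    weighings = pd.read_csv(ind / "weighings.csv")
    geometry = pd.read_csv(ind / "geometry.csv")
    incubations = pd.read_csv(ind / "incubations.csv")

    carb = carbonate_table(water)
    _write_csv(carb, outd / "carbonate.csv")

    var, summaries = variability_table(temps, config.calendar, config.metric)
    _write_csv(var, outd / "variability.csv")
    _write_csv(summaries, outd / "summaries.csv")

    rates, qc = compute_rate_table(
        specimens,
        weighings,
        geometry,
        incubations,
        calendar=config.calendar,
        deep_stations=config.deep_stations,
        aragonite_density=config.aragonite_density,
    )
    _write_csv(rates, outd / "rates.csv")
    _write_json(qc, outd / "rates_qc.json")

    lmm = _lmm_report(rates, config.contrast_adjust)
    _write_json(lmm, outd / "lmm_report.json")

    joined = station_season_table(rates, var, carb)
    _write_csv(joined, outd / "station_season.csv")
    predictors = [p for p in ENV_PREDICTORS if p in joined.columns]
    sel = exhaustive_subset_selection(
        joined, "calcification_g", predictors, criterion=config.criterion
    )
    sel_table = sel.table.copy()
    sel_table["subset"] = sel_table["subset"].map(lambda s: "+".join(s))
    sel_table["coefficients"] = sel_table["coefficients"].map(
        lambda d: json.dumps(d, sort_keys=True)
    )
    _write_csv(sel_table.drop(columns=["criterion_value"]), outd / "model_selection.csv")

    best = sel.best_model
    x = np.column_stack(
        [np.ones(len(joined))] + [joined[c].to_numpy(dtype=float) for c in best]
    )
    y = joined["calcification_g"].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    diag = residual_diagnostics(y - x @ beta, exog=x, response=y)
    diag["best_model"] = list(best)
    diag["best_adj_r2"] = float(sel.table.iloc[0]["adj_r2"])
    _write_json(diag, outd / "diagnostics.json")

    artifacts = [
        "carbonate.csv",
        "variability.csv",
        "summaries.csv",
        "rates.csv",
        "rates_qc.json",
        "lmm_report.json",
        "station_season.csv",
        "model_selection.csv",
        "diagnostics.json",
    ]
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "metric": config.metric,
        "criterion": config.criterion,
        "artifacts": {name: _sha256(outd / name) for name in artifacts},
    }
    _write_json(manifest, outd / "manifest.json")
    return manifest
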