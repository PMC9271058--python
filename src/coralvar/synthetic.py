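"""Synthetic fjord scenario with known ground truth.

Generates every input the analysis pipeline consumes — 15-min station
temperature series, seasonal discrete water samples, and a coral cohort
with longitudinal buoyant weighings, closed-chamber incubations and
calliper geometry — from an explicit :class:`ScenarioConfig`, so that every
downstream stage is testable by parameter recovery without the deposited
field data.

The default scenario emulates the study system: six shallow stations
(head A to mouth F, ~20 m) with a mean annual temperature near 12.5 degC,
strong tidal/diurnal fluctuations (largest at the head, daily swings up to
~3.7 degC, summer maxima above 16 degC), and one deep station Ed (~300 m)
near 11.4 +/- 0.2 degC with weak variability and aragonite undersaturation.
True calcification follows a linear response in station-season mean
temperature (positive) and temperature variability (negative) with
specimen random intercepts; a coral's response depends on its deployment
station only (acclimatisation), so the true transplantation effect is zero
unless configured otherwise.

Randomness: one root seed; every stream (station series, specimen,
incubation) draws from a seed derived from the root seed and a stable
label hash, so adding a station or specimen leaves other streams untouched.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .carbonate import (
    WaterSample,
    depth_to_pressure,
    equilibrium_constants,
    seawater_density,
    total_alkalinity_from_ph_dic,
)
from .rates import ARAGONITE_DENSITY
from .variability import (
    DEFAULT_SEASONS,
    SeasonCalendar,
    TemperatureSeries,
    diurnal_anomalies,
    variability_metric,
)

__all__ = [
    "StationConfig",
    "ResponseModel",
    "RespirationModel",
    "NoiseModel",
    "ScenarioConfig",
    "TruthBundle",
    "SyntheticDataset",
    "default_scenario",
    "gen_temperature_series",
    "gen_water_samples",
    "gen_coral_cohort",
    "generate_scenario",
    "station_season_stats",
    "environment_table",
    "gen_rate_table",
]

_MINUTES = 15
_TIDAL_PERIOD_H = 12.42


def _stream_rng(seed: int, *labels: str) -> np.random.Generator:
    """Deterministic per-stream generator: root seed + stable label hashes."""
    keys = [seed & 0x7FFFFFFF] + [zlib.crc32(lab.encode()) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(keys))


@dataclass(frozen=True)
class StationConfig:
    """Physical description of one station's environment."""

    label: str
    depth_m: float
    mean_temp: float  # annual mean, degC
    seasonal_amplitude: float  # degC, annual harmonic
    anomaly_scale: float  # degC, tidal/diurnal harmonic amplitude scale
    ar1_sigma: float  # degC, AR(1) innovation SD
    ar1_phi: float = 0.7
    summer_variability_boost: float = 0.35  # >0: anomalies larger in summer
    # discrete seasonal water properties co-vary with seasonal mean
    # temperature along the water-mass axis: X = base + slope*(T - mean_temp)
    salinity_base: float = 32.0
    salinity_temp_slope: float = -0.25  # warmer season -> fresher surface influence
    oxygen_base: float = 265.0  # umol kg-1
    oxygen_temp_slope: float = -12.0  # umol kg-1 per degC
    carbonate: dict[str, tuple[float, float]] = field(default_factory=dict)
    # per season: (target total-scale pH, DIC umol kg-1)

    def seasonal_salinity(self, t_mean: float) -> float:
        return self.salinity_base + self.salinity_temp_slope * (t_mean - self.mean_temp)

    def seasonal_oxygen(self, t_mean: float) -> float:
        return self.oxygen_base + self.oxygen_temp_slope * (t_mean - self.mean_temp)


@dataclass(frozen=True)
class ResponseModel:
    """True linear calcification response at the station-season level.

    G = intercept + coef_mean_temp * (meanT - temp_ref)
        + coef_variability * variability + u_specimen + eps,
    in mg CaCO3 cm-2 d-1.  A nonzero ``transplant_effect`` is added for
    novel corals (zero by default: pure acclimatisation).
    """

    intercept: float = 1.12
    coef_mean_temp: float = 0.15
    coef_variability: float = -1.5
    temp_ref: float = 12.0
    specimen_sd: float = 0.10
    residual_sd: float = 0.15
    transplant_effect: float = 0.0

    def true_g(self, mean_temp: float, variability: float, novel: bool = False) -> float:
        g = (
            self.intercept
            + self.coef_mean_temp * (mean_temp - self.temp_ref)
            + self.coef_variability * variability
        )
        if novel:
            g += self.transplant_effect
        return g


@dataclass(frozen=True)
class RespirationModel:
    """True dark respiration, umol O2 cm-2 d-1, at standardised temperature."""

    shallow_mean: float = 1.2
    deep_mean: float = 2.0
    season_offsets: dict[str, float] = field(
        default_factory=lambda: {"summer": 0.3, "autumn": 0.0, "winter": -0.1}
    )
    specimen_sd: float = 0.15
    residual_sd: float = 0.20

    def true_r(self, deep: bool, season: str) -> float:
        base = self.deep_mean if deep else self.shallow_mean
        return base + self.season_offsets.get(season, 0.0)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise standard deviations of the instrument chain."""

    balance_sd_g: float = 0.001  # buoyant-weight handling noise
    o2_probe_sd: float = 1.0  # umol L-1
    calliper_sd_mm: float = 0.05
    blank_drift: float = 2.0  # umol L-1 control-vial drawdown over 6 h
    blank_sd: float = 0.3

    def scaled(self, factor: float) -> "NoiseModel":
        return NoiseModel(
            balance_sd_g=self.balance_sd_g * factor,
            o2_probe_sd=self.o2_probe_sd * factor,
            calliper_sd_mm=self.calliper_sd_mm * factor,
            blank_drift=self.blank_drift,
            blank_sd=self.blank_sd * factor,
        )


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of one synthetic field year."""

    stations: tuple[StationConfig, ...]
    seasons: SeasonCalendar = DEFAULT_SEASONS
    response: ResponseModel = ResponseModel()
    respiration: RespirationModel = RespirationModel()
    noise: NoiseModel = NoiseModel()
    n_native: int = 10
    n_native_deep: int = 8
    transplant_pairs: tuple[tuple[str, str], ...] = (("A", "F"), ("Es", "Ed"))
    deep_threshold_m: float = 100.0
    start: str = "2016-09-15"
    end: str = "2017-08-15"
    seed: int = 0

    def station(self, label: str) -> StationConfig:
        for st in self.stations:
            if st.label == label:
                return st
        raise KeyError(f"unknown station {label!r}")

    @property
    def deep_stations(self) -> frozenset[str]:
        return frozenset(
            st.label for st in self.stations if st.depth_m >= self.deep_threshold_m
        )

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=seed)


def _shallow_carbonate(ph_summer: float) -> dict[str, tuple[float, float]]:
    # DIC higher in winter (mixing), pH highest in autumn
    return {
        "summer": (ph_summer, 2020.0),
        "autumn": (ph_summer + 0.06, 2050.0),
        "winter": (ph_summer - 0.04, 2080.0),
    }


def default_scenario(seed: int = 0) -> ScenarioConfig:
    """The default fjord scenario: six shallow stations plus one deep.

    Variability declines from the head (A) to the mouth (F); the deep
    station is cold, stable and aragonite-undersaturated; the fjord-head
    summer sample is a low-pH excursion comparable to depth.
    """
    shallow = []
    scales = {"A": 1.10, "B": 0.95, "C": 0.85, "D": 0.75, "Es": 0.70, "F": 0.55}
    means = {"A": 12.60, "B": 12.55, "C": 12.50, "D": 12.45, "Es": 12.50, "F": 12.45}
    ph_summer = {"A": 7.78, "B": 7.95, "C": 8.00, "D": 8.02, "Es": 8.04, "F": 8.05}
    for lab in ("A", "B", "C", "D", "Es", "F"):
        shallow.append(
            StationConfig(
                label=lab,
                depth_m=20.0,
                mean_temp=means[lab],
                seasonal_amplitude=1.8,
                anomaly_scale=scales[lab],
                ar1_sigma=0.15 * scales[lab],
                salinity_base=32.0,
                oxygen_base=265.0,
                carbonate=_shallow_carbonate(ph_summer[lab]),
            )
        )
    deep = StationConfig(
        label="Ed",
        depth_m=300.0,
        mean_temp=11.4,
        seasonal_amplitude=0.12,
        anomaly_scale=0.04,
        ar1_sigma=0.02,
        summer_variability_boost=-0.3,  # deep waters fluctuate more in winter
        salinity_base=32.8,
        oxygen_base=110.0,
        carbonate={
            "summer": (7.68, 2290.0),
            "autumn": (7.70, 2280.0),
            "winter": (7.67, 2295.0),
        },
    )
    return ScenarioConfig(stations=tuple(shallow) + (deep,), seed=seed)


# ----------------------------------------------------------------------
# temperature series


def gen_temperature_series(config: ScenarioConfig, station: str) -> TemperatureSeries:
    """15-min logger series: seasonal harmonic + tidal/diurnal mixture + AR(1).

    The anomaly envelope is modulated over the year so shallow stations are
    most variable in austral summer/autumn (negative boost inverts this for
    the deep station).  The austral seasonal maximum falls in late January.
    """
    st = config.station(station)
    rng = _stream_rng(config.seed, "temperature", station)

    idx = pd.date_range(config.start, config.end, freq=f"{_MINUTES}min", inclusive="left")
    t_hours = (idx - idx[0]) / pd.Timedelta(hours=1)
    t_hours = np.asarray(t_hours, dtype=float)
    doy = idx.dayofyear.to_numpy(dtype=float)

    seasonal_phase = 2.0 * np.pi * (doy - 25.0) / 365.25  # peak ~Jan 25
    seasonal = st.mean_temp + st.seasonal_amplitude * np.cos(seasonal_phase)

    envelope = np.clip(1.0 + st.summer_variability_boost * np.cos(seasonal_phase), 0.05, None)
    ph1, ph2 = rng.uniform(0.0, 2.0 * np.pi, size=2)
    harmonics = st.anomaly_scale * (
        0.6 * np.sin(2.0 * np.pi * t_hours / _TIDAL_PERIOD_H + ph1)
        + 0.4 * np.sin(2.0 * np.pi * t_hours / 24.0 + ph2)
    )
    innov = rng.normal(0.0, st.ar1_sigma, size=len(idx))
    ar1 = lfilter([1.0], [1.0, -st.ar1_phi], innov)

    values = seasonal + envelope * harmonics + envelope * ar1
    return TemperatureSeries(
        station_id=station, depth=st.depth_m, timestamps=idx, values=values
    )


def station_season_stats(
    config: ScenarioConfig,
    metric: str = "mean_daily_sd",
    include_annual: bool = False,
) -> pd.DataFrame:
    """Per station x season mean temperature and variability of the scenario.

    These realized series statistics are the ground-truth predictors of the
    response model (the generator draws the series first, then conditions
    the coral responses on the series' statistics).
    """
    rows = []
    for st in config.stations:
        series = gen_temperature_series(config, st.label)
        anom = diurnal_anomalies(series)
        temps = series.to_frame()["temp_C"]
        windows = list(config.seasons.windows)
        if include_annual:
            windows.append(("annual", config.start, config.end))
        for label, start, end in windows:
            stat = variability_metric(
                anom,
                window=(pd.Timestamp(start), pd.Timestamp(end)),
                metric=metric,
                station_id=st.label,
                window_label=label,
                temperatures=temps,
            )
            rows.append(
                {
                    "station_id": st.label,
                    "season": label,
                    "depth_m": st.depth_m,
                    "mean_temp_C": stat.mean_temperature,
                    "temp_variability_C": stat.variability,
                    "n_days": stat.n_days,
                }
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# water samples


def gen_water_samples(
    config: ScenarioConfig, station: str, season: str, t_mean: float | None = None
) -> tuple[WaterSample, float]:
    """One discrete sample built by forward-computing TA from a pH target.

    The station's configured (pH_T, DIC) target for the season is combined
    with the seasonal mean temperature and salinity; TA is computed with
    the same constant set the solver will use, so the inverse solve is an
    exact recovery test.  Returns ``(sample, target_ph)``.
    """
    st = config.station(station)
    if season not in st.carbonate:
        raise KeyError(f"station {station!r} has no carbonate target for {season!r}")
    ph_target, dic = st.carbonate[season]
    if not (7.0 <= ph_target <= 9.0):
        raise ValueError(f"target pH {ph_target} outside [7, 9]")
    rng = _stream_rng(config.seed, "watersample", station, season)

    if t_mean is None:
        start, end = config.seasons.bounds(season)
        series = gen_temperature_series(config, station)
        temps = series.to_frame()["temp_C"]
        t_mean = float(temps[(temps.index >= start) & (temps.index < end)].mean())
    sal = st.seasonal_salinity(t_mean) + rng.normal(0.0, 0.05)
    pressure = depth_to_pressure(st.depth_m)
    phosphate = 1.5 + rng.normal(0.0, 0.1)
    silicate = 15.0 + rng.normal(0.0, 1.0)

    constants = equilibrium_constants(t_mean, sal, pressure)
    ta = total_alkalinity_from_ph_dic(ph_target, dic, constants, phosphate, silicate)
    sample = WaterSample(
        station_id=station,
        season=season,
        temperature=t_mean,
        salinity=sal,
        pressure=pressure,
        ta=ta,
        dic=dic,
        phosphate=phosphate,
        silicate=silicate,
    )
    return sample, ph_target


def environment_table(
    config: ScenarioConfig,
    stats: pd.DataFrame | None = None,
    metric: str = "mean_daily_sd",
) -> pd.DataFrame:
    """Station x season table of all six environmental predictors.

    Mean temperature and variability come from the scenario's realized
    temperature series; pH_T and Omega_arag from the forward-generated
    bottle samples resolved with the CO2-system solver (so the chemical
    coupling between pH and saturation state is preserved); salinity and
    oxygen from the configured seasonal profiles with sampling noise.
    """
    from .carbonate import solve_ph_from_ta_dic

    if stats is None:
        stats = station_season_stats(config, metric=metric)
    rows = []
    for row in stats.itertuples():
        st = config.station(row.station_id)
        sample, _ = gen_water_samples(
            config, row.station_id, row.season, t_mean=row.mean_temp_C
        )
        state = solve_ph_from_ta_dic(sample)
        rng = _stream_rng(config.seed, "oxygen", row.station_id, row.season)
        rows.append(
            {
                "station": row.station_id,
                "season": row.season,
                "mean_temp_C": row.mean_temp_C,
                "temp_variability_C": row.temp_variability_C,
                "ph_total": state.ph_total,
                "omega_arag": state.omega_arag,
                "salinity": sample.salinity,
                "oxygen_umol_kg": st.seasonal_oxygen(row.mean_temp_C)
                + rng.normal(0.0, 3.0),
            }
        )
    return pd.DataFrame(rows)


def gen_rate_table(
    config: ScenarioConfig,
    stats: pd.DataFrame,
    rng: np.random.Generator,
    stations: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Response-level cohort draw: observed rates without the instrument chain.

    Draws each specimen's seasonal calcification (and respiration) directly
    from the true response model plus specimen and residual noise — the
    simulation fast path used by replicated recovery and calibration
    studies.  The full measurement chain (weighing, incubation, geometry)
    is exercised separately and is exact at zero instrument noise, so
    response-level draws are statistically equivalent for those studies.
    """
    stats_idx = stats.set_index(["station_id", "season"])
    roster = _specimen_roster(config)
    if stations is not None:
        roster = roster[roster["deployment_station"].isin(stations)]
    resp = config.respiration
    deep_set = config.deep_stations
    rows = []
    for spec in roster.itertuples():
        dep = spec.deployment_station
        deep = dep in deep_set
        novel = spec.transplant_status == "novel"
        u_g = rng.normal(0.0, config.response.specimen_sd)
        u_r = rng.normal(0.0, resp.specimen_sd)
        for season in config.seasons.labels:
            row = stats_idx.loc[(dep, season)]
            g = (
                config.response.true_g(
                    row["mean_temp_C"], row["temp_variability_C"], novel=novel
                )
                + u_g
                + rng.normal(0.0, config.response.residual_sd)
            )
            r = resp.true_r(deep, season) + u_r + rng.normal(0.0, resp.residual_sd)
            rows.append(
                {
                    "specimen_id": spec.specimen_id,
                    "station": dep,
                    "origin_station": spec.origin_station,
                    "transplant": spec.transplant_status,
                    "season": season,
                    "calcification_g": g,
                    "respiration": r,
                }
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# coral cohort


@dataclass
class TruthBundle:
    """Ground truth underlying one generated cohort."""

    station_stats: pd.DataFrame  # station x season mean T and variability
    true_rates: pd.DataFrame  # specimen x season: g_true, g_rel_true, resp_true
    trajectories: pd.DataFrame  # specimen x date: true dry mass
    response: ResponseModel
    respiration: RespirationModel


@dataclass
class SyntheticDataset:
    """All pipeline input tables plus the truth that generated them."""

    specimens: pd.DataFrame
    weighings: pd.DataFrame
    geometry: pd.DataFrame
    incubations: pd.DataFrame
    temperatures: pd.DataFrame
    water_samples: pd.DataFrame
    truth: TruthBundle
    config: ScenarioConfig

    def write(self, directory) -> None:
        """Write the six pipeline input CSVs plus truth.json to a directory."""
        import json
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        tables = {
            "specimens.csv": self.specimens,
            "weighings.csv": self.weighings,
            "geometry.csv": self.geometry,
            "incubations.csv": self.incubations,
            "temperatures.csv": self.temperatures,
            "water_samples.csv": self.water_samples,
        }
        for name, df in tables.items():
            df.to_csv(
                directory / name, index=False, float_format="%.10g", lineterminator="\n"
            )
        truth = {
            "seed": self.config.seed,
            "response": {
                "intercept": self.truth.response.intercept,
                "coef_mean_temp": self.truth.response.coef_mean_temp,
                "coef_variability": self.truth.response.coef_variability,
                "temp_ref": self.truth.response.temp_ref,
                "transplant_effect": self.truth.response.transplant_effect,
            },
            "station_stats": self.truth.station_stats.to_dict("records"),
            "true_rates": self.truth.true_rates.to_dict("records"),
        }
        (directory / "truth.json").write_text(
            json.dumps(truth, indent=2, sort_keys=True) + "\n"
        )


def _specimen_roster(config: ScenarioConfig) -> pd.DataFrame:
    rows = []
    counter = 0

    def n_for(label: str) -> int:
        return (
            config.n_native_deep
            if label in config.deep_stations
            else config.n_native
        )

    for st in config.stations:
        for _ in range(n_for(st.label)):
            counter += 1
            rows.append(
                {
                    "specimen_id": f"{st.label}-n{counter:03d}",
                    "origin_station": st.label,
                    "deployment_station": st.label,
                    "transplant_status": "native",
                    "cohort": "experimental",
                }
            )
    for origin, dest in config.transplant_pairs:
        for a, b in ((origin, dest), (dest, origin)):
            for _ in range(n_for(a)):
                counter += 1
                rows.append(
                    {
                        "specimen_id": f"{a}-x{counter:03d}",
                        "origin_station": a,
                        "deployment_station": b,
                        "transplant_status": "novel",
                        "cohort": "experimental",
                    }
                )
    return pd.DataFrame(rows)


def gen_coral_cohort(
    config: ScenarioConfig, stats: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthBundle]:
    """Cohort with longitudinal weighings, geometry and incubations.

    ``stats`` is the station-season statistics table (computed from the
    scenario's own temperature series if omitted).  True seasonal G follows
    the linear response model at the deployment station; the dry-mass
    trajectory integrates G over the tissue-covered area actually used by
    the rate pipeline (final-geometry area for shallow corals, period-start
    area for deep corals, matching the area-policy default); buoyant
    weights, O2 endpoints and calliper readings add instrument noise.
    """
    if stats is None:
        stats = station_season_stats(config)
    stats_idx = stats.set_index(["station_id", "season"])

    specimens = _specimen_roster(config)
    seasons = list(config.seasons.labels)
    boundaries = [config.seasons.bounds(s) for s in seasons]
    dates = [boundaries[0][0]] + [b[1] for b in boundaries]
    season_days = [(b[1] - b[0]).days for b in boundaries]

    resp_model = config.respiration
    noise = config.noise
    deep_set = config.deep_stations

    w_rows, g_rows, i_rows, t_rows, r_rows = [], [], [], [], []

    bath_ts = {"init": 12.5, "summer": 14.16, "autumn": 12.19, "winter": 11.76}
    bath_sal = 32.1

    for spec in specimens.itertuples():
        rng = _stream_rng(config.seed, "specimen", spec.specimen_id)
        dep = spec.deployment_station
        deep = dep in deep_set
        novel = spec.transplant_status == "novel"

        u_g = rng.normal(0.0, config.response.specimen_sd)
        u_r = rng.normal(0.0, resp_model.specimen_sd)

        # base geometry from the sampled-size distribution
        oral0 = max(rng.normal(18.10, 4.47), 8.0)
        basal0 = 0.55 * oral0
        height0 = 1.40 * oral0
        tissue = 1.0 if deep else 0.85
        growth_factor = 1.08 if deep else 1.005  # deep calyxes expand visibly

        # true geometry per campaign date (index 0..3)
        geoms = []
        for j in range(len(dates)):
            f = growth_factor ** j
            geoms.append((oral0 * f, basal0 * f, height0 * f))

        def area_of(idx: int) -> float:
            o, b, h = geoms[idx]
            r_o, r_b = o / 2.0, b / 2.0
            slant = np.hypot(h, r_o - r_b)
            return tissue * 2.0 * np.pi * (r_o + r_b) * slant / 100.0

        # geometry records: deep corals measured every campaign, shallow once
        # at the end (their area changes little)
        geo_idx = range(len(dates)) if deep else [len(dates) - 1]
        for j in geo_idx:
            o, b, h = geoms[j]
            g_rows.append(
                {
                    "specimen_id": spec.specimen_id,
                    "date": dates[j].date().isoformat(),
                    "oral_diameter_mm": o + rng.normal(0.0, noise.calliper_sd_mm),
                    "basal_diameter_mm": b + rng.normal(0.0, noise.calliper_sd_mm),
                    "height_mm": h + rng.normal(0.0, noise.calliper_sd_mm),
                    "tissue_fraction": tissue,
                }
            )

        mass = 4.0 + 0.012 * oral0 ** 2 + rng.normal(0.0, 0.3)  # initial dry mass, g
        masses = [mass]
        for k, season in enumerate(seasons):
            row = stats_idx.loc[(dep, season)]
            g_true = (
                config.response.true_g(
                    row["mean_temp_C"], row["temp_variability_C"], novel=novel
                )
                + u_g
                + rng.normal(0.0, config.response.residual_sd)
            )
            # area the rate pipeline will use for this growth period
            area = area_of(k) if deep else area_of(len(dates) - 1)
            dm = g_true * area * season_days[k] / 1000.0
            masses.append(masses[-1] + dm)

            r_true = (
                resp_model.true_r(deep, season)
                + u_r
                + rng.normal(0.0, resp_model.residual_sd)
            )
            o2_start = 250.0 + rng.normal(0.0, 2.0)
            duration = 6.0
            volume = 0.8
            drop = r_true * area * duration / 24.0 / volume  # umol L-1
            blank = noise.blank_drift
            i_rows.append(
                {
                    "specimen_id": spec.specimen_id,
                    "station": dep,
                    "season": season,
                    "control": 0,
                    "o2_start_umol_l": o2_start,
                    "o2_end_umol_l": o2_start
                    - drop
                    - blank
                    + rng.normal(0.0, noise.o2_probe_sd),
                    "vial_volume_l": volume,
                    "duration_h": duration,
                    "bath_temp_C": bath_ts[season],
                }
            )
            r_rows.append(
                {
                    "specimen_id": spec.specimen_id,
                    "season": season,
                    "station": dep,
                    "g_true": g_true,
                    "g_rel_true": 100.0 * dm / (masses[-2] * season_days[k]),
                    "resp_true": r_true,
                    "area_true": area,
                    "growth_days": season_days[k],
                }
            )

        for j, (d, m) in enumerate(zip(dates, masses)):
            season_key = "init" if j == 0 else seasons[j - 1]
            rho_sw = seawater_density(bath_ts[season_key], bath_sal) / 1000.0
            w_rows.append(
                {
                    "specimen_id": spec.specimen_id,
                    "date": d.date().isoformat(),
                    "buoyant_mass_g": m * (1.0 - rho_sw / ARAGONITE_DENSITY)
                    + rng.normal(0.0, noise.balance_sd_g),
                    "bath_temp_C": bath_ts[season_key],
                    "bath_salinity": bath_sal,
                }
            )
            t_rows.append(
                {
                    "specimen_id": spec.specimen_id,
                    "date": d.date().isoformat(),
                    "dry_mass_true_g": m,
                }
            )

    # two seawater control vials per deployment station and season
    for st in config.stations:
        for season in seasons:
            rng = _stream_rng(config.seed, "controls", st.label, season)
            for rep in range(2):
                o2_start = 250.0 + rng.normal(0.0, 2.0)
                i_rows.append(
                    {
                        "specimen_id": f"CTRL-{st.label}-{season}-{rep}",
                        "station": st.label,
                        "season": season,
                        "control": 1,
                        "o2_start_umol_l": o2_start,
                        "o2_end_umol_l": o2_start
                        - noise.blank_drift
                        + rng.normal(0.0, noise.blank_sd),
                        "vial_volume_l": 0.8,
                        "duration_h": 6.0,
                        "bath_temp_C": bath_ts[season],
                    }
                )

    truth = TruthBundle(
        station_stats=stats,
        true_rates=pd.DataFrame(r_rows),
        trajectories=pd.DataFrame(t_rows),
        response=config.response,
        respiration=config.respiration,
    )
    return (
        specimens,
        pd.DataFrame(w_rows),
        pd.DataFrame(g_rows),
        pd.DataFrame(i_rows),
        truth,
    )


def generate_scenario(config: ScenarioConfig) -> SyntheticDataset:
    """Full input-file set for the pipeline: loggers, bottles and cohort."""
    temp_frames = []
    for st in config.stations:
        series = gen_temperature_series(config, st.label)
        temp_frames.append(
            pd.DataFrame(
                {
                    "station_id": st.label,
                    "depth_m": st.depth_m,
                    "timestamp": series.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
                    "temp_C": series.values,
                }
            )
        )
    temperatures = pd.concat(temp_frames, ignore_index=True)

    ws_rows = []
    for st in config.stations:
        for season in config.seasons.labels:
            sample, ph_target = gen_water_samples(config, st.label, season)
            o2_rng = _stream_rng(config.seed, "oxygen", st.label, season)
            ws_rows.append(
                {
                    "station_id": st.label,
                    "season": season,
                    "depth_m": st.depth_m,
                    "temp_C": sample.temperature,
                    "salinity": sample.salinity,
                    "ta_umol_kg": sample.ta,
                    "dic_umol_kg": sample.dic,
                    "po4_umol_kg": sample.phosphate,
                    "sioh4_umol_kg": sample.silicate,
                    "oxygen_umol_kg": st.seasonal_oxygen(sample.temperature)
                    + o2_rng.normal(0.0, 3.0),
                    "ph_target": ph_target,
                }
            )
    water_samples = pd.DataFrame(ws_rows)

    stats = station_season_stats(config)
    specimens, weighings, geometry, incubations, truth = gen_coral_cohort(
        config, stats
    )
    return SyntheticDataset(
        specimens=specimens,
        weighings=weighings,
        geometry=geometry,
        incubations=incubations,
        temperatures=temperatures,
        water_samples=water_samples,
        truth=truth,
        config=config,
    )
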