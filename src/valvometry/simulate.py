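"""Synthetic clam behavior, environmental drivers, and sensor transduction.

Generates the study conditions of a tropical indoor mesocosm housing
photosymbiotic giant clams under mixed sun/LED lighting, with known ground
truth for every pipeline stage:

* diurnal PAR: an asymmetric solar hump peaking mid-morning (~600 umol
  photons/m2/s) over an LED square wave (08:00-20:00), dark nights;
* pH and DO diurnal cycles within the observed ranges (pH 8.1-8.25, DO
  6.89-9.94 mg/L), peaking at night — in the emulated mesocosm the diurnal
  carbonate/oxygen cycle is respiration-dominated, so both are in phase with
  the clams' nocturnal closure and anti-phased with light; temperature held
  at 25 +/- <0.25 degC; chlorophyll-a with episodic bloom spikes and
  independent phycoerythrin bursts;
* clam gape: daytime basking (~12.7% closed) vs nocturnal partial closure
  (~44.1% closed, SD ~31%) via a logistic light response around 100 umol
  photons/m2/s, AR(1) jitter with 1-h correlation time, nocturnal
  valve-claps from an inhomogeneous Poisson process whose nightly rate is
  modulated by chlorophyll lagged 4 days, long-tailed log-normal clap
  durations mostly under 100 s, and rare long daytime threat closures;
* Hall-sensor transduction: offset ~2500 mV, gain, Gaussian noise, slow
  drift, optional rail-fault injection, clipped to [0, 5000] mV.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .series import EnvSeries, ValveSeries


@dataclass
class LightConfig:
    solar_peak_h: float = 9.0        # local clock hour of the solar maximum
    solar_amplitude: float = 540.0   # umol photons/m2/s at the peak
    sigma_rise_h: float = 2.0        # morning flank width
    sigma_fall_h: float = 2.0        # afternoon flank width
    led_amplitude: float = 60.0      # LED square wave level
    led_on_h: float = 8.0
    led_off_h: float = 20.0
    weather_sd: float = 0.10         # day-to-day lognormal solar variability
    midnight_artifact: bool = False  # one-sample logger spike at 00:00
    midnight_artifact_par: float = 400.0


@dataclass
class BehaviorConfig:
    bright_closure: float = 0.127    # basking baseline closure fraction
    dark_closure: float = 0.441      # nocturnal partial-closure baseline
    light_threshold: float = 100.0   # umol photons/m2/s logistic midpoint
    light_width: float = 20.0        # logistic softness
    jitter_sd: float = 0.04          # AR(1) posture jitter, stationary SD
    jitter_tau_s: float = 3600.0     # jitter correlation time
    clap_rate_night_per_h: float = 0.75   # per clam; ~34 claps/day pooled over 3
    clap_rate_day_per_h: float = 0.15
    clap_duration_median_s: float = 40.0
    clap_duration_sigma: float = 0.715   # ~90% of claps under 100 s
    clap_depth: float = 0.95             # closure fraction at the clap peak
    long_closure_rate_per_day: float = 0.15
    long_closure_median_s: float = 900.0
    long_closure_sigma: float = 0.5


@dataclass
class CouplingConfig:
    lag_days: int = 4          # closure frequency lags chlorophyll by this
    chl_gain: float = 0.8      # log-chl anomaly -> log clap-rate multiplier
    clam_gain_factors: tuple = (1.0, 0.9, 0.6)  # per-clam response strength
    ph_mid: float = 8.175
    ph_amplitude: float = 0.06
    ph_range: tuple = (8.1, 8.25)
    do_mid: float = 8.4
    do_amplitude: float = 1.3
    do_range: tuple = (6.89, 9.94)
    env_peak_h: float = 0.0    # pH/DO diurnal maximum (midnight: anti-phased
                               # with light, in phase with nocturnal closure)
    temp_mean: float = 25.0
    temp_amplitude: float = 0.1


@dataclass
class FaultSpec:
    clam_id: int
    start_h: float      # hours from the start of the simulation
    duration_s: float
    kind: str = "high"  # "high" (~5000 mV) or "low" (~0 mV)


@dataclass
class SensorConfig:
    offset_mv: float = 2500.0
    gain_mv: float = 800.0        # mV per unit closure fraction; sign flips
                                  # with magnet orientation
    noise_sd_mv: float = 8.0
    drift_mv_per_day: float = 3.0
    drift_walk_sd_mv: float = 3.0  # daily random-walk drift increment
    rail_high_mv: float = 4990.0
    rail_low_mv: float = 5.0
    faults: list = field(default_factory=list)
    quantize: bool = True          # round to integer mV (ADC)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_days: int = 60
    n_clams: int = 3
    start: str = "2021-05-03"
    grid_s: float = 5.0
    par_grid_s: float = 15.0
    env_grid_s: float = 900.0
    light: LightConfig = field(default_factory=LightConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    sensor: SensorConfig = field(default_factory=SensorConfig)

    def __post_init__(self):
        if self.n_days < 1 or self.n_clams < 1:
            raise ValueError("n_days and n_clams must be positive")
        for g in (self.grid_s, self.par_grid_s, self.env_grid_s):
            if 86400 % g != 0:
                raise ValueError(f"grid {g}s must divide one day evenly")


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    events: pd.DataFrame          # clam_id, start, duration_s, kind
    faults: list
    lag_days: int
    bloom_days: list
    config: SimulationConfig

    def daily_counts(self, pooled: bool = True) -> pd.DataFrame:
        df = self.events.copy()
        df["date"] = pd.to_datetime(df["start"]).dt.date
        keys = ["date"] if pooled else ["date", "clam_id"]
        return df.groupby(keys).size().to_frame("count")


def _time_index(cfg: SimulationConfig, step_s: float) -> pd.DatetimeIndex:
    n = int(cfg.n_days * 86400 / step_s)
    return pd.date_range(cfg.start, periods=n, freq=pd.Timedelta(seconds=step_s))


def _hour_of_day(idx: pd.DatetimeIndex) -> np.ndarray:
    return (idx - idx.normalize()).total_seconds().to_numpy() / 3600.0


def simulate_light(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> EnvSeries:
    """PAR on the fine light grid: solar hump + LED square wave.

    With ``rng=None`` the curve is deterministic (no weather variability).
    """
    lc = cfg.light
    idx = _time_index(cfg, cfg.par_grid_s)
    h = _hour_of_day(idx)
    sigma = np.where(h <= lc.solar_peak_h, lc.sigma_rise_h, lc.sigma_fall_h)
    solar = lc.solar_amplitude * np.exp(-0.5 * ((h - lc.solar_peak_h) / sigma) ** 2)
    solar[solar < 1.0] = 0.0  # truncate the far tails: true night is dark
    if rng is not None and lc.weather_sd > 0:
        day = (idx - idx[0]).days.to_numpy()
        factor = np.exp(rng.normal(0.0, lc.weather_sd, size=cfg.n_days))
        solar = solar * factor[day]
    led = np.where((h >= lc.led_on_h) & (h < lc.led_off_h), lc.led_amplitude, 0.0)
    par = solar + led
    if lc.midnight_artifact:
        par[h == 0.0] += lc.midnight_artifact_par
    return EnvSeries("PAR", pd.Series(par, index=idx),
                     nominal_period_s=cfg.par_grid_s)


def _bloom_factor(
    cfg: SimulationConfig, rng: np.random.Generator, steps_per_day: int
) -> tuple[np.ndarray, list]:
    """Multiplicative bloom envelope (episodic bursts with slow die-off)."""
    n = cfg.n_days * steps_per_day
    t_days = np.arange(n) / steps_per_day
    factor = np.ones(n)
    n_blooms = rng.poisson(cfg.n_days / 12.0)
    bloom_days = []
    for _ in range(n_blooms):
        peak = rng.uniform(1.0, max(1.5, cfg.n_days - 1.0))
        amp = rng.lognormal(np.log(3.0), 0.4)
        rise = rng.uniform(0.8, 1.5)
        decay = rng.uniform(2.5, 4.5)
        shape = np.where(
            t_days < peak,
            np.exp(-0.5 * ((t_days - peak) / rise) ** 2),
            np.exp(-(t_days - peak) / decay),
        )
        factor += amp * shape
        bloom_days.append(float(peak))
    return factor, sorted(bloom_days)


def simulate_env(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, EnvSeries], list]:
    """pH, DO, temperature, chlorophyll-a and phycoerythrin on the 15-min grid.

    Returns (series-by-variable, bloom_peak_days). pH/DO are clipped into
    their observed ranges; chlorophyll is a slowly wandering baseline times
    the bloom envelope.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    cc = cfg.coupling
    idx = _time_index(cfg, cfg.env_grid_s)
    h = _hour_of_day(idx)
    steps_per_day = int(86400 / cfg.env_grid_s)
    diurnal = np.cos(2.0 * np.pi * (h - cc.env_peak_h) / 24.0)

    ph = cc.ph_mid + cc.ph_amplitude * diurnal + rng.normal(0, 0.004, len(idx))
    ph = np.clip(ph, *cc.ph_range)
    do = cc.do_mid + cc.do_amplitude * diurnal + rng.normal(0, 0.05, len(idx))
    do = np.clip(do, *cc.do_range)
    temp = cc.temp_mean + cc.temp_amplitude * diurnal + rng.normal(0, 0.02, len(idx))

    # chlorophyll: lognormal AR(1) baseline (multi-day memory) x bloom bursts
    phi = np.exp(-cfg.env_grid_s / (86400.0 * 2.0))
    eps = rng.normal(0, 0.25 * np.sqrt(1 - phi**2), len(idx))
    logbase = lfilter([1.0], [1.0, -phi], eps)
    bloom, bloom_days = _bloom_factor(cfg, rng, steps_per_day)
    chl = 5.0 * np.exp(logbase) * bloom
    pe_eps = rng.normal(0, 0.2 * np.sqrt(1 - phi**2), len(idx))
    pe_base = lfilter([1.0], [1.0, -phi], pe_eps)
    pe_bloom, _ = _bloom_factor(cfg, rng, steps_per_day)
    pe = 2.0 * np.exp(pe_base) * pe_bloom

    out = {
        "pH": EnvSeries("pH", pd.Series(ph, index=idx), nominal_period_s=cfg.env_grid_s),
        "DO": EnvSeries("DO", pd.Series(do, index=idx), nominal_period_s=cfg.env_grid_s),
        "temperature": EnvSeries(
            "temperature", pd.Series(temp, index=idx), nominal_period_s=cfg.env_grid_s
        ),
        "chlorophyll_a": EnvSeries(
            "chlorophyll_a", pd.Series(chl, index=idx), nominal_period_s=cfg.env_grid_s
        ),
        "phycoerythrin": EnvSeries(
            "phycoerythrin", pd.Series(pe, index=idx), nominal_period_s=cfg.env_grid_s
        ),
    }
    return out, bloom_days


def daily_log_chl(chl: EnvSeries) -> pd.Series:
    daily = chl.data.resample("1D").mean()
    return np.log(daily)


def _clap_day_rates(
    cfg: SimulationConfig, log_chl_daily: np.ndarray, gain_factor: float
) -> tuple[np.ndarray, np.ndarray]:
    """Expected clap counts per (night, day) window for each simulation day.

    The nightly rate is modulated by the log-chl anomaly ``lag_days`` earlier;
    days with no lagged observation use the baseline rate.
    """
    bc, cc = cfg.behavior, cfg.coupling
    anom = log_chl_daily - np.nanmean(log_chl_daily)
    lagged = np.zeros(cfg.n_days)
    lag = cc.lag_days
    if lag < cfg.n_days:
        lagged[lag:] = anom[: cfg.n_days - lag]
    mult = np.clip(np.exp(cc.chl_gain * gain_factor * lagged), 0.1, 6.0)
    night_expect = bc.clap_rate_night_per_h * 14.0 * mult
    day_expect = np.full(cfg.n_days, bc.clap_rate_day_per_h * 10.0)
    return night_expect, day_expect


def simulate_daily_clap_counts(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Fast daily-resolution path: chlorophyll + pooled true clap counts.

    Shares the rate model of :func:`simulate_behavior` without generating
    sample-level series; used for lag-recovery experiments.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    env, _ = simulate_env(cfg, rng)
    logc = daily_log_chl(env["chlorophyll_a"]).to_numpy()[: cfg.n_days]
    counts = np.zeros(cfg.n_days, dtype=int)
    for c in range(cfg.n_clams):
        gf = cfg.coupling.clam_gain_factors[c % len(cfg.coupling.clam_gain_factors)]
        night, day = _clap_day_rates(cfg, logc, gf)
        counts += rng.poisson(night) + rng.poisson(day)
    dates = pd.date_range(cfg.start, periods=cfg.n_days, freq="1D")
    chl_daily = env["chlorophyll_a"].data.resample("1D").mean().reindex(dates)
    return pd.DataFrame({"closure_count": counts,
                         "mean_chl_rfu": chl_daily.to_numpy()}, index=dates)


def simulate_behavior(
    cfg: SimulationConfig,
    light: EnvSeries,
    chl: EnvSeries,
    rng: np.random.Generator | None = None,
) -> tuple[dict[int, pd.Series], GroundTruth]:
    """True closure-fraction series per clam plus the ground-truth event list.

    Baseline closure is a logistic function of instantaneous PAR crossing the
    light threshold between the bright and dark means, with AR(1) jitter.
    Valve-claps arrive as an inhomogeneous Poisson process (nightly rate
    modulated by lagged chlorophyll); each clap rises rapidly to near-full
    closure, holds, and reopens after a log-normal duration. Rare long
    daytime closures form a separate sparse process.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    bc = cfg.behavior
    idx = _time_index(cfg, cfg.grid_s)
    n = len(idx)
    par = light.data.reindex(idx, method="ffill").bfill().to_numpy()
    baseline = bc.bright_closure + (bc.dark_closure - bc.bright_closure) / (
        1.0 + np.exp((par - bc.light_threshold) / bc.light_width)
    )
    logc = daily_log_chl(chl).to_numpy()[: cfg.n_days]

    phi = np.exp(-cfg.grid_s / bc.jitter_tau_s)
    closure: dict[int, pd.Series] = {}
    rows = []
    t0 = idx[0]
    for c in range(cfg.n_clams):
        clam_id = c + 1
        eps = rng.normal(0, bc.jitter_sd * np.sqrt(1 - phi**2), n)
        jitter = lfilter([1.0], [1.0, -phi], eps)
        x = np.clip(baseline + jitter, 0.0, 1.0)

        gf = cfg.coupling.clam_gain_factors[c % len(cfg.coupling.clam_gain_factors)]
        night_expect, day_expect = _clap_day_rates(cfg, logc, gf)
        events = []
        for d in range(cfg.n_days):
            k_n = rng.poisson(night_expect[d])
            starts = d * 24.0 + 14.0 + np.sort(rng.uniform(0.0, 14.0, k_n))
            events += [(s, "clap_night") for s in starts]
            k_d = rng.poisson(day_expect[d])
            starts = d * 24.0 + 4.0 + np.sort(rng.uniform(0.0, 10.0, k_d))
            events += [(s, "clap_day") for s in starts]
            k_l = rng.poisson(bc.long_closure_rate_per_day)
            starts = d * 24.0 + 5.0 + np.sort(rng.uniform(0.0, 8.0, k_l))
            events += [(s, "long_day") for s in starts]
        events.sort()

        for start_h, kind in events:
            if kind == "long_day":
                dur = rng.lognormal(np.log(bc.long_closure_median_s),
                                    bc.long_closure_sigma)
                depth = 0.92
            else:
                dur = rng.lognormal(np.log(bc.clap_duration_median_s),
                                    bc.clap_duration_sigma)
                depth = bc.clap_depth
            dur = max(dur, 3.0 * cfg.grid_s)
            i0 = int(round(start_h * 3600.0 / cfg.grid_s))
            i1 = min(n, i0 + int(round(dur / cfg.grid_s)))
            if i0 >= n:
                continue
            m = i1 - i0
            rise = max(1, min(2, m // 3))
            fall = max(1, min(3, m // 3))
            prof = np.full(m, depth)
            prof[:rise] = np.linspace(x[i0], depth, rise + 1)[1:]
            if fall:
                prof[m - fall:] = np.linspace(depth, x[i1 - 1], fall + 1)[:-1]
            np.maximum(x[i0:i1], prof, out=x[i0:i1])
            rows.append(
                {"clam_id": clam_id,
                 "start": t0 + pd.Timedelta(hours=start_h),
                 "duration_s": float(dur), "kind": kind}
            )
        closure[clam_id] = pd.Series(np.clip(x, 0.0, 1.0), index=idx,
                                     name=f"clam{clam_id}")

    truth = GroundTruth(
        events=pd.DataFrame(rows),
        faults=list(cfg.sensor.faults),
        lag_days=cfg.coupling.lag_days,
        bloom_days=[],
        config=cfg,
    )
    return closure, truth


def transduce(
    cfg: SimulationConfig,
    closure: pd.Series,
    clam_id: int,
    rng: np.random.Generator | None = None,
    quantize: bool | None = None,
) -> ValveSeries:
    """Hall-sensor transduction: affine map + noise + drift + faults + clipping.

    With zero noise and drift the output is an exact affine map of closure
    (set ``quantize=False`` to avoid ADC rounding). Fault spans from
    ``cfg.sensor.faults`` matching this clam are replaced with rail values.
    """
    sc = cfg.sensor
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 100 + clam_id)
    if quantize is None:
        quantize = sc.quantize
    x = closure.to_numpy()
    n = len(x)
    t_days = np.arange(n) * cfg.grid_s / 86400.0
    mv = sc.offset_mv + sc.gain_mv * x
    if sc.noise_sd_mv > 0:
        mv = mv + rng.normal(0, sc.noise_sd_mv, n)
    if sc.drift_mv_per_day != 0 or sc.drift_walk_sd_mv > 0:
        n_days = int(np.ceil(t_days[-1])) + 1 if n else 1
        walk = np.cumsum(rng.normal(0, sc.drift_walk_sd_mv, n_days))
        drift = sc.drift_mv_per_day * t_days + np.interp(
            t_days, np.arange(n_days), walk
        )
        mv = mv + drift
    for f in sc.faults:
        if f.clam_id != clam_id:
            continue
        i0 = int(round(f.start_h * 3600.0 / cfg.grid_s))
        i1 = min(n, i0 + int(round(f.duration_s / cfg.grid_s)))
        mv[i0:i1] = sc.rail_high_mv if f.kind == "high" else sc.rail_low_mv
    mv = np.clip(mv, 0.0, 5000.0)
    if quantize:
        mv = np.round(mv)
    return ValveSeries(clam_id=clam_id,
                       data=pd.Series(mv, index=closure.index),
                       nominal_period_s=cfg.grid_s)


@dataclass
class SimulatedDataset:
    valve: list[ValveSeries]
    env: dict[str, EnvSeries]
    truth: GroundTruth


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Full deterministic simulation: light, water chemistry, behavior, sensors."""
    rng = np.random.default_rng(cfg.seed)
    light = simulate_light(cfg, rng)
    env, bloom_days = simulate_env(cfg, rng)
    env["PAR"] = light
    closure, truth = simulate_behavior(cfg, light, env["chlorophyll_a"], rng)
    truth.bloom_days = bloom_days
    valve = [transduce(cfg, closure[cid], cid, rng) for cid in sorted(closure)]
    return SimulatedDataset(valve=valve, env=env, truth=truth)


# ---------------------------------------------------------------- fixtures --

VALVE_LOG_NAME = "valve_log.tsv"
TS_FMT = "%Y-%m-%d %H:%M:%S"


def write_valve_log(valve: list[ValveSeries], path) -> None:
    """Write the tab-delimited valve-log dialect (UTF-8, LF, header row)."""
    idx = valve[0].timestamps
    for v in valve[1:]:
        if not v.timestamps.equals(idx):
            raise ValueError("valve series must share a grid to share a log")
    cols = "\t".join(f"mv_sensor{v.clam_id}" for v in valve)
    arrays = [v.voltage_mv for v in valve]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"timestamp\t{cols}\n")
        stamps = idx.strftime(TS_FMT)
        for i, ts in enumerate(stamps):
            vals = "\t".join(_fmt_mv(a[i]) for a in arrays)
            fh.write(f"{ts}\t{vals}\n")


def _fmt_mv(v: float) -> str:
    if np.isnan(v):
        return "nan"
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_env_csv(env: EnvSeries, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"timestamp,{env.variable}\n")
        stamps = env.timestamps.strftime(TS_FMT)
        for ts, v in zip(stamps, env.values):
            fh.write(f"{ts},{float(v)!r}\n")


def write_fixtures(dataset: SimulatedDataset, out_dir) -> dict:
    """Write valve log, env CSVs, and ground_truth.json; deterministic bytes."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"valve_log": out / VALVE_LOG_NAME}
    write_valve_log(dataset.valve, paths["valve_log"])
    for var, series in sorted(dataset.env.items()):
        p = out / f"env_{var}.csv"
        write_env_csv(series, p)
        paths[f"env_{var}"] = p
    truth = dataset.truth
    gt = {
        "lag_days": truth.lag_days,
        "bloom_days": truth.bloom_days,
        "faults": [asdict(f) for f in truth.faults],
        "events": [
            {"clam_id": int(r.clam_id), "start": r.start.strftime(TS_FMT),
             "duration_s": r.duration_s, "kind": r.kind}
            for r in truth.events.itertuples()
        ],
        "n_days": truth.config.n_days,
        "n_clams": truth.config.n_clams,
        "seed": truth.config.seed,
    }
    p = out / "ground_truth.json"
    with open(p, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(gt, fh, indent=1, sort_keys=True)
    paths["ground_truth"] = p
    return {k: str(v) for k, v in paths.items()}
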