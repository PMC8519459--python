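"""Seeded synthetic logger deployments with ground-truth behaviour labels.

No public raw dataset exists for this kind of deployment, so every pipeline
stage is exercised against a forward model of the study system: adult female
pond turtles in a small outdoor pond at ~47.6 N, tagged over the nesting
season.  The generator produces, per individual, a 1 Hz environmental stream
(temperature, pressure, light), a 10 Hz tri-axial acceleration stream and
metadata (including the RTC drift and its GPS anchors), plus site-level
reference temperatures, 3-h weather and a sunrise/sunset table — together
with the exact behaviour intervals used to drive the sensors.

Daily structure: nocturnal rest just below the surface (mean pressure
0.037 bar) with breathing bouts (~22.5 min apart, ~9.6 inhalations per bout,
~4.4 cm surfacing rises); foraging from one hour before sunrise; on
favourable days an emerged basking bout around solar noon (heating ramps,
cooling plateaus and brief dives); evening activity until one hour after
sunset; and, in a mid-season window, evening nest-digging bouts (~73 min)
with strong pitch oscillation, low roll variance and doubled VeDBA.

State-specific VeDBA means default to the field regime: rest 0.117, forage
0.173, bask 0.151, evening 0.160, digging 0.31 m s⁻².  The dynamic noise of
three i.i.d. normal axes with per-axis sd s has E[VeDBA] = s * 2 sqrt(2/pi)
(chi distribution, 3 dof), so per-axis sds are set analytically from the
target means; the injected noise is high-passed above the decomposition
cutoff so the analysis recovers the targets.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit

from . import logger_io
from .logger_io import DeploymentMeta
from .motion_signal import GRAVITY, lowpass

#: E[chi_3] = sqrt(2) * Gamma(2) / Gamma(3/2) = 2 sqrt(2/pi)
CHI3_MEAN = 2.0 * math.sqrt(2.0 / math.pi)

# state codes
NIGHT, FORAGE, BASK, DIVE, EVENING, DIG = 0, 1, 2, 3, 4, 5
STATE_NAMES = {
    NIGHT: "night_rest", FORAGE: "forage", BASK: "bask", DIVE: "dive",
    EVENING: "evening_active", DIG: "dig",
}

#: biometrics of the default eight-animal roster (g, mm)
DEFAULT_BODY_MASS_G = (549.0, 551.0, 670.0, 730.0, 726.0, 790.0, 962.0,
                       1015.0)
DEFAULT_CARAPACE_MM = (135.0, 138.0, 150.0, 155.0, 161.0, 155.0, 169.0,
                       177.0)
LOGGER_MASS_G = 7.0


class GeneratorConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """All tunables of the forward model (defaults = study conditions)."""

    n_individuals: int = 8
    n_days: int = 20              # full field season: 137
    season_start: str = "2017-04-14"
    latitude_deg: float = 47.6
    longitude_deg: float = 7.54

    # schedule
    night_offset_h: float = 1.0   # night = sunset+1h .. sunrise-1h
    bask_logit_intercept: float = 1.8
    bask_slope_cloud: float = -2.5
    bask_slope_day_length: float = 0.75
    bask_slope_rain: float = -0.35
    overcast_cutoff: float = 0.9  # cloud above this suppresses basking
    bask_duration_mean_h: float = 5.1
    bask_duration_sd_h: float = 1.5

    # basking thermals
    heating_rate_c_per_min: float = 0.45
    heating_rate_sd: float = 0.08
    ramp_s: tuple = (480.0, 960.0)
    plateau_s: tuple = (600.0, 1800.0)
    plateau_cooling_c_per_min: float = 0.03
    dive_prob: float = 0.25
    dive_s: tuple = (120.0, 240.0)
    bask_cap_above_air_c: float = 12.0

    # nesting
    nesting_window_frac: tuple = (0.30, 0.65)
    attempts_mean: float = 3.25
    attempts_sd: float = 1.75
    dig_duration_mean_min: float = 73.0
    dig_duration_sd_min: float = 38.0
    dig_pitch_amp_deg: tuple = (12.0, 19.0)
    dig_freq_hz: float = 0.25

    # breathing
    night_pressure_mean_bar: float = 0.037
    night_pressure_sd_bar: float = 0.016
    interbout_mean_min: float = 22.5
    inhalations_per_bout_mean: float = 9.6
    inhalation_spacing_s: float = 17.0
    inhalation_spacing_sd_s: float = 4.0
    rise_mean_cm: float = 4.4
    rise_sd_cm: float = 3.1

    # state VeDBA means, m s^-2 (field regime)
    vedba_rest: float = 0.117
    vedba_forage: float = 0.173
    vedba_bask: float = 0.151
    vedba_evening: float = 0.160
    vedba_dig: float = 0.31

    # environment
    light_peak_lux: float = 80000.0
    underwater_light_factor: float = 0.2
    cloud_attenuation: float = 0.88
    cloud_mean: float = 0.45
    cloud_rho: float = 0.55
    cloud_sd: float = 0.22
    diurnal_amp_c: float = 5.5

    # RTC drift (minutes accumulated over a reference span)
    drift_mean_min: float = 21.30
    drift_sd_min: float = 2.72
    drift_span_days: float = 141.0

    def __post_init__(self):
        if self.n_individuals < 1 or self.n_days < 2:
            raise GeneratorConfigError("need >= 1 individual and >= 2 days")
        f0, f1 = self.nesting_window_frac
        if not (0.0 <= f0 < f1 <= 1.0):
            raise GeneratorConfigError(
                "nesting window must lie within the deployment"
            )
        for name in ("night_pressure_mean_bar", "night_pressure_sd_bar",
                     "interbout_mean_min", "inhalations_per_bout_mean",
                     "rise_mean_cm", "rise_sd_cm", "vedba_rest",
                     "vedba_forage", "vedba_bask", "vedba_evening",
                     "vedba_dig"):
            if getattr(self, name) <= 0:
                raise GeneratorConfigError(f"{name} must be > 0")

    @property
    def duration_s(self) -> float:
        return self.n_days * 86400.0

    def vedba_by_state(self) -> dict:
        return {
            NIGHT: self.vedba_rest, FORAGE: self.vedba_forage,
            BASK: self.vedba_bask, DIVE: self.vedba_bask,
            EVENING: self.vedba_evening, DIG: self.vedba_dig,
        }


@dataclass
class TruthLabels:
    """Ground truth behind the sensor streams (all times are true seconds)."""

    states: pd.DataFrame        # individual,state,t_start,t_end,success
    phases: pd.DataFrame        # individual,day,phase,t_start,t_end
    breathing_bouts: pd.DataFrame  # individual,t_start,t_end,n_inhalations
    inhalations: pd.DataFrame   # individual,t,rise_cm
    heating: pd.DataFrame       # individual,t_start,t_end (bask ramps)
    digs: pd.DataFrame          # individual,t_start,t_end,duration_min,success


def _solar_table(cfg: GeneratorConfig) -> pd.DataFrame:
    """Sunrise/sunset (seconds since epoch) per deployment day."""
    start = pd.Timestamp(cfg.season_start)
    doy0 = int(start.day_of_year)
    days = np.arange(cfg.n_days + 1)  # +1: the last night needs sunrise d+1
    doy = doy0 + days
    decl = np.radians(23.44) * np.sin(2 * np.pi * (doy - 80) / 365.25)
    lat = np.radians(cfg.latitude_deg)
    cos_h = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    half_day_h = np.degrees(np.arccos(cos_h)) / 15.0
    noon_h = 12.0 - cfg.longitude_deg / 15.0
    sunrise = days * 86400.0 + (noon_h - half_day_h) * 3600.0
    sunset = days * 86400.0 + (noon_h + half_day_h) * 3600.0
    return pd.DataFrame({
        "date": days, "sunrise": sunrise, "sunset": sunset,
        "noon": days * 86400.0 + noon_h * 3600.0,
    })


def _season_mean_temp(doy) -> np.ndarray:
    """Smooth seasonal mean air temperature (degC) for a NE-France spring
    to late summer."""
    return 12.0 + 9.0 * np.sin(np.pi * (np.asarray(doy, float) - 95.0)
                               / 220.0)


def _generate_weather(cfg: GeneratorConfig, sun: pd.DataFrame,
                      rng: np.random.Generator):
    """Daily cloud AR(1) process, 3-h airport weather and daily anomalies."""
    n = cfg.n_days
    cloud = np.empty(n)
    c = cfg.cloud_mean
    for d in range(n):
        c = cfg.cloud_mean + cfg.cloud_rho * (c - cfg.cloud_mean) \
            + rng.normal(0.0, cfg.cloud_sd)
        c = float(np.clip(c, 0.0, 1.0))
        cloud[d] = c
    anom = np.empty(n)
    a = 0.0
    for d in range(n):
        a = 0.7 * a + rng.normal(0.0, 1.3)
        anom[d] = a

    start = pd.Timestamp(cfg.season_start)
    doy0 = int(start.day_of_year)
    t3 = np.arange(0.0, cfg.duration_s, 3 * 3600.0)
    day3 = np.minimum((t3 // 86400).astype(int), n - 1)
    hour3 = (t3 % 86400.0) / 3600.0
    amp = cfg.diurnal_amp_c * (1.0 - 0.55 * cloud[day3])
    t_air = (_season_mean_temp(doy0 + day3) + anom[day3]
             + amp * np.cos(2 * np.pi * (hour3 - 13.0) / 24.0)
             + rng.normal(0.0, 0.4, len(t3)))
    rain = np.where(
        cloud[day3] > 0.55,
        rng.exponential(0.8, len(t3)) * np.clip(cloud[day3] - 0.4, 0, None),
        0.0,
    )
    weather = pd.DataFrame({
        "time": t3, "t_air_mulhouse": t_air, "cloud_frac": cloud[day3],
        "rain_mm": rain,
    })
    return weather, cloud, rain


def _generate_reference(cfg: GeneratorConfig, weather: pd.DataFrame,
                        rng: np.random.Generator) -> pd.DataFrame:
    """10-min field reference series: air and three water strata.

    Water temperatures are exponentially smoothed, increasingly damped and
    lagged copies of field air temperature — surface (tau ~ 5 h), 20 cm
    (tau ~ 16 h), bottom (tau ~ 72 h, slightly cooler).
    """
    t = np.arange(0.0, cfg.duration_s, 600.0)
    base = np.interp(t, weather["time"], weather["t_air_mulhouse"])
    t_air = 0.053 + 1.014 * base + rng.normal(0.0, 0.3, len(t))

    def ema(x, tau_s, x0):
        alpha = 600.0 / tau_s
        # y_t = (1-alpha) y_{t-1} + alpha x_t  via IIR filter
        y = lfilter([alpha], [1.0, -(1.0 - alpha)], x,
                    zi=[(1.0 - alpha) * x0])[0]
        return y

    m0 = float(np.mean(base[:144])) if len(base) >= 144 else float(base[0])
    surface = ema(base, 5 * 3600.0, m0) + rng.normal(0.0, 0.05, len(t))
    t20 = ema(surface, 16 * 3600.0, m0) - 0.3 + rng.normal(0.0, 0.05, len(t))
    bottom = ema(t20, 72 * 3600.0, m0) - 0.8 + rng.normal(0.0, 0.05, len(t))
    return pd.DataFrame({
        "time": t, "t_air": t_air, "t_surface": surface, "t_20cm": t20,
        "t_bottom": bottom,
    })


def _interp_fn(t_grid, values):
    t_grid = np.asarray(t_grid, float)
    values = np.asarray(values, float)
    return lambda x: np.interp(x, t_grid, values)


@dataclass
class _BaskSegment:
    kind: str      # ramp | plateau | dive
    t0: float
    t1: float
    temp0: float
    temp1: float


@dataclass
class _DaySchedule:
    day: int
    night_start: float            # sunset + offset of this day
    night_end: float              # sunrise - offset of the NEXT day (clipped)
    morning_start: float          # sunrise - offset (clipped >= 0)
    bask: tuple | None            # (start, end)
    segments: list = field(default_factory=list)
    digs: list = field(default_factory=list)   # (t0, t1, amp, success)


@dataclass
class _IndividualSchedule:
    index: int
    meta: DeploymentMeta
    drift_rate: float             # true = logger * (1 + rate)
    days: list = field(default_factory=list)
    night_depth: dict = field(default_factory=dict)     # day -> bar
    bout_spans: list = field(default_factory=list)      # (t0, t1, n)
    inhal_times: np.ndarray = None
    inhal_rises: np.ndarray = None

    def to_logger_time(self, t_true):
        return np.asarray(t_true, float) / (1.0 + self.drift_rate)


def _schedule_bask(cfg, start, end, water_fn, air_fn, rng):
    """Lay out ramp/plateau/dive segments with a precomputed temperature
    path so the env synthesis is purely piecewise linear."""
    segments = []
    temp = float(water_fn(start)) + 0.3
    cur = start
    while end - cur >= 360.0:
        cap = float(air_fn(cur)) + cfg.bask_cap_above_air_c
        dur = min(float(rng.uniform(*cfg.ramp_s)), end - cur)
        rate = float(np.clip(rng.normal(cfg.heating_rate_c_per_min,
                                        cfg.heating_rate_sd), 0.25, 0.65))
        t1 = min(temp + rate * dur / 60.0, cap)
        if t1 - temp >= 0.25 * dur / 60.0:
            segments.append(_BaskSegment("ramp", cur, cur + dur, temp, t1))
            temp = t1
            cur += dur
        if end - cur < 240.0:
            break
        if rng.uniform() < cfg.dive_prob or temp >= cap - 1.0:
            dur = min(float(rng.uniform(*cfg.dive_s)), end - cur)
            w = float(water_fn(cur)) + 0.3
            segments.append(_BaskSegment("dive", cur, cur + dur, temp, w))
            temp = w
            cur += dur
        else:
            dur = min(float(rng.uniform(*cfg.plateau_s)), end - cur)
            t1 = temp - cfg.plateau_cooling_c_per_min * dur / 60.0
            segments.append(_BaskSegment("plateau", cur, cur + dur, temp, t1))
            temp = t1
            cur += dur
    if cur < end and segments:
        # trailing stretch too short for a ramp: hold as plateau
        t1 = temp - cfg.plateau_cooling_c_per_min * (end - cur) / 60.0
        segments.append(_BaskSegment("plateau", cur, end, temp, t1))
    return segments


def _schedule_individual(cfg, idx, sun, cloud, rain_daily, day_length,
                         water_fn, air_fn, seed) -> _IndividualSchedule:
    rng = np.random.default_rng(np.random.SeedSequence([seed, idx, 11]))
    n = cfg.n_days
    if idx < len(DEFAULT_BODY_MASS_G):
        mass = DEFAULT_BODY_MASS_G[idx]
        length = DEFAULT_CARAPACE_MM[idx]
    else:
        mass = float(np.clip(rng.normal(749.0, 171.0), 400.0, 1200.0))
        length = float(np.clip(rng.normal(155.0, 14.0), 120.0, 190.0))
    drift_total_min = rng.normal(cfg.drift_mean_min, cfg.drift_sd_min)
    rate = drift_total_min * 60.0 / (cfg.drift_span_days * 86400.0)
    t_end_true = cfg.duration_s - 1.0
    t_end_logger = t_end_true / (1.0 + rate)

    # basking presence probability from standardized daily weather
    def z(x):
        x = np.asarray(x, float)
        sd = np.std(x, ddof=1)
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    logit = (cfg.bask_logit_intercept
             + cfg.bask_slope_cloud * z(cloud)
             + cfg.bask_slope_day_length * z(day_length)
             + cfg.bask_slope_rain * z(rain_daily))
    p = expit(logit)
    p = np.where(cloud > cfg.overcast_cutoff, p * 0.05, p)
    bask_present = rng.uniform(size=n) < p

    # nesting attempt days
    w0 = int(np.floor(cfg.nesting_window_frac[0] * n))
    w1 = int(np.ceil(cfg.nesting_window_frac[1] * n))
    window_days = np.arange(w0, min(w1, n - 1))
    if cfg.attempts_mean <= 0:
        n_attempts = 0
    else:
        if len(window_days) == 0:
            raise GeneratorConfigError("nesting window outside deployment")
        n_attempts = int(np.clip(round(rng.normal(cfg.attempts_mean,
                                                  cfg.attempts_sd)),
                                 1, len(window_days)))
    dig_days = np.sort(rng.choice(window_days, n_attempts, replace=False)) \
        if n_attempts else np.empty(0, dtype=int)

    sunrise = sun["sunrise"].to_numpy()
    sunset = sun["sunset"].to_numpy()
    noon = sun["noon"].to_numpy()
    off = cfg.night_offset_h * 3600.0

    sched = _IndividualSchedule(
        index=idx,
        meta=DeploymentMeta(
            individual_id=f"T{idx + 1}",
            body_mass_g=mass, carapace_length_mm=length,
            logger_mass_g=LOGGER_MASS_G,
            rtc_anchor_pairs=[(0.0, 0.0), (t_end_logger, t_end_true)],
            observed_nesting_times=[],
        ),
        drift_rate=rate,
    )

    for d in range(n):
        is_dig_day = d in dig_days
        ds = _DaySchedule(
            day=d,
            night_start=sunset[d] + off,
            night_end=min(sunrise[d + 1] - off, cfg.duration_s),
            morning_start=max(sunrise[d] - off, 0.0),
            bask=None,
        )
        if bask_present[d]:
            start = noon[d] - rng.uniform(1.5, 3.0) * 3600.0
            start = max(start, sunrise[d] + 2.5 * 3600.0)
            latest_end = sunset[d] - (2.8 * 3600.0 if is_dig_day
                                      else 1.0 * 3600.0)
            max_dur = (latest_end - start) / 3600.0
            if max_dur >= 2.0:
                dur = float(np.clip(rng.normal(cfg.bask_duration_mean_h,
                                               cfg.bask_duration_sd_h),
                                    2.0, min(7.5, max_dur)))
                end = start + dur * 3600.0
                ds.bask = (start, end)
                ds.segments = _schedule_bask(cfg, start, end, water_fn,
                                             air_fn, rng)
        if is_dig_day:
            ev0 = ds.bask[1] if ds.bask else sunset[d] - 2.5 * 3600.0
            ev1 = ds.night_start - 300.0
            dur_s = float(np.clip(rng.normal(cfg.dig_duration_mean_min,
                                             cfg.dig_duration_sd_min),
                                  30.0, 140.0)) * 60.0
            t0 = ev0 + 600.0
            if t0 + dur_s > ev1:
                t0 = max(ev0 + 60.0, ev1 - dur_s)
                dur_s = min(dur_s, ev1 - t0)
            if dur_s >= 1800.0:
                amp = float(rng.uniform(*cfg.dig_pitch_amp_deg))
                success = d == dig_days[-1]
                ds.digs.append((t0, t0 + dur_s, amp, success))
                if success:
                    sched.meta.observed_nesting_times.append(t0 + dur_s)
        sched.days.append(ds)

    # breathing schedule, including the partial first night before day 0
    bouts, times, rises = [], [], []
    night_spans = [(0.0, sched.days[0].morning_start, -1)] + [
        (ds.night_start, ds.night_end, ds.day) for ds in sched.days
    ]
    for t0, t1, d in night_spans:
        if t1 - t0 < 600.0:
            continue
        # clip symmetrically (+-1.4 sd) so the configured mean is unbiased
        depth = float(np.clip(
            rng.normal(cfg.night_pressure_mean_bar,
                       cfg.night_pressure_sd_bar),
            cfg.night_pressure_mean_bar - 1.4 * cfg.night_pressure_sd_bar,
            cfg.night_pressure_mean_bar + 1.4 * cfg.night_pressure_sd_bar,
        ))
        sched.night_depth[d] = depth
        t = t0 + float(rng.exponential(300.0))
        while t < t1 - 120.0:
            n_inh = 1 + int(rng.poisson(cfg.inhalations_per_bout_mean - 1.0))
            gaps = np.clip(
                rng.normal(cfg.inhalation_spacing_s,
                           cfg.inhalation_spacing_sd_s, n_inh - 1),
                6.0, 40.0,
            )
            ts = t + np.concatenate(([0.0], np.cumsum(gaps)))
            ts = ts[ts < t1 - 30.0]
            if len(ts) == 0:
                break
            rs = np.clip(
                rng.normal(cfg.rise_mean_cm, cfg.rise_sd_cm, len(ts)),
                0.5, min(12.0, 0.9 * depth * 1000.0),
            )
            bouts.append((float(ts[0]), float(ts[-1]), len(ts)))
            times.append(ts)
            rises.append(rs)
            t = float(ts[-1]) + max(
                150.0, float(rng.gamma(2.0, cfg.interbout_mean_min * 30.0))
            )
    sched.bout_spans = bouts
    sched.inhal_times = (np.concatenate(times) if times
                         else np.empty(0))
    sched.inhal_rises = (np.concatenate(rises) if rises
                         else np.empty(0))
    return sched


def _state_intervals(cfg, sched: _IndividualSchedule):
    """Flat, ordered (state, t0, t1) covering [0, duration); digs override."""
    ivs = []
    first = sched.days[0]
    if first.morning_start > 0:
        ivs.append((NIGHT, 0.0, first.morning_start))
    for ds in sched.days:
        if ds.bask:
            ivs.append((FORAGE, ds.morning_start, ds.bask[0]))
            for seg in ds.segments:
                ivs.append((DIVE if seg.kind == "dive" else BASK,
                            seg.t0, seg.t1))
            ivs.append((EVENING, ds.bask[1], ds.night_start))
        else:
            ivs.append((FORAGE, ds.morning_start, ds.night_start))
        if ds.night_end > ds.night_start:
            ivs.append((NIGHT, ds.night_start, ds.night_end))
    # dig overrides
    out = []
    digs = [(t0, t1) for ds in sched.days for (t0, t1, _, _) in ds.digs]
    for state, a, b in ivs:
        pieces = [(a, b)]
        for d0, d1 in digs:
            nxt = []
            for x0, x1 in pieces:
                if d1 <= x0 or d0 >= x1:
                    nxt.append((x0, x1))
                else:
                    if x0 < d0:
                        nxt.append((x0, d0))
                    if d1 < x1:
                        nxt.append((d1, x1))
            pieces = nxt
        out += [(state, x0, x1) for x0, x1 in pieces if x1 > x0]
    for ds in sched.days:
        out += [(DIG, t0, t1) for (t0, t1, _, _) in ds.digs]
    out.sort(key=lambda iv: iv[1])
    return out


class SyntheticDeployment:
    """Handle onto one generated deployment.

    Site-level products (weather, reference, sun table, metadata, truth
    labels and schedules) are materialised eagerly; the per-individual 1 Hz
    and 10 Hz streams are synthesised on demand by :meth:`env_stream` and
    :meth:`accel_stream` so large deployments can be processed one animal at
    a time.  Streams are deterministic functions of (config, seed,
    individual), independent of call order.
    """

    def __init__(self, config: GeneratorConfig, seed: int):
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0]))
        self.sun = _solar_table(config)
        self.weather, self._cloud_daily, rain3 = _generate_weather(
            config, self.sun, rng
        )
        self.reference = _generate_reference(config, self.weather, rng)
        rain_daily = (
            self.weather.assign(
                day=(self.weather["time"] // 86400).astype(int))
            .groupby("day")["rain_mm"].sum()
            .reindex(range(config.n_days), fill_value=0.0).to_numpy()
        )
        day_length = ((self.sun["sunset"] - self.sun["sunrise"]) / 3600.0
                      ).to_numpy()[:config.n_days]
        self._water_fn = _interp_fn(self.reference["time"],
                                    self.reference["t_surface"])
        self._air_fn = _interp_fn(self.reference["time"],
                                  self.reference["t_air"])
        self.schedules = [
            _schedule_individual(config, i, self.sun, self._cloud_daily,
                                 rain_daily, day_length, self._water_fn,
                                 self._air_fn, self.seed)
            for i in range(config.n_individuals)
        ]
        self.meta = [s.meta for s in self.schedules]
        self.truth = self._build_truth()

    # ------------------------------------------------------------------
    @property
    def n_individual_days(self) -> int:
        return self.config.n_individuals * self.config.n_days

    def _build_truth(self) -> TruthLabels:
        srows, prows, brows, irows, hrows, drows = [], [], [], [], [], []
        for sched in self.schedules:
            ind = sched.meta.individual_id
            for state, a, b in _state_intervals(self.config, sched):
                srows.append((ind, STATE_NAMES[state], a, b, False))
            for ds in sched.days:
                if ds.bask:
                    prows.append((ind, ds.day, "Morning", ds.morning_start,
                                  ds.bask[0]))
                    prows.append((ind, ds.day, "Midday", ds.bask[0],
                                  ds.bask[1]))
                    prows.append((ind, ds.day, "Evening", ds.bask[1],
                                  ds.night_start))
                    for seg in ds.segments:
                        if seg.kind == "ramp":
                            hrows.append((ind, seg.t0, seg.t1))
                else:
                    prows.append((ind, ds.day, "Morning", ds.morning_start,
                                  ds.night_start))
                prows.append((ind, ds.day, "Night", ds.night_start,
                              ds.night_end))
                for t0, t1, _, success in ds.digs:
                    drows.append((ind, t0, t1, (t1 - t0) / 60.0, success))
            for t0, t1, n in sched.bout_spans:
                brows.append((ind, t0, t1, n))
            for t, r in zip(sched.inhal_times, sched.inhal_rises):
                irows.append((ind, float(t), float(r)))
        return TruthLabels(
            states=pd.DataFrame(
                srows, columns=["individual", "state", "t_start", "t_end",
                                "success"]),
            phases=pd.DataFrame(
                prows, columns=["individual", "day", "phase", "t_start",
                                "t_end"]),
            breathing_bouts=pd.DataFrame(
                brows, columns=["individual", "t_start", "t_end",
                                "n_inhalations"]),
            inhalations=pd.DataFrame(
                irows, columns=["individual", "t", "rise_cm"]),
            heating=pd.DataFrame(hrows, columns=["individual", "t_start",
                                                 "t_end"]),
            digs=pd.DataFrame(
                drows, columns=["individual", "t_start", "t_end",
                                "duration_min", "success"]),
        )

    # ------------------------------------------------------------------
    def _state_code_1hz(self, sched) -> np.ndarray:
        n1 = int(self.config.duration_s)
        code = np.full(n1, FORAGE, dtype=np.int8)
        for state, a, b in _state_intervals(self.config, sched):
            code[int(max(a, 0)):int(min(b, n1))] = state
        return code

    def env_stream(self, i: int) -> pd.DataFrame:
        """Synthesise the 1 Hz environmental stream of individual i
        (timestamps in drifting logger time)."""
        cfg = self.config
        sched = self.schedules[i]
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, i, 21])
        )
        n1 = int(cfg.duration_s)
        t = np.arange(n1, dtype=float)
        code = self._state_code_1hz(sched)

        # --- temperature ------------------------------------------------
        water = np.interp(t, self.reference["time"],
                          self.reference["t_surface"])
        slow = lfilter([1.0], [1.0, -0.98], rng.normal(0.0, 0.02, n1))
        temp = water + 0.5 + slow
        air = np.interp(t, self.reference["time"], self.reference["t_air"])
        dig_mask = code == DIG
        temp[dig_mask] = air[dig_mask] + 1.0 + slow[dig_mask]
        for ds in sched.days:
            for seg in ds.segments:
                s, e = int(seg.t0), int(min(seg.t1, n1))
                if e <= s:
                    continue
                if seg.kind == "dive":
                    k = min(40, e - s)
                    prof = np.concatenate([
                        np.linspace(seg.temp0, seg.temp1, k),
                        np.full(e - s - k, seg.temp1),
                    ])
                else:
                    prof = np.linspace(seg.temp0, seg.temp1, e - s)
                temp[s:e] = prof + slow[s:e]
        temp += rng.normal(0.0, 0.02, n1)

        # --- pressure ---------------------------------------------------
        rw = np.cumsum(rng.normal(0.0, 0.01, n1))
        span = 0.17
        rw = 0.01 + np.abs((rw - 0.01) % (2 * span) - span)  # reflect
        pressure = rw
        night_mask = code == NIGHT
        ar = lfilter([1.0], [1.0, -0.97], rng.normal(0.0, 1.5e-4, n1))
        depth = np.full(n1, cfg.night_pressure_mean_bar)
        night_spans = [(0.0, sched.days[0].morning_start, -1)] + [
            (ds.night_start, ds.night_end, ds.day) for ds in sched.days
        ]
        for t0, t1, d in night_spans:
            if d in sched.night_depth:
                depth[int(t0):int(min(t1, n1))] = sched.night_depth[d]
        pressure = np.where(night_mask, depth + ar, pressure)
        pressure[code == BASK] = 0.002
        pressure[code == DIVE] = 0.06
        pressure[dig_mask] = 0.002
        pressure += np.where(
            np.isin(code, (BASK, DIVE)), np.abs(rng.normal(0, 8e-4, n1)), 0.0
        )
        pressure += np.where(dig_mask, rng.normal(0.0, 8e-3, n1), 0.0)
        # inhalation dips: short triangular pressure decreases
        prof = np.array([0.2, 0.7, 1.0, 0.7, 0.2])
        for tt, rise in zip(sched.inhal_times, sched.inhal_rises):
            c = int(round(tt))
            lo, hi = max(0, c - 2), min(n1, c + 3)
            pressure[lo:hi] -= rise / 1000.0 * prof[2 - (c - lo):2 + (hi - c)]
        np.clip(pressure, -0.009, None, out=pressure)

        # --- light --------------------------------------------------------
        sunrise = self.sun["sunrise"].to_numpy()
        sunset = self.sun["sunset"].to_numpy()
        day_idx = np.minimum((t // 86400).astype(int), cfg.n_days - 1)
        frac = (t - sunrise[day_idx]) / (sunset[day_idx] - sunrise[day_idx])
        elev = np.clip(np.sin(np.pi * np.clip(frac, 0.0, 1.0)), 0.0, None)
        elev = elev ** 1.2
        cloudf = 1.0 - cfg.cloud_attenuation * np.interp(
            t, self.weather["time"], self.weather["cloud_frac"]
        )
        medium = np.where(np.isin(code, (BASK, DIG)), 1.0,
                          cfg.underwater_light_factor)
        light = (cfg.light_peak_lux * elev * cloudf * medium
                 * np.exp(rng.normal(0.0, 0.08, n1)))
        light += rng.uniform(0.0, 30.0, n1)

        t_logger = sched.to_logger_time(t)
        return pd.DataFrame({
            "time": t_logger, "temp_c": temp, "pressure_bar": pressure,
            "light_lux": light,
        })

    def accel_stream(self, i: int) -> pd.DataFrame:
        """Synthesise the 10 Hz tri-axial acceleration stream of
        individual i (timestamps in drifting logger time).

        Gravity is rotated through a slowly varying posture (orientation
        random walk, plus a slow body-rocking sway while swimming and the
        stereotyped pitch oscillation while digging), band-limited below the
        decomposition cutoff; dynamic noise is high-passed white noise with
        per-axis sd set from the state VeDBA targets.
        """
        cfg = self.config
        sched = self.schedules[i]
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, i, 31])
        )
        n1 = int(cfg.duration_s)
        n10 = n1 * 10
        fs = 10.0
        code1 = self._state_code_1hz(sched)

        # posture at 1 Hz: unit OU processes scaled by state
        phi = math.exp(-1.0 / 60.0)
        step = math.sqrt(1.0 - phi * phi)
        ou_p = lfilter([step], [1.0, -phi], rng.standard_normal(n1))
        ou_r = lfilter([step], [1.0, -phi], rng.standard_normal(n1))
        scale = np.array([0.8, 4.0, 0.8, 2.0, 4.0, 2.0])  # by state code
        sc1 = scale[code1]
        base_p = float(rng.normal(0.0, 2.0))
        base_r = float(rng.normal(0.0, 2.0))
        pitch1 = base_p + ou_p * sc1
        roll1 = base_r + ou_r * sc1

        t1 = np.arange(n1, dtype=float)
        t10 = np.arange(n10, dtype=float) / fs
        pitch = np.interp(t10, t1, pitch1)
        roll = np.interp(t10, t1, roll1)
        del pitch1, roll1, ou_p, ou_r

        # slow swimming sway on active states (keeps roll variance off the
        # digging region) and the digging pitch oscillation
        active10 = np.repeat(np.isin(code1, (FORAGE, EVENING)), 10)
        ph_p, ph_r = rng.uniform(0, 2 * np.pi, 2)
        pitch += np.where(active10,
                          3.5 * np.sin(2 * np.pi * 0.30 * t10 + ph_p), 0.0)
        roll += np.where(active10,
                         5.5 * np.sin(2 * np.pi * 0.25 * t10 + ph_r), 0.0)
        del active10
        for ds in sched.days:
            for (d0, d1, amp, _) in ds.digs:
                s, e = int(d0 * fs), int(min(d1 * fs, n10))
                seg_t = t10[s:e]
                pitch[s:e] += amp * np.sin(
                    2 * np.pi * cfg.dig_freq_hz * (seg_t - seg_t[0])
                )

        p_rad = np.radians(pitch)
        r_rad = np.radians(roll)
        del pitch, roll
        cosp = np.cos(p_rad)
        gx = GRAVITY * np.sin(p_rad)
        gy = GRAVITY * cosp * np.sin(r_rad)
        gz = GRAVITY * cosp * np.cos(r_rad)
        del p_rad, r_rad, cosp

        sd_table = np.zeros(6)
        for state, mean in cfg.vedba_by_state().items():
            sd_table[state] = mean / CHI3_MEAN
        sd10 = np.repeat(sd_table[code1], 10)

        out = {}
        for name, g in (("ax", gx), ("ay", gy), ("az", gz)):
            g = lowpass(g, fs, 2.0)          # keep posture below the cutoff
            w = rng.standard_normal(n10)
            w -= lowpass(w, fs, 2.0)         # high-pass above the cutoff
            w /= w.std()
            out[name] = g + w * sd10
            del g, w
        del gx, gy, gz, sd10

        t_logger = sched.to_logger_time(t10)
        return pd.DataFrame({"time": t_logger, **out})


def generate(config: GeneratorConfig | None = None,
             seed: int = 0) -> SyntheticDeployment:
    """Generate one fully labelled synthetic deployment (see module docs)."""
    return SyntheticDeployment(config or GeneratorConfig(), seed)


def export_truth(truth: TruthLabels, out_dir: str) -> dict:
    """Write the ground-truth tables as CSVs (header-only when empty)."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name in ("states", "phases", "breathing_bouts", "inhalations",
                 "heating", "digs"):
        path = os.path.join(out_dir, f"truth_{name}.csv")
        getattr(truth, name).to_csv(path, index=False, lineterminator="\n")
        paths[name] = path
    return paths


def write_deployment(dep: SyntheticDeployment, out_dir: str) -> dict:
    """Write all streams and site files in the formats the readers expect.

    Intended for small configurations (the text files are full precision);
    large deployments are better processed in memory.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {"env": [], "accel": [], "meta": []}
    for i, meta in enumerate(dep.meta):
        env_p = os.path.join(out_dir, f"env_{meta.individual_id}.csv")
        acc_p = os.path.join(out_dir, f"accel_{meta.individual_id}.csv")
        meta_p = os.path.join(out_dir, f"meta_{meta.individual_id}.yaml")
        logger_io.write_stream(dep.env_stream(i), env_p)
        logger_io.write_stream(dep.accel_stream(i), acc_p)
        logger_io.write_meta(meta, meta_p)
        paths["env"].append(env_p)
        paths["accel"].append(acc_p)
        paths["meta"].append(meta_p)
    ref_p = os.path.join(out_dir, "reference.csv")
    wea_p = os.path.join(out_dir, "weather.csv")
    sun_p = os.path.join(out_dir, "sun.csv")
    logger_io.write_stream(dep.reference, ref_p)
    logger_io.write_stream(dep.weather, wea_p)
    dep.sun[["date", "sunrise", "sunset"]].to_csv(sun_p, index=False,
                                                  lineterminator="\n")
    paths.update(reference=ref_p, weather=wea_p, sun=sun_p)
    export_truth(dep.truth, out_dir)
    return paths
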