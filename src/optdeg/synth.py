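"""Synthetic greenhouse sensor-grid generator.

Emulates the statistical structure of a 20-node wireless sensor grid in a
large asymmetric multi-span greenhouse: two horizontal sensor planes,
minute cadence, a diurnal temperature cycle, a west-to-east horizontal
gradient, heater and vent schedules, optional night thermal inversion
relative to the outside air, Gaussian sensor noise and i.i.d. reading
dropout.

The deterministic ground-truth temperature field is

    T(t, x) = base + amplitude * max(0, sin(pi (h - sunrise)/(sunset - sunrise)))
              + gradient * (x - x_centre) + heater(h) - vent_dip(h)

with h the clock hour.  Relative humidity follows an anti-correlated rule:
it interpolates between a night level and a (lower) day level along the
same daylight factor, plus its own west-to-east gradient, clipped to
[0, 100] % -- a statistical emulation, not a psychrometric simulation.
A light channel (lux) proportional to the daylight factor is emitted so
the downstream sun/cloud/night classifier has data to work on.

Every run returns the noise-free, pre-dropout ground truth alongside the
readings, so downstream statistics always have an oracle.  Presets are
level-matched to the study conditions the generator emulates (winter
heated day, a ventilated late-spring day with night inversion, and a hot
July day); their day/night mean temperatures and humidities equal the
configured targets by construction (the profile is solved against the
actual sample grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ScenarioConfig",
    "default_layout",
    "simulate",
    "preset_scenarios",
    "plateau_scenario",
]


def default_layout(heights=(1.4, 2.2)) -> pd.DataFrame:
    """20-node demo layout: ten lateral positions x two heights.

    Positions span the three spans of an asymmetric ~91 x 51 m greenhouse
    (origin at the south-west corner, x east-positive).
    """
    lateral = [
        # (x, y, section)
        (9.0, 25.0, "old"), (22.0, 13.0, "old"), (22.0, 38.0, "old"),
        (36.0, 25.0, "old"),
        (50.0, 15.0, "new3"), (50.0, 30.0, "new3"), (62.0, 22.0, "new3"),
        (78.0, 14.0, "new2"), (78.0, 28.0, "new2"), (87.0, 21.0, "new2"),
    ]
    rows = []
    i = 1
    for h in heights:
        for x, y, sec in lateral:
            rows.append({"sensor_id": f"S{i:02d}", "x": x, "y": y,
                         "height": h, "section": sec})
            i += 1
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one synthetic measurement day.

    Temperatures in degC, humidities in %, times as fractional clock hours,
    gradients per metre of west-to-east distance (both T and RH increase
    eastwards by default, as ventilation-driven advection produces in
    practice).  ``outside_night_t`` is the ambient night temperature; a
    night base below it represents thermal inversion.
    """

    name: str = "custom"
    layout: pd.DataFrame = field(default_factory=default_layout)
    start: str = "2018-01-10 00:00"
    duration_min: int = 1440
    cadence_min: float = 1.0
    # temperature profile
    t_night_base: float = 15.0
    t_day_amplitude: float = 8.0
    sunrise_hour: float = 7.0
    sunset_hour: float = 17.25
    t_gradient: float = 0.02        # degC per metre, west -> east
    # humidity profile
    rh_night: float = 74.0
    rh_day: float = 60.0
    rh_gradient: float = 0.05       # % per metre, west -> east
    # equipment schedules
    heater_on_hour: float | None = None   # window may wrap past midnight
    heater_off_hour: float | None = None
    heater_lift: float = 0.0
    vent_open_hour: float | None = None
    vent_close_hour: float | None = None
    vent_dip: float = 0.0
    vent_ramp_min: float = 10.0
    # ambient reference
    outside_night_t: float | None = None
    # stochastic components
    noise_sd_t: float = 0.3
    noise_sd_rh: float = 1.0
    dropout: float = 0.0
    sun_peak_lux: float = 50_000.0
    seed: int = 0
    # solved-for targets (informational; set by solve_targets)
    target_day_t: float | None = None
    target_night_t: float | None = None
    target_day_rh: float | None = None
    target_night_rh: float | None = None

    def __post_init__(self):
        if self.cadence_min <= 0:
            raise ValueError("cadence must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.noise_sd_t < 0 or self.noise_sd_rh < 0:
            raise ValueError("noise sd must be non-negative")
        if not (0.0 <= self.sunrise_hour < self.sunset_hour <= 24.0):
            raise ValueError("need 0 <= sunrise < sunset <= 24")
        if (self.vent_open_hour is None) != (self.vent_close_hour is None):
            raise ValueError("vent schedule needs both open and close hours")
        if (self.vent_open_hour is not None
                and not self.vent_open_hour < self.vent_close_hour):
            raise ValueError("vent must open before it closes")
        if (self.heater_on_hour is None) != (self.heater_off_hour is None):
            raise ValueError("heater schedule needs both on and off hours")

    # -- deterministic building blocks ------------------------------------
    def _clock_hours(self) -> tuple[pd.DatetimeIndex, np.ndarray]:
        n = int(round(self.duration_min / self.cadence_min))
        times = pd.date_range(self.start, periods=n,
                              freq=pd.Timedelta(minutes=self.cadence_min))
        h = (times.hour + times.minute / 60.0 + times.second / 3600.0).to_numpy()
        return times, h

    def daylight_factor(self, h: np.ndarray) -> np.ndarray:
        span = self.sunset_hour - self.sunrise_hour
        s = np.sin(np.pi * (h - self.sunrise_hour) / span)
        s[(h <= self.sunrise_hour) | (h >= self.sunset_hour)] = 0.0
        return np.maximum(s, 0.0)

    def heater_factor(self, h: np.ndarray) -> np.ndarray:
        if self.heater_on_hour is None:
            return np.zeros_like(h)
        on, off = self.heater_on_hour, self.heater_off_hour
        if on < off:
            active = (h >= on) & (h < off)
        else:  # wraps midnight
            active = (h >= on) | (h < off)
        return active.astype(float)

    def vent_factor(self, h: np.ndarray) -> np.ndarray:
        """Rectangular dip with linear ramps of ``vent_ramp_min`` minutes."""
        if self.vent_open_hour is None:
            return np.zeros_like(h)
        ramp = self.vent_ramp_min / 60.0
        up = np.clip((h - self.vent_open_hour) / max(ramp, 1e-9), 0.0, 1.0)
        down = np.clip((self.vent_close_hour - h) / max(ramp, 1e-9), 0.0, 1.0)
        return np.minimum(up, down)

    # -- profile solving ---------------------------------------------------
    def solve_targets(self, day_t: float, night_t: float,
                      day_rh: float, night_rh: float,
                      night_lux: float = 10.0) -> "ScenarioConfig":
        """Return a config whose ground-truth day/night means equal the
        given targets.

        Day/night is taken as lux >= / < ``night_lux`` (the downstream
        classifier's night threshold), and the base/amplitude/levels are
        solved against the actual discrete sample grid, so the match is by
        construction rather than asymptotic.
        """
        _, h = self._clock_hours()
        s = self.daylight_factor(h)
        day = (s * self.sun_peak_lux) >= night_lux
        night = ~day
        if not day.any() or not night.any():
            raise ValueError("targets need both day and night samples")
        heat = self.heater_factor(h) * self.heater_lift
        vent = self.vent_factor(h) * self.vent_dip
        base = night_t - heat[night].mean() + vent[night].mean()
        s_day = s[day].mean()
        amp = (day_t - base - heat[day].mean() + vent[day].mean()) / s_day
        rh_day_level = night_rh + (day_rh - night_rh) / s_day
        return replace(self, t_night_base=base, t_day_amplitude=amp,
                       rh_night=night_rh, rh_day=rh_day_level,
                       target_day_t=day_t, target_night_t=night_t,
                       target_day_rh=day_rh, target_night_rh=night_rh)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "layout"}
        d["layout"] = self.layout.to_dict(orient="records")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d["layout"] = pd.DataFrame(d["layout"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def simulate(config: ScenarioConfig, seed: int | None = None
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (readings, ground_truth) for a scenario.

    Both tables have columns timestamp, sensor_id, T, RH, light; the
    readings add Gaussian noise and i.i.d. dropout to the truth.  Given
    the same (config, seed) the output is reproducible; ``seed`` defaults
    to ``config.seed``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    times, h = config._clock_hours()
    s = config.daylight_factor(h)
    heat = config.heater_factor(h) * config.heater_lift
    vent = config.vent_factor(h) * config.vent_dip
    lux = config.sun_peak_lux * s
    x_centre = float(config.layout["x"].mean())

    frames = []
    for _, sensor in config.layout.iterrows():
        dx = sensor["x"] - x_centre
        t_true = (config.t_night_base + config.t_day_amplitude * s
                  + config.t_gradient * dx + heat - vent)
        rh_true = (config.rh_night + (config.rh_day - config.rh_night) * s
                   + config.rh_gradient * dx)
        rh_true = np.clip(rh_true, 0.0, 100.0)
        frames.append(pd.DataFrame({
            "timestamp": times, "sensor_id": sensor["sensor_id"],
            "T": t_true, "RH": rh_true, "light": lux}))
    truth = pd.concat(frames, ignore_index=True)
    truth = truth.sort_values(["sensor_id", "timestamp"],
                              kind="mergesort").reset_index(drop=True)

    readings = truth.copy()
    n = len(readings)
    readings["T"] = readings["T"] + rng.normal(0.0, config.noise_sd_t, n)
    readings["RH"] = np.clip(
        readings["RH"] + rng.normal(0.0, config.noise_sd_rh, n), 0.0, 100.0)
    if config.dropout > 0:
        keep = rng.random(n) >= config.dropout
        readings = readings[keep].reset_index(drop=True)
    return readings, truth


def preset_scenarios() -> dict[str, ScenarioConfig]:
    """Three level-matched study conditions.

    * ``winter_heated`` -- cold-season day: heater on overnight, side
      vents open over midday, mild diurnal cycle (day/night T 21.6/16.1
      degC, RH 66.4/74.4 %).
    * ``june_ventilated`` -- late spring with exhaust fans: large diurnal
      swing (29.1/14.7 degC, RH 45.1/90.3 %) and night thermal inversion
      below the 17.0 degC ambient.
    * ``july_hot`` -- hot-season early growth stage: extreme daytime heat
      and dryness (38.8/24.7 degC, RH 19.3/37.3 %), sensors at 0.6/2.2 m
      because of the young crop.
    """
    winter = ScenarioConfig(
        name="winter_heated", start="2018-01-10 00:00",
        sunrise_hour=7.25, sunset_hour=17.25,
        heater_on_hour=16.5, heater_off_hour=8.0, heater_lift=1.5,
        vent_open_hour=8.5, vent_close_hour=16.5, vent_dip=1.0,
        t_gradient=0.02, rh_gradient=0.05,
        noise_sd_t=0.3, noise_sd_rh=1.0, dropout=0.02, seed=1001,
    ).solve_targets(day_t=21.6, night_t=16.1, day_rh=66.4, night_rh=74.4)

    june = ScenarioConfig(
        name="june_ventilated", start="2018-06-10 00:00",
        sunrise_hour=5.5, sunset_hour=19.5,
        vent_open_hour=8.5, vent_close_hour=20.5, vent_dip=1.0,
        outside_night_t=17.0,
        t_gradient=0.015, rh_gradient=0.04,
        noise_sd_t=0.3, noise_sd_rh=1.5, dropout=0.02, seed=1002,
    ).solve_targets(day_t=29.1, night_t=14.7, day_rh=45.1, night_rh=90.3)

    july = ScenarioConfig(
        name="july_hot", start="2018-07-29 00:00",
        layout=default_layout(heights=(0.6, 2.2)),
        sunrise_hour=5.75, sunset_hour=19.75,
        vent_open_hour=8.5, vent_close_hour=20.5, vent_dip=0.5,
        outside_night_t=27.2,
        t_gradient=0.01, rh_gradient=0.03,
        noise_sd_t=0.4, noise_sd_rh=1.5, dropout=0.02, seed=1003,
    ).solve_targets(day_t=38.8, night_t=24.7, day_rh=19.3, night_rh=37.3)

    return {"winter_heated": winter, "june_ventilated": june,
            "july_hot": july}


def plateau_scenario() -> ScenarioConfig:
    """A sun-hours scenario whose ground truth sits inside the GS2-sun
    optimal plateaus (T = 25.5 degC, RH = 75 %, VPD ~= 0.82 kPa), for
    end-to-end consistency checks: mean OptDeg should be ~1 throughout."""
    return ScenarioConfig(
        name="gs2_sun_plateau", start="2018-05-01 10:00", duration_min=240,
        sunrise_hour=0.0, sunset_hour=24.0,
        t_night_base=25.5, t_day_amplitude=0.0,
        rh_night=75.0, rh_day=75.0,
        t_gradient=0.0, rh_gradient=0.0,
        noise_sd_t=0.2, noise_sd_rh=0.5, dropout=0.02, seed=1004)
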