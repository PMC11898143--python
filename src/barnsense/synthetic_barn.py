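"""Synthetic barn: ground-truth environmental fields with known parameters.

Generates per-zone time series of every channel a monitoring node can
sample (temperature, RH, NH3, CO2, H2S, PM, sound, illuminance, VOC,
NOx) on a fixed 10 s grid, plus an outdoor background point. Gas
concentrations come from a well-mixed single-compartment mass balance

    V dC/dt = S(t) + Q(t) (C_out - C)

integrated with the exact exponential step for piecewise-constant
coefficients, so the discrete trajectory matches the analytic solution
of the linear ODE on every step. All generating parameters are recorded
in the output, which makes downstream estimators testable by parameter
recovery: the CO2-tracer identity E = P_CO2 * dC_NH3 / dC_CO2 holds
exactly at the steady state of this model, for any ventilation rate.

Temperature is a diurnal sinusoid; the indoor air sits a constant
animal-heat offset above outdoor. Feeding events multiply the gas
sources inside their windows. RH is mean + clipped AR(1) noise. The
whole field is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import CHANNEL_ORDER as CHANNELS
from .config import ClimateConfig, EventSchedule, Scenario, ZoneConfig
from .units import mass_conc_to_ppm, ppm_to_mass_conc

#: base time step of the generator, seconds (fastest sensor sampling rate)
DT_SECONDS = 10

GASES = ("nh3", "co2", "h2s")


def steady_state_conc(source: float, ventilation: float, background: float) -> float:
    """Steady-state mass concentration of the well-mixed balance, g m^-3.

    ``C_ss = background + source / ventilation`` with source in g h^-1
    and ventilation in m^3 h^-1.
    """
    if ventilation <= 0:
        raise ValueError("ventilation must be positive")
    return background + source / ventilation


@dataclass
class GroundTruth:
    """Per-zone channel time series plus the full generating parameter set.

    ``zones`` maps zone_id -> DataFrame (10 s DatetimeIndex, one column
    per channel; gases in ppm). The outdoor background point is the
    ``"outdoor"`` entry.
    """

    zones: dict[str, pd.DataFrame]
    params: dict = field(repr=False)
    seed: int = 0

    def frame(self, zone_id: str) -> pd.DataFrame:
        try:
            return self.zones[zone_id]
        except KeyError:
            raise KeyError(f"unknown zone {zone_id!r}; have {sorted(self.zones)}") from None

    @property
    def index(self) -> pd.DatetimeIndex:
        return next(iter(self.zones.values())).index


def _event_mask(minutes_of_day: np.ndarray, events: EventSchedule) -> np.ndarray:
    """True where a management-event window is active."""
    mask = np.zeros_like(minutes_of_day, dtype=bool)
    for start in events.minutes_of_day():
        end = start + events.duration_min
        mask |= (minutes_of_day >= start) & (minutes_of_day < end)
        if end > 1440:  # window wraps past midnight
            mask |= minutes_of_day < end - 1440
    return mask


def _integrate_gas(c0: float, c_out: np.ndarray, source: np.ndarray,
                   ventilation: np.ndarray, volume: float) -> np.ndarray:
    """Exact exponential integration of the well-mixed balance (mass units)."""
    n = len(c_out)
    dt_h = DT_SECONDS / 3600.0
    css = c_out + source / ventilation
    decay = np.exp(-ventilation * dt_h / volume)
    c = np.empty(n)
    c[0] = c0
    for k in range(n - 1):
        c[k + 1] = css[k] + (c[k] - css[k]) * decay[k]
    return c


def _ar1(rng: np.random.Generator, n: int, sigma: float, phi: float) -> np.ndarray:
    if sigma == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, sigma, size=n)
    x = np.empty(n)
    x[0] = eps[0] / np.sqrt(1 - phi**2)
    for k in range(1, n):
        x[k] = phi * x[k - 1] + eps[k]
    return x


def _daylight(hours_of_day: np.ndarray, peak: float) -> np.ndarray:
    """Half-sinusoid daylight curve, zero between 18:00 and 06:00."""
    frac = np.sin(np.pi * (hours_of_day - 6.0) / 12.0)
    return peak * np.clip(frac, 0.0, None)


def make_truth(zones: list[ZoneConfig], climate: ClimateConfig,
               events: EventSchedule, duration_days: int, seed: int,
               start: str = "2023-03-14", initial: str = "background") -> GroundTruth:
    """Generate ground truth for every zone plus the outdoor point.

    Parameters
    ----------
    initial
        ``"background"`` starts each gas at the outdoor concentration
        (the barn fills up over the first few time constants);
        ``"steady"`` starts on the steady state of the base (non-event)
        source, so an event-free run sits at steady state throughout.
    """
    if duration_days < 1:
        raise ValueError("duration must be at least 1 day")
    if initial not in ("background", "steady"):
        raise ValueError("initial must be 'background' or 'steady'")
    ids = [z.zone_id for z in zones]
    if len(set(ids)) != len(ids) or "outdoor" in ids:
        raise ValueError("zone ids must be unique and 'outdoor' is reserved")

    n = duration_days * 24 * 3600 // DT_SECONDS
    index = pd.date_range(start, periods=n, freq=f"{DT_SECONDS}s")
    t_sec = np.arange(n) * float(DT_SECONDS)
    hours = (t_sec / 3600.0) % 24.0
    minutes = (t_sec / 60.0) % 1440.0

    temp_out = climate.mean_temp + climate.diurnal_amplitude * np.cos(
        2 * np.pi * (hours - climate.peak_hour) / 24.0)
    lux = _daylight(hours, climate.lux_peak)
    ev_mult = np.where(_event_mask(minutes, events), events.multiplier, 1.0)

    # outdoor gas backgrounds, mass units at outdoor temperature
    c_out_mass = {
        g: ppm_to_mass_conc(getattr(climate, f"outdoor_{g}"), g,
                            temp_out, climate.pressure_pa)
        for g in GASES
    }

    rng = np.random.default_rng(seed)
    # fixed spawn order: outdoor first, then zones in list order
    streams = rng.spawn(len(zones) + 1)

    frames: dict[str, pd.DataFrame] = {}

    def _common(df: pd.DataFrame, temp: np.ndarray, rh_stream: np.random.Generator):
        df["temp"] = temp
        rh = climate.mean_rh + _ar1(rh_stream, n, climate.rh_sigma, climate.rh_phi)
        df["rh"] = np.clip(rh, 0.0, 100.0)
        df["sound"] = np.full(n, climate.sound_base)
        df["lux"] = lux
        df["voc"] = np.full(n, climate.voc_base)
        df["nox"] = np.full(n, climate.nox_base)
        df["pm25"] = np.full(n, climate.pm25_base)
        df["pm1"] = 0.6 * df["pm25"]
        df["pm4"] = 1.1 * df["pm25"]
        df["pm10"] = 1.3 * df["pm25"]

    outdoor = pd.DataFrame(index=index)
    _common(outdoor, temp_out, streams[0])
    for g in GASES:
        outdoor[g] = np.full(n, float(getattr(climate, f"outdoor_{g}")))
    frames["outdoor"] = outdoor[list(CHANNELS)]

    for zi, zone in enumerate(zones):
        temp_in = temp_out + climate.indoor_offset
        df = pd.DataFrame(index=index)
        _common(df, temp_in, streams[zi + 1])
        q = np.full(n, zone.ventilation_rate)
        if zone.ventilation_profile is not None:
            q = q * np.asarray(zone.ventilation_profile)[hours.astype(int)]
        for g in GASES:
            s_base = getattr(zone, f"{g}_source")
            s = s_base * ev_mult
            if initial == "steady":
                c0 = steady_state_conc(s_base, q[0], c_out_mass[g][0])
            else:
                c0 = c_out_mass[g][0]
            c_mass = _integrate_gas(c0, c_out_mass[g], s, q, zone.volume)
            df[g] = mass_conc_to_ppm(c_mass, g, temp_in, climate.pressure_pa)
        frames[zone.zone_id] = df[list(CHANNELS)]

    params = {
        "zones": [z.model_dump() for z in zones],
        "climate": climate.model_dump(),
        "events": events.model_dump(),
        "duration_days": duration_days,
        "start": start,
        "initial": initial,
        "dt_seconds": DT_SECONDS,
    }
    return GroundTruth(zones=frames, params=params, seed=seed)


def truth_from_scenario(scenario: Scenario, seed: int,
                        initial: str = "background") -> GroundTruth:
    """Convenience wrapper: generate truth for a loaded scenario."""
    return make_truth(scenario.zones, scenario.climate, scenario.events,
                      scenario.duration_days, seed, start=scenario.start,
                      initial=initial)


_UNITS_COMMENT = ("# units: temp=degC rh=% sound=dBA lux=lux h2s=ppm nh3=ppm "
                  "co2=ppm voc=ppb nox=ppb pm*=ug/m3")


def write_truth(truth: GroundTruth, outdir: str | Path) -> None:
    """Write one CSV per zone plus a JSON sidecar of generator parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for zone_id, df in truth.zones.items():
        path = outdir / f"truth_{zone_id}.csv"
        with open(path, "w") as fh:
            fh.write(_UNITS_COMMENT + "\n")
            df.to_csv(fh, index_label="timestamp", date_format="%Y-%m-%dT%H:%M:%S")
    (outdir / "truth_params.json").write_text(
        json.dumps({"seed": truth.seed, **truth.params}, indent=2))
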