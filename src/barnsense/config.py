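"""Scenario configuration: barn zones, climate, management events, herd.

A scenario file (YAML or JSON) fully determines a synthetic monitoring
campaign: barn geometry and emission sources per zone, the outdoor
climate, feeding events that pulse the gas sources, the herd (for
metabolic CO2 production), and where the monitoring devices sit.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class ZoneConfig(BaseModel):
    """One well-mixed compartment of the housing.

    Gas dynamics in the zone follow a single-compartment mass balance
    ``V dC/dt = S(t) + Q(t) (C_out - C)`` with source ``S`` (g h^-1) and
    ventilation ``Q`` (m^3 h^-1).
    """

    zone_id: str
    volume: float = Field(gt=0, description="zone air volume, m^3")
    ventilation_rate: float = Field(gt=0, description="base ventilation, m^3 h^-1")
    #: optional 24 hourly multipliers on ventilation_rate (cycled per day)
    ventilation_profile: Optional[list[float]] = None
    nh3_source: float = Field(default=0.0, ge=0, description="NH3 source, g h^-1")
    co2_source: float = Field(default=0.0, ge=0, description="CO2 source, g h^-1")
    h2s_source: float = Field(default=0.0, ge=0, description="H2S source, g h^-1")

    @field_validator("ventilation_profile")
    @classmethod
    def _profile_ok(cls, v):
        if v is not None:
            if len(v) != 24:
                raise ValueError("ventilation_profile must have 24 hourly values")
            if min(v) <= 0:
                raise ValueError("ventilation_profile values must be > 0")
        return v


class ClimateConfig(BaseModel):
    """Outdoor climate and indoor offsets driving the generator."""

    mean_temp: float = Field(default=15.0, description="outdoor daily mean, degC")
    diurnal_amplitude: float = Field(default=5.0, ge=0, description="degC")
    peak_hour: float = Field(default=15.0, ge=0, lt=24, description="hour of daily max")
    #: animal heat raises the indoor air above outdoor by roughly this much
    indoor_offset: float = 3.0
    mean_rh: float = Field(default=65.0, ge=0, le=100, description="%")
    rh_sigma: float = Field(default=1.0, ge=0, description="AR(1) innovation SD, %")
    rh_phi: float = Field(default=0.98, ge=0, lt=1, description="AR(1) coefficient")
    outdoor_nh3: float = Field(default=0.05, ge=0, description="ppm")
    outdoor_co2: float = Field(default=420.0, ge=400, description="ppm (NDIR floor 400)")
    outdoor_h2s: float = Field(default=0.0, ge=0, description="ppm")
    pressure_pa: float = Field(default=101325.0, gt=0)
    # non-gas channel baselines
    lux_peak: float = Field(default=500.0, ge=0, description="midday illuminance, lux")
    sound_base: float = Field(default=58.0, description="dBA")
    pm25_base: float = Field(default=17.0, ge=0, description="ug m^-3")
    voc_base: float = Field(default=800.0, ge=0, description="ppb")
    nox_base: float = Field(default=100.0, ge=0, description="ppb")


class EventSchedule(BaseModel):
    """Management events (feed delivery) that pulse gas sources.

    During each window the zone gas sources are multiplied by
    ``multiplier``; the defaults reproduce twice-daily feeding at
    07:15 and 16:30 with a doubled source for an hour.
    """

    event_times: list[str] = Field(default=["07:15", "16:30"])
    multiplier: float = Field(default=2.0, ge=1)
    duration_min: float = Field(default=60.0, gt=0)

    @field_validator("event_times")
    @classmethod
    def _times_ok(cls, v):
        for t in v:
            hh, mm = t.split(":")
            if not (0 <= int(hh) < 24 and 0 <= int(mm) < 60):
                raise ValueError(f"event time {t!r} outside [00:00, 24:00)")
        return v

    def minutes_of_day(self) -> list[float]:
        return [int(t.split(":")[0]) * 60 + int(t.split(":")[1]) for t in self.event_times]


class HerdConfig(BaseModel):
    """Herd description for metabolic CO2 production."""

    n_animals: int = Field(gt=0)
    body_mass: float = Field(default=650.0, gt=0, description="kg head^-1")
    milk_yield: float = Field(default=0.0, ge=0, description="kg head^-1 day^-1")
    pregnancy_days: float = Field(default=0.0, ge=0)


class DevicePlacement(BaseModel):
    """Where a monitoring node sits: its zone and floor-plan coordinates."""

    node_id: str
    zone: str
    x_m: float = 0.0
    y_m: float = 0.0


class Scenario(BaseModel):
    """A complete synthetic monitoring campaign."""

    name: str = "scenario"
    zones: list[ZoneConfig]
    climate: ClimateConfig = ClimateConfig()
    events: EventSchedule = EventSchedule()
    herd: Optional[HerdConfig] = None
    devices: list[DevicePlacement] = []
    duration_days: int = Field(default=1, ge=1)
    start: str = "2023-03-14"

    @model_validator(mode="after")
    def _devices_in_zones(self):
        known = {z.zone_id for z in self.zones} | {"outdoor"}
        for d in self.devices:
            if d.zone not in known:
                raise ValueError(f"device {d.node_id} placed in unknown zone {d.zone!r}")
        return self


def load_scenario(path: str | Path) -> Scenario:
    """Read a scenario from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return Scenario.model_validate(data)


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    path = Path(path)
    data = scenario.model_dump()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
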