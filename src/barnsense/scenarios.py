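"""Ready-made illustrative scenarios for the three housing types.

These parameterize the synthetic barn after the three field cases —
a mechanically ventilated rabbit house with uneven ventilation, a
naturally ventilated sow gestation room with twice-daily feeding
pulses, and an open dairy barn monitored for emission estimation.
Ventilation rates and barn volumes are illustrative (no farm publishes
them), chosen so the simulated concentration levels land on the ranges
observed in practice; they are not reconstructions of specific farms.
"""

from __future__ import annotations

from .config import (ClimateConfig, DevicePlacement, EventSchedule, HerdConfig,
                     Scenario, ZoneConfig)
from .emission import co2_production

#: average NH3 (ppm) observed at six cage-level monitoring points in a
#: commercial rabbit house over one week — the worked example for the
#: welfare-limit check (points 4 and 6 sit above the 10 ppm guideline).
RABBIT_NH3_MEANS = {"ID1": 7.3, "ID2": 6.5, "ID3": 9.5,
                    "ID4": 11.4, "ID5": 7.9, "ID6": 10.4}

#: floor-plan coordinates (m) of the six rabbit-house monitoring points
#: in a 30 m x 12 m room, three per long side
RABBIT_POSITIONS = {"ID1": (5.0, 3.0), "ID2": (15.0, 3.0), "ID3": (25.0, 3.0),
                    "ID4": (25.0, 9.0), "ID5": (15.0, 9.0), "ID6": (5.0, 9.0)}


def dairy_herd() -> HerdConfig:
    """140 lactating cows at 37 kg milk head^-1 day^-1, 650 kg body mass."""
    return HerdConfig(n_animals=140, body_mass=650.0, milk_yield=37.0)


def dairy_scenario(nh3_source: float = 220.0, ventilation: float = 200_000.0,
                   volume: float = 10_000.0, mean_temp: float = 12.0,
                   diurnal_amplitude: float = 0.0,
                   outdoor_co2: float = 420.0, outdoor_nh3: float = 0.05,
                   duration_days: int = 2) -> Scenario:
    """Open dairy barn sized for the tracer-gas emission estimate.

    The zone CO2 source is set to the herd's metabolic production at
    the (constant, by default) barn temperature, so the generated field
    is exactly the situation the tracer balance assumes. With the
    defaults the barn sits near 620 ppm CO2 over a 420 ppm background
    and 1.6 ppm NH3, and the true emission is 220 g h^-1, i.e. 37.7 g
    animal^-1 day^-1 from 140 cows.
    """
    herd = dairy_herd()
    climate = ClimateConfig(mean_temp=mean_temp,
                            diurnal_amplitude=diurnal_amplitude,
                            outdoor_co2=outdoor_co2, outdoor_nh3=outdoor_nh3,
                            mean_rh=70.0)
    barn_temp = mean_temp + climate.indoor_offset
    zone = ZoneConfig(zone_id="barn", volume=volume,
                      ventilation_rate=ventilation,
                      nh3_source=nh3_source,
                      co2_source=co2_production(herd, barn_temp,
                                                climate.pressure_pa))
    devices = [DevicePlacement(node_id=f"B{i}", zone="barn", x_m=10.0 * i, y_m=5.0)
               for i in (1, 2, 3)]
    devices.append(DevicePlacement(node_id="OUT", zone="outdoor", x_m=-10.0, y_m=0.0))
    return Scenario(name="dairy", zones=[zone], climate=climate,
                    events=EventSchedule(event_times=[], multiplier=1.0),
                    herd=herd, devices=devices, duration_days=duration_days,
                    start="2023-09-05")


def random_dairy_scenario(rng, duration_days: int = 1) -> Scenario:
    """Randomized steady dairy barn for recovery testing.

    Draws ventilation, NH3 source, outdoor backgrounds and temperature
    over wide but physically sensible ranges; the herd CO2 source stays
    matched to the metabolic model, which is the condition the tracer
    balance assumes.
    """
    return dairy_scenario(
        nh3_source=float(rng.uniform(50, 500)),
        ventilation=float(rng.uniform(60_000, 400_000)),
        volume=float(rng.uniform(5_000, 15_000)),
        mean_temp=float(rng.uniform(5, 20)),
        outdoor_co2=float(rng.uniform(400, 500)),
        outdoor_nh3=float(rng.uniform(0.0, 0.5)),
        duration_days=duration_days,
    )


def pig_scenario(duration_days: int = 4) -> Scenario:
    """Sow gestation room with feeding pulses at 07:15 and 16:30.

    Natural ventilation; sources sized for a daily-average NH3 of a few
    ppm and CO2 around 700 ppm, with the feeding events doubling the
    gas sources for an hour.
    """
    climate = ClimateConfig(mean_temp=24.0, diurnal_amplitude=4.0,
                            peak_hour=15.0, mean_rh=60.0,
                            outdoor_co2=420.0, outdoor_nh3=0.02)
    zone = ZoneConfig(zone_id="gestation", volume=1700.0,
                      ventilation_rate=30_000.0,
                      nh3_source=65.0, co2_source=15_000.0)
    devices = [DevicePlacement(node_id="P1", zone="gestation", x_m=8.0, y_m=6.0),
               DevicePlacement(node_id="P2", zone="gestation", x_m=20.0, y_m=6.0)]
    return Scenario(name="pig", zones=[zone], climate=climate,
                    events=EventSchedule(),  # 07:15 and 16:30, x2 for 60 min
                    devices=devices, duration_days=duration_days,
                    start="2023-06-13")


def rabbit_scenario(duration_days: int = 2) -> Scenario:
    """Rabbit house with two zones of unequal ventilation.

    The poorly ventilated zone runs at a third of the airflow of the
    well-ventilated one, producing the kind of spatial NH3 gradient the
    uniformity analysis is meant to expose.
    """
    climate = ClimateConfig(mean_temp=19.0, diurnal_amplitude=1.5,
                            mean_rh=62.0, outdoor_co2=420.0, outdoor_nh3=0.02,
                            lux_peak=40.0)  # no natural light program
    zones = [
        ZoneConfig(zone_id="well_vent", volume=720.0, ventilation_rate=9000.0,
                   nh3_source=45.0, co2_source=12_000.0),
        ZoneConfig(zone_id="poor_vent", volume=720.0, ventilation_rate=3000.0,
                   nh3_source=45.0, co2_source=12_000.0),
    ]
    devices = [
        DevicePlacement(node_id="ID1", zone="well_vent", x_m=5, y_m=3),
        DevicePlacement(node_id="ID2", zone="well_vent", x_m=15, y_m=3),
        DevicePlacement(node_id="ID3", zone="well_vent", x_m=25, y_m=3),
        DevicePlacement(node_id="ID4", zone="poor_vent", x_m=25, y_m=9),
        DevicePlacement(node_id="ID5", zone="poor_vent", x_m=15, y_m=9),
        DevicePlacement(node_id="ID6", zone="poor_vent", x_m=5, y_m=9),
    ]
    return Scenario(name="rabbit", zones=zones, climate=climate,
                    events=EventSchedule(event_times=["06:00", "18:00"],
                                         multiplier=1.5, duration_min=45),
                    devices=devices, duration_days=duration_days,
                    start="2023-03-14")
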