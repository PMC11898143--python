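"""CO2-tracer estimation of ammonia emission from animal housing.

The tracer-gas balance uses metabolic CO2 as an internally generated
tracer: at (quasi-)steady state both gases are diluted by the same
unknown ventilation flow, so the flow cancels from the ratio and

    E_NH3 = P_CO2 * (C_NH3,in - C_NH3,out) / (C_CO2,in - C_CO2,out)

gives the NH3 emission (g h^-1) from the herd's CO2 production P_CO2
(g h^-1) and the indoor/outdoor mass concentrations (g m^-3).

P_CO2 follows the CIGR dairy-cow heat-production model: total heat per
head Phi_tot = 5.6 m^0.75 + 22 Y + 1.6e-5 p^3 (W; m body mass kg, Y
milk yield kg/day, p days of pregnancy), corrected for ambient
temperature as Phi(T) = Phi_tot (1000 + 4 (20 - T)) / 1000, expressed
in heat-producing units (1 hpu = 1000 W) and converted at 0.185 m^3
CO2 h^-1 hpu^-1. Calculations run on an hourly basis — the correction
tracks the fluctuating barn temperature — and are averaged over the
day; hours where the CO2 difference is not positive are excluded as
singular.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import HerdConfig
from .ingest_aggregate import DeviceSeries
from .units import STANDARD_PRESSURE_PA, ppm_to_mass_conc

#: volumetric CO2 production per heat-producing unit, m^3 h^-1
CO2_PER_HPU = 0.185

#: warn outside this ambient range: the linear correction is extrapolated
TEMP_VALID_RANGE = (-25.0, 45.0)


class TracerUndefined(ValueError):
    """Raised when the indoor-outdoor CO2 difference is not positive."""


@dataclass(frozen=True)
class EmissionInputs:
    """One hour's inputs to the tracer balance (mass concentrations)."""

    c_nh3_barn: float      # g m^-3
    c_nh3_outside: float   # g m^-3
    c_co2_barn: float      # g m^-3
    c_co2_outside: float   # g m^-3
    p_co2: float           # g h^-1
    temperature: float = 20.0
    timestamp: Optional[pd.Timestamp] = None


@dataclass
class EmissionEstimate:
    """Hourly NH3 emissions and their daily per-animal summary.

    ``hourly`` has columns E_g_per_h and valid; ``daily`` has the daily
    mean over valid hours, the per-animal rate (24 x mean / n_animals,
    g animal^-1 day^-1) and the number of valid hours. Days with fewer
    than the required valid hours are missing.
    """

    hourly: pd.DataFrame
    daily: pd.DataFrame
    n_animals: int


def total_heat_per_head(herd: HerdConfig) -> float:
    """CIGR total heat production of one cow at 20 degC, W."""
    return (5.6 * herd.body_mass ** 0.75
            + 22.0 * herd.milk_yield
            + 1.6e-5 * herd.pregnancy_days ** 3)


def co2_production(herd: HerdConfig, temp_c: float,
                   pressure_pa: float = STANDARD_PRESSURE_PA) -> float:
    """Herd CO2 production at ambient temperature, g h^-1.

    Heat output rises in cold air (4 W per hpu and degC below 20), and
    CO2 output scales with heat: 0.185 m^3 h^-1 per heat-producing
    unit, converted to mass at the barn temperature.
    """
    import warnings
    if not (TEMP_VALID_RANGE[0] <= temp_c <= TEMP_VALID_RANGE[1]):
        warnings.warn(f"temperature {temp_c} degC outside {TEMP_VALID_RANGE}: "
                      "CO2 correction extrapolated", stacklevel=2)
    phi = total_heat_per_head(herd) * (1000.0 + 4.0 * (20.0 - temp_c)) / 1000.0
    hpu = phi / 1000.0
    vol_m3_h = CO2_PER_HPU * hpu
    co2_density = ppm_to_mass_conc(1e6, "co2", temp_c, pressure_pa)  # pure gas, g m^-3
    return float(vol_m3_h * co2_density * herd.n_animals)


def nh3_emission(inputs: EmissionInputs) -> float:
    """Tracer-balance NH3 emission for one hour, g h^-1."""
    d_co2 = inputs.c_co2_barn - inputs.c_co2_outside
    if d_co2 <= 0:
        raise TracerUndefined(
            f"indoor-outdoor CO2 difference {d_co2:g} g m^-3 is not positive")
    d_nh3 = inputs.c_nh3_barn - inputs.c_nh3_outside
    return float(inputs.p_co2 * d_nh3 / d_co2)


def hourly_emissions(indoor: Sequence[DeviceSeries], outdoor: DeviceSeries,
                     herd: HerdConfig,
                     pressure_pa: float = STANDARD_PRESSURE_PA) -> pd.DataFrame:
    """Run the tracer balance on each common hour of the device series.

    ``indoor`` are the barn nodes (their NH3/CO2/temperature readings
    are averaged across devices before entering the balance), and
    ``outdoor`` the background node. Sensor ppm readings are converted
    to mass concentrations at each measurement point's own temperature.
    Returns a frame indexed by hour with E_g_per_h, the inputs used,
    and a ``valid`` flag (False where the CO2 difference is
    non-positive or inputs are missing).
    """
    if not indoor:
        raise ValueError("need at least one indoor device")
    for ds in list(indoor) + [outdoor]:
        if ds.freq != "hourly":
            raise ValueError("emission inputs must be hourly series")
    barn = sum(ds.data[["nh3", "co2", "temp"]] for ds in indoor) / len(indoor)
    out = outdoor.data[["nh3", "co2", "temp"]]
    idx = barn.index.intersection(out.index)
    barn, out = barn.loc[idx], out.loc[idx]

    c_nh3_in = ppm_to_mass_conc(barn["nh3"], "nh3", barn["temp"], pressure_pa)
    c_co2_in = ppm_to_mass_conc(barn["co2"], "co2", barn["temp"], pressure_pa)
    c_nh3_out = ppm_to_mass_conc(out["nh3"], "nh3", out["temp"], pressure_pa)
    c_co2_out = ppm_to_mass_conc(out["co2"], "co2", out["temp"], pressure_pa)
    p_co2 = np.array([co2_production(herd, t, pressure_pa) if np.isfinite(t) else np.nan
                      for t in barn["temp"]])

    d_nh3 = c_nh3_in - c_nh3_out
    d_co2 = c_co2_in - c_co2_out
    valid = np.isfinite(d_nh3) & np.isfinite(d_co2) & np.isfinite(p_co2) & (d_co2 > 0)
    e = np.where(valid, p_co2 * d_nh3 / np.where(d_co2 > 0, d_co2, np.nan), np.nan)
    return pd.DataFrame({
        "E_g_per_h": e, "valid": valid, "p_co2": p_co2,
        "d_nh3": d_nh3, "d_co2": d_co2, "temp": barn["temp"],
    }, index=idx)


def daily_emission(hourly: pd.DataFrame, herd: HerdConfig,
                   min_valid_hours: int = 12) -> EmissionEstimate:
    """Summarize hourly tracer estimates into daily per-animal values.

    The daily value is the mean over valid hours; days with fewer than
    ``min_valid_hours`` valid hours are reported missing. Per-animal
    rate = 24 x daily mean / herd size.
    """
    by_day = hourly.groupby(hourly.index.date)
    rows = []
    for day, chunk in by_day:
        valid = chunk[chunk["valid"]]
        n_valid = len(valid)
        if n_valid >= min_valid_hours:
            mean_e = float(valid["E_g_per_h"].mean())
            per_animal = 24.0 * mean_e / herd.n_animals
        else:
            mean_e, per_animal = np.nan, np.nan
        rows.append({"date": pd.Timestamp(day), "E_g_per_h": mean_e,
                     "E_g_per_animal_day": per_animal, "valid_hours": n_valid})
    daily = pd.DataFrame(rows).set_index("date")
    return EmissionEstimate(hourly=hourly, daily=daily, n_animals=herd.n_animals)
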