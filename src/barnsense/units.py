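"""Gas concentration unit conversions (ideal-gas law).

Sensors report volumetric mixing ratios (ppm); the tracer-gas mass
balance works in mass concentrations (g m^-3). The two are linked by
the molar volume of air at the prevailing temperature and pressure.
"""

from __future__ import annotations

import numpy as np

R = 8.314462618  # J mol^-1 K^-1
STANDARD_PRESSURE_PA = 101325.0

#: Molar masses, g mol^-1
MOLAR_MASS = {
    "nh3": 17.031,
    "co2": 44.01,
    "h2s": 34.08,
}


def molar_density(temp_c: float, pressure_pa: float = STANDARD_PRESSURE_PA):
    """Moles of ideal gas per m^3 of air at the given conditions."""
    t_k = np.asarray(temp_c, dtype=float) + 273.15
    if np.any(t_k <= 0):
        raise ValueError("temperature must be above absolute zero")
    if pressure_pa <= 0:
        raise ValueError("pressure must be positive")
    return pressure_pa / (R * t_k)


def ppm_to_mass_conc(ppm, gas: str, temp_c=20.0,
                     pressure_pa: float = STANDARD_PRESSURE_PA):
    """Convert a mixing ratio (ppm) to mass concentration (g m^-3)."""
    gas = gas.lower()
    if gas not in MOLAR_MASS:
        raise ValueError(f"unknown gas {gas!r}; expected one of {sorted(MOLAR_MASS)}")
    return np.asarray(ppm, dtype=float) * 1e-6 * MOLAR_MASS[gas] * molar_density(temp_c, pressure_pa)


def mass_conc_to_ppm(g_per_m3, gas: str, temp_c=20.0,
                     pressure_pa: float = STANDARD_PRESSURE_PA):
    """Convert a mass concentration (g m^-3) to a mixing ratio (ppm)."""
    gas = gas.lower()
    if gas not in MOLAR_MASS:
        raise ValueError(f"unknown gas {gas!r}; expected one of {sorted(MOLAR_MASS)}")
    return np.asarray(g_per_m3, dtype=float) / (MOLAR_MASS[gas] * molar_density(temp_c, pressure_pa)) * 1e6
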