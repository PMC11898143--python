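"""Generator checks: mass balance, steady states, determinism, events."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from barnsense.config import ClimateConfig, EventSchedule, ZoneConfig
from barnsense.synthetic_barn import (DT_SECONDS, make_truth, steady_state_conc,
                                      write_truth)
from barnsense.units import mass_conc_to_ppm, ppm_to_mass_conc


def quiet_climate(**kw):
    defaults = dict(mean_temp=15.0, diurnal_amplitude=0.0, rh_sigma=0.0,
                    outdoor_nh3=0.0, outdoor_co2=420.0, outdoor_h2s=0.0)
    defaults.update(kw)
    return ClimateConfig(**defaults)


NO_EVENTS = EventSchedule(event_times=[], multiplier=1.0)


def nh3_mass(truth, zone):
    """Zone NH3 back in g m^-3 (inverts the generator's own conversion)."""
    df = truth.frame(zone)
    return ppm_to_mass_conc(df["nh3"].to_numpy(), "nh3", df["temp"].to_numpy())


@pytest.mark.parametrize("source,vent,background,expected", [
    (0, 1000, 0.001, 0.001),
    (50, 10000, 0, 0.005),
    (100, 5000, 0.0004, 0.0204),
])
def test_steady_state_closed_form(source, vent, background, expected):
    assert steady_state_conc(source, vent, background) == pytest.approx(expected)


def test_steady_state_rejects_nonpositive_ventilation():
    with pytest.raises(ValueError):
        steady_state_conc(10, 0, 0)


def test_zero_source_zones_sit_at_background():
    zone = ZoneConfig(zone_id="a", volume=500, ventilation_rate=5000)
    climate = quiet_climate(outdoor_nh3=0.1, outdoor_h2s=0.0)
    truth = make_truth([zone], climate, NO_EVENTS, 1, seed=1)
    # the state variable is mass concentration: with no source the zone
    # matches outdoor exactly (the mixing ratio then differs only by the
    # indoor/outdoor temperature ratio)
    assert np.allclose(nh3_mass(truth, "a"),
                       ppm_to_mass_conc(0.1, "nh3", quiet_climate().mean_temp),
                       rtol=1e-9)
    assert np.allclose(truth.frame("a")["h2s"], 0.0)
    # with no animal-heat offset the mixing ratios coincide too
    same_t = make_truth([zone], quiet_climate(outdoor_nh3=0.1, indoor_offset=0.0),
                        NO_EVENTS, 1, seed=1)
    assert np.allclose(same_t.frame("a")["nh3"], 0.1, rtol=1e-9)
    assert np.allclose(same_t.frame("a")["co2"], 420.0, rtol=1e-9)


def test_convergence_to_steady_state_from_background():
    """C_out + S/Q is reached within 1e-9 relative well past 10 time constants."""
    zone = ZoneConfig(zone_id="a", volume=100, ventilation_rate=10000,
                      nh3_source=50)
    truth = make_truth([zone], quiet_climate(), NO_EVENTS, 1, seed=0)
    c = nh3_mass(truth, "a")
    assert c[0] == pytest.approx(0.0, abs=1e-15)
    # tau = V/Q = 36 s; by the end of the day thousands of taus have passed
    assert c[-1] == pytest.approx(0.005, rel=1e-9)


def test_steady_initialization_holds_steady_state_throughout():
    zone = ZoneConfig(zone_id="a", volume=4000, ventilation_rate=8000,
                      nh3_source=40, co2_source=50000)
    truth = make_truth([zone], quiet_climate(), NO_EVENTS, 1, seed=0,
                       initial="steady")
    c = nh3_mass(truth, "a")
    assert np.allclose(c, 0.005, rtol=1e-12)


@given(volume=st.floats(50, 5000), vent=st.floats(500, 50000),
       source=st.floats(0, 500))
def test_discrete_update_matches_analytic_solution(volume, vent, source):
    """The exact-exponential step reproduces the linear-ODE solution."""
    zone = ZoneConfig(zone_id="a", volume=volume, ventilation_rate=vent,
                      nh3_source=source)
    truth = make_truth([zone], quiet_climate(), NO_EVENTS, 1, seed=0)
    c = nh3_mass(truth, "a")
    t_h = np.arange(len(c)) * DT_SECONDS / 3600.0
    css = source / vent
    analytic = css * (1 - np.exp(-vent * t_h / volume))
    assert np.allclose(c, analytic, rtol=1e-9, atol=1e-15)


def test_identical_config_and_seed_reproduce_bit_for_bit():
    zone = ZoneConfig(zone_id="a", volume=500, ventilation_rate=5000, nh3_source=20)
    climate = ClimateConfig()  # RH noise on
    a = make_truth([zone], climate, EventSchedule(), 1, seed=42)
    b = make_truth([zone], climate, EventSchedule(), 1, seed=42)
    for z in a.zones:
        pd.testing.assert_frame_equal(a.frame(z), b.frame(z))
    c = make_truth([zone], climate, EventSchedule(), 1, seed=43)
    assert not a.frame("a")["rh"].equals(c.frame("a")["rh"])


def test_larger_source_never_lowers_concentration():
    base = dict(volume=800, ventilation_rate=6000)
    lo = make_truth([ZoneConfig(zone_id="a", nh3_source=20, **base)],
                    quiet_climate(), EventSchedule(), 1, seed=7)
    hi = make_truth([ZoneConfig(zone_id="a", nh3_source=35, **base)],
                    quiet_climate(), EventSchedule(), 1, seed=7)
    assert (hi.frame("a")["nh3"].to_numpy()
            >= lo.frame("a")["nh3"].to_numpy() - 1e-12).all()


def test_zones_ordered_by_source_to_ventilation_ratio():
    zones = [
        ZoneConfig(zone_id="low", volume=500, ventilation_rate=10000, nh3_source=20),
        ZoneConfig(zone_id="mid", volume=500, ventilation_rate=5000, nh3_source=20),
        ZoneConfig(zone_id="high", volume=500, ventilation_rate=5000, nh3_source=60),
    ]
    truth = make_truth(zones, quiet_climate(), NO_EVENTS, 1, seed=0,
                       initial="steady")
    last = {z: truth.frame(z)["nh3"].iloc[-1] for z in ("low", "mid", "high")}
    assert last["low"] < last["mid"] < last["high"]


def test_feeding_events_raise_concentration_inside_window():
    zone = ZoneConfig(zone_id="a", volume=300, ventilation_rate=9000, nh3_source=30)
    events = EventSchedule(event_times=["07:15"], multiplier=2.0, duration_min=60)
    truth = make_truth([zone], quiet_climate(), events, 1, seed=0, initial="steady")
    s = truth.frame("a")["nh3"]
    before = s.between_time("06:30", "07:10").mean()
    during = s.between_time("07:45", "08:10").mean()  # past the rise transient
    assert during > 1.5 * before


def test_event_free_days_equal_with_and_without_schedule():
    zone = ZoneConfig(zone_id="a", volume=300, ventilation_rate=9000, nh3_source=30)
    none = make_truth([zone], quiet_climate(), NO_EVENTS, 1, seed=5)
    unit = make_truth([zone], quiet_climate(),
                      EventSchedule(multiplier=1.0), 1, seed=5)
    pd.testing.assert_frame_equal(none.frame("a"), unit.frame("a"))


def test_temperature_sinusoid_and_indoor_offset():
    zone = ZoneConfig(zone_id="a", volume=500, ventilation_rate=5000)
    climate = ClimateConfig(mean_temp=10, diurnal_amplitude=6, peak_hour=15,
                            indoor_offset=3.0, rh_sigma=0.0)
    truth = make_truth([zone], climate, NO_EVENTS, 1, seed=0)
    t_out = truth.frame("outdoor")["temp"]
    t_in = truth.frame("a")["temp"]
    assert t_out.max() == pytest.approx(16.0, abs=1e-6)
    assert t_out.idxmax().hour == 15
    assert np.allclose(t_in - t_out, 3.0)


def test_concentrations_never_below_background():
    zone = ZoneConfig(zone_id="a", volume=300, ventilation_rate=4000,
                      nh3_source=10, co2_source=20000, h2s_source=0.5)
    climate = quiet_climate(outdoor_nh3=0.05, outdoor_h2s=0.01)
    truth = make_truth([zone], climate, EventSchedule(), 2, seed=3)
    df = truth.frame("a")
    for gas, bg in (("nh3", 0.05), ("co2", 420.0), ("h2s", 0.01)):
        assert (df[gas] >= bg - 1e-9).all()


def test_invalid_configuration_rejected():
    with pytest.raises(ValueError):
        ZoneConfig(zone_id="bad", volume=-1, ventilation_rate=100)
    with pytest.raises(ValueError):
        ZoneConfig(zone_id="bad", volume=10, ventilation_rate=0)
    with pytest.raises(ValueError):
        EventSchedule(event_times=["25:00"])
    with pytest.raises(ValueError):
        make_truth([ZoneConfig(zone_id="a", volume=1, ventilation_rate=1)],
                   quiet_climate(), NO_EVENTS, 0, seed=0)


def test_truth_round_trips_through_csv_and_sidecar(tmp_path):
    zone = ZoneConfig(zone_id="a", volume=500, ventilation_rate=5000, nh3_source=20)
    truth = make_truth([zone], quiet_climate(), NO_EVENTS, 1, seed=9)
    write_truth(truth, tmp_path)
    back = pd.read_csv(tmp_path / "truth_a.csv", comment="#",
                       index_col="timestamp", parse_dates=True)
    assert np.allclose(back["nh3"], truth.frame("a")["nh3"], rtol=1e-6)
    sidecar = (tmp_path / "truth_params.json").read_text()
    assert '"seed": 9' in sidecar
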