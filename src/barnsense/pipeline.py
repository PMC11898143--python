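"""End-to-end campaign helpers: truth -> nodes -> packets -> analytics.

Chains the generator, the virtual nodes, the telemetry path and the
estimators for a whole scenario, the way a field campaign would run.
These helpers are what the acceptance checks and the CLI drive.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .channels import DEFAULT_POLICIES, DEFAULT_SPECS
from .codec import decode_packet, encode_packet
from .config import Scenario
from .emission import EmissionEstimate, daily_emission, hourly_emissions
from .ingest_aggregate import DeviceSeries, packets_to_series, resample
from .node_sim import assign_slots, packetize, simulate_node
from .synthetic_barn import GroundTruth, truth_from_scenario


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive n reproducible sub-seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % 2**31 for s in ss.generate_state(n, dtype=np.uint32)]


def simulate_campaign(scenario: Scenario, seed: int,
                      truth: Optional[GroundTruth] = None,
                      channels: Optional[Sequence[str]] = None,
                      noise_scale: float = 1.0,
                      via_codec: bool = False,
                      initial: str = "background") -> dict[str, DeviceSeries]:
    """Simulate every device of a scenario into 10-minute series.

    ``channels`` restricts the simulated fit-out (default: all).
    ``via_codec`` pushes each packet through the binary wire format,
    which quantizes values to the fixed-point resolution — leave off
    when exact recovery matters.
    """
    if truth is None:
        truth = truth_from_scenario(scenario, seed, initial=initial)
    policies = {ch: p for ch, p in DEFAULT_POLICIES.items()
                if channels is None or ch in channels}
    node_ids = [d.node_id for d in scenario.devices]
    slots = assign_slots(node_ids)
    seeds = child_seeds(seed, len(node_ids))
    out: dict[str, DeviceSeries] = {}
    for i, dev in enumerate(scenario.devices):
        samples = simulate_node(truth, dev.zone, DEFAULT_SPECS, policies,
                                noise_seed=seeds[i], node_id=i,
                                noise_scale=noise_scale)
        packets = packetize(samples, policies, node_id=i, slot=slots[dev.node_id])
        if via_codec:
            packets = [decode_packet(encode_packet(p)) for p in packets]
        out[dev.node_id] = packets_to_series(packets, node_id=dev.node_id)
    return out


def run_emission_pipeline(scenario: Scenario, seed: int,
                          truth: Optional[GroundTruth] = None,
                          noise_scale: float = 1.0,
                          initial: str = "steady",
                          via_codec: bool = False,
                          min_valid_hours: int = 12) -> EmissionEstimate:
    """Full tracer-gas emission estimate for a scenario with a herd.

    Simulates the barn nodes and the outdoor background node (NH3, CO2
    and temperature channels), aggregates to hourly series, and runs
    the CO2-tracer balance with herd CO2 production evaluated at the
    hourly barn temperature.
    """
    if scenario.herd is None:
        raise ValueError("scenario has no herd configuration")
    series = simulate_campaign(scenario, seed, truth=truth,
                               channels=("temp", "nh3", "co2"),
                               noise_scale=noise_scale, via_codec=via_codec,
                               initial=initial)
    hourly = {nid: resample(ds, "hourly") for nid, ds in series.items()}
    outdoor_ids = [d.node_id for d in scenario.devices if d.zone == "outdoor"]
    if len(outdoor_ids) != 1:
        raise ValueError("emission pipeline expects exactly one outdoor device")
    indoor = [hourly[nid] for nid in hourly if nid not in outdoor_ids]
    hr = hourly_emissions(indoor, hourly[outdoor_ids[0]], scenario.herd,
                          scenario.climate.pressure_pa)
    return daily_emission(hr, scenario.herd, min_valid_hours=min_valid_hours)
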