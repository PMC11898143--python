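"""Virtual-node checks: sampling, noise convention, aggregation, codec, slots."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from barnsense.channels import (CHANNEL_ORDER, DEFAULT_POLICIES, DEFAULT_SPECS,
                                ChannelSpec, SamplingPolicy)
from barnsense.codec import (BadChecksum, BadMagic, SCALE, Truncated,
                             decode_packet, encode_packet, read_pkt, write_pkt)
from barnsense.node_sim import (ChannelStats, PacketRecord, aggregate_window,
                                assign_slots, packetize, simulate_node)
from conftest import make_constant_truth


def tidy(channel, values, period_s=10, start="2023-01-01"):
    idx = pd.date_range(start, periods=len(values), freq=f"{period_s}s")
    return pd.DataFrame({"node_id": 0, "channel": channel,
                         "timestamp": idx, "value": values})


# ---------------------------------------------------------------------------
# sampling and noise

def test_noiseless_sensor_reports_truth_exactly():
    truth = make_constant_truth({"nh3": 5.0}, n=360)
    samples = simulate_node(truth, "z", DEFAULT_SPECS, DEFAULT_POLICIES,
                            noise_seed=0, noise_scale=0.0)
    assert (samples["value"] == 5.0).all()
    assert len(samples) == 360  # 10 s channel keeps the full grid


def test_accuracy_is_a_two_sigma_band():
    """NH3 at 20 ppm with +/-10% accuracy: ~95% of draws within [18, 22]."""
    truth = make_constant_truth({"nh3": 20.0}, n=10_000)
    samples = simulate_node(truth, "z", DEFAULT_SPECS, DEFAULT_POLICIES,
                            noise_seed=123)
    frac = samples["value"].between(18, 22).mean()
    assert 0.94 < frac < 0.96


def test_readings_below_range_floor_are_clipped():
    truth = make_constant_truth({"co2": 300.0}, n=120)
    samples = simulate_node(truth, "z", DEFAULT_SPECS, DEFAULT_POLICIES,
                            noise_seed=0, noise_scale=0.0)
    assert (samples["value"] == 400.0).all()  # NDIR range floor


def test_noisy_samples_never_leave_sensor_range():
    truth = make_constant_truth({"h2s": 9.9, "lux": 10.0}, n=2000)
    samples = simulate_node(truth, "z", DEFAULT_SPECS, DEFAULT_POLICIES,
                            noise_seed=5)
    for ch, spec in (("h2s", DEFAULT_SPECS["h2s"]), ("lux", DEFAULT_SPECS["lux"])):
        vals = samples.loc[samples["channel"] == ch, "value"]
        assert vals.between(spec.range_low, spec.range_high).all()


def test_sampling_periods_respected():
    truth = make_constant_truth({"nh3": 5.0, "temp": 20.0, "pm25": 15.0}, n=360)
    samples = simulate_node(truth, "z", DEFAULT_SPECS, DEFAULT_POLICIES,
                            noise_seed=0, noise_scale=0.0)
    counts = samples.groupby("channel").size()
    assert counts["nh3"] == 360      # every 10 s
    assert counts["temp"] == 60      # every minute
    assert counts["pm25"] == 4       # every 15 min over the hour


def test_unknown_zone_raises_lookup_error():
    truth = make_constant_truth({"nh3": 5.0})
    with pytest.raises(KeyError):
        simulate_node(truth, "nowhere", DEFAULT_SPECS, DEFAULT_POLICIES, 0)


# ---------------------------------------------------------------------------
# aggregation

def test_constant_window_collapses_to_one_value():
    policies = {"temp": SamplingPolicy("temp", 60)}
    rec = aggregate_window(tidy("temp", [22.0] * 10, period_s=60), policies,
                           window_start=int(pd.Timestamp("2023-01-01").timestamp()))
    s = rec.stats["temp"]
    assert s.avg == s.min == s.max == 22.0


def test_window_statistics_of_a_ramp():
    policies = {"nh3": SamplingPolicy("nh3", 10)}
    rec = aggregate_window(tidy("nh3", list(range(1, 61))), policies,
                           window_start=int(pd.Timestamp("2023-01-01").timestamp()))
    assert rec.stats["nh3"] == ChannelStats(30.5, 1.0, 60.0)


def test_slow_channel_skips_windows_without_a_fresh_measurement():
    """A 15-min sensor reports into the window its measurement lands in."""
    idx = pd.to_datetime(["2023-01-01 00:00:00", "2023-01-01 00:15:00"])
    samples = pd.DataFrame({"node_id": 0, "channel": "pm25",
                            "timestamp": idx, "value": [7.0, 9.0]})
    policies = {"pm25": SamplingPolicy("pm25", 900)}
    records = packetize(samples, policies)
    present = {r.window_start % 3600: r.stats.get("pm25") for r in records}
    t0 = 0
    assert present[t0] == ChannelStats(7.0, 7.0, 7.0)
    assert present[600] == ChannelStats(9.0, 9.0, 9.0)


def test_empty_window_clears_presence_flag():
    policies = {"nh3": SamplingPolicy("nh3", 10), "temp": SamplingPolicy("temp", 60)}
    rec = aggregate_window(tidy("temp", [20.0] * 10, period_s=60), policies,
                           window_start=int(pd.Timestamp("2023-01-01").timestamp()))
    assert "nh3" not in rec.stats and "temp" in rec.stats


def test_hourly_mean_of_packet_averages_conserves_raw_mean():
    """Six equal-weight windows reproduce the hour's raw mean to 1e-12."""
    rng = np.random.default_rng(0)
    values = rng.uniform(0, 50, 360)
    policies = {"nh3": SamplingPolicy("nh3", 10)}
    records = packetize(tidy("nh3", values), policies)
    assert len(records) == 6
    packet_mean = np.mean([r.stats["nh3"].avg for r in records])
    assert packet_mean == pytest.approx(values.mean(), rel=1e-12)


# ---------------------------------------------------------------------------
# codec

def record_strategy():
    def build(present, draws, node_id, slot, window):
        stats = {}
        for ch, triple in zip(present, draws):
            spec = DEFAULT_SPECS[ch]
            hi_cap = min(spec.range_high, 32767 / SCALE[ch])
            vals = sorted(spec.range_low + (hi_cap - spec.range_low) * f
                          for f in triple)
            # snap to the wire fixed-point grid so round-trip is identity
            q = [round(v * SCALE[ch]) / SCALE[ch] for v in vals]
            stats[ch] = ChannelStats(sorted(q)[1], min(q), max(q))
        return PacketRecord(node_id=node_id, slot=slot, window_start=window * 600,
                            stats=stats)

    return st.builds(
        build,
        st.lists(st.sampled_from(CHANNEL_ORDER), unique=True, min_size=0, max_size=13),
        st.lists(st.tuples(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)),
                 min_size=13, max_size=13),
        st.integers(0, 65535), st.integers(0, 599), st.integers(0, 7_000_000))


@given(record_strategy())
def test_codec_round_trip_is_identity_on_quantized_records(record):
    decoded = decode_packet(encode_packet(record))
    assert decoded.node_id == record.node_id
    assert decoded.slot == record.slot
    assert decoded.window_start == record.window_start
    assert set(decoded.stats) == set(record.stats)
    for ch, s in record.stats.items():
        d = decoded.stats[ch]
        assert d.avg == pytest.approx(s.avg, abs=1e-9)
        assert d.min == pytest.approx(s.min, abs=1e-9)
        assert d.max == pytest.approx(s.max, abs=1e-9)


def test_flipped_byte_fails_checksum():
    rec = PacketRecord(0, 1, 1200, {"temp": ChannelStats(20.0, 19.5, 21.0)})
    blob = bytearray(encode_packet(rec))
    blob[13] ^= 0xFF  # corrupt a payload byte past the 12-byte header
    with pytest.raises(BadChecksum):
        decode_packet(bytes(blob))


def test_decode_error_taxonomy():
    rec = PacketRecord(0, 1, 1200, {"temp": ChannelStats(20.0, 19.5, 21.0)})
    blob = encode_packet(rec)
    with pytest.raises(BadMagic):
        decode_packet(b"\x00" + blob[1:])
    with pytest.raises(Truncated):
        decode_packet(blob[:5])
    with pytest.raises(Truncated):
        decode_packet(blob[:-4])


def test_empty_packet_is_header_plus_crc_only():
    rec = PacketRecord(7, 3, 0, {})
    blob = encode_packet(rec)
    assert len(blob) == 12 + 2  # header (magic..bitmap) + CRC
    assert decode_packet(blob).stats == {}


def test_pkt_file_round_trip(tmp_path):
    records = [PacketRecord(1, 0, k * 600,
                            {"nh3": ChannelStats(2.5, 2.0, 3.0)})
               for k in range(5)]
    path = tmp_path / "node.pkt"
    write_pkt(records, path)
    back = read_pkt(path)
    assert [r.window_start for r in back] == [r.window_start for r in records]


# ---------------------------------------------------------------------------
# slots

def test_slot_assignment_is_injective_and_order_deterministic():
    ids = [f"N{i}" for i in range(600)]
    slots = assign_slots(ids)
    assert slots["N0"] == 0 and slots["N599"] == 599
    assert len(set(slots.values())) == 600
    assert assign_slots(["A", "B", "C"]) == {"A": 0, "B": 1, "C": 2}


def test_more_nodes_than_slots_is_a_capacity_error():
    with pytest.raises(ValueError):
        assign_slots([f"N{i}" for i in range(601)])
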