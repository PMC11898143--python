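"""Virtual sensor node: multi-rate sampling, aggregation, slot assignment.

Emulates the measurement firmware: each channel is read from the
ground-truth field at its native period through a noisy, range-limited
sensor transfer function, then every 10 minutes the in-window samples
are folded into a compact telemetry record (average, minimum, maximum
per channel). Slow channels (PM, VOC — 15 min period) legitimately miss
some windows; their presence flag is cleared rather than padded.

Noise convention: the datasheet accuracy is treated as a 2-sigma
half-width, i.e. additive Gaussian noise with SD = accuracy/2 (relative
accuracies are evaluated at the reading). Values are clipped to the
sensor range — physical sensors saturate rather than report out of
range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .channels import CHANNEL_ORDER, REPORT_PERIOD, ChannelSpec, SamplingPolicy
from .synthetic_barn import GroundTruth

logger = logging.getLogger(__name__)

#: one-second uplink slots in each 10-minute reporting period
N_SLOTS = 600


class RawSample(NamedTuple):
    """One timestamped reading of one channel on one node."""

    node_id: int
    channel: str
    timestamp: pd.Timestamp
    value: float


class ChannelStats(NamedTuple):
    avg: float
    min: float
    max: float


@dataclass
class PacketRecord:
    """One node's 10-minute aggregate — the unit of telemetry.

    ``stats`` holds (avg, min, max) per channel; a channel absent from
    the mapping has its presence flag cleared in the binary packet.
    """

    node_id: int
    slot: int
    window_start: int  # epoch seconds, multiple of REPORT_PERIOD
    stats: dict[str, ChannelStats]

    def __post_init__(self):
        if self.window_start % REPORT_PERIOD:
            raise ValueError("window_start must be aligned to the reporting period")
        for ch, s in self.stats.items():
            if not (s.min <= s.avg <= s.max):
                raise ValueError(f"{ch}: expected min <= avg <= max, got {s}")


def simulate_node(truth: GroundTruth, zone: str,
                  specs: Mapping[str, ChannelSpec],
                  policies: Mapping[str, SamplingPolicy],
                  noise_seed: int, node_id: int = 0,
                  noise_scale: float = 1.0) -> pd.DataFrame:
    """Sample the ground-truth field through each channel's sensor.

    Returns a tidy frame of raw samples (``node_id, channel, timestamp,
    value``), deterministic in ``noise_seed``. Channels without a policy
    are not sampled. ``noise_scale`` scales the sensor noise SD
    (0 gives an ideal noiseless sensor, still range-clipped).
    """
    field = truth.frame(zone)
    dt = int((field.index[1] - field.index[0]).total_seconds())
    rng = np.random.default_rng(noise_seed)
    parts = []
    for ch in CHANNEL_ORDER:  # fixed order keeps the noise stream reproducible
        if ch not in policies or ch not in field.columns:
            continue
        spec = specs[ch]
        stride = policies[ch].sample_period // dt
        series = field[ch].iloc[::stride]
        values = series.to_numpy(dtype=float)
        sd = spec.accuracy_at(values) / 2.0 * noise_scale
        noisy = values + rng.normal(0.0, 1.0, size=len(values)) * sd
        clipped = np.clip(noisy, spec.range_low, spec.range_high)
        parts.append(pd.DataFrame({
            "node_id": node_id, "channel": ch,
            "timestamp": series.index, "value": clipped,
        }))
    return pd.concat(parts, ignore_index=True)


def iter_samples(samples: pd.DataFrame) -> Iterable[RawSample]:
    """View a tidy sample frame as a stream of RawSample tuples."""
    for row in samples.itertuples(index=False):
        yield RawSample(row.node_id, row.channel, row.timestamp, row.value)


def aggregate_window(samples: pd.DataFrame,
                     policies: Mapping[str, SamplingPolicy],
                     window_start: int, node_id: int = 0,
                     slot: int = 0) -> PacketRecord:
    """Fold the raw samples of one 10-minute window into a PacketRecord.

    ``avg``/``min``/``max`` are computed over the in-window samples of
    each channel. A channel with no sample in the window (a slow sensor
    whose measurement was not yet ready, or a dropout) has its presence
    flag cleared; for channels expected every window this logs a warning.
    """
    t0 = pd.Timestamp(window_start, unit="s")
    t1 = t0 + pd.Timedelta(seconds=REPORT_PERIOD)
    in_win = samples[(samples["timestamp"] >= t0) & (samples["timestamp"] < t1)]
    stats: dict[str, ChannelStats] = {}
    for ch, policy in policies.items():
        vals = in_win.loc[in_win["channel"] == ch, "value"].to_numpy()
        if len(vals) == 0:
            if policy.sample_period < REPORT_PERIOD:
                logger.warning("node %s window %s: no samples for mandatory channel %s",
                               node_id, t0, ch)
            continue
        lo, hi = float(vals.min()), float(vals.max())
        # guard against 1-ulp excursions of the float mean on constant data
        avg = min(max(float(vals.mean()), lo), hi)
        stats[ch] = ChannelStats(avg, lo, hi)
    return PacketRecord(node_id=node_id, slot=slot, window_start=window_start,
                        stats=stats)


def packetize(samples: pd.DataFrame, policies: Mapping[str, SamplingPolicy],
              node_id: int = 0, slot: int = 0) -> list[PacketRecord]:
    """Aggregate a full sample stream into consecutive 10-minute packets."""
    epoch = samples["timestamp"].astype("int64") // 10**9
    first = int(epoch.min()) // REPORT_PERIOD * REPORT_PERIOD
    last = int(epoch.max())
    records = []
    work = samples.copy()
    work["_win"] = (epoch // REPORT_PERIOD) * REPORT_PERIOD
    grouped = dict(iter(work.groupby("_win")))
    for ws in range(first, last + 1, REPORT_PERIOD):
        chunk = grouped.get(ws)
        if chunk is None:
            continue
        records.append(aggregate_window(chunk, policies, ws, node_id, slot))
    return records


def assign_slots(node_ids: list) -> dict:
    """Deterministically assign each node a one-second uplink slot.

    The 10-minute reporting period holds 600 one-second slots; nodes
    get slots in registration order.
    """
    if len(node_ids) > N_SLOTS:
        raise ValueError(f"at most {N_SLOTS} nodes fit in the reporting period, "
                         f"got {len(node_ids)}")
    if len(set(node_ids)) != len(node_ids):
        raise ValueError("duplicate node ids")
    return {nid: i for i, nid in enumerate(node_ids)}
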