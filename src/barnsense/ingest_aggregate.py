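"""Gateway and cloud-side data path.

Covers three things: (1) the gateway's resilient store-and-forward
buffering — incoming telemetry is held in RAM across short outages,
spilled to persistent flash under pressure, and delivered exactly once
with its origin timestamps when the uplink returns; (2) decoding packet
streams into per-device time series and resampling them to hourly and
daily aggregates with coverage bookkeeping; (3) derived metrics
computed in the cloud rule chain: the temperature-humidity index and
rolling-window aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .channels import REPORT_PERIOD
from .node_sim import PacketRecord

_FREQ_ALIAS = {"10min": "10min", "hourly": "h", "daily": "D"}
_FREQ_RANK = {"10min": 0, "hourly": 1, "daily": 2}
#: records per target bin when the source grid is complete
_EXPECTED = {("10min", "hourly"): 6, ("10min", "daily"): 144, ("hourly", "daily"): 24}


# ---------------------------------------------------------------------------
# gateway buffering

def message_key(msg) -> tuple:
    """Identity of a telemetry message: (node_id, window_start)."""
    if isinstance(msg, PacketRecord):
        return (msg.node_id, msg.window_start)
    if isinstance(msg, tuple) and len(msg) >= 2:
        return (msg[0], msg[1])
    raise TypeError(f"cannot key message of type {type(msg).__name__}")


@dataclass
class BufferState:
    """Double-buffered gateway state.

    A message lives in exactly one of RAM, flash, or the delivered
    ledger. RAM is bounded and lost on power cycles; flash is
    persistent. Messages carry their node-side timestamps, so delayed
    delivery never changes their time of generation.
    """

    ram: list = field(default_factory=list)
    flash: list = field(default_factory=list)
    delivered: dict = field(default_factory=dict)  # key -> message
    link_up: bool = True
    ram_capacity: int = 64

    def holds(self, msg) -> str:
        key = message_key(msg)
        if key in self.delivered:
            return "delivered"
        if any(message_key(m) == key for m in self.flash):
            return "flash"
        if any(message_key(m) == key for m in self.ram):
            return "ram"
        return "absent"


def _deliver(state: BufferState, msg) -> None:
    key = message_key(msg)
    if key not in state.delivered:  # duplicate suppression
        state.delivered[key] = msg


def _flush(state: BufferState) -> None:
    for msg in state.flash:
        _deliver(state, msg)
    state.flash.clear()
    for msg in state.ram:
        _deliver(state, msg)
    state.ram.clear()


def gateway_step(state: BufferState, event: str, msg=None) -> BufferState:
    """Advance the gateway state machine by one event.

    Events: ``receive`` (with ``msg``) — deliver immediately when the
    link is up, else buffer in RAM, spilling the oldest entries to
    flash beyond ``ram_capacity``; ``link_up`` — flush flash then RAM
    to the cloud; ``link_down``; ``power_cycle`` — RAM contents not yet
    spilled are lost, flash survives and is flushed at the next link-up.
    Duplicate messages (same node and window) are delivered once.
    """
    if event == "receive":
        if msg is None:
            raise ValueError("receive event needs a message")
        if state.link_up:
            _deliver(state, msg)
        else:
            state.ram.append(msg)
            while len(state.ram) > state.ram_capacity:
                state.flash.append(state.ram.pop(0))
    elif event == "link_up":
        state.link_up = True
        _flush(state)
    elif event == "link_down":
        state.link_up = False
    elif event == "power_cycle":
        state.ram.clear()
        state.link_up = False
    else:
        raise ValueError(f"unknown event {event!r}")
    return state


# ---------------------------------------------------------------------------
# device series and resampling

@dataclass
class DeviceSeries:
    """Time-indexed multichannel series for one device.

    ``data`` is a wide frame (DatetimeIndex x channels); ``coverage``
    is aligned to it and gives, per aggregate, the fraction of expected
    underlying records that were present.
    """

    node_id: object
    freq: str                      # "10min" | "hourly" | "daily"
    data: pd.DataFrame
    coverage: pd.DataFrame

    def __post_init__(self):
        if self.freq not in _FREQ_RANK:
            raise ValueError(f"freq must be one of {sorted(_FREQ_RANK)}")
        if not self.data.index.is_monotonic_increasing or self.data.index.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")


def packets_to_series(records: Iterable[PacketRecord], stat: str = "avg",
                      node_id=None) -> DeviceSeries:
    """Decode a packet stream into a 10-minute DeviceSeries.

    ``stat`` selects which per-window statistic becomes the series
    value (the cloud pipeline aggregates on averages; min/max remain
    available for exceedance checks by re-running with another stat).
    """
    rows, times = [], []
    nid = node_id
    for rec in records:
        if nid is None:
            nid = rec.node_id
        times.append(pd.Timestamp(rec.window_start, unit="s"))
        rows.append({ch: getattr(s, stat) for ch, s in rec.stats.items()})
    data = pd.DataFrame(rows, index=pd.DatetimeIndex(times)).sort_index()
    coverage = (~data.isna()).astype(float)
    return DeviceSeries(node_id=nid, freq="10min", data=data, coverage=coverage)


def series_from_frame(data: pd.DataFrame, node_id=None,
                      freq: str = "10min") -> DeviceSeries:
    """Wrap a complete wide frame as a DeviceSeries with full coverage."""
    cov = (~data.isna()).astype(float)
    return DeviceSeries(node_id=node_id, freq=freq, data=data, coverage=cov)


def resample(series: DeviceSeries, target: str,
             min_coverage: float = 0.5) -> DeviceSeries:
    """Aggregate a DeviceSeries to hourly or daily means.

    Each target bin gets the arithmetic mean of the available records;
    bins whose coverage falls below ``min_coverage`` are marked missing
    (NaN) but keep their recorded coverage.
    """
    if target not in ("hourly", "daily"):
        raise ValueError("target must be 'hourly' or 'daily'")
    if _FREQ_RANK[series.freq] >= _FREQ_RANK[target]:
        raise ValueError(f"cannot resample {series.freq} input to {target}")
    expected = _EXPECTED[(series.freq, target)]
    rule = _FREQ_ALIAS[target]
    grouped = series.data.resample(rule)
    mean = grouped.mean()
    count = grouped.count()
    coverage = count / expected
    mean = mean.where(coverage >= min_coverage)
    return DeviceSeries(node_id=series.node_id, freq=target,
                        data=mean, coverage=coverage)


# ---------------------------------------------------------------------------
# derived metrics

def compute_thi(temp_c, rh_pct):
    """Temperature-humidity index (NRC/Kelly-Bond form).

    THI = (1.8 T + 32) - (0.55 - 0.0055 RH) (1.8 T - 26), with T in
    degC and RH in percent. Above ~68 dairy cows begin to experience
    heat stress; the index grows with temperature and, for warm air,
    with humidity.
    """
    t = np.asarray(temp_c, dtype=float)
    rh = np.asarray(rh_pct, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("RH must lie in [0, 100]")
    thi = (1.8 * t + 32) - (0.55 - 0.0055 * rh) * (1.8 * t - 26)
    return float(thi) if thi.ndim == 0 else thi


def rolling_aggregate(series: DeviceSeries, window_hours: float,
                      stat: str = "mean") -> DeviceSeries:
    """Trailing-window statistic, right-aligned, missing until filled."""
    step_h = {"10min": 1 / 6, "hourly": 1.0, "daily": 24.0}[series.freq]
    n = int(round(window_hours / step_h))
    if n < 1:
        raise ValueError("window shorter than the series resolution")
    roll = series.data.rolling(window=n, min_periods=n)
    data = getattr(roll, stat)()
    cov = series.coverage.rolling(window=n, min_periods=n).mean()
    return DeviceSeries(node_id=series.node_id, freq=series.freq,
                        data=data, coverage=cov)


# ---------------------------------------------------------------------------
# tidy CSV interface

def series_to_csv(series: DeviceSeries, path: str | Path) -> None:
    """Write tidy rows: node_id, timestamp, channel, value, coverage."""
    tidy = series.data.stack(future_stack=True).rename("value").reset_index()
    tidy.columns = ["timestamp", "channel", "value"]
    cov = series.coverage.stack(future_stack=True).rename("coverage").reset_index()
    tidy["coverage"] = cov["coverage"]
    tidy.insert(0, "node_id", series.node_id)
    tidy.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")


def series_from_csv(path: str | Path, freq: str) -> DeviceSeries:
    tidy = pd.read_csv(path, parse_dates=["timestamp"])
    node_id = tidy["node_id"].iloc[0]
    data = tidy.pivot(index="timestamp", columns="channel", values="value")
    cov = tidy.pivot(index="timestamp", columns="channel", values="coverage")
    return DeviceSeries(node_id=node_id, freq=freq, data=data, coverage=cov)
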