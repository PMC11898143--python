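"""Sensor channel characteristics and firmware sampling policies.

The defaults describe the multi-sensor node's fit-out: measurement
range and datasheet accuracy per channel, and how often the firmware
samples each sensor before aggregating into 10-minute telemetry
records. Accuracy may be absolute (in channel units), relative (a
fraction of the reading), or both — the effective half-width at a
reading x is max(accuracy_abs, accuracy_rel * x).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: telemetry reporting period, seconds
REPORT_PERIOD = 600

#: canonical channel order (fixes the packet presence-bitmap layout)
CHANNEL_ORDER = ("temp", "rh", "sound", "lux", "h2s", "nh3", "co2",
                 "voc", "nox", "pm1", "pm25", "pm4", "pm10")


@dataclass(frozen=True)
class ChannelSpec:
    """Measurement range and accuracy of one sensor channel."""

    channel: str
    range_low: float
    range_high: float
    accuracy_abs: float = 0.0    # channel units
    accuracy_rel: float = 0.0    # fraction of reading
    interface: str = "digital"   # "analog" | "digital"

    def __post_init__(self):
        if self.range_low >= self.range_high:
            raise ValueError(f"{self.channel}: range_low must be < range_high")
        if self.accuracy_abs <= 0 and self.accuracy_rel <= 0:
            raise ValueError(f"{self.channel}: accuracy must be positive")

    def accuracy_at(self, value):
        """Effective accuracy half-width at a given reading."""
        import numpy as np
        return np.maximum(self.accuracy_abs, self.accuracy_rel * np.abs(value))


@dataclass(frozen=True)
class SamplingPolicy:
    """How the firmware samples one channel into a 10-min record."""

    channel: str
    sample_period: int            # seconds: 10, 60 or 900
    stats: tuple[str, ...] = ("avg", "min", "max")
    report_period: int = REPORT_PERIOD

    def __post_init__(self):
        if self.sample_period not in (10, 60, 900):
            raise ValueError("sample_period must be 10, 60 or 900 s")
        if not self.stats:
            raise ValueError("stats must be non-empty")
        if self.channel == "sound" and not {"avg", "max"} <= set(self.stats):
            raise ValueError("sound must report both avg and max")


#: node sensor fit-out: range and accuracy per channel
DEFAULT_SPECS: dict[str, ChannelSpec] = {s.channel: s for s in [
    ChannelSpec("temp", -10, 60, accuracy_abs=0.2),
    ChannelSpec("rh", 0, 100, accuracy_rel=0.02),
    ChannelSpec("sound", 30, 130, accuracy_rel=0.02, interface="analog"),
    ChannelSpec("lux", 0, 128_000, accuracy_rel=0.30, interface="analog"),
    ChannelSpec("h2s", 0, 10, accuracy_rel=0.10, interface="analog"),
    ChannelSpec("nh3", 0, 100, accuracy_rel=0.10, interface="analog"),
    ChannelSpec("co2", 400, 10_000, accuracy_abs=30, accuracy_rel=0.03),
    ChannelSpec("voc", 500, 10_000, accuracy_abs=15, interface="analog"),
    ChannelSpec("nox", 50, 650, accuracy_abs=50, interface="analog"),
    ChannelSpec("pm1", 0, 1000, accuracy_abs=10),
    ChannelSpec("pm25", 0, 1000, accuracy_abs=10),
    ChannelSpec("pm4", 0, 1000, accuracy_abs=25),
    ChannelSpec("pm10", 0, 1000, accuracy_abs=25),
]}

#: firmware sampling schedule: electrochemical and sound every 10 s,
#: temperature/RH/CO2/light every minute, PM and VOC every 15 min
DEFAULT_POLICIES: dict[str, SamplingPolicy] = {p.channel: p for p in [
    SamplingPolicy("temp", 60),
    SamplingPolicy("rh", 60),
    SamplingPolicy("sound", 10, stats=("avg", "max")),
    SamplingPolicy("lux", 60),
    SamplingPolicy("h2s", 10),
    SamplingPolicy("nh3", 10),
    SamplingPolicy("co2", 60),
    SamplingPolicy("voc", 900),
    SamplingPolicy("nox", 900),
    SamplingPolicy("pm1", 900),
    SamplingPolicy("pm25", 900),
    SamplingPolicy("pm4", 900),
    SamplingPolicy("pm10", 900),
]}
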