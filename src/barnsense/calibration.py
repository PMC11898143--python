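"""Electrochemical sensor calibration and multi-device repeatability.

Electrochemical gas channels (NH3, H2S) produce a raw current of the
order of 10–200 nA/ppm with a zero-level offset; a two-point span
calibration against known concentrations recovers the (offset, gain)
pair that the analog frontend stores in the sensor board's EEPROM.
The NDIR CO2 channel already reads in ppm and only needs a zero
(offset) correction against a reference analyzer reading of the same
air.

The repeatability assessment places several calibrated nodes in the
same environment and reports, per 10-minute interval, the mean and SD
of the absolute deviations from a reference (the cross-node mean by
default, or a known applied concentration on the calibration bench),
then time-averages those statistics over the whole run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .channels import DEFAULT_SPECS, ChannelSpec


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationParams:
    """Per-sensor offset and gain (the EEPROM contents).

    For span-calibrated channels the sensor response model is
    ``raw = offset + gain * ppm``; for zero-calibrated CO2 the model is
    ``raw_ppm = ppm + offset`` and ``gain`` is 1.
    """

    channel: str
    offset: float            # raw-signal units (nA), or ppm for CO2
    gain: float = 1.0        # raw-signal units per ppm
    mode: str = "span"       # "span" | "zero"
    calibrated_at: str = ""
    reference_concentrations: tuple[float, ...] = ()

    def to_json(self, path: str | Path) -> None:
        """Persist to the small JSON document that emulates the EEPROM."""
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationParams":
        data = json.loads(Path(path).read_text())
        data["reference_concentrations"] = tuple(data["reference_concentrations"])
        return cls(**data)


def span_calibrate(point1: tuple[float, float], point2: tuple[float, float],
                   channel: str = "nh3", calibrated_at: str = "") -> CalibrationParams:
    """Two-point span calibration from (known_ppm, raw_signal) pairs.

    Fits the line ``raw = offset + gain * ppm`` through the two points;
    applying the inverse map to the calibration points returns the known
    concentrations exactly.
    """
    (c1, y1), (c2, y2) = point1, point2
    if c1 == c2:
        raise CalibrationError("the two reference concentrations must differ")
    gain = (y2 - y1) / (c2 - c1)
    if gain <= 0:
        raise CalibrationError(f"non-positive inferred gain {gain:g}: sensor fault")
    offset = y1 - gain * c1
    return CalibrationParams(channel=channel, offset=offset, gain=gain, mode="span",
                             calibrated_at=calibrated_at,
                             reference_concentrations=(c1, c2))


def zero_calibrate(raw_reading: float, reference_ppm: float,
                   channel: str = "co2", calibrated_at: str = "") -> CalibrationParams:
    """Zero (offset-only) calibration against a reference analyzer."""
    spec = DEFAULT_SPECS[channel]
    if not (spec.range_low <= reference_ppm <= spec.range_high):
        raise CalibrationError(
            f"reference {reference_ppm} ppm outside {channel} range "
            f"[{spec.range_low:g}, {spec.range_high:g}]")
    return CalibrationParams(channel=channel, offset=raw_reading - reference_ppm,
                             gain=1.0, mode="zero", calibrated_at=calibrated_at,
                             reference_concentrations=(reference_ppm,))


def apply_calibration(raw_signal, params: CalibrationParams,
                      spec: Optional[ChannelSpec] = None):
    """Map a raw sensor signal to a concentration in ppm.

    ``(raw - offset) / gain`` for span-calibrated channels,
    ``raw - offset`` for zero-calibrated ones; the result is clipped to
    the channel's measurement range when a spec is available.
    """
    if params is None:
        raise CalibrationError("channel has no stored calibration parameters")
    raw = np.asarray(raw_signal, dtype=float)
    ppm = (raw - params.offset) / params.gain if params.mode == "span" else raw - params.offset
    if spec is None:
        spec = DEFAULT_SPECS.get(params.channel)
    if spec is not None:
        ppm = np.clip(ppm, spec.range_low, spec.range_high)
    return float(ppm) if ppm.ndim == 0 else ppm


@dataclass
class RepeatabilityReport:
    """Inter-device error statistics at each interval plus their time average.

    ``per_interval`` has one row per timestamp and channel with the mean
    and sample SD of the absolute errors across nodes, in absolute and
    relative (fraction of the interval reference) form. ``summary`` is
    the time average of those four statistics per channel.
    """

    per_interval: pd.DataFrame
    summary: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        self.summary.to_csv(path, index_label="channel")


def repeatability_report(series: Mapping[str, pd.DataFrame],
                         reference: Optional[pd.DataFrame] = None) -> RepeatabilityReport:
    """Assess inter-device agreement on a common 10-minute time base.

    Parameters
    ----------
    series
        node_id -> DataFrame (DatetimeIndex x channels) of decoded
        10-minute averages; all frames must share index and columns.
    reference
        Optional known applied concentrations (bench mode). When
        omitted, the cross-node mean at each interval is the reference —
        the ambient-air check has no independent truth.
    """
    if len(series) < 2:
        raise ValueError("repeatability needs at least 2 nodes")
    frames = list(series.values())
    idx, cols = frames[0].index, frames[0].columns
    for f in frames[1:]:
        if not (f.index.equals(idx) and f.columns.equals(cols)):
            raise ValueError("all node series must share time base and channels")
    stack = np.stack([f.to_numpy(dtype=float) for f in frames])  # (node, time, ch)
    ref = reference.to_numpy(dtype=float) if reference is not None else stack.mean(axis=0)
    abs_err = np.abs(stack - ref)
    mean_err = abs_err.mean(axis=0)
    sd_err = abs_err.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_mean = np.where(ref != 0, mean_err / np.abs(ref), np.nan)
        rel_sd = np.where(ref != 0, sd_err / np.abs(ref), np.nan)

    per_interval = pd.concat({
        "mean_abs_err": pd.DataFrame(mean_err, index=idx, columns=cols),
        "sd_abs_err": pd.DataFrame(sd_err, index=idx, columns=cols),
        "mean_rel_err": pd.DataFrame(rel_mean, index=idx, columns=cols),
        "sd_rel_err": pd.DataFrame(rel_sd, index=idx, columns=cols),
    }, axis=1)

    summary = pd.DataFrame({
        "mean_abs_err": np.nanmean(mean_err, axis=0),
        "sd_abs_err": np.nanmean(sd_err, axis=0),
        "mean_rel_err": np.nanmean(rel_mean, axis=0),
        "sd_rel_err": np.nanmean(rel_sd, axis=0),
    }, index=cols)
    return RepeatabilityReport(per_interval=per_interval, summary=summary)
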