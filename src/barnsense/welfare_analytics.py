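"""Welfare adequacy and spatial/temporal structure of barn conditions.

Implements the analyses run on the recorded device series: exceedance
of air-quality welfare limits (EFSA-style: NH3 10 ppm, CO2 3000 ppm,
H2S 0.5 ppm), a uniformity comparison across monitoring points
(all-pairs Tukey test with a compact letter display, as used to spot
poorly ventilated zones), hour-of-day profiles that reveal
feeding-time concentration peaks, pairwise correlations of daily
values, and an inverse-distance-weighted concentration map of the
floor plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ingest_aggregate import DeviceSeries


@dataclass(frozen=True)
class WelfareLimits:
    """Upper concentration limits for adequate air quality (ppm)."""

    limits: Mapping[str, float] = field(default_factory=lambda: {
        "nh3": 10.0, "co2": 3000.0, "h2s": 0.5, "co": 10.0})
    species_overrides: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"rabbit": {"nh3": 10.0}})

    def limit_for(self, channel: str, species: Optional[str] = None) -> Optional[float]:
        if species and channel in self.species_overrides.get(species, {}):
            return self.species_overrides[species][channel]
        return self.limits.get(channel)


@dataclass
class ExceedanceReport:
    """Per device and channel: period mean, time above limit, flag.

    ``table`` columns: node_id, channel, mean, limit, frac_above,
    exceeds (strict inequality on the period mean — a series sitting
    exactly at the limit is not flagged).
    """

    table: pd.DataFrame

    def flagged(self, channel: Optional[str] = None) -> list:
        t = self.table[self.table["exceeds"]]
        if channel is not None:
            t = t[t["channel"] == channel]
        return list(t["node_id"])


def assess_thresholds(series: Mapping[object, DeviceSeries],
                      limits: WelfareLimits = WelfareLimits(),
                      species: Optional[str] = None) -> ExceedanceReport:
    """Compare each device's period means against the welfare limits.

    The time-above-limit fraction is computed from the finest
    resolution supplied. Channels without a limit are skipped.
    """
    if not series:
        raise ValueError("no device series supplied")
    rows = []
    for nid, ds in series.items():
        for ch in ds.data.columns:
            limit = limits.limit_for(ch, species)
            if limit is None:
                continue
            vals = ds.data[ch].dropna()
            if vals.empty:
                continue
            mean = float(vals.mean())
            rows.append({
                "node_id": nid, "channel": ch, "mean": mean, "limit": limit,
                "frac_above": float((vals > limit).mean()),
                "exceeds": mean > limit,
            })
    return ExceedanceReport(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# uniformity across monitoring points

@dataclass
class UniformityResult:
    """All-pairs comparison of device means on hourly values.

    Devices sharing a letter in ``letters`` show no pairwise difference
    at the chosen alpha; ``f_stat``/``f_pvalue`` give the overall
    one-way heterogeneity test.
    """

    means: pd.Series
    pvalues: pd.DataFrame
    letters: dict
    f_stat: float
    f_pvalue: float
    alpha: float


def _compact_letters(names: Sequence, means: pd.Series,
                     significant: set[frozenset]) -> dict:
    """Insert-and-absorb compact letter display.

    Starts from one column containing every device and splits a column
    for each significantly different pair it still joins, then drops
    columns that became subsets of others. Letters are assigned in
    descending order of group mean.
    """
    columns: list[set] = [set(names)]
    for pair in significant:
        a, b = tuple(pair)
        for col in list(columns):
            if a in col and b in col:
                columns.remove(col)
                columns.extend([col - {a}, col - {b}])
        # absorb duplicates / subsets
        columns = [c for c in columns
                   if c and not any(c < other for other in columns)]
        deduped = []
        for c in columns:
            if c not in deduped:
                deduped.append(c)
        columns = deduped
    columns.sort(key=lambda c: -max(means[n] for n in c))
    letters = {n: "" for n in names}
    for i, col in enumerate(columns):
        tag = chr(ord("a") + i) if i < 26 else f"z{i}"
        for n in col:
            letters[n] += tag
    return {n: "".join(sorted(v)) for n, v in letters.items()}


def uniformity_test(hourly: Mapping[object, Sequence[float]],
                    alpha: float = 0.01) -> UniformityResult:
    """Tukey all-pairs comparison of device means on hourly values.

    A one-way location comparison across the monitoring points with
    familywise-adjusted pairwise p-values; devices that never differ
    share a letter.
    """
    names = list(hourly)
    groups = [np.asarray(hourly[n], dtype=float) for n in names]
    if len(names) < 2:
        raise ValueError("uniformity needs at least 2 devices")
    if any(len(g) < 3 for g in groups):
        raise ValueError("each device needs at least 3 hourly values")
    means = pd.Series([g.mean() for g in groups], index=names)
    res = sps.tukey_hsd(*groups)
    pmat = pd.DataFrame(res.pvalue, index=names, columns=names)
    f_stat, f_pvalue = sps.f_oneway(*groups)
    significant = {frozenset((names[i], names[j]))
                   for i in range(len(names)) for j in range(i + 1, len(names))
                   if pmat.iloc[i, j] < alpha}
    letters = _compact_letters(names, means, significant)
    return UniformityResult(means=means, pvalues=pmat, letters=letters,
                            f_stat=float(f_stat), f_pvalue=float(f_pvalue),
                            alpha=alpha)


# ---------------------------------------------------------------------------
# temporal structure

def diurnal_profile(series: pd.Series) -> pd.DataFrame:
    """Hour-of-day means with standard errors across days.

    Input is a time-indexed series (10-min or hourly). Each day
    contributes one mean per hour-of-day; the profile reports the mean
    and SE (SD across days / sqrt(n_days)) for each of the 24 hours.
    """
    s = series.dropna()
    day_hour = s.groupby([s.index.date, s.index.hour]).mean()
    n_days = day_hour.index.get_level_values(0).nunique()
    if n_days < 2:
        raise ValueError("diurnal profile needs at least 2 days of data")
    by_hour = day_hour.groupby(level=1)
    prof = pd.DataFrame({
        "mean": by_hour.mean(),
        "se": by_hour.std(ddof=1) / np.sqrt(by_hour.count()),
    })
    prof.index.name = "hour"
    return prof


def correlate(a: pd.Series, b: pd.Series) -> tuple[float, float]:
    """Pearson correlation of two paired daily series with two-sided p."""
    joined = pd.concat([a, b], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("correlation needs at least 3 paired points")
    x, y = joined.iloc[:, 0], joined.iloc[:, 1]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# spatial structure

@dataclass
class SpatialMap:
    """IDW-interpolated concentration field over the floor plan."""

    x: np.ndarray          # grid x coordinates, m
    y: np.ndarray          # grid y coordinates, m
    field: np.ndarray      # shape (len(y), len(x))
    positions: pd.DataFrame  # node_id, x_m, y_m, value

    def to_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame({"x": xx.ravel(), "y": yy.ravel(),
                             "value": self.field.ravel()})


def spatial_map(positions: Mapping[object, tuple[float, float]],
                means: Mapping[object, float], grid_step: float = 0.5,
                power: float = 2.0) -> SpatialMap:
    """Inverse-distance-weighted map of device means.

    The field equals each device's value at its own position and is a
    convex combination of the device means elsewhere, so it stays
    within [min, max] of the inputs.
    """
    if len(positions) < 3:
        raise ValueError("spatial map needs at least 3 devices")
    pts = np.array([positions[n] for n in positions], dtype=float)
    if len(np.unique(pts, axis=0)) != len(pts):
        raise ValueError("duplicate device positions")
    vals = np.array([means[n] for n in positions], dtype=float)
    x = np.arange(pts[:, 0].min(), pts[:, 0].max() + grid_step / 2, grid_step)
    y = np.arange(pts[:, 1].min(), pts[:, 1].max() + grid_step / 2, grid_step)
    xx, yy = np.meshgrid(x, y)
    d2 = ((xx[..., None] - pts[:, 0]) ** 2 + (yy[..., None] - pts[:, 1]) ** 2)
    dist = np.sqrt(d2)
    fieldv = np.empty(xx.shape)
    at_node = dist.min(axis=-1) == 0
    with np.errstate(divide="ignore"):
        w = 1.0 / dist ** power
    w_ok = np.where(np.isfinite(w), w, 0.0)
    fieldv = (w_ok * vals).sum(axis=-1) / w_ok.sum(axis=-1)
    # exact value at (grid points coinciding with) device positions
    idx = np.argmin(dist, axis=-1)
    fieldv = np.where(at_node, vals[idx], fieldv)
    pos_df = pd.DataFrame({
        "node_id": list(positions),
        "x_m": pts[:, 0], "y_m": pts[:, 1], "value": vals,
    })
    return SpatialMap(x=x, y=y, field=fieldv, positions=pos_df)


def idw_at(point: tuple[float, float],
           positions: Mapping[object, tuple[float, float]],
           means: Mapping[object, float], power: float = 2.0) -> float:
    """IDW prediction at a single point (exact at device positions)."""
    pts = np.array([positions[n] for n in positions], dtype=float)
    vals = np.array([means[n] for n in positions], dtype=float)
    d = np.hypot(pts[:, 0] - point[0], pts[:, 1] - point[1])
    if np.any(d == 0):
        return float(vals[np.argmin(d)])
    w = 1.0 / d ** power
    return float((w * vals).sum() / w.sum())
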