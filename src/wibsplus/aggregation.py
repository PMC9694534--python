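"""Time-binned number concentrations, diurnal profiles and size/AF summaries.

A concentration series divides per-bin particle counts by the air volume
sampled in the bin (flow × bin duration). Bins falling in declared
instrument downtime are reported as missing (NaN), never as zero; a bin
with full uptime and no particles is a genuine zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError

logger = logging.getLogger(__name__)

Interval = tuple[pd.Timestamp, pd.Timestamp]


@dataclass
class ConcentrationSeries:
    """Binned number concentrations for a named particle selection.

    ``data`` is indexed by bin start and carries ``count``, ``volume_m3``,
    ``coverage`` (fraction of the bin inside instrument uptime) and
    ``concentration_m3`` (NaN where coverage is below the reporting
    threshold). ``flow`` is the sample flow in L/min used for the volume.
    """

    name: str
    flow: float
    freq: str
    min_coverage: float
    data: pd.DataFrame

    @property
    def concentrations(self) -> pd.Series:
        return self.data["concentration_m3"]


def _coverage(
    starts: pd.DatetimeIndex, duration: pd.Timedelta, uptime: Sequence[Interval] | None
) -> np.ndarray:
    if uptime is None:
        return np.ones(len(starts))
    t0 = starts.asi8.astype(float)
    t1 = t0 + duration.value
    cov = np.zeros(len(starts))
    for lo, hi in uptime:
        lo_ns = float(pd.Timestamp(lo).value)
        hi_ns = float(pd.Timestamp(hi).value)
        overlap = np.minimum(t1, hi_ns) - np.maximum(t0, lo_ns)
        cov += np.clip(overlap / duration.value, 0.0, 1.0)
    return np.clip(cov, 0.0, 1.0)


def aggregate_concentration(
    particles: pd.DataFrame,
    freq: str = "1h",
    flow: float = 0.23,
    uptime: Sequence[Interval] | None = None,
    span: Interval | None = None,
    name: str = "",
    min_coverage: float = 0.75,
) -> ConcentrationSeries:
    """Bin particle timestamps and convert counts to number concentrations.

    Parameters
    ----------
    particles
        Collection with a ``timestamp`` column (any prior selection).
    freq
        Bin width as a pandas offset (``"1h"``, ``"1D"``); must divide a
        day evenly so hourly and daily series align.
    flow
        Sample flow in L/min; per-bin volume is ``flow × duration`` in m³.
    uptime
        Intervals of instrument operation. Bins whose uptime coverage is
        below ``min_coverage`` are reported missing (NaN).
    span
        Optional (start, end) to bin over; defaults to the calendar days
        covering the data.
    """
    if flow <= 0:
        raise ConfigurationError("flow must be positive")
    duration = pd.Timedelta(freq)
    day = pd.Timedelta("1D")
    if duration <= pd.Timedelta(0) or (day.value % duration.value) != 0:
        raise ConfigurationError(f"bin width {freq!r} must divide a day evenly")

    ts = pd.to_datetime(particles["timestamp"])
    if span is not None:
        start, end = pd.Timestamp(span[0]), pd.Timestamp(span[1])
    elif len(ts):
        start = ts.min().floor("D")
        end = ts.max().ceil("D")
        if end == ts.max():  # timestamp exactly at midnight
            end = end + day
    else:
        raise InsufficientDataError(
            "empty selection and no span given; nothing to bin"
        )
    starts = pd.date_range(start, end, freq=freq, inclusive="left")

    binned = ts.dt.floor(freq)
    counts = binned.value_counts().reindex(starts, fill_value=0).astype(int)
    volume = flow * (duration / pd.Timedelta("1min")) / 1000.0  # m³ per bin
    cov = _coverage(starts, duration, uptime)
    conc = counts.to_numpy() / volume
    conc = np.where(cov >= min_coverage, conc, np.nan)

    data = pd.DataFrame(
        {
            "count": counts.to_numpy(),
            "volume_m3": volume,
            "coverage": cov,
            "concentration_m3": conc,
        },
        index=pd.Index(starts, name="bin_start"),
    )
    return ConcentrationSeries(
        name=name, flow=flow, freq=freq, min_coverage=min_coverage, data=data
    )


def rebin(series: ConcentrationSeries, freq: str) -> ConcentrationSeries:
    """Aggregate a series to coarser bins (e.g. hourly → daily).

    Counts and volumes add; coverage averages. The missing-bin rule is
    re-applied at the coarser width, so rebinning an hourly series to daily
    matches a directly computed daily series.
    """
    duration = pd.Timedelta(freq)
    if duration < pd.Timedelta(series.freq):
        raise ConfigurationError("rebin target must be coarser than the source")
    grouped = series.data.groupby(series.data.index.floor(freq))
    counts = grouped["count"].sum()
    volume = grouped["volume_m3"].sum()
    cov = grouped["coverage"].mean()
    conc = np.where(cov >= series.min_coverage, counts / volume, np.nan)
    data = pd.DataFrame(
        {
            "count": counts,
            "volume_m3": volume,
            "coverage": cov,
            "concentration_m3": conc,
        }
    )
    data.index.name = "bin_start"
    return ConcentrationSeries(
        name=series.name,
        flow=series.flow,
        freq=freq,
        min_coverage=series.min_coverage,
        data=data,
    )


def daily(series: ConcentrationSeries) -> pd.Series:
    """Daily concentrations (per m³) indexed by calendar date."""
    d = series if series.freq.upper() in ("1D", "D") else rebin(series, "1D")
    out = d.data["concentration_m3"].copy()
    out.index = out.index.normalize()
    return out


@dataclass
class DiurnalProfile:
    """24 hourly values normalised to [0, 1]."""

    values: np.ndarray
    mode: str

    def peak_hour(self) -> int:
        return int(np.argmax(self.values))


def diurnal_profile(series: ConcentrationSeries, mode: str = "max") -> DiurnalProfile:
    """Mean concentration per hour of day across days, normalised.

    ``mode="max"`` divides by the largest hourly mean (the peak hour reads
    1.0); ``mode="mean"`` divides by the mean of the 24 hourly means.
    Missing bins are excluded from the hourly means.
    """
    if pd.Timedelta(series.freq) != pd.Timedelta("1h"):
        raise ConfigurationError("diurnal profiles require an hourly series")
    if mode not in ("max", "mean"):
        raise ConfigurationError("mode must be 'max' or 'mean'")
    data = series.data
    if len(data) < 24:
        raise InsufficientDataError("at least one full day of hourly bins required")
    valid = data["concentration_m3"].dropna()
    if valid.empty:
        raise InsufficientDataError("all bins missing; no diurnal profile")
    hourly = valid.groupby(valid.index.hour).mean().reindex(range(24))
    values = hourly.to_numpy(dtype=float)
    values = np.nan_to_num(values, nan=0.0)
    denom = values.max() if mode == "max" else values.mean()
    if denom == 0:
        return DiurnalProfile(values=np.zeros(24), mode=mode)
    return DiurnalProfile(values=values / denom, mode=mode)


def size_af_summary(
    classified: pd.DataFrame,
    by: str = "perring_class",
    size_bins: np.ndarray | None = None,
    af_bins: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]]:
    """Per-class median optical size and asymmetry factor, plus 2-D
    size × AF histograms for plotting.

    Classes with no particles are simply absent from the output.
    """
    if classified.empty:
        logger.warning("size_af_summary called on an empty collection")
        return pd.DataFrame(columns=["n", "median_size", "median_af"]), {}
    size_bins = size_bins if size_bins is not None else np.linspace(0, 40, 41)
    af_bins = af_bins if af_bins is not None else np.linspace(0, 100, 51)
    rows = []
    hists: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for label, grp in classified.groupby(by, sort=True):
        rows.append(
            {
                "class": label,
                "n": len(grp),
                "median_size": float(grp["size"].median()),
                "median_af": float(grp["af"].median()),
            }
        )
        H, se, ae = np.histogram2d(grp["size"], grp["af"], bins=[size_bins, af_bins])
        hists[str(label)] = (H, se, ae)
    summary = pd.DataFrame(rows).set_index("class")
    return summary, hists
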