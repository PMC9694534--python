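"""Reading and writing of single-particle event tables and daily taxon series.

The on-disk formats are plain comma-separated UTF-8 text with a header row:

* particle events:   ``timestamp,size,af,fl1,fl2,fl3,fl4,fl5``
* forced trigger:    same fluorescence columns; ``timestamp``, ``size`` and
  ``af`` are optional because the instrument fires on particle-free air
* daily taxon table: ``date,taxon,concentration`` (grains or spores per m³)

Timestamps are treated as local campaign time throughout; no timezone
conversion is applied.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical column order of a particle-event table.
PARTICLE_COLUMNS = ("timestamp", "size", "af", "fl1", "fl2", "fl3", "fl4", "fl5")

#: The five fluorescence detection channels of the WIBS-4+.
FLUOR_CHANNELS = ("fl1", "fl2", "fl3", "fl4", "fl5")

TAXON_COLUMNS = ("date", "taxon", "concentration")

VALID_SIGMA = (3, 6, 9)


@dataclass
class CampaignConfig:
    """Instrument and campaign settings used across the pipeline.

    Parameters
    ----------
    wibs_flow
        WIBS sample flow in L/min. The default of 0.23 L/min is typical of
        the instrument family; every concentration output records the flow
        actually used.
    hirst_flow
        Hirst volumetric sampler flow in L/min (10 L/min by convention).
    saturation_ceiling
        Detector intensity ceiling in arbitrary units. Values at the
        ceiling are kept and flagged as saturated, never dropped.
    size_max
        Largest optical-equivalent diameter the instrument reports, µm.
    sigma_multiplier
        Fluorescence threshold multiplier k in ``mean + k·sd``; one of
        3, 6 or 9.
    fluorescence_basis
        Which channels define the "fluorescent" designation of a particle:
        ``"fl12345"`` (any of the five channels, the default) or
        ``"fl123"`` (the three classic channels only).
    """

    wibs_flow: float = 0.23
    hirst_flow: float = 10.0
    saturation_ceiling: float = 2047.0
    size_max: float = 40.0
    sigma_multiplier: int = 3
    fluorescence_basis: str = "fl12345"
    timezone_note: str = "local campaign time, no conversion applied"

    def __post_init__(self) -> None:
        if self.wibs_flow <= 0 or self.hirst_flow <= 0:
            raise ValidationError("sample flows must be positive")
        if self.sigma_multiplier not in VALID_SIGMA:
            raise ValidationError(
                f"sigma_multiplier must be one of {VALID_SIGMA}, "
                f"got {self.sigma_multiplier}"
            )
        if self.fluorescence_basis not in ("fl123", "fl12345"):
            raise ValidationError(
                "fluorescence_basis must be 'fl123' or 'fl12345'"
            )
        if self.size_max <= 0 or self.saturation_ceiling <= 0:
            raise ValidationError("size_max and saturation_ceiling must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CampaignConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _first_invalid(mask: pd.Series, reason: str, rejects: list) -> None:
    for idx in mask.index[mask]:
        rejects.append((int(idx), reason))


def _validate_particles(
    df: pd.DataFrame, config: CampaignConfig
) -> list[tuple[int, str]]:
    """Return (row, reason) pairs for every invalid row, in row order."""
    rejects: list[tuple[int, str]] = []
    _first_invalid(~(df["size"] > 0), "size must be positive", rejects)
    _first_invalid(df["size"] > config.size_max,
                   f"size exceeds instrument maximum {config.size_max} µm", rejects)
    _first_invalid(df["af"] < 0, "asymmetry factor must be >= 0", rejects)
    for ch in FLUOR_CHANNELS:
        _first_invalid(df[ch] < 0, f"{ch} intensity must be >= 0", rejects)
        _first_invalid(df[ch] > config.saturation_ceiling,
                       f"{ch} intensity exceeds saturation ceiling", rejects)
    nan_rows = df[list(PARTICLE_COLUMNS)].isna().any(axis=1)
    _first_invalid(nan_rows, "missing or unparseable value", rejects)
    return sorted(set(rejects))


def read_particles(
    path: str | Path,
    config: CampaignConfig | None = None,
    on_invalid: str = "raise",
) -> pd.DataFrame:
    """Read and validate a particle-event CSV.

    Rows are sorted by timestamp (stable sort). A boolean ``saturated``
    column flags particles with any channel at the detector ceiling.

    Parameters
    ----------
    on_invalid
        ``"raise"`` (default) raises :class:`ValidationError` naming the
        first offending row; ``"report"`` drops invalid rows and records
        them in ``df.attrs["rejected"]`` so that
        ``len(accepted) + len(rejected) == input rows``.
    """
    config = config or CampaignConfig()
    df = pd.read_csv(path)
    missing = [c for c in PARTICLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    except (ValueError, TypeError) as exc:
        raise FormatError(f"unparseable timestamp: {exc}") from exc
    for col in PARTICLE_COLUMNS[1:]:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    rejects = _validate_particles(df, config)
    if rejects and on_invalid == "raise":
        row, reason = rejects[0]
        raise ValidationError(f"row {row}: {reason}")
    if rejects:
        df = df.drop(index=[r for r, _ in rejects])

    df = df.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
    df["saturated"] = (
        df[list(FLUOR_CHANNELS)] >= config.saturation_ceiling
    ).any(axis=1)
    df.attrs["flow"] = config.wibs_flow
    df.attrs["rejected"] = rejects
    logger.info("read %d particle records (%d rejected) from %s",
                len(df), len(rejects), path)
    return df


def write_particles(df: pd.DataFrame, path: str | Path) -> None:
    """Write a particle table back to CSV in the canonical column order."""
    out = df.loc[:, list(PARTICLE_COLUMNS)].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).map(
        lambda t: t.isoformat()
    )
    out.to_csv(path, index=False)


def read_forced_trigger(
    path: str | Path, config: CampaignConfig | None = None
) -> pd.DataFrame:
    """Read a forced-trigger (particle-free background) CSV.

    Only the five fluorescence columns are required; size, asymmetry and
    timestamp are meaningless for background firings and optional.
    """
    config = config or CampaignConfig()
    df = pd.read_csv(path)
    missing = [c for c in FLUOR_CHANNELS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    for ch in FLUOR_CHANNELS:
        df[ch] = pd.to_numeric(df[ch], errors="coerce")
        bad = df.index[df[ch].isna() | (df[ch] < 0)]
        if len(bad):
            raise ValidationError(
                f"row {int(bad[0])}: invalid {ch} intensity in forced-trigger file"
            )
    logger.info("read %d forced-trigger records from %s", len(df), path)
    return df


def read_taxon_daily(path: str | Path) -> pd.DataFrame:
    """Read a Hirst-style daily concentration table.

    Returns a frame with columns ``date`` (datetime64, midnight-aligned),
    ``taxon`` (str) and ``concentration`` (float, per m³). At most one
    record per (date, taxon) is allowed.
    """
    df = pd.read_csv(path)
    missing = [c for c in TAXON_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        logger.warning("taxon table %s is empty", path)
        df["date"] = pd.to_datetime(df["date"])
        return df
    try:
        df["date"] = pd.to_datetime(df["date"])
    except (ValueError, TypeError) as exc:
        raise FormatError(f"unparseable date: {exc}") from exc
    df["concentration"] = pd.to_numeric(df["concentration"], errors="coerce")
    bad = df.index[~np.isfinite(df["concentration"]) | (df["concentration"] < 0)]
    if len(bad):
        raise ValidationError(
            f"row {int(bad[0])}: concentration must be finite and >= 0"
        )
    dup = df.duplicated(subset=["date", "taxon"], keep=False)
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise ValidationError(
            f"duplicate record for ({first['date'].date()}, {first['taxon']})"
        )
    return df.sort_values(["date", "taxon"]).reset_index(drop=True)


def write_taxon_daily(df: pd.DataFrame, path: str | Path) -> None:
    out = df.loc[:, list(TAXON_COLUMNS)].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
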