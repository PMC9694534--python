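"""Fluorescence threshold calibration from forced-trigger background data.

With no particle in the beam the detector still records a background
fluorescence in each channel. The classification threshold for a channel is
the background mean plus k standard deviations (k ∈ {3, 6, 9}); raising k
trades sensitivity for robustness against weakly fluorescent interferents.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import InsufficientDataError, ValidationError
from .io import FLUOR_CHANNELS, VALID_SIGMA


@dataclass(frozen=True)
class ThresholdSet:
    """Per-channel background statistics and the derived k·σ thresholds.

    ``mean`` and ``sd`` are the forced-trigger background mean and sample
    standard deviation per channel, in detector intensity units. The
    threshold for channel ``c`` is ``mean[c] + k * sd[c]``.
    """

    mean: Mapping[str, float]
    sd: Mapping[str, float]
    k: int
    session: str | None = None

    def __post_init__(self) -> None:
        if self.k not in VALID_SIGMA:
            raise ValidationError(f"k must be one of {VALID_SIGMA}, got {self.k}")
        for ch in FLUOR_CHANNELS:
            if ch not in self.mean or ch not in self.sd:
                raise ValidationError(f"thresholds missing channel {ch}")
            if self.sd[ch] < 0:
                raise ValidationError(f"negative standard deviation for {ch}")

    def threshold(self, channel: str) -> float:
        return self.mean[channel] + self.k * self.sd[channel]

    @property
    def thresholds(self) -> dict[str, float]:
        return {ch: self.threshold(ch) for ch in FLUOR_CHANNELS}

    def with_multiplier(self, k: int) -> "ThresholdSet":
        """Same background statistics at a different σ multiplier."""
        return replace(self, k=k)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "session": self.session,
            "channels": {
                ch: {
                    "mean": float(self.mean[ch]),
                    "sd": float(self.sd[ch]),
                    "threshold": float(self.threshold(ch)),
                }
                for ch in FLUOR_CHANNELS
            },
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdSet":
        data = yaml.safe_load(Path(path).read_text())
        channels = data["channels"]
        return cls(
            mean={ch: float(channels[ch]["mean"]) for ch in FLUOR_CHANNELS},
            sd={ch: float(channels[ch]["sd"]) for ch in FLUOR_CHANNELS},
            k=int(data["k"]),
            session=data.get("session"),
        )


def compute_thresholds(
    forced_trigger: pd.DataFrame, k: int = 3, session: str | None = None
) -> ThresholdSet:
    """Per-channel mean, sample standard deviation and k·σ threshold.

    Parameters
    ----------
    forced_trigger
        Background records with columns ``fl1``..``fl5``; at least two rows.
    k
        σ multiplier, one of 3, 6 or 9.
    """
    if len(forced_trigger) < 2:
        raise InsufficientDataError(
            "at least 2 forced-trigger records are required"
        )
    if k not in VALID_SIGMA:
        raise ValidationError(f"k must be one of {VALID_SIGMA}, got {k}")
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for ch in FLUOR_CHANNELS:
        values = forced_trigger[ch].to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValidationError(f"NaN intensity in forced-trigger channel {ch}")
        mean[ch] = float(np.mean(values))
        sd[ch] = float(np.std(values, ddof=1))
    return ThresholdSet(mean=mean, sd=sd, k=k, session=session)


def aggregate_daily_thresholds(
    sessions: Sequence[ThresholdSet], policy: str = "mean"
) -> tuple[ThresholdSet, dict[str, float]]:
    """Combine daily forced-trigger sessions into one effective threshold set.

    Policies: ``"mean"`` averages the per-channel background mean and sd
    across sessions; ``"latest"`` returns the last session as given.

    Returns the effective set and, per channel, the relative spread of the
    session thresholds (sample sd / mean of the k·σ threshold values; 0 for
    a single session), the quantity one inspects to confirm the daily
    background showed no large variation.
    """
    sessions = list(sessions)
    if not sessions:
        raise InsufficientDataError("no threshold sessions supplied")
    if policy not in ("mean", "latest"):
        raise ValidationError(f"unknown aggregation policy: {policy}")
    ks = {s.k for s in sessions}
    if len(ks) > 1:
        raise ValidationError("sessions use different sigma multipliers")

    spread: dict[str, float] = {}
    for ch in FLUOR_CHANNELS:
        values = np.array([s.threshold(ch) for s in sessions], dtype=float)
        if len(values) == 1:
            spread[ch] = 0.0
        else:
            center = float(np.mean(values))
            spread[ch] = float(np.std(values, ddof=1) / center) if center else 0.0

    if policy == "latest":
        return sessions[-1], spread
    mean = {
        ch: float(np.mean([s.mean[ch] for s in sessions])) for ch in FLUOR_CHANNELS
    }
    sd = {
        ch: float(np.mean([s.sd[ch] for s in sessions])) for ch in FLUOR_CHANNELS
    }
    combined = ThresholdSet(mean=mean, sd=sd, k=sessions[0].k, session="aggregate")
    return combined, spread
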