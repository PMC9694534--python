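"""Perring and chlorophyll-band classification of single particles.

A particle exceeds a channel when its intensity is strictly greater than
that channel's calibrated threshold. The exceedance pattern in FL1–FL3
determines the Perring class (A, B, C and their combinations, or
NonFluorescent), and the pattern in the chlorophyll-band channels FL4–FL5
independently determines the classes D, E, DE or None. Both taxonomies are
mutually exclusive and exhaustive by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import ThresholdSet
from .errors import ValidationError
from .io import FLUOR_CHANNELS

logger = logging.getLogger(__name__)

#: Perring label for exceedance bits (fl1, fl2, fl3) read as an integer
#: fl1*4 + fl2*2 + fl3.
PERRING_LABELS = np.array(
    ["NonFluorescent", "C", "B", "BC", "A", "AC", "AB", "ABC"]
)

#: Chlorophyll-band label for bits (fl4, fl5) read as fl4*2 + fl5.
CHLORO_LABELS = np.array(["None", "E", "D", "DE"])

PERRING_CLASSES = ("A", "B", "C", "AB", "AC", "BC", "ABC", "NonFluorescent")
CHLORO_CLASSES = ("D", "E", "DE", "None")


@dataclass
class ClassificationSummary:
    """Class composition of a particle collection (the shape of a campaign
    summary table: counts and fractions of total and of fluorescent
    particles, per class)."""

    n_total: int
    n_fluorescent: int
    fluorescence_basis: str
    perring: pd.DataFrame
    chloro: pd.DataFrame

    @property
    def fluorescent_fraction(self) -> float:
        return self.n_fluorescent / self.n_total if self.n_total else float("nan")


def classify_all(
    particles: pd.DataFrame,
    thresholds: ThresholdSet,
    fluorescence_basis: str = "fl12345",
) -> tuple[pd.DataFrame, ClassificationSummary]:
    """Classify every particle and summarise the class composition.

    Returns a copy of ``particles`` with boolean ``exceed_fl1``..
    ``exceed_fl5`` columns, ``perring_class``, ``chloro_class`` and a
    ``fluorescent`` flag; the σ multiplier used is recorded in
    ``df.attrs["sigma"]``.

    ``fluorescence_basis`` selects which channels define "fluorescent":
    any of the five (``"fl12345"``, default) or FL1–FL3 only (``"fl123"``).
    """
    if fluorescence_basis not in ("fl123", "fl12345"):
        raise ValidationError("fluorescence_basis must be 'fl123' or 'fl12345'")
    df = particles.copy()
    if df.empty:
        logger.warning("classify_all called on an empty particle collection")
        for ch in FLUOR_CHANNELS:
            df[f"exceed_{ch}"] = pd.Series(dtype=bool)
        df["perring_class"] = pd.Series(dtype=object)
        df["chloro_class"] = pd.Series(dtype=object)
        df["fluorescent"] = pd.Series(dtype=bool)
        df.attrs["sigma"] = thresholds.k
        return df, _summarise(df, fluorescence_basis)

    exceed = {}
    for ch in FLUOR_CHANNELS:
        exceed[ch] = df[ch].to_numpy(dtype=float) > thresholds.threshold(ch)
        df[f"exceed_{ch}"] = exceed[ch]

    perring_code = (
        exceed["fl1"].astype(int) * 4
        + exceed["fl2"].astype(int) * 2
        + exceed["fl3"].astype(int)
    )
    chloro_code = exceed["fl4"].astype(int) * 2 + exceed["fl5"].astype(int)
    df["perring_class"] = PERRING_LABELS[perring_code]
    df["chloro_class"] = CHLORO_LABELS[chloro_code]

    basis = FLUOR_CHANNELS if fluorescence_basis == "fl12345" else FLUOR_CHANNELS[:3]
    df["fluorescent"] = np.logical_or.reduce([exceed[ch] for ch in basis])
    df.attrs["sigma"] = thresholds.k
    return df, _summarise(df, fluorescence_basis)


def _summarise(df: pd.DataFrame, basis: str) -> ClassificationSummary:
    n = len(df)
    n_fluor = int(df["fluorescent"].sum()) if n else 0

    def table(column: str, classes: tuple[str, ...]) -> pd.DataFrame:
        counts = df[column].value_counts().reindex(classes, fill_value=0)
        out = pd.DataFrame({"count": counts})
        out["frac_total"] = out["count"] / n if n else np.nan
        if n_fluor:
            fluor_counts = (
                df.loc[df["fluorescent"], column]
                .value_counts()
                .reindex(classes, fill_value=0)
            )
            out["frac_fluorescent"] = fluor_counts / n_fluor
        else:
            out["frac_fluorescent"] = np.nan
        return out

    return ClassificationSummary(
        n_total=n,
        n_fluorescent=n_fluor,
        fluorescence_basis=basis,
        perring=table("perring_class", PERRING_CLASSES),
        chloro=table("chloro_class", CHLORO_CLASSES),
    )


def classify(
    particle: dict | pd.Series,
    thresholds: ThresholdSet,
    fluorescence_basis: str = "fl12345",
) -> dict:
    """Classify a single particle record; returns a plain dict."""
    frame = pd.DataFrame([dict(particle)])
    classified, _ = classify_all(frame, thresholds, fluorescence_basis)
    return classified.iloc[0].to_dict()
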